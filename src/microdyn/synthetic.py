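"""Seeded synthetic cohorts emulating a small enclosed-habitat crew study.

The generator produces every artifact the downstream analyses consume —
OTU counts, a rooted tree, a block taxonomy, sample metadata, air source
communities and cytokine series — together with a truth record sufficient
to score recovery, so the whole pipeline is testable without sequencing
data.

The emulated design: a handful of subjects sampled repeatedly across three
experimental phases (outside / inside an enclosed shared habitat / outside
again). Each subject carries a persistent individual baseline community;
while inside, every subject's composition is pulled toward a common
shared-environment community with a configurable mixing weight, which is
what the convergence analyses downstream are meant to detect. Optional
per-taxon linear trends and AR(1) log-abundance autocorrelation exercise
the trend and stationarity tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    CytokineTable,
    OtuTable,
    TaxonomyMap,
    parse_newick,
    write_cytokines,
    write_metadata,
    write_otu_table,
    write_taxonomy,
    write_tree,
)

CYTOKINE_PANEL = ("IL-1b", "IL-6", "IL-10", "TNF-a", "IFN-g")

PHYLUM_NAMES = ("Firmicutes", "Bacteroidetes", "Proteobacteria",
                "Actinobacteria", "Fusobacteria")


class SpecValidationError(ValueError):
    """A CohortSpec field violates its invariant; the message names the field."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate the study design the pipeline targets: 4 subjects
    (two male, two female), 18 time points split 5/8/5 over the
    outside/inside/outside phases, sequencing depth log-normal around a
    mean of ~34k reads, and a shared-environment mixing weight of 0.5
    inside the enclosure.
    """

    n_subjects: int = 4
    n_timepoints_per_phase: tuple[int, int, int] = (5, 8, 5)
    n_otus: int = 200
    depth_mean: float = 33820.0
    depth_cv: float = 0.3
    shared_weight_inside: float = 0.5
    trend_taxa: tuple[tuple[str, float], ...] = ()
    ar1_phi: float = 0.0
    n_air_sources: int = 3
    cytokine_links: tuple[tuple[str, str, int, float], ...] = (
        ("TNF-a", "G01", 1, 0.1),
        ("IL-10", "G03", -1, 0.1),
        ("IL-1b", "G05", 1, 0.1),
    )
    seed: int = 0
    # shape of the community model, not part of the study design knobs
    base_concentration: float = 40.0
    profile_sigma: float = 1.5
    log_noise_sd: float = 0.4

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise SpecValidationError("n_subjects must be >= 1")
        if len(self.n_timepoints_per_phase) != 3 or any(
            t < 0 for t in self.n_timepoints_per_phase
        ):
            raise SpecValidationError(
                "n_timepoints_per_phase must be three nonnegative counts"
            )
        if self.n_otus < 2:
            raise SpecValidationError("n_otus must be >= 2")
        if self.depth_mean <= 0:
            raise SpecValidationError("depth_mean must be > 0")
        if self.depth_cv < 0:
            raise SpecValidationError("depth_cv must be >= 0")
        if not 0.0 <= self.shared_weight_inside <= 1.0:
            raise SpecValidationError("shared_weight_inside must lie in [0, 1]")
        if not abs(self.ar1_phi) < 1:
            raise SpecValidationError("ar1_phi must satisfy |ar1_phi| < 1")
        if self.n_air_sources < 1:
            raise SpecValidationError("n_air_sources must be >= 1")
        if self.log_noise_sd < 0:
            raise SpecValidationError("log_noise_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the truth record that produced it."""

    otu_table: OtuTable
    tree: TreeNode
    taxonomy: TaxonomyMap
    cytokines: CytokineTable
    air_sources: pd.DataFrame  # OTUs x air sample counts
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all artifacts as plain-text files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "otu_table": outdir / "otu_table.tsv",
            "metadata": outdir / "metadata.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "tree": outdir / "tree.nwk",
            "cytokines": outdir / "cytokines.tsv",
            "air_sources": outdir / "air_sources.tsv",
            "truth": outdir / "truth.txt",
        }
        write_otu_table(self.otu_table, paths["otu_table"])
        write_metadata(self.otu_table.metadata, paths["metadata"])
        write_taxonomy(self.taxonomy, paths["taxonomy"])
        write_tree(self.tree, paths["tree"])
        write_cytokines(self.cytokines, paths["cytokines"])
        air = self.air_sources.copy()
        air.index.name = "#OTU ID"
        air.to_csv(paths["air_sources"], sep="\t")
        with open(paths["truth"], "w") as fh:
            for key, val in sorted(_flatten_truth(self.truth).items()):
                fh.write(f"{key}\t{val}\n")
        return paths


def _flatten_truth(truth: dict, prefix: str = "") -> dict[str, str]:
    out: dict[str, str] = {}
    for key, val in truth.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            out.update(_flatten_truth(val, prefix=f"{name}."))
        elif isinstance(val, (list, tuple, np.ndarray)):
            out[name] = ",".join(str(x) for x in np.asarray(val).ravel())
        else:
            out[name] = str(val)
    return out


# ---------------------------------------------------------------------------
# helpers

def _otu_ids(n: int) -> list[str]:
    return [f"OTU_{i + 1:04d}" for i in range(n)]


def _heavy_tailed_profile(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal abundance profile: a few dominant taxa, many rare ones."""
    prof = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return prof / prof.sum()


def _lognormal_depth(mean: float, cv: float, rng: np.random.Generator) -> int:
    if cv == 0:
        return max(1, int(round(mean)))
    s2 = np.log1p(cv**2)
    mu = np.log(mean) - s2 / 2.0
    return max(1, int(round(rng.lognormal(mean=mu, sigma=np.sqrt(s2)))))


def generate_tree(n_otus: int, seed: int) -> TreeNode:
    """Random rooted binary tree over ordered OTU leaves.

    The tree is built by recursively bisecting the ordered leaf list, so
    contiguous blocks of OTU ids form coherent clades (which the block
    taxonomy exploits). Branch lengths are exponential with a small floor,
    hence strictly positive.
    """
    if n_otus < 2:
        raise ValueError("n_otus must be >= 2")
    rng = np.random.default_rng([seed, 7])
    ids = _otu_ids(n_otus)

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return ids[lo]
        mid = (lo + hi) // 2
        left, right = build(lo, mid), build(mid, hi)
        bl, br = 0.05 + rng.exponential(0.5, size=2)
        return f"({left}:{bl:.6f},{right}:{br:.6f})"

    return parse_newick(build(0, n_otus) + ":0.0;")


def make_block_taxonomy(n_otus: int, otus_per_genus: int = 10,
                        genera_per_phylum: int = 4) -> TaxonomyMap:
    """Assign OTUs to synthetic genera/phyla by contiguous blocks of leaves."""
    ids = _otu_ids(n_otus)
    lineages: dict[str, tuple[str, ...]] = {}
    for i, otu in enumerate(ids):
        g = i // otus_per_genus
        p = g // genera_per_phylum
        phylum = PHYLUM_NAMES[p % len(PHYLUM_NAMES)] + (
            "" if p < len(PHYLUM_NAMES) else f"_{p}"
        )
        lineages[otu] = (
            "k__Bacteria",
            f"p__{phylum}",
            f"c__C{p + 1:02d}",
            f"o__O{p + 1:02d}",
            f"f__F{g + 1:02d}",
            f"g__G{g + 1:02d}",
        )
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# main generator

def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``spec.seed``.

    Per subject ``s`` and time point ``t`` the expected composition is
    ``(1 - w_t) * base_s + w_t * shared`` where ``w_t`` equals
    ``shared_weight_inside`` for inside-phase samples and 0 otherwise.
    Linear trends (if any) are added on the composition scale and the
    simplex renormalized; AR(1) log-abundance noise then multinomial count
    sampling follow.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_otus
    ids = _otu_ids(n)
    id_index = {o: i for i, o in enumerate(ids)}
    for otu, _slope in spec.trend_taxa:
        if otu not in id_index:
            raise SpecValidationError(f"trend_taxa: unknown OTU id {otu!r}")

    profile = _heavy_tailed_profile(n, spec.profile_sigma, rng)
    # total Dirichlet concentration ~40: subjects get strongly distinct,
    # person-specific baselines, as saliva communities do
    alpha = spec.base_concentration * profile + 1e-6
    bases = rng.dirichlet(alpha, size=spec.n_subjects)
    shared = rng.dirichlet(alpha)

    n1, n2, n3 = spec.n_timepoints_per_phase
    total_t = n1 + n2 + n3
    phases = [1] * n1 + [2] * n2 + [3] * n3
    subjects = [chr(ord("A") + s) for s in range(spec.n_subjects)]
    genders = ["male" if s % 2 == 0 else "female" for s in range(spec.n_subjects)]

    counts = np.zeros((n, spec.n_subjects * total_t), dtype=np.int64)
    meta_rows = []
    col = 0
    for s_idx, subject in enumerate(subjects):
        sub_rng = np.random.default_rng([spec.seed, 1, s_idx])
        # stationary AR(1) noise on log abundances
        noise = np.zeros((total_t, n))
        if spec.log_noise_sd > 0:
            z = sub_rng.standard_normal((total_t, n))
            noise[0] = spec.log_noise_sd * z[0]
            scale = spec.log_noise_sd * np.sqrt(1.0 - spec.ar1_phi**2)
            for t in range(1, total_t):
                noise[t] = spec.ar1_phi * noise[t - 1] + scale * z[t]
        for t in range(total_t):
            w = spec.shared_weight_inside if phases[t] == 2 else 0.0
            target = (1.0 - w) * bases[s_idx] + w * shared
            for otu, slope in spec.trend_taxa:
                target[id_index[otu]] = max(target[id_index[otu]] + slope * t, 1e-12)
            target = target / target.sum()
            comp = target * np.exp(noise[t])
            comp = comp / comp.sum()
            depth = _lognormal_depth(spec.depth_mean, spec.depth_cv, sub_rng)
            counts[:, col] = sub_rng.multinomial(depth, comp)
            meta_rows.append(
                {
                    "sample_id": f"{subject}T{t + 1:02d}",
                    "subject": subject,
                    "time_point": t + 1,
                    "phase": phases[t],
                    "environment": "inside" if phases[t] == 2 else "outside",
                    "gender": genders[s_idx],
                }
            )
            col += 1

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = OtuTable(
        pd.DataFrame(counts, index=ids, columns=metadata.index), metadata
    )

    tree = generate_tree(n, spec.seed)
    taxonomy = make_block_taxonomy(n)

    # air source communities: a systematically different environment, so
    # they get their own heavy-tailed profile (sharing the taxon universe
    # but not the saliva communities' dominance structure)
    air_rng = np.random.default_rng([spec.seed, 2])
    air_profile = _heavy_tailed_profile(n, spec.profile_sigma, air_rng)
    air_alpha = spec.base_concentration * air_profile + 1e-6
    air_comps = air_rng.dirichlet(air_alpha, size=spec.n_air_sources)
    air_counts = np.stack(
        [
            air_rng.multinomial(
                _lognormal_depth(spec.depth_mean, spec.depth_cv, air_rng), c
            )
            for c in air_comps
        ],
        axis=1,
    )
    air_sources = pd.DataFrame(
        air_counts,
        index=ids,
        columns=[f"Air{k + 1}" for k in range(spec.n_air_sources)],
    )

    truth: dict = {
        "shared_weight_inside": spec.shared_weight_inside,
        "ar1_phi": spec.ar1_phi,
        "seed": spec.seed,
        "trends": {otu: slope for otu, slope in spec.trend_taxa},
        "cytokine_links": {
            f"{cyt}:{genus}": f"{sign:+d}(sd={sd})"
            for cyt, genus, sign, sd in spec.cytokine_links
        },
        "subjects": subjects,
        "phase_sizes": list(spec.n_timepoints_per_phase),
    }

    cohort = SyntheticCohort(table, tree, taxonomy, None, air_sources, truth)
    cohort.cytokines = generate_cytokines(
        cohort, spec.cytokine_links, seed=spec.seed
    )
    return cohort


def generate_cytokines(
    cohort: SyntheticCohort,
    links: Sequence[tuple[str, str, int, float]],
    seed: int,
) -> CytokineTable:
    """Cytokine series monotonically linked to genus abundances.

    A linked cytokine equals ``exp(sign * z + noise)`` where ``z`` is the
    subject-wise standardized log relative abundance of the linked genus
    (signal sd 1 by construction) and the noise is Gaussian with the
    stated sd; exponentiation keeps concentrations positive without
    breaking rank correlations. Unlinked panel cytokines are iid
    log-normal noise.
    """
    from .io import aggregate_to_rank

    rng = np.random.default_rng([seed, 3])
    genus_table = aggregate_to_rank(cohort.otu_table, cohort.taxonomy, "genus")
    genus_frac = genus_table.fractions()
    linked = {cyt: (genus, sign, sd) for cyt, genus, sign, sd in links}
    for cyt, (genus, _sign, _sd) in linked.items():
        if genus not in genus_frac.index:
            raise SpecValidationError(
                f"cytokine_links: unknown genus id {genus!r} for {cyt!r}"
            )

    meta = cohort.otu_table.metadata
    values = pd.DataFrame(
        index=genus_frac.columns, columns=list(CYTOKINE_PANEL), dtype=float
    )
    for cyt in CYTOKINE_PANEL:
        if cyt in linked:
            genus, sign, sd = linked[cyt]
            series = np.log(genus_frac.loc[genus] + 1e-9)
            col = pd.Series(index=values.index, dtype=float)
            for subject in meta["subject"].unique():
                samp = meta.index[meta["subject"] == subject]
                z = series[samp]
                denom = z.std(ddof=0)
                z = (z - z.mean()) / (denom if denom > 0 else 1.0)
                eps = rng.normal(0.0, sd, size=len(samp)) if sd > 0 else 0.0
                col[samp] = np.exp(sign * z.to_numpy() + eps)
            values[cyt] = col
        else:
            values[cyt] = np.exp(rng.standard_normal(len(values.index)))
    return CytokineTable(values)


def generate_air_and_sink(
    mix: Sequence[float],
    unknown_frac: float,
    depth: int,
    seed: int,
    n_taxa: int = 200,
    n_sinks: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate known source communities and sink(s) mixed from them.

    Returns ``(sources, sink, truth)``: sources as an (n_sources, n_taxa)
    count array, the sink count vector (or (n_sinks, n_taxa) array when
    ``n_sinks > 1``) drawn multinomially from
    ``sum_k mix_k * source_k + unknown_frac * novel``, and the truth
    proportions ``(*mix, unknown_frac)``. The novel community is an
    independent draw from the same heavy-tailed family, so its support
    overlaps — but is not identical to — the sources'.
    """
    mix = np.asarray(mix, dtype=float)
    if (mix < 0).any():
        raise ValueError("mix entries must be >= 0")
    if abs(mix.sum() + unknown_frac - 1.0) > 1e-9:
        raise ValueError(
            f"mix + unknown_frac must sum to 1 (got {mix.sum() + unknown_frac})"
        )
    rng = np.random.default_rng([seed, 4])
    profile = _heavy_tailed_profile(n_taxa, 1.5, rng)
    alpha = 20.0 * profile + 1e-6
    source_comps = rng.dirichlet(alpha, size=len(mix))
    # the unknown pool is a systematically different community (its own
    # abundance profile), not another draw around the sources' profile
    novel_profile = _heavy_tailed_profile(n_taxa, 1.5, rng)
    novel = rng.dirichlet(20.0 * novel_profile + 1e-6)
    sink_comp = mix @ source_comps + unknown_frac * novel
    sources = np.stack(
        [rng.multinomial(depth, c) for c in source_comps], axis=0
    )
    sink_comp = sink_comp / sink_comp.sum()
    sinks = rng.multinomial(depth, sink_comp, size=n_sinks)
    sink = sinks[0] if n_sinks == 1 else sinks
    truth = np.append(mix, unknown_frac)
    return sources, sink, truth
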