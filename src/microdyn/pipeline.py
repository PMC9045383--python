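"""End-to-end orchestration of the study replication on synthetic data.

Stages (dependency order): simulate -> refnorm -> trends -> diversity ->
ordination -> sourcetrack -> network. Each stage writes its outputs under
the configured output directory and appends a row to the stage report;
every analysis output embeds the config hash and seed in a leading
comment line, making the demo run bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import network as net
from . import ordination as ordn
from . import refnorm
from . import sourcetrack as st
from . import temporal
from .io import OtuTable, aggregate_to_rank
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "refnorm", "trends", "diversity", "ordination",
    "sourcetrack", "network",
)


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cohort: dict = field(default_factory=dict)    # CohortSpec overrides
    abundant_threshold: float = 0.90
    trend_rank: str = "genus"
    trend_min_abundance: float = 0.01
    trend_window_phases: tuple[int, int] = (1, 2)
    max_lag: int = 5
    normalized_unifrac: bool = True
    use_tree: bool = True
    n_pcs: int = 25
    network_min_abundance: float = 0.01
    network_min_rho: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    def config_hash(self) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns stage results.

    A stage failure aborts all downstream stages with a clear message in
    the stage report. Output row counts are logged at INFO level.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"# microdyn config_hash={config.config_hash()} seed={config.seed}\n"

    report_rows: list[dict] = []
    results: dict = {}
    aborted = False

    def record(stage: str, status: str, detail: str) -> None:
        report_rows.append({"stage": stage, "status": status, "detail": detail})
        logger.info("stage %s: %s (%s)", stage, status, detail)

    for stage in ALL_STAGES:
        if stage not in config.stages:
            record(stage, "skipped", "disabled in config")
            continue
        if aborted:
            record(stage, "aborted", "upstream stage failed")
            continue
        t0 = time.perf_counter()
        try:
            detail = _STAGE_FUNCS[stage](config, outdir, tag, results)
            logger.info("stage %s took %.1fs", stage, time.perf_counter() - t0)
            record(stage, "ok", detail)
        except Exception as exc:
            record(stage, "failed", f"{type(exc).__name__}: {exc}")
            aborted = True

    report = pd.DataFrame(report_rows).set_index("stage")
    _write_tsv(report, outdir / "stage_report.tsv", tag)
    results["report"] = report
    if aborted:
        failed = report[report["status"] == "failed"].index.tolist()
        raise RuntimeError(f"pipeline failed at stage(s): {failed}")
    return results


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: PipelineConfig, outdir: Path, tag: str, results: dict) -> str:
    spec = CohortSpec(seed=config.seed, **config.cohort)
    cohort = generate_cohort(spec)
    cohort.write(outdir / "cohort")
    results["cohort"] = cohort
    table = cohort.otu_table
    return f"{len(table.otu_ids)} OTUs x {len(table.sample_ids)} samples"


def _get_cohort(results: dict) -> SyntheticCohort:
    if "cohort" not in results:
        raise FileNotFoundError(
            "no cohort available; enable the 'simulate' stage (producer of cohort/)"
        )
    return results["cohort"]


def _stage_refnorm(config: PipelineConfig, outdir: Path, tag: str, results: dict) -> str:
    cohort = _get_cohort(results)
    table = cohort.otu_table
    normalized: dict[str, refnorm.NormalizedSeries] = {}
    for subject in sorted(table.metadata["subject"].unique()):
        series = refnorm.normalize_subject(
            table, subject, threshold=config.abundant_threshold
        )
        normalized[subject] = series
        _write_tsv(series.abundances, outdir / f"norm_{subject}.tsv", tag)
        _write_tsv(
            series.scale_factors.to_frame(),
            outdir / f"norm_{subject}.scale_factors.tsv", tag,
        )
    results["normalized"] = normalized
    n_ab = {s: len(v.abundant_otus) for s, v in normalized.items()}
    return f"subjects={list(normalized)}, abundant OTUs={n_ab}"


def _stage_trends(config: PipelineConfig, outdir: Path, tag: str, results: dict) -> str:
    cohort = _get_cohort(results)
    table = cohort.otu_table
    agg = aggregate_to_rank(table, cohort.taxonomy, config.trend_rank)
    frames = []
    for subject in sorted(table.metadata["subject"].unique()):
        meta = table.samples_for(subject)
        window_tp = meta[meta["phase"].isin(config.trend_window_phases)]["time_point"]
        frac = refnorm.fractional_normalize(agg, subject)
        keep = frac.columns[frac.mean(axis=0) > config.trend_min_abundance]
        frac = frac[keep]
        # taxon trends over the contiguous outside-to-inside window
        tr = temporal.trend_table(
            frac, window=(window_tp.min(), window_tp.max())
        )
        tr.insert(0, "subject", subject)
        tr.insert(1, "kind", config.trend_rank)
        # ACF stationarity over the full series
        max_lag = min(config.max_lag, len(frac) - 2)
        tr["stationary"] = [
            temporal.acf(frac[c].to_numpy(), max_lag).stationary_verdict
            if frac[c].nunique() > 1 else True
            for c in frac.columns
        ]
        frames.append(tr)
        # cytokine trends for the same subject/window
        cyto = cohort.cytokines.values.loc[meta.index]
        cyto.index = pd.Index(meta["time_point"], name="time_point")
        ct = temporal.trend_table(cyto, window=(window_tp.min(), window_tp.max()))
        ct.insert(0, "subject", subject)
        ct.insert(1, "kind", "cytokine")
        ct["stationary"] = [
            temporal.acf(cyto[c].to_numpy(), max_lag).stationary_verdict
            if cyto[c].nunique() > 1 else True
            for c in cyto.columns
        ]
        frames.append(ct)
    trends = pd.concat(frames)
    _write_tsv(trends, outdir / "trends.tsv", tag)
    results["trends"] = trends
    n_sig = int((trends["p"] <= 0.05).sum())
    return f"{len(trends)} series tested, {n_sig} with p<=0.05"


def _stage_diversity(config: PipelineConfig, outdir: Path, tag: str, results: dict) -> str:
    cohort = _get_cohort(results)
    table = cohort.otu_table
    alpha = div.alpha_diversity(table, "shannon")
    _write_tsv(alpha.to_frame(), outdir / "alpha_shannon.tsv", tag)
    results["alpha"] = alpha
    if not config.use_tree or cohort.tree is None:
        logger.info("tree disabled; skipping weighted UniFrac convergence analysis")
        return "alpha only (tree disabled)"
    dm = div.unifrac_matrix(table, cohort.tree, normalized=config.normalized_unifrac)
    dm_df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    _write_tsv(dm_df, outdir / "weighted_unifrac.tsv", tag)
    by_phase = div.between_subject_distances(dm, table.metadata, "phase")
    kw, medians = div.convergence_test(dm, table.metadata)
    pooled_medians = {
        k: float(np.median(v)) if v else np.nan for k, v in by_phase.items()
    }
    summary = pd.DataFrame(
        {
            "median_tp_mean_distance": pd.Series(medians),
            "pooled_median_distance": pd.Series(pooled_medians),
            "n_pairs": pd.Series({k: len(v) for k, v in by_phase.items()}),
        }
    )
    summary.index.name = "phase"
    summary["KW_H"] = kw.H
    summary["KW_p"] = kw.p
    _write_tsv(summary, outdir / "convergence_by_phase.tsv", tag)
    results["unifrac"] = dm
    results["convergence"] = {"kw": kw, "medians": medians, "distances": by_phase}
    return f"KW H={kw.H:.3f} p={kw.p:.2e}; phase medians={ {k: round(v, 4) for k, v in medians.items()} }"


def _stage_ordination(config: PipelineConfig, outdir: Path, tag: str, results: dict) -> str:
    cohort = _get_cohort(results)
    table = cohort.otu_table
    frac = table.fractions().T    # samples x OTUs
    n_comp = min(config.n_pcs, len(frac) - 1, frac.shape[1])
    model = ordn.pca(frac, n_components=n_comp)
    _write_tsv(model.scores, outdir / "pca_scores.tsv", tag)
    seps = {}
    rows = []
    for grouping in ("subject", "gender", "phase"):
        labels = table.metadata.loc[model.scores.index, grouping]
        sep = ordn.group_separation(model.scores, labels, n_pcs=config.n_pcs)
        seps[grouping] = sep
        rows.append(
            {"grouping": grouping, "statistic": sep.statistic_name,
             "wilks_lambda": sep.statistic, "F": sep.F, "p": sep.p,
             "n_pcs": sep.n_pcs_used}
        )
        _write_tsv(sep.mahalanobis, outdir / f"mahalanobis_{grouping}.tsv", tag)
    summary = pd.DataFrame(rows).set_index("grouping")
    _write_tsv(summary, outdir / "separation_summary.tsv", tag)
    results["separation"] = seps
    return "; ".join(f"{g}: p={seps[g].p:.2e}" for g in seps)


def _stage_sourcetrack(config: PipelineConfig, outdir: Path, tag: str, results: dict) -> str:
    cohort = _get_cohort(results)
    table = cohort.otu_table
    inside = table.metadata[table.metadata["environment"] == "inside"].index
    combined = pd.concat([table.counts, cohort.air_sources], axis=1).fillna(0).astype(int)
    estimates, mean = st.attribute_cohort(
        combined, list(cohort.air_sources.columns), list(inside)
    )
    out = pd.DataFrame(
        [dict(zip(e.source_names, e.proportions),
              iterations=e.iterations, converged=e.converged)
         for e in estimates],
        index=[e.sink_id for e in estimates],
    )
    out.index.name = "sink"
    _write_tsv(out, outdir / "source_attribution.tsv", tag)
    results["attribution"] = (estimates, mean)
    air_total = float(mean.drop("unknown").sum())
    # Venn overlap between air and inside-phase saliva at genus level
    air_meta = pd.DataFrame(
        {"subject": "air", "time_point": 0, "phase": 2,
         "environment": "inside", "gender": "na"},
        index=cohort.air_sources.columns,
    )
    combined_table = OtuTable(
        combined, pd.concat([table.metadata, air_meta])
    )
    shared = st.shared_taxa(
        combined_table, cohort.taxonomy,
        list(cohort.air_sources.columns), list(inside),
    )
    results["shared_genera"] = shared
    return f"mean air-attributed={air_total:.3f}, shared genera={len(shared)}"


def _stage_network(config: PipelineConfig, outdir: Path, tag: str, results: dict) -> str:
    cohort = _get_cohort(results)
    table = cohort.otu_table
    networks = {}
    for subject in sorted(table.metadata["subject"].unique()):
        cn = net.build_network(
            table, cohort.taxonomy, cohort.cytokines, subject,
            abundance_threshold=config.network_min_abundance,
            rho_threshold=config.network_min_rho,
        )
        networks[subject] = cn
        _write_tsv(cn.edges, outdir / f"network_{subject}.edges.tsv", tag)
        _write_tsv(cn.nodes, outdir / f"network_{subject}.nodes.tsv", tag)
    results["networks"] = networks
    return "; ".join(f"{s}: {len(networks[s].edges)} edges" for s in networks)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "refnorm": _stage_refnorm,
    "trends": _stage_trends,
    "diversity": _stage_diversity,
    "ordination": _stage_ordination,
    "sourcetrack": _stage_sourcetrack,
    "network": _stage_network,
}
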