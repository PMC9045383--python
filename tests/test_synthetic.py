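import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microdyn import (
    CohortSpec,
    generate_air_and_sink,
    generate_cohort,
    generate_tree,
    jsd,
)
from microdyn.synthetic import SpecValidationError


def _mean_between_subject_jsd(cohort, phase):
    from itertools import combinations

    frac = cohort.otu_table.fractions()
    meta = cohort.otu_table.metadata
    vals = []
    for _, rows in meta[meta["phase"] == phase].groupby("time_point"):
        for a, b in combinations(rows.index, 2):
            if rows.loc[a, "subject"] != rows.loc[b, "subject"]:
                vals.append(jsd(frac[a], frac[b]))
    return float(np.mean(vals))


class TestCohortGeneration:
    def test_determinism_same_seed(self):
        spec = CohortSpec(n_otus=50, n_timepoints_per_phase=(2, 3, 2), seed=5)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        pd.testing.assert_frame_equal(a.otu_table.counts, b.otu_table.counts)
        pd.testing.assert_frame_equal(a.cytokines.values, b.cytokines.values)
        assert str(a.tree) == str(b.tree)

    def test_written_artifacts_bitwise_identical(self, tmp_path):
        spec = CohortSpec(
            n_otus=40, n_timepoints_per_phase=(2, 2, 2), seed=3,
            cytokine_links=(("TNF-a", "G01", 1, 0.1), ("IL-10", "G03", -1, 0.1)),
        )
        pa = generate_cohort(spec).write(tmp_path / "a")
        pb = generate_cohort(spec).write(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_every_sample_has_metadata_and_tree_leaves_match(self, small_cohort):
        table = small_cohort.otu_table
        assert set(table.sample_ids) <= set(table.metadata.index)
        leaves = {t.name for t in small_cohort.tree.tips()}
        assert set(table.otu_ids) == leaves

    def test_zero_mixing_gives_independent_subjects(self):
        # degenerate case: no shared component, no AR coupling; between-
        # subject dissimilarity is the same inside and outside
        spec = CohortSpec(shared_weight_inside=0.0, ar1_phi=0.0, seed=2)
        c = generate_cohort(spec)
        inside = _mean_between_subject_jsd(c, 2)
        outside = _mean_between_subject_jsd(c, 1)
        assert abs(inside - outside) < 0.05

    def test_shared_environment_reduces_between_subject_distance(self):
        c = generate_cohort(CohortSpec(shared_weight_inside=0.5, seed=0))
        assert _mean_between_subject_jsd(c, 2) < _mean_between_subject_jsd(c, 1)

    def test_convergence_knob_monotone(self):
        vals = [
            _mean_between_subject_jsd(
                generate_cohort(CohortSpec(shared_weight_inside=w, seed=0)), 2
            )
            for w in (0.0, 0.25, 0.5, 0.75)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_phase_layout(self, small_cohort):
        meta = small_cohort.otu_table.metadata
        sub = meta[meta["subject"] == "A"].sort_values("time_point")
        assert list(sub["phase"]) == [1] * 3 + [2] * 4 + [3] * 3
        assert (sub["environment"] == "inside").sum() == 4

    def test_invalid_spec_names_field(self):
        with pytest.raises(SpecValidationError, match="ar1_phi"):
            generate_cohort(CohortSpec(ar1_phi=1.5))
        with pytest.raises(SpecValidationError, match="shared_weight_inside"):
            generate_cohort(CohortSpec(shared_weight_inside=1.2))
        with pytest.raises(SpecValidationError, match="depth_mean"):
            generate_cohort(CohortSpec(depth_mean=0))

    def test_ar1_induces_lag1_autocorrelation(self):
        # log-abundance noise with phi=0.7 should show up in the realized
        # fractional series of an abundant OTU
        spec = CohortSpec(
            n_timepoints_per_phase=(20, 20, 20), ar1_phi=0.7,
            shared_weight_inside=0.0, seed=4,
        )
        c = generate_cohort(spec)
        frac = c.otu_table.fractions()
        meta = c.otu_table.samples_for("A")
        series = np.log(frac[meta.index].max(axis=0).to_numpy() + 1e-12)
        top = frac[meta.index].mean(axis=1).idxmax()
        x = np.log(frac.loc[top, meta.index].to_numpy())
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 > 0.3


class TestTree:
    def test_two_leaves(self):
        tree = generate_tree(2, seed=0)
        tips = list(tree.tips())
        assert len(tips) == 2
        assert all(t.length > 0 for t in tips)

    def test_binary_tree_arithmetic(self):
        tree = generate_tree(200, seed=0)
        n_tips = tree.count(tips=True)
        n_internal = sum(1 for n in tree.traverse(include_self=True) if not n.is_tip())
        assert n_tips == 200
        assert n_internal == 199

    def test_determinism(self):
        assert str(generate_tree(50, seed=9)) == str(generate_tree(50, seed=9))

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            generate_tree(1, seed=0)


class TestAirAndSink:
    def test_pure_source_sink(self):
        sources, sink, truth = generate_air_and_sink([1.0, 0.0, 0.0], 0.0,
                                                     depth=100000, seed=0)
        s0 = sources[0] / sources[0].sum()
        sk = sink / sink.sum()
        assert np.abs(s0 - sk).sum() < 0.05  # multinomial noise only
        assert truth.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_truth_bookkeeping(self):
        _, _, truth = generate_air_and_sink([0.4, 0.3, 0.1], 0.2, 10000, seed=1)
        assert truth == pytest.approx([0.4, 0.3, 0.1, 0.2])

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_air_and_sink([0.5, 0.2], 0.1, 1000, seed=0)


class TestCytokines:
    def test_noiseless_link_is_perfect_rank_correlation(self):
        spec = CohortSpec(
            cytokine_links=(("TNF-a", "G01", 1, 0.0), ("IL-10", "G03", -1, 0.0)),
            seed=6,
        )
        c = generate_cohort(spec)
        from microdyn.io import aggregate_to_rank

        genus = aggregate_to_rank(c.otu_table, c.taxonomy, "genus").fractions()
        meta = c.otu_table.samples_for("A")
        g = genus.loc["G01", meta.index]
        y = c.cytokines.values.loc[meta.index, "TNF-a"]
        rho = stats.spearmanr(g, y).statistic
        assert rho == pytest.approx(1.0)
        g3 = genus.loc["G03", meta.index]
        y3 = c.cytokines.values.loc[meta.index, "IL-10"]
        assert stats.spearmanr(g3, y3).statistic == pytest.approx(-1.0)

    def test_unknown_genus_rejected(self):
        with pytest.raises(SpecValidationError, match="G99"):
            generate_cohort(CohortSpec(cytokine_links=(("IL-6", "G99", 1, 0.1),)))

    def test_all_values_nonnegative(self, default_cohort):
        assert (default_cohort.cytokines.values.values >= 0).all()

    def test_null_link_rate_at_n18(self):
        # an unlinked cytokine should rarely reach |rho| >= 0.5 at n=18
        rng = np.random.default_rng(0)
        hits = 0
        reps = 500
        for _ in range(reps):
            x, y = rng.standard_normal((2, 18))
            if abs(stats.spearmanr(x, y).statistic) >= 0.5:
                hits += 1
        assert hits / reps < 0.12
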