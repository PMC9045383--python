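import numpy as np
import pandas as pd
import pytest

from microdyn.refnorm import (
    fractional_normalize,
    jsd,
    normalize_subject,
    reference_normalize,
    select_abundant_otus,
    weighted_median,
)


def brute_force_jsd(p, q):
    """Independent oracle: sqrt of JS divergence from the KL definition,
    base-2 logs, 0*log(0) := 0."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = (p + q) / 2

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return np.sqrt(0.5 * kl(p, m) + 0.5 * kl(q, m))


class TestJsd:
    def test_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsd(p, p) == 0.0

    def test_disjoint_support_is_one(self):
        assert jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_example(self):
        # JS divergence of (0.5,0.5) vs (1,0) is 0.31128... in bits
        assert jsd([0.5, 0.5], [1.0, 0.0]) == pytest.approx(
            np.sqrt(0.311278124459), abs=1e-9
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            assert jsd(p, q) == pytest.approx(brute_force_jsd(p, q), abs=1e-9)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(100):
            p, q, r = rng.dirichlet(np.ones(6), size=3)
            dpq, dqr, dpr = jsd(p, q), jsd(q, r), jsd(p, r)
            assert dpq == pytest.approx(jsd(q, p), abs=1e-12)   # symmetry
            assert dpr <= dpq + dqr + 1e-9                      # triangle
            assert 0.0 <= dpq <= 1.0

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            jsd([0.5, 0.4], [0.5, 0.5])
        with pytest.raises(ValueError):
            jsd([0.5, 0.5], [0.5, 0.5, 0.0])


class TestWeightedMedian:
    def test_equal_weights_is_median(self):
        assert weighted_median([1, 2, 3], [1, 1, 1]) == 2

    def test_cumulative_weight_rule(self):
        assert weighted_median([1, 10], [0.9, 0.1]) == 1

    def test_singleton(self):
        assert weighted_median([5], [0.2]) == 5

    def test_order_invariance(self, rng):
        vals = rng.normal(size=9)
        w = rng.uniform(0.1, 1, size=9)
        perm = rng.permutation(9)
        assert weighted_median(vals, w) == weighted_median(vals[perm], w[perm])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_median([1, 2], [0, 0])


class TestFractionalNormalize:
    def test_simple_fractions(self, toy_table):
        frac = fractional_normalize(toy_table, "A")
        assert frac.loc[1].tolist() == pytest.approx([0.5, 0.5, 0.0])

    def test_rows_sum_to_one(self, default_cohort):
        frac = fractional_normalize(default_cohort.otu_table, "B")
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_total_sample_named(self, toy_table):
        bad = toy_table.counts.copy()
        bad["A2"] = 0
        from microdyn.io import FormatError, OtuTable

        with pytest.raises(FormatError, match="A2"):
            OtuTable(bad, toy_table.metadata)


class TestSelectAbundant:
    def test_prefix_rule(self):
        frac = pd.DataFrame(
            {"o1": [0.6, 0.6], "o2": [0.3, 0.3], "o3": [0.1, 0.1]},
            index=[1, 2],
        )
        assert select_abundant_otus(frac, 0.90) == ["o1", "o2"]

    def test_threshold_one_keeps_all_nonzero(self):
        frac = pd.DataFrame(
            {"o1": [0.7, 0.7], "o2": [0.3, 0.3], "o3": [0.0, 0.0]},
            index=[1, 2],
        )
        assert set(select_abundant_otus(frac, 1.0)) == {"o1", "o2"}

    def test_single_otu(self):
        frac = pd.DataFrame({"only": [1.0, 1.0]}, index=[1, 2])
        assert select_abundant_otus(frac) == ["only"]


def _series(rows, otus=None):
    arr = np.asarray(rows, float)
    otus = otus or [f"o{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=otus, index=range(1, len(arr) + 1))


class TestReferenceNormalize:
    def test_constant_series_is_fixed_point(self):
        frac = _series([[0.5, 0.3, 0.2]] * 5)
        res = reference_normalize(frac, ["o0", "o1", "o2"])
        assert np.allclose(res.scale_factors, 1.0)
        pd.testing.assert_frame_equal(res.abundances, frac)

    def test_most_similar_time_point_gets_largest_weight(self):
        # directly check monotonicity of (1-j)^2 via the jsd values
        base = np.array([0.5, 0.3, 0.2])
        near = np.array([0.48, 0.32, 0.2])
        far = np.array([0.2, 0.3, 0.5])
        w_near = (1 - jsd(base, near)) ** 2
        w_far = (1 - jsd(base, far)) ** 2
        assert w_near > w_far

    def test_needs_three_time_points(self):
        frac = _series([[0.6, 0.4], [0.5, 0.5]])
        with pytest.raises(ValueError):
            reference_normalize(frac, ["o0", "o1"])

    def test_otu_relabeling_invariance(self, rng):
        arr = rng.dirichlet(np.ones(6), size=5)
        frac = _series(arr)
        res = reference_normalize(frac, ["o0", "o1", "o2", "o3"])
        perm = ["o3", "o1", "o0", "o2", "o5", "o4"]
        res_p = reference_normalize(frac[perm], ["o3", "o1", "o0", "o2"])
        assert np.allclose(res.scale_factors, res_p.scale_factors)

    def test_non_focal_permutation_invariance(self, rng):
        arr = rng.dirichlet(np.ones(5), size=6)
        frac = _series(arr)
        abundant = ["o0", "o1", "o2"]
        res = reference_normalize(frac, abundant)
        # permute rows 2..6, keep row 1 focal; its scale factor must not move
        order = [1, 5, 3, 2, 6, 4]
        frac_p = frac.loc[order]
        res_p = reference_normalize(frac_p, abundant)
        assert res.scale_factors.loc[1] == pytest.approx(
            res_p.scale_factors.loc[1]
        )

    def test_spike_correction(self, spiked_series):
        """A 10x single-OTU count spike squeezes every other OTU's fraction;
        reference normalization must restore them toward their unspiked values
        better than fractional normalization alone."""
        clean, spiked, spike_t = spiked_series
        abundant = select_abundant_otus(clean)
        res = reference_normalize(spiked, abundant)
        others = [o for o in abundant if o != "o0"]

        log_err_frac = np.abs(
            np.log(spiked.loc[spike_t, others].to_numpy()
                   / clean.loc[spike_t, others].to_numpy())
        ).mean()
        log_err_ref = np.abs(
            np.log(res.abundances.loc[spike_t, others].to_numpy()
                   / clean.loc[spike_t, others].to_numpy())
        ).mean()
        assert log_err_ref < log_err_frac

    def test_spiked_neighbours_near_their_medians(self, spiked_series):
        clean, spiked, spike_t = spiked_series
        abundant = select_abundant_otus(clean)
        res = reference_normalize(spiked, abundant)
        others = [o for o in abundant if o != "o0"][:5]
        for otu in others:
            med = clean[otu].median()
            assert res.abundances.loc[spike_t, otu] == pytest.approx(med, rel=0.25)


@pytest.fixture()
def spiked_series(rng):
    """A stable 12-point composition series plus a copy where the dominant
    OTU's counts are spiked 10x at one time point."""
    n_otus, n_t = 20, 12
    base = np.sort(rng.dirichlet(np.ones(n_otus) * 2))[::-1]
    counts = np.stack(
        [rng.multinomial(20000, base) for _ in range(n_t)]
    ).astype(float)
    clean = counts / counts.sum(axis=1, keepdims=True)
    spike_t = 6
    spiked_counts = counts.copy()
    spiked_counts[spike_t - 1, 0] *= 10
    spiked = spiked_counts / spiked_counts.sum(axis=1, keepdims=True)
    cols = [f"o{i}" for i in range(n_otus)]
    idx = range(1, n_t + 1)
    return (
        pd.DataFrame(clean, columns=cols, index=idx),
        pd.DataFrame(spiked, columns=cols, index=idx),
        spike_t,
    )


class TestNormalizeSubject:
    def test_end_to_end_on_cohort(self, default_cohort):
        res = normalize_subject(default_cohort.otu_table, "A")
        assert res.subject == "A"
        assert len(res.abundant_otus) > 0
        assert (res.scale_factors > 0).all()
        assert res.abundances.shape[0] == 18
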