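import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from xsanno.mapping import CountMatrix
from xsanno.model import AnnotationSet, GeneModel, GenomicInterval, TranscriptModel
from xsanno.stats import (
    VarianceComparison,
    bh_adjust,
    dex_and_intersect,
    dim_filter,
    dispersion_estimates,
    exon_in_out_test,
    log2fc_rpkm,
    nb_test,
    nb_test_matrix,
    size_factors,
    truncation_filter,
    var_f_test,
)

# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def brute_force_size_factors(counts):
    """Median-of-ratios computed the long way, feature by feature."""
    counts = np.asarray(counts, dtype=float)
    usable = [row for row in counts if (row > 0).all()]
    geo = [math.exp(sum(math.log(v) for v in row) / len(row)) for row in usable]
    sf = []
    for j in range(counts.shape[1]):
        ratios = sorted(row[j] / g for row, g in zip(usable, geo))
        n = len(ratios)
        med = ratios[n // 2] if n % 2 else 0.5 * (ratios[n // 2 - 1] + ratios[n // 2])
        sf.append(med)
    return np.array(sf)


class TestSizeFactors:
    def test_identical_samples_unity(self):
        counts = np.array([[10, 10], [55, 55], [3, 3]])
        assert size_factors(counts) == pytest.approx([1.0, 1.0])

    def test_scale_equivariance(self):
        counts = np.array([[10, 20], [50, 100], [7, 14]])
        sf = size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(30, 4)) + 1
        assert size_factors(counts) == pytest.approx(brute_force_size_factors(counts))

    def test_no_all_positive_feature_raises(self):
        with pytest.raises(ValueError):
            size_factors(np.array([[0, 5], [5, 0]]))


# ---------------------------------------------------------------------------
# NB exact test vs exhaustive enumeration
# ---------------------------------------------------------------------------


def enumeration_nb_p(counts_a, counts_b, dispersion):
    """Exhaustive-split oracle, written directly from the test definition."""
    k_a, k_b = int(sum(counts_a)), int(sum(counts_b))
    k_s = k_a + k_b
    n_a, n_b = len(counts_a), len(counts_b)
    q0 = k_s / (n_a + n_b)
    mu_a, mu_b = q0 * n_a, q0 * n_b
    var_a = mu_a + dispersion * q0 * q0 * n_a
    var_b = mu_b + dispersion * q0 * q0 * n_b

    def pmf(x, mu, var):
        var = max(var, mu * (1 + 1e-8) + 1e-8)
        p = mu / var
        n = mu * mu / (var - mu)
        return sps.nbinom.pmf(x, n, p)

    probs = [pmf(a, mu_a, var_a) * pmf(k_s - a, mu_b, var_b) for a in range(k_s + 1)]
    obs = probs[k_a]
    num = sum(p for p in probs if p <= obs * (1 + 1e-8))
    return min(1.0, num / sum(probs))


class TestNbTest:
    def test_identical_groups_p_one(self):
        assert nb_test([100] * 10, [100] * 10, dispersion=0.01) == pytest.approx(1.0)

    def test_symmetry(self):
        p1 = nb_test([5, 6, 7], [10, 12, 14], 0.05)
        p2 = nb_test([10, 12, 14], [5, 6, 7], 0.05)
        assert p1 == pytest.approx(p2, rel=1e-9)

    @pytest.mark.parametrize(
        "a,b,disp",
        [
            ([3, 4], [8, 10], 0.1),
            ([0, 1], [12, 9], 0.05),
            ([5, 5, 5], [5, 5, 5], 0.2),
            ([2, 0, 1], [7, 9, 11], 0.01),
            ([10, 8], [10, 12], 0.5),
        ],
    )
    def test_matches_enumeration_small_totals(self, a, b, disp):
        """Pooled totals <= 50: implementation equals exhaustive enumeration."""
        assert sum(a) + sum(b) <= 50
        assert nb_test(a, b, disp) == pytest.approx(
            enumeration_nb_p(a, b, disp), abs=1e-10
        )

    def test_all_zero_feature(self):
        assert nb_test([0, 0], [0, 0], 0.1) == 1.0

    def test_strong_difference_small_p(self):
        p = nb_test([100] * 5, [10] * 5, 0.01)
        assert p < 1e-6


class TestBhAdjust:
    def test_hand_stepped_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_ties(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_independent_step_up_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_step_up_properties(self, p):
        """Adjusted values dominate raw p, stay in [0,1], preserve order."""
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all() and (adj >= 0.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _count_matrix(rows, samples, lengths):
    return CountMatrix(
        feature_ids=list(rows),
        sample_ids=samples,
        counts=np.array([rows[k] for k in rows]),
        lengths=np.array([lengths[k] for k in rows]),
    )


def _flat_ann():
    return AnnotationSet(
        [
            GeneModel("g1", [TranscriptModel("t1", [GenomicInterval("chr1", 0, 500),
                                                    GenomicInterval("chr1", 600, 1100)])]),
            GeneModel("g2", [TranscriptModel("t2", [GenomicInterval("chr1", 2000, 2800)])]),
        ]
    )


class TestDimFilter:
    def _matrices(self, shift_exon=None, factor=1.0):
        rng = np.random.default_rng(1)
        samples = [f"sp1_L{i}" for i in range(5)] + [f"sp2_L{i}" for i in range(5)]
        ann = _flat_ann()
        exon_rows, lengths = {}, {}
        for key, iv in ann.exon_items():
            base = rng.poisson(200, size=10) + 50
            if key == shift_exon:
                base = base.astype(float)
                base[5:] = base[5:] * factor
            exon_rows[key] = base.astype(int)
            lengths[key] = iv.length
        gene_rows = {
            "g1": exon_rows[("g1", "t1", 0)] + exon_rows[("g1", "t1", 1)],
            "g2": exon_rows[("g2", "t2", 0)],
        }
        glen = {"g1": 1000, "g2": 800}
        return (
            ann,
            _count_matrix(exon_rows, samples, lengths),
            _count_matrix(gene_rows, samples, glen),
            samples[:5],
            samples[5:],
        )

    def test_identical_counts_nothing_removed(self):
        ann, ecm, gcm, s1, s2 = self._matrices()
        out, reports = dim_filter(ann, ecm, gcm, s1, s2, alpha=0.01)
        assert out.counts() == ann.counts()
        assert not reports["exons"]["removed"].any()

    def test_alpha_zero_removes_nothing(self):
        ann, ecm, gcm, s1, s2 = self._matrices(shift_exon=("g2", "t2", 0), factor=0.05)
        out, _ = dim_filter(ann, ecm, gcm, s1, s2, alpha=0.0)
        assert out.counts() == ann.counts()

    def test_planted_mappability_loss_removed(self):
        ann, ecm, gcm, s1, s2 = self._matrices(shift_exon=("g2", "t2", 0), factor=0.05)
        out, reports = dim_filter(ann, ecm, gcm, s1, s2, alpha=0.01)
        assert "g2" not in out.gene_ids()
        assert reports["genes"].set_index("feature").loc["g2", "removed"]

    def test_feature_mismatch_raises(self):
        ann, ecm, gcm, s1, s2 = self._matrices()
        ecm.feature_ids = ecm.feature_ids[:-1] + [("gX", "tX", 0)]
        with pytest.raises(ValueError):
            dim_filter(ann, ecm, gcm, s1, s2)


class TestTruncationFilter:
    def _ann(self, length):
        return AnnotationSet(
            [GeneModel("g", [TranscriptModel("t", [GenomicInterval("chr1", 0, length)])])]
        )

    @pytest.mark.parametrize(
        "orig,current,rule,removed",
        [
            (3000, 900, "and", True),   # below 1/3 and below 1 kb
            (3000, 1500, "and", False), # above 1 kb
            (600, 600, "and", False),   # short but untruncated
            (600, 600, "or", True),     # 'or' purges short genes
            (2400, 900, "and", False),  # above 1/3 of original
        ],
    )
    def test_rule_application(self, orig, current, rule, removed):
        ann = self._ann(current)
        out, report = truncation_filter(ann, {"g": orig}, rule=rule)
        assert ("g" not in out.gene_ids()) == removed
        assert bool(report["removed"].iloc[0]) == removed

    def test_missing_original_length_raises(self):
        with pytest.raises(ValueError):
            truncation_filter(self._ann(100), {})


# ---------------------------------------------------------------------------
# assessment statistics
# ---------------------------------------------------------------------------


class TestLog2Fc:
    def test_values(self):
        assert log2fc_rpkm(3, 1) == pytest.approx(1.0)
        assert log2fc_rpkm(0, 0) == 0.0
        assert log2fc_rpkm(1, 3) == pytest.approx(-1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(50) * 10, rng.random(50) * 10
        assert log2fc_rpkm(a, b) == pytest.approx(-log2fc_rpkm(b, a))


class TestVarFTest:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = var_f_test(x, x)
        assert r.f_statistic == pytest.approx(1.0)
        assert r.p_value == pytest.approx(0.5)

    def test_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 2, 25)
        b = rng.normal(0, 1, 25)
        r = var_f_test(a, b)
        expected = 1 - sps.f.cdf(r.f_statistic, 24, 24)
        assert r.p_value == pytest.approx(expected, abs=1e-12)

    def test_reciprocal_law_equal_df(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 2, 20)
        b = rng.normal(0, 1, 20)
        r_ab = var_f_test(a, b)
        r_ba = var_f_test(b, a)
        assert r_ba.f_statistic == pytest.approx(1 / r_ab.f_statistic)
        assert r_ab.p_value + r_ba.p_value == pytest.approx(1.0)

    def test_zero_reference_variance_raises(self):
        with pytest.raises(ValueError):
            var_f_test([1.0, 2.0], [3.0, 3.0])


def wilcoxon_enumeration_p(d):
    """Exact one-sided (less) signed-rank p by full sign enumeration."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if w <= w_obs:
            count += 1
    return count / total


class TestInOutTest:
    def test_all_in_smaller_minimal_p(self):
        # |in| < |out| for every gene, no ties: one-sided p = 1/2^n
        fc_in = [0.1, 0.15, 0.2, 0.12, 0.18, 0.11, 0.16, 0.14]
        fc_out = [0.5, 0.6, 0.7, 0.55, 0.65, 0.52, 0.62, 0.58]
        r = exon_in_out_test(fc_in, fc_out)
        assert r.p_value == pytest.approx(1 / 2**8)

    def test_swapped_direction_large_p(self):
        fc_in = [0.5, 0.6, 0.7, 0.55, 0.65, 0.52, 0.62, 0.58]
        fc_out = [0.1, 0.15, 0.2, 0.12, 0.18, 0.11, 0.16, 0.14]
        assert exon_in_out_test(fc_in, fc_out).p_value >= 0.5

    def test_matches_full_enumeration_n_le_12(self):
        rng = np.random.default_rng(3)
        for n in (6, 8, 10, 12):
            fc_in = rng.normal(0, 0.5, n)
            fc_out = rng.normal(0, 0.8, n)
            d = np.abs(fc_in) - np.abs(fc_out)
            r = exon_in_out_test(fc_in, fc_out)
            assert r.p_value == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_statistic_equals_hand_ranking(self):
        fc_in = [0.9, 0.1, 0.4, 0.6, 0.2, 0.3, 0.7, 0.05]
        fc_out = [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        d = np.abs(np.array(fc_in)) - 0.5
        ranks = sps.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        r = exon_in_out_test(fc_in, fc_out)
        # scipy reports min(W+, W-) only for two-sided; for 'less' it is W+
        assert r.statistic == pytest.approx(w_plus)

    def test_all_zero_differences_p_one(self):
        x = [0.5] * 8
        r = exon_in_out_test(x, x)
        assert r.p_value == 1.0


class TestDexIntersect:
    def _gene_cm(self, rows, prefix_a="sp1", prefix_b="sp2"):
        samples = [f"{prefix_a}_L{i}" for i in range(5)] + [
            f"{prefix_b}_L{i}" for i in range(5)
        ]
        lengths = {k: 1000 for k in rows}
        return _count_matrix(rows, samples, lengths), samples[:5], samples[5:]

    def test_same_direction_recovered_opposite_excluded(self):
        rng = np.random.default_rng(8)
        base = {f"g{i}": rng.poisson(300, 10) + 100 for i in range(20)}
        up12 = dict(base)
        up13 = {k: v.copy() for k, v in base.items()}
        # g0 up in sp1 vs both; g1 up vs sp2 but down vs sp3
        for d in (up12, up13):
            d["g0"] = d["g0"].copy()
            d["g0"][5:] = (d["g0"][5:] * 0.2).astype(int)
        up12["g1"] = up12["g1"].copy()
        up12["g1"][5:] = (up12["g1"][5:] * 0.2).astype(int)
        up13["g1"] = up13["g1"].copy()
        up13["g1"][:5] = (up13["g1"][:5] * 0.2).astype(int)
        cm12, s1a, s2 = self._gene_cm(up12)
        cm13, s1b, s3 = self._gene_cm(up13, prefix_b="sp3")
        dex = dex_and_intersect(cm12, cm13, s1a, s2, s1b, s3, alpha=0.01)
        ids = {d.gene_id: d.direction for d in dex}
        assert ids.get("g0") == "up_in_sp1"
        assert "g1" not in ids

    def test_empty_universe_raises(self):
        cm, s1, s2 = self._gene_cm({"g1": np.ones(10, dtype=int) * 10})
        cm2, _, _ = self._gene_cm({"g2": np.ones(10, dtype=int) * 10})
        with pytest.raises(ValueError):
            dex_and_intersect(cm, cm2, s1, s2, s1, s2)
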