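"""Stage 3c and assessment statistics.

Implements the differential-count machinery used to find mappability-biased
features under the equal-expression simulation (median-of-ratios
normalisation, per-feature negative-binomial dispersion, a conditioned exact
NB test, Benjamini-Hochberg FDR), the DIM and truncation filters, DEX calling
with same-direction intersection, and the bias-assessment statistics
(log2 fold changes of RPKM, one-sided F test on group variances, paired
Wilcoxon signed-rank test on in- vs out-exon fold changes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mapping import CountMatrix
from .model import AnnotationSet, ExonKey

_DISP_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Normalisation and dispersion
# ---------------------------------------------------------------------------


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (features x samples matrix).

    s_j = median over features (positive in all samples) of
    k_ij / geometric_mean_i(k_i.).
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has positive counts in every sample")
    sub = counts[positive]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    return np.median(sub / geo[:, None], axis=0)


def dispersion_estimates(counts: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Per-feature NB dispersion: max(method-of-moments, pooled trend, floor).

    The method-of-moments estimate comes from normalised counts
    (alpha = (var - mu * mean(1/s)) / mu^2); the trend is the pooled median
    of the positive per-feature estimates, serving as the fitted
    mean-dispersion curve of the cited approach at the flat limit.
    """
    counts = np.asarray(counts, dtype=float)
    z = counts / sf[None, :]
    mu = z.mean(axis=1)
    w = z.var(axis=1, ddof=1)
    xim = np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (w - mu * xim) / np.square(mu), 0.0)
    positive = raw[raw > 0]
    trend = float(np.median(positive)) if positive.size else _DISP_FLOOR
    return np.maximum(np.maximum(raw, trend), _DISP_FLOOR)


# ---------------------------------------------------------------------------
# Conditioned NB exact test
# ---------------------------------------------------------------------------


def _nb_params(mu: float, var: float) -> Tuple[float, float]:
    """scipy (n, p) parameterisation from mean/variance, var > mu enforced."""
    var = max(var, mu * (1 + 1e-8) + 1e-8)
    p = mu / var
    n = mu * mu / (var - mu)
    return n, p


def nb_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    dispersion: float,
    sf_a: Optional[Sequence[float]] = None,
    sf_b: Optional[Sequence[float]] = None,
) -> float:
    """Conditioned NB exact test for one feature.

    Sums K_A, K_B of the two replicate groups are modelled as NB with the
    pooled per-base rate q0 = (K_A + K_B) / (sum of all size factors), means
    mu_g = q0 * S_g and variances mu_g + dispersion * q0^2 * sum_j s_gj^2.
    The p-value is the total probability of all splits (a, b) of the pooled
    sum whose joint probability does not exceed that of the observed split.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    sf_a = np.ones(len(counts_a)) if sf_a is None else np.asarray(sf_a, dtype=float)
    sf_b = np.ones(len(counts_b)) if sf_b is None else np.asarray(sf_b, dtype=float)

    k_a = int(round(counts_a.sum()))
    k_b = int(round(counts_b.sum()))
    k_s = k_a + k_b
    if k_s == 0:
        return 1.0
    s_a, s_b = sf_a.sum(), sf_b.sum()
    q0 = k_s / (s_a + s_b)
    mu_a, mu_b = q0 * s_a, q0 * s_b
    var_a = mu_a + dispersion * q0 * q0 * np.square(sf_a).sum()
    var_b = mu_b + dispersion * q0 * q0 * np.square(sf_b).sum()
    n_a, p_a = _nb_params(mu_a, var_a)
    n_b, p_b = _nb_params(mu_b, var_b)

    a = np.arange(k_s + 1)
    with np.errstate(divide="ignore"):
        logp = sps.nbinom.logpmf(a, n_a, p_a) + sps.nbinom.logpmf(k_s - a, n_b, p_b)
    log_obs = logp[k_a]
    if not np.isfinite(log_obs):
        return 1.0
    num = np.logaddexp.reduce(logp[logp <= log_obs + 1e-8])
    den = np.logaddexp.reduce(logp[np.isfinite(logp)])
    return float(min(1.0, np.exp(num - den)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


@dataclass
class NBTestResult:
    feature_id: object
    base_mean_a: float
    base_mean_b: float
    log2fc: float
    p_value: float
    fdr: float = np.nan

    def flagged(self, alpha: float) -> bool:
        return self.fdr < alpha


def nb_test_matrix(
    cm: CountMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Per-feature NB exact tests between two sample groups of a CountMatrix.

    Size factors are estimated jointly across all samples; dispersions per
    feature via :func:`dispersion_estimates`.  Returns a DataFrame with
    base means (normalised), log2FC of normalised means, p and BH fdr.
    """
    idx_a = [cm.sample_ids.index(s) for s in group_a]
    idx_b = [cm.sample_ids.index(s) for s in group_b]
    counts = cm.counts[:, idx_a + idx_b]
    sf = size_factors(counts)
    sf_a, sf_b = sf[: len(idx_a)], sf[len(idx_a) :]
    ka = cm.counts[:, idx_a]
    kb = cm.counts[:, idx_b]
    disp = dispersion_estimates(counts, sf)

    p_values = np.ones(len(cm.feature_ids))
    for i in range(len(cm.feature_ids)):
        if ka[i].sum() + kb[i].sum() > 0:
            p_values[i] = nb_test(ka[i], kb[i], disp[i], sf_a, sf_b)
    mean_a = (ka / sf_a[None, :]).mean(axis=1)
    mean_b = (kb / sf_b[None, :]).mean(axis=1)
    df = pd.DataFrame(
        {
            "feature": cm.feature_ids,
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2fc": np.log2(mean_a + 1) - np.log2(mean_b + 1),
            "p_value": p_values,
        }
    )
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# DIM and truncation filters
# ---------------------------------------------------------------------------


def dim_filter(
    ann: AnnotationSet,
    exon_counts: CountMatrix,
    gene_counts: CountMatrix,
    samples_sp1: Sequence[str],
    samples_sp2: Sequence[str],
    alpha: float = 0.01,
) -> Tuple[AnnotationSet, Dict[str, pd.DataFrame]]:
    """Remove exons and genes whose equal-expression simulated counts differ
    between species at BH FDR < alpha (difference in mappability).

    Genes with zero counts in every lane of one species are reported in a
    separate ``silent`` category (they cannot be tested), not removed.
    """
    ann_keys = set(ann.exon_map())
    exon_key_set = set(exon_counts.feature_ids)
    if not set(k for k in ann_keys) <= exon_key_set:
        missing = next(iter(ann_keys - exon_key_set))
        raise ValueError(f"exon count matrix lacks annotation exon {missing}")

    exon_df = nb_test_matrix(exon_counts, samples_sp1, samples_sp2)
    gene_df = nb_test_matrix(gene_counts, samples_sp1, samples_sp2)
    exon_df["removed"] = exon_df["fdr"] < alpha
    gene_df["removed"] = gene_df["fdr"] < alpha

    idx1 = [gene_counts.sample_ids.index(s) for s in samples_sp1]
    idx2 = [gene_counts.sample_ids.index(s) for s in samples_sp2]
    silent = (gene_counts.counts[:, idx1].sum(axis=1) == 0) | (
        gene_counts.counts[:, idx2].sum(axis=1) == 0
    )
    gene_df["silent"] = silent

    bad_exons = {
        f for f, r in zip(exon_df["feature"], exon_df["removed"]) if r
    }
    bad_genes = {
        f for f, r in zip(gene_df["feature"], gene_df["removed"]) if r
    }
    keep = lambda key: key not in bad_exons and key[0] not in bad_genes
    filtered = ann.subset_exons(keep)
    return filtered, {"exons": exon_df, "genes": gene_df}


def truncation_filter(
    ann_filtered: AnnotationSet,
    original_lengths: Dict[str, int],
    min_fraction: float = 1.0 / 3.0,
    min_length: int = 1000,
    rule: str = "and",
) -> Tuple[AnnotationSet, pd.DataFrame]:
    """Remove genes truncated too much by the preceding filters.

    Under the default ``and`` rule a gene goes only when its current exonic
    length is below ``min_fraction`` of the original *and* below
    ``min_length`` bases; ``or`` removes on either condition.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    rows = []
    drop: Set[str] = set()
    for g in ann_filtered.genes:
        if g.gene_id not in original_lengths:
            raise ValueError(f"gene {g.gene_id} missing original length")
        cur = g.exonic_length
        orig = original_lengths[g.gene_id]
        short_frac = cur < orig * min_fraction
        short_abs = cur < min_length
        removed = (short_frac and short_abs) if rule == "and" else (short_frac or short_abs)
        rows.append((g.gene_id, orig, cur, short_frac, short_abs, removed))
        if removed:
            drop.add(g.gene_id)
    report = pd.DataFrame(
        rows,
        columns=["gene_id", "original_length", "current_length",
                 "below_fraction", "below_min_length", "removed"],
    )
    kept = ann_filtered.subset_exons(lambda key: key[0] not in drop)
    return kept, report


# ---------------------------------------------------------------------------
# Assessment statistics
# ---------------------------------------------------------------------------


def log2fc_rpkm(rpkm_sp1, rpkm_sp2):
    """Inter-species expression difference: log2(RPKM1 + 1) - log2(RPKM2 + 1)."""
    return np.log2(np.asarray(rpkm_sp1) + 1.0) - np.log2(np.asarray(rpkm_sp2) + 1.0)


@dataclass
class VarianceComparison:
    var_a: float
    var_b: float
    f_statistic: float
    df_a: int
    df_b: int
    p_value: float


def var_f_test(fc_group_a: Sequence[float], fc_group_b: Sequence[float]) -> VarianceComparison:
    """One-sided F test for var(A) > var(B) on log2 fold changes."""
    a = np.asarray(fc_group_a, dtype=float)
    b = np.asarray(fc_group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in reference group")
    f = va / vb
    p = float(sps.f.sf(f, len(a) - 1, len(b) - 1))
    return VarianceComparison(va, vb, f, len(a) - 1, len(b) - 1, p)


@dataclass
class InOutResult:
    n_genes: int
    statistic: float
    p_value: float
    in_out: np.ndarray  # per-gene |exonFC_in| - |exonFC_out|


def exon_in_out_test(
    exonfc_in: Sequence[float], exonfc_out: Sequence[float]
) -> InOutResult:
    """Paired Wilcoxon signed-rank test of |exonFC_in| < |exonFC_out|.

    Inputs are per-gene mean log2FCs of retained (in) and removed (out)
    exons; only genes with both classes should be supplied.  Exact null for
    n <= 25 without ties, normal approximation with continuity correction
    otherwise.
    """
    x = np.abs(np.asarray(exonfc_in, dtype=float))
    y = np.abs(np.asarray(exonfc_out, dtype=float))
    if len(x) != len(y) or len(x) < 6:
        raise ValueError("need >= 6 paired genes")
    d = x - y
    if np.all(d == 0):
        return InOutResult(len(x), 0.0, 1.0, d)
    nz = d[d != 0]
    exact_ok = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)
    res = sps.wilcoxon(
        x, y, alternative="less",
        method="exact" if exact_ok else "approx",
        correction=not exact_ok,
    )
    return InOutResult(len(x), float(res.statistic), float(res.pvalue), d)


# ---------------------------------------------------------------------------
# DEX
# ---------------------------------------------------------------------------


@dataclass
class DexGene:
    gene_id: str
    direction: str  # up_in_sp1 | down_in_sp1
    fdr: float


def dex_and_intersect(
    counts_sp1_vs_sp2: CountMatrix,
    counts_sp1_vs_sp3: CountMatrix,
    samples_sp1_a: Sequence[str],
    samples_sp2: Sequence[str],
    samples_sp1_b: Sequence[str],
    samples_sp3: Sequence[str],
    alpha: float = 0.01,
) -> List[DexGene]:
    """DEX genes of Sp1 supported by both pairwise comparisons.

    A gene is reported when it is differential at BH FDR < alpha in the
    Sp1-vs-Sp2 and the Sp1-vs-Sp3 comparison and its Sp1-relative direction
    of change agrees.
    """
    universe = set(counts_sp1_vs_sp2.feature_ids) & set(counts_sp1_vs_sp3.feature_ids)
    if not universe:
        raise ValueError("empty shared gene universe")
    df12 = nb_test_matrix(counts_sp1_vs_sp2, samples_sp1_a, samples_sp2)
    df13 = nb_test_matrix(counts_sp1_vs_sp3, samples_sp1_b, samples_sp3)
    d12 = {r.feature: r for r in df12.itertuples()}
    d13 = {r.feature: r for r in df13.itertuples()}
    out: List[DexGene] = []
    for gid in sorted(universe, key=str):
        r12, r13 = d12[gid], d13[gid]
        if r12.fdr < alpha and r13.fdr < alpha and r12.log2fc * r13.log2fc > 0:
            out.append(
                DexGene(
                    gid,
                    "up_in_sp1" if r12.log2fc > 0 else "down_in_sp1",
                    max(r12.fdr, r13.fdr),
                )
            )
    return out
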