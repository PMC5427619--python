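"""Gene-level ranking metrics for two-phenotype expression data.

Sixteen metrics are provided through one dispatcher, :func:`rank_genes`.
They span three families:

* parametric statistics on group means and variances — Welch t, moderated
  Welch t (``MWT``) and its absolute value, minimum significant difference
  (``MSD``), signal-to-noise ratio and its absolute value, weighted average
  difference and its absolute value, plain mean difference, ratio of means
  and its log2;
* rank statistics — the group-1 rank sum (``SoR``) and the
  Baumgartner-Weiss-Schindler statistic (``BWS``), plus the truncated-mean
  fold-change statistic ``FCROS``;
* the ReliefF nearest-neighbour feature weight and its tied-rank form.

All metrics return a :class:`~gsearank.dataset.RankVector`; larger values
mean stronger evidence that a gene separates the phenotypes (for signed
metrics, stronger up-regulation in group 1).

Constant genes would produce zero denominators in several statistics.  Rather
than dropping them (which would change the gene-list length between metrics)
a small variance floor ``1e-8 * sd(all values)`` replaces a zero denominator.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from scipy.special import digamma, polygamma

from .dataset import ExpressionDataset, GroupSummary, RankVector, group_summaries

log = logging.getLogger(__name__)

__all__ = [
    "METRIC_NAMES",
    "rank_genes",
    "metric_ttest",
    "metric_mwt",
    "metric_msd",
    "metric_s2n",
    "metric_wad",
    "metric_mean_based",
    "metric_fcros",
    "metric_sor",
    "metric_bws",
    "metric_relieff",
    "fit_mwt_params",
    "MwtParams",
]


def _variance_floor(dataset_or_values) -> float:
    values = (
        dataset_or_values.values
        if isinstance(dataset_or_values, ExpressionDataset)
        else np.asarray(dataset_or_values)
    )
    g = float(np.std(values))
    return 1e-8 * g if g > 0 else 1e-8


def _floored(denom: np.ndarray, floor: float) -> np.ndarray:
    denom = np.asarray(denom, dtype=float)
    out = denom.copy()
    zero = ~(out > 0)
    if zero.any():
        log.debug("degenerate variance for %d genes; applying floor %g", zero.sum(), floor)
        out[zero] = floor
    return out


def _require_sds(summ: GroupSummary, metric: str) -> None:
    if summ.n1 < 2 or summ.n2 < 2:
        raise ValueError(
            f"{metric} needs at least 2 samples per group to estimate a "
            f"standard deviation (got n1={summ.n1}, n2={summ.n2})"
        )


# ----------------------------------------------------------------------
# parametric family
# ----------------------------------------------------------------------

def metric_ttest(summ: GroupSummary, floor: float | None = None) -> np.ndarray:
    """Welch t statistic (x̄1 − x̄2) / sqrt(s1²/n1 + s2²/n2)."""
    _require_sds(summ, "T-test")
    if floor is None:
        floor = 1e-8
    se = np.sqrt(summ.sd1**2 / summ.n1 + summ.sd2**2 / summ.n2)
    return summ.diff / _floored(se, floor)


class MwtParams:
    """Hyperparameters of the moderated Welch t statistic.

    The per-gene unpooled squared standard error ``sw²`` is shrunk towards a
    prior ``s0²`` with prior weight ``d0`` (degrees of freedom):

        se_m² = (d0·s0² + dw·sw²) / (d0 + dw)

    where ``dw`` is the per-gene Welch-Satterthwaite df.  ``d0`` and ``s0²``
    are estimated across all genes by the method of moments on log variances
    (empirical-Bayes, same family of estimator as moderated-t pipelines).
    """

    def __init__(self, s0_sq: float, d0: float, dw: np.ndarray, sw_sq: np.ndarray):
        self.s0_sq = float(s0_sq)
        self.d0 = float(d0)
        self.dw = np.asarray(dw, dtype=float)
        self.sw_sq = np.asarray(sw_sq, dtype=float)

    @property
    def se_m(self) -> np.ndarray:
        if np.isinf(self.d0):
            se_sq = np.full_like(self.sw_sq, self.s0_sq)
        else:
            se_sq = (self.d0 * self.s0_sq + self.dw * self.sw_sq) / (self.d0 + self.dw)
        return np.sqrt(se_sq)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def fit_mwt_params(summ: GroupSummary, floor: float | None = None) -> MwtParams:
    """Estimate (s0², d0) across genes and the per-gene (sw², dw)."""
    _require_sds(summ, "MWT")
    if floor is None:
        floor = 1e-8
    v1 = summ.sd1**2 / summ.n1
    v2 = summ.sd2**2 / summ.n2
    sw_sq = _floored(v1 + v2, floor**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dw = (v1 + v2) ** 2 / (v1**2 / (summ.n1 - 1) + v2**2 / (summ.n2 - 1))
    # constant genes have 0/0 df; give them the maximal (pooled) df
    dw = np.where(np.isfinite(dw), dw, summ.n1 + summ.n2 - 2)
    dw = np.clip(dw, 1.0, None)
    ok = sw_sq > floor**2
    if ok.sum() < 10:
        raise ValueError(
            f"MWT hyperparameter estimation needs >=10 genes with positive "
            f"variance, got {int(ok.sum())}"
        )
    z = np.log(sw_sq[ok])
    e = z - digamma(dw[ok] / 2.0) + np.log(dw[ok] / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(polygamma(1, dw[ok] / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:  # no excess dispersion: variances look identical across genes
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return MwtParams(s0_sq=s0_sq, d0=d0, dw=dw, sw_sq=sw_sq)


def metric_mwt(
    summ: GroupSummary,
    params: MwtParams | None = None,
    absolute: bool = False,
) -> np.ndarray:
    """Moderated Welch t statistic (x̄1 − x̄2)/se_m; optionally |MWT|."""
    if params is None:
        params = fit_mwt_params(summ)
    t = summ.diff / params.se_m
    return np.abs(t) if absolute else t


def metric_msd(
    summ: GroupSummary,
    conf: float = 0.95,
    df_mode: str = "pooled",
    floor: float | None = None,
) -> np.ndarray:
    """Minimum significant difference: signed distance of the logFC CI from 0.

    The two-sided ``conf`` t-interval of the mean difference is computed on
    the log scale; the metric is the interval bound nearer zero, signed so
    that a negative value means the interval contains zero (non-significant
    fold change).  ``df_mode`` selects pooled-variance df (default,
    n1+n2−2) or per-gene Welch-Satterthwaite df.
    """
    _require_sds(summ, "MSD")
    if floor is None:
        floor = 1e-8
    n1, n2 = summ.n1, summ.n2
    if df_mode == "pooled":
        sp_sq = ((n1 - 1) * summ.sd1**2 + (n2 - 1) * summ.sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp_sq * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, n1 + n2 - 2.0)
    elif df_mode == "welch":
        v1, v2 = summ.sd1**2 / n1, summ.sd2**2 / n2
        se = np.sqrt(v1 + v2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, n1 + n2 - 2.0)
    else:
        raise ValueError(f"df_mode must be 'pooled' or 'welch', got {df_mode!r}")
    se = _floored(se, floor)
    half = stats.t.ppf(0.5 + conf / 2.0, df) * se
    logfc = summ.diff
    ci_left = logfc - half
    ci_right = logfc + half
    return np.where(logfc > 0, ci_left, -ci_right)


def metric_s2n(
    summ: GroupSummary, absolute: bool = False, floor: float | None = None
) -> np.ndarray:
    """Signal-to-noise ratio (x̄1 − x̄2)/(s1 + s2); optionally |S2N|."""
    _require_sds(summ, "S2N")
    if floor is None:
        floor = 1e-8
    s2n = summ.diff / _floored(summ.sd1 + summ.sd2, floor)
    return np.abs(s2n) if absolute else s2n


def metric_wad(summ: GroupSummary, absolute: bool = False) -> np.ndarray:
    """Weighted average difference AD·w, w = (x̄ − min)/(max − min).

    ``x̄`` is the per-gene average of the two group means; min/max are taken
    across genes, so highly expressed genes carry weight near 1.
    """
    if len(summ.mean1) < 2:
        raise ValueError("WAD needs at least 2 genes to normalise average expression")
    avg = (summ.mean1 + summ.mean2) / 2.0
    lo, hi = avg.min(), avg.max()
    if hi == lo:
        raise ValueError("WAD weight undefined: all genes share the same average expression")
    w = (avg - lo) / (hi - lo)
    wad = summ.diff * w
    return np.abs(wad) if absolute else wad


def metric_mean_based(summ: GroupSummary, variant: str = "Difference") -> np.ndarray:
    """Difference (x̄1−x̄2), Ratio (x̄1/x̄2) or log2(Ratio) of the group means.

    Ratios are undefined when x̄2 = 0 (and log2 additionally when the ratio
    is not positive); such genes are assigned 0, which leaves them mid-list.
    """
    if variant == "Difference":
        return summ.diff
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = summ.mean1 / summ.mean2
    bad = (summ.mean2 == 0) | ~np.isfinite(ratio)
    if variant == "Ratio":
        if bad.any():
            log.warning("Ratio undefined for %d genes (zero group-2 mean); set to 0", bad.sum())
        return np.where(bad, 0.0, ratio)
    if variant == "log2Ratio":
        bad = bad | (ratio <= 0)
        if bad.any():
            log.warning("log2(Ratio) undefined for %d genes; set to 0", bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.log2(ratio)
        return np.where(bad, 0.0, lr)
    raise ValueError(f"unknown mean-based variant {variant!r}")


# ----------------------------------------------------------------------
# rank / fold-change family
# ----------------------------------------------------------------------

def metric_fcros(
    dataset: ExpressionDataset, trim: float = 0.10, variant: str = "trimmed_mean"
) -> np.ndarray:
    """Fold-change statistic over all n1·n2 pairwise sample comparisons.

    For each gene the k = n1·n2 pairwise log fold changes (differences on
    the log scale, group-1 sample minus group-2 sample) are formed.  The
    default returns their symmetric ``trim``-truncated mean (``trim`` is the
    total fraction removed, half from each tail).  ``variant='rank'``
    selects the rank-averaging form of the original fold-change
    rank-ordering statistic: genes are ranked by fold change within each
    pairwise comparison and the ranks averaged, rescaled to (0, 1).
    """
    x1, x2 = dataset.group_values()
    # genes x (n1*n2) matrix of pairwise log fold changes
    fc = (x1[:, :, None] - x2[:, None, :]).reshape(dataset.n_genes, -1)
    k = fc.shape[1]
    if variant == "rank":
        ranks = np.apply_along_axis(stats.rankdata, 0, fc)
        return ranks.mean(axis=1) / (dataset.n_genes + 1)
    if variant != "trimmed_mean":
        raise ValueError(f"unknown FCROS variant {variant!r}")
    if k < 3:
        warnings.warn(
            f"only {k} pairwise comparison(s); FCROS truncation skipped, plain mean used",
            stacklevel=2,
        )
        return fc.mean(axis=1)
    return stats.trim_mean(fc, proportiontocut=trim / 2.0, axis=1)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks along the sample axis of a genes x samples matrix."""
    return np.apply_along_axis(stats.rankdata, 1, values)


def metric_sor(dataset: ExpressionDataset) -> np.ndarray:
    """Sum of combined-sample midranks over the group-1 samples, per gene."""
    ranks = _midranks(dataset.values)
    return ranks[:, dataset.group1_mask].sum(axis=1)


def metric_bws(dataset: ExpressionDataset) -> np.ndarray:
    """Baumgartner-Weiss-Schindler two-sample statistic, per gene.

    B = (B1 + B2)/2 with B_g built from the sorted combined-sample ranks of
    group g, squared deviations from their null expectation and weighted by
    the null variance term.  Ranks are midranks, so heavy ties are handled
    (and noted in the log).  The statistic is nonnegative and invariant
    under strictly monotone transforms of the expression values.
    """
    if min(dataset.n1, dataset.n2) < 2:
        raise ValueError("BWS needs at least 2 samples per group")
    ranks = _midranks(dataset.values)
    if (ranks % 1 != 0).any():
        log.info("ties present in expression values; midranks used for BWS")
    n1, n2 = dataset.n1, dataset.n2
    r1 = np.sort(ranks[:, dataset.group1_mask], axis=1)
    r2 = np.sort(ranks[:, dataset.group2_mask], axis=1)
    j = np.arange(1, n1 + 1, dtype=float)
    i = np.arange(1, n2 + 1, dtype=float)
    denom1 = (j / (n1 + 1)) * (1 - j / (n1 + 1)) * (n2 * (n1 + n2) / n1)
    denom2 = (i / (n2 + 1)) * (1 - i / (n2 + 1)) * (n1 * (n1 + n2) / n2)
    b1 = ((r1 - (n1 + n2) / n1 * j) ** 2 / denom1).mean(axis=1)
    b2 = ((r2 - (n1 + n2) / n2 * i) ** 2 / denom2).mean(axis=1)
    return (b1 + b2) / 2.0


# ----------------------------------------------------------------------
# ReliefF
# ----------------------------------------------------------------------

def metric_relieff(
    dataset: ExpressionDataset, k: int | None = None, ranked: bool = False
) -> np.ndarray:
    """ReliefF feature weight per gene, in [−1, 1].

    Every sample is visited once (a deterministic full pass, t = n): for each
    instance the K nearest same-class neighbours (hits) and K nearest
    other-class neighbours (misses) are found under a Manhattan distance on
    range-normalised features, and each gene's weight is decreased by its
    normalised distance contribution to the hits and increased by its
    contribution to the misses, the latter weighted by the miss-class prior
    P(c)/(1 − P(class(x))).  With two classes that prior weight is 1.

    ``k=None`` uses 10 capped at (smallest group size − 1); an explicit
    ``k`` at or above the smallest group size is an error.  ``ranked=True``
    replaces the weights by their ascending tied ranks.
    """
    n = dataset.n_samples
    min_group = min(dataset.n1, dataset.n2)
    if k is None:
        k = min(10, min_group - 1)
    if k < 1 or k >= min_group:
        raise ValueError(
            f"ReliefF neighbour count k={k} must satisfy 1 <= k < smallest "
            f"group size ({min_group}); try k={max(1, min_group - 1)}"
        )
    rng_span = dataset.values.max(axis=1) - dataset.values.min(axis=1)
    scale = np.where(rng_span > 0, rng_span, np.inf)  # constant genes contribute 0
    xn = (dataset.values - dataset.values.min(axis=1, keepdims=True)) / scale[:, None]
    dist = cdist(xn.T, xn.T, metric="cityblock")
    np.fill_diagonal(dist, np.inf)
    g1 = dataset.group1_mask
    idx = np.arange(n)
    weights = np.zeros(dataset.n_genes)
    t = n
    for a in range(n):
        same = idx[(g1 == g1[a]) & (idx != a)]
        other = idx[g1 != g1[a]]
        hits = same[np.argsort(dist[a, same], kind="stable")[:k]]
        misses = other[np.argsort(dist[a, other], kind="stable")[:k]]
        d_hit = np.abs(xn[:, [a]] - xn[:, hits]).sum(axis=1)
        d_miss = np.abs(xn[:, [a]] - xn[:, misses]).sum(axis=1)
        weights += (d_miss - d_hit) / (t * k)
    if ranked:
        # weights are sums/differences of normalised distances and can cancel
        # to float-noise level; snap to 12 decimals so such ties rank as ties
        return stats.rankdata(np.round(weights, 12))
    return weights


# ----------------------------------------------------------------------
# dispatcher
# ----------------------------------------------------------------------

METRIC_NAMES = (
    "T-test",
    "MWT",
    "|MWT|",
    "MSD",
    "S2N",
    "|S2N|",
    "WAD",
    "|WAD|",
    "Difference",
    "Ratio",
    "log2(Ratio)",
    "FCROS",
    "SoR",
    "BWS",
    "ReliefF",
    "ReliefF_ranked",
)


def rank_genes(dataset: ExpressionDataset, metric_name, **options) -> RankVector:
    """Compute a named ranking metric (or a user callable) for every gene.

    ``metric_name`` is one of :data:`METRIC_NAMES` or a callable taking
    ``(values_matrix, labels)`` and returning one value per gene.  Extra
    keyword options are forwarded to the metric (e.g. ``trim`` for FCROS,
    ``k`` for ReliefF, ``conf``/``df_mode`` for MSD, ``params`` for MWT).
    """
    if callable(metric_name):
        values = np.asarray(metric_name(dataset.values, dataset.labels), dtype=float)
        if values.shape != (dataset.n_genes,):
            raise ValueError(
                f"user metric returned shape {values.shape}, expected ({dataset.n_genes},)"
            )
        name = getattr(metric_name, "__name__", "user_metric")
        return RankVector(name, dataset.gene_ids, values)
    if metric_name not in METRIC_NAMES:
        raise ValueError(
            f"unknown ranking metric {metric_name!r}; valid names: {', '.join(METRIC_NAMES)}"
        )
    floor = _variance_floor(dataset)
    summ = group_summaries(dataset)
    if metric_name == "T-test":
        values = metric_ttest(summ, floor=floor)
    elif metric_name in ("MWT", "|MWT|"):
        params = options.pop("params", None) or fit_mwt_params(summ, floor=floor)
        values = metric_mwt(summ, params, absolute=metric_name == "|MWT|")
    elif metric_name == "MSD":
        values = metric_msd(summ, floor=floor, **options)
    elif metric_name in ("S2N", "|S2N|"):
        values = metric_s2n(summ, absolute=metric_name == "|S2N|", floor=floor)
    elif metric_name in ("WAD", "|WAD|"):
        values = metric_wad(summ, absolute=metric_name == "|WAD|")
    elif metric_name == "Difference":
        values = metric_mean_based(summ, "Difference")
    elif metric_name == "Ratio":
        values = metric_mean_based(summ, "Ratio")
    elif metric_name == "log2(Ratio)":
        values = metric_mean_based(summ, "log2Ratio")
    elif metric_name == "FCROS":
        values = metric_fcros(dataset, **options)
    elif metric_name == "SoR":
        values = metric_sor(dataset)
    elif metric_name == "BWS":
        values = metric_bws(dataset)
    elif metric_name == "ReliefF":
        values = metric_relieff(dataset, **options)
    elif metric_name == "ReliefF_ranked":
        values = metric_relieff(dataset, ranked=True, **options)
    return RankVector(str(metric_name), dataset.gene_ids, values)
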