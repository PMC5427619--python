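"""Statistical benchmarking of ranking metrics.

A ranking metric is judged on two axes, plus compute cost:

* **surrogate sensitivity** — the nominal GSEA p-value it assigns to a
  dataset's designated target pathway (the known positive); across many
  datasets the proportion of truly alternative targets is summarised as
  1 − π̂0 with Storey's estimator of the null proportion;
* **false positive rate** — on label-permuted (null) collections the
  fraction of gene sets significant at the 5% level should be 5%; the
  overall score is the absolute deviation of the mean FPR from that level.

The scores of all metrics are min-max normalised and grouped by k-means
(Euclidean distance), with the number of clusters picked by the Dunn
index.  A robustness experiment repeats the sensitivity/FPR assessment on
stratified subsamples of decreasing size.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from statsmodels.stats.diagnostic import lilliefors

from .dataset import ExpressionDataset
from .gsea import PermutationPlan, run_gsea
from .metrics import rank_genes

log = logging.getLogger(__name__)

__all__ = [
    "storey_pi0",
    "permutation_pvalues",
    "surrogate_sensitivity",
    "FprEstimate",
    "fpr_experiment",
    "MetricScorecard",
    "overall_scores",
    "time_metric",
    "ClusterAssignment",
    "cluster_metrics",
    "RobustnessCurve",
    "robustness_experiment",
    "normality_fraction",
]


# ----------------------------------------------------------------------
# Storey's null-proportion estimator
# ----------------------------------------------------------------------

def storey_pi0(pvalues, lam: float = 0.5, method: str = "fixed") -> float:
    """Estimate the proportion of truly null hypotheses, π̂0.

    ``method='fixed'`` is the single-λ counting estimator
    π̂0 = #{p > λ} / ((1 − λ)·m), clipped to [0, 1] — conservative
    (biased upward) under any alternative.  ``method='smoother'`` evaluates
    the estimator over λ ∈ {0.05, …, 0.95}, fits a cubic and extrapolates
    to λ → 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("storey_pi0 needs at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "fixed":
        if not 0 <= lam < 1:
            raise ValueError("lambda must be in [0, 1)")
        return float(np.clip(np.mean(p > lam) / (1.0 - lam), 0.0, 1.0))
    if method == "smoother":
        grid = np.arange(0.05, 0.96, 0.05)
        pi0_grid = np.array([np.mean(p > g) / (1.0 - g) for g in grid])
        coef = np.polyfit(grid, pi0_grid, deg=3)
        return float(np.clip(np.polyval(coef, 1.0), 0.0, 1.0))
    raise ValueError(f"unknown pi0 method {method!r}")


# ----------------------------------------------------------------------
# per-gene permutation p-values (metric-level calibration checks)
# ----------------------------------------------------------------------

def permutation_pvalues(
    dataset: ExpressionDataset,
    metric_name,
    n_perm: int = 200,
    seed: int | None = None,
    **metric_options,
) -> np.ndarray:
    """Upper-tail label-permutation p-value of the metric for every gene.

    p = (1 + #{permuted value >= observed}) / (1 + n_perm), with the same
    label permutation shared across genes.  Under exchangeable data this is
    a valid (slightly conservative under ties) p-value for any statistic.
    """
    rng = np.random.default_rng(seed)
    obs = rank_genes(dataset, metric_name, **dict(metric_options)).values
    count = np.zeros(dataset.n_genes)
    for _ in range(n_perm):
        perm = rank_genes(
            dataset.with_labels(rng.permutation(dataset.labels)),
            metric_name,
            **dict(metric_options),
        ).values
        count += perm >= obs
    return (1.0 + count) / (1.0 + n_perm)


# ----------------------------------------------------------------------
# sensitivity and FPR
# ----------------------------------------------------------------------

def surrogate_sensitivity(results, target_set_id: str) -> float:
    """Nominal p-value of the designated target set (smaller is better)."""
    for r in results:
        if r.set_id == target_set_id:
            return r.p
    raise ValueError(
        f"target set {target_set_id!r} not among the {len(results)} scored sets; "
        "it may have been removed by the gene set size filter"
    )


@dataclass
class FprEstimate:
    """Per-replicate false positive rates at significance level alpha."""

    fprs: np.ndarray
    alpha: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.fprs))


def fpr_experiment(
    dataset: ExpressionDataset,
    genesets,
    metric_name,
    n_collections: int = 50,
    alpha: float = 0.05,
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: int | None = None,
    min_size: int = 15,
    max_size: int = 500,
    workers: int = 1,
    **metric_options,
) -> FprEstimate:
    """False positive rate on label-permuted collections.

    Each collection is the dataset with its phenotype labels randomly
    permuted (group sizes preserved), on which a full GSEA run (with its own
    nested permutation null) is performed; the collection's FPR is the
    fraction of gene sets with nominal p < alpha.
    """
    if n_collections < 1:
        raise ValueError("n_collections must be >= 1")
    ss = np.random.SeedSequence(seed)
    label_seeds, plan_seeds = ss.spawn(2)
    label_rngs = [np.random.default_rng(s) for s in label_seeds.spawn(n_collections)]
    plan_children = plan_seeds.spawn(n_collections)
    fprs = np.empty(n_collections)
    for c in range(n_collections):
        null_ds = dataset.with_labels(label_rngs[c].permutation(dataset.labels))
        plan = PermutationPlan(
            mode=mode, n_perm=n_perm, seed=int(plan_children[c].generate_state(1)[0] % 2**31)
        )
        results = run_gsea(
            null_ds,
            genesets,
            metric_name,
            plan,
            min_size=min_size,
            max_size=max_size,
            workers=workers,
            **metric_options,
        )
        if not results:
            raise ValueError("no gene sets survive the size filter; cannot estimate FPR")
        pvals = np.array([r.p for r in results])
        fprs[c] = np.mean(pvals < alpha)
    return FprEstimate(fprs=fprs, alpha=alpha)


# ----------------------------------------------------------------------
# scorecards and clustering
# ----------------------------------------------------------------------

@dataclass
class MetricScorecard:
    metric_name: str
    overall_sensitivity: float  # 1 - pi0 over per-dataset target p-values
    overall_fpr_dev: float  # |mean FPR - expected level|
    compute_time: float = np.nan  # seconds; wall-clock, not portable


def overall_scores(
    metric_name: str,
    target_pvalues,
    fpr_estimates,
    compute_time: float = np.nan,
    expected_fpr: float = 0.05,
    pi0_lambda: float = 0.5,
) -> MetricScorecard:
    """Summarise a metric across datasets into its scorecard.

    ``target_pvalues`` holds one surrogate-sensitivity p per dataset;
    ``fpr_estimates`` is one or more :class:`FprEstimate` (their replicate
    FPRs are pooled before taking the mean).
    """
    if np.ndim(target_pvalues) == 0 or len(target_pvalues) == 0:
        raise ValueError("at least one dataset's target p-value is required")
    if isinstance(fpr_estimates, FprEstimate):
        fpr_estimates = [fpr_estimates]
    all_fprs = np.concatenate([np.asarray(e.fprs, dtype=float) for e in fpr_estimates])
    return MetricScorecard(
        metric_name=metric_name,
        overall_sensitivity=1.0 - storey_pi0(target_pvalues, lam=pi0_lambda),
        overall_fpr_dev=float(abs(all_fprs.mean() - expected_fpr)),
        compute_time=compute_time,
    )


def time_metric(dataset: ExpressionDataset, metric_name, repeats: int = 1, **options) -> float:
    """Wall-clock seconds of the ranking step (median over repeats)."""
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        rank_genes(dataset, metric_name, **dict(options))
        times.append(time.perf_counter() - t0)
    return float(np.median(times))


@dataclass
class ClusterAssignment:
    assignment: dict  # metric name -> cluster id
    k: int
    dunn_by_k: dict  # candidate k -> Dunn index
    normalized_scores: "np.ndarray"
    metric_names: list = field(default_factory=list)
    columns: list = field(default_factory=list)


def _dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """min inter-cluster distance / max intra-cluster diameter."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(points))
    ks = np.unique(labels)
    diam = max(
        (d[np.ix_(labels == k, labels == k)].max() if (labels == k).sum() > 1 else 0.0)
        for k in ks
    )
    sep = min(
        d[np.ix_(labels == a, labels == b)].min() for a in ks for b in ks if a < b
    )
    if diam == 0.0:
        return np.inf if sep > 0 else 0.0
    return float(sep / diam)


def cluster_metrics(
    scorecards,
    use_time: bool = True,
    k_range=range(2, 9),
    seed: int | None = None,
    n_init: int = 50,
) -> ClusterAssignment:
    """Group ranking metrics by performance with k-means + Dunn index.

    Each score column (overall sensitivity, overall FPR deviation and, when
    ``use_time``, compute time) is min-max normalised across metrics to
    avoid favouring any single criterion; k-means with Euclidean distance
    is run for every candidate k (with ``n_init`` restarts) and the k with
    the largest Dunn index is kept (ties towards fewer clusters).
    Metrics are processed in name order, so the result does not depend on
    the order in which scorecards are supplied.
    """
    cards = sorted(scorecards, key=lambda c: c.metric_name)
    if len(cards) < 3:
        raise ValueError("clustering needs at least 3 metric scorecards")
    cols = ["overall_sensitivity", "overall_fpr_dev"] + (["compute_time"] if use_time else [])
    raw = np.array([[getattr(c, col) for col in cols] for c in cards], dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError(f"non-finite scores in columns {cols}; cannot cluster")
    span = raw.max(axis=0) - raw.min(axis=0)
    if (span == 0).all():
        raise ValueError("all scorecards identical; clustering is degenerate")
    span = np.where(span > 0, span, 1.0)  # constant column -> all zeros
    normed = (raw - raw.min(axis=0)) / span
    names = [c.metric_name for c in cards]
    dunn_by_k: dict[int, float] = {}
    best: tuple[float, int, np.ndarray] | None = None
    for k in k_range:
        if k >= len(cards):
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(normed)
        if len(np.unique(labels)) < k:
            continue
        dunn = _dunn_index(normed, labels)
        dunn_by_k[k] = dunn
        if best is None or dunn > best[0]:
            best = (dunn, k, labels)
    if best is None:
        raise ValueError("no candidate k produced a valid clustering")
    _, k, labels = best
    return ClusterAssignment(
        assignment=dict(zip(names, (int(c) for c in labels))),
        k=k,
        dunn_by_k=dunn_by_k,
        normalized_scores=normed,
        metric_names=names,
        columns=cols,
    )


# ----------------------------------------------------------------------
# robustness to sample size
# ----------------------------------------------------------------------

@dataclass
class RobustnessCurve:
    sizes: list
    target_pvalues: dict  # size -> array of per-replicate target p
    fprs: dict  # size -> array of per-replicate FPRs (empty if not assessed)
    metric_name: str = ""


def _stratified_subsample(dataset: ExpressionDataset, size: int, rng) -> ExpressionDataset:
    """Subsample preserving the group proportion (within one sample)."""
    if size >= dataset.n_samples:
        return dataset
    n1_sub = int(round(size * dataset.n1 / dataset.n_samples))
    n1_sub = int(np.clip(n1_sub, 2, min(dataset.n1, size - 2)))
    n2_sub = size - n1_sub
    if n2_sub > dataset.n2 or n2_sub < 2:
        raise ValueError(f"cannot draw a stratified subsample of size {size}")
    idx1 = rng.choice(np.flatnonzero(dataset.group1_mask), size=n1_sub, replace=False)
    idx2 = rng.choice(np.flatnonzero(dataset.group2_mask), size=n2_sub, replace=False)
    return dataset.subset_samples(np.sort(np.concatenate([idx1, idx2])))


def robustness_experiment(
    dataset: ExpressionDataset,
    genesets,
    metric_name,
    target_set_id: str,
    sizes=(10, 20, 30, 40, 60, 80, 100),
    n_reps: int = 30,
    n_perm: int = 1000,
    alpha: float = 0.05,
    fpr_collections: int = 1,
    seed: int | None = None,
    min_size: int = 15,
    max_size: int = 500,
    **metric_options,
) -> RobustnessCurve:
    """Sensitivity and FPR on repeated stratified subsamples per sample size.

    For every requested size the dataset is subsampled ``n_reps`` times in a
    stratified manner; each replicate records the target set's nominal p and
    (when ``fpr_collections > 0``) an FPR estimate on that subsample.  Sizes
    exceeding the dataset are skipped with a warning.
    """
    ss = np.random.SeedSequence(seed)
    target_p: dict[int, np.ndarray] = {}
    fprs: dict[int, np.ndarray] = {}
    kept_sizes = []
    for size in sizes:
        if size > dataset.n_samples:
            warnings.warn(f"requested size {size} exceeds dataset; skipped", stacklevel=2)
            continue
        kept_sizes.append(size)
        sub_seed, plan_seed, fpr_seed = ss.spawn(3)
        sub_rngs = [np.random.default_rng(s) for s in sub_seed.spawn(n_reps)]
        plan_children = plan_seed.spawn(n_reps)
        fpr_children = fpr_seed.spawn(n_reps)
        ps, fs = [], []
        for rep in range(n_reps):
            sub = _stratified_subsample(dataset, size, sub_rngs[rep])
            plan = PermutationPlan(
                mode="phenotype",
                n_perm=n_perm,
                seed=int(plan_children[rep].generate_state(1)[0] % 2**31),
            )
            results = run_gsea(
                sub, genesets, metric_name, plan,
                min_size=min_size, max_size=max_size, **metric_options,
            )
            ps.append(surrogate_sensitivity(results, target_set_id))
            if fpr_collections > 0:
                est = fpr_experiment(
                    sub, genesets, metric_name,
                    n_collections=fpr_collections, alpha=alpha, n_perm=n_perm,
                    seed=int(fpr_children[rep].generate_state(1)[0] % 2**31),
                    min_size=min_size, max_size=max_size, **metric_options,
                )
                fs.append(est.mean)
        target_p[size] = np.asarray(ps)
        fprs[size] = np.asarray(fs)
    return RobustnessCurve(
        sizes=kept_sizes, target_pvalues=target_p, fprs=fprs, metric_name=str(metric_name)
    )


# ----------------------------------------------------------------------
# distributional diagnostics
# ----------------------------------------------------------------------

def normality_fraction(
    dataset: ExpressionDataset, alpha: float = 0.05, scope: str = "either"
) -> float:
    """Fraction of genes whose expression is non-normally distributed.

    The Lilliefors (Kolmogorov-Smirnov with estimated mean/sd) test is
    applied per gene within each phenotype group; under ``scope='either'``
    (default) a gene counts as non-normal when either group rejects at
    ``alpha``, under ``scope='pooled'`` the within-group-centred residuals
    are pooled into a single test per gene.  Groups smaller than 4 samples
    cannot be tested and the gene is skipped (logged).
    """
    if alpha == 0:
        return 0.0
    if scope not in ("either", "pooled"):
        raise ValueError(f"scope must be 'either' or 'pooled', got {scope!r}")
    x1, x2 = dataset.group_values()
    tested = 0
    rejected = 0
    skipped = 0
    for g in range(dataset.n_genes):
        if scope == "pooled":
            resid = np.concatenate([x1[g] - x1[g].mean(), x2[g] - x2[g].mean()])
            if resid.size < 4 or resid.std() == 0:
                skipped += 1
                continue
            tested += 1
            rejected += lilliefors(resid, dist="norm")[1] < alpha
        else:
            if min(x1.shape[1], x2.shape[1]) < 4 or x1[g].std() == 0 or x2[g].std() == 0:
                skipped += 1
                continue
            tested += 1
            p1 = lilliefors(x1[g], dist="norm")[1]
            p2 = lilliefors(x2[g], dist="norm")[1]
            rejected += (p1 < alpha) or (p2 < alpha)
    if skipped:
        log.info("normality test skipped for %d genes (group too small or constant)", skipped)
    if tested == 0:
        raise ValueError("no gene could be tested for normality (groups too small)")
    return rejected / tested
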