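"""Weighted Kolmogorov-Smirnov gene set enrichment with permutation nulls.

Genes are sorted by a ranking metric (descending).  Walking down the list,
a running sum increases by ``|r_j|/N_R`` at every gene in the set (a hit,
with ``N_R`` the sum of |metric| over member genes) and decreases by
``1/(N - N_H)`` at every non-member (a miss).  Both cumulative terms reach 1
at the end of the list, so the running sum returns to 0.  The enrichment
score (ES) is the deviation of maximal absolute value, keeping its sign.

Significance comes from a permutation test.  Phenotype permutation shuffles
the sample labels (preserving group sizes and the gene-gene correlation
structure) and re-ranks all genes each time; gene permutation keeps the
observed ranking and randomises set membership.  The normalised enrichment
score (NES) rescales ES by the mean magnitude of same-sign null ES, which
adjusts for gene set size, and the nominal p-value is computed on the
same-sign portion of the null NES distribution only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .dataset import ExpressionDataset, GeneSet, RankVector
from .metrics import rank_genes

log = logging.getLogger(__name__)

__all__ = [
    "PermutationPlan",
    "RunningSum",
    "EnrichmentResult",
    "enrichment_score",
    "null_distribution",
    "normalize_es",
    "empirical_pvalue",
    "run_gsea",
    "results_to_table",
]


@dataclass
class PermutationPlan:
    """How the null ES distribution is generated."""

    mode: str = "phenotype"  # "phenotype" (sample labels) or "gene" (set membership)
    n_perm: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("phenotype", "gene"):
            raise ValueError(f"permutation mode must be 'phenotype' or 'gene', got {self.mode!r}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")


@dataclass
class RunningSum:
    """Per-position running deviation P_hit(S,i) − P_miss(S,i), i = 1..N."""

    deviations: np.ndarray
    n_r: float
    n_h: int
    n: int

    @property
    def es(self) -> float:
        i = int(np.argmax(np.abs(self.deviations)))  # ties -> earlier position
        return float(self.deviations[i])


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    size: int  # N_H after intersection with the dataset
    es: float
    nes: float = np.nan
    p: float = np.nan
    null_es: np.ndarray | None = None
    null_nes: np.ndarray | None = None
    sparse_null: bool = False  # few same-sign null samples; p unreliable
    running_sum: RunningSum | None = field(default=None, repr=False)

    @property
    def direction(self) -> int:
        return int(np.sign(self.es))


# ----------------------------------------------------------------------
# core running sum
# ----------------------------------------------------------------------

def _es_matrix(abs_r_sorted: np.ndarray, member_sorted: np.ndarray) -> np.ndarray:
    """ES for several sets on one sorted gene list.

    ``member_sorted`` is (n_sets, N) boolean in sorted-list order.  Returns
    the (n_sets,) ES vector.  A set whose member |r| sum is zero falls back
    to equal hit weights 1/N_H (unweighted KS walk).
    """
    deviations = _running_sums(abs_r_sorted, member_sorted)
    idx = np.argmax(np.abs(deviations), axis=1)
    return deviations[np.arange(deviations.shape[0]), idx]


def _running_sums(abs_r_sorted: np.ndarray, member_sorted: np.ndarray) -> np.ndarray:
    n = abs_r_sorted.shape[0]
    member_sorted = np.atleast_2d(member_sorted)
    n_h = member_sorted.sum(axis=1)
    if (n_h == 0).any() or (n_h == n).any():
        raise ValueError("gene set must satisfy 1 <= N_H < N after intersection")
    n_r = (member_sorted * abs_r_sorted).sum(axis=1)
    hit_w = np.where(
        n_r[:, None] > 0,
        abs_r_sorted / np.where(n_r[:, None] > 0, n_r[:, None], 1.0),
        1.0 / n_h[:, None],
    )
    miss_w = 1.0 / (n - n_h)
    increments = np.where(member_sorted, hit_w, -miss_w[:, None])
    return np.cumsum(increments, axis=1)


def enrichment_score(rank: RankVector, gene_set: GeneSet) -> tuple[RunningSum, float]:
    """Running sum and ES of one gene set on one ranked gene list.

    The set is intersected with the dataset's genes first; an empty
    intersection or a set covering every gene is an error (the miss weight
    would be undefined).
    """
    gs = gene_set.intersect(rank.gene_ids)
    n = len(rank.values)
    if len(gs) == 0:
        raise ValueError(f"gene set {gene_set.set_id!r} has no genes in the dataset")
    if len(gs) == n:
        raise ValueError(f"gene set {gene_set.set_id!r} covers all genes; P_miss undefined")
    order = rank.order
    sorted_ids = rank.gene_ids[order].astype(str)
    member = np.isin(sorted_ids, list(gs.members))
    abs_r = np.abs(rank.values[order])
    deviations = _running_sums(abs_r, member[None, :])[0]
    rs = RunningSum(
        deviations=deviations,
        n_r=float(abs_r[member].sum()),
        n_h=int(member.sum()),
        n=n,
    )
    return rs, rs.es


# ----------------------------------------------------------------------
# permutation null
# ----------------------------------------------------------------------

def _phenotype_null_chunk(
    dataset: ExpressionDataset,
    member: np.ndarray,
    metric_name,
    metric_options: dict,
    label_perms: np.ndarray,
) -> np.ndarray:
    """(n_sets, n_chunk) null ES for a block of permuted label vectors."""
    out = np.empty((member.shape[0], label_perms.shape[0]))
    for p, lab in enumerate(label_perms):
        rank = rank_genes(dataset.with_labels(lab), metric_name, **dict(metric_options))
        order = rank.order
        out[:, p] = _es_matrix(np.abs(rank.values[order]), member[:, order])
    return out


def _null_es_all_sets(
    dataset: ExpressionDataset,
    member: np.ndarray,
    metric_name,
    metric_options: dict,
    plan: PermutationPlan,
    observed_rank: RankVector,
    workers: int = 1,
) -> np.ndarray:
    """(n_sets, n_perm) null ES matrix under the plan's permutation mode."""
    rng = np.random.default_rng(plan.seed)
    n_sets, n = member.shape
    if plan.mode == "phenotype":
        if min(dataset.n1, dataset.n2) < 2:
            warnings.warn(
                "phenotype permutation with a group of size 1 is degenerate", stacklevel=2
            )
        label_perms = np.array(
            [rng.permutation(dataset.labels) for _ in range(plan.n_perm)], dtype=object
        )
        if workers > 1:
            chunks = np.array_split(np.arange(plan.n_perm), workers)
            parts = Parallel(n_jobs=workers)(
                delayed(_phenotype_null_chunk)(
                    dataset, member, metric_name, metric_options, label_perms[c]
                )
                for c in chunks
                if len(c)
            )
            return np.hstack(parts)
        return _phenotype_null_chunk(dataset, member, metric_name, metric_options, label_perms)
    # gene-label permutation: fixed ranking, random membership of the same size
    order = observed_rank.order
    abs_r = np.abs(observed_rank.values[order])
    n_h = member.sum(axis=1)
    out = np.empty((n_sets, plan.n_perm))
    for p in range(plan.n_perm):
        rand_member = np.zeros((n_sets, n), dtype=bool)
        for s in range(n_sets):
            rand_member[s, rng.choice(n, size=n_h[s], replace=False)] = True
        out[:, p] = _es_matrix(abs_r, rand_member)
    return out


def null_distribution(
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    metric_name,
    plan: PermutationPlan,
    **metric_options,
) -> np.ndarray:
    """Null ES samples for one gene set (n_perm values, reproducible by seed)."""
    rank = rank_genes(dataset, metric_name, **dict(metric_options))
    gs = gene_set.intersect(dataset.gene_ids)
    if len(gs) == 0:
        raise ValueError(f"gene set {gene_set.set_id!r} has no genes in the dataset")
    member = np.isin(dataset.gene_ids.astype(str), list(gs.members))[None, :]
    return _null_es_all_sets(
        dataset, member, metric_name, metric_options, plan, rank, workers=1
    )[0]


# ----------------------------------------------------------------------
# normalisation and p-values
# ----------------------------------------------------------------------

def normalize_es(es: float, null_es: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Sign-wise NES: divide by the mean |null ES| of matching sign.

    Returns ``(nes, null_nes, sparse)``.  Null samples are rescaled the same
    way, each by the mean of its own sign's magnitudes.  When no null sample
    shares the observed sign the NES is undefined (NaN) and ``sparse`` is
    set; callers report p below the permutation resolution in that case.
    """
    null_es = np.asarray(null_es, dtype=float)
    pos = null_es > 0
    neg = null_es < 0
    mean_pos = np.abs(null_es[pos]).mean() if pos.any() else np.nan
    mean_neg = np.abs(null_es[neg]).mean() if neg.any() else np.nan
    null_nes = np.zeros_like(null_es)
    if pos.any():
        null_nes[pos] = null_es[pos] / mean_pos
    if neg.any():
        null_nes[neg] = null_es[neg] / mean_neg
    if es > 0:
        scale, sparse = mean_pos, not pos.any()
    elif es < 0:
        scale, sparse = mean_neg, not neg.any()
    else:
        return 0.0, null_nes, False
    nes = np.nan if sparse else float(es / scale)
    return nes, null_nes, sparse


def empirical_pvalue(nes: float, null_nes: np.ndarray, n_perm: int | None = None) -> float:
    """Sign-matched empirical p with add-one smoothing.

    p = (1 + #{same-sign null, |value| >= |nes|}) / (1 + #{same-sign null}).
    Only the portion of the null NES distribution with the observed sign is
    used.  When the same-sign portion is small relative to the number of
    permutations (common for metrics that yield mostly one-signed scores,
    e.g. MSD under label permutation) the estimate is coarse and a warning
    is emitted.
    """
    null_nes = np.asarray(null_nes, dtype=float)
    if nes == 0:
        return 1.0
    same = null_nes[np.sign(null_nes) == np.sign(nes)]
    if n_perm is not None and same.size < 0.1 * n_perm:
        warnings.warn(
            f"only {same.size} of {n_perm} null samples share the observed sign; "
            "the p-value is coarse - consider more permutations",
            stacklevel=2,
        )
    return float((1 + np.sum(np.abs(same) >= abs(nes))) / (1 + same.size))


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------

def run_gsea(
    dataset: ExpressionDataset,
    genesets,
    metric_name,
    plan: PermutationPlan | None = None,
    min_size: int = 15,
    max_size: int = 500,
    workers: int = 1,
    keep_traces: bool = False,
    keep_nulls: bool = False,
    **metric_options,
) -> list[EnrichmentResult]:
    """Run GSEA for a collection of gene sets.

    Sets are intersected with the dataset and filtered to
    ``min_size <= N_H <= max_size`` (pass ``min_size=1, max_size=None`` to
    disable).  Each surviving set is scored independently; results do not
    depend on the order of the collection or on ``workers``.  ``plan=None``
    skips the permutation test and reports ES only.
    """
    genesets = list(genesets)
    if not genesets:
        raise ValueError("empty gene set collection")
    if max_size is None:
        max_size = np.inf
    gene_ids = dataset.gene_ids.astype(str)
    kept: list[GeneSet] = []
    for gs in genesets:
        inter = gs.intersect(gene_ids)
        if len(inter) == 0:
            log.info("gene set %s skipped: no overlap with dataset", gs.set_id)
            continue
        if len(inter) == dataset.n_genes:
            log.info("gene set %s skipped: covers every gene", gs.set_id)
            continue
        if not (min_size <= len(inter) <= max_size):
            log.debug("gene set %s filtered by size (%d)", gs.set_id, len(inter))
            continue
        kept.append(inter)
    if not kept:
        warnings.warn("all gene sets were filtered out; empty result", stacklevel=2)
        return []
    kept.sort(key=lambda g: g.set_id)  # canonical order, independent of input order

    rank = rank_genes(dataset, metric_name, **dict(metric_options))
    member = np.vstack([np.isin(gene_ids, list(g.members)) for g in kept])
    order = rank.order
    abs_r_sorted = np.abs(rank.values[order])
    member_sorted = member[:, order]
    observed_es = _es_matrix(abs_r_sorted, member_sorted)

    null_es = None
    if plan is not None:
        null_es = _null_es_all_sets(
            dataset, member, metric_name, metric_options, plan, rank, workers=workers
        )

    results = []
    for s, gs in enumerate(kept):
        res = EnrichmentResult(
            set_id=gs.set_id, name=gs.name, size=len(gs), es=float(observed_es[s])
        )
        if keep_traces:
            res.running_sum = RunningSum(
                deviations=_running_sums(abs_r_sorted, member_sorted[s][None, :])[0],
                n_r=float(abs_r_sorted[member_sorted[s]].sum()),
                n_h=len(gs),
                n=dataset.n_genes,
            )
        if null_es is not None:
            nes, null_nes, sparse = normalize_es(res.es, null_es[s])
            res.nes = nes
            res.sparse_null = sparse
            if sparse:
                res.p = 1.0 / (plan.n_perm + 1)
                log.warning(
                    "set %s: no null sample with the observed ES sign; "
                    "p reported as < 1/(n_perm+1)",
                    gs.set_id,
                )
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res.p = empirical_pvalue(nes, null_nes, n_perm=plan.n_perm)
            if keep_nulls:
                res.null_es = null_es[s]
                res.null_nes = null_nes
        results.append(res)
    return results


def results_to_table(results):
    """Result list as a tidy table (one row per gene set)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.name for r in results],
            "size_after_intersection": [r.size for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p_nominal": [r.p for r in results],
            "direction": [r.direction for r in results],
        }
    )
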