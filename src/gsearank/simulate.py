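"""Synthetic two-phenotype expression fixtures with known ground truth.

The generator emulates the structure of a preprocessed microarray study:
log-scale intensities with per-gene baselines drawn over a plausible range
(uniform on [4, 14] log2 units), i.i.d. per-gene noise, an optional
fraction of genes with a skewed (standardised shifted log-normal) noise
distribution to mimic non-normally distributed genes, optional
within-set block correlation, and a collection of gene sets of which a few
designated *target* sets carry a mean shift between the two groups.

Null fixtures are exchangeable by construction (both groups drawn from the
same per-gene distribution), which is exactly the regime where a nominal
5% significance level should yield a 5% positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, GeneSet

__all__ = ["SimulationConfig", "simulate_null", "simulate_signal", "write_fixture"]


@dataclass
class SimulationConfig:
    """Generative parameters for synthetic fixtures.

    ``effect_size`` is the mean shift (log-scale units) added to target-set
    genes in group 2; ``down_fraction`` shifts that fraction of target genes
    by −effect_size instead, emulating pathways containing both up- and
    down-regulated genes.  ``contamination`` is the fraction of genes whose
    noise is drawn from a skewed distribution instead of a normal one.
    ``rho`` adds exchangeable correlation between genes of the same set.
    """

    n_genes: int = 1000
    n1: int = 15
    n2: int = 15
    n_sets: int = 100
    set_size: int = 20
    n_target_sets: int = 1
    effect_size: float = 2.0
    noise_sd: float = 1.0
    contamination: float = 0.0
    down_fraction: float = 0.0
    rho: float = 0.0
    baseline_range: tuple = (4.0, 14.0)
    group_names: tuple = ("control", "case")
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must be in [0, 1]")
        if not 0.0 <= self.down_fraction <= 1.0:
            raise ValueError("down_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(f"both groups need >= 2 samples (got {self.n1}, {self.n2})")
        if self.n_target_sets * self.set_size > self.n_genes:
            raise ValueError("target sets need more genes than the matrix provides")


# standardised LogNormal(0,1): mean exp(1/2), sd sqrt((e-1)e)
_LN_MEAN = float(np.exp(0.5))
_LN_SD = float(np.sqrt((np.e - 1.0) * np.e))


def _gene_ids(n: int) -> np.ndarray:
    width = len(str(n))
    return np.asarray([f"g{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def _noise(rng, shape, contaminated_rows, sd):
    """Per-gene noise: unit-sd normal, or standardised log-normal for
    contaminated genes (right-skewed, mean 0, sd 1), scaled by ``sd``."""
    eps = rng.standard_normal(shape)
    if contaminated_rows.size:
        skew = (rng.lognormal(0.0, 1.0, (contaminated_rows.size, shape[1])) - _LN_MEAN) / _LN_SD
        eps[contaminated_rows] = skew
    return sd * eps


def _build(config: SimulationConfig, signal: bool):
    # independent streams so a zero-effect signal fixture is bitwise
    # identical to the null fixture from the same seed
    ss = np.random.SeedSequence(config.seed)
    rng_noise, rng_sets, rng_shift = (np.random.default_rng(c) for c in ss.spawn(3))
    g = config.n_genes
    n = config.n1 + config.n2
    ids = _gene_ids(g)
    labels = np.asarray(
        [config.group_names[0]] * config.n1 + [config.group_names[1]] * config.n2,
        dtype=object,
    )
    mu = rng_noise.uniform(*config.baseline_range, size=g)
    contaminated = rng_noise.choice(
        g, size=int(round(config.contamination * g)), replace=False
    )

    # gene set layout: target sets first, on disjoint genes; null sets drawn
    # from the remaining genes so they stay null under a signal model
    perm = rng_sets.permutation(g)
    target_sets: list[GeneSet] = []
    used = 0
    for t in range(config.n_target_sets):
        members = ids[perm[used : used + config.set_size]]
        target_sets.append(GeneSet(f"target_{t + 1:02d}", f"target_{t + 1:02d}", members))
        used += config.set_size
    pool = perm[used:] if signal else np.arange(g)
    null_sets = []
    n_null = config.n_sets - (config.n_target_sets if signal else 0)
    for s in range(n_null):
        members = ids[rng_sets.choice(pool, size=min(config.set_size, pool.size), replace=False)]
        null_sets.append(GeneSet(f"set_{s + 1:04d}", f"set_{s + 1:04d}", members))

    noise = _noise(rng_noise, (g, n), contaminated, config.noise_sd)
    if config.rho > 0:
        block_of_gene = np.full(g, -1)
        blocks = target_sets + null_sets if signal else null_sets
        for b, gs in enumerate(blocks):
            for gi in np.flatnonzero(np.isin(ids, list(gs.members))):
                if block_of_gene[gi] < 0:
                    block_of_gene[gi] = b
        z = rng_noise.standard_normal((len(blocks), n)) * config.noise_sd
        in_block = block_of_gene >= 0
        noise[in_block] = (
            np.sqrt(config.rho) * z[block_of_gene[in_block]]
            + np.sqrt(1.0 - config.rho) * noise[in_block]
        )
    values = mu[:, None] + noise

    truth_rows = []
    if signal:
        group2 = labels == config.group_names[1]
        for gs in target_sets:
            member_idx = np.flatnonzero(np.isin(ids, list(gs.members)))
            n_down = int(round(config.down_fraction * member_idx.size))
            down = set(rng_shift.choice(member_idx, size=n_down, replace=False))
            for gi in member_idx:
                shift = -config.effect_size if gi in down else config.effect_size
                values[gi, group2] += shift
                truth_rows.append({"gene": ids[gi], "set": gs.set_id, "shift": shift})

    dataset = ExpressionDataset(values, ids, labels)
    collection = (target_sets + null_sets) if signal else null_sets
    truth = pd.DataFrame(truth_rows, columns=["gene", "set", "shift"])
    return dataset, collection, [gs.set_id for gs in target_sets], truth


def simulate_null(config: SimulationConfig):
    """Exchangeable null fixture: ``(dataset, gene set collection)``.

    The effect size is ignored; both groups are i.i.d. from the same
    per-gene distribution, so relabelling samples leaves the generative
    distribution unchanged.
    """
    dataset, collection, _, _ = _build(config, signal=False)
    return dataset, collection


def simulate_signal(config: SimulationConfig):
    """Fixture with shifted target sets.

    Returns ``(dataset, collection, target_set_ids, truth)`` where ``truth``
    is a (gene, set, shift) table recording every generative mean shift.
    With ``effect_size=0`` the dataset is distributionally identical to a
    null fixture (the shift applied is zero).
    """
    if config.n_target_sets < 1:
        raise ValueError("simulate_signal needs at least one target set")
    return _build(config, signal=True)


def write_fixture(out_dir, dataset: ExpressionDataset, collection, truth=None) -> dict:
    """Write the standard fixture trio (+ truth table) and return the paths."""
    from .io import write_cls, write_expression, write_gmt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "cls": out_dir / "phenotype.cls",
        "gmt": out_dir / "sets.gmt",
    }
    sample_ids = [f"s{i + 1:03d}_{lab}" for i, lab in enumerate(dataset.labels)]
    write_expression(paths["expression"], dataset.values, dataset.gene_ids, sample_ids)
    write_cls(paths["cls"], dataset.labels)
    write_gmt(paths["gmt"], collection)
    if truth is not None and len(truth):
        paths["truth"] = out_dir / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
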