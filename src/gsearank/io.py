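"""Readers and writers for the plain-text formats the tool consumes.

Expression matrices are tab-delimited (first column gene/probe id, header
row of sample ids), phenotypes use the three-line categorical CLS dialect,
and gene set collections come either as GMT (one set per line: id,
description, members...) or as a two-column ``set_id<TAB>gene`` table — the
latter covers collections exported from a spreadsheet.  Readers validate
and reject malformed input rather than silently coercing it.

Expression values are assumed to be already normalised / log-transformed;
no preprocessing is applied here.  Microarray platforms often carry several
probe sets per gene; :func:`collapse_probes` reduces them to one row per
gene by keeping the probe with the smallest p-value (Welch t by default) or
with the highest average expression across all samples.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_cls",
    "write_cls",
    "read_gmt",
    "write_gmt",
    "read_geneset_table",
    "ProbeMap",
    "collapse_probes",
    "welch_pvalues",
]


def read_expression(path, allow_duplicate_ids: bool = False):
    """Read a tab-delimited genes x samples matrix.

    Returns an :class:`ExpressionDataset` with placeholder labels when
    ``allow_duplicate_ids`` is false and ids are unique is required; since a
    phenotype file is read separately, this function returns the pieces:
    ``(values, gene_ids, sample_ids)``.
    """
    path = Path(path)
    raw = path.read_text()
    if not raw.strip():
        raise ValueError(f"{path}: empty expression file")
    header = raw.splitlines()[0].rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dups = [h for h in header if h in seen or seen.add(h)]
    if dups:
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise ValueError(
            f"{path}: missing/ragged cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric value at row {bad!r}, column {col!r}"
            ) from None
    gene_ids = np.asarray(df.index.astype(str), dtype=object)
    if not allow_duplicate_ids and pd.Index(gene_ids).duplicated().any():
        log.info("%s: duplicate row ids present; collapse probes before analysis", path)
    return values, gene_ids, list(df.columns)


def write_expression(path, values, gene_ids, sample_ids) -> None:
    df = pd.DataFrame(np.asarray(values), index=list(gene_ids), columns=list(sample_ids))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_cls(path) -> list:
    """Read a categorical CLS phenotype file with exactly two classes.

    Line 1: ``<n_samples> <n_classes> 1``; line 2: ``# name1 name2``;
    line 3: space-separated per-sample labels (class names or 0/1 indices).
    The first class named on line 2 is group 1.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: CLS file needs 3 non-empty lines, got {len(lines)}")
    head = lines[0].split()
    if len(head) != 3:
        raise ValueError(f"{path}: malformed CLS header line {lines[0]!r}")
    n_samples, n_classes = int(head[0]), int(head[1])
    if n_classes != 2:
        raise ValueError(f"{path}: exactly 2 phenotype classes required, got {n_classes}")
    names_line = lines[1].split()
    if names_line[0] != "#":
        # tolerate '#name1 name2' without the space
        names_line = lines[1].lstrip("#").split()
    else:
        names_line = names_line[1:]
    if len(names_line) != 2:
        raise ValueError(f"{path}: CLS class-name line must name 2 classes")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ValueError(
            f"{path}: header declares {n_samples} samples but {len(tokens)} labels found"
        )
    labels = []
    for tok in tokens:
        if tok in names_line:
            labels.append(tok)
        elif tok in ("0", "1"):
            labels.append(names_line[int(tok)])
        else:
            raise ValueError(f"{path}: unknown class token {tok!r}")
    return labels


def write_cls(path, labels) -> None:
    labels = list(labels)
    classes = list(dict.fromkeys(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {len(classes)}")
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write(f"# {classes[0]} {classes[1]}\n")
        fh.write(" ".join(str(lab) for lab in labels) + "\n")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT collection; empty set lines are skipped with a warning."""
    path = Path(path)
    sets: list[GeneSet] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            log.warning("%s line %d: gene set %r has no members; skipped", path, i, fields[0])
            continue
        members = [f.strip() for f in fields[2:] if f.strip()]
        if len(members) != len(set(members)):
            log.warning("%s line %d: duplicate members in %r deduplicated", path, i, fields[0])
        sets.append(GeneSet(set_id=fields[0], name=fields[1], members=members))
    return sets


def write_gmt(path, genesets) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            members = sorted(gs.members)
            fh.write("\t".join([gs.set_id, gs.name, *members]) + "\n")


def read_geneset_table(path, delimiter: str | None = None) -> list[GeneSet]:
    """Read a two-column (set_id, gene) table; CSV or TSV is auto-detected.

    This covers gene set collections kept in spreadsheets: export the sheet
    as delimited text with one (set, gene) pair per row.  Repeated pairs are
    counted once.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty gene set table")
    if delimiter is None:
        delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    members: dict[str, set] = {}
    reader = csv.reader(text.splitlines(), delimiter=delimiter)
    header = next(reader)
    rows = list(reader)
    if len(header) < 2:
        raise ValueError(f"{path}: expected two columns (set_id, gene)")
    for row in rows:
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            continue
        members.setdefault(row[0].strip(), set()).add(row[1].strip())
    return [
        GeneSet(set_id=sid, name=sid, members=genes) for sid, genes in sorted(members.items())
    ]


# ----------------------------------------------------------------------
# probe collapsing
# ----------------------------------------------------------------------

@dataclass
class ProbeMap:
    """probe_id -> gene_id mapping with an optional per-probe statistic."""

    mapping: dict
    pvalues: dict | None = None  # probe_id -> p, required for min_pvalue collapsing


def welch_pvalues(values, gene_ids, labels) -> dict:
    """Per-row Welch t-test p-values, the default statistic for collapsing."""
    labels = np.asarray(labels, dtype=object)
    classes = list(dict.fromkeys(labels))
    x1 = values[:, labels == classes[0]]
    x2 = values[:, labels == classes[1]]
    p = stats.ttest_ind(x1, x2, axis=1, equal_var=False).pvalue
    p = np.where(np.isfinite(p), p, 1.0)  # constant probes: no evidence
    return dict(zip(list(gene_ids), p))


def collapse_probes(
    values,
    probe_ids,
    probe_map: ProbeMap,
    strategy: str = "max_avg_expression",
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate probe sets to one row per gene.

    ``strategy='min_pvalue'`` keeps, for each gene, the probe with the
    smallest p-value (``probe_map.pvalues`` must be supplied, e.g. from
    :func:`welch_pvalues`); ``'max_avg_expression'`` keeps the probe with
    the highest average expression across all samples.  The chosen probe's
    values are retained verbatim.  Probes absent from the mapping keep
    their probe id as gene id.  Collapsing is idempotent.
    """
    if strategy not in ("min_pvalue", "max_avg_expression"):
        raise ValueError(f"unknown collapse strategy {strategy!r}")
    if strategy == "min_pvalue" and probe_map.pvalues is None:
        raise ValueError("min_pvalue collapsing requires per-probe p-values in the ProbeMap")
    values = np.asarray(values, dtype=float)
    probe_ids = list(probe_ids)
    avg = values.mean(axis=1)
    best_row: dict[str, int] = {}
    best_score: dict[str, float] = {}
    for i, probe in enumerate(probe_ids):
        gene = str(probe_map.mapping.get(probe, probe))
        if strategy == "min_pvalue":
            if probe not in probe_map.pvalues:
                raise ValueError(f"no p-value supplied for probe {probe!r}")
            score = -float(probe_map.pvalues[probe])  # larger = better
        else:
            score = float(avg[i])
        if gene not in best_row or score > best_score[gene]:
            best_row[gene] = i
            best_score[gene] = score
    genes = sorted(best_row)
    rows = [best_row[g] for g in genes]
    return values[rows], np.asarray(genes, dtype=object)


def load_dataset(expression_path, cls_path) -> ExpressionDataset:
    """Convenience: expression TSV + CLS file -> :class:`ExpressionDataset`."""
    values, gene_ids, sample_ids = read_expression(expression_path)
    labels = read_cls(cls_path)
    if len(labels) != len(sample_ids):
        raise ValueError(
            f"{cls_path}: {len(labels)} labels for {len(sample_ids)} expression columns"
        )
    return ExpressionDataset(values, gene_ids, np.asarray(labels, dtype=object))
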