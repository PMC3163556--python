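"""The expression arm: preprocessing, DEG calling, and list partitioning.

The pipeline consumes a pre-normalized gene-by-sample intensity matrix (e.g.
GCRMA output).  Preprocessing floors intensities at 10, removes genes with an
absent detection call on every array, and moves to log2 scale.  Differential
expression between a treatment and a control group is called through a
three-filter cascade:

1. per-gene class comparison (two-sample Student's t-test on log2 values),
   significant at p < 0.01;
2. Benjamini-Hochberg false-discovery control across genes, FDR < 5%;
3. a per-gene Student's t-test within the survivors, p < 0.01 — retained as a
   documented near-duplicate of filter 1 to reproduce the cascade structure
   of the original analysis tool, whose "class comparison" statistic is not
   further specified.

A fold-change threshold (|log2 ratio| >= 1.1, i.e. 2.1-fold) is then applied
to the significant genes and the survivors are split into up- and
down-regulated lists.  Zero-variance genes receive p = 1.0 rather than an
exception.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, FormatError
from .target_prediction import TargetPartition, partition_sets

DEFAULT_FLOOR = 10.0
DEFAULT_ALPHA = 0.01
DEFAULT_FDR = 0.05
DEFAULT_T_ALPHA = 0.01
DEFAULT_LOG2_CUT = 1.1


@dataclass
class ExpressionMatrix:
    """A gene-by-sample matrix; ``log2`` records whether values are log2."""

    values: pd.DataFrame  # genes x samples
    presence: pd.DataFrame | None = None  # P/A/M detection calls
    log2: bool = False

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group assignment plus the (treatment, control) contrast."""

    groups: Mapping[str, str]  # sample id -> group label
    contrast: tuple[str, str]

    def samples_of(self, group: str) -> list[str]:
        return sorted(s for s, g in self.groups.items() if g == group)


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression evidence and filter outcomes."""

    gene: str
    log2_ratio: float
    p_class: float
    fdr_pass: bool
    p_t: float
    direction: str  # up | down
    passes_fold: bool
    significant: bool  # all three significance filters passed (fold excluded)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_presence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = set(np.unique(df.values)) - {"P", "A", "M"}
    if bad:
        raise FormatError(f"presence calls must be P/A/M, found {sorted(bad)}")
    return df


def read_design(path: str | Path, contrast: tuple[str, str]) -> GroupDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise FormatError("design file needs columns: sample, group")
    return GroupDesign(groups=dict(zip(df["sample"], df["group"])), contrast=contrast)


def preprocess_matrix(
    m: ExpressionMatrix, floor: float = DEFAULT_FLOOR
) -> ExpressionMatrix:
    """Floor intensities, drop all-absent genes, log2-transform.

    Values below ``floor`` are replaced by ``floor``; genes whose detection
    call is absent on every array are removed (when presence calls are
    supplied); the result is log2 scale.  Non-numeric cells are reported with
    their coordinates.
    """
    if m.log2:
        raise ValueError("matrix is already log2-transformed")
    values = m.values.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        sample = values.columns[values.loc[gene].isna()][0]
        raise FormatError(f"non-numeric expression value at gene {gene!r}, sample {sample!r}")

    values = values.clip(lower=floor)
    presence = m.presence
    if presence is not None:
        presence = presence.reindex(index=values.index, columns=values.columns)
        keep = (presence != "A").any(axis=1)
        values = values.loc[keep]
        presence = presence.loc[keep]
    return ExpressionMatrix(values=np.log2(values), presence=presence, log2=True)


def _group_matrix(m: ExpressionMatrix, d: GroupDesign, group: str) -> np.ndarray:
    samples = [s for s in d.samples_of(group) if s in m.values.columns]
    if len(samples) < 2:
        raise DesignError(f"group {group!r} has fewer than 2 samples in the matrix")
    return m.values[samples].to_numpy()


def _student_t_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise pooled-variance two-sample t-test; zero-variance rows get p=1."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def call_degs(
    m: ExpressionMatrix,
    d: GroupDesign,
    alpha: float = DEFAULT_ALPHA,
    fdr: float = DEFAULT_FDR,
    t_alpha: float = DEFAULT_T_ALPHA,
) -> list[DEGRecord]:
    """Run the three-filter significance cascade for one contrast.

    Returns one record per gene with all filter outcomes, so downstream steps
    (and audits) can see exactly which filter removed a gene.
    """
    if not m.log2:
        raise ValueError("call_degs expects a preprocessed (log2) matrix")
    treatment, control = d.contrast
    a = _group_matrix(m, d, treatment)
    b = _group_matrix(m, d, control)

    log2_ratio = a.mean(axis=1) - b.mean(axis=1)
    p_class = _student_t_pvalues(a, b)
    from .enrichment import adjust_bh

    q = np.asarray(adjust_bh(p_class))
    fdr_pass = q < fdr
    # the cascade's final per-gene Student's t-test; identical statistic by
    # construction, recomputed and recorded separately for auditability
    p_t = _student_t_pvalues(a, b)

    records = []
    for i, gene in enumerate(m.genes):
        lr = float(log2_ratio[i])
        records.append(
            DEGRecord(
                gene=gene,
                log2_ratio=lr,
                p_class=float(p_class[i]),
                fdr_pass=bool(fdr_pass[i]),
                p_t=float(p_t[i]),
                direction="down" if lr < 0 else "up",
                passes_fold=abs(lr) >= DEFAULT_LOG2_CUT,
                significant=bool(
                    p_class[i] < alpha and fdr_pass[i] and p_t[i] < t_alpha
                ),
            )
        )
    return records


def apply_fold_threshold(
    records: Sequence[DEGRecord],
    log2_cut: float = DEFAULT_LOG2_CUT,
) -> tuple[list[DEGRecord], list[DEGRecord]]:
    """Keep significant records with |log2 ratio| >= cut; split by direction.

    The boundary is inclusive; the fold filter applies only to genes that
    already passed the significance cascade.
    """
    up, down = [], []
    for r in records:
        if not r.significant or abs(r.log2_ratio) < log2_cut:
            continue
        (down if r.log2_ratio < 0 else up).append(r)
    return up, down


def partition_deg_lists(lists: Mapping[str, set[str]]) -> TargetPartition:
    """Common/similar/unique partition of per-drug DEG lists.

    Identical semantics to the target-set partition; exposed here because the
    expression arm applies it to gene lists.
    """
    return partition_sets(lists)


def write_deg_table(path: str | Path, records: Sequence[DEGRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlog2_ratio\tp_class\tfdr_pass\tp_t\tdirection\tpasses_fold\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.log2_ratio:.6f}\t{r.p_class:.6e}\t{int(r.fdr_pass)}"
                f"\t{r.p_t:.6e}\t{r.direction}\t{int(r.passes_fold)}\n"
            )


def write_gene_list(path: str | Path, records: Sequence[DEGRecord]) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: r.gene):
            fh.write(r.gene + "\n")
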