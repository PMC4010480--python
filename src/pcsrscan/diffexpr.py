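"""Per-cancer differential-expression calls from normalized log2 matrices.

Direction calls use a symmetric linear fold-change threshold on the log2
scale together with a per-probe Welch two-sample t-test: ``over`` when
log2FC >= log2(threshold) and p < alpha, ``down`` when log2FC <=
-log2(threshold) and p < alpha, ``unchanged`` otherwise.  Field defaults:
2-fold for mRNA, 1.5-fold for miRNA, 1.2-fold for tracing RNAs shared
across cancers, alpha 0.05 with no multiplicity correction.

An alternative ranking mode keeps, per direction, the N probes with the
largest absolute fold change among significant probes (default N=200).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MRNA_FOLD = 2.0
MIRNA_FOLD = 1.5
TRACE_FOLD = 1.2
DEFAULT_ALPHA = 0.05
DEFAULT_TOP_N = 200

OVER, DOWN, UNCHANGED = "over", "down", "unchanged"


@dataclass
class ExpressionStudy:
    """One cancer-vs-normal experiment: log2 matrix plus group labels."""

    cancer_id: str
    matrix: pd.DataFrame  # probes x samples, log2 intensities
    group: pd.Series  # sample -> "case" | "control"

    def __post_init__(self) -> None:
        self.group = self.group.reindex(self.matrix.columns)
        if self.group.isna().any():
            missing = self.matrix.columns[self.group.isna()].tolist()
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.group.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in ("case", "control"):
            if (self.group == g).sum() < 2:
                raise ValueError(f"group {g!r} has <2 samples in {self.cancer_id}")
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.matrix.to_numpy(dtype=float)
        case = m[:, (self.group == "case").to_numpy()]
        control = m[:, (self.group == "control").to_numpy()]
        return case, control


def log2_fold_change(study: ExpressionStudy) -> pd.Series:
    """Signed per-probe log2 fold change: mean(case) - mean(control)."""
    case, control = study.split()
    return pd.Series(case.mean(axis=1) - control.mean(axis=1), index=study.matrix.index)


def welch_t(study: ExpressionStudy) -> pd.Series:
    """Two-sided Welch unequal-variance t-test p-value per probe.

    Degenerate probes (zero variance in both groups) get p=1 when the group
    means are equal and p=0 when they differ.
    """
    case, control = study.split()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        diff = case.mean(axis=1) - control.mean(axis=1)
        p[degenerate] = np.where(diff[degenerate] == 0.0, 1.0, 0.0)
    return pd.Series(p, index=study.matrix.index)


def call_directions(
    fold: pd.Series,
    p: pd.Series,
    fold_threshold: float = MRNA_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Partition probes into over / down / unchanged (inclusive fold boundary)."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1 (linear ratio)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cut = np.log2(fold_threshold)
    p = p.reindex(fold.index)
    direction = np.full(len(fold), UNCHANGED, dtype=object)
    sig = (p < alpha).to_numpy()
    direction[sig & (fold.to_numpy() >= cut)] = OVER
    direction[sig & (fold.to_numpy() <= -cut)] = DOWN
    return pd.Series(direction, index=fold.index)


def top_n_by_fold(
    fold: pd.Series,
    p: pd.Series,
    n: int = DEFAULT_TOP_N,
    direction: str = OVER,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """The n significant probes of the given sign with largest |log2FC|.

    Ties at the cut are broken by probe id (lexicographic), so the selection
    is deterministic.  Returns fewer than n when the supply is short.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in (OVER, DOWN):
        raise ValueError(f"direction must be over|down, got {direction!r}")
    p = p.reindex(fold.index)
    mask = (p < alpha) & ((fold > 0) if direction == OVER else (fold < 0))
    sub = fold[mask]
    order = sorted(sub.index, key=lambda pid: (-abs(sub[pid]), str(pid)))
    return order[:n]


def de_table(
    study: ExpressionStudy,
    fold_threshold: float = MRNA_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Convenience: probe_id, log2fc, p, direction for one study."""
    fold = log2_fold_change(study)
    p = welch_t(study)
    direction = call_directions(fold, p, fold_threshold=fold_threshold, alpha=alpha)
    return pd.DataFrame(
        {"probe_id": fold.index, "log2fc": fold.values, "p": p.values, "direction": direction.values}
    )


def calls_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Altered probes only (probe_id, direction) from a DE table."""
    keep = table[table["direction"].isin([OVER, DOWN])]
    return keep[["probe_id", "direction"]].reset_index(drop=True)
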