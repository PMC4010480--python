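"""Digital differential display (DDD) on EST library pools.

For each transcript cluster the fraction of expressed-sequence tags in a
normal library pool (A) is compared with a cancer pool (B).  A cluster is a
hit when Fisher's exact test on the 2x2 table (cluster vs rest, pool A vs
pool B) is significant and the fold difference exceeds a strict ratio
threshold (default >10).  The published screen reports the pool B / pool A
ratio; the default here is the direction-symmetric max(B/A, A/B) with the
direction recorded, since down-expressed DDD hits also appear in the
source tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RATIO_THRESHOLD = 10.0
DEFAULT_ALPHA = 0.05


@dataclass
class ESTPools:
    """Per-cluster EST counts in pool A (normal) and pool B (cancer)."""

    counts: pd.DataFrame  # cluster_id, count_A, count_B
    size_A: int
    size_B: int

    def __post_init__(self) -> None:
        if self.size_A <= 0 or self.size_B <= 0:
            raise ValueError("pool sizes must be positive")
        c = self.counts
        if (c["count_A"] < 0).any() or (c["count_B"] < 0).any():
            raise ValueError("negative EST counts")
        if (c["count_A"] > self.size_A).any() or (c["count_B"] > self.size_B).any():
            raise ValueError("cluster count exceeds pool size")
        if c["cluster_id"].duplicated().any():
            raise ValueError("duplicate cluster ids")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def ddd_screen(
    pools: ESTPools,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    ratio_mode: str = "symmetric",
) -> pd.DataFrame:
    """Fractions, fold difference, Fisher p and pass flag per cluster.

    ``ratio_mode="b_over_a"`` reproduces the one-directional published
    ratio (infinite when fraction_A = 0 and fraction_B > 0);
    ``"symmetric"`` (default) uses max(B/A, A/B) and records the
    direction.  The ratio test is strict: fold must exceed
    ``ratio_threshold``.  No pseudocounts are applied.
    """
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must be > 1")
    if ratio_mode not in ("b_over_a", "symmetric"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")

    c = pools.counts
    fa = c["count_A"].to_numpy(dtype=float) / pools.size_A
    fb = c["count_B"].to_numpy(dtype=float) / pools.size_B

    with np.errstate(divide="ignore", invalid="ignore"):
        b_over_a = np.where(fa > 0, fb / fa, np.where(fb > 0, np.inf, np.nan))
        a_over_b = np.where(fb > 0, fa / fb, np.where(fa > 0, np.inf, np.nan))
    if ratio_mode == "b_over_a":
        fold = b_over_a
    else:
        fold = np.fmax(b_over_a, a_over_b)
    direction = np.where(fb > fa, "over", np.where(fb < fa, "down", "none"))

    p = np.array(
        [
            fisher_exact_2x2(
                int(ca), pools.size_A - int(ca), int(cb), pools.size_B - int(cb)
            )
            for ca, cb in zip(c["count_A"], c["count_B"])
        ]
    )
    passes = (p < alpha) & (np.nan_to_num(fold, nan=0.0) > ratio_threshold)
    return pd.DataFrame(
        {
            "cluster_id": c["cluster_id"],
            "fraction_A": fa,
            "fraction_B": fb,
            "fold_difference": fold,
            "direction": direction,
            "p_value": p,
            "passes": passes,
        }
    )


def ddd_calls(results: pd.DataFrame) -> pd.DataFrame:
    """Passing clusters as (probe-style) call records: cluster_id, direction."""
    keep = results[results["passes"] & results["direction"].isin(["over", "down"])]
    return keep[["cluster_id", "direction"]].reset_index(drop=True)
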