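"""Motif scanning of promoter sets and common-regulator prediction.

A JASPAR-style position frequency matrix (4 rows, A/C/G/T) is turned into
a log2-odds position weight matrix with pseudocount smoothing; each
promoter is scored by its best hit over both strands on the relative
profile scale (s - s_min) / (s_max - s_min), so thresholds like "at least
99% relative profile score" are matrix-independent.  Enrichment of a
motif in an input promoter set against a genomic background is assessed
with a one-sample z-test on mean best-hit scores (an approximation of the
pscan statistic, whose exact internals are not published with the study
this package models).  Common regulators of a miRNA positional cluster
are motifs hitting every member promoter at the threshold; for mRNA sets,
motifs enriched (p below the selection level, default 0.1) in every
cancer's promoter set.

Promoter window conventions carried by :class:`PromoterSet`: -1 kb..0 of
the TSS for mRNAs, -3 kb..+1 kb for miRNAs (anchor coordinates are
caller-supplied; sequences are never fetched).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_RELATIVE_THRESHOLD = 0.99
DEFAULT_PSCAN_ALPHA = 0.1


@dataclass
class PWMModel:
    """Log2-odds matrix (positions x 4, columns A,C,G,T) with score range."""

    name: str
    matrix: np.ndarray
    s_min: float
    s_max: float
    pfm: np.ndarray | None = None

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement_matrix(self) -> np.ndarray:
        # reverse positions, swap A<->T and C<->G
        return self.matrix[::-1, ::-1]


@dataclass
class PromoterSet:
    """id -> DNA sequence over A,C,G,T,N with a declared TSS window."""

    sequences: dict[str, str]
    window: tuple[int, int] = (-1000, 0)

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if re.search(r"[^ACGTN]", seq.upper()):
                raise ValueError(f"{sid}: non-ACGTN characters")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class TFEnrichment:
    tf: str
    mean_input: float
    mean_background: float
    z: float
    p_value: float


def pfm_to_pwm(
    pfm: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: tuple[float, float, float, float] = UNIFORM_BG,
    name: str = "",
) -> PWMModel:
    """Counts -> log2-odds with the pseudocount split by background.

    Cell value: log2(((count + pc*bg) / (colsum + pc)) / bg).  s_min and
    s_max are the sums of per-position minima and maxima, the attainable
    score range used for relative scoring.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or 4 not in pfm.shape or pfm.size == 0:
        raise ValueError("PFM must be a non-empty 4xL or Lx4 matrix")
    if pfm.shape[0] == 4 and pfm.shape[1] != 4:
        pfm = pfm.T  # accept JASPAR row-per-base orientation
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background must sum to 1")
    colsum = pfm.sum(axis=1, keepdims=True)
    prob = (pfm + pseudocount * bg) / (colsum + pseudocount)
    matrix = np.log2(prob / bg)
    return PWMModel(
        name=name,
        matrix=matrix,
        s_min=float(matrix.min(axis=1).sum()),
        s_max=float(matrix.max(axis=1).sum()),
        pfm=pfm,
    )


def parse_jaspar_pfm(stream: IO[str] | Iterable[str]) -> list[PWMModel]:
    """Parse JASPAR flat PFM records (``>ID name`` then 4 base rows)."""
    models = []
    name, rows = "", []
    def flush():
        if rows:
            if len(rows) != 4:
                raise ValueError(f"{name or 'PFM'}: expected 4 base rows, got {len(rows)}")
            models.append(pfm_to_pwm(np.array(rows), name=name))
    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name, rows = line[1:].strip(), []
        else:
            nums = re.sub(r"^[ACGTacgt]\s*\[?|\]$", "", line)
            rows.append([float(x) for x in nums.replace("]", "").split()])
    flush()
    return models


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(encoded: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Scores of all windows (NaN where the window contains N)."""
    L = matrix.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (win >= 0).all(axis=1)
    scores = np.full(win.shape[0], np.nan)
    if valid.any():
        v = win[valid]
        scores[valid] = matrix[np.arange(L), v].sum(axis=1)
    return scores


def best_hit_relative_score(sequence: str, pwm: PWMModel) -> float:
    """Best two-strand hit on the relative profile scale, in [0, 1].

    Windows containing N are skipped; a sequence whose every window has an
    N scores 0.  A degenerate matrix (s_max == s_min) scores 1 by
    convention.  Sequences shorter than the motif raise.
    """
    L = len(pwm)
    seq = sequence.upper()
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} < motif length {L}")
    if pwm.s_max == pwm.s_min:
        return 1.0
    enc = _encode(seq)
    best = np.nanmax(
        np.concatenate(
            [
                _window_scores(enc, pwm.matrix),
                _window_scores(enc, pwm.reverse_complement_matrix()),
            ]
        ),
        initial=np.nan,
    )
    if np.isnan(best):
        return 0.0
    rel = (best - pwm.s_min) / (pwm.s_max - pwm.s_min)
    return float(min(max(rel, 0.0), 1.0))


def best_hit_scores(promoters: PromoterSet, pwm: PWMModel) -> pd.Series:
    return pd.Series(
        {sid: best_hit_relative_score(seq, pwm) for sid, seq in promoters.sequences.items()}
    )


def scan_threshold(
    promoters: PromoterSet,
    pwm: PWMModel,
    threshold: float = DEFAULT_RELATIVE_THRESHOLD,
) -> set[str]:
    """Promoter ids whose best hit is at least ``threshold`` (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    scores = best_hit_scores(promoters, pwm)
    return set(scores.index[scores >= threshold])


def pscan_ztest(
    input_set: PromoterSet, background: PromoterSet, pwm: PWMModel
) -> TFEnrichment:
    """One-sided z-test of mean best-hit scores, input vs background.

    z = (mean_input - mean_bg) / (sd_bg / sqrt(m)) with m = |input| and
    sd_bg the background sample standard deviation; upper-tail p from the
    standard normal.
    """
    if len(input_set) == 0:
        raise ValueError("empty input promoter set")
    s_in = best_hit_scores(input_set, pwm).to_numpy()
    s_bg = best_hit_scores(background, pwm).to_numpy()
    sd_bg = s_bg.std(ddof=1)
    if sd_bg == 0:
        raise ValueError("degenerate background: zero score variance")
    z = (s_in.mean() - s_bg.mean()) / (sd_bg / math.sqrt(len(s_in)))
    return TFEnrichment(
        tf=pwm.name,
        mean_input=float(s_in.mean()),
        mean_background=float(s_bg.mean()),
        z=float(z),
        p_value=float(stats.norm.sf(z)),
    )


def common_regulators(
    hits_by_group: Mapping[str, Mapping[str, set[str]]],
    members_by_group: Mapping[str, Iterable[str]],
    mode: str = "all_members",
    min_fraction: float = 1.0,
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-group common regulators plus the cross-group intersection.

    ``hits_by_group[group][tf]`` is the set of member promoters the motif
    hits at threshold.  Under ``all_members`` a TF is common to a group
    iff it hits every member (``threshold`` mode relaxes this to a
    fraction ``min_fraction``).  The cross-group set contains TFs common
    to at least two groups.
    """
    if mode not in ("all_members", "threshold"):
        raise ValueError(f"unknown mode {mode!r}")
    need = 1.0 if mode == "all_members" else min_fraction
    per_group: dict[str, set[str]] = {}
    for group, tf_hits in hits_by_group.items():
        members = set(members_by_group[group])
        if not members:
            per_group[group] = set()
            continue
        per_group[group] = {
            tf for tf, hits in tf_hits.items()
            if len(hits & members) / len(members) >= need
        }
    counts: dict[str, int] = {}
    for tfs in per_group.values():
        for tf in tfs:
            counts[tf] = counts.get(tf, 0) + 1
    shared = {tf for tf, c in counts.items() if c >= 2}
    return per_group, shared


def common_regulators_enrichment(
    pvalues_by_group: Mapping[str, Mapping[str, float]],
    alpha: float = DEFAULT_PSCAN_ALPHA,
) -> set[str]:
    """TFs enriched (p < alpha) in every group's promoter set."""
    groups = list(pvalues_by_group)
    if not groups:
        return set()
    common = set(pvalues_by_group[groups[0]])
    for g in groups[1:]:
        common &= set(pvalues_by_group[g])
    return {tf for tf in common if all(pvalues_by_group[g][tf] < alpha for g in groups)}


def read_fasta(stream: IO[str] | Iterable[str]) -> dict[str, str]:
    """Minimal FASTA reader for promoter files."""
    seqs: dict[str, str] = {}
    sid = None
    chunks: list[str] = []
    for line in stream:
        line = line.rstrip()
        if line.startswith(">"):
            if sid is not None:
                seqs[sid] = "".join(chunks)
            sid = line[1:].split()[0]
            chunks = []
        elif line:
            chunks.append(line)
    if sid is not None:
        seqs[sid] = "".join(chunks)
    return seqs
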