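"""Region participation scoring: the core susceptibility-region statistic.

For every cytogenetic band, altered-probeset calls are tallied over the n
cancer studies (FOR = over-expressed frequency, FDR = down-expressed
frequency, both summed across cancers) against the number of probesets the
chip annotates to that band (FTP, counted once per chip).  Participation
percentages are

    percent_over = 100 * FOR / (n * FTP)
    percent_down = 100 * FDR / (n * FTP)

and analogously FOC / FDC / FCTP at chromosome level.  Per chromosome and
direction, the k (default 5) bands with the highest percentage are the
potential cancer-susceptibility regions (PCSRs).  A goodness-of-fit
chi-square compares per-chromosome altered counts with expectation
proportional to chip content.

The percentage equations are printed as images in the source publication;
the 100*FOR/(n*FTP) form is reconstructed from the variable legend ("FOR
... summation of 11 HCs, n is the number of cancers") and the Table 1
footnote.  A ``denominator="pooled"`` flag drops the 1/n factor for
sensitivity analysis; rankings (hence PCSR membership) are identical under
both since n is constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import UNMAPPED, band_sort_key, chromosome_sort_key
from .diffexpr import DOWN, OVER

DEFAULT_K = 5


@dataclass
class RegionFrequencyTable:
    """Per-band altered/total probe counts with per-cancer breakdown.

    ``table``: band-level frequencies (chromosome, band, start, ftp,
    over_total, down_total).  ``per_cancer``: long table (chromosome, band,
    cancer, over, down).
    """

    table: pd.DataFrame
    per_cancer: pd.DataFrame
    n_cancers: int
    level: str = "region"  # or "chromosome"


def region_frequencies(
    calls: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    chip_probes: pd.DataFrame | None = None,
) -> RegionFrequencyTable:
    """Tally altered-probe calls per band per cancer plus the chip totals.

    ``calls`` maps cancer id -> DataFrame with columns probe_id, direction
    (over/down rows only are counted).  ``annotation`` maps probe_id to
    chromosome and band; ``chip_probes`` (defaults to ``annotation``)
    defines the chip universe used for FTP.  Every called probe must be on
    the chip; a cancer whose probes are disjoint from the chip indicates a
    chip mismatch and raises.  Unmapped probes are excluded from counting.
    """
    if chip_probes is None:
        chip_probes = annotation
    ann = annotation.set_index("probe_id")
    chip_ids = set(chip_probes["probe_id"])

    mapped_chip = chip_probes[chip_probes["band"] != UNMAPPED]
    ftp = (
        mapped_chip.groupby(["chromosome", "band"], sort=False)
        .size()
        .rename("ftp")
        .reset_index()
    )

    rows = []
    for cancer, table in calls.items():
        probes = set(table["probe_id"])
        if probes and not (probes & chip_ids):
            raise ValueError(
                f"cancer {cancer!r}: probe universe disjoint from chip (chip mismatch)"
            )
        unknown = probes - set(ann.index)
        if unknown:
            raise ValueError(
                f"cancer {cancer!r}: {len(unknown)} called probes missing from annotation"
            )
        sub = table[table["direction"].isin([OVER, DOWN])].copy()
        sub["band"] = ann.loc[sub["probe_id"], "band"].to_numpy()
        sub["chromosome"] = ann.loc[sub["probe_id"], "chromosome"].to_numpy()
        sub = sub[sub["band"] != UNMAPPED]
        if len(sub) == 0:
            continue
        tally = (
            sub.groupby(["chromosome", "band"])["direction"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=[OVER, DOWN], fill_value=0)
            .reset_index()
            .rename(columns={OVER: "over", DOWN: "down"})
        )
        tally["cancer"] = cancer
        rows.append(tally)

    per_cancer = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chromosome", "band", "over", "down", "cancer"])
    )
    totals = (
        per_cancer.groupby(["chromosome", "band"])[["over", "down"]].sum().reset_index()
        if len(per_cancer)
        else pd.DataFrame(columns=["chromosome", "band", "over", "down"])
    )
    table = ftp.merge(totals, on=["chromosome", "band"], how="left")
    for col in ("over", "down"):
        if col not in table.columns:
            table[col] = 0
        table[col] = pd.to_numeric(table[col], errors="coerce").fillna(0)
    table = table.rename(columns={"over": "over_total", "down": "down_total"})
    table[["over_total", "down_total"]] = table[["over_total", "down_total"]].astype(int)

    starts = None
    if "position" in chip_probes.columns:
        starts = mapped_chip.groupby("band")["position"].min()
    table["start"] = (
        table["band"].map(starts).fillna(0).astype(int) if starts is not None else 0
    )
    table = table.sort_values(
        ["chromosome", "start", "band"],
        key=lambda s: s.map(chromosome_sort_key) if s.name == "chromosome" else s,
    ).reset_index(drop=True)
    return RegionFrequencyTable(
        table=table[["chromosome", "band", "start", "ftp", "over_total", "down_total"]],
        per_cancer=per_cancer,
        n_cancers=len(calls),
    )


def chromosome_frequencies(freq: RegionFrequencyTable) -> RegionFrequencyTable:
    """Collapse a band-level table to chromosome level (FOC/FDC/FCTP)."""
    table = (
        freq.table.groupby("chromosome", sort=False)[["ftp", "over_total", "down_total"]]
        .sum()
        .reset_index()
    )
    table["band"] = table["chromosome"]
    table["start"] = 0
    per_cancer = (
        freq.per_cancer.groupby(["chromosome", "cancer"])[["over", "down"]]
        .sum()
        .reset_index()
        if len(freq.per_cancer)
        else freq.per_cancer
    )
    return RegionFrequencyTable(
        table=table[["chromosome", "band", "start", "ftp", "over_total", "down_total"]],
        per_cancer=per_cancer,
        n_cancers=freq.n_cancers,
        level="chromosome",
    )


def participation_percent(
    freq: RegionFrequencyTable,
    n_cancers: int | None = None,
    denominator: str = "per_cancer",
) -> pd.DataFrame:
    """Participation percentages per band (or chromosome).

    ``denominator="per_cancer"`` (default) divides by n*FTP per the
    published equations; ``"pooled"`` divides by FTP alone.  Regions with
    FTP=0 are omitted rather than scored 0, so they can never enter a
    top-k list.
    """
    n = freq.n_cancers if n_cancers is None else n_cancers
    if n < 1:
        raise ValueError("n_cancers must be >= 1")
    if denominator not in ("per_cancer", "pooled"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    t = freq.table[freq.table["ftp"] > 0].copy()
    denom = t["ftp"] * (n if denominator == "per_cancer" else 1)
    t["percent_over"] = 100.0 * t["over_total"] / denom
    t["percent_down"] = 100.0 * t["down_total"] / denom
    return t[["chromosome", "band", "start", "percent_over", "percent_down"]].reset_index(
        drop=True
    )


@dataclass
class PCSRSet:
    """Top-k regions per chromosome and direction, with their percentages."""

    k: int
    over: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    down: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def bands(self) -> set[str]:
        """All selected band labels, either direction."""
        out: set[str] = set()
        for d in (self.over, self.down):
            for entries in d.values():
                out.update(b for b, _ in entries)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for direction, per_chrom in (("over", self.over), ("down", self.down)):
            for chrom, entries in per_chrom.items():
                for rank, (band, pct) in enumerate(entries, start=1):
                    rows.append((chrom, direction, rank, band, pct))
        return pd.DataFrame(
            rows, columns=["chromosome", "direction", "rank", "band", "percent"]
        )


def select_pcsrs(scores: pd.DataFrame, k: int = DEFAULT_K) -> PCSRSet:
    """Per chromosome and direction, the k highest-percentage regions.

    Ties are broken by genomic order (interval start, then band label);
    chromosomes with fewer scored regions return shorter lists.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    result = PCSRSet(k=k)
    for chrom, sub in scores.groupby("chromosome", sort=False):
        for direction, store in (("percent_over", result.over), ("percent_down", result.down)):
            ranked = sorted(
                sub.itertuples(index=False),
                key=lambda r: (-getattr(r, direction), r.start, r.band),
            )[:k]
            store[str(chrom)] = [(r.band, float(getattr(r, direction))) for r in ranked]
    return result


def chromosome_chi_square(
    freq: RegionFrequencyTable, direction: str = OVER
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of per-chromosome altered counts.

    Observed counts are FOC (or FDC); expected counts are proportional to
    FCTP (total chip probes per chromosome).  Returns (statistic, df, p).
    """
    table = freq.table if freq.level == "chromosome" else chromosome_frequencies(freq).table
    col = "over_total" if direction == OVER else "down_total"
    observed = table[col].to_numpy(dtype=float)
    weights = table["ftp"].to_numpy(dtype=float)
    if len(observed) < 2:
        raise ValueError("need >= 2 chromosomes")
    total = observed.sum()
    if total <= 0:
        raise ValueError("no altered probes observed")
    expected = total * weights / weights.sum()
    if (expected == 0).any():
        zero = table.loc[expected == 0, "chromosome"].tolist()
        raise ValueError(
            f"expected count 0 for chromosomes {zero}; merge or exclude them first"
        )
    stat, p = stats.chisquare(observed, expected)
    return float(stat), len(observed) - 1, float(p)
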