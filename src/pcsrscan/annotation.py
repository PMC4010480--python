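"""Cytogenetic band maps and probe-to-band assignment.

Coordinates follow the UCSC cytoBand dialect: 0-based, half-open
``[start, end)`` intervals.  Band labels are the chromosome name (without
any ``chr`` prefix) concatenated with the arm/band name, e.g. ``1p31.2``.
Probes are treated as point features; a probe lies in the unique band whose
interval contains its position, or is ``unmapped``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNMAPPED = "unmapped"

#: canonical sort order for human-style chromosome labels
CHROMOSOME_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y", "M"]

_BAND_RE = re.compile(r"^(chr)?([0-9]+|[XYMxym])([pq].*)$")


def normalize_chromosome(name: str) -> str:
    """Strip any ``chr`` prefix and upper-case letter chromosomes (X, Y, M)."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.upper() if name.lower() in ("x", "y", "m") else name


def normalize_band(label: str) -> str:
    """Normalize a band label: drop ``chr``, upper-case X/Y/M, keep band text.

    ``chr12p13.31`` -> ``12p13.31``; ``chryq11.22`` -> ``Yq11.22``.
    Labels that do not look like chromosome+arm are returned stripped as-is.
    """
    label = str(label).strip()
    m = _BAND_RE.match(label)
    if m is None:
        return label
    chrom = m.group(2)
    chrom = chrom.upper() if chrom.lower() in ("x", "y", "m") else chrom
    return chrom + m.group(3)


def chromosome_sort_key(chrom: str):
    chrom = normalize_chromosome(chrom)
    try:
        return (CHROMOSOME_ORDER.index(chrom), chrom)
    except ValueError:
        return (len(CHROMOSOME_ORDER), chrom)


def band_sort_key(band: str, cmap: "CytobandMap | None" = None):
    """Genomic sort key for a band label: (chromosome rank, interval start).

    Without a map, falls back to the label text after the chromosome token,
    which preserves chromosome grouping and gives a deterministic order.
    """
    m = _BAND_RE.match(band)
    chrom, rest = (m.group(2), m.group(3)) if m else (band, "")
    key = chromosome_sort_key(chrom)
    if cmap is not None:
        start = cmap.band_start(normalize_band(band))
        if start is not None:
            return (*key, 0, start)
    return (*key, 1, rest)


class CytobandValidationError(ValueError):
    pass


@dataclass
class CytobandMap:
    """Ordered, validated cytogenetic intervals.

    ``entries`` has columns ``chromosome`` (no ``chr`` prefix), ``start``,
    ``end`` (0-based half-open), ``band`` (full label, e.g. ``1p31.2``) and
    ``stain``.
    """

    entries: pd.DataFrame
    _starts: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.entries.reset_index(drop=True)
        required = {"chromosome", "start", "end", "band"}
        missing = required - set(df.columns)
        if missing:
            raise CytobandValidationError(f"missing columns: {sorted(missing)}")
        if "stain" not in df.columns:
            df["stain"] = ""
        bad = df[df["start"] >= df["end"]]
        if len(bad):
            raise CytobandValidationError(
                f"start >= end in rows: {bad.index.tolist()}"
            )
        for chrom, sub in df.groupby("chromosome", sort=False):
            sub = sub.sort_values("start")
            overlap = sub["start"].values[1:] < sub["end"].values[:-1]
            if overlap.any():
                rows = sub.index[1:][overlap].tolist()
                raise CytobandValidationError(
                    f"overlapping intervals on chromosome {chrom}, rows {rows}"
                )
            if sub["band"].duplicated().any():
                dup = sub.loc[sub["band"].duplicated(), "band"].tolist()
                raise CytobandValidationError(
                    f"duplicate band labels on chromosome {chrom}: {dup}"
                )
        df = df.sort_values(
            ["chromosome", "start"],
            key=lambda s: s.map(chromosome_sort_key) if s.name == "chromosome" else s,
        ).reset_index(drop=True)
        self.entries = df
        self._index = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub["band"].to_numpy())
            for chrom, sub in df.groupby("chromosome", sort=False)
        }
        self._starts = dict(zip(df["band"], df["start"]))
        self._warned_chroms: set[str] = set()

    @property
    def bands(self) -> list[str]:
        return self.entries["band"].tolist()

    def band_start(self, band: str):
        return self._starts.get(band)

    def locate(self, chromosome: str, position: int) -> str:
        """Band label containing ``position`` on ``chromosome``, or ``unmapped``."""
        if position < 0:
            raise ValueError(f"negative position: {position}")
        chrom = normalize_chromosome(chromosome)
        idx = self._index.get(chrom)
        if idx is None:
            if chrom not in self._warned_chroms:
                logger.warning("unknown chromosome %r; probes there are unmapped", chrom)
                self._warned_chroms.add(chrom)
            return UNMAPPED
        starts, ends, bands = idx
        i = np.searchsorted(starts, position, side="right") - 1
        if i >= 0 and position < ends[i]:
            return str(bands[i])
        return UNMAPPED


def parse_cytoband_file(stream: IO[str] | Iterable[str]) -> CytobandMap:
    """Read a UCSC-style cytoBand file (chrom, start, end, name, gieStain).

    The ``chr`` prefix is stripped; band labels become chromosome + name.
    Overlapping or inverted intervals raise :class:`CytobandValidationError`
    naming the offending lines.
    """
    rows = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise CytobandValidationError(
                f"line {lineno}: expected >=4 tab-separated fields, got {len(fields)}"
            )
        chrom = normalize_chromosome(fields[0])
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise CytobandValidationError(f"line {lineno}: bad coordinates") from exc
        stain = fields[4] if len(fields) > 4 else ""
        rows.append((chrom, start, end, chrom + fields[3], stain, lineno))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "band", "stain", "line"])
    try:
        return CytobandMap(df.drop(columns="line"))
    except CytobandValidationError as exc:
        raise CytobandValidationError(f"{exc} (row indices refer to input order)") from None


def locate(chromosome: str, position: int, cmap: CytobandMap) -> str:
    return cmap.locate(chromosome, position)


def annotate_probes(probes: pd.DataFrame, cmap: CytobandMap) -> pd.DataFrame:
    """Fill in a ``band`` column via :func:`locate`; row count preserved.

    ``probes`` needs ``chromosome`` and ``position`` columns; probes given
    as intervals (``start``/``end`` instead of ``position``) are treated as
    point features at their midpoint.  Probes outside every band keep the
    explicit ``unmapped`` marker.
    """
    out = probes.copy()
    if "position" not in out.columns and {"start", "end"} <= set(out.columns):
        out["position"] = (out["start"] + out["end"]) // 2
    out["chromosome"] = out["chromosome"].map(normalize_chromosome)
    out["band"] = [
        cmap.locate(c, p) for c, p in zip(out["chromosome"], out["position"])
    ]
    return out


def read_probe_annotation(path) -> pd.DataFrame:
    """Probe annotation TSV: probe_id, gene_symbol, rna_class, chromosome, position."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"duplicate probe ids: {dup}")
    return df
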