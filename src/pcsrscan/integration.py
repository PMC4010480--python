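"""Cross-cancer synthesis of altered-RNA evidence.

Per-cancer direction calls from microarray analysis and from digital
differential display are merged per gene with union semantics.  Genes
altered in at least ``min_cancers`` distinct cancers (default 6 of 11) are
the common altered RNAs.  Each gets an expression-pattern class:

* Class I  — over-expressed wherever altered (no opposing call),
* Class II — down-expressed wherever altered,
* Class III — mixed directions across (or within) cancers.

"Majority" over/down in the source tables is operationalized as purity:
every direction-pure row in those tables is Class I/II while every row
with at least one opposing call is Class III.  miRNAs sharing one cytoband
(>=2 members) form positional clusters; records and clusters are flagged
when their band is a selected susceptibility region.  Small printed
regulatory subnetworks are summarized by node/edge counts around a focus
entity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .annotation import band_sort_key, normalize_band

logger = logging.getLogger(__name__)

MICROARRAY = "microarray"
DDD = "DDD"

CALL_COLUMNS = ["gene_symbol", "cancer", "source", "direction"]


@dataclass
class AlteredRNARecord:
    """One gene/miRNA with its per-cancer direction evidence."""

    gene_symbol: str
    band: str
    calls: dict[str, set[tuple[str, str]]]  # cancer -> {(source, direction)}
    on_pcsr: bool = False

    @property
    def n_cancers_altered(self) -> int:
        return sum(1 for v in self.calls.values() if v)

    def directions(self, cancer: str) -> set[str]:
        return {d for _, d in self.calls.get(cancer, set())}


@dataclass
class MiRNACluster:
    """>=2 distinct miRNAs sharing one cytogenetic band."""

    band: str
    members: list[str]
    directions_by_cancer: dict[str, set[str]] = field(default_factory=dict)
    on_pcsr: bool = False


def collect_common(
    calls: pd.DataFrame,
    min_cancers: int = 6,
    n_cancers: int = 11,
    locations: Mapping[str, str] | None = None,
) -> list[AlteredRNARecord]:
    """Records for genes altered in >= min_cancers distinct cancers.

    ``calls`` is a long table with columns gene_symbol, cancer, source
    (microarray/DDD), direction (over/down).  Any direction and any
    evidence source counts a cancer as altered.
    """
    if min_cancers > n_cancers:
        raise ValueError("min_cancers cannot exceed n_cancers")
    records = []
    locations = locations or {}
    for gene, sub in calls.groupby("gene_symbol", sort=True):
        per_cancer: dict[str, set[tuple[str, str]]] = {}
        for row in sub.itertuples(index=False):
            per_cancer.setdefault(row.cancer, set()).add((row.source, row.direction))
        if sum(1 for v in per_cancer.values() if v) >= min_cancers:
            records.append(
                AlteredRNARecord(
                    gene_symbol=str(gene),
                    band=normalize_band(locations.get(str(gene), "")),
                    calls=per_cancer,
                )
            )
    return records


def assign_class(record: AlteredRNARecord) -> str:
    """Expression-pattern class I / II / III (purity rule)."""
    if not any(record.calls.values()):
        raise ValueError(f"{record.gene_symbol}: record has no calls")
    u = d = m = 0
    for cancer in record.calls:
        dirs = record.directions(cancer)
        if dirs == {"over"}:
            u += 1
        elif dirs == {"down"}:
            d += 1
        elif dirs:
            m += 1
    if d == 0 and m == 0:
        return "I"
    if u == 0 and m == 0:
        return "II"
    return "III"


def count_direction(record: AlteredRNARecord, direction: str) -> int:
    """Number of distinct cancers with >=1 call of the given direction."""
    return sum(1 for cancer in record.calls if direction in record.directions(cancer))


def flag_pcsr(
    records: Iterable[AlteredRNARecord | MiRNACluster],
    pcsr_bands: Iterable[str],
) -> list[AlteredRNARecord | MiRNACluster]:
    """Set ``on_pcsr`` where the record's band is a selected risk region."""
    bands = {normalize_band(b) for b in pcsr_bands}
    out = list(records)
    for rec in out:
        band = normalize_band(rec.band)
        rec.on_pcsr = band in bands
        if not rec.on_pcsr and band and band not in bands:
            logger.debug("band %s not in PCSR set", band)
    return out


def detect_mirna_clusters(records: Iterable[AlteredRNARecord]) -> list[MiRNACluster]:
    """Positional clusters: one per band carrying >=2 distinct miRNAs.

    Member lists keep input order; clusters are sorted genomically.
    Per-cancer directions are the union over members.
    """
    by_band: dict[str, list[AlteredRNARecord]] = {}
    for rec in records:
        band = normalize_band(rec.band)
        if band:
            by_band.setdefault(band, []).append(rec)
    clusters = []
    for band, members in by_band.items():
        names = list(dict.fromkeys(r.gene_symbol for r in members))
        if len(names) < 2:
            continue
        directions: dict[str, set[str]] = {}
        for r in members:
            for cancer in r.calls:
                directions.setdefault(cancer, set()).update(r.directions(cancer))
        clusters.append(MiRNACluster(band=band, members=names, directions_by_cancer=directions))
    clusters.sort(key=lambda c: band_sort_key(c.band))
    return clusters


def network_summary(
    edges: pd.DataFrame, focus: str, radius: int = 1
) -> tuple[int, int, list[str]]:
    """Induced subgraph around ``focus`` within ``radius`` hops.

    ``edges`` has columns source, effect, target; reachability ignores
    edge direction.  Returns (node count, edge count within the node set,
    sorted member list).  An absent focus yields an empty result.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    g = nx.DiGraph()
    for row in edges.itertuples(index=False):
        if row.source == row.target:
            raise ValueError(f"self-loop on {row.source!r}")
        g.add_edge(row.source, row.target, effect=row.effect)
    if focus not in g:
        logger.warning("focus %r absent from edge table", focus)
        return 0, 0, []
    lengths = nx.single_source_shortest_path_length(g.to_undirected(as_view=True), focus, cutoff=radius)
    nodes = set(lengths)
    n_edges = sum(1 for u, v in g.edges if u in nodes and v in nodes)
    return len(nodes), n_edges, sorted(nodes)


def records_to_frame(records: Iterable[AlteredRNARecord], cancers: list[str]) -> pd.DataFrame:
    """Report table: gene, band, pcsr flag, per-cancer direction marks, class."""
    rows = []
    for rec in records:
        row = {
            "gene_symbol": rec.gene_symbol,
            "band": rec.band,
            "on_pcsr": int(rec.on_pcsr),
            "n_cancers_altered": rec.n_cancers_altered,
            "expression_class": assign_class(rec),
        }
        for cancer in cancers:
            dirs = rec.directions(cancer)
            row[cancer] = "/".join(sorted(dirs)) if dirs else ""
        rows.append(row)
    columns = ["gene_symbol", "band", "on_pcsr", "n_cancers_altered",
               "expression_class"] + list(cancers)
    return pd.DataFrame(rows, columns=columns)
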