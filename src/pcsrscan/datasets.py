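"""Bundled reference tables transcribed from the published cross-cancer study.

Three small TSVs ship with the package (see ``data/SHA256SUMS``):

* ``common_mrnas.tsv`` — the common altered mRNAs with per-cancer
  microarray (M) / digital-differential-display (D) direction marks, the
  printed cytoband, risk-region flag and expression class.
* ``common_mirnas.tsv`` — the common altered miRNAs across 15 cancers
  with per-cancer direction marks, cytoband and risk-region flag.
* ``ddx5_edges.tsv`` — the four printed regulatory relations of the DDX5
  subnetwork.

Cells hold ``up``, ``down``, ``up/down`` (both observed) or empty.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .integration import DDD, MICROARRAY, AlteredRNARecord

MRNA_CANCERS = [
    "Breast", "Endometrial", "Ovarian", "Prostate", "Testicular", "Colorectal",
    "Liver", "Gastric", "Pancreatic", "Glioblastoma", "Lung",
]
MIRNA_CANCERS = [
    "Breast", "Cervical", "Endometrial", "Ovarian", "Prostate", "Testicular",
    "Renal", "Colorectal", "Gastric", "Liver", "Pancreatic", "Glioblastoma",
    "Lung", "IntestinalNeuroendocrine", "Bladder",
]


def _path(name: str):
    return resources.files("pcsrscan").joinpath("data", name)


def verify_checksums() -> dict[str, bool]:
    """Recompute SHA256 digests of the bundled tables against SHA256SUMS."""
    expected = {}
    for line in _path("SHA256SUMS").read_text().splitlines():
        digest, name = line.split()
        expected[name] = digest
    return {
        name: hashlib.sha256(_path(name).read_bytes()).hexdigest() == digest
        for name, digest in expected.items()
    }


def _directions(cell) -> list[str]:
    if not isinstance(cell, str) or not cell:
        return []
    return [{"up": "over", "down": "down"}[tok] for tok in cell.split("/")]


def load_common_mrna_table() -> pd.DataFrame:
    with _path("common_mrnas.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_common_mirna_table() -> pd.DataFrame:
    with _path("common_mirnas.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def common_mrna_records() -> tuple[list[AlteredRNARecord], pd.DataFrame]:
    """The mRNA table as AlteredRNARecord objects plus the raw frame.

    Evidence columns ``<Cancer>_M`` / ``<Cancer>_D`` become (source,
    direction) call sets per cancer.
    """
    df = load_common_mrna_table()
    records = []
    for row in df.itertuples(index=False):
        calls: dict[str, set[tuple[str, str]]] = {}
        for cancer in MRNA_CANCERS:
            found = set()
            for suffix, source in (("M", MICROARRAY), ("D", DDD)):
                for d in _directions(getattr(row, f"{cancer}_{suffix}")):
                    found.add((source, d))
            if found:
                calls[cancer] = found
        records.append(
            AlteredRNARecord(gene_symbol=row.gene_symbol, band=row.location, calls=calls)
        )
    return records, df


def common_mirna_records() -> tuple[list[AlteredRNARecord], pd.DataFrame]:
    """The miRNA table as AlteredRNARecord objects plus the raw frame."""
    df = load_common_mirna_table()
    records = []
    for row in df.itertuples(index=False):
        calls: dict[str, set[tuple[str, str]]] = {}
        for cancer in MIRNA_CANCERS:
            found = {(MICROARRAY, d) for d in _directions(getattr(row, cancer))}
            if found:
                calls[cancer] = found
        records.append(
            AlteredRNARecord(gene_symbol=row.mirna, band=row.location, calls=calls)
        )
    return records, df


def published_pcsr_bands() -> set[str]:
    """Band labels flagged as risk regions in the bundled tables."""
    from .annotation import normalize_band

    bands: set[str] = set()
    for df, col in ((load_common_mrna_table(), "location"), (load_common_mirna_table(), "location")):
        flagged = df[df["pcsr"] == 1]
        bands.update(normalize_band(b) for b in flagged[col])
    return bands


def ddx5_subnetwork_edges() -> pd.DataFrame:
    with _path("ddx5_edges.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
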