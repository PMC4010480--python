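"""Plain-text readers/writers for the pipeline's on-disk formats.

Everything is TSV or FASTA so runs are diffable and reproducible; floats
are written with %.6g so repeated runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ddd import ESTPools
from .diffexpr import ExpressionStudy
from .promoter_scan import PromoterSet

FLOAT_FORMAT = "%.6g"


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_cytoband(cmap, path: Path) -> None:
    rows = cmap.entries.copy()
    rows["chrom"] = "chr" + rows["chromosome"].astype(str)
    rows["name"] = [
        b[len(c):] for b, c in zip(rows["band"], rows["chromosome"].astype(str))
    ]
    out = rows[["chrom", "start", "end", "name", "stain"]]
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, header=False)


def write_expression_study(study: ExpressionStudy, matrix_path: Path, samples_path: Path) -> None:
    matrix_path.parent.mkdir(parents=True, exist_ok=True)
    study.matrix.to_csv(matrix_path, sep="\t", index_label="probe_id", float_format=FLOAT_FORMAT)
    sheet = pd.DataFrame(
        {"sample_id": study.group.index, "group": study.group.values, "cancer_id": study.cancer_id}
    )
    write_tsv(sheet, samples_path)


def read_expression_study(matrix_path: Path, samples_path: Path) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    sheet = pd.read_csv(samples_path, sep="\t")
    cancer = str(sheet["cancer_id"].iloc[0])
    group = pd.Series(sheet["group"].values, index=sheet["sample_id"].values)
    return ExpressionStudy(cancer_id=cancer, matrix=matrix, group=group)


def write_est(pools: ESTPools, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"#size_A={pools.size_A}\tsize_B={pools.size_B}\n")
        pools.counts.to_csv(fh, sep="\t", index=False)


def read_est(path: Path) -> ESTPools:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
        sizes = dict(kv.split("=") for kv in header.split("\t"))
        counts = pd.read_csv(fh, sep="\t")
    return ESTPools(counts=counts, size_A=int(sizes["size_A"]), size_B=int(sizes["size_B"]))


def write_fasta(seqs: dict[str, str], path: Path, width: int = 70) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_promoters(path: Path, window=(-1000, 0)) -> PromoterSet:
    from .promoter_scan import read_fasta

    with open(path) as fh:
        return PromoterSet(read_fasta(fh), window=window)
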