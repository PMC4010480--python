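"""End-to-end orchestration: simulate -> call -> score -> integrate -> report.

``run_pipeline`` wires the stages together over synthetic inputs and
writes the report tables the analysis is organized around: per-cancer DE
tables, the top-k risk-region table under both thresholding modes
(symmetric fold cutoff and top-N-by-fold), chromosome participation with
the goodness-of-fit chi-square, the EST digital-differential-display
screen, the cross-cancer common-RNA table with expression classes and
risk-region flags, miRNA positional clusters, and motif-enrichment
results — plus a manifest with the configuration hash so a run is fully
reproducible.  All randomness lives in the synthetic generators; the
analysis stages are deterministic, so one (config, seed) pair yields
byte-identical output directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import UNMAPPED
from .ddd import ddd_screen
from .diffexpr import (
    DEFAULT_ALPHA,
    DEFAULT_TOP_N,
    MIRNA_FOLD,
    MRNA_FOLD,
    TRACE_FOLD,
    call_directions,
    log2_fold_change,
    top_n_by_fold,
    welch_t,
)
from .integration import (
    collect_common,
    detect_mirna_clusters,
    flag_pcsr,
    records_to_frame,
)
from .io import write_tsv
from .promoter_scan import pscan_ztest, scan_threshold
from .region_scoring import (
    DEFAULT_K,
    chromosome_chi_square,
    chromosome_frequencies,
    participation_percent,
    region_frequencies,
    select_pcsrs,
)
from .synthetic import (
    SimulationConfig,
    cancer_ids,
    demo_pwm,
    generate_est,
    generate_expression,
    generate_genome,
    generate_promoters,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis thresholds; defaults are the published operating point."""

    mrna_fold: float = MRNA_FOLD
    mirna_fold: float = MIRNA_FOLD
    trace_fold: float = TRACE_FOLD
    alpha: float = DEFAULT_ALPHA
    top_n: int = DEFAULT_TOP_N
    min_cancers: int = 6
    k: int = DEFAULT_K
    ddd_ratio: float = 10.0
    ddd_alpha: float = 0.05
    ddd_ratio_mode: str = "symmetric"
    pscan_alpha: float = 0.1
    relative_score: float = 0.99
    denominator: str = "per_cancer"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _config_hash(sim: SimulationConfig, run: RunConfig) -> str:
    blob = json.dumps(
        {"sim": dataclasses.asdict(sim), "run": dataclasses.asdict(run)},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def de_calls_for_study(study, annotation, run: RunConfig, fold_mode: str = "fold"):
    """Direction calls for one study, thresholded per RNA class.

    ``fold_mode="fold"`` applies the symmetric cutoffs (2-fold mRNA,
    1.5-fold miRNA); ``"top_n"`` keeps the run.top_n significant probes
    per direction with the largest |log2FC|; ``"trace"`` applies the
    relaxed tracing cutoff to all probes.
    """
    fold = log2_fold_change(study)
    p = welch_t(study)
    rna_class = annotation.set_index("probe_id")["rna_class"].reindex(fold.index)
    if fold_mode == "top_n":
        chosen: dict[str, str] = {}
        for direction in ("over", "down"):
            for pid in top_n_by_fold(fold, p, n=run.top_n, direction=direction, alpha=run.alpha):
                chosen[pid] = direction
        calls = pd.DataFrame(
            {"probe_id": list(chosen), "direction": list(chosen.values())}
        )
        return fold, p, calls
    direction = pd.Series("unchanged", index=fold.index, dtype=object)
    for cls, threshold in (("mRNA", run.mrna_fold), ("miRNA", run.mirna_fold)):
        mask = (rna_class == cls).to_numpy()
        if fold_mode == "trace":
            threshold = run.trace_fold
        if mask.any():
            direction[mask] = call_directions(
                fold[mask], p[mask], fold_threshold=threshold, alpha=run.alpha
            )
    altered = direction[direction.isin(["over", "down"])]
    calls = pd.DataFrame({"probe_id": altered.index, "direction": altered.values})
    return fold, p, calls


def _pcsr_stage(calls_by_cancer, annotation, run: RunConfig):
    freq = region_frequencies(calls_by_cancer, annotation)
    scores = participation_percent(freq, denominator=run.denominator)
    pcsrs = select_pcsrs(scores, k=run.k)
    return freq, scores, pcsrs


def run_pipeline(
    sim: SimulationConfig, run: RunConfig | None = None, outdir: str | Path = "pcsr_run"
) -> Path:
    """Execute every stage on synthetic inputs; return the output directory."""
    run = run or RunConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        cmap, annotation = generate_genome(sim)
        studies, truth = generate_expression(sim, annotation)
        write_tsv(annotation, out / "probe_annotation.tsv")
        write_tsv(truth, out / "planted_truth.tsv")

        stage = "differential_expression"
        calls_fold, calls_top, calls_trace = {}, {}, {}
        for cid in cancer_ids(sim):
            study = studies[cid]
            fold, p, calls = de_calls_for_study(study, annotation, run, "fold")
            calls_fold[cid] = calls
            direction = pd.Series("unchanged", index=fold.index, dtype=object)
            direction[calls.set_index("probe_id").index] = calls.set_index("probe_id")["direction"]
            write_tsv(
                pd.DataFrame(
                    {"probe_id": fold.index, "log2fc": fold.values, "p": p.values,
                     "direction": direction.values}
                ),
                out / "de" / f"{cid}.tsv",
            )
            _, _, calls_top[cid] = de_calls_for_study(study, annotation, run, "top_n")
            _, _, calls_trace[cid] = de_calls_for_study(study, annotation, run, "trace")
        logger.info("DE: %s altered calls (fold mode)",
                    sum(len(c) for c in calls_fold.values()))

        stage = "region_scoring"
        freq, scores, pcsrs = _pcsr_stage(calls_fold, annotation, run)
        write_tsv(pcsrs.to_frame(), out / "regions_fold.tsv")
        _, _, pcsrs_top = _pcsr_stage(calls_top, annotation, run)
        write_tsv(pcsrs_top.to_frame(), out / "regions_top200.tsv")

        chrom = chromosome_frequencies(freq)
        write_tsv(
            participation_percent(chrom, denominator=run.denominator)
            .drop(columns=["band", "start"]),
            out / "chromosome_participation.tsv",
        )
        chi_rows = []
        for direction in ("over", "down"):
            try:
                stat, df, p_value = chromosome_chi_square(chrom, direction)
            except ValueError as exc:
                logger.warning("chi-square (%s) skipped: %s", direction, exc)
                stat = df = p_value = float("nan")
            chi_rows.append((direction, stat, df, p_value))
        write_tsv(
            pd.DataFrame(chi_rows, columns=["direction", "statistic", "df", "p_value"]),
            out / "chromosome_chi_square.tsv",
        )

        stage = "ddd"
        pools, est_truth = generate_est(sim)
        ddd_table = ddd_screen(
            pools, ratio_threshold=run.ddd_ratio, alpha=run.ddd_alpha,
            ratio_mode=run.ddd_ratio_mode,
        )
        write_tsv(ddd_table, out / "ddd.tsv")

        stage = "integration"
        gene_of = annotation.set_index("probe_id")["gene_symbol"]
        band_of_gene = annotation.set_index("gene_symbol")["band"].to_dict()
        long_rows = []
        for cid, calls in calls_trace.items():
            sub = calls.copy()
            sub["gene_symbol"] = gene_of.reindex(sub["probe_id"]).values
            sub["cancer"] = cid
            sub["source"] = "microarray"
            long_rows.append(sub[["gene_symbol", "cancer", "source", "direction"]])
        long_calls = pd.concat(long_rows, ignore_index=True) if long_rows else pd.DataFrame(
            columns=["gene_symbol", "cancer", "source", "direction"]
        )
        min_cancers = min(run.min_cancers, sim.n_cancers)
        if min_cancers < run.min_cancers:
            logger.info("min_cancers clamped to %d (only %d cancers simulated)",
                        min_cancers, sim.n_cancers)
        records = collect_common(
            long_calls, min_cancers=min_cancers, n_cancers=sim.n_cancers,
            locations=band_of_gene,
        )
        records = [r for r in records if r.band != UNMAPPED]
        flag_pcsr(records, pcsrs.bands)
        write_tsv(
            records_to_frame(records, cancer_ids(sim)), out / "common_rnas.tsv"
        )
        rna_class_of = annotation.set_index("gene_symbol")["rna_class"].to_dict()
        mirna_records = [r for r in records if rna_class_of.get(r.gene_symbol) == "miRNA"]
        clusters = detect_mirna_clusters(mirna_records)
        flag_pcsr(clusters, pcsrs.bands)
        write_tsv(
            pd.DataFrame(
                [
                    {"band": c.band, "n_members": len(c.members),
                     "members": ",".join(c.members), "on_pcsr": int(c.on_pcsr)}
                    for c in clusters
                ],
                columns=["band", "n_members", "members", "on_pcsr"],
            ),
            out / "mirna_clusters.tsv",
        )

        stage = "promoters"
        planted = demo_pwm("PLANTED")
        control = demo_pwm("CONTROL")
        # the control motif is the planted one with shuffled columns: same
        # information content, different consensus, absent from the input
        control.matrix = control.matrix[:, [1, 3, 0, 2]]
        inp, bg, prom_truth = generate_promoters(sim, planted)
        tf_rows = []
        for pwm in (planted, control):
            enr = pscan_ztest(inp, bg, pwm)
            hits = scan_threshold(inp, pwm, threshold=run.relative_score)
            tf_rows.append(
                {"tf": pwm.name, "mean_input": enr.mean_input,
                 "mean_background": enr.mean_background, "z": enr.z,
                 "p_value": enr.p_value, "selected": int(enr.p_value < run.pscan_alpha),
                 "n_hits": len(hits)}
            )
        write_tsv(pd.DataFrame(tf_rows), out / "tf_enrichment.tsv")

        stage = "manifest"
        manifest = {
            "package": "pcsrscan",
            "version": __version__,
            "config_hash": _config_hash(sim, run),
            "sim": dataclasses.asdict(sim),
            "run": dataclasses.asdict(run),
            "counts": {
                "probes": int(len(annotation)),
                "altered_calls_fold": int(sum(len(c) for c in calls_fold.values())),
                "common_rnas": len(records),
                "mirna_clusters": len(clusters),
                "ddd_hits": int(ddd_table["passes"].sum()),
                "planted_est_clusters": len(est_truth),
                "planted_promoters": int(len(prom_truth)),
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1, default=str)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
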