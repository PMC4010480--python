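"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate, at desk scale, the data the pipeline was designed
for: RMA-normalized log2 microarray matrices for several cancers with
case/control groups, a cytoband map with probe annotations, EST library
pools, and promoter sequences.  Region-level signal is planted by shifting
case-group means for a fraction of the probes in chosen bands, in a chosen
subset of cancers — risk regions in the real data are not altered in every
cancer, and the planted truth tables make recall/precision exactly
computable for every downstream stage.

Every generator is a pure function of (config, seed): the same
:class:`SimulationConfig` reproduces outputs bit-identically.  Default
simulation size (5 chromosomes x 8 bands x 40 probes, 11 cancers, 5
samples per group, noise SD 0.25 log2 units, three planted bands with
effect 1.5 log2 over 30% of band probes in 8 of 11 cancers) is the
reference condition used throughout the test-suite power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import CytobandMap
from .ddd import ESTPools
from .diffexpr import ExpressionStudy
from .promoter_scan import ALPHABET, PromoterSet, PWMModel


@dataclass
class PlantedRegion:
    band: str
    direction: str = "over"
    effect: float = 1.5  # log2 shift applied to case samples
    fraction: float = 0.3  # fraction of band probes altered
    n_cancers_affected: int = 8


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 5
    bands_per_chromosome: int = 8
    probes_per_band: int = 40
    band_length: int = 1_000_000
    n_cancers: int = 11
    samples_per_group: int = 5
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    mirna_fraction: float = 0.1
    n_planted: int = 3
    planted_effect: float = 1.5
    planted_fraction: float = 0.3
    planted_cancers: int = 8
    planted_regions: list[PlantedRegion] | None = None
    # EST / digital differential display
    est_n_clusters: int = 200
    est_pool_size: int = 10_000
    est_n_planted: int = 5
    est_planted_fold: float = 50.0
    # promoters
    prom_n_input: int = 20
    prom_n_background: int = 200
    prom_length: int = 200
    prom_planted_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mirna_fraction", "planted_fraction", "prom_planted_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.planted_effect < 0 or self.est_planted_fold < 1:
            raise ValueError("effect sizes must be >= 0 and EST fold >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per stream so stages stay decoupled."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def cancer_ids(config: SimulationConfig) -> list[str]:
    return [f"cancer{i + 1:02d}" for i in range(config.n_cancers)]


def generate_genome(config: SimulationConfig) -> tuple[CytobandMap, pd.DataFrame]:
    """Contiguous bands per chromosome plus uniformly placed probes.

    Band names follow cytogenetic style: the first half of each chromosome
    is the p arm (numbered outward, i.e. descending towards the start),
    the second half the q arm.  Probe annotations carry the true band, a
    gene symbol per probe, and an mRNA/miRNA class label.
    """
    rng = config.rng(1)
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        nb = config.bands_per_chromosome
        n_p = nb // 2
        names = [f"{c}p{n_p - i}" for i in range(n_p)] + [
            f"{c}q{i + 1}" for i in range(nb - n_p)
        ]
        for i, name in enumerate(names):
            rows.append(
                (str(c), i * config.band_length, (i + 1) * config.band_length, name, "gneg")
            )
    cmap = CytobandMap(
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "band", "stain"])
    )

    probes = []
    for _, entry in cmap.entries.iterrows():
        pos = np.sort(
            rng.integers(entry["start"], entry["end"], size=config.probes_per_band)
        )
        for j, p in enumerate(pos):
            probes.append((entry["chromosome"], int(p), entry["band"], j))
    ann = pd.DataFrame(probes, columns=["chromosome", "position", "band", "j"])
    ann["probe_id"] = [f"probe_{i:05d}" for i in range(len(ann))]
    is_mirna = rng.random(len(ann)) < config.mirna_fraction
    ann["rna_class"] = np.where(is_mirna, "miRNA", "mRNA")
    ann["gene_symbol"] = [
        (f"mir-{b}-{j}" if mi else f"G{b}-{j}")
        for b, j, mi in zip(ann["band"], ann["j"], is_mirna)
    ]
    ann = ann[["probe_id", "gene_symbol", "rna_class", "chromosome", "position", "band"]]
    return cmap, ann


def plan_planted_regions(
    config: SimulationConfig, annotation: pd.DataFrame
) -> list[PlantedRegion]:
    """Resolve the planted-region plan (random bands when none is given)."""
    if config.planted_regions is not None:
        return [replace(r) for r in config.planted_regions]
    rng = config.rng(2)
    bands = annotation["band"].unique()
    chosen = rng.choice(bands, size=min(config.n_planted, len(bands)), replace=False)
    return [
        PlantedRegion(
            band=str(b),
            direction="over",
            effect=config.planted_effect,
            fraction=config.planted_fraction,
            n_cancers_affected=config.planted_cancers,
        )
        for b in chosen
    ]


def generate_expression(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[dict[str, ExpressionStudy], pd.DataFrame]:
    """Per-cancer log2 matrices with planted region-level alterations.

    Returns the studies and a truth table (probe_id, band, direction,
    cancer) listing every planted probe-cancer alteration.
    """
    rng = config.rng(3)
    ids = cancer_ids(config)
    n_probes = len(annotation)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
    plan = plan_planted_regions(config, annotation)

    # choose altered probes once per band; share them across affected cancers
    truth_rows = []
    shift = np.zeros((n_probes, config.n_cancers))
    for region in plan:
        in_band = np.flatnonzero((annotation["band"] == region.band).to_numpy())
        k = int(round(region.fraction * len(in_band)))
        altered = rng.choice(in_band, size=k, replace=False)
        affected = rng.choice(
            config.n_cancers, size=min(region.n_cancers_affected, config.n_cancers),
            replace=False,
        )
        sign = 1.0 if region.direction == "over" else -1.0
        for ci in affected:
            shift[altered, ci] += sign * region.effect
            for pi in altered:
                truth_rows.append(
                    (annotation["probe_id"].iat[pi], region.band, region.direction, ids[ci])
                )

    studies = {}
    ns = config.samples_per_group
    for ci, cid in enumerate(ids):
        control = baseline[:, None] + rng.normal(0, config.noise_sd, size=(n_probes, ns))
        case = (
            baseline[:, None]
            + shift[:, ci][:, None]
            + rng.normal(0, config.noise_sd, size=(n_probes, ns))
        )
        cols = [f"{cid}_ctrl{j}" for j in range(ns)] + [f"{cid}_case{j}" for j in range(ns)]
        matrix = pd.DataFrame(
            np.hstack([control, case]), index=annotation["probe_id"], columns=cols
        )
        group = pd.Series(["control"] * ns + ["case"] * ns, index=cols)
        studies[cid] = ExpressionStudy(cancer_id=cid, matrix=matrix, group=group)
    truth = pd.DataFrame(truth_rows, columns=["probe_id", "band", "direction", "cancer"])
    return studies, truth


def generate_est(config: SimulationConfig) -> tuple[ESTPools, set[str]]:
    """EST pool pair with fold-inflated pool-B probabilities for planted clusters."""
    rng = config.rng(4)
    n = config.est_n_clusters
    base = rng.dirichlet(np.full(n, 5.0))
    planted = set(rng.choice(n, size=min(config.est_n_planted, n), replace=False).tolist())
    p_b = base.copy()
    for i in planted:
        p_b[i] *= config.est_planted_fold
    p_b /= p_b.sum()
    ids = [f"Cluster{i:04d}" for i in range(n)]
    counts = pd.DataFrame(
        {
            "cluster_id": ids,
            "count_A": rng.multinomial(config.est_pool_size, base),
            "count_B": rng.multinomial(config.est_pool_size, p_b),
        }
    )
    pools = ESTPools(counts=counts, size_A=config.est_pool_size, size_B=config.est_pool_size)
    return pools, {ids[i] for i in planted}


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def generate_promoters(
    config: SimulationConfig, pwm: PWMModel
) -> tuple[PromoterSet, PromoterSet, pd.DataFrame]:
    """Uniform-random promoters; motif consensus planted in part of the input.

    Returns (input set, background set, truth) where truth lists the
    promoter id and insertion offset of every planted site.
    """
    rng = config.rng(5)
    L = config.prom_length
    motif = pwm.consensus
    if L < len(motif):
        raise ValueError("promoter length shorter than motif")
    background = PromoterSet(
        {f"bg_{i:04d}": random_dna(rng, L) for i in range(config.prom_n_background)}
    )
    sequences = {}
    truth_rows = []
    n_planted = int(round(config.prom_planted_fraction * config.prom_n_input))
    for i in range(config.prom_n_input):
        sid = f"inp_{i:04d}"
        seq = random_dna(rng, L)
        if i < n_planted:
            off = int(rng.integers(0, L - len(motif) + 1))
            seq = seq[:off] + motif + seq[off + len(motif):]
            truth_rows.append((sid, off))
        sequences[sid] = seq
    truth = pd.DataFrame(truth_rows, columns=["promoter_id", "offset"])
    return PromoterSet(sequences), background, truth


#: a small built-in motif used by the pipeline's promoter stage and examples
def demo_pwm(name: str = "DEMO1") -> PWMModel:
    from .promoter_scan import pfm_to_pwm

    pfm = np.array(
        [
            [12, 0, 0, 0, 0, 2, 0, 12],  # A
            [0, 12, 0, 0, 1, 0, 0, 0],  # C
            [0, 0, 12, 0, 11, 0, 0, 0],  # G
            [0, 0, 0, 12, 0, 10, 12, 0],  # T
        ]
    )
    return pfm_to_pwm(pfm, name=name)
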