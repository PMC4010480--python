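"""Calibration and parameter-recovery experiments on synthetic data.

These are the package's own quality checks: can the region statistic
recover bands with planted enrichment, and do the screening tests hold
their nominal error rates when nothing is planted?  Every experiment is
seeded and returns plain numbers, so the test suite and the reproduction
script share one implementation.

Reference conditions (the defaults of :class:`~pcsrscan.synthetic.SimulationConfig`):
11 cancers, 5 chromosomes x 8 bands x 40 probes, 5 samples per group,
noise SD 0.25 log2 units, three planted bands with a 1.5 log2 effect on
30% of band probes in 8 of 11 cancers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .ddd import ESTPools, ddd_screen
from .pipeline import RunConfig, de_calls_for_study
from .promoter_scan import PWMModel, pscan_ztest
from .region_scoring import (
    RegionFrequencyTable,
    chromosome_chi_square,
    participation_percent,
    region_frequencies,
    select_pcsrs,
)
from .synthetic import (
    SimulationConfig,
    cancer_ids,
    demo_pwm,
    generate_expression,
    generate_genome,
    generate_promoters,
    plan_planted_regions,
)


def planted_band_recovery(
    n_seeds: int = 50,
    base_seed: int = 0,
    effect: float | None = None,
    sim: SimulationConfig | None = None,
    run: RunConfig | None = None,
) -> dict:
    """Fraction of (seed, planted band) pairs recovered in the top-5 list.

    Per seed: simulate, call differential expression, score regions and
    check every planted band against its own chromosome's top-k
    over-expression list.  ``effect`` overrides the planted effect size
    (0 gives the chance-level control).  Returns per-band and per-seed
    recovery rates plus the chance rate k / bands_per_chromosome.
    """
    run = run or RunConfig()
    base = sim or SimulationConfig()
    if effect is not None:
        base = dataclasses.replace(base, planted_effect=effect)
    hits = trials = 0
    all_recovered = 0
    for i in range(n_seeds):
        cfg = dataclasses.replace(base, seed=base_seed + i)
        cmap, annotation = generate_genome(cfg)
        studies, _ = generate_expression(cfg, annotation)
        plan = plan_planted_regions(cfg, annotation)
        calls = {
            cid: de_calls_for_study(studies[cid], annotation, run, "fold")[2]
            for cid in cancer_ids(cfg)
        }
        freq = region_frequencies(calls, annotation)
        scores = participation_percent(freq, denominator=run.denominator)
        pcsrs = select_pcsrs(scores, k=run.k)
        band_chrom = annotation.drop_duplicates("band").set_index("band")["chromosome"]
        seed_ok = True
        for region in plan:
            chrom = str(band_chrom[region.band])
            top = {b for b, _ in pcsrs.over.get(chrom, [])}
            trials += 1
            if region.band in top:
                hits += 1
            else:
                seed_ok = False
        all_recovered += seed_ok
    return {
        "band_recovery_rate": hits / trials,
        "all_bands_recovered_rate": all_recovered / n_seeds,
        "chance_rate": run.k / base.bands_per_chromosome,
        "n_seeds": n_seeds,
        "n_trials": trials,
    }


def ddd_null_pass_rate(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_clusters: int = 200,
    pool_size: int = 10_000,
    alpha: float = 0.05,
) -> dict:
    """Pass rate of the DDD screen when both pools share one multinomial.

    The ratio filter is disabled (threshold just above 1, symmetric mode)
    so the rate measures the calibration of the Fisher screen alone; the
    expectation is ``alpha`` within Monte-Carlo error.
    """
    passes = total = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        base = rng.dirichlet(np.full(n_clusters, 5.0))
        counts = pd.DataFrame(
            {
                "cluster_id": [f"c{j}" for j in range(n_clusters)],
                "count_A": rng.multinomial(pool_size, base),
                "count_B": rng.multinomial(pool_size, base),
            }
        )
        pools = ESTPools(counts, size_A=pool_size, size_B=pool_size)
        res = ddd_screen(pools, ratio_threshold=1.0 + 1e-9, alpha=alpha, ratio_mode="symmetric")
        passes += int(res["passes"].sum())
        total += n_clusters
    rate = passes / total
    se = float(np.sqrt(alpha * (1 - alpha) / total))
    return {"pass_rate": rate, "alpha": alpha, "mc_se": se, "n_clusters_total": total}


def pscan_null_pvalues(
    n_seeds: int = 200, base_seed: int = 0, pwm: PWMModel | None = None
) -> np.ndarray:
    """Motif-enrichment p-values when no motif is planted (one per seed)."""
    pwm = pwm or demo_pwm()
    out = []
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=base_seed + i, prom_planted_fraction=0.0)
        inp, bg, _ = generate_promoters(cfg, pwm)
        out.append(pscan_ztest(inp, bg, pwm).p_value)
    return np.asarray(out)


def chisq_null_pvalues(
    n_seeds: int = 200,
    base_seed: int = 0,
    n_chromosomes: int = 8,
    total_altered: int = 2000,
) -> np.ndarray:
    """Chromosome chi-square p-values when alterations follow chip content."""
    out = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        fctp = rng.integers(200, 2000, size=n_chromosomes)
        p = fctp / fctp.sum()
        observed = rng.multinomial(total_altered, p)
        table = pd.DataFrame(
            {
                "chromosome": [str(c + 1) for c in range(n_chromosomes)],
                "band": [str(c + 1) for c in range(n_chromosomes)],
                "start": 0,
                "ftp": fctp,
                "over_total": observed,
                "down_total": 0,
            }
        )
        freq = RegionFrequencyTable(
            table=table, per_cancer=pd.DataFrame(), n_cancers=1, level="chromosome"
        )
        _, _, pval = chromosome_chi_square(freq, "over")
        out.append(pval)
    return np.asarray(out)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive two-sided Fisher p: sum hypergeometric probabilities of
    all tables with the observed margins no more probable than observed.

    Independent of the screening implementation; used as its oracle.
    """
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, row1 + col1 - n_total), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n_total, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
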