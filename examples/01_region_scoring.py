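"""Score cytogenetic bands across simulated cancers and pick risk regions.

Simulates 11 cancer-vs-normal microarray studies with three bands of
planted over-expression, calls differential expression at the 2-fold /
p<0.05 criterion, and ranks bands by their participation percentage
100*FOR/(n*FTP).  The planted bands should dominate their chromosomes'
top-5 lists.
"""

from pcsrscan.pipeline import RunConfig, de_calls_for_study
from pcsrscan.region_scoring import (
    chromosome_chi_square,
    chromosome_frequencies,
    participation_percent,
    region_frequencies,
    select_pcsrs,
)
from pcsrscan.synthetic import (
    SimulationConfig,
    cancer_ids,
    generate_expression,
    generate_genome,
    plan_planted_regions,
)

sim = SimulationConfig(seed=42)
run = RunConfig()

cmap, annotation = generate_genome(sim)
studies, truth = generate_expression(sim, annotation)
planted = [r.band for r in plan_planted_regions(sim, annotation)]
print(f"simulated {sim.n_cancers} cancers, {len(annotation)} probes; "
      f"planted bands: {planted}")

calls = {
    cid: de_calls_for_study(studies[cid], annotation, run, "fold")[2]
    for cid in cancer_ids(sim)
}
freq = region_frequencies(calls, annotation)
scores = participation_percent(freq)
pcsrs = select_pcsrs(scores, k=run.k)

print("\ntop-5 over-expression regions per chromosome (band: percent):")
for chrom, entries in pcsrs.over.items():
    pretty = ", ".join(f"{b}: {pct:.1f}%" for b, pct in entries if pct > 0)
    print(f"  chr{chrom}: {pretty or '(no altered probes)'}")

stat, df, p = chromosome_chi_square(chromosome_frequencies(freq), "over")
print(f"\nchromosome participation chi-square: stat={stat:.1f}, df={df}, p={p:.3g}")
print("A tiny p says alterations concentrate on some chromosomes rather than "
      "following chip content — here driven by the planted regions.")
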