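# Methods

## The region statistic

The analysis treats the genome as a fixed partition into cytogenetic bands
(UCSC cytoBand dialect: 0-based, half-open intervals; band labels are
chromosome + arm name, e.g. `12p13.31`). Probesets are point features; a
probe interval, if supplied, is represented by its midpoint. For each band
*r* and cancer study *c*, the pipeline counts the probesets called over- or
down-expressed; the band's frequencies FOR and FDR sum these counts over
the *n* studies, while FTP counts the probesets the chip annotates to the
band **once per chip**, not per study. The participation percentages are

    %over(r) = 100 · FOR / (n · FTP),    %down(r) = 100 · FDR / (n · FTP),

and the chromosome analogues use FOC/FDC/FCTP. The source publication
prints these equations only as images; the form above is reconstructed from
its variable legend and table footnote. Because *n* is constant, dividing by
FTP alone (`denominator="pooled"`) rescales every band equally and leaves
rankings — hence PCSR membership — unchanged; the flag exists for
sensitivity reading only. Per chromosome and direction, the five bands with
the highest percentage are selected. Bands with FTP = 0 are omitted rather
than scored 0, so a band with no chip content can never enter a top-5 list.
Ties are broken by genomic order (interval start, then label), which makes
selection deterministic; the original description is silent on ties.

The chromosome-level test is an ordinary goodness-of-fit χ² of observed
per-chromosome altered counts against expectation proportional to FCTP,
with df = #chromosomes − 1. Chromosomes with zero expected count must be
merged or excluded by the caller; the function refuses them explicitly.

Assumptions worth keeping in mind: all studies share one probe universe
(the implementation raises on disjoint universes); counts are probeset
counts, so genes covered by several probesets weigh more; and no
significance is attached to the percentages themselves — the top-5 rule is
a ranking, not a test.

## Differential expression

Direction calls combine a symmetric linear fold threshold on the log2 scale
with a per-probe two-sided Welch (unequal-variance) t-test:

* over: log2FC ≥ log2(T) and p < α;
* down: log2FC ≤ −log2(T) and p < α;
* unchanged otherwise.

Defaults: T = 2.0 for mRNA, 1.5 for miRNA, 1.2 for the tracing mode used
when following common RNAs across cancers; α = 0.05 with no
multiple-testing correction, matching the original operating point. The
boundary is inclusive ("at least T-fold"). The original analysis used an
empirical-Bayes moderated t-test from a GUI package whose internals are not
published; Welch's t is used here because the downstream region statistic
consumes only the binary calls, and a moderated variant can be slotted in
behind the same interface. Degenerate probes (zero variance in both groups)
get p = 1 when means are equal, p = 0 otherwise.

The alternative "top-200" mode ranks significant probes (p < α) by |log2FC|
separately per direction and keeps the N largest, ties broken by probe id.
Whether the original top-200 lists were p-filtered, and whether N applied
per direction, is not stated; both are controlled by arguments
(`alpha`, per-direction calls), with the defaults above.

## Digital differential display

For each transcript cluster the 2×2 table (cluster vs rest, pool A vs pool
B) is tested with Fisher's exact test (two-sided; sidedness was not stated
in the original description, and two-sided is the conservative default).
The fold difference is the ratio of pool fractions. The published screen
reports pool B / pool A; because down-expressed DDD hits also appear in the
published tables, the default here is the direction-symmetric
max(B/A, A/B) with the direction recorded (`ratio_mode="b_over_a"` restores
the one-directional form). The ratio filter is strict (> 10). A cluster
absent from pool A but present in pool B has infinite fold and passes the
ratio side; no pseudocounts are applied by default, so the Fisher p alone
guards against small-count artifacts. Significance level α = 0.05,
configurable; the original says only "statistically significant hits".

Under a null where both pools are drawn from one multinomial, the pass rate
with the ratio filter disabled estimates the Fisher level; exact tests on
discrete tables are mildly conservative, so rates slightly below α are
expected at moderate pool sizes.

## Cross-cancer integration

Microarray and DDD evidence are merged per (gene, cancer) with union
semantics. A gene is a *common altered RNA* when ≥ `min_cancers` (default
6) of the cancers carry at least one call of any direction from either
source. Expression classes use a purity rule: Class I when no cancer has a
down call, Class II when none has an over call, Class III otherwise
(including conflicts within one cancer). The published class definitions
say "majority"; purity is the operationalization that reproduces the
printed labels — every direction-pure printed row is Class I/II and every
row with at least one opposing call is Class III — with one caveat: one
printed row (CENPF) carries only over marks yet is labelled Class III,
identical in shape to a row labelled Class I, so the printed table is
internally inconsistent there and no direction-based rule can reproduce
both labels. The bundled fixture transcribes the table faithfully and the
discrepancy is surfaced by the tests rather than patched.

miRNA positional clusters are bands carrying ≥ 2 distinct common miRNAs;
per-cancer directions are unioned over members. Risk-region flags test band
labels (normalized: `chr` stripped, X/Y upper-cased) against the selected
PCSR set of either direction. Subnetwork summaries count nodes within a hop
radius of a focus entity (reachability ignores edge direction) and edges
with both endpoints inside; network *construction* from interaction
databases is out of scope — edge tables are inputs.

## Promoter scanning

PFMs become log2-odds PWMs via

    w[i, b] = log2( ((count[i, b] + pc · bg[b]) / (colsum[i] + pc)) / bg[b] ),

with pseudocount pc = 0.8 split by the background composition (a common
JASPAR-tooling convention; the original names only the database) and
uniform background by default. s_min/s_max, the sums of per-position column
minima/maxima, define the relative profile score (s − s_min)/(s_max −
s_min) ∈ [0, 1]. A promoter's score is the maximum over both strands and
all offsets; windows containing N are skipped, an all-N sequence scores 0,
and a degenerate matrix (s_max = s_min) scores 1 by convention. Threshold
scans are inclusive ("at least 99%").

Promoter-set enrichment approximates the pscan statistic with a one-sample
z-test: z = (mean_input − mean_bg)/(sd_bg/√m), m = |input|, sd with ddof=1,
upper-tail normal p, selection at p < 0.1. The published tool's exact
statistic is not documented in the study this models; under the no-motif
null the approximation's p-values are uniform to within the background
estimation error (variance inflated by m/n_bg, negligible at the default
20/200 sizes — verified by the calibration suite). Window conventions
(−1 kb..0 for mRNA, −3 kb..+1 kb for miRNA promoters) are carried as
metadata; anchor coordinates and sequences are caller-supplied, and the
package never fetches genomes. Common regulators of a miRNA cluster are
motifs hitting **every** member promoter at threshold (`threshold` mode
relaxes to a fraction); for mRNA groups, motifs enriched at p < 0.1 in
every group.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
the raw platform artifacts. Expression: per-probe baselines ~
Normal(8, 1.5) log2 units with i.i.d. Normal(0, noise_sd) sample noise —
a log2-normal model mimicking RMA-normalized intensities. Region signal is
planted by shifting case means of a fraction of a band's probes in a subset
of cancers; risk regions in real data are not altered in every cancer, so
the default plants each band in 8 of 11 cancers. Reference condition
(the config defaults, used by the recovery suite): 11 cancers, 5
chromosomes × 8 bands × 40 probes, 5 samples/group, noise SD 0.25, three
planted bands at effect 1.5 log2 on 30% of band probes. These sizes keep a
50-seed recovery experiment in the tens of seconds while leaving the
planted effect comfortably detectable (t ≈ 9.5 at the reference settings) —
small enough to iterate on, structured enough to expose ranking errors.
EST pools: cluster probabilities ~ Dirichlet(5·1), planted clusters get a
fold-multiplied pool-B probability before renormalization, counts are
multinomial (default 200 clusters, 10,000 tags/pool, 5 planted at 50-fold).
Promoters: i.i.d. uniform DNA with the motif consensus inserted at a random
offset in a fraction of input promoters.

What the generators do **not** emulate: probe-level CEL structure, batch
and lab effects, correlated probes within genes, chip-specific probe sets,
EST library heterogeneity, promoter GC structure and repeats. Passing the
recovery and calibration suites therefore shows the statistics are computed
correctly and hold their nominal behavior under the assumed model — not
that the thresholds are optimal for any particular real platform.

All generators are pure functions of (config, seed); independent seed
streams per stage keep, e.g., the EST draw unchanged when the expression
config changes.

## Numerical and design notes

* Coordinates 0-based half-open throughout; position 0 belongs to the
  first band, an interval's end to the next.
* All rankings have stated deterministic tie-breaks (genomic order for
  bands, lexicographic probe id for fold ranks), so outputs are stable
  across platforms and reruns; report floats are written at %.6g for
  byte-identical reruns.
* Fisher's exact test and the Welch t come from scipy; the test-suite
  checks them against independent oracles (exhaustive hypergeometric
  enumeration over all 2×2 tables with margins ≤ 30; the hand-written
  Welch–Satterthwaite formula).
* Unknown chromosomes at lookup are "unmapped", logged once, never an
  error; unmapped probes are kept in annotations but excluded from region
  counts.
* The pipeline clamps `min_cancers` to the number of simulated cancers so
  small desk-scale runs remain meaningful.

## Known limitations

* Probeset-level counting inherits chip design bias; no per-gene collapse
  is attempted (the original counts probesets).
* No multiplicity correction in differential expression, by design
  fidelity; users integrating many chips may want one.
* The pscan approximation ignores background score estimation error and
  positional effects; it is a screening statistic, not a calibrated
  hypothesis test at small background sizes.
* Cross-chip integration (different probe universes) is limited to the
  per-cancer-FTP denominator variant; no probe matching across platforms.
* The top-5 rule has no significance attached; with sparse alteration the
  lists fill with near-zero percentages (ranked by genomic order), which
  is visible in the reports as percent = 0 rows.
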