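# Methods

`copmap` analyses meiotic crossovers (COs) transmitted by the gametes of an
*Arabidopsis thaliana* Col/Ler hybrid, as read out in BC1 individuals from
shallow whole-genome sequencing. Every individual reports the genotype of one
gamete against the recurrent (Col, "A") parent: regions where the gamete
carried the Col allele are homozygous in the BC1 plant (HOM_A), regions where
it carried the Ler ("B") allele are heterozygous (HET), and every HOM_A/HET
transition along a chromosome marks one crossover.

## Coordinate conventions

All files use 1-based inclusive positions (the convention of SNP tables);
zones are additionally exported as standard 0-based BED. In memory every
interval is 0-based half-open, and the readers/writers in `copmap.layout` and
`copmap.io` are the only code that shifts offsets. The default genome layout
is TAIR10 (five chromosomes, 119.1 Mb) with centromere midpoints and
centromere-spanning Non-Recombining Zones (NRZs) rounded to 100 kb;
chromosome 4 is flagged excluded-for-interference because of a translocation
and a megabase-scale inversion segregating in the cross.

## Synthetic meiosis generator (`copmap.sim`)

The generator is first-class, tested code. It models:

* **Class I (interfering) chiasmata** as a stationary gamma-renewal process
  with shape `nu >= 1` on the cumulative axis of a positional intensity
  ("Crossover Potential") map, rescaled so the expected count per chromosome
  equals `class1_mean`. `nu = 1` is exactly Poisson; larger `nu`
  underdisperses counts and spaces events evenly, reproducing coefficient-of-
  coincidence (CoC) curves that dip below 1 at short distances and recover
  with distance. Stationarity is achieved by a 25-mean-gap burn-in, so the
  count law on the chromosome is the equilibrium one. An `obligate` flag
  redraws chromosomes with zero events (truncated-at-one scheme); it is off
  by default so that the expected-count calibration below stays exact.
* **Class II (non-interfering) chiasmata** as an independent inhomogeneous
  Poisson draw from the same or another intensity.
* **Thinning**: every chiasma involves two non-sister chromatids chosen
  uniformly (no chromatid interference) and the gamete inherits one of the
  four chromatids; each chiasma is therefore transmitted with probability
  exactly 1/2 and the mean CO count per gamete is half the mean chiasma count
  per meiocyte. The per-meiosis class I chiasma counts double as the
  synthetic analogue of MLH1/HEI10 focus counts.
* **Sequencing**: per-marker read counts are Poisson at
  `depth x (1 - dropout)`; HET markers emit B reads with probability 0.5, and
  HOM_A markers with the symmetric genotyping error `epsilon`
  (default 0.005). A duplicated (trisomic) chromosome has 1.5x depth —
  three copies instead of two in the BC1 plant.

Defaults emulate the experimental design: 25 diagnostic markers/Mb (~3,000
genome-wide), 2x depth, `epsilon = 0.005`, wild-type female class I chiasma
mean 1.12/chromosome (5.6/meiosis, i.e. 2.8 COs per gamete) with `nu = 5`,
male 2.08/chromosome (5.2 COs per gamete). Sex differences are pure
parameterization — the positional intensity is shared, mirroring the
conclusion that only the maturation of precursors differs between sexes.

The generator does **not** model DSB formation and fate, gene-conversion/
non-crossover tracts, chromatid interference, mapping bias, GC-biased
coverage, or selection against aneuploid gametes. Passing tests therefore
demonstrate the pipeline's correctness under this idealized read model, not
robustness to alignment artifacts in real data.

## Crossover caller (`copmap.caller`)

Windows of 30 kb advancing in 15-kb steps pool the reads of contained
markers and are classified UNKNOWN (pooled reads < `min_reads`, default 4),
HET (B-allele fraction >= `het_baf_min`, default 0.2, ties to HET) or HOM_A.
Runs of identically classified informative windows form segments; UNKNOWN
windows are absorbed and never break a run, so marker deserts only widen
breakpoint uncertainty. Support filtering removes, iteratively to a
fixpoint, terminal segments with fewer than 2 informative windows and
internal segments with fewer than 5 (removal order: terminals first, left
before right, then the weakest internal segment, leftmost on ties; neighbors
re-merge after every removal). The order is prescribed because the fixpoint
is not order-independent in general (e.g. states A1 B4 A1). By construction
this imposes a resolution floor: double crossovers whose middle segment
cannot muster 5 supporting windows collapse, and terminal crossovers whose
distal segment cannot muster 2 windows (45 kb of window extent) are dropped.
At the default marker density the double-CO floor is at least the nominal
90 kb; with very dense markers partially overlapping windows can support a
segment, and the effective floor tightens to ~65 kb.

Two marker-level likelihood layers make the caller robust at ~2x depth,
where a handful of reads per window is easily fooled (a 4-read HET window is
all-A with probability 1/16):

1. **Segment evidence audit.** Each segment's log-likelihood ratio — its
   state versus the flanking state, summed over every read-covered marker in
   its window span with the Binomial read model (B probability `epsilon`
   under HOM_A, 0.5 under HET) — must reach ln(1000). Chance runs of all-A
   marker clusters fail because their spans also contain sub-threshold
   markers carrying B reads; the weakest failing segment is removed and the
   audit iterates.
2. **Breakpoint support intervals.** Each retained transition is re-placed
   on the raw marker counts spanning the five boundary informative windows
   of both segments: the reported interval is the contiguous run of
   inter-marker splits whose two-sided log-likelihood is within ln(1000) of
   the optimum. At shallow depth several adjacent gaps are genuinely
   indistinguishable, and a single best gap would be overconfident; the
   support interval contains the true breakpoint in >99% of simulated
   gametes at 2x depth.

Sample QC flags low-coverage samples (informative reads/Mb below threshold)
and contamination suspects (genome-wide B-allele fraction outside
[0.10, 0.40]; a clean BC1 sits near 0.25, a diploid F1 near 0.5).

## Landscapes, CO_P and zones (`copmap.landscape`)

CO landscapes count breakpoint-interval midpoints in sliding windows (1 Mb /
50 kb by default) and divide by the gamete count. Normalizations:
per-chromosome relative (each chromosome sums to 1 — the proportion of that
chromosome's COs per interval) and per-genome relative (divided by the
genome-wide mean, so the track averages 1). Crossover-Potential (CO_P) maps
pool the calls of several hyper-recombinant populations over pooled gametes
(300 kb / 50 kb). Hot/cold zones compare per-window mutant/wild-type fold
changes: a window supports "hot" in a genotype when its fold change is at
least twice that genotype's genome-wide median fold change (cold: at most
half), and zones are maximal runs supported by the anchor genotype plus at
least three others, merged over overlapping windows. Wild-type zero-count
windows receive a pseudocount of half the smallest nonzero wild-type rate so
distal fold changes stay finite. The "two-fold above the median" reading of
the zone rule, and the contiguity requirement, are genuinely open choices;
both are config-exposed. The NRZ audit counts calls whose entire breakpoint
interval lies inside an NRZ; straddling intervals are not counted.

## Interference and summary statistics (`copmap.interference`)

The CoC splits each chromosome into K = 10 equal intervals and scores
per-gamete presence/absence: for intervals i, j the statistic is
x_ij / (x_i x_j); pairs with a zero marginal are undefined (NaN), never
zero-filled, and the distance curve averages defined pairs at each interval
separation. Chromosomes flagged excluded (chromosome 4) are skipped. The
genome summary weights chromosomes by gamete count. Presence/absence is the
classical CoC definition; note that populations with a *fixed* CO count per
gamete show CoC < 1 from the multinomial constraint alone — only
Poisson-count placement is interference-free.

Heterochiasmy is the female/male ratio of mean COs per gamete with a
two-sided Mann-Whitney test on per-gamete counts. Pathway decomposition uses
the halving law: expected class I COs per gamete = mean foci per meiocyte / 2;
the class II estimate is the excess of the genetic mean and may be reported
negative (sampling noise) with a warning, never clamped. Additive
predictions are wild type plus the per-mutant gains. Printed-precision
comparisons round half away from zero (1 d.p. for fold changes, 2 d.p. for
ratios).

## Aneuploidy screen (`copmap.aneuploidy`)

Non-overlapping 100-kb windows (config-overridable) carry per-window depth,
either ingested from a depth TSV or summed from marker counts. Every
unordered chromosome pair is compared by a two-sided Mann-Whitney test on
window depths with Benjamini-Hochberg adjustment across pairs within the
sample; a pair is flagged when the median-depth fold change (larger/smaller)
exceeds 1.2 **and** the adjusted p value is below 1e-20. The 1e-20 bar is
applied to adjusted p values (a switch exposes raw p; the adjustment is
otherwise nearly inert at this threshold), and fold change uses medians for
robustness, with the mean-based value also reported. Verdicts: a chromosome
flagged against all others as the consistently deeper (shallower) member,
and itself deviating from the majority median by more than sqrt(1.2), is a
gain (loss); chromosomes flagged only against another shifted chromosome
while sitting at the majority depth are euploid; mixed or partial patterns
(e.g. segmental CNVs, which are out of scope) are ambiguous.

## CO_P prediction (`copmap.cop_model`)

Seventeen canonical feature tracks (SNPs, INV_TRANS, Synteny, Genes, TEs,
GC, ATAC, DNase, H3K4me1/2/3, H3K9me2, H3K27me1, mCG, mCHG, mCHH, MNase)
share the CO_P windowing. Random-forest regression
(scikit-learn, `n_estimators = 2000`, `max_features = 3`,
`min_samples_leaf = 5`, seeded) provides: per-feature Spearman correlations;
permutation-importance ranking from a full-panel fit; a stepwise cumulative
variance-explained curve (out-of-bag R² of refits on the top-k features,
reported as measured, not forced monotone); and leave-one-chromosome-out
cross-validation over the non-excluded chromosomes, reporting per-fold and
pooled predicted-vs-observed Spearman r. Windows with missing values are
dropped from fitting and flagged in predictions. Feature panels are stored
in sorted-name order so fits and rankings are invariant to input order.
Overlapping 50-kb-step windows are used as-is (autocorrelated training rows,
as the windowing implies); the tests use smaller forests purely for speed.

## Numerical and testing choices

Problem sizes in the test-suite and acceptance script are chosen for desk
scale: 200-gamete populations at 2x depth for caller performance, 10,000
gametes for CoC calibration, 50,000 meioses for the halving law, 1,000
euploid plus 300 trisomic depth profiles for the screen, and ~2,400 windows
x 17 features with 500-tree forests for CO_P recovery. All randomness flows
from explicit seeds; seeded reruns are byte-identical down to written files.
Synthetic feature tracks are moving-average-smoothed white noise, which
reproduces the megabase autocorrelation of chromatin tracks but not their
heavy tails or inter-feature correlation structure; the parameter-recovery
results therefore validate the modelling machinery, not any biological claim
about real feature panels.
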