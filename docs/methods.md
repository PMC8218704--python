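# Methods

## The measurement model

Droplet digital PCR partitions a PCR reaction into N ≈ 15,000 nanoliter
droplets (v = 0.85 nL by default) so that template molecules distribute
approximately independently across partitions. After end-point amplification
each droplet is read on two fluorescence channels — channel 1 for the
mutant-specific probe (FAM), channel 2 for the wild-type probe (VIC/HEX) — and
thresholded into mutant-positive, wild-type-positive, double-positive and
empty classes. Channel totals include double positives.

Under the Poisson partitioning model the per-droplet occupancy of an allele is
λ = −ln(1 − p), where p is that channel's positive-droplet fraction, and the
concentration in the PCR mix is

    C = λ / v                       [copies/µL, v in µL]

`poisson_concentration` implements this inversion; it refuses saturated wells
(p = 1), where λ is unbounded.

### Allele fraction

Two estimators are provided:

* `count_ratio` (default): AF = n_mut / (n_mut + n_wt). This is the
  convention used when VAF tables are printed at 3-decimal percent precision,
  and it is what the package reproduces exactly against the bundled reference
  table.
* `poisson`: AF = λ_mut / (λ_mut + λ_wt), which corrects each channel for
  multiple occupancy and needs the total droplet count.

The two agree to within ~1e-3 absolute only in the truly dilute regime
(channel occupancy below about 1%): the absolute gap grows roughly as
f(1−f)·(p_wt − p_mut)/2 where f is the allele fraction and p the channel
occupancies, so at a few percent occupancy the raw quotient already deviates
by more than 1e-3, and near saturation (the cystic-fluid well in the bundled
table, 10,944/15,000 mutant droplets) the printed count-ratio VAF and the
Poisson-corrected concentration ratio differ by ~2 percentage points. The
tests encode exactly this: printed VAFs are checked as count ratios, the
ng/mL columns as Poisson-corrected quantities, and the consistency check
between the two uses an occupancy-dependent tolerance.

The same mechanism makes the count-ratio estimator *biased* at standard study
conditions. At 5 ng input (~1667 haploid copies in 15,000 droplets) the
wild-type channel runs at λ ≈ 0.11 while a low-VAF mutant channel is nearly
single-occupancy; the busier channel is compressed by the factor
(1 − e^−λ)/λ ≈ 0.95, inflating the mutant share by up to a few relative
percent. The simulator-recovery test therefore checks the count-ratio
estimator for unbiasedness at the scale of a single estimate's Monte-Carlo
spread, and the Poisson-mode estimator — which removes the distortion — for
unbiasedness within 3 standard errors of a 200-replicate mean.

### Back-calculation and mass concentration

Concentrations are projected back to the original biofluid by volume
bookkeeping,

    C_ori = (V_PCR · C · V_ELU) / (V_DNA-PCR · V_SAMPLE)   [copies/mL],

with V_PCR the final mix volume (µL), V_ELU the extraction eluate volume
(µL), V_DNA-PCR the eluate volume loaded (µL, ≤ V_ELU) and V_SAMPLE the
biofluid volume (mL); V_SAMPLE normally comes from the sample sheet. The
cfDNA mass concentration uses the mass of one haploid human genome,
0.003 ng (configurable; 0.0033 is sometimes used elsewhere):

    C_cfDNA ≈ 0.003 · (C_MUT_ori + C_WT_ori)   [ng/mL].

### Call rules

* ctDNA positivity: at least **2** mutant-positive droplets (≥ 2; a strict
  ">2" reading exists in casual phrasing of such rules, and the threshold is
  a parameter).
* Copy-number amplification: target/reference concentration ratio strictly
  greater than 4. The ratio is reported raw, without a ploidy factor.

## Limit of detection

The serial-dilution rule: mutant DNA is diluted 1:10 … 1:10,000 into a
constant wild-type background (constant *copies*, not constant VAF) and run
in duplicate at 5 ng per well. A dilution point is detectable when its
pooled (summed-across-replicates) mutant droplets reach the positivity
threshold; an `any`-replicate rule is available as a flag. Then

    LoD = neat fractional abundance / deepest detectable dilution factor,

e.g. 79.3% neat detectable down to 1:100 → LoD 0.793%. Pooling duplicates
is the default because it uses both wells of the stated duplicate design;
whether the original experiments pooled or required each replicate is not
documented, so both behaviors ship.

Note that at the 5 ng design the 1:1000 point carries ~1.3 expected mutant
copies per well, so its detectability is genuinely stochastic
(P(pooled ≥ 2) ≈ 0.74 under Poisson partitioning); the LoD of a single
experiment is a realization, not a parameter. The package computes the rule
for whatever detectability the series shows.

## Droplet classification

A deterministic per-channel threshold: positive iff amplitude **strictly**
exceeds the cutoff (ties are negative; documented once, applied everywhere).
Cutoffs are either fixed or control-derived as mean + k·SD of the no-template
control (k = 5 default), with a separation warning when a cutoff does not
fall below the positive-control cluster mean. A k-sigma cutoff leaves a
~5σ tail on the negative cluster (≈3e-7 per droplet), so exact ground-truth
recovery over millions of simulated droplets is only guaranteed with a cutoff
placed in the gap between clusters (the fidelity tests use the cluster-mean
midpoint). Intermediate-amplitude "rain" is not modeled by the classifier;
the simulator can inject it to probe robustness.

## Fusion-candidate filtering

Candidates from an SV caller on a capture fusion panel pass six rejection
rules: read support ("more than 2" implemented as ≥ 3 on both genes),
both-breakpoints-outside-capture, proximity (≤ 10 bp) to blocklisted
false-positive positions, blocklisted unordered gene pairs, intragenic
junctions, and flanking homology > 10 bp. One targeted end suffices to keep a
candidate, matching capture designs that bait one side of a junction.
Blocklists are user-supplied resources; empty blocklists are valid. BED
intervals are half-open and the half-open convention is applied to the
breakpoint position value itself (a position equal to an interval's BED end
is outside); the package centralizes coordinate conversion in two helpers.
Homology length is consumed from the caller, not recomputed from sequence.

## The synthetic-data generator

`simulate_well` emulates: mass → copies conversion (DNA input / 0.003 ng,
default 5 ng), designed VAF → integer mutant/wild-type copy split, random
partitioning into droplets (independent Poisson per channel by default —
the model the inversion formula assumes — or exact multinomial scattering
for conservation tests), and Gaussian amplitude clusters per channel
(negative 1000 ± 150, positive 8000 ± 300 by default; the gap is ~23σ,
chosen for clean separation since no amplitude statistics are published for
these assays). Optional knobs: uniform-amplitude rain and per-droplet false
positives (default 0; wild-type controls in validation runs showed no mutant
droplets). A master seed spawns per-well child streams via numpy
`SeedSequence.spawn`, so replicates differ but runs reproduce bit-for-bit.

`simulate_dilution_series` scales mutant copies by 1/factor with the
wild-type background held constant. `simulate_cohort` draws zero-inflated
per-sample VAFs (positive with a per-fluid probability, log-normal VAF when
positive) and emits sample sheet + well counts + a truth table; the default
fluid mix mirrors the feasibility cohort (27 plasma / 6 serum / 9 CSF / 1
cyst with positivity parameters 7/27, 2/6, 6/9, 1).

What the generator does **not** emulate: PCR chemistry and efficiency,
droplet-volume variability, amplitude drift and rain structure of real
plates, fragmentation-dependent extraction yields, and genomic-DNA
contamination. Passing tests therefore demonstrate the statistical
correctness of the estimators and rules under the partitioning model, not
instrument-level robustness.

## Numerical and interface choices

* Printed-precision serialization: VAF percent and ng/mL at 3 decimals;
  positivity percentages as half-up-rounded integers (26, 67, 33 style),
  with exact fractions retained internally.
* Counts tables without a total droplet count yield only count-ratio AF and
  positivity; concentration fields stay `None` (absent, never zero).
* Degenerate inputs raise typed errors: saturated wells, zero-droplet allele
  fractions, undetectable dilution series, zero-variance controls.
* Problem sizes in the test suite: Monte-Carlo partitioning oracles use
  1,000–2,000 replicates at 15,000 droplets; estimator-recovery runs 200
  wells per VAF; classification fidelity runs 100 seeded wells. These sizes
  put Monte-Carlo standard errors well below the tested tolerances while the
  whole suite runs in seconds.

## Known limitations

* No confidence intervals on λ or AF (a Wilson/likelihood interval would be
  the natural extension).
* LoD follows the dilution rule only; no probit LoB/LoQ modeling.
* The classifier is 1-D per channel; model-based 2-D clustering and plate
  drift correction are out of scope.
* Cohort statistics stop at descriptive summaries; group comparisons are
  left to external tools on the exported tables.
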