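# Methods

## The quantification model

A droplet digital PCR reaction of volume `V_r` (default 20 µL) is
partitioned into `n` droplets of volume `V_d` (default 0.85 nL).  If
template molecules are dispersed at concentration `c` copies/µL, the
count captured by one droplet is Poisson with mean `λ = c·V_d`.  Endpoint
amplification saturates, so a droplet reads positive iff it captured at
least one molecule, and the positive fraction estimates `1 − e^{−λ}`.
Inverting,

    λ̂ = −ln(1 − p̂),     p̂ = n_positive / n,
    copies/µL = λ̂ / V_d,     copies/reaction = copies/µL × V_r.

This is a one-to-one transform of a binomial proportion, so all interval
estimation happens on `p̂`:

* **Bulk of the range** (more than 5 positives and 5 negatives): the
  delta method gives `SE(λ̂) = sqrt(p̂ / (n(1−p̂)))`; the 95% CI is
  `λ̂ ± 1.96·SE`, clipped at 0 and scaled to copies/reaction.
* **Extreme counts** (≤ 5 positives or ≤ 5 negatives): exact
  Clopper–Pearson beta-quantile bounds on `p̂` are pushed through
  `−ln(1−p)`.  At 0 positives the lower bound is exactly 0 and the upper
  bound is `−ln(1 − p_u)` with `p_u = 1 − (0.025)^{1/n} ≈ 3.689/n`.
* **Saturated wells** (`n_positive = n`): λ has no finite estimate; the
  result is flagged rather than raised, and only the lower bound is
  finite.

The delta interval's coverage at the study's droplet counts is checked by
simulation (1,000 wells at λ = 0.2 → 94–96% empirical coverage).

A well enters downstream analysis only if it yielded at least 10,000
droplets (configurable); failing wells keep their estimates but carry
`qc_pass = False`.

### Limit of detection

The LOD of an assay is the upper limit of the 95% confidence interval of
the no-template controls, rounded up to whole copies per reaction.  With
two or more NTC wells we use the two-sided t-interval of copies/reaction
across wells (reading "the 95% CI of the no-template controls" as
across-replicate variation); with a single well, that well's own CI upper
bound.  When every NTC had zero positive droplets the across-well
variance degenerates, so the implementation pools all NTC droplets and
takes the Clopper–Pearson upper bound of the pooled proportion — this is
never exactly zero, so the LOD is always a positive, finite number.
Eight simulated NTCs at the default contamination rate yield an LOD of
~0.6–0.8 copies/reaction, i.e. 1 copy after rounding — the single-copy
sensitivity regime.

## Droplet classification

Thresholding is deterministic: per channel, a 1-D two-means split with
centers initialized at the 5th and 95th amplitude percentiles, cutoff at
the midpoint of the converged cluster means.  If the two means are closer
than 4 pooled within-cluster SDs the channel is declared single-cluster
(an all-negative well) and the cutoff is placed at mean + 5 SD, so no
droplet is positive; a Gaussian negative cluster crosses that line with
probability ~3·10⁻⁷ per droplet.

Duplex assays add two artefacts the classifier must absorb:

* **Spectral crosstalk** — FAM fluorescence bleeds linearly into the HEX
  detector.  The bleed coefficient `α̂` is estimated as the regression
  slope of HEX on FAM among FAM-positive/HEX-negative droplets (≥ 50
  required, else 0) and HEX amplitudes are compensated by
  `hex − α̂·max(0, fam − fam_neg_mean)` before thresholding.
* **Amplitude competition** — in double-positive droplets the two
  targets compete for reagents, depressing the HEX-positive amplitude to
  a fraction κ of its usual mean.  With κ = 0.5 the double-positive HEX
  cluster (~2,100 compensated units at default amplitudes) lies midway
  between HEX-negative (~1,030) and HEX-positive (~4,280), so a single
  pooled HEX cutoff would land on top of it.  The HEX split is therefore
  fitted separately within the FAM-negative droplets (negative vs
  HEX-only clusters) and within the FAM-positive droplets (FAM-only vs
  double clusters).  FAM classification never depends on the HEX state.

With both artefacts active at their default strengths this classifier
recovers simulator ground-truth labels at ≈100% accuracy (acceptance
threshold 99.5%).

## The simulator

The generator reproduces the statistical structure of real duplex wells,
not their chemistry:

| parameter | default | rationale |
|---|---|---|
| `n_droplets` | 15,000 | middle of the 10,000–20,000 yield range of the droplet reader |
| `droplet_volume_nl` | 0.85 | the conventional droplet volume of the instrument class; copies/µL scales inversely with it, so it is exposed in the config |
| FAM neg/pos means | 702 / 9,603 | negative and best-case positive amplitude scales observed on the FAM channel |
| HEX neg/pos means | 1,032 / 4,284 | same for the HEX channel |
| all SDs | 3% of mean | instruments report cluster means, not spreads; 3% keeps clusters >10 SD apart, matching the unambiguous separation seen in real wells |
| `crosstalk_alpha` | 0.05 | produces an intermediate HEX cluster in FAM-only droplets of the size seen in two-dimensional droplet plots; the true magnitude is not published |
| `competition_kappa` | 0.5 | places the double-positive HEX cluster midway between negative and positive, the qualitative geometry of the spike-competition cluster |
| `ntc_contamination_rate` | 0.005 copies/µL | gives ~0.06 expected positive droplets per NTC well — mostly clean NTCs with occasional single positives, and a rounded LOD of 1 copy |
| `rain_fraction` | 0 | rain is off under standard conditions; enable only for threshold robustness testing |

Occupancy is Poisson per droplet and independent across channels;
amplitude is binary in occupancy (any count ≥ 1 joins the positive
cluster) because endpoint PCR saturates.  Crosstalk is additive on every
droplet; competition is multiplicative on the HEX positive mean only in
double positives.  Dilution series sub-seed each well as
`seed + 1000·level_index + replicate` so any single well can be
regenerated.  Everything is bit-reproducible given `(params, truth,
seed)`.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: droplet volume variability, rain between
clusters (beyond the optional uniform stand-in), PCR inhibition,
amplitude drift across a run, template degradation, or reverse
transcription efficiency below 1.  Processing loss is modelled as exactly
proportional between spike and target, which is the assumption the
spike-in strategy itself makes.

## Normalization

Spike-in: efficiency = measured/expected spike copies; corrected target =
raw/efficiency.  The published phrasing ("multiplying raw counts against
processing efficiency") is implemented as division because the stated
purpose is compensating loss — multiplying by an efficiency < 1 would
shrink counts further.  Efficiencies above 1 are allowed but warn, since
they indicate a miscalibrated expected input.  The expected spike input
is a configuration parameter (the commercial spike's absolute copy number
is proprietary); when it is unknown, recoveries can be normalized to the
batch mean instead, which corrects relative differences between samples.
The corrected count carries a delta-method CI combining the relative
variances of the target and spike estimates.

Reference-gene: ratio of target to reference copies with a
ratio-of-independent-estimates delta CI; a zero reference returns an
undefined flag, never an infinity.

## Validation statistics

* Dilution linearity is the Pearson correlation of log10(copies) on
  log10(nominal fraction).  A 1:5 series spans ~4 orders of magnitude, so
  a raw-scale correlation would be dominated entirely by the top level;
  the raw-scale least-squares slope is still reported for transparency.
  Levels containing a zero estimate are excluded from the log fit and
  flagged.
* Replicate CV uses the sample SD (n−1) — series run two technical
  replicates per level, where the n−1 convention matters most.
* The estimator-bias acceptance check compares the **mean** of 100
  seeded wells to truth (a bias criterion): per-well noise at λ = 0.05
  with 15,000 droplets is ~4% and is irreducible counting error, while
  the estimator itself is unbiased well below 2%.
* Percent reduction, yield slope, purity improvement, and amplitude
  separation are direct arithmetic/t-test wrappers; values are displayed
  at two decimals where bench reports use two decimals, with full
  precision retained internally.

## Oligo QC

Tm uses the SantaLucia unified nearest-neighbor ΔH/ΔS table with
initiation terms, `Tm = ΔH/(ΔS + R·ln(C_T/4)) − 273.15`, an entropy salt
correction, and the von Ahsen monovalent-equivalent conversion
`Na_eq = monovalent + 120·sqrt(divalent − dNTP)` (mM).  Default
conditions are 50 mM monovalent, 3 mM divalent, 0.8 mM dNTP.  Primer Tm
is evaluated at 50 nM total strand concentration — the design-tool
convention under which the bundled primers fall inside their 58–62 °C
window — rather than the 900 nM they are run at, which would shift every
primer ~4 °C above the window; probes are evaluated at their working
250 nM.  All conditions are per-call configurable and echoed into
reports.  Tm acceptance is window membership, never point equality,
because the exact design-time ion settings are not published.

The GC clamp rule reads "clamp of 2" as the 3′-terminal two bases both
G/C (the common design-tool meaning).  In-silico PCR is exact-match by
default; the mismatch-tolerant extension (≤ 2 mismatches, none in the
3′-terminal 3 bases) exists for cross-strain screening.  The bundled
reference-gene template is a synthetic construct embedding the
β-spectrin oligos at the declared 107 bp spacing — a stand-in for the
natural mRNA sequence, used to exercise the amplicon-size machinery, not
a biological claim.

Consensus building drops gap-majority columns and ignores minority gaps
when comparing residues; two or more distinct residues in a column mask
it to N.

## Known limitations

* Copies/reaction scales by the full `V_r` regardless of the fraction of
  the reaction actually partitioned into droplets (dead volume); this is
  the convention under which copies/20 µL figures are reported, but it
  means the "reaction" is the assembled mix, not the droplet subset.
* The threshold classifier assumes at most four clusters; heavy rain or
  more complex multiplexes need a different geometry.
* The t-interval LOD treats NTC wells as exchangeable; systematic
  contamination differences between runs are outside the model.
* Problem sizes in the test suite and acceptance script (20–1,000 wells
  per study, 15,000 droplets per well) were chosen to make sampling error
  small relative to the tolerances being checked.
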