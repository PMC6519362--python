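# Methods

## Measurand

The assay quantifies low-level microsatellite instability in blood: at each
of 24 short (7–12 bp) monomorphic mononucleotide repeats, the fraction of
sequenced template molecules whose repeat tract has the reference
("wild-type", WT) length. Mismatch-repair-deficient tissue shows a small,
panel-wide depression of this fraction; the classifier aggregates that
signal into one score.

## Read processing

**Anchoring.** Markers are short amplicons with known 10 bp flanks, so reads
are assigned without genome alignment: a read matches a marker when both
flanks occur in it, left before right, each with at most one substitution
and no indels — indels must remain confined to the homopolymer tract, which
is exactly the part being measured (aligner gap placement inside
homopolymers is unreliable, which is why the BAM input path also re-anchors
by flanks and uses the alignment only to fetch candidate reads). The
observed repeat length is the count of repeat-unit bases strictly between
the anchors, not the tract width: an interrupting substitution therefore
shortens the call, a conservative choice since interruption and contraction
are indistinguishable to a frequency-based score. A read matching zero or
several markers, or with out-of-order anchors, is a no-match; the reverse
complement is tried when the forward orientation fails.

For speed, matching runs in two tiers: an exact substring pass over all
markers first (a unique exact double-anchor hit is accepted; two exact hits
are ambiguous), and only reads without an exact hit enter the
mismatch-tolerant Hamming scan over all markers. The two tiers can disagree
with a single-pass mismatch-tolerant search only if one marker matches
exactly while another matches inexactly in the same read, which requires
near-identical flanks within one panel.

**UMI consensus.** Reads sharing a (marker, UMI) key are treated as copies
of one template molecule. The family consensus is the modal observed length,
called only when the family has ≥ 2 reads and the mode reaches ≥ 66% of
members; ties and sub-threshold modes are no-calls. Majority-of-≥2 is the
minimal scheme that corrects independent per-read slippage errors: with
per-read miscall probability e ≤ 0.2, a miscalled consensus needs a
coinciding majority of errors, so the family-level error rate falls below e
(verified by simulation at e = 0.1, family size 3, 10,000 families). All
three knobs (`min_family_size`, `min_consensus_fraction`, tie handling) are
exposed in configuration, as is a raw-read counting mode obtained by setting
`min_family_size = 1`.

**QC.** Every input read is exactly one of anchored / no-match /
UMI-no-call; the tallies are asserted to partition the input and written to
the QC report. Markers with fewer than 100 called families (default;
generous at the assay's ~3,600 reads/marker) fail coverage QC and are
excluded from scoring rather than imputed.

## Control model and score

Per marker, control WT frequencies are modelled as Beta(α, β). Frequencies
are clamped into [ε, 1−ε] with ε = 10⁻⁶ before any Beta operation, because
exact 1.0 is common in controls and the Beta log-density is unbounded at the
support boundary. The default fit is the closed-form method of moments
(sample mean m, unbiased variance v, c = m(1−m)/v − 1, α = mc, β = (1−m)c),
chosen for determinism and reproducibility; maximum likelihood
(scipy's constrained fit, initialised at the moments estimate) is available
and recorded in the model file. Degenerate inputs raise explicit errors:
zero variance (all controls identical) and moment combinations no Beta can
attain (c ≤ 0). Training frequencies are not winsorized or trimmed — any
contamination of the control cohort is meant to surface in calibration.

A sample's per-marker evidence is the lower-tail probability
p_m = P(control ≤ observed) under the fitted Beta — the direction in which
depressed WT frequency (more instability) yields small p_m. Probabilities
are floored at 10⁻³⁰⁰ before logs. Fisher's method combines the k included
markers (X² = −2 Σ ln p, χ² with 2k df; exclusions shrink the degrees of
freedom rather than being imputed, since Fisher's method is valid at any k),
and the score is −log10 of the combined upper-tail probability. Thresholds
are inclusive: score ≥ 1.30 (5% control probability) and ≥ 2.00 (1%). Each
sample is scored independently; no cross-sample multiple-testing correction
is applied.

An empirical-rank tail probability ((1 + #{controls ≤ x})/(n+1)) is provided
for comparison with the parametric CDF on models fitted with
`keep_training_data=True`; it is deliberately not the default (see
Calibration).

## Synthetic data

The generator mirrors the model layer by layer: marker-specific control
Betas (means drawn in 0.95–0.999, concentrations in 50–300 — the
Beta(60, 2) neighbourhood typical of clean homopolymer assays), a
multiplicative CMMRD depression of 2–15% per marker, depth drawn at
3,642 ± 1,659 reads/marker/sample split into UMI families of ~12 reads, WT
family counts binomial at the sample's true fraction, variant molecules
offset by −1/+1/−2/+2 bases with an 80/20 split and a 0.7 contraction bias
(homopolymer PCR slippage is deletion-biased), and per-read ±1 slippage at
5% by default. The CMMRD effect range was set so that synthetic cohorts
reproduce the qualitative geometry of the assay — complete separation of
cases from controls — without claiming any real cohort's exact score values.
UMIs are drawn uniformly, so barcode collisions occur and are flagged in the
truth table.

What the generator does *not* emulate: base-quality errors outside the
tract, chimeric molecules, marker-specific capture bias, and real
inter-marker correlation structure. Passing tests therefore demonstrate the
pipeline's correctness under its own model assumptions, not clinical
performance on patient material.

All randomness flows through `numpy.random.default_rng([seed, stream])`
with fixed stream ids per purpose; identical configuration gives
byte-identical outputs (gzip members are written with fixed mtime and no
filename field).

## Calibration

With the model fitted on a large control cohort, the classifier is exactly
calibrated: scoring fresh control-model samples yields positive fractions of
5.0% and 1.0% at the two thresholds (measured at 100,000 samples with the
true generative parameters, and within 1 point with a 20,000-control fit).

At realistic training sizes the picture is different, and worth stating
plainly: with 40 training controls, plug-in parameter noise inflates the
Fisher statistic (E[−ln F̂(x)] exceeds E[−ln F(x)] by convexity), and the
realized type-I rate at the 1.30 threshold scatters around ~8% with a
spread of several points across training cohorts; the empirical-rank mode
errs in the opposite direction (≈1%) because its p-values are capped at
1/41. Neither deviation is a defect of the combination rule — it is the
price of estimating two shape parameters per marker from 40 observations.
In practice the thresholds function as they do because CMMRD samples score
far above the null scatter; users wanting nominal type-I control at small
training sizes should validate thresholds on held-out controls.

## Problem sizes used in the checks

The shipped checks run the calibration at 40 training / 10,000 scored
samples, the Monte-Carlo oracle for Fisher's method at 10⁶ draws for panel
sizes 1/5/24, Beta recovery at 200 replicates of n = 10,000, consensus error
suppression at 10,000 families, and the end-to-end cohort comparison at 20
control + 10 CMMRD samples simulated as reads at full assay depth against a
disjoint 40-control training cohort.

## Known limitations

- The bundled 24-marker panel is synthetic: structurally valid (lengths,
  units, anchor-terminating flanks) but not the published loci. Substitute a
  real panel by supplying its BED + metadata TSV to `--panel/--meta`.
- Dinucleotide repeats, somatic/tumor MSI calling and probe design are out
  of scope.
- Scores from aplastic or post-chemotherapy samples reflect the repopulating
  cell pool and should be interpreted cautiously; the package computes the
  score and leaves clinical interpretation to the user.
- Paired reads are family-merged by (marker, UMI) without fragment-level
  modelling; no Phred-based error weighting is performed.
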