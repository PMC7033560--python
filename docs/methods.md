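# Methods

## Quantification model

A pulse-labeled sample channel contains, for each peptide, a light and a
heavy species whose amounts split the precursor amount `A` by the heavy/total
fraction `h`: heavy `A·h`, light `A·(1−h)`. The booster channel is fully
heavy at molar ratio `r` (amount `r·A`); the noise channel is fully light.
Quantification proceeds strictly in the order

sum-normalize → collapse heavy states → subtract noise channel → divide by
booster → per-protein median.

The order is load-bearing: interference correction by noise-channel
subtraction is exact only if it happens after channels are put on a common
intensity scale and before ratios are formed.

Two normalization conventions are supported:

* **default** — booster and noise channels are included in the
  total-intensity calculation. Channels are pooled equimolar apart from the
  booster, so this rescales the booster's 2× total down to the per-sample
  level, and a peptide with heavy fraction `h` quantifies as `h` directly.
* **`exclude_booster_from_norm`** — the booster keeps its molar scale and
  samples quantify as `h / r`. This is the convention under which the exact
  identities hold (see below) and under which booster-amount invariance is
  literal: measured ratios times `r` are identical across booster amounts.

Exact inversion identities (verified to ≤1e−9 relative error in the tests,
in practice ~1e−13): with zero reporter noise and zero detection threshold,
the chain recovers every protein's true heavy fraction up to the booster
scaling constant, for any interference fraction `f < 1`. Without baseline
subtraction the measured ratio `(A·h + f·b)/(r·A + f·b)` exceeds `h/r`
whenever `h < r`, and the bias grows strictly with `f` — the simulated form
of TMT ratio compression.

Degenerate inputs: peptides whose booster signal is zero after subtraction
have an undefined ratio and are dropped (counted, never imputed). Blank
intensity cells read as 0 and are flagged; a channel with zero total
intensity is a hard normalization error. The S/N ≥ 5 record filter is
provided (`filter_records`, inclusive threshold, records without an S/N
value dropped whenever the threshold is positive) but defaults to off in the
pipeline: acquisition software applies this filter in its consensus step, so
real exports arrive pre-filtered and simulated tables model that state.

## Statistics

* Fold change: `log2(mean_treated / mean_control)` over replicate
  booster-relative values; unpaired two-sided equal-variance t-test (pooled
  variance; identical groups give t=0, p=1; zero pooled variance with
  distinct means gives ±inf, p=0).
* BH step-up is implemented directly as `adj_(i) = min_{j≥i} p_(j)·(n/j)`,
  with the factor written `n/j` so the adjusted value can never round below
  the raw p-value; statsmodels' implementation serves as an independent
  cross-check in the tests. The family is all proteins with a computable
  fold change: *not determinable* proteins (all treated replicates at zero
  with positive control mean) are excluded, since an undefined statistic
  cannot enter the family.
* Classification thresholds: strict on adjusted p (<0.05), inclusive on
  |log2 FC| (≥0.5); both are parameters.
* Z-scores are row-wise with sample standard deviation (n−1); constant rows
  map to zero and are flagged; rows with fewer than two finite values are
  excluded.
* Hierarchical clustering uses Euclidean distance; the linkage is average by
  default and configurable, as no single convention is canonical for these
  matrices. SciPy's input-order tie-breaking makes results deterministic.
* MDS is classical (Torgerson) scaling — double-centered squared distances,
  top-2 spectral coordinates — chosen over stress-minimizing variants for
  determinism; axis signs are fixed so the first sample's coordinate is
  non-negative.
* Ternary shares are computed on absolute log2 fold changes (sign handling
  is a design choice; shares of signed values would not be simplex-valued).
* The titration screen fits ordinary least squares per protein and selects
  on the raw slope p-value (<0.05) with a negative slope required by
  default; both knobs are exposed because the selection rule is a
  reconstruction rather than a published cutoff.

## Simulator

What it emulates: a log-normal proteome (abundance median 100 a.u.,
ln-sigma 0.6) digested into NB(mean 3, dispersion 0.3) peptides per protein
with log-normal ionization factors (ln-sigma 0.4) — a detected-peptide
dynamic range of roughly two orders of magnitude; linear short-pulse
labeling `h = rate × time × attenuation` capped at 1 (default rate 0.05/h,
i.e. 10% heavy after a 2 h pulse — consistent with proteome-median turnover
on the day scale); an exponential-saturation alternative was considered and
deferred since all supported scenarios stay in the ≤2 h linear regime.
Treatments act through a channel-level attenuation factor, optionally
modulated per protein by a sensitivity exponent (`a^γ`, γ log-normal) or by
per-condition uniform multipliers whose values are retained as ground truth.

Acquisition: a modification-state row is emitted only if its plex-summed
amount reaches the detection threshold — with the booster contributing
`r·A` to every heavy row's sum, this is precisely the rescue mechanism.
The default threshold is calibrated so that 20% of heavy rows would pass
without any booster (computed as the k-th largest no-booster heavy sum so
the passing count is exact). Reporter noise is multiplicative log-normal
with CV 0.08 per (row, channel); additive counting noise is deliberately
omitted at this stage. Co-isolation interference adds
`f × background` to every channel of an emitted row, with the per-row
background log-normal (ln-sigma 0.5) around the median peptide amount and
`f = 0.03` by default.

Interference is *identical across channels* within a row. This is what
makes noise-channel subtraction exactly correct in the model and is the
idealization the method itself relies on: in a real plex the booster's
extra material contributes proportionally more to the co-isolated
background, so subtraction is near-exact rather than exact. Other
non-emulated features of real data: isotopic impurity of reporter tags,
retention-time/chromatography structure, missed cleavages, peptide-level
detectability differences beyond ionization efficiency, and protein
inference ambiguity beyond the `shared` flag. Passing tests therefore
demonstrate correctness of the processing chain under the stated acquisition
model, not robustness to every artifact of real spectra.

Randomness: ground truth and acquisition noise use separate child streams of
the seed, so acquisition settings (booster amount, threshold, noise levels)
can be varied while holding the proteome fixed — this is what makes the
identification-monotonicity and bias-monotonicity checks deterministic
per-seed.

## Problem sizes

Scenario presets default to 400 proteins (~1,200 peptides; the stress
titration uses 300, the replicated contrast 1,000). The acceptance script
runs the dilution and time-course fits at 700 proteins (~2,100 peptides per
plex) so the channel medians are estimated tightly, and evaluates
attenuation-level clustering over five consecutive seeds. These sizes keep
every computation deterministic-in-seed and quick while leaving the measured
quantities dominated by the model, not by sampling noise.

## Known limitations

* PSM-level inputs must be pre-aggregated to one row per peptide
  modification state before reading.
* No isotopic-impurity correction matrix for reporter tags and no protein
  grouping/inference; the caller's master accessions are taken as given.
* Cross-run merging relies entirely on the booster as the common reference;
  no additional batch correction is applied, by design.
* The n.d. rule keys on all treated replicates reading zero after baseline
  subtraction; partially-zero proteins are tested normally, which slightly
  understates their fold change.
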