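# Methods

`pxrfkit` is a tested pipeline for the kind of study that asks how portable
X-ray fluorescence (pXRF) data from animal samples depend on how the sample
is presented to the instrument: sample state (thawed vs oven-dried),
scan location on the body, dwell time per beam, and whether the sample is
thick enough to satisfy the infinite-thickness assumption. Because real
instrument scans of this kind are not generally available, the package pairs
every analysis stage with a seeded synthetic-data generator whose ground
truth is known, so that each stage can be validated by parameter recovery.

## Forward model of a scan

A scan comprises three beam spectra (10, 40, 50 keV excitation; 2048
channels at 0.02 keV/channel) plus a 42-element concentration table, the two
outputs of a geochemistry-mode field instrument.

**Spectra.** Expected counts per channel are the sum of

* a bremsstrahlung-like continuum `A · t · x·e^(1−x)` with `x = E/(E_beam/3)`,
  rolled off smoothly at the beam energy (detector smearing softens the
  Duane–Hunt cutoff). Default amplitude `A = 0.5` counts/s/channel at the
  continuum peak.
* characteristic lines of each element present: area
  `r_e · c · t · I_line`, where `r_e` is the element's counts per %
  concentration per second, `c` the true concentration (% mass), `t` the
  dwell time and `I_line` the line's relative intensity (Kα1 = 1, Kβ1 = 0.15,
  Kβ2 = 0.04, L-lines 0.45–0.5). Every line is deposited in the beam whose
  energy best excites it (the lowest beam above the line's absorption-edge
  proxy, line + 1 keV) at full efficiency and in other exciting beams at a
  reduced efficiency of 0.3 — without this, the 50 keV beam would contain
  almost nothing but tube scatter and total-count normalisation would be
  meaningless.
* tungsten anode L-lines (Lα1 8.398, Lβ1 9.672 keV) scattered into every
  beam at 300/250 counts/s.

Each line is spread as a Gaussian with detector resolution
`FWHM(E) = 100 eV + 45 eV·√(E/keV)` (≈150 eV at Mn Kα, a typical silicon
drift detector), deposited by channel-edge CDF differences so areas are
exact. Realised counts are Poisson draws of the expectation. There are no
escape peaks, pile-up, or matrix absorption: the model's job is to exercise
the downstream processing and statistics with recoverable truth, not to
emulate detector physics.

**Physical effects.**

* *Moisture*: thawed tissue attenuates characteristic intensities (×0.7)
  and increases scatter (continuum and tube lines ×1.3).
* *Thin samples* (feathers by default): characteristic intensity ×0.5, and
  when scanned against the silica backing the tungsten-L window expectation
  is multiplied by 1.5 — the backing is "visible" through the sample.
* *Drying*: true concentrations are multiplied by a per-element state
  effect (default 1.4 for the biological panel — loss of water raises
  dry-matter concentrations).

**Reported concentrations.** The on-board quantification algorithm is not
implemented; reported values are generated as

    measured = truth · exp(−b₁/N − b₂/√N − τ/t) · LogNormal(mean 1, sd 1/√N)

with `N` the expected counts under the element's quantification peak and
`t` the dwell time. The three bias terms model, respectively: peak-area
loss near the detection limit (`b₁ = 8` counts), baseline-subtraction error
growing with relative counting noise (`b₂ = 1.2`), and dead-time /
stabilisation throughput error in short scans (`τ = 8` s). Each shrinks
with dwell time; together they are what makes 20 s scans systematically
different from 40–80 s scans while leaving 40/60/80 s near-equivalent,
the pattern such studies report. The mean-one lognormal makes the *median*
reported value decrease as noise grows, so median-based tests can see
noise-level differences. `N < 50` counts censors the element (below limit
of detection; the value is absent, never zero). Per-specimen biological
variation is lognormal with σ_log = 0.3 per (specimen, element), drawn once
and shared by all of that specimen's scans.

**Element panel.** The instrument reports 42 elements. The study this
emulates retained 20 after peak screening; the paper-style excluded set is
known but the retained 20 are not published, so the default panel is a
plausible biological choice (Mg Al P S Cl K Ca Ti Mn Fe Ni Cu Zn As Se Br
Rb Sr Zr Mo) — a fixture of this package, not a reproduced result.
Sensitivities `r_e = 3000·e^(−0.08(Z−12))` counts/%/s decrease with atomic
number so that replicate precision degrades for heavier elements,
reproducing the instrument's precision gradient. (On real hardware the
gradient has a different physical origin; here it is imposed directly
because only its consequences matter downstream.)

**Design grid.** Four taxa × 10 specimens, fish/mammal/reptile scanned
thawed and dried at three body locations, bird flight feathers scanned in
their natural state at two locations (vane, calamus — thin by default);
dwell times 20/40/60/80 s per beam, with and without silica backing, two
replicate scans. One JSON export per cell, byte-identical under the same
seed. Exports follow the schema in `schema/scan_export.json`; validation
is implemented with pydantic models mirroring that document.

## Spectrum processing

Processing is smooth → baseline → net, with `net = smoothed − baseline`
held exactly.

* *Smoothing*: convolution with a normalised Gaussian kernel truncated at
  ±4σ, reflective boundaries. The general-purpose default is σ = 2 channels
  (40 eV), well below detector resolution; peak screening uses
  resolution-matched smoothing (σ = FWHM at the axis midpoint / 2.355 ≈ 6.4
  channels), which suppresses the Poisson noise floor that otherwise
  dominates signal-to-noise decisions.
* *Baseline*: SNIP-style iterative clipping. One full sweep runs the
  half-window `m` from 24 channels down to 1, replacing `b[i]` with
  `min(b[i], (b[i−m]+b[i+m])/2)` on interior channels; edge channels are
  left untouched so straight-line continua are exact fixed points. The
  default is a **single** sweep: repeated sweeps erode any concave continuum
  toward its convex minorant, which systematically inflates net counts and
  invalidates SNR-based presence decisions (measured directly on synthetic
  spectra during development). More sweeps remain available for spectra with
  heavy peak crowding.
* *Windows*: a line's counts are summed over channels whose centres lie
  within ±1.5 × FWHM(E) of the line energy (closed interval). This window
  holds ≈97% of a resolution-broadened peak; tests that compare window sums
  to injected areas correct for the truncated tail.

Energy calibration is taken from export metadata (`E_i = offset + gain·i`,
channel centres, 0-based); no peak-based recalibration is attempted.

## Element screening

An element is trusted only if its diagnostic Kα1 *and* Kβ peaks are visible
in the net spectra of the longest (80 s) thawed-state scans. "Kβ" is Kβ2
where it is a resolved line (Z ≥ 33) and the Kβ1-dominated complex centroid
for lighter elements, where an SDD cannot resolve Kβ2. Visibility is
Currie-style: `snr = net / √(max(baseline, 1)) ≥ 3` with positive net.
Lines no beam can excite, lines beyond the 40.94 keV axis, and lines below
1 keV (air-path and detector-window absorption) count as absent — this is
what excludes the heavy metals (W, Pb, Th, U: K-lines ≥ 57 keV) exactly as
a real screening would. By default an element is excluded only when a
diagnostic line is absent in *all* screened scans; the fraction is
configurable, and recovery testing uses a majority rule (0.5), which is
much more robust to single-scan noise flukes.

Two physical limits of deconvolution-free screening are worth stating
because the test fixtures are built around them. First, adjacent-Z panel
members overlap: element Z's Kβ1 falls inside element (Z+1)'s Kα window
through the whole 3d row, and Z's Kα tail reaches (Z−1)'s Kβ window, so
whenever one of the pair is genuinely present the neighbour's windows are
contaminated. Second, below ~5 keV the Kα and Kβ windows of one element
nearly coincide, so the two-line rule gives no independent confirmation
there. Exact panel-recovery tests therefore inject well-separated elements
(As, In) — any fixture with panel neighbours at Z±1 would be testing peak
overlap, not the screening logic. The tungsten L-lines similarly sit on the
Cu/Zn Kα/Kβ region, so recovery fixtures switch tube scatter off.

The LOD filter blanks below-LOD entries to missing and drops an element
from a given comparison when any compared group has fewer than 3 detected
values.

## Infinite-thickness QC

For each scan site, net counts in the tungsten Lα1 and Lβ1 windows of the
50 keV beam are normalised by the spectrum's total net counts (making the
measure invariant to dwell and source intensity), averaged over replicates
and dwell times, and compared between backed and unbacked scans:

    rel_diff = |b − u| / ((b + u)/2),   met ⇔ rel_diff ≤ 0.10 for both lines.

The 0.10 threshold operationalises "the same characteristic lines with and
without backing"; counting noise alone gives rel_diff ≲ 0.02 at these count
rates, while a thin sample with backing gain 1.5 gives ≈ 0.35 (the raw
forward-model value 0.4 is pulled down slightly because the inflated
windows also enter the normalising total). Verdicts on fully synthetic
studies reproduce generator truth — carcass sites pass, feathers fail.

## Statistics

* **Per-element tests** are median (τ = 0.5) quantile regressions on a
  binary factor. For a two-level design the check-loss minimiser is the
  pair of group medians, so the fit is computed directly and verified
  against grid minimisation of the check loss. Inference is by permutation
  of group labels on the |median difference| statistic,
  `p = (1 + #{permuted ≥ observed}) / (n_perm + 1)`, seeded and
  deterministic. The median statistic is insensitive to some alternatives a
  mean would catch (e.g. two-point distributions whose every regrouping has
  the same medians); exact enumeration in the test suite documents this.
  Multi-level factors run all pairwise tests with Benjamini–Hochberg
  adjustment within the family; results carry both raw and adjusted p.
* **Overall tests** fit one Gaussian linear model per element on
  `log(x + δ)` (δ = half the smallest positive value; identity transform
  available) under null and one-way designs, form `LR_j = n·ln(RSS0/RSS1)`,
  and sum over elements. Significance comes from jointly permuting response
  rows — the Freedman–Lane scheme, which under an intercept-only null is
  row permutation — preserving inter-element correlation. Gaussian-on-log
  is chosen because concentrations are continuous positive percentages, not
  counts; negative-binomial-style families are out of scope.
* **Replicate precision** is Spearman's rank correlation (mid-ranks for
  ties) between duplicate scans, pooled over all (element, scan-pair)
  values and per element. The pooled coefficient is dominated by the
  four-decade spread of element concentrations and sits at ≈ 0.998 under
  default conditions; the per-element coefficients decline with atomic
  number (rank correlation ≈ −0.65) because counting noise grows as
  sensitivity falls.
* Permutation count defaults to 999 (α = 0.05 resolvable); calibration
  tests use 199 permutations over 500 null replications and require type-I
  error in [0.03, 0.08]. The summary matrix flags cells at strict p < α on
  raw p-values, mirroring supplement-style reporting; adjusted p-values are
  carried alongside.

Replicates enter factor tests as separate observations by default; a
config switch (`aggregate_replicates`) averages them first.

## Pipeline and provenance

`run_pipeline` executes ingest → panel screening → thickness QC → LOD
filtering → state/scan-time/location tests → replicate precision → summary.
State and scan-time are tested within each (taxon, location); location is
tested within the thawed state (natural for taxa never thawed). Every
output CSV carries a header with the stage name, a hash of the analysis
parameters and the seed; a manifest lets a re-run with the same
configuration skip completed stages. Per-comparison seeds are derived from
the run seed plus a stable hash of (taxon, factor, context), so results are
reproducible file-by-file.

## Problem sizes used in validation

Unit and acceptance tests run on deliberately compact studies: recovery of
the ×1.5 drying effect uses the full 10 specimens per taxon but one taxon,
one location and one dwell time (80 s, the screening condition);
scan-time and precision patterns use 10 specimens × 4 dwell times × 2
replicates; panel recovery uses 4 specimens × 16 eighty-second scans per
study, 20 studies; thickness agreement uses 3 specimens each of fish
(thick) and bird (thin). These sizes give the properties under test
comfortable margins while keeping the whole suite fast enough to run on
every change.

## Known limitations

* The forward model omits escape/sum peaks, matrix absorption and
  inter-element enhancement; fundamental-parameters quantification is
  explicitly out of scope (concentrations are simulated, not inverted from
  spectra).
* Screening without peak deconvolution cannot separate adjacent-Z panel
  members or the Cu/Zn region from tungsten scatter; on dense panels it
  both misses weak trace elements and picks up overlap ghosts, much as a
  visual screening would.
* Passing tests demonstrate that the pipeline recovers what this generator
  encodes. Real scans add detector artefacts, heterogeneous matrices and
  calibration drift that the generator does not emulate; conclusions about
  real instruments require real scans.
* The statistical battery treats scans as exchangeable under the null;
  specimen identity is not modelled as a blocking factor. With strong
  between-specimen variation this is conservative for balanced designs but
  costs power for subtle within-specimen effects.
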