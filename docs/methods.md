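# Methods

`isopick` extracts a peak list — one (monoisotopic mass, charge, intensity)
entry per detected biomolecule — from profile-mode proteomic mass spectra by
modelling the spectrum as a sum of isotopic distributions (IDs) and greedily
fitting and subtracting theoretical IDs (TIDs). This note records the model,
its assumptions, the numerical choices, and what the synthetic tests do and
do not demonstrate.

## The model

A peptide or protein of monoisotopic mass M0 carrying Z protons appears at
m/z = (M0 + Z·1.00728)/Z as a comb of isotope peaks spaced 1.00235/Z Da (the
average ¹³C-driven spacing), with relative abundances fixed by elemental
isotope frequencies. Each peak is rendered as a Gaussian of
σ = (m/z)/(2.35482·RP), where RP = m/Δm is the resolution power and
2.35482 = 2√(2 ln 2) converts FWHM to σ.

### Isotopic distributions by matrix convolution

The ID of a molecule is built atom by atom: at each step the outer product of
the current abundance vector with the next atom's isotope abundances is
formed and its anti-diagonals — isotopologue configurations sharing a nominal
neutron count — are summed. Grouping is by integer mass shift; fine isotopic
structure (¹³C vs ¹⁵N at the same nominal shift) is deliberately not
resolved, matching unit-resolution bookkeeping. Exactness is verified against
exhaustive isotopologue enumeration for all CHNOS molecules up to 10 atoms
(max abs error ~3e-16).

### Reference residues and TID tables

Real compositions are unknown at extraction time, so TIDs come from
artificial homopolymers of a reference residue: the classical Averagine
average residue (C4.9384 H7.7583 N1.3577 O1.4773 S0.0417, 111.054 Da), real
Leucine (C6H11NO, 113.084 Da), and an updated average residue refit on a
newer proteome composition (C4.949 H7.833 O1.473 N1.361 S0.038; its
monoisotopic mass evaluates to 111.116 Da). For n = 1..N residues, each
sequence gets one terminal H2O (peptide convention, switchable off), its
fractional formula is integerized — counts rounded, hydrogen adjusted until
the integer formula's monoisotopic mass matches the fractional target within
half a hydrogen — and its ID is computed and truncated to 30 positions.
Tables reach 20 kDa by default and 170 kDa when the input range demands it
(built lazily; optional on-disk cache keyed by residue, limit and isotope
table). A TID at an arbitrary mass is the position-wise linear interpolation
of the two bracketing rows; at 5 kDa this differs from a direct fractional
computation by < 0.01 per position.

Truncation to 30 positions discards < 1e-6 per position up to ~10 kDa and
< 1e-4 at the 20 kDa limit — negligible against the 0.1% TID pruning used in
fitting.

### The double model

The most-likely (apex) isotope index k\*(M0) is the argmax of the table rows,
made non-decreasing in mass. Its inverse — apex mass back to monoisotopic
mass — is a piecewise-linear interpolation through the (apex mass, M0) pairs
of all rows: exact at the knots, monotone, bounded error. When isotope peaks
are resolvable (m/z / RP < 1/Z) the candidate peak is fitted as the
monoisotopic one; otherwise only the envelope apex is observable and the
inverse regression supplies M0. This is what lets one algorithm serve both a
RP 500 linear TOF and a RP 60 000 FTICR.

## Pipeline stages

**Preprocessing.** Baseline correction is applied twice per input spectrum:
a moving-window minimum envelope (window = 5% of the points by default),
smoothed by a moving average of the same width, subtracted, clamped at zero.
The estimator is a stand-in for the published method's uncited algorithm and
is pluggable. Two passes remove both the offset and the residual a single
pass leaves on sloping baselines; a third pass changes the signal by < 1%
RMS. No normalization is applied anywhere, so each replicate contributes in
proportion to its total ion current. Savitzky–Golay and a hand-rolled
tricube local-linear Lowess are available but off by default.

**Replicates.** M spectra are resampled (linearly) onto the first spectrum's
grid clipped to the common range; the N×M matrix's row sums form the
representative spectrum. Quality control drops replicates whose Pearson
correlation with the representative is below 0.4 (single recompute by
default; an `iterate` flag repeats to stability).

**Resolution-power estimation.** The representative is split into four
intervals of equal point counts; each interval's most intense point is fitted
by the monoisotoping machinery at 15 log-spaced RPs in [RPin/2, 2·RPin]; the
RP minimizing the mean best score wins. The full-TID evaluation stencil is
always used here — the ZMax = 1 reduced stencil's RP contrast is smaller
than the noise floor. The score-vs-RP profile is asymmetric (over-estimated
RP is penalized much harder than under-estimated), so estimates err slightly
low; on seeded fixtures they land within one grid step (~10%) of the
rendering RP.

**Peak detection.** The maximal curve takes, at every grid point, the
spectrum maximum over a window of one resolution element (m/z)/RP. A
candidate peak is reported for each plateau of this curve, at the spectrum's
argmax within the plateau (ties toward lower m/z) — with noise, the plateau's
geometric center can sit half a window off-apex, which would put the true
placement beyond the fine-shift search. Maxima closer than one resolution
element to a stronger maximum are merged into it.

**Intensity threshold.** Local-maxima intensities are modelled per window as
a noise Gaussian; the threshold at the window center is μ+2σ, interpolated
linearly across the spectrum. Windows tile the spectrum with widths inversely
proportional to a proteome mass-density model (a bundled log-normal with
median 1.5 kDa standing in for a database-derived histogram; replaceable by a
two-column file), sized to hold ~100 maxima and clamped to [200 points, 10%
of the spectrum]; windows with < 5 maxima merge leftward. μ and σ are the
median and 1.4826·MAD — robust to windows where up to half the maxima are
real isotope peaks, where trimmed moments demonstrably fail. On pure
Gaussian noise the curve leaves ~4% of maxima above it; those survivors are
the method's false-positive budget, consistent with the permissive
peak-selection philosophy of profile-mode deisotoping.

**Monoisotoping loop.** Repeatedly: take the lowest-m/z surviving candidate;
drop it if the current representative is below the threshold there;
otherwise, for every charge 1..ZMax and every configured residue, retrieve
the TID at the implied monoisotopic mass, prune it to peaks ≥ 1/1000 of its
maximum, and render it over a region padded 3σ beyond the outer kept peaks,
scaled so the curve equals the observed intensity at the reference position,
on top of the region minimum as a local residual baseline. Curve-value (not
stick) scaling is essential at low resolution, where the envelope apex
exceeds any single stick. Coarse shifts: for a monoisotopic reference, also
try the placement k\* positions left (the observed peak may really be the
apex, with the true monoisotopic peak lost under the threshold); for a
most-likely reference, ±1 position absorbs regression error. Each coarse
placement is refined by sliding over ±0.25·FWHM at grid resolution.

The score is the weighted mean absolute difference between curve and
spectrum — both divided by the reference intensity, making the 0.35
acceptance threshold dimensionless — at a small stencil: for ZMax > 1, each
stick's apex, its two flank points (min(FWHM/2, spacing/4) away) and the two
inter-stick midpoints; the midpoints are what distinguish charge states,
since a z-fold coarser comb leaves real peaks in its valleys. For ZMax = 1,
the reference position plus points straddling one and two isotope positions
left of the estimated monoisotopic peak — positioned to catch a real peak
lurking where the placement claims there is none. In ESI mode the score is
inflated by (1 + λ·(ZMax−Z)/ZMax), λ = 0.05, penalizing improbable low
charges. Ties break toward lower charge, then residue order.

A winning fit below 0.35 is emitted (intensity = sum of scaled TID sticks,
the full isotopologue population), subtracted from the representative
(clamped at zero), and every candidate within half an isotope spacing of a
stick where the fitted curve reaches ≥ 80% of the observed intensity is
consumed. Each iteration removes at least the current candidate, so the loop
terminates.

**Replicate options.** Overlap management weights each evaluation position
by the cross-replicate Pearson correlation (clamped at zero) between the
reference peak and that position — two species varying independently across
replicates decorrelate exactly where they do not share peaks — and
additionally consumes, with an accepted fit, region candidates correlating
≥ 0.8 with its reference peak (needs M ≥ 3). Alignment shifts each replicate
by the integer grid offset (|shift| ≤ FWHM in steps, edge-clamped) that
maximizes its correlation with the representative over the most
informative half of the region's points, ranked by cross-replicate
correlation against the replicates' regional totals (intensity-ranked when
that is degenerate); shift 0 is always a candidate, so correlation never
decreases (needs M ≥ 2). Because alignment recomputes row sums, earlier TID
subtractions are re-applied to the realigned region.

## Synthetic data and study conditions

The generator renders species through the same TID machinery at a stated RP,
with an exponentially decaying additive baseline, Gaussian noise, and —
across replicates — independent per-species log-normal abundance factors
(CV 0.3 by default; this independent co-variation is precisely what makes
overlap weights informative) plus a rounded-Gaussian whole-scan grid jitter.
Grids default to 10 points per FWHM.

Standard conditions used by the tests and the acceptance script, chosen once
as representative of the instrument classes involved:

* recovery: 5 species (1.2–4.2 kDa, charges 1 and 2, apex SNR 10–15 over
  σ = 10 noise with a decaying baseline) at RP 10 000, 20 seeds;
* low-resolution double model: one 20 kDa species at RP 500 — only the
  envelope apex is resolvable;
* RP estimation: four charge-1 species at RP 1000, mild noise;
* overlap: two species 3 Da apart (the second monoisotopic peak coinciding
  with the first species' third isotope), 30 replicates, CV 0.4, 1-step
  jitter;
* thresholding: pure i.i.d. N(10, 2) noise.

What passing these does **not** show: real spectra have heteroscedastic and
correlated (chemical) noise, detector saturation, calibration drift that is
mass-dependent rather than a rigid shift, and composition deviating from any
average residue; the generator models none of these. Recovery rates here are
upper bounds on real-data behavior; the published evaluations of this
algorithm family report precisions of 20–30% on real MALDI data, i.e. noise
entries alongside correct ones are expected output, not a defect — the score
threshold trades recall against them.

## Numerical choices and degenerate inputs

* Isotope table: built-in IUPAC-style CHNOS masses/abundances, replaceable
  by a plain-text file (element, mass, abundance per line; validated).
* Isotope position spacing 1.00235 Da; proton mass 1.00727646688 Da
  (positive-mode proton adducts).
* Interpolated TIDs are exact at table rows; out-of-range masses raise.
* Zero-variance replicate columns: correlation weights fall back to 1 with a
  warning; overlap removal retains the candidate.
* All-zero evaluation weights: score 0 with a warning.
* Alignment regions shorter than twice the shift bound are skipped with a
  warning; all-zero shifts returned.
* Non-monotone or duplicated m/z on input is repaired (sort, average) with a
  warning; centroided mzXML scans and single-point files are rejected.
* Scores tie-break to lower charge, then configured residue order, then
  smaller fine shift, keeping output deterministic; the whole extraction is
  RNG-free.

## Known limitations

* Greedy subtraction: a wrong early fit can damage later overlapping IDs;
  no global optimization is attempted (by design).
* The baseline estimator leaves the noise floor roughly 3.5σ above zero
  (it removes the lower envelope, not the mean), which makes the normalized
  score more permissive toward noise candidates.
* The ±1-isotope-position ambiguity near the monoisotopic/most-likely
  transition (~3–8 kDa at charge 1) is decided purely by score and can flip
  under noise — visible as occasional whole-spacing mass errors, a known
  behavior of this algorithm family.
* Only CHNOS chemistry by default; glycans, nucleotides and metal adducts
  need a custom residue/table.
* mzXML is read (profile scans summed); mzML and vendor formats are out of
  scope.
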