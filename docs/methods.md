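# Methods

## The detection statistic

The detector operates on merged or unmerged integrated intensities
after scaling. Reflections are assigned to equally spaced bins in
inverse resolution, index k = ⌊(1/d)/w⌋ with default width
w = 0.001 Å⁻¹ — fine enough to resolve ice rings (the curated ranges
span 7–40 bins) while keeping tens of reflections per bin in ordinary
datasets. Per bin the count N, sample mean ⟨I⟩, sample standard
deviation s (denominator N−1; the convention is a free choice and is
documented here because it is not standardized) and standardized mean
m = ⟨I⟩/s are computed. A bin is *valid* when N ≥ 3 and s > 0: a sample
SD needs at least two points, and three avoids pathological two-point
bins. Negative intensities are retained everywhere — they are the
signature being detected, not outliers to clean.

m is invariant under rescaling all intensities by a positive constant,
which is what makes one threshold work across arbitrarily scaled
datasets. For ideal acentric Wilson data in a thin shell the intensities
are exponential, so m → 1; real data drift smoothly with resolution
(noise inflates s at high resolution, centric fractions and anisotropy
shift m), which is why a fitted baseline replaces any theoretical
constant.

When a file carries only amplitudes, the same machinery runs on F; the
contamination signature is attenuated but the pipeline is unchanged.

## Baseline estimation

The baseline f(1/d) is fitted to the valid bins whose centers lie
outside all candidate ice-ring ranges:

1. **IQR pre-filter** — bins with m outside
   [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are dropped (Tukey fences).
2. **Robust smoothing** — local-linear Gaussian-kernel regression in
   1/d with bandwidth σ = 0.005 Å⁻¹ (five default bin widths: wide
   enough to average bin noise, narrow enough to track the Wilson
   falloff). Three reweighting iterations follow, each giving zero
   weight to bins whose residual exceeds 3 robust SDs
   (scale = 1.4826 × MAD, floored relative to the data magnitude so a
   numerically clean series is never clipped). The local-linear form is
   used rather than a kernel-weighted mean because the zeroth-order
   smooth is biased at the edges of the fitted interval; that bias
   masquerades as outliers under MAD clipping and erodes the fit
   inward on low-noise data, while the first-order fit reproduces
   linear trends exactly everywhere.
3. **Interpolation** — the smoothed values at retained bins are
   linearly interpolated onto every bin center, including those inside
   the masked ranges; beyond the outermost retained bin the baseline is
   held constant.

Because masked bins never enter the fit, the baseline is provably
independent of the data inside the candidate ranges — contamination
cannot drag its own reference down.

All four constants are exposed in `BaselineParams`; the defaults above
are package choices, made once for stability, not fitted quantities.

## Scoring and flagging

S = √N (m − f) on valid bins; invalid bins carry no score. A candidate
range is flagged when any valid bin centered inside it reaches |S| ≥ 5.
The per-bin rule (rather than a range average) matches how a narrow
ring concentrates in one or two bins; weak rings below threshold
legitimately escape. Both signs flag identically — background
underestimation inflates m in the ring core, overestimation (the
flanks) depresses it — and the report records the signed peak score per
range. Bins outside the curated table are never flagged, whatever their
score: restricting the search to expected resolutions is what keeps the
false-positive rate low, at the cost of missing rings shifted by
wavelength or detector-distance errors (a documented limitation).

The curated table of 25 resolution ranges covering hexagonal- and
cubic-ice rings is shipped as data and treated as opaque constants; a
user table can replace it. Range membership is closed at both
endpoints. The table covers about a third of the 1/d axis it spans, so
the baseline always retains a majority of bins.

The theoretical ring-position helper treats cubic ice as a diamond-type
lattice — allowed reflections have h,k,l all odd, or all even with
h+k+l ≡ 0 (mod 4) — which yields exactly three rings above 1.9 Å
(3.67, 2.25, 1.92 Å at a = 6.358 Å); plain face-centring rules would
wrongly admit a (200) ring at 3.18 Å. Hexagonal positions come from the
standard 1/d² = 4(h²+hk+k²)/(3a²) + l²/c². The helper exists for visual
comparison only; flagging uses the curated table exclusively.

## Merging and centricity

Symmetry equivalents (Friedel mates included) are mapped to the
lexicographically greatest equivalent index. Merging uses the
unweighted mean, I = (1/N)ΣIᵢ, with independent errors summed in
quadrature: σ² = (1/N²)Σσᵢ², hence σ/√N for equal sigmas. This is what
produces the discrete I/σ "ladder" at low resolution, with rungs at
ratios √N. Inverse-variance weighting is deliberately not the default.
Epsilon factors (symmetry enhancement of zone intensities) are not
applied anywhere; this is a known limitation relative to production
merging programs.

## French–Wilson conversion

The measured intensity is modelled as I ~ Normal(J, σI²) about the true
intensity J = F², with the Wilson prior on F for the reflection's
resolution shell: acentric p(F) ∝ (2F/Σ)exp(−F²/Σ), centric
p(F) ∝ exp(−F²/2Σ). Reported are the posterior mean E[F] and SD.

Σ per shell is the mean intensity in equal-count shells in 1/d³
(≈ equal reciprocal volume, default 20 shells), floored at 10⁻³ of the
global mean so heavily contaminated shells cannot produce a
non-positive prior scale (the floor is logged when it engages).

Moments are evaluated by composite Gauss–Legendre quadrature on
F ∈ [0, Fmax], Fmax = √(max(I,0) + 10 σI). The posterior of a strong
reflection is a spike of width ≈ σI/(2√I) that a fixed grid cannot
resolve, so per reflection a 128-node panel is placed on a ±10-width
window around the posterior peak (located from the truncated-normal
form of the posterior in J: mode at I − σI²/Σ_eff, Σ_eff = Σ or 2Σ for
centrics) with 64-node panels covering the remainder; the integrand is
exponentiated after subtracting its running maximum. Against fine-grid
and adaptive-quadrature oracles this is accurate to ~10⁻¹⁰ relative
away from the degenerate Σ → 0 corner. Limits: I/σI → ∞ gives
F → √I, σF → σI/(2√I); I ≪ 0 or Σ → 0 gives small positive F with
prior-dominated σF. No closed-form table lookup is used, and no outlier
truncation precedes conversion: the module intentionally reproduces,
not repairs, the conversion's behaviour on contaminated data.

## Synthetic data generator

The generator emulates the statistical regime the detector assumes, at
the level of integrated, merged intensities (no detector images, spot
shapes or geometry):

- all unique reflections of the cell (default orthorhombic
  40 × 50 × 60 Å, P2₁2₁2₁ operators) to d_min = 1.6 Å — about 16 500
  unique reflections after Friedel and point-group merging, enough for
  well-populated 0.001 Å⁻¹ bins through the ice-ring region while a
  full detection run takes about a second;
- true intensities J ~ Exponential(Σ(d)) for acentrics,
  Σ(d)·χ²₁ for centrics, with Σ(d) = K·exp(−B/2d²), defaults K = 100
  (arbitrary units), B = 20 Å² (a typical macromolecular temperature
  factor);
- measurement noise I = J + Normal(0, σ/√mult) with
  σ = a·Σ(d) + b·√max(J,0), defaults a = 0.05, b = 0.3 — a fractional
  background term plus a counting-statistics term giving peak I/σ ≈ 20,
  unexceptional for scaled synchrotron data;
- stepped multiplicity by resolution (8/4/2/1 below 6, 4, 2.5 Å),
  merged with the σ/√N algebra, reproducing the I/σ ladder;
- systematic absences of the screw axes are not modelled, and the σ
  model is stationary per reflection (no image-to-image variation).

Ice contamination adds amplitude·Σ(d)·w(u) inside a resolution range,
where u ∈ [−1, 1] spans the range in 1/d: a raised-cosine core over the
central (1 − flank_fraction) of the range and negative cosine lobes of
half the core amplitude in the flanks, emulating background
underestimation under the ring and overestimation beside it; at
amplitude ≥ 1 the flanks drive weak reflections negative. Sigmas are
untouched — the bias lives in the background model, not the counting
noise. Scaling by the local Wilson mean keeps the perturbation
scale-free, so invariance tests stay meaningful. The exact lobe shape
is a synthetic stand-in; real profiles depend on the integration
software.

Defaults for the detection experiments: contamination amplitude 2 with
flank fraction 0.3 injected into curated ranges 5, 6 and 8; 20 seeded
datasets per condition. Under these conditions all three ranges are
recovered in 20/20 runs and clean data produces ≤ 0.1 false flags per
dataset.

## What passing tests do and do not show

The generator matches the detector's distributional assumptions by
construction, so recovery results demonstrate the statistic's
mechanics — scale invariance, baseline robustness, per-range flagging —
not its performance on real depositions, where anisotropy, radiation
damage, twinning and non-ice rings add structure the generator omits.
Conversely the false-flag rate on clean synthetic data is a lower bound
on what real data would show.

## Numerical choices and degenerate inputs

- Bin edges are half-open in 1/d ([kw, (k+1)w)); a d-spacing exactly on
  an edge goes to the higher-index bin.
- Ice-range membership is closed; ties favour "in range" (conservative
  for masking, generous for flagging).
- Baseline estimation requires ≥ 10 valid bins outside the masked
  ranges after filtering; fewer raises a degenerate-data error (CLI
  exit code 3).
- Merging requires unmerged input with intensities; canonical-index
  choice is deterministic, so output order is reproducible.
- The generator is bitwise reproducible for a fixed seed.
- MTZ column discovery prefers intensity pairs (I/SIGI, IMEAN/SIGIMEAN)
  over amplitude pairs (F/SIGF, FP/SIGFP); the choice is logged.

## Known limitations

- Detection only: no correction of contaminated intensities.
- Only ice rings at their usual resolutions: shifted rings (wrong
  wavelength/detector distance) and non-ice rings (detergent, plate,
  sample-holder) are out of scope, though `powder_ring_positions`
  supports eyeballing shifts.
- No epsilon factors, no anomalous-pair separation, no unmerged
  multi-batch MTZ handling.
- The contamination profile and σ model are plausible stand-ins, not
  fits to any instrument.
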