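# Methods

`stillsmerge` turns per-still integrated reflection lists from a serial
femtosecond crystallography (SFX) experiment into a merged, quality-assessed
intensity set.  Each XFEL pulse destroys its crystal, so every image is a
still from a different, randomly oriented crystal, recorded with a
self-amplified spontaneous emission (SASE) pulse whose spectrum jitters from
shot to shot.  The pipeline models that physics explicitly instead of
averaging it away Monte-Carlo style.

## Geometry and conventions

The incident beam travels along +z in the lab frame.  The Ewald sphere for
wavelength λ has centre (0, 0, −1/λ) and radius 1/λ; a reciprocal vector
**q** = U·**h**/a (cubic cell, edge a = 106.1 Å, space group I23) is excited
at λ = −2q_z/|**q**|².  Merging symmetry is point group 23 with Friedel
mates merged (Laue m-3); anomalous differences are not modelled.  Miller
indices are stored signed and unreduced per observation — the ambiguity
stage needs them — and are mapped to a canonical asymmetric-unit
representative (lexicographic maximum over the 24-member orbit) only when
correlating or merging.  I-centring means reflections with odd h+k+l do not
exist.

## Beam spectrum

Each pulse's wavelength distribution is a Gaussian N(μ, σ) truncated at
μ ± 2σ; the truncation points define the *limiting Ewald spheres*.  μ is
nominally 1.46 Å and is re-estimated per image during refinement.  The width
of a fitted excitation-wavelength histogram overstates σ because mosaicity
and finite crystal size broaden it too; multiplying the fitted s.d. by a
deconvolution factor (default 0.27) recovers the bandwidth alone.  That
factor is calibrated for a particular diffraction regime, so a pipeline run
can instead supply a known bandwidth (`use_derived_sigma = False`), which is
what the synthetic recovery studies do — there the generating σ is a known
condition of the experiment.

## Partiality model

A reciprocal-lattice point (rlp) is a spherical top-hat of radius
r(q) = r₀ + |q|·sin(η), with base radius r₀ = 1.8 × 10⁻⁴ Å⁻¹ (from the
~0.5 μm crystal size) and mosaicity η = 0.03°, so spots grow with
resolution.  Each wavelength in [l, h] = [μ−2σ, μ+2σ] contributes an Ewald
sphere; the nest of spheres sweeps a slab through the rlp.  A sphere cutting
the diameter at fraction x (0 and 1 at the two edges) intersects the rlp in
a disc whose area, relative to the central section, is 4x(1−x) — the
cylindrical approximation with the cylinder base in the Ewald tangent
plane.  Partiality is the Gaussian-weighted integral of that relative area
over the wavelengths the rlp excites, normalised by the weight of the full
truncated band:

    P = ∫ 4x(λ)(1−x(λ)) G(λ; μ, σ) [0 ≤ x(λ) ≤ 1] dλ / ∫ G(λ; μ, σ) dλ,

both integrals over [l, h], with x(λ) linear through the fractions p and q
cut by the two limiting spheres.  The quadratic-times-Gaussian integral has
a closed form in erf/exp, which is what the code evaluates; the test suite
checks it against an independent fine-quadrature integration of the same
geometric model (exact sphere distances, no linearisation) to |Δ| < 10⁻³
over random configurations.  The linearisation of wavelength across the rlp
diameter is accurate to order r/(Ewald radius) ≈ 10⁻⁴.

Properties anchored by construction: a central cut spanning the whole band
scores 1 (the 000 reflection limit); an rlp missing the band scores 0; the
value is monotone in the offset from the mean-wavelength sphere.  No Lorentz
or polarisation corrections are applied anywhere — the still-diffraction
model needs neither.

Corrected intensity and sigma are I/p and σ/p; reflections with p ≤ 0.3 are
discarded as too poorly estimated.  The boundary is inclusive (a reflection
at exactly 0.3 is discarded).

## Orientation refinement

Indexing software supplies an approximate orientation matrix per still.
Refinement predicts candidate reflections with an inflated bandwidth "net"
(μ ± 3.5%, rlps as delta functions, resolution-limited), selects hits with
integrated intensity strictly above 150 ADU, and sharpens the histogram of
hit excitation wavelengths by rotating the orientation about the two
beam-orthogonal axes.  A rotation about the beam axis leaves every
excitation wavelength unchanged (it preserves q_z and |q|), so it is
unobservable here and is not searched.

The search is coordinate descent on a halving grid: starting step 0.5°,
evaluate the four single-axis neighbours, move on strict improvement (ties
prefer the smaller total rotation), halve the step at a local minimum, stop
below 0.001° — nine halvings.  The first target is (sample s.d. of λ)/(hit
count), a weight-free combination of "spread down, count up".  After three
halvings the target switches to the quality of the Gaussian core of the
histogram: the spread/count of the sample trimmed to a fixed window (±6 bins
of width μ×10⁻³) around the fitted Gaussian peak.  The histogram of a still
is a sharp core of well-excited reflections on a broad pedestal of
marginally excited ones; statistics computed over the whole net window are
pedestal-dominated, while the core carries nearly all the orientation
signal.  The per-pulse mean wavelength is refit after every halving as the
least-squares Gaussian peak position (falling back to the sample mean if the
fit wanders out of the window).

Identifiability: with a finite hit list the objective's minimum sits a small,
sample-dependent distance from the true orientation — roughly
(core width)/(leverage × √n) radians, about 0.005–0.02° for a few hundred
hits.  Synthetic recovery is therefore quoted as an ensemble mean (≈0.007°
over 50 stills at 1.75 Å), not a per-still guarantee; no grid schedule can
beat this floor because it is a property of the estimator, not the search.

## Indexing-ambiguity resolution

In point group 23 the lattice supports two indistinguishable indexings
related by (h,k,l) → (k,h,−l); images must be brought to one convention
before merging.  Each image a receives a 2-vector x_a (components uniform in
[0,1], seeded); the functional

    f = Σ_{a<b} (x_a·x_b − r_ab)² + (x_a·S x_b − r′_ab)²,   S = [[0,1],[1,0]],

is minimised by L-BFGS with an analytic gradient.  r_ab is the
through-origin correlation between the two images' partiality-corrected
intensities on shared asymmetric-unit reflections (resolution-limited to
d ≥ 1.8 Å); r′_ab is the same with one image reindexed — the second term
doubles the pairwise information.  The swap matrix S mirrors the reindexing
operator in vector space: swapping an image's hand in the data while
swapping its vector components leaves f invariant.  Pairs sharing fewer
than two reflections contribute nothing (no imputation).

The through-origin correlation is

    r = √(1 − [SS_res(y|x) + SS_res(x|y)] / [SS_tot(y) + SS_tot(x)]),

with both through-origin regressions (slope Σxy/Σx² and its mirror) and
totals about the means.  It is symmetric, lies in [0,1], equals 1 exactly
for proportional inputs (hence is meaningful from just two shared
reflections), and a negative radicand — an "imaginary" value — is reassigned
0.

After minimisation the vectors fall into two clusters.  A deterministic
2-means on the normalised vectors (farthest-pair initialisation) labels
them; the larger cluster is hand A, a silhouette below 0.2 flags an
ambiguous separation, and near-coincident centres collapse to a single
hand.  Hand-B images are reindexed in place, with the orientation matrix
post-multiplied by the operator so geometry stays consistent.  The global
labelling is arbitrary: all recovery figures are quoted up to a global swap.

## Scaling and merging

Stage one equalises each image's mean corrected intensity over reflections
with d ≥ 3.5 Å; the scale is a divisor (scale_a = mean_a / grand mean), so
after division every surviving image has the same low-resolution mean.
Images with a mean below 333 ADU are rejected as too weak, with reasons
logged.  A crude unweighted merge of the equalised images forms an interim
reference; stage two sets each image's scale to the through-origin slope
Σ(I_img·I_ref)/Σ(I_ref²) over shared uniques, remerges, and iterates until
the largest relative scale change drops below 10⁻⁴ (default; the noiseless
fixed point is exact, so recovery tests tighten it).  An image's own
observations are not excluded from the reference — a small bias at low image
counts, negligible at the scales used here.  The final merge is
inverse-variance weighted.  Sigmas propagate as σ/(p·scale); absent a
detector-gain model their absolute values are indicative only, though
relative errors are preserved exactly.

## Quality statistics

Resolution shells are equal-volume (uniform in 1/d³, 20 by default, lower-d
edge inclusive).  CC½ splits each unique's observations into two balanced
halves (seeded shuffle, then alternation), merges each half and takes the
Pearson correlation of the half-set means, per shell and overall.  R_split
uses the standard still-merging definition with the 1/√2 prefactor, applied
here between the two indexing-hand halves (and between CC½ half-sets per
shell).  R_pim is the multiplicity-weighted precision R factor
Σ_h √(1/(n_h−1)) Σ|I−⟨I⟩| / ΣΣI over uniques with n ≥ 2.  The per-image
resolution limit is the deepest contiguous shell whose mean I/σ stays at or
above 2.0, scanning from low resolution; the dataset's nominal resolution
is the d where shell CC½ first drops below 0.30 (reported, not used to
truncate).  All statistics are invariant under a global intensity scale.

## Synthetic data generator

The generator is the package's ground-truth instrument.  It emulates the
target regime: cubic I23 cell (106.1 Å), mean wavelength 1.46 Å with
per-pulse jitter (s.d. 0.001 Å), truncated-Gaussian bandwidth σ = 0.0015 Å
(≈0.1%, typical SASE), rlp radius 1.8 × 10⁻⁴ Å⁻¹ plus a 0.03° mosaic term,
exponential (acentric Wilson) true intensities with mean 2000 ADU, lognormal
per-image scales (σ_log = 0.3), uniform random orientations via normalised
quaternions, and a configurable fraction of images emitted in the alternate
indexing hand (reported indices reindexed, orientation compensated, so the
two hands are genuinely indistinguishable from geometry).  Under these
defaults a still carries ≈215 observations of which ≈50 fall at or below the
0.3 partiality cutoff — the same census shape as the experimental regime.

Emission is gated on partiality alone (> 0.05): a finite rlp diffracts with
its centre wavelength many σ outside the truncated band, which is exactly
why the real analysis over-predicts and then discards.  Noise, when enabled,
is Gaussian with a counting-statistics sigma √(I + 100) at unit gain,
optionally inflated so the per-image mean I/σ hits a stated target.
Missets for refinement studies are injected about the two beam-orthogonal
axes only, since an in-plane (beam-axis) misset is invisible to the
wavelength histogram by construction.

Desk-scale choice: recovery studies run with 200 images where the
experiment used thousands.  Pairwise ambiguity resolution needs shared
reflections per image pair; with 200 images the defaults yield only ~1
shared reflection per pair, so recovery studies simulate at mosaicity 0.3°
and σ = 0.003 Å — typical protein-crystal mosaicity (the target crystals'
0.03° is noted as unusually low) — restoring ≥30 shared reflections per
pair.  Orientation-recovery studies run at the experimental resolution
(1.75 Å) for the same reason: estimator precision scales as 1/√n.  Problem
sizes used by the shipped studies: 50 stills for orientation recovery, 200
for ambiguity and end-to-end runs, 60 for scale recovery, d_min 2.5 Å
except where stated.

What the generator does not emulate: pixel-level detector effects (the
pipeline starts after 2D integration), non-Gaussian SASE spikes, centric-
zone intensity statistics, detector gain, radiation damage, and non-spherical
rlp profiles.  Passing recovery tests therefore demonstrates correctness of
the inference given the model, not robustness to every real-data pathology.

## Numerical choices and edge cases

Degenerate rlp geometry (zero wavelength span across the diameter) scores
partiality 0; fractions are clipped to [0,1] only for reporting, with raw
values retained for the integral.  Grid-search ties keep the smaller
rotation; refinement with fewer than 10 hits is refused ("degenerate").
Merging uses exact integer asu keys; bincount-based grouping makes all
statistics deterministic given the seed.  The cc-half split seed, ambiguity
initialisation seed and all generator seeds are recorded run parameters.

## Known limitations

Sigma estimates lack a gain model and should not feed downstream weighting
schemes that assume absolute calibration.  The deconvolution factor 0.27 is
regime-specific.  Cells other than cubic I23, >2-fold ambiguities,
anomalous pairs, B-factor (resolution-dependent) scaling and
reference-structure hand resolution are out of scope.
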