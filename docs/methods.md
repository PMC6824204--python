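# Methods

This note documents the model, the synthetic plant that stands in for a
biomechanical vocal tract, the numerical choices, and what the simulations
do and do not demonstrate.

## Planning model

Planning a vowel is Bayesian inference over a 6-D motor command
`M = (λ₁…λ₆)`, the control variables of an equilibrium-point muscle model,
uniform-prior over a bounded box (default [−1, 1] per dimension).  Each
phoneme carries Gaussian sensory targets: auditory (μ_A, Γ_A) over the first
three formants in Hz, somatosensory (μ_S, Γ_S) over the first three
principal-component scores of the 17-node mid-sagittal tongue contour.
Internal models ρ_a, ρ_s map commands to predicted sensory consequences
deterministically (Dirac observation model), so the three planning
posteriors reduce to products of target densities evaluated at the
predictions; binary coherence variables that gate each modality's matching
constraint are collapsed analytically and never sampled.  The auditory-only,
somatosensory-only and fusion posteriors differ only in which factors are
present.

Dispersion ellipsoids of order k (mean ± k·√eigenvalue axes of the sample
covariance) summarise posterior clouds; order 2 is used for display, order 3
for coverage checks, interpreting the target regions as 2-standard-deviation
Gaussian contours.

## Synthetic articulatory plant

No biomechanical simulator is bundled; the plant is a smooth, seeded,
deterministic surrogate with the structural properties the model needs.
Design choices, in order of importance:

* **Three saturating shape features.**  `g(m) = tanh(W m + b)` (unit-norm
  rows, 3 features) drives the contour: 17 nodes = resting arc + orthogonal
  loading directions (gains 1.6/1.1/0.8) × g, plus a small (0.06) full-rank
  tanh residual so the contour Jacobian has column rank 6.  Three PCs then
  explain ≈99% of contour variance, giving a faithful 3-D somatosensory
  space, while the best affine fit from commands to contours leaves ≈20%
  relative residual — the maps are genuinely nonlinear.
* **Acoustics is a function of tongue shape.**  Formants are logistic range
  squashes of an orthogonal 3×3 mixing of the *same* features g (F1 channel
  gain 2.9, F2/F3 2.1), plus a small motor residual (0.02) and quadratic
  cross-terms (0.01).  This mirrors the physical fact that vocal-tract
  geometry determines acoustics: a somatosensory value pins the formants to
  within a few Hz.  It is what makes somatosensory-only planning land inside
  the auditory region, and fusion planning land midway between the pure
  modes after adaptation.  The residual keeps the relation non-deterministic
  and the two sensory geometries mutually distorted (F1–PC1 correlation
  ≈0.4, far from ±1).
* **Formant ranges** default to F1 ∈ [150, 900], F2 ∈ [800, 2800],
  F3 ∈ [2000, 3800] Hz, bracketing adult French vowels; the logistic squash
  guarantees every output is in range.

What the surrogate does *not* emulate: muscle dynamics, tissue contact, jaw
and lip articulators, acoustic wave propagation, sensory noise, or temporal
structure.  Passing tests demonstrate properties of the planning machinery
under a plausible geometry, not claims about any real vocal tract.

## Vowel target construction

Auditory targets for {i, e, ɛ, a, œ, ɔ} are laid out on the classic vowel
quadrilateral in robust-normalised (F1, F2) coordinates and snapped to local
averages of plant outputs, so every mean is reachable by construction.  Two
constraints shape the layout:

* **Interiority with an F1 margin (default 100 Hz).**  Candidate locations
  must have corpus density at least half the bulk median both at the point
  and at its F1 + margin image.  Targets therefore never sit on the boundary
  of the reachable region, and the reference perturbation's compensation
  demand (raise produced F1 by 100 Hz) stays feasible for every vowel.
* **Covariances**: per-formant sd = 3% of the robust span, with 1.8×
  anisotropy on F2/F3 only and a seeded rotation in the (F1, F2) plane.
  F1 is kept tight deliberately: the posterior pushforward mean is tilted by
  Γ·∇log v(a), where v is the motor-fiber volume, and this tilt — the only
  systematic bias between "produced mean" and "target mean" — scales with
  the F1 target variance.  Pairwise Mahalanobis separation ≥ 2.2 is enforced
  by a common shrink (rarely active).

Somatosensory targets are not free parameters: commands are sampled from the
auditory-only posterior (default 5000 draws), pushed through ρ_s, and
moment-matched (sample mean/covariance).  This uses only machinery the model
already has.  An affine-plant control (where the push-forward is available
in closed form: if the somato map is an affine image T·a + u of the acoustic
map and the prior box is wide, the derived target must be
N(Tμ_A + u, TΓ_A Tᵀ)) validates the construction to Monte-Carlo error.
Derivation quality matters: under-sampled derivations (few chains) bias μ_S
enough to cost a few percent of region coverage downstream.

## Internal models

Gaussian-kernel RBF regression with an affine tail and ridge (1e-8) on the
kernel block only, so an affine ground truth is recovered exactly.  Centers:
seeded k-means, default 800 on a 50k-sample corpus; bandwidth: half the
median inter-center distance.  At those defaults the held-out RMSE (20%
split) is below 1% of each output's standard deviation for both modalities;
the fitted map stores its RMSE as a fidelity budget that downstream tests
check against (fresh-sample MAE ≤ 1.5× budget).  Adaptation to a constant
auditory shift δ is a stored additive offset — for a constant perturbation a
"complete and perfect" internal-model update is mathematically an output
shift, and the offset makes the adaptation identity exact rather than a
refit approximation.  The somatosensory map is never touched by auditory
adaptation.

## Sampler

Random-walk Metropolis–Hastings with symmetric Gaussian proposals,
independent per-chain seeds spawned from one master seed, rejection of
out-of-box proposals (the uniform prior's support), and proposal-scale
adaptation toward 23% acceptance during burn-in only (every 50 steps,
multiplicative update, clipped; the kernel used for retained draws is
frozen).  Chains start at the best of 200 uniform probes.  Defaults: 20
chains × (1000 burn + 1000 retained) = 2·10⁴ retained draws.  Diagnostics:
per-chain acceptance rates and between-chain standard errors on every
reported mean; an error is raised if all chains accept < 1% of proposals.
The λ-posterior concentrates on a curved manifold (more commands than
sensory constraints), so per-λ chain means mix slowly — but the mapped
sensory outcomes, which are what the experiments report, are tightly
constrained and their between-chain SEs are small.

A reduced 2-D problem (tanh forward map, tight Gaussian target) with an
exhaustively grid-normalised posterior serves as the sampler's oracle:
marginal CDFs agree to Kolmogorov–Smirnov distance ≤ 0.05 at 2·10⁴ draws.

## Perturbation experiment and the compensation ratio

Three conditions: unperturbed; pre-adaptation (perception shifted by δ, no
re-planning — plans are bit-identical to unperturbed ones); post-adaptation
(planning redone with the updated auditory map).  The sampler seed is
derived from (master seed, phoneme, mode, preference) but never the
condition, so a posterior that a condition does not change yields
bit-identical draws — somatosensory-only planning after auditory adaptation
being the key case.

Compensation is summarised as a scalar because ellipse positions alone are
not testable: the displacement of the *produced* (plant ground-truth)
auditory mean from the unperturbed baseline, projected on −δ/‖δ‖, divided by
‖δ‖.  1 = full counter-shift, 0 = none.  Under the study conditions
auditory-only planning scores ≈1.0, somatosensory-only exactly 0, fusion
≈0.4–0.6 depending on the master seed.

## Preference sweeps

One parameter varies per sweep; runs share seeds for variance reduction;
κ grids are geometric over 10^±2.  η has units of the sensory space it acts
in, and only its ratio to the target covariance matters, so η grids are
anchored at the phoneme target's RMS sd: 0.1–10× for η_S, 0.1–3× for η_A
(the auditory pathway's influence saturates to zero sooner; points beyond
saturation only add noise ties to a trend statistic).  Expected behaviour,
asserted by the acceptance suite: ratio decreasing in κ_A and η_A,
increasing in κ_S and η_S (|Spearman| ≥ 0.9), extreme endpoints within 0.1
of the corresponding pure-mode ratios.

The κ–η relationship: in 1-D the mechanisms are one Gaussian
(κ = 1 + η²/Γ, an identity the suite checks to 1e-12; note the additive
increment to the variance is η², the squared kernel width).  In 3-D they
differ unless Γ is isotropic — κ scales eigenvalues jointly (orientation and
eccentricity preserved), η adds η² to each (condition number monotonically
→ 1).  Γ + η²I keeps exactly Γ's eigenvectors, so "losing orientation" is
implemented and tested as progressive isotropy, not as rotation of axes.
The comparison-based fusion density is additionally verified against the
explicit convolution integral ∫N(a; μ_A, Γ_A)·N(a; ρ_a(m), η²I) da by
3-D Gauss–Hermite quadrature (50 nodes/dim, relative error ≤ 1e-4).

The modality-shutoff limit (extreme κ_A or η_A makes fusion equal
somatosensory-only planning) is tested with *coupled* chains: both runs use
the same seed, so the Kolmogorov–Smirnov distance between their draws
reflects only genuine density differences, not Monte-Carlo noise (an
uncoupled two-sample KS at feasible draw counts has an autocorrelation noise
floor of 0.06–0.14 and cannot resolve the limit).  A power check — moderate
preference values must produce clearly nonzero coupled KS — guards against
the coupling passing vacuously.

## Problem sizes

Defaults mirror the full study conditions (50k-sample training corpus,
2·10⁴ retained draws, 5000-draw target derivations).  The test suite builds
one session-scoped stack at 20k/500-center maps with 6000-draw derivations,
and runs sweeps at 5·10³ retained draws; the acceptance script uses
40k/700-center maps with the full sampling protocol.  These sizes keep the
relevant Monte-Carlo errors (between-chain SEs of reported means, coverage
fractions) several times smaller than every asserted tolerance.

## Known limitations

* The fiber-volume tilt biases produced means by up to ~0.3 target-sd in
  some regions of the space; the compensation ratio largely cancels it
  (difference of two tilts), but single-condition means inherit it.
* Somatosensory-only planning's auditory coverage is the tightest invariant
  (≈91–95% against a 90% floor at the suite's problem sizes): the image of
  the somato Gaussian's 2–3σ shell under the curved sensory correspondence
  has mildly heavy tails.
* Moment-matched somatosensory targets ignore skewness of the pushforward
  cloud.
* No learning dynamics: adaptation jumps to its asymptote; pre-adaptation
  behaviour is modelled as no re-planning (immediate compensation is out of
  scope).
* Single-phoneme planning only; no sequences, coarticulation, effort
  levels, speaking-rate control, or somatosensory perturbations.
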