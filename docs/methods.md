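# Methods

## The physical picture

A DNA curtain extends single λ-phage molecules (48,502 bp) between surface
anchors ~13 µm apart — about 80% of the B-form contour length — and a
fluorescently labelled protein is imaged at 0.2 s/frame while it moves
along the DNA. A clamp-shaped protein can translocate in two modes:
continuous 1D **sliding** in contact with the duplex, and **hopping** —
brief micro-dissociation and recapture. Hopping is what lets a protein
pass protein obstacles, respond to ionic strength, and transfer to a
neighbouring DNA; the package's analysis chain is built to quantify all
three signatures and the simulator generates trajectories under exactly
this two-mode model so every analysis stage can be checked against a known
answer.

All coordinates are continuous base pairs on [0, L], origin at the
anchored end; physical distances always go through the tether span
(13 µm / 48,502 bp ≈ 0.268 nm/bp at curtain extension), never through the
B-form rise, because the DNA is under-extended.

## Simulator

Per frame of length Δt (default 0.2 s):

1. the number of hops is Poisson(hop_rate·Δt), each resolved at a uniform
   sub-frame time. A hop escapes to solution with probability
   `p_escape_per_hop`, otherwise relands at a Normal(0, hop_sigma_bp)
   displacement. A landing that would cross a roadblock is accepted with
   that roadblock's permeability and otherwise rejected (the clamp
   re-closes where it opened); every attempt is recorded in the crossing
   log. Hops are treated as instantaneous relative to the frame because
   observed transfers complete within one 200 ms frame;
2. sliding adds a Gaussian increment of variance 2·D·Δt, specularly
   reflected at DNA ends and roadblock edges (Euler discretization at the
   frame interval — adequate because all observables are frame-resolution);
3. a molecule within the lesion's capture radius is captured with a
   per-visit probability and frozen; in single-tether mode the distal end
   is open and sliding past it dissociates the molecule ("sliding off"),
   recorded separately from hop-mediated internal escape;
4. fluorophore blinking is a two-state telegraph process with off/on
   rates; dark frames are simulated but not rendered/detected.

States never resume motion after capture or dissociation. Reproducibility:
trajectory *i* of a population uses the RNG stream seeded by
`(config.seed, i)`, so enlarging the population never reshuffles earlier
molecules.

Defaults mirror the study conditions: Δt = 0.2 s, 48,502 bp/13 µm
geometry, localization noise σ = 250 bp (so 3σ = 750 bp matches the
collision-zone width), per-molecule D of order 0.025–0.12 µm²/s, dwell
half-lives 76 s (25 s with competitor), lesion at 20 kb. Hop rate and hop
excursion length are not published quantities; they are free simulator
parameters, and tests choose them per scenario (documented in each test).

What the generator does **not** emulate: 3D diffusion between encounters,
force/flow extension fluctuations, nucleosome breathing, multi-exponential
photophysics, uneven illumination, camera EM gain noise. Passing tests
therefore demonstrate correctness of the estimators and classifiers under
the stated model, not robustness to every artefact of real movies.

## Rendering and tracking

The renderer draws each visible molecule as a symmetric 2D Gaussian PSF
(default σ = 0.9 px at 0.16 µm/px, 1000 photons/frame over 10
photons/px background) and applies Poisson shot noise, quantized to 16-bit.
Spot detection finds local maxima above median + k·MAD (robust to the
spots themselves) and refines each by nonlinear least squares over
(amplitude, x, y, σ, background); a fit that fails to converge or whose
amplitude does not clear 3× the robust noise is a "no spot" result.
Linking is greedy nearest-neighbour with a jump cap (default
4·√(2·D_max·Δt) with D_max = 0.5 µm²/s ≈ 1.13 µm) and up to 5 bridged
dark frames; ties break deterministically on the lower spot index.
Overlapping molecules closer than one PSF σ merge into one detection — a
documented limitation shared with the real analysis.

The trajectory filter keeps tracks with ≥ 50 detected frames, inclusive
at exactly 50 (the 10 s minimum at 0.2 s/frame equates the two).

## Diffusion estimation

The MSD is time-averaged over all overlapping windows; gapped frames
contribute only pairs with both endpoints detected, and denominators are
actual pair counts. The line fit uses the first 10 lags (0.2–2 s) with a
free intercept: static localization noise of variance σ² adds ≈ 2σ² to
every lag, which the intercept absorbs, leaving D (= slope/2, from
MSD = 2DΔt in 1D) nearly unbiased — verified as a property test. A
through-origin fit is available for sensitivity analysis. Negative fitted
D on noise-dominated tracks is retained and flagged, but excluded (with a
count) from log-scale statistics. Population comparisons use Welch's
two-tailed t-test on log₁₀ D — "Student's t-test" with unequal variances
is the safer default; pooled is a flag.

The rotation-coupled sliding limit uses the Schurr/Bagchi–Blainey–Xie
friction for a sphere of radius *a* tracking the helical pitch
b = 3.57 nm at centre offset R from the helix axis:
ζ = 6πηa + (2π/b)²(8πηa³ + 6πηaR²), D_max = kT/ζ — about 0.27 µm²/s for
a = R = 5 nm in water at 25 °C.

## Ionic strength

I = ½ Σ cᵢzᵢ² over all ions, with DTT and BSA treated as non-ionic. Tris
is handled in two modes. The *paper* mode reproduces the worked
decomposition this pipeline is validated against: TrisH⁺ from a 45%
charged fraction (9 mM at 40 mM Tris) and titration Cl⁻ from the
Henderson–Hasselbalch protonated fraction at pH 8.0/pKa 8.1 (11 mM).
Those two fractions cannot both be right under electroneutrality — the
45% figure actually equals the *deprotonated* fraction — so a *consistent*
mode uses Henderson–Hasselbalch for both ions. The difference is ~2 mM on
the standard buffer; *paper* mode is used when matching published totals
(51–176 mM), *consistent* is the physically coherent choice for new
buffers. Contributions are reported at full precision and rounded to the
nearest mM only for display against the published arithmetic.

The salt-dependence fit is OLS of log₁₀ D on log₁₀ I; the slope's standard
error comes from the regression residuals, and screened charges =
slope/ψ with ψ = 0.88 for dsDNA, uncertainty propagated linearly.

## Dwell-time kinetics

A dwell runs from first to last detection; blink gaps never terminate it
(blinking is photophysics, not dissociation). Tracks detected within one
frame of the movie end are censored and excluded from the locus tally.
Dissociation within 1 kb of a free DNA end is classed "end" (sliding
off), elsewhere "internal" (clamp opening); the 1 kb default matches the
granularity at which sliding distances are resolved and is a flag.

The default survival fit mirrors a plotted single-exponential decay:
least squares of the Kaplan–Meier survival fraction against
exp(−t ln2/t½), with censored records contributing up to their censoring
time. The censoring-aware exponential MLE (rate = events/total time,
s.e. from Fisher information) is the alternative; at n = 10⁴ it recovers
truth within 2%. The reported s.e. is the fit/Fisher s.e.; whether a
published ±s.e. was a fit error or a bootstrap cannot be determined from a
figure, so no equivalence is claimed, and a bootstrap is easy to run on
the returned records if needed.

## Event classification

**Collisions.** Protein and roadblock cannot be resolved within 3× the
localization s.d. — a 750 bp (≈200 nm) collision zone. Scoring is a
three-region state machine (left of zone / in zone / right of zone) per
roadblock over detected positions, with linear interpolation between
detections so a traversal spanning the zone within one frame still
counts. Each maximal in-zone episode is one collision: a bypass if entry
and exit sides differ, a rejection if they match, unresolved if the track
ends inside. Episodes that *begin* inside the zone have no defined entry
side and are not scored. The bypass frequency is bypasses over resolved
collisions with a Wilson 95% interval. Note the zone-width dependence: a
wider zone merges wall crossings into fewer resolvable traversals, so the
bypass count is non-increasing in the zone halfwidth.

**Transfers.** Each detection is assigned to the nearest DNA axis within a
register tolerance (default 0.25 µm ≈ 3× localization s.d. at curtain
extension). An event requires ≥ 4 s of continuous assignment to one axis,
an assignment switch completing within one frame, and ≥ 4 further seconds
on the neighbour; all three criteria flags are carried on the event.

**Lesion recognition.** Arrest is ≥ 10 consecutive frames within one
localization s.d. of the final position — long enough to distinguish
binding from a slow excursion at 0.2 s cadence. A track arresting within
300 bp of the lesion is a recognition event: *direct-3D* if the first
detection was already within 300 bp and arrest was immediate, *sliding-1D*
if the cumulative pre-arrest path is ≥ 1 kb, otherwise *ambiguous*. The
300 bp direct threshold (detection resolution) and the 250 bp localization
s.d. are deliberately independent knobs. Binding-position histograms get a
nonlinear Gaussian peak fit; degenerate or non-peaked data are flagged
rather than fitted silently.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make sampling
error small relative to each tolerance: 10⁴ draws for distributional
checks (KS distance < 0.02), 400 × 2000-frame trajectories for the
ensemble MSD intercept bound, 100 × 600-frame confined trajectories for
the L²/6 plateau, populations of 47–72 molecules × 150 frames matching the
published per-condition sample sizes, and ≥ 500 simulated collisions for
classifier-oracle agreement. Optimizer settings: Gaussian spot fits are
bounded least squares with at most 200 function evaluations; survival and
peak fits use scipy `curve_fit` with moment-based initial guesses.
Degenerate inputs (flat images, all-censored dwells, single-lag MSD
curves, identical ionic strengths) are rejected with explicit messages
rather than returning unstable numbers.

## Known limitations

Greedy linking can swap identities when two molecules approach within the
jump cap; the classifier cannot distinguish hopping from intersegmental
transfer (neither can the experiment on extended DNA); collision scoring
counts per-episode, so a printed per-trajectory collision tally could
differ; and the simulator's free hop parameters mean absolute bypass or
transfer frequencies are scenario choices, not predictions.
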