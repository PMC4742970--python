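# curtainlab

Analysis toolkit for single-molecule DNA-curtain experiments on proteins
that scan DNA by facilitated diffusion — written around the kind of study
in which a quantum-dot-labelled mismatch-repair clamp (e.g. Msh2–Msh3)
diffuses along λ-phage DNA (48,502 bp extended to a 13 µm tether span),
hops over nucleosome roadblocks, transfers between adjacent DNA molecules
and arrests at a lesion.

It is aimed at single-molecule biophysicists who need a tested, scriptable
version of the standard kymograph-analysis chain, plus a ground-truth
simulator to validate every stage of it.

## What it computes

* **Tracking** — sub-pixel spot localization by 2D Gaussian fitting,
  greedy nearest-neighbour linking across quantum-dot blink gaps, and the
  standard ≥ 50-frame (10 s at 0.2 s/frame) trajectory filter.
* **Diffusion** — time-averaged mean squared displacement
  `MSD(nΔt) = (1/(N−n)) Σᵢ (y_{i+n} − y_i)²`, a free-intercept line fit
  over the first 10 lags, and `D = slope/2` (1D convention). Conditions
  are compared by a two-tailed Welch t-test on log₁₀ D.
* **Ionic strength** — `I = ½ Σ cᵢzᵢ²` with explicit Tris-HCl accounting,
  and the salt-dependence regression: the slope of log₁₀ D vs log₁₀ I
  divided by the dsDNA counterion-condensation parameter ψ = 0.88 gives
  the number of screened charge–charge contacts.
* **Kinetics** — dwell-time extraction with end-vs-internal dissociation
  loci, censoring at the movie end, and single-exponential survival fits
  (`S(t) = exp(−t ln2/t½)`, least squares on the Kaplan–Meier curve, or
  censoring-aware MLE).
* **Events** — roadblock-collision scoring inside a 750 bp collision zone
  (bypass / same-side return / unresolved), inter-DNA transfer calls under
  the ≥ 4 s + single-frame-switch + ≥ 4 s criteria, lesion-binding
  histograms with Gaussian peak fits, and direct-3D vs sliding-1D
  lesion-recognition calls.
* **Simulator** — 1D Brownian sliding plus Poissonian micro-hops on
  obstacle-bearing DNA (reflecting roadblocks that only hops may cross,
  hop-mediated escape, lesion capture, two-state blinking), and a renderer
  that turns ground-truth trajectories into 16-bit TIFF movies with
  Poisson shot noise for end-to-end validation.

## Worked example

Simulate two salt conditions at their published sample sizes, estimate
per-molecule diffusion coefficients, and count screened charges:

```python
from curtainlab import (BufferComposition, total_ionic_strength,
                        MsdDiffusionEstimator, summarize_population,
                        fit_salt_dependence)
from curtainlab.pipeline import synthetic_condition_tracks
from curtainlab.geometry import DnaGeometry

geo = DnaGeometry()                      # 48,502 bp over 13 um
points = []
for label, nacl, d_true, n in [("51 mM", 25.0, 0.031, 47),
                               ("176 mM", 150.0, 0.12, 49)]:
    I = total_ionic_strength(BufferComposition(nacl_mM=nacl), "paper").total_mM
    tracks = synthetic_condition_tracks(d_true, n, 150, geo, seed=2)
    s = summarize_population(MsdDiffusionEstimator().fit(tracks).estimates_, label)
    points.append((I, s.mean_d))
    print(f"{label}: I = {I:.0f} mM, mean D = {s.mean_d:.3f} +/- {s.sd_d:.3f} um^2/s (n={s.n})")
fit = fit_salt_dependence(points)
print(f"log-log slope = {fit.slope:.2f}, screened charges = {fit.screened_charges:.2f}")
```

prints

```
51 mM: I = 51 mM, mean D = 0.033 +/- 0.010 um^2/s (n=47)
176 mM: I = 176 mM, mean D = 0.125 +/- 0.041 um^2/s (n=49)
log-log slope = 1.07, screened charges = 1.22
```

The ionic strengths are the buffer totals (40 mM Tris-HCl pH 8.0, 2 mM
MgCl₂, 25 or 150 mM NaCl → 51 and 176 mM); the mean D values recover the
simulated inputs within sampling error; the slope of log D against log I,
divided by ψ = 0.88, counts the electrostatic contacts disrupted by salt
screening (here ~1.2 from a two-point fit — a real experiment would use
four or more salt conditions).

A CLI covers the same chain stage by stage:

```bash
curtainlab ionic --nacl-mm 25          # per-species ionic-strength table
curtainlab simulate --d-slide 0.025 --n 20 --out tracks.csv
curtainlab dfit --trajectories tracks.csv --out estimates.csv
curtainlab dwell --t-half 76 --n 50 --seed 1
curtainlab report --config run.yaml --out results/
```

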