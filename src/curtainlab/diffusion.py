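"""Time-averaged MSD curves and 1D diffusion-coefficient estimation.

For a trajectory y_1..y_N sampled every Dt seconds, the time-averaged mean
squared displacement at lag n is

    MSD(n Dt) = 1/(N - n) * sum_{i=1..N-n} (y_{i+n} - y_i)^2,

averaged over all overlapping start frames.  For 1D Brownian motion
MSD = 2 D t, so D is half the slope of an ordinary least-squares line
through the first ``n_lags`` MSD points (free intercept: static
localization noise adds a constant ~2 sigma^2 which the intercept absorbs,
leaving the slope — and hence D — nearly unbiased).

Population comparisons are made on log10(D) with a two-tailed t-test
(Welch degrees of freedom by default), since per-molecule D values are
approximately log-normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

BOLTZMANN_J_PER_K = 1.380649e-23
HELICAL_PITCH_NM = 10.5 * 0.34  # one turn per 10.5 bp of B-form DNA


@dataclass
class MsdCurve:
    lag_times_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    molecule_id: int = 0


@dataclass
class DiffusionEstimate:
    d_um2_s: float
    intercept_um2: float
    rmse_um2: float
    n_lags: int
    molecule_id: int = 0

    @property
    def is_noise_dominated(self) -> bool:
        return self.d_um2_s <= 0


@dataclass
class PopulationSummary:
    label: str
    mean_d: float
    sd_d: float
    n: int
    single_member: bool = False


def compute_msd(track, n_max: int = 10) -> MsdCurve:
    """Time-averaged MSD over the first ``n_max`` lags.

    ``track`` provides ``positions_um``, ``detected``, ``frame_interval_s``.
    Gapped frames contribute no pairs: a displacement enters the average
    only when both endpoints were detected, and the denominator is the
    actual pair count (not N - n).
    """
    y = np.asarray(track.positions_um, dtype=float)
    det = (
        np.asarray(track.detected, dtype=bool)
        if getattr(track, "detected", None) is not None
        else np.isfinite(y)
    )
    det = det & np.isfinite(y)
    n_frames = int(det.sum())
    if n_frames < n_max + 1:
        raise ValueError(
            f"track has {n_frames} detected frames; need >= {n_max + 1} "
            f"for {n_max} lags"
        )
    dt = track.frame_interval_s
    msd = np.empty(n_max)
    pairs = np.empty(n_max, dtype=int)
    for n in range(1, n_max + 1):
        ok = det[:-n] & det[n:]
        disp = y[n:][ok] - y[:-n][ok]
        pairs[n - 1] = ok.sum()
        msd[n - 1] = np.mean(disp**2) if ok.any() else np.nan
    return MsdCurve(
        lag_times_s=np.arange(1, n_max + 1) * dt,
        msd_um2=msd,
        n_pairs=pairs,
        molecule_id=getattr(track, "molecule_id", 0),
    )


class MsdDiffusionEstimator(BaseEstimator):
    """Per-molecule 1D diffusion coefficients from MSD-vs-lag lines.

    Parameters
    ----------
    n_lags : int
        Number of MSD lags in the line fit (default 10, i.e. 0.2-2 s at a
        0.2 s frame interval).
    through_origin : bool
        Force the intercept to zero (sensitivity analysis only; the free
        intercept is the default because it absorbs localization noise).

    Attributes
    ----------
    estimates_ : list of DiffusionEstimate
    d_coefficients_ : ndarray
        Fitted D per molecule, um^2/s (may be <= 0 for noise-dominated
        tracks; such values are flagged, not silently dropped).
    """

    def __init__(self, n_lags: int = 10, through_origin: bool = False):
        self.n_lags = n_lags
        self.through_origin = through_origin

    def fit(self, tracks):
        self.estimates_ = []
        for tr in tracks:
            curve = tr if isinstance(tr, MsdCurve) else compute_msd(tr, self.n_lags)
            self.estimates_.append(self._fit_curve(curve))
        self.d_coefficients_ = np.array([e.d_um2_s for e in self.estimates_])
        return self

    def _fit_curve(self, curve: MsdCurve) -> DiffusionEstimate:
        t = np.asarray(curve.lag_times_s, dtype=float)
        m = np.asarray(curve.msd_um2, dtype=float)
        ok = np.isfinite(m)
        t, m = t[ok], m[ok]
        if len(t) < 2:
            raise ValueError("MSD line fit needs >= 2 lags")
        if self.through_origin:
            slope = float(np.dot(t, m) / np.dot(t, t))
            intercept = 0.0
        else:
            slope, intercept = np.polyfit(t, m, 1)
        resid = m - (slope * t + intercept)
        return DiffusionEstimate(
            d_um2_s=float(slope) / 2.0,
            intercept_um2=float(intercept),
            rmse_um2=float(np.sqrt(np.mean(resid**2))),
            n_lags=len(t),
            molecule_id=curve.molecule_id,
        )


def fit_diffusion(curve: MsdCurve, through_origin: bool = False) -> DiffusionEstimate:
    est = MsdDiffusionEstimator(through_origin=through_origin)
    return est.fit([curve]).estimates_[0]


def summarize_population(
    estimates: Sequence[DiffusionEstimate], label: str = ""
) -> PopulationSummary:
    if len(estimates) < 1:
        raise ValueError("population summary needs >= 1 estimate")
    d = np.array([e.d_um2_s for e in estimates])
    single = len(d) == 1
    return PopulationSummary(
        label=label,
        mean_d=float(d.mean()),
        sd_d=0.0 if single else float(d.std(ddof=1)),
        n=len(d),
        single_member=single,
    )


@dataclass
class LogDComparison:
    p_value: float
    ci_low: float  # 95% CI of the difference of log10 means
    ci_high: float
    n_excluded_a: int
    n_excluded_b: int


def compare_log_d(a, b, pooled: bool = False) -> LogDComparison:
    """Two-tailed t-test on log10(D) between two conditions.

    Non-positive D values cannot be log-transformed; they are excluded and
    counted.  Welch (unequal-variance) degrees of freedom by default,
    pooled-variance available via ``pooled=True``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ex_a, ex_b = int((a <= 0).sum()), int((b <= 0).sum())
    la, lb = np.log10(a[a > 0]), np.log10(b[b > 0])
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("each group needs >= 2 positive D values")
    res = stats.ttest_ind(la, lb, equal_var=pooled)
    diff = la.mean() - lb.mean()
    if pooled:
        df = len(la) + len(lb) - 2
        sp2 = ((len(la) - 1) * la.var(ddof=1) + (len(lb) - 1) * lb.var(ddof=1)) / df
        se = math.sqrt(sp2 * (1 / len(la) + 1 / len(lb)))
    else:
        va, vb = la.var(ddof=1) / len(la), lb.var(ddof=1) / len(lb)
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (
            va**2 / (len(la) - 1) + vb**2 / (len(lb) - 1)
        )
    tcrit = stats.t.ppf(0.975, df)
    return LogDComparison(
        p_value=float(res.pvalue),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        n_excluded_a=ex_a,
        n_excluded_b=ex_b,
    )


def rotational_sliding_limit(
    protein_radius_nm: float = 5.0,
    offset_from_axis_nm: float = 5.0,
    temperature_K: float = 298.15,
    viscosity_Pa_s: float = 0.89e-3,
) -> float:
    """Upper bound on D for sliding that tracks the helical backbone.

    A protein of hydrodynamic radius a that follows the helix must rotate
    once per pitch b = 3.57 nm travelled.  Translating the Stokes-Einstein
    friction through that coupling (translation + spinning + revolution of
    the protein centre at offset R_oc from the helical axis) gives

        D_max = kT / [ 6 pi eta a + (2 pi / b)^2 (8 pi eta a^3
                                                  + 6 pi eta a R_oc^2) ]

    (Schurr's rotation-coupled friction as extended by Bagchi, Blainey &
    Xie, J Phys Chem B 112:6282, 2008).  Returns um^2/s.
    """
    a = protein_radius_nm * 1e-9
    r_oc = offset_from_axis_nm * 1e-9
    b = HELICAL_PITCH_NM * 1e-9
    if a <= 0 or r_oc < 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("physical parameters must be positive")
    eta = viscosity_Pa_s
    friction = (
        6 * math.pi * eta * a
        + (2 * math.pi / b) ** 2 * (8 * math.pi * eta * a**3 + 6 * math.pi * eta * a * r_oc**2)
    )
    d_m2_s = BOLTZMANN_J_PER_K * temperature_K / friction
    return d_m2_s * 1e12  # m^2/s -> um^2/s
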