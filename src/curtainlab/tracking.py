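"""Spot localization and trajectory building for curtain movies.

Each fluorescent particle is localized per frame by nonlinear least-squares
fitting of a symmetric 2D Gaussian, giving a sub-pixel centre.  Detections
are linked frame-to-frame by greedy nearest-neighbour assignment; a track
may bridge short dark gaps (quantum-dot blinking).  Tracks shorter than the
minimum length (default 50 detected frames = 10 s at 0.2 s/frame) are
excluded before diffusion analysis, since MSD fits on very short tracks are
strongly biased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from sklearn.base import BaseEstimator

from .geometry import DnaGeometry


@dataclass
class SpotFit:
    frame: int
    x_px: float
    y_px: float
    sigma_px: float
    amplitude: float
    background: float
    residual: float
    accepted: bool = True

    @classmethod
    def no_spot(cls, frame: int = -1) -> "SpotFit":
        return cls(frame, math.nan, math.nan, math.nan, 0.0, 0.0, math.inf, accepted=False)


@dataclass
class Trajectory:
    """One molecule's positions along a DNA axis over time.

    ``positions_um`` is the coordinate along the DNA (0 at the anchored
    end); ``lateral_um`` the transverse coordinate (used to tell adjacent
    DNA molecules apart); ``detected`` marks frames with a real
    localization — blink-gap frames are retained with detected=False and
    interpolated positions so indices stay aligned to the frame grid.
    """

    molecule_id: int
    frame_interval_s: float
    times_s: np.ndarray
    positions_um: np.ndarray
    detected: np.ndarray
    lateral_um: Optional[np.ndarray] = None
    dna_axis_id: str = "dna0"
    geometry: Optional[DnaGeometry] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions_um[self.detected])):
            raise ValueError("detected positions must be finite")

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    @property
    def positions_bp(self) -> np.ndarray:
        if self.geometry is None:
            raise ValueError("trajectory has no geometry; cannot convert to bp")
        return self.geometry.um_to_bp(self.positions_um)

    @classmethod
    def from_positions_bp(
        cls,
        positions_bp,
        frame_interval_s: float = 0.2,
        geometry: DnaGeometry = DnaGeometry(),
        detected=None,
        molecule_id: int = 0,
        **kw,
    ) -> "Trajectory":
        positions_bp = np.asarray(positions_bp, dtype=float)
        if detected is None:
            detected = np.isfinite(positions_bp)
        times = np.arange(len(positions_bp)) * frame_interval_s
        pos_um = geometry.bp_to_um(np.where(np.isfinite(positions_bp), positions_bp, 0.0))
        return cls(
            molecule_id=molecule_id,
            frame_interval_s=frame_interval_s,
            times_s=times,
            positions_um=pos_um,
            detected=detected,
            geometry=geometry,
            **kw,
        )


def _gaussian2d(params, xx, yy):
    amp, x0, y0, sigma, bg = params
    return bg + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))


class Gaussian2DFitter(BaseEstimator):
    """Sub-pixel spot localization by symmetric 2D Gaussian least squares.

    ``fit(window)`` estimates (amplitude, x, y, sigma, background) and
    exposes them as ``x_``, ``y_``, ``sigma_``, ``amplitude_``,
    ``background_``, ``accepted_``.  A fit that fails to converge, or whose
    amplitude does not clear ``min_snr`` times the robust background noise,
    is reported as a rejected ("no spot") result rather than an error.
    """

    def __init__(self, min_snr: float = 3.0, initial_sigma_px: float = 1.2):
        self.min_snr = min_snr
        self.initial_sigma_px = initial_sigma_px

    def fit(self, window, initial_guess=None):
        window = np.asarray(window, dtype=float)
        if window.ndim != 2 or min(window.shape) < 5:
            raise ValueError("window must be a 2D patch of at least 5x5 pixels")
        ny, nx = window.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        bg0 = float(np.median(window))
        noise = 1.4826 * float(np.median(np.abs(window - bg0))) + 1e-12
        if initial_guess is None:
            j = int(np.argmax(window))
            y0, x0 = divmod(j, nx)
            amp0 = float(window[y0, x0]) - bg0
            initial_guess = (max(amp0, noise), float(x0), float(y0), self.initial_sigma_px, bg0)
        try:
            res = least_squares(
                lambda p: (_gaussian2d(p, xx, yy) - window).ravel(),
                x0=initial_guess,
                bounds=(
                    [0.0, -1.0, -1.0, 0.3, -np.inf],
                    [np.inf, nx, ny, max(nx, ny), np.inf],
                ),
                max_nfev=200,
            )
            converged = res.success
            amp, x0, y0, sigma, bg = res.x
            resid = float(np.sqrt(np.mean(res.fun**2)))
        except Exception:
            converged = False
        # amplitude must clear the robust noise floor; a flat window has
        # noise ~0, so also require it to stand out from the background level
        if (
            not converged
            or amp <= self.min_snr * noise
            or amp <= 1e-6 * max(1.0, abs(bg))
        ):
            self.accepted_ = False
            self.x_ = self.y_ = self.sigma_ = math.nan
            self.amplitude_ = self.background_ = 0.0
            self.residual_ = math.inf
            return self
        self.accepted_ = True
        self.x_, self.y_ = float(x0), float(y0)
        self.sigma_ = float(sigma)
        self.amplitude_, self.background_ = float(amp), float(bg)
        self.residual_ = resid
        return self

    def spot(self, frame: int = 0) -> SpotFit:
        if not self.accepted_:
            return SpotFit.no_spot(frame)
        return SpotFit(
            frame=frame,
            x_px=self.x_,
            y_px=self.y_,
            sigma_px=self.sigma_,
            amplitude=self.amplitude_,
            background=self.background_,
            residual=self.residual_,
        )


def fit_gaussian_2d(window, initial_guess=None, min_snr: float = 3.0, frame: int = 0) -> SpotFit:
    return Gaussian2DFitter(min_snr=min_snr).fit(window, initial_guess).spot(frame)


def robust_background(frame) -> tuple:
    """(median, MAD-scaled s.d.) of a frame — robust to bright spots."""
    frame = np.asarray(frame, dtype=float)
    med = float(np.median(frame))
    sd = 1.4826 * float(np.median(np.abs(frame - med)))
    return med, sd


def detect_spots(
    frame,
    threshold_sigmas: float = 5.0,
    psf_sigma_px: float = 1.2,
    frame_index: int = 0,
    min_snr: float = 3.0,
) -> List[SpotFit]:
    """Local maxima above the robust background, refined by Gaussian fits.

    Candidates within one PSF sigma of a brighter accepted fit are merged.
    """
    if threshold_sigmas <= 0:
        raise ValueError("threshold_sigmas must be positive")
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or frame.ndim != 2:
        return []
    med, sd = robust_background(frame)
    if sd == 0 and np.all(frame == frame.flat[0]):
        return []
    half = max(4, int(math.ceil(4 * psf_sigma_px)))
    peaks = peak_local_max(
        frame,
        min_distance=max(1, int(round(psf_sigma_px))),
        threshold_abs=med + threshold_sigmas * max(sd, 1e-12),
        exclude_border=False,
    )
    spots: List[SpotFit] = []
    for py, px in peaks:
        y0, y1 = max(0, py - half), min(frame.shape[0], py + half + 1)
        x0, x1 = max(0, px - half), min(frame.shape[1], px + half + 1)
        if (y1 - y0) < 5 or (x1 - x0) < 5:
            continue
        fit = fit_gaussian_2d(frame[y0:y1, x0:x1], min_snr=min_snr, frame=frame_index)
        if not fit.accepted:
            continue
        fit.x_px += x0
        fit.y_px += y0
        dup = False
        for s in spots:
            if math.hypot(s.x_px - fit.x_px, s.y_px - fit.y_px) < psf_sigma_px:
                if fit.amplitude > s.amplitude:
                    spots[spots.index(s)] = fit
                dup = True
                break
        if not dup:
            spots.append(fit)
    return sorted(spots, key=lambda s: s.x_px)


def link_trajectories(
    detections_per_frame: Sequence[Sequence[SpotFit]],
    max_jump_um: float = 1.131,
    max_gap_frames: int = 5,
    pixel_size_um: float = 0.16,
    frame_interval_s: float = 0.2,
    geometry: Optional[DnaGeometry] = None,
) -> List[Trajectory]:
    """Greedy nearest-neighbour linking with blink-gap closing.

    Candidate (track, detection) pairs within ``max_jump_um`` are assigned
    in order of increasing distance; ties break deterministically on the
    lower spot index.  A track survives up to ``max_gap_frames`` frames
    without a detection; gap frames get linearly interpolated positions
    with detected=False.  The default ``max_jump_um`` is
    4*sqrt(2 * 0.5 um^2/s * 0.2 s): four step s.d. at the fastest expected
    diffusion.
    """
    active: List[dict] = []
    finished: List[dict] = []
    for f, dets in enumerate(detections_per_frame):
        dets = [d for d in dets if d.accepted]
        pairs = []
        for ti, tr in enumerate(active):
            for di, det in enumerate(dets):
                dist = pixel_size_um * math.hypot(
                    det.x_px - tr["last"].x_px, det.y_px - tr["last"].y_px
                )
                if dist <= max_jump_um:
                    pairs.append((dist, di, ti))
        used_d, used_t = set(), set()
        for dist, di, ti in sorted(pairs):
            if di in used_d or ti in used_t:
                continue
            used_d.add(di)
            used_t.add(ti)
            active[ti]["spots"].append(dets[di])
            active[ti]["last"] = dets[di]
        for di, det in enumerate(dets):
            if di not in used_d:
                active.append({"spots": [det], "last": det})
        still = []
        for tr in active:
            if f - tr["last"].frame > max_gap_frames:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
    finished.extend(active)

    out: List[Trajectory] = []
    for mid, tr in enumerate(finished):
        spots = tr["spots"]
        f0, f1 = spots[0].frame, spots[-1].frame
        n = f1 - f0 + 1
        det = np.zeros(n, dtype=bool)
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        for s in spots:
            det[s.frame - f0] = True
            x[s.frame - f0] = s.x_px
            y[s.frame - f0] = s.y_px
        idx = np.arange(n)
        x = np.interp(idx, idx[det], x[det])
        y = np.interp(idx, idx[det], y[det])
        out.append(
            Trajectory(
                molecule_id=mid,
                frame_interval_s=frame_interval_s,
                times_s=(f0 + idx) * frame_interval_s,
                positions_um=x * pixel_size_um,
                detected=det,
                lateral_um=y * pixel_size_um,
                geometry=geometry,
            )
        )
    return out


def filter_trajectories(tracks: Sequence[Trajectory], min_frames: int = 50):
    """Keep tracks with at least ``min_frames`` detected frames (inclusive:
    a 50-frame track at 0.2 s/frame is exactly the 10 s minimum and is
    kept).  Returns (kept, n_removed)."""
    kept = [t for t in tracks if t.n_detected >= min_frames]
    return kept, len(tracks) - len(kept)
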