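"""Synthetic kymograph rendering: ground-truth trajectories -> TIFF movies.

Each visible molecule is drawn as a symmetric 2D Gaussian point-spread
function on a constant fluorescence background; photon shot noise is
Poisson and the result is quantized to the camera bit depth.  The DNA axis
runs along image columns (x); adjacent DNA molecules occupy different rows.
Dark-state (blinking) and dissociated frames render nothing, so the
downstream tracker sees realistic gaps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .geometry import DnaGeometry
from .simulate import GroundTruthTrajectory


@dataclass
class OpticsConfig:
    """Camera and PSF model (defaults: 100x objective on a 16 um-pixel
    EMCCD, QD emission PSF)."""

    pixel_size_um: float = 0.16
    psf_sigma_px: float = 0.9
    photons_per_frame: float = 1000.0
    background_photons_per_px: float = 10.0
    camera_bit_depth: int = 16
    margin_px: int = 6

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")


def render_kymograph(
    trajectories: Sequence[GroundTruthTrajectory],
    optics: OpticsConfig = OpticsConfig(),
    geometry: DnaGeometry = DnaGeometry(),
    axis_separation_um: float = 1.0,
    shot_noise: bool = True,
    seed: int = 0,
):
    """Render trajectories into a 16-bit image stack with a truth sidecar.

    Returns ``(stack, sidecar)``: stack has shape (n_frames, height,
    width); the sidecar echoes the optics/geometry and carries per-molecule
    true positions (px and bp), visibility and axis rows so trackers can be
    scored against it.  Positions falling outside the image are clipped
    (the sidecar counts them).
    """
    if not trajectories:
        raise ValueError("no trajectories to render")
    n_frames = trajectories[0].n_frames
    if any(t.n_frames != n_frames for t in trajectories):
        raise ValueError("trajectories must share one frame grid")
    rng = np.random.default_rng(seed)

    n_axes = 1
    for t in trajectories:
        if t.axis_per_frame is not None:
            n_axes = max(n_axes, int(t.axis_per_frame.max()) + 1)
    sep_px = axis_separation_um / optics.pixel_size_um
    width = int(math.ceil(geometry.tether_span_um / optics.pixel_size_um)) + 2 * optics.margin_px
    height = 2 * optics.margin_px + int(math.ceil((n_axes - 1) * sep_px)) + 1
    axis_rows = [optics.margin_px + a * sep_px for a in range(n_axes)]
    maxval = 2**optics.camera_bit_depth - 1

    half = int(math.ceil(5 * optics.psf_sigma_px))
    stack = np.empty((n_frames, height, width), dtype=np.uint16)
    clipped = 0
    truth_rows = []
    for f in range(n_frames):
        photons = np.full((height, width), optics.background_photons_per_px)
        for t in trajectories:
            visible = t.visible_mask()[f]
            x_px = t.true_positions_bp[f] * geometry.um_per_bp / optics.pixel_size_um + optics.margin_px
            axis = int(t.axis_per_frame[f]) if t.axis_per_frame is not None else 0
            y_px = axis_rows[axis]
            if visible:
                if not (0 <= x_px < width):
                    clipped += 1
                    x_draw = min(max(x_px, 0.0), width - 1.0)
                else:
                    x_draw = x_px
                xi = int(round(x_draw))
                yi = int(round(y_px))
                y0, y1 = max(0, yi - half), min(height, yi + half + 1)
                x0, x1 = max(0, xi - half), min(width, xi + half + 1)
                yy, xx = np.mgrid[y0:y1, x0:x1]
                psf = np.exp(
                    -((xx - x_draw) ** 2 + (yy - y_px) ** 2) / (2 * optics.psf_sigma_px**2)
                )
                psf *= optics.photons_per_frame / (2 * math.pi * optics.psf_sigma_px**2)
                photons[y0:y1, x0:x1] += psf
            truth_rows.append(
                {
                    "molecule_id": t.molecule_id,
                    "frame": f,
                    "true_position_bp": float(t.true_positions_bp[f]),
                    "true_x_px": float(x_px),
                    "true_y_px": float(y_px),
                    "visible": bool(visible),
                    "state": str(t.state_per_frame[f]),
                    "axis": axis,
                }
            )
        if shot_noise:
            photons = rng.poisson(photons)
        stack[f] = np.clip(photons, 0, maxval).astype(np.uint16)

    if clipped:
        warnings.warn(f"{clipped} molecule-frames fell outside the image and were clipped")
    sidecar = {
        "format_version": 1,
        "optics": {
            "pixel_size_um": optics.pixel_size_um,
            "psf_sigma_px": optics.psf_sigma_px,
            "photons_per_frame": optics.photons_per_frame,
            "background_photons_per_px": optics.background_photons_per_px,
            "camera_bit_depth": optics.camera_bit_depth,
            "margin_px": optics.margin_px,
        },
        "geometry": {
            "length_bp": geometry.length_bp,
            "tether_span_um": geometry.tether_span_um,
        },
        "axis_rows_px": axis_rows,
        "n_clipped": clipped,
        "seed": seed,
        "truth": truth_rows,
    }
    return stack, sidecar
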