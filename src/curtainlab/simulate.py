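"""Stochastic sliding + hopping simulator on obstacle-bearing DNA.

The model: a protein clamp performs 1D Brownian sliding along the duplex
(diffusion coefficient ``d_slide_um2_s``) interrupted by Poissonian
micro-dissociation events ("hops").  A hop is instantaneous on the 0.2 s
frame scale: the clamp opens, the protein excursions briefly into solution
and re-lands at a Gaussian-displaced position.  Hops are the only way past
a roadblock (sliding reflects at roadblock edges) and each hop carries a
probability of macroscopic escape.  A lesion site captures and arrests
visiting molecules.  Fluorophore blinking is a two-state telegraph process
overlaid on the motion.

Every trajectory carries its full ground truth (per-frame state, roadblock
crossing log, escape mode), so the downstream tracker, diffusion estimator,
dwell-time fitter and event classifiers can all be validated against a
known answer.

Units: positions are continuous base pairs on [0, length_bp]; diffusion
coefficients are given in um^2/s and converted through the tether geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .geometry import DnaGeometry
from .kinetics import DwellRecord
from .obstacles import LesionSite, Roadblock

STATE_SLIDING = "sliding"
STATE_HOPPING = "hopping"
STATE_CAPTURED = "captured"
STATE_DISSOCIATED = "dissociated"
STATE_DARK = "dark"

_TERMINAL = (STATE_CAPTURED, STATE_DISSOCIATED)


@dataclass
class SimulationConfig:
    """Parameters of one simulated condition.

    Rates are per second; ``hop_sigma_bp`` is the s.d. of the landing
    displacement of a single micro-hop; ``p_escape_per_hop`` converts a hop
    into macroscopic dissociation; ``t_half_s`` parameterizes standalone
    dwell-time draws.  ``loc_sigma_bp`` (default 250 bp) is the Gaussian
    localization noise added by :func:`observe_positions`.
    """

    d_slide_um2_s: float = 0.025
    hop_rate_per_s: float = 0.0
    hop_sigma_bp: float = 500.0
    p_escape_per_hop: float = 0.0
    t_half_s: float = 76.0
    roadblocks: List[Roadblock] = field(default_factory=list)
    lesion: Optional[LesionSite] = None
    blink_off_rate_per_s: float = 0.0
    blink_on_rate_per_s: float = 0.0
    loc_sigma_bp: float = 250.0
    frame_interval_s: float = 0.2
    n_frames: int = 300
    start_position_bp: Optional[float] = None
    distal_end_open: bool = False  # single-tether mode: sliding off the free end
    seed: int = 0

    def validate(self, geometry: DnaGeometry) -> None:
        for name in (
            "d_slide_um2_s",
            "hop_rate_per_s",
            "hop_sigma_bp",
            "blink_off_rate_per_s",
            "blink_on_rate_per_s",
            "loc_sigma_bp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_escape_per_hop <= 1.0:
            raise ValueError("p_escape_per_hop must lie in [0, 1]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.t_half_s <= 0:
            raise ValueError("t_half_s must be positive")
        if self.lesion is not None and not (
            0 <= self.lesion.position_bp <= geometry.length_bp
        ):
            raise ValueError("lesion lies outside the DNA")
        for rb in self.roadblocks:
            if not 0 <= rb.position_bp <= geometry.length_bp:
                raise ValueError(f"roadblock {rb.id} lies outside the DNA")


@dataclass
class CrossingRecord:
    roadblock_id: str
    time_s: float
    crossed: bool


@dataclass
class TransferRecord:
    time_s: float
    from_axis: int
    to_axis: int


@dataclass
class GroundTruthTrajectory:
    """Noiseless simulator output for one molecule."""

    times_s: np.ndarray
    true_positions_bp: np.ndarray
    state_per_frame: np.ndarray  # of STATE_* strings
    crossing_log: List[CrossingRecord] = field(default_factory=list)
    axis_per_frame: Optional[np.ndarray] = None
    transfer_log: List[TransferRecord] = field(default_factory=list)
    escape_mode: Optional[str] = None  # "internal" | "end" | None (survived)
    molecule_id: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    def visible_mask(self) -> np.ndarray:
        """Frames where the molecule is on DNA and fluorescent."""
        on_dna = ~np.isin(self.state_per_frame, [STATE_DISSOCIATED, STATE_DARK])
        return on_dna


def _blink_step(rng, dark: bool, off_rate: float, on_rate: float, dt: float) -> bool:
    if dark:
        if on_rate > 0 and rng.random() < -math.expm1(-on_rate * dt):
            return False
        return True
    if off_rate > 0 and rng.random() < -math.expm1(-off_rate * dt):
        return True
    return False


def _interval_bounds(pos: float, walls: Sequence[float], lo: float, hi: float):
    """Reflecting interval around pos given sorted roadblock walls."""
    left, right = lo, hi
    for w in walls:
        if w <= pos and w > left:
            left = w
        if w > pos and w < right:
            right = w
    return left, right


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposed position into [lo, hi] (specular reflection)."""
    if hi <= lo:
        return lo
    span = hi - lo
    x = (x - lo) % (2.0 * span)
    if x > span:
        x = 2.0 * span - x
    return x + lo


def simulate_trajectory(
    config: SimulationConfig,
    geometry: DnaGeometry = DnaGeometry(),
    rng: Optional[np.random.Generator] = None,
    molecule_id: int = 0,
    n_axes: int = 1,
    transfer_p_per_hop: float = 0.0,
) -> GroundTruthTrajectory:
    """Euler-step one molecule at the frame interval.

    Hops, escapes and captures are resolved at sub-frame times drawn
    uniformly within the frame.  Sliding reflects at DNA ends and roadblock
    edges; a hop landing may cross a roadblock subject to its permeability.
    With ``n_axes > 1`` each non-escape hop may additionally relocate the
    molecule to a random adjacent DNA axis with ``transfer_p_per_hop``.
    """
    config.validate(geometry)
    if not 0.0 <= transfer_p_per_hop <= 1.0:
        raise ValueError("transfer_p_per_hop must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    dt = config.frame_interval_s
    length = float(geometry.length_bp)
    sigma_step_bp = math.sqrt(2.0 * config.d_slide_um2_s * dt) / geometry.um_per_bp
    walls = sorted(rb.position_bp for rb in config.roadblocks)
    rb_by_pos = {rb.position_bp: rb for rb in config.roadblocks}

    if config.start_position_bp is None:
        pos = rng.uniform(0.0, length)
    else:
        pos = float(config.start_position_bp)
        if not 0.0 <= pos <= length:
            raise ValueError("start_position_bp outside DNA")
    axis = 0

    n = config.n_frames
    times = np.arange(n) * dt
    positions = np.empty(n)
    states = np.empty(n, dtype="U11")
    axes = np.zeros(n, dtype=int)
    crossing_log: List[CrossingRecord] = []
    transfer_log: List[TransferRecord] = []
    escape_mode: Optional[str] = None

    dark = False
    captured = False
    dissociated = False
    # one contact log entry per continuous sliding-contact episode
    in_contact = {rb.id: False for rb in config.roadblocks}

    def lesion_here(p: float) -> bool:
        return (
            config.lesion is not None
            and axis == 0
            and abs(p - config.lesion.position_bp) <= config.lesion.capture_radius_bp
        )

    for i in range(n):
        t = times[i]
        if dissociated:
            positions[i] = pos
            states[i] = STATE_DISSOCIATED
            axes[i] = axis
            continue
        if captured:
            positions[i] = pos
            states[i] = STATE_DARK if dark else STATE_CAPTURED
            dark = _blink_step(
                rng, dark, config.blink_off_rate_per_s, config.blink_on_rate_per_s, dt
            )
            axes[i] = axis
            continue

        hopped = False
        n_hops = rng.poisson(config.hop_rate_per_s * dt) if config.hop_rate_per_s else 0
        hop_times = np.sort(rng.uniform(t, t + dt, size=n_hops)) if n_hops else []
        for ht in hop_times:
            hopped = True
            if config.p_escape_per_hop and rng.random() < config.p_escape_per_hop:
                dissociated = True
                escape_mode = "internal"
                break
            if n_axes > 1 and transfer_p_per_hop and rng.random() < transfer_p_per_hop:
                new_axis = (axis + (1 if n_axes == 2 else rng.integers(1, n_axes))) % n_axes
                transfer_log.append(TransferRecord(float(ht), axis, new_axis))
                axis = new_axis
            landing = pos + rng.normal(0.0, config.hop_sigma_bp)
            # roadblocks live on axis 0 only in multi-axis scenes
            blocked = False
            if axis == 0:
                lo_p, hi_p = min(pos, landing), max(pos, landing)
                between = [w for w in walls if lo_p < w < hi_p]
                for w in between:
                    rb = rb_by_pos[w]
                    crossed = rng.random() < rb.permeability
                    crossing_log.append(CrossingRecord(rb.id, float(ht), crossed))
                    if crossed:
                        in_contact[rb.id] = False
                    else:
                        blocked = True
                        break
            if blocked:
                continue  # clamp re-closes where it opened
            if landing < 0.0:
                landing = -landing
            if landing > length:
                if config.distal_end_open:
                    dissociated = True
                    escape_mode = "end"
                    break
                landing = 2.0 * length - landing
            pos = min(max(landing, 0.0), length)
            if lesion_here(pos) and rng.random() < config.lesion.p_capture_per_visit:
                captured = True
                pos = config.lesion.position_bp
                break

        if not dissociated and not captured and sigma_step_bp > 0:
            lo, hi = (0.0, length) if axis != 0 else _interval_bounds(pos, walls, 0.0, length)
            proposal = pos + rng.normal(0.0, sigma_step_bp)
            if axis == 0:
                for w in walls:
                    rb = rb_by_pos[w]
                    hits = (pos <= w <= proposal) or (proposal <= w <= pos)
                    if hits and not in_contact[rb.id]:
                        crossing_log.append(
                            CrossingRecord(rb.id, float(t + dt), False)
                        )
                        in_contact[rb.id] = True
                    elif not hits and abs(pos - w) > rb.collision_zone_halfwidth_bp:
                        in_contact[rb.id] = False
            if config.distal_end_open and proposal > length and hi >= length:
                dissociated = True
                escape_mode = "end"
                pos = length
            else:
                pos = _reflect(proposal, lo, hi)
            if (
                not dissociated
                and lesion_here(pos)
                and rng.random() < config.lesion.p_capture_per_visit
            ):
                captured = True
                pos = config.lesion.position_bp

        positions[i] = pos
        axes[i] = axis
        if dissociated:
            states[i] = STATE_DISSOCIATED
        elif captured:
            states[i] = STATE_CAPTURED
        elif dark:
            states[i] = STATE_DARK
        else:
            states[i] = STATE_HOPPING if hopped else STATE_SLIDING
        dark = _blink_step(
            rng, dark, config.blink_off_rate_per_s, config.blink_on_rate_per_s, dt
        )

    return GroundTruthTrajectory(
        times_s=times,
        true_positions_bp=positions,
        state_per_frame=states,
        crossing_log=crossing_log,
        axis_per_frame=axes if n_axes > 1 else None,
        transfer_log=transfer_log,
        escape_mode=escape_mode,
        molecule_id=molecule_id,
    )


def simulate_population(
    config: SimulationConfig,
    n: int,
    geometry: DnaGeometry = DnaGeometry(),
) -> List[GroundTruthTrajectory]:
    """n independent trajectories with per-molecule counter-derived streams.

    Stream ``i`` is seeded by ``(config.seed, i)``, so growing ``n`` never
    reshuffles earlier trajectories.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    out = []
    for i in range(n):
        rng = np.random.default_rng([config.seed, i])
        out.append(simulate_trajectory(config, geometry, rng=rng, molecule_id=i))
    return out


def make_two_dna_scene(
    separation_um: float,
    transfer_p_per_hop: float,
    config: SimulationConfig,
    geometry: DnaGeometry = DnaGeometry(),
    n: int = 1,
) -> List[GroundTruthTrajectory]:
    """Molecules hopping between two parallel DNA axes ~1 um apart.

    Each non-escape hop relocates to the neighbouring axis with
    ``transfer_p_per_hop``; the ground truth logs every transfer with its
    sub-frame time.  ``axis_per_frame`` gives the axis occupied at each
    frame; lateral positions are ``axis * separation_um``.
    """
    if separation_um <= 0:
        raise ValueError("separation_um must be positive")
    if not 0.0 <= transfer_p_per_hop <= 1.0:
        raise ValueError("transfer_p_per_hop must lie in [0, 1]")
    out = []
    for i in range(n):
        rng = np.random.default_rng([config.seed, 2, i])
        out.append(
            simulate_trajectory(
                config,
                geometry,
                rng=rng,
                molecule_id=i,
                n_axes=2,
                transfer_p_per_hop=transfer_p_per_hop,
            )
        )
    return out


def simulate_dwell_times(
    t_half_s: float,
    n: int,
    censor_at_s: float = math.inf,
    seed: int = 0,
) -> List[DwellRecord]:
    """Exponential on-DNA lifetimes with rate ln2 / t_half.

    Lifetimes exceeding ``censor_at_s`` (the movie end) are truncated there
    and flagged censored.
    """
    if t_half_s <= 0:
        raise ValueError("t_half_s must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rate = math.log(2.0) / t_half_s
    draws = rng.exponential(1.0 / rate, size=n)
    records = []
    for i, d in enumerate(draws):
        censored = bool(d >= censor_at_s)
        records.append(
            DwellRecord(
                molecule_id=i,
                bind_time_s=0.0,
                release_time_s=float(min(d, censor_at_s)),
                censored=censored,
            )
        )
    return records


def observe_positions(
    traj: GroundTruthTrajectory,
    loc_sigma_bp: float,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> np.ndarray:
    """True positions plus i.i.d. Gaussian localization noise (bp).

    Frames where the molecule is dark or off DNA are NaN, mimicking missed
    detections.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = traj.true_positions_bp + rng.normal(0.0, loc_sigma_bp, traj.n_frames)
    obs[~traj.visible_mask()] = np.nan
    return obs
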