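"""Obstacles on the DNA substrate: protein roadblocks and the flap lesion.

A roadblock (nucleosome, stalled restriction enzyme, ...) blocks continuous
1D sliding; only a hop landing may cross it.  The ``permeability`` field is
the probability that a hop landing on the far side is accepted — it encodes
how easily the obstacle is bypassed without asserting a molecular mechanism.
The ``collision_zone_halfwidth_bp`` is an analysis property: within 3x the
localization s.d. of the obstacle, protein and obstacle cannot be resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: localization s.d. for a stationary labelled particle, bp
LOCALIZATION_SIGMA_BP = 250.0

#: half of the 750 bp collision zone (3 x localization s.d.)
COLLISION_ZONE_HALFWIDTH_BP = 1.5 * LOCALIZATION_SIGMA_BP


@dataclass
class Roadblock:
    position_bp: float
    id: str = "rb0"
    dna_axis_id: str = "dna0"
    kind: str = "nucleosome"
    collision_zone_halfwidth_bp: float = COLLISION_ZONE_HALFWIDTH_BP
    permeability: float = 1.0  # probability a hop landing may cross

    def __post_init__(self) -> None:
        if self.collision_zone_halfwidth_bp <= 0:
            raise ValueError("collision_zone_halfwidth_bp must be positive")
        if not 0.0 <= self.permeability <= 1.0:
            raise ValueError("permeability must lie in [0, 1]")


@dataclass
class LesionSite:
    """Capture site (a 3'-ssDNA flap in the reference substrate, 20 kb from
    the anchored end).  A molecule within ``capture_radius_bp`` is captured
    with probability ``p_capture_per_visit`` per frame; capture freezes it."""

    position_bp: float = 20000.0
    capture_radius_bp: float = 150.0
    p_capture_per_visit: float = 1.0

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError("lesion position must be non-negative")
        if self.capture_radius_bp < 0:
            raise ValueError("capture_radius_bp must be non-negative")
        if not 0.0 <= self.p_capture_per_visit <= 1.0:
            raise ValueError("p_capture_per_visit must lie in [0, 1]")
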