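"""DNA-curtain geometry and bp <-> micrometre conversions.

A curtain extends a single DNA molecule (default: the 48,502 bp lambda-phage
substrate) between two surface anchors.  The tether span is shorter than the
B-form contour length, so every conversion between base-pair coordinates and
physical distance must go through the measured span, never through a
hard-coded 0.34 nm/bp.
"""

from __future__ import annotations

from dataclasses import dataclass

RISE_PER_BP_NM = 0.34  # B-form helical rise


@dataclass(frozen=True)
class DnaGeometry:
    """Physical layout of one tethered DNA molecule.

    Parameters
    ----------
    length_bp : int
        Substrate length in base pairs.
    tether_span_um : float
        Distance between the two tether points in micrometres.
    rise_per_bp_nm : float
        Helical rise used to compute the B-form contour length.

    Position 0 bp is the anchored (biotin/barrier) end; positions increase
    toward the distal end.
    """

    length_bp: int = 48502
    tether_span_um: float = 13.0
    rise_per_bp_nm: float = RISE_PER_BP_NM

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.tether_span_um <= 0:
            raise ValueError("tether_span_um must be positive")
        if self.tether_span_um > self.contour_length_um + 1e-12:
            raise ValueError(
                "tether span exceeds B-form contour length "
                f"({self.tether_span_um} um > {self.contour_length_um:.3f} um)"
            )

    @property
    def contour_length_um(self) -> float:
        return self.length_bp * self.rise_per_bp_nm / 1000.0

    @property
    def fractional_extension(self) -> float:
        """Extension relative to B-form contour (~0.8 for a 13 um curtain)."""
        return self.tether_span_um / self.contour_length_um

    @property
    def um_per_bp(self) -> float:
        return self.tether_span_um / self.length_bp

    def bp_to_um(self, position_bp):
        return position_bp * self.um_per_bp

    def um_to_bp(self, position_um):
        return position_um / self.um_per_bp

    def bp_to_nm(self, position_bp):
        return self.bp_to_um(position_bp) * 1000.0
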