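"""Buffer ionic strength and the salt dependence of 1D diffusion.

Ionic strength is I = 1/2 * sum_i c_i z_i^2 over all ions.  The standard
imaging buffer is 40 mM Tris-HCl pH 8.0 with 2 mM MgCl2 and 25-150 mM NaCl
(DTT and BSA are treated as non-ionic), giving totals of 51-176 mM.

Tris is a weak base (pKa 8.1 at 25 C), so its contribution depends on the
protonated fraction f = 1 / (1 + 10^(pH - pKa)).  Two accounting modes are
provided:

* ``"paper"`` reproduces the worked decomposition this pipeline was built
  against: the TrisH+ cation term uses a 45% charged fraction (9 mM at
  40 mM Tris) while the chloride counter-ion term uses the
  Henderson-Hasselbalch protonated fraction (11 mM).  The two fractions are
  mutually inconsistent under electroneutrality (equal cation and anion
  counts force equal contributions) but match the published arithmetic.
* ``"consistent"`` uses the Henderson-Hasselbalch fraction for both ions
  (electroneutral); this is the physically coherent choice for new work.

The difference between modes is confined to the Tris terms and is ~2 mM
for the standard buffer.

For a protein held on DNA by n charge-charge contacts, counterion
condensation theory predicts log10(D) rises linearly in log10(I) with slope
n * psi, where psi = 0.88 is the fraction of dsDNA phosphate charge
neutralized by condensed counterions.  ``SaltDependenceRegression``
recovers n = slope / psi from (I, mean D) points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

PSI_DSDNA = 0.88  # counterion condensation parameter for double-stranded DNA
PAPER_TRIS_CHARGED_FRACTION = 0.45

MODE_PAPER = "paper"
MODE_CONSISTENT = "consistent"


@dataclass
class BufferComposition:
    tris_mM: float = 40.0
    pH: float = 8.0
    tris_pKa: float = 8.1
    nacl_mM: float = 25.0
    mgcl2_mM: float = 2.0
    extra_species: List[Tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("tris_mM", "nacl_mM", "mgcl2_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.pH < 14:
            raise ValueError("pH must lie in (0, 14)")
        for c, _z in self.extra_species:
            if c < 0:
                raise ValueError("extra species concentrations must be non-negative")


@dataclass
class IonicStrengthResult:
    contributions_mM: dict
    total_mM: float
    mode: str


def species_contribution(concentration_mM: float, z: int) -> float:
    """One ion's term in I = 1/2 sum c z^2, in mM."""
    if concentration_mM < 0:
        raise ValueError("concentration must be non-negative")
    return 0.5 * concentration_mM * z**2


def protonated_fraction(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch fraction of a base carrying the proton."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def tris_contributions(
    tris_mM: float, pH: float, pKa: float = 8.1, mode: str = MODE_PAPER
) -> Tuple[float, float]:
    """(TrisH+ term, titration Cl- term) of the ionic strength, in mM."""
    f_hh = protonated_fraction(pH, pKa)
    if mode == MODE_PAPER:
        cation = species_contribution(PAPER_TRIS_CHARGED_FRACTION * tris_mM, 1)
        anion = species_contribution(f_hh * tris_mM, -1)
    elif mode == MODE_CONSISTENT:
        cation = species_contribution(f_hh * tris_mM, 1)
        anion = species_contribution(f_hh * tris_mM, -1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return cation, anion


def total_ionic_strength(
    buffer: BufferComposition, mode: str = MODE_PAPER
) -> IonicStrengthResult:
    tris_cat, tris_cl = tris_contributions(buffer.tris_mM, buffer.pH, buffer.tris_pKa, mode)
    contributions = {
        "trisH+": tris_cat,
        "tris_Cl-": tris_cl,
        "Na+": species_contribution(buffer.nacl_mM, 1),
        "NaCl_Cl-": species_contribution(buffer.nacl_mM, -1),
        "Mg2+": species_contribution(buffer.mgcl2_mM, 2),
        "MgCl2_Cl-": species_contribution(2 * buffer.mgcl2_mM, -1),
    }
    for j, (c, z) in enumerate(buffer.extra_species):
        contributions[f"extra_{j}"] = species_contribution(c, z)
    return IonicStrengthResult(
        contributions_mM=contributions,
        total_mM=sum(contributions.values()),
        mode=mode,
    )


@dataclass
class SaltDependenceFit:
    points: List[Tuple[float, float]]
    slope: float
    slope_se: float
    intercept: float
    psi: float
    screened_charges: float
    screened_charges_se: float


class SaltDependenceRegression(BaseEstimator):
    """log10(D) vs log10(I) regression -> screened-charge count.

    Attributes (after ``fit(I_mM, mean_D)``):
    ``slope_``, ``slope_se_`` (standard error of the slope),
    ``screened_charges_`` = slope / psi with linearly propagated s.e.
    """

    def __init__(self, psi: float = PSI_DSDNA):
        self.psi = psi

    def fit(self, ionic_strength_mM, mean_d):
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        I = np.asarray(ionic_strength_mM, dtype=float)
        D = np.asarray(mean_d, dtype=float)
        if len(I) < 2 or len(I) != len(D):
            raise ValueError("need >= 2 (I, D) points of equal length")
        if np.any(I <= 0) or np.any(D <= 0):
            raise ValueError("ionic strengths and diffusion coefficients must be positive")
        x, y = np.log10(I), np.log10(D)
        if np.ptp(x) == 0:
            raise ValueError("degenerate regression: all ionic strengths identical")
        n = len(x)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        if n > 2:
            s2 = float(resid @ resid) / (n - 2)
            se = math.sqrt(s2 / float(((x - x.mean()) ** 2).sum()))
        else:
            se = 0.0
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.slope_se_ = se
        self.screened_charges_ = self.slope_ / self.psi
        self.screened_charges_se_ = se / self.psi
        self._points = list(zip(I.tolist(), D.tolist()))
        return self

    def result_(self) -> SaltDependenceFit:
        return SaltDependenceFit(
            points=self._points,
            slope=self.slope_,
            slope_se=self.slope_se_,
            intercept=self.intercept_,
            psi=self.psi,
            screened_charges=self.screened_charges_,
            screened_charges_se=self.screened_charges_se_,
        )


def fit_salt_dependence(points: Sequence[Tuple[float, float]], psi: float = PSI_DSDNA) -> SaltDependenceFit:
    I, D = zip(*points)
    return SaltDependenceRegression(psi=psi).fit(I, D).result_()


def screened_charges(slope: float, psi: float = PSI_DSDNA, slope_se: float = 0.0):
    """Charge-contact count n = slope / psi, with propagated uncertainty."""
    if psi <= 0:
        raise ValueError("psi must be positive")
    return slope / psi, slope_se / psi
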