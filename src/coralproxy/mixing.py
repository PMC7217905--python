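"""Estuarine Ba-salinity endmember mixing and coral/seawater Ba conversion.

Dissolved Ba in an estuary mixes quasi-conservatively between a
high-Ba, low-salinity river endmember (fed by desorption of Ba2+ from
suspended sediment) and a low-Ba marine endmember, giving a linear
Ba-salinity relation. A coral skeleton records seawater Ba through the
Ba/Ca ratio with a partition coefficient of ~1, so skeletal Ba/Ca
(umol/mol) converts to seawater Ba (nmol/kg) by multiplying with the
seawater Ca concentration (mmol/kg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import WaterSample, pearson
from .errors import DegenerateDataError

__all__ = [
    "SEAWATER_CA_MMOL_KG",
    "MixingFit",
    "ba_salinity_fit",
    "coral_to_seawater_ba",
    "seawater_to_coral_ba",
]

#: seawater Ca concentration at salinity 35 (mmol/kg)
SEAWATER_CA_MMOL_KG = 10.28


@dataclass(frozen=True)
class MixingFit:
    """OLS fit of Ba (nmol/kg) on practical salinity."""

    slope: float  # nmol/kg per salinity unit
    intercept: float  # zero-salinity (river) endmember, nmol/kg
    r: float
    p: float
    n: int
    marine_endmember: float  # prediction at salinity 35

    def predict(self, salinity) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(salinity, dtype=float)


def ba_salinity_fit(samples: list[WaterSample]) -> MixingFit:
    """Fit the conservative-mixing line through water samples.

    Needs at least 3 samples with nonzero salinity variance; evaluates the
    endmembers at salinity 0 (river) and 35 (marine).
    """
    if len(samples) < 3:
        raise DegenerateDataError("mixing fit needs at least 3 samples")
    sal = np.array([s.salinity for s in samples], dtype=float)
    ba = np.array([s.ba_nmol_kg for s in samples], dtype=float)
    if np.ptp(sal) == 0:
        raise DegenerateDataError("salinity has zero variance")
    slope, intercept = np.polyfit(sal, ba, 1)
    corr = pearson(sal, ba)
    return MixingFit(
        slope=float(slope),
        intercept=float(intercept),
        r=corr.r,
        p=corr.p,
        n=len(samples),
        marine_endmember=float(intercept + 35.0 * slope),
    )


def coral_to_seawater_ba(
    ba_ca_coral_umol_mol, ca_seawater_mmol_kg: float = SEAWATER_CA_MMOL_KG
):
    """Seawater Ba (nmol/kg) implied by a skeletal Ba/Ca ratio (umol/mol).

    With a partition coefficient of 1, Ba/Ca(coral) = Ba/Ca(seawater), so
    Ba_sw = Ba/Ca * Ca_sw; the unit product 1e-6 mol/mol * 1e-3 mol/kg
    lands exactly on 1e-9 mol/kg. E.g. 3.8 umol/mol -> 39.064 nmol/kg.
    """
    ba = np.asarray(ba_ca_coral_umol_mol, dtype=float)
    if np.any(ba <= 0) or ca_seawater_mmol_kg <= 0:
        raise DegenerateDataError("Ba/Ca and seawater Ca must be positive")
    out = ba * ca_seawater_mmol_kg
    return float(out) if np.isscalar(ba_ca_coral_umol_mol) else out


def seawater_to_coral_ba(
    ba_sw_nmol_kg, ca_seawater_mmol_kg: float = SEAWATER_CA_MMOL_KG
):
    """Inverse of :func:`coral_to_seawater_ba`."""
    ba = np.asarray(ba_sw_nmol_kg, dtype=float)
    if np.any(ba <= 0) or ca_seawater_mmol_kg <= 0:
        raise DegenerateDataError("Ba and seawater Ca must be positive")
    out = ba / ca_seawater_mmol_kg
    return float(out) if np.isscalar(ba_sw_nmol_kg) else out
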