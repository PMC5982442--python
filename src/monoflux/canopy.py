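"""Canopy bookkeeping (LAI, community-weighted SLA) and monolith water balance.

LAI sums leaf biomass (g m^-2, converted to kg) times specific leaf area
(m^2 kg^-1) over functional groups; the community-weighted mean SLA weights
each group's SLA by its share of total leaf biomass. Evapotranspiration is
closed from the water balance: inputs minus leachate minus the change in
soil water storage over an effective depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MONOLITH_DEPTH_MM",
    "lai",
    "cwm_sla",
    "evapotranspiration",
]

MONOLITH_DEPTH_MM = 280.0  # monolith height, default storage depth


def _leaf_sla(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    leaf = records["leaf_biomass"].to_numpy(dtype=float)
    sla = records["sla"].to_numpy(dtype=float)
    if np.any(leaf < 0):
        raise ValueError("leaf_biomass must be >= 0")
    bad = (leaf > 0) & ~(sla > 0)
    if np.any(bad):
        groups = records.loc[bad, "functional_group"].tolist() if "functional_group" in records else []
        raise ValueError(f"missing SLA where leaf biomass > 0: {groups}")
    return leaf, sla


def lai(records: pd.DataFrame) -> float:
    """Leaf area index (m^2 m^-2) for one monolith's functional groups."""
    leaf, sla = _leaf_sla(records)
    return float(np.sum(np.where(leaf > 0, leaf / 1000.0 * sla, 0.0)))


def cwm_sla(records: pd.DataFrame) -> float:
    """Leaf-biomass-weighted mean SLA (m^2 kg^-1) across functional groups."""
    leaf, sla = _leaf_sla(records)
    total = leaf.sum()
    if total <= 0:
        raise ValueError("community-weighted SLA is undefined with zero total leaf biomass")
    return float(np.sum(leaf / total * np.where(leaf > 0, sla, 0.0)))


@dataclass(frozen=True)
class EtResult:
    et_mm: float
    delta_storage_mm: float
    suspect: bool  # physically suspect: negative ET or leachate > input


def evapotranspiration(
    water_in_mm: float,
    leachate_mm: float,
    theta_start: float,
    theta_end: float,
    effective_depth_mm: float = MONOLITH_DEPTH_MM,
) -> EtResult:
    """Water-balance evapotranspiration over a period.

    delta_storage = (theta_end - theta_start)/100 * depth (theta in vol.%);
    ET = inputs - leachate - delta_storage. Negative ET is returned but
    flagged as physically suspect rather than raised.
    """
    if effective_depth_mm <= 0:
        raise ValueError("effective_depth_mm must be positive")
    for name, theta in (("theta_start", theta_start), ("theta_end", theta_end)):
        if not 0.0 <= theta <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100] vol.%, got {theta}")
    if leachate_mm < 0:
        raise ValueError("leachate_mm must be >= 0")
    delta_storage = (theta_end - theta_start) / 100.0 * effective_depth_mm
    et = water_in_mm - leachate_mm - delta_storage
    suspect = et < 0 or leachate_mm > water_in_mm
    return EtResult(et_mm=float(et), delta_storage_mm=float(delta_storage), suspect=bool(suspect))
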