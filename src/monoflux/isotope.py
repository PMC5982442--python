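"""15N tracer accounting: delta-notation conversion, excess and label budget.

delta15N values (per mil vs the AIR-N2 standard) convert to isotope ratios
via R = R_std * (delta/1000 + 1) and to atom percent via
atom% = 100 * R / (1 + R). The tracer incorporated into a tissue pool is

    incorporated 15N = (atom%_labelled - atom%_NA) * N_pool / 100

with atom%_NA taken from paired natural-abundance (unlabelled) samples of
the same tissue, and N_pool the areal nitrogen pool (mg N m^-2). Dividing
by the label applied per monolith gives recovery fractions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "R_STANDARD_AIR_N2",
    "MONOLITH_AREA_M2",
    "IsotopeError",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "nitrogen_pool",
    "incorporated_15n",
    "label_budget",
]

R_STANDARD_AIR_N2 = 0.0036765  # 15N/14N of atmospheric N2
MONOLITH_AREA_M2 = math.pi * 0.125**2  # 25 cm diameter core


class IsotopeError(ValueError):
    pass


def delta_to_atom_percent(delta15n, r_standard: float = R_STANDARD_AIR_N2):
    """Convert delta15N (per mil) to atom percent 15N."""
    delta15n = np.asarray(delta15n, dtype=float)
    if np.any(delta15n <= -1000.0):
        raise IsotopeError("delta15n <= -1000 permil implies a negative isotope ratio")
    r = r_standard * (delta15n / 1000.0 + 1.0)
    out = 100.0 * r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def atom_percent_to_delta(atom_percent, r_standard: float = R_STANDARD_AIR_N2):
    """Inverse of :func:`delta_to_atom_percent`."""
    atom_percent = np.asarray(atom_percent, dtype=float)
    if np.any((atom_percent <= 0) | (atom_percent >= 100)):
        raise IsotopeError("atom_percent must lie in (0, 100)")
    f = atom_percent / 100.0
    r = f / (1.0 - f)
    out = (r / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def nitrogen_pool(n_conc_mg_g, dry_mass_g_m2):
    """Areal N pool (mg N m^-2) from concentration (mg g^-1) and dry mass."""
    return np.asarray(n_conc_mg_g, dtype=float) * np.asarray(dry_mass_g_m2, dtype=float)


def incorporated_15n(atom_labelled, atom_na, n_pool):
    """(atom%_labelled - atom%_NA) * N_pool / 100, in mg 15N m^-2.

    Negative results (label below natural abundance) are permitted and left
    to the caller to flag; a negative pool is an error.
    """
    n_pool = np.asarray(n_pool, dtype=float)
    if np.any(n_pool < 0):
        raise IsotopeError("n_pool must be >= 0")
    for a in (atom_labelled, atom_na):
        a = np.asarray(a, dtype=float)
        if np.any((a <= 0) | (a >= 100)):
            raise IsotopeError("atom percent values must lie in (0, 100)")
    out = (np.asarray(atom_labelled, dtype=float) - np.asarray(atom_na, dtype=float)) * n_pool / 100.0
    return float(out) if out.ndim == 0 else out


def label_budget(
    samples: pd.DataFrame,
    applied_label_mg: float = 2.0,
    area_m2: float = MONOLITH_AREA_M2,
) -> dict[str, float]:
    """Recovery fractions of the applied label per tissue and in total.

    ``samples`` holds one row per measured sample with columns tissue,
    atom_percent, n_pool_mg_m2 and a boolean ``labelled`` flag. The
    natural-abundance reference for each tissue is the mean atom% of its
    unlabelled samples; a labelled tissue without such a reference is an
    error. Fractions are means over the labelled samples of
    incorporated-15N * area / applied label.
    """
    if area_m2 <= 0:
        raise IsotopeError("area_m2 must be positive")
    if applied_label_mg <= 0:
        raise IsotopeError("applied_label_mg must be positive")
    required = {"tissue", "atom_percent", "n_pool_mg_m2", "labelled"}
    missing = required - set(samples.columns)
    if missing:
        raise IsotopeError(f"samples missing columns: {sorted(missing)}")

    na_ref = (
        samples[~samples["labelled"]]
        .groupby("tissue", observed=True)["atom_percent"]
        .mean()
    )
    out: dict[str, float] = {}
    total = 0.0
    labelled = samples[samples["labelled"]]
    for tissue, rows in labelled.groupby("tissue", observed=True):
        if tissue not in na_ref.index:
            raise IsotopeError(
                f"no natural-abundance reference samples for tissue {tissue!r}"
            )
        inc = incorporated_15n(
            rows["atom_percent"].to_numpy(),
            float(na_ref[tissue]),
            rows["n_pool_mg_m2"].to_numpy(),
        )
        frac = float(np.mean(inc) * area_m2 / applied_label_mg)
        out[str(tissue)] = frac
        total += frac
    out["total"] = total
    return out
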