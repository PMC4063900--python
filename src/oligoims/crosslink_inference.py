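"""Cross-link stoichiometry from before/after mass shifts.

A tyrosine-tyrosine covalent bond removes two hydrogen atoms, so an
oligomer carrying k bonds is lighter than its non-covalent counterpart by a
nominal 2k Da. Matching species measured before and after the cross-linking
reaction at equal (order, charge) therefore turns the mass shift
``delta = M_after - M_before`` into a bond count ``k = round(-delta / 2)``.

The inferred k is independent of the m/z convention: the charge-carrier
term cancels in the difference at fixed z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccs_calibration import CalibrationModel

__all__ = ["BondInference", "SpeciesMatch", "infer_bonds", "build_species_table"]

#: Flags attached to a bond inference.
FLAG_OK = "ok"
FLAG_NO_EVIDENCE = "no cross-link evidence"
FLAG_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BondInference:
    delta: float  # M_after - M_before, Da
    k: int | None  # bonds; None when the shift matches no integer count
    residual: float  # |delta + 2k|, Da
    flag: str = FLAG_OK


@dataclass(frozen=True)
class SpeciesMatch:
    """A before/after pair of one (n, z) species at one drift feature."""

    n: int
    z: int
    mass_before: float
    mass_after: float
    delta: float
    k: int | None
    residual: float
    flag: str


def infer_bonds(mass_before: float, mass_after: float, tolerance: float = 0.5) -> BondInference:
    """Infer the Tyr-Tyr bond count from a before/after mass pair.

    ``k = round(-delta/2)`` clamped at >= 0; the residual is the distance of
    the shift from the nearest -2k Da. A residual beyond ``tolerance`` means
    the shift matches no bond count: for a mass loss k is reported as None
    ('unassigned'); for a mass gain k = 0 with a 'no cross-link evidence'
    flag.
    """
    if mass_before <= 0 or mass_after <= 0:
        raise ValueError("masses must be positive")
    delta = mass_after - mass_before
    k = max(0, round(-delta / 2.0))
    residual = abs(delta + 2.0 * k)
    if residual > tolerance:
        if delta > 0:
            return BondInference(delta=delta, k=0, residual=residual, flag=FLAG_NO_EVIDENCE)
        return BondInference(delta=delta, k=None, residual=residual, flag=FLAG_UNASSIGNED)
    return BondInference(delta=delta, k=k, residual=residual, flag=FLAG_OK)


_REQUIRED = ("n", "z", "avg_mz", "mass", "t_d")


def _check_frame(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table lacks columns: {missing}")
    return df.reset_index(drop=True)


def build_species_table(
    assignments_before: pd.DataFrame,
    assignments_after: pd.DataFrame,
    calibration: CalibrationModel | None = None,
    tolerance: float = 0.5,
    drift_match: float = 0.3,
) -> pd.DataFrame:
    """Pair before/after species assignments into a per-row report.

    Input frames need columns ``n, z, avg_mz, mass, t_d`` (one row per
    species and drift feature) and, if present, a ``convention`` column that
    must agree between the two frames. After-rows are matched to before-rows
    of the same (n, z) by nearest drift time (within ``drift_match`` ms);
    unmatched after-rows — species that only exist once cross-linked — keep
    empty before m/z / drift columns but still take the (n, z) reference
    mass from the before table so the mass shift and bond count can be
    computed. A calibration model, when given, adds collisional
    cross-sections for both drift times.

    Returns one row per after-species: ``n, z, mz_before, mass_before,
    t_d_before, omega_before, mz_after, mass_after, t_d_after, omega_after,
    delta, k, residual, flag``.
    """
    before = _check_frame(assignments_before, "before")
    after = _check_frame(assignments_after, "after")
    for df_ in (before, after):
        if "convention" in df_.columns:
            df_["convention"] = df_["convention"].astype(str)
    if "convention" in before.columns and "convention" in after.columns:
        conv = set(before["convention"]) | set(after["convention"])
        if len(conv) > 1:
            raise ValueError(f"mass-convention mismatch between tables: {sorted(conv)}")

    rows = []
    for _, arow in after.iterrows():
        n, z = int(arow["n"]), int(arow["z"])
        cands = before[(before["n"] == n) & (before["z"] == z)]
        bmz = bmass = btd = np.nan
        if len(cands):
            # the (n, z) reference mass: mean over that species' before rows
            ref_mass = float(cands["mass"].mean())
            dt = (cands["t_d"] - arow["t_d"]).abs()
            if dt.min() <= drift_match:
                brow = cands.loc[dt.idxmin()]
                bmz, bmass, btd = float(brow["avg_mz"]), float(brow["mass"]), float(brow["t_d"])
        else:
            # charge state seen only after reaction (e.g. a 9+ dimer that
            # exists only cross-linked): the neutral reference mass is
            # z-independent, so take it from the same order's other charges
            same_n = before[before["n"] == n]
            ref_mass = float(same_n["mass"].mean()) if len(same_n) else np.nan
        if np.isfinite(ref_mass):
            inf = infer_bonds(ref_mass, float(arow["mass"]), tolerance)
            delta, k, resid, flag = inf.delta, inf.k, inf.residual, inf.flag
            bmass_ref = ref_mass
        else:
            delta = k = resid = np.nan
            flag = "no before-species"
            bmass_ref = np.nan
        row = {
            "n": n,
            "z": z,
            "mz_before": bmz,
            "mass_before": bmass if np.isfinite(bmass) else bmass_ref,
            "t_d_before": btd,
            "mz_after": float(arow["avg_mz"]),
            "mass_after": float(arow["mass"]),
            "t_d_after": float(arow["t_d"]),
            "delta": delta,
            "k": k,
            "residual": resid,
            "flag": flag,
        }
        if calibration is not None:
            row["omega_before"] = (
                calibration.omega(btd, z) if np.isfinite(btd) else np.nan
            )
            row["omega_after"] = calibration.omega(float(arow["t_d"]), z)
        rows.append(row)
    cols = [
        "n", "z", "mz_before", "mass_before", "t_d_before", "mz_after",
        "mass_after", "t_d_after", "delta", "k", "residual", "flag",
    ]
    if calibration is not None:
        cols[5:5] = ["omega_before"]
        cols[9:9] = ["omega_after"]
    out = pd.DataFrame(rows)
    return out[cols] if len(out) else pd.DataFrame(columns=cols)
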