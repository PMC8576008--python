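"""Hydrogen-bond strengths from electron densities and the sheet-stability
energy ledger.

Two independent quantum-chemistry-derived inputs are consumed as tables
(the package never runs electronic-structure calculations):

* **Bond-critical-point densities.**  The electron density rho at the
  O-H...O bond critical point maps linearly to a hydrogen-bond energy
  (kcal/mol)::

      E_HB = -223.08 * rho + 0.7423        (rho in atomic units)

  Energies are banded weak / medium / strong with configurable
  breakpoints (defaults -7.0 and -15.0 kcal/mol).

* **Sheet-model total energies.**  For a chain-sheet model split into an
  oligomer pair, the binding energy is dE_bind = E_total - E_i and the
  sheet stabilization energy dE_sheet = E_i + dE_bind, re-referenced so a
  designated reference sheet family is zero.  A counterpoise (BSSE)
  correction may be added to dE_bind.  Vacuum/water column pairs yield
  per-row solvent shifts, reported as -|vacuum - water| (stabilization on
  solvation), with magnitude extrema.

Reference CSVs with the published values for the six nanocrystal models
ship with the package (``load_reference_densities``,
``load_reference_sheet_energies``).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EQ_SLOPE",
    "EQ_INTERCEPT",
    "hb_energy_from_density",
    "classify_hb_strength",
    "binding_energy",
    "sheet_energies",
    "solvent_shift",
    "bind_family_sums",
    "density_report",
    "load_reference_densities",
    "load_reference_sheet_energies",
]

#: linear rho(BCP) -> energy map, kcal/mol per a.u.
EQ_SLOPE = -223.08
EQ_INTERCEPT = 0.7423

#: default strength-band breakpoints (kcal/mol): weak >= -7.0 > medium >= -15.0 > strong
STRENGTH_BREAKS = (-7.0, -15.0)


def hb_energy_from_density(rho):
    """Hydrogen-bond energy (kcal/mol) from the BCP electron density (a.u.).

    Affine map ``-223.08 * rho + 0.7423``; vectorized.  Negative densities
    are rejected.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("electron density must be non-negative")
    e = EQ_SLOPE * rho + EQ_INTERCEPT
    return float(e) if e.ndim == 0 else e


def classify_hb_strength(e_hb, breaks: tuple[float, float] = STRENGTH_BREAKS):
    """Band a hydrogen-bond energy as weak / medium / strong.

    ``breaks = (weak_floor, medium_floor)``: energies above ``weak_floor``
    are weak, between the two are medium, below ``medium_floor`` strong.
    """
    weak_floor, medium_floor = breaks
    if not weak_floor > medium_floor:
        raise ValueError("breakpoints must satisfy weak_floor > medium_floor")
    e = np.atleast_1d(np.asarray(e_hb, dtype=float))
    out = np.full(e.shape, "medium", dtype="<U6")
    out[e >= weak_floor] = "weak"
    out[e < medium_floor] = "strong"
    if np.ndim(e_hb) == 0:
        return str(out[0])
    return out


def density_report(densities: pd.DataFrame) -> pd.DataFrame:
    """Attach predicted energies and strength bands to a density table.

    Expects a ``rho`` column; adds ``e_hb_predicted`` and ``strength``,
    and, when a printed ``e_hb`` column is present, the residual
    ``e_hb_residual = e_hb_predicted - e_hb``.
    """
    out = densities.copy()
    out["e_hb_predicted"] = hb_energy_from_density(out["rho"].to_numpy())
    out["strength"] = classify_hb_strength(out["e_hb_predicted"].to_numpy())
    if "e_hb" in out.columns:
        out["e_hb_residual"] = out["e_hb_predicted"] - out["e_hb"]
    return out


# --------------------------------------------------------------------------
# Sheet / binding ledger
# --------------------------------------------------------------------------

def binding_energy(
    e_total: float,
    e_i: float,
    medium_total: str = "vacuum",
    medium_i: str = "vacuum",
    bsse: float | None = None,
) -> float:
    """dE_bind = E_total - E_i (optionally counterpoise-corrected).

    Both energies must come from the same medium (vacuum or water).
    """
    if medium_total != medium_i:
        raise ValueError(
            f"medium mismatch: E_total is {medium_total!r}, E_i is {medium_i!r}"
        )
    de = e_total - e_i
    if bsse is not None:
        de = de + bsse
    return de


def sheet_energies(
    ledger: pd.DataFrame,
    reference: tuple[str, str] | None = None,
    e_i_col: str = "e_i",
    de_bind_col: str = "de_bind",
) -> pd.Series:
    """dE_sheet = E_i + dE_bind per row, re-referenced to a zero row.

    ``reference`` is a (model, family) pair; by default the row with the
    smallest raw dE_sheet is the reference.  Adding a constant to every
    input energy leaves the re-referenced values unchanged.
    """
    raw = ledger[e_i_col] + ledger[de_bind_col]
    if reference is not None:
        mask = (ledger["model"] == reference[0]) & (ledger["family"] == reference[1])
        if not mask.any():
            raise KeyError(f"reference row {reference} missing from ledger")
        ref_value = float(raw[mask].iloc[0])
    else:
        ref_value = float(raw.min())
    return raw - ref_value


def solvent_shift(ledger: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Vacuum vs water differences for matched sheet-family rows.

    Expects matched columns ``de_sheet_vacuum``/``de_sheet_water`` and
    ``de_bind_vacuum``/``de_bind_water`` (or a long table with a
    ``medium`` column, which is pivoted first).  Shifts are reported as
    ``-|vacuum - water|``: both quantities move toward stability on
    solvation, and the sign convention makes that a negative "decrease".

    Returns (per-row table, extrema dict).  The magnitude extrema for
    dE_sheet exclude the reference row, which is zero in both media by
    construction.  Headline extrema are rounded to 1 decimal.
    """
    df = ledger.copy()
    if "medium" in df.columns:
        df = df.pivot_table(
            index=["model", "family"],
            columns="medium",
            values=["de_sheet", "de_bind"],
        )
        df.columns = [f"{a}_{b}" for a, b in df.columns]
        df = df.reset_index()
    needed = ["de_sheet_vacuum", "de_sheet_water", "de_bind_vacuum", "de_bind_water"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"unmatched vacuum/water rows; missing columns {missing}")
    if df[needed].isna().any().any():
        bad = df[df[needed].isna().any(axis=1)][["model", "family"]]
        raise ValueError(f"unmatched vacuum/water rows:\n{bad}")

    df["de_sheet_shift"] = -(df.de_sheet_vacuum - df.de_sheet_water).abs()
    df["de_bind_shift"] = -(df.de_bind_vacuum - df.de_bind_water).abs()

    is_reference = (df.de_sheet_vacuum == 0.0) & (df.de_sheet_water == 0.0)
    sheet = df.loc[~is_reference, "de_sheet_shift"]
    bind = df["de_bind_shift"]
    extrema = {
        "de_sheet_shift_min": round(float(sheet.max()), 1),  # smallest magnitude
        "de_sheet_shift_max": round(float(sheet.min()), 1),  # largest magnitude
        "de_bind_shift_min": round(float(bind.max()), 1),
        "de_bind_shift_max": round(float(bind.min()), 1),
    }
    return df, extrema


def bind_family_sums(ledger: pd.DataFrame, medium: str = "vacuum") -> pd.Series:
    """Signed sum of dE_bind over the sheet families of each model.

    Sums of negative binding energies are negative; the values are
    computed, never transcribed.
    """
    col = f"de_bind_{medium}"
    if col not in ledger.columns:
        raise KeyError(f"no column {col!r} in ledger")
    return ledger.groupby("model")[col].sum()


# --------------------------------------------------------------------------
# Bundled reference tables
# --------------------------------------------------------------------------

def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("cellufacet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_densities() -> pd.DataFrame:
    """Published BCP densities / HB geometries for the six models."""
    return _load_csv("reference_bcp_densities.csv")


def load_reference_sheet_energies() -> pd.DataFrame:
    """Published sheet-family energy ledger for 6A12 / 6B12 / 6O12."""
    return _load_csv("reference_sheet_energies.csv")
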