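"""Hydrogen-bond detection, typing and occupancy statistics.

Hydroxyl oxygens O2, O3 and O6 donate; O2, O3, O4, O5 and O6 accept (the
ring O5 and glycosidic O4 carry no hydrogen and only accept).  A contact
counts as a hydrogen bond when the donor-acceptor O...O distance is below
``max_oo_distance`` AND the D-H...A angle at the hydrogen exceeds
``min_dha_angle``.  Types are directed labels ``O{d}H..O{a}`` (so
O2H..O6 and O6H..O2 are distinct).

Per-trajectory statistics follow the sample-fraction formalism: with
x_j^i the count of type j in sample (frame) i and N_i = sum_j x_j^i,

* fraction        F_j^i  = x_j^i / N_i,
* maximum         F_max(j) = max_i F_j^i (ties -> smallest sample index),
* weighted mean   Fbar_j = sum_i F_j^i N_i / sum_i N_i, which reduces to
  the plain mean of F_j^i when all N_i are equal.

A persistence filter keeps only types whose mean (or any per-sample)
fraction strictly exceeds a threshold (default 0.60).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.spatial import cKDTree

from .crystal import NanocrystalModel

__all__ = [
    "HBondCriteria",
    "detect_hbonds",
    "detect_hbonds_trajectory",
    "sample_fractions",
    "max_fraction",
    "mean_fraction",
    "persistence_filter",
    "terminal_position_labels",
    "fraction_summary",
    "DONOR_OXYGENS",
    "ACCEPTOR_OXYGENS",
]

DONOR_OXYGENS = ("O2", "O3", "O6")
ACCEPTOR_OXYGENS = ("O2", "O3", "O4", "O5", "O6")
#: hydroxyl hydrogen attached to each donor oxygen
DONOR_HYDROGEN = {"O2": "HO2", "O3": "HO3", "O6": "HO6"}


class MissingHydrogenError(ValueError):
    """Donor hydroxyl hydrogens absent; re-run with distance-only fallback."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric detection criteria (standard MD practice defaults)."""

    max_oo_distance: float = 3.5     # angstrom
    min_dha_angle: float = 140.0     # degrees
    donors: tuple[str, ...] = DONOR_OXYGENS
    acceptors: tuple[str, ...] = ACCEPTOR_OXYGENS
    exclude_intra_residue: bool = True
    distance_only: bool = False      # fallback when hydrogens are absent

    def __post_init__(self):
        if self.max_oo_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("angle cutoff must be in (0, 180]")


def hb_type_label(donor_oxygen: str, acceptor_oxygen: str) -> str:
    return f"{donor_oxygen}H..{acceptor_oxygen}"


def _angle_deg(a, b, c):
    """Angle at b (degrees), vectorized over leading dimensions."""
    u = a - b
    v = c - b
    cu = np.linalg.norm(u, axis=-1)
    cv = np.linalg.norm(v, axis=-1)
    cosang = np.sum(u * v, axis=-1) / (cu * cv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    frame: struc.AtomArray,
    criteria: HBondCriteria | None = None,
    residue_scope: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All donor->acceptor hydrogen bonds in one frame.

    ``residue_scope``, if given, is a frame with ``chain_index``/``res_id``
    rows restricting which residues may participate (used for
    terminal+proximal scoping).  Pairs sharing the same oxygen atom are
    never counted; intra-residue pairs are excluded by default.

    Returns a table with donor/acceptor identifiers, geometry and the
    directed type label.
    """
    criteria = criteria or HBondCriteria()
    names = frame.atom_name
    coord = frame.coord

    in_scope = np.ones(frame.array_length(), dtype=bool)
    if residue_scope is not None:
        keys = set(zip(residue_scope.chain_index, residue_scope.res_id))
        in_scope = np.fromiter(
            ((c, r) in keys for c, r in zip(frame.chain_index, frame.res_id)),
            dtype=bool,
            count=frame.array_length(),
        )

    don_idx = np.flatnonzero(np.isin(names, criteria.donors) & in_scope)
    acc_idx = np.flatnonzero(np.isin(names, criteria.acceptors) & in_scope)
    if don_idx.size == 0 or acc_idx.size == 0:
        return _empty_records()

    # hydroxyl hydrogen for each donor oxygen: same residue, named HO{n}
    h_for_donor = np.full(don_idx.size, -1, dtype=int)
    if not criteria.distance_only:
        hyd = {
            (c, r, n): i
            for i, (c, r, n) in enumerate(
                zip(frame.chain_index, frame.res_id, names)
            )
            if n in DONOR_HYDROGEN.values()
        }
        for j, di in enumerate(don_idx):
            key = (
                frame.chain_index[di],
                frame.res_id[di],
                DONOR_HYDROGEN[names[di]],
            )
            if key in hyd:
                h_for_donor[j] = hyd[key]
        if np.any(h_for_donor < 0):
            raise MissingHydrogenError(
                "hydroxyl hydrogens missing for some donors; set "
                "HBondCriteria(distance_only=True) to detect on O...O "
                "distance alone"
            )

    tree = cKDTree(coord[acc_idx])
    neighbor_lists = tree.query_ball_point(coord[don_idx], r=criteria.max_oo_distance)

    rows = []
    for j, (di, neigh) in enumerate(zip(don_idx, neighbor_lists)):
        for aj in neigh:
            ai = acc_idx[aj]
            if ai == di:
                continue
            same_res = (
                frame.chain_index[di] == frame.chain_index[ai]
                and frame.res_id[di] == frame.res_id[ai]
            )
            if same_res and criteria.exclude_intra_residue:
                continue
            dist = float(np.linalg.norm(coord[ai] - coord[di]))
            if criteria.distance_only:
                angle = np.nan
            else:
                hi = h_for_donor[j]
                angle = float(_angle_deg(coord[di], coord[hi], coord[ai]))
                if angle < criteria.min_dha_angle:
                    continue
            rows.append(
                (
                    frame.chain_index[di], int(frame.res_id[di]), names[di],
                    frame.chain_index[ai], int(frame.res_id[ai]), names[ai],
                    hb_type_label(names[di], names[ai]), dist, angle,
                )
            )
    if not rows:
        return _empty_records()
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


_RECORD_COLUMNS = [
    "donor_chain", "donor_res", "donor_atom",
    "acceptor_chain", "acceptor_res", "acceptor_atom",
    "hb_type", "oo_distance", "dha_angle",
]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=_RECORD_COLUMNS)


def detect_hbonds_trajectory(
    trajectory: struc.AtomArrayStack,
    criteria: HBondCriteria | None = None,
    scope: str = "terminal",
    model: NanocrystalModel | None = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Hydrogen-bond records over trajectory frames (1 sample = 1 frame).

    ``scope``: ``"terminal"`` restricts participants to terminal+proximal
    residues of each chain's exposed-facet end (requires ``model`` or
    falls back to the first frame's geometry); ``"all"`` analyses the
    whole crystal.
    """
    residue_scope = None
    if scope == "terminal":
        source = model.atoms if model is not None else trajectory[0]
        labels = terminal_position_labels(model or _as_model(source))
        residue_scope = labels[labels.position.isin(["terminal", "proximal"])]
    elif scope != "all":
        raise ValueError("scope must be 'terminal' or 'all'")

    frames = range(0, trajectory.stack_depth(), stride)
    tables = []
    for fi in frames:
        rec = detect_hbonds(trajectory[fi], criteria, residue_scope)
        rec.insert(0, "sample", fi)
        tables.append(rec)
    if not tables:
        return pd.DataFrame(columns=["sample", *_RECORD_COLUMNS])
    return pd.concat(tables, ignore_index=True)


def _as_model(frame: struc.AtomArray) -> NanocrystalModel:
    from .conformers import _pseudo_model

    return _pseudo_model(frame)


# --------------------------------------------------------------------------
# Residue position labels
# --------------------------------------------------------------------------

def terminal_position_labels(model: NanocrystalModel) -> pd.DataFrame:
    """Label residues terminal / proximal / distal counted from the
    exposed-facet end of each chain: first residue = terminal, second =
    proximal, all remaining = distal."""
    atoms = model.atoms
    rows = []
    for ci in range(model.n_chains):
        sub = atoms[model.chain_mask(ci)]
        res_ids = np.unique(sub.res_id)
        mean_z = np.array([sub.coord[sub.res_id == r, 2].mean() for r in res_ids])
        order = res_ids[np.argsort(-mean_z)]  # facet (top) end first
        for rank, r in enumerate(order):
            position = "terminal" if rank == 0 else "proximal" if rank == 1 else "distal"
            rows.append((ci, int(r), position))
    return pd.DataFrame(rows, columns=["chain_index", "res_id", "position"])


# --------------------------------------------------------------------------
# Fraction statistics
# --------------------------------------------------------------------------

def sample_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample type fractions F_j^i = x_j^i / N_i.

    Input: record table with ``sample`` and ``hb_type`` columns.  Samples
    with zero bonds simply contribute no rows.  Returns a long table
    (sample, hb_type, count, n_sample, fraction).
    """
    if records.empty:
        return pd.DataFrame(columns=["sample", "hb_type", "count", "n_sample", "fraction"])
    counts = (
        records.groupby(["sample", "hb_type"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["n_sample"] = counts.groupby("sample")["count"].transform("sum")
    counts["fraction"] = counts["count"] / counts["n_sample"]
    return counts


def max_fraction(fractions: pd.DataFrame, hb_type: str) -> tuple[float, int]:
    """(F_max, argmax sample) for one type; ties break toward the
    smallest sample index.  Raises KeyError for a type never observed."""
    sub = fractions[fractions.hb_type == hb_type]
    if sub.empty:
        raise KeyError(f"hydrogen-bond type {hb_type!r} absent in all samples")
    sub = sub.sort_values("sample")
    # make the tie rule explicit against the sample ordering
    top = sub[np.isclose(sub.fraction, sub.fraction.max())]
    sample = int(top["sample"].min())
    value = float(top[top["sample"] == sample].fraction.iloc[0])
    return value, sample


def mean_fraction(fractions: pd.DataFrame) -> pd.Series:
    """N_i-weighted mean fraction per type.

    Exactly equals the unweighted mean of per-sample fractions when every
    sample has the same bond count.  Samples in which a type is absent
    contribute F = 0 with their weight N_i.  Raises on an all-empty table.
    """
    if fractions.empty:
        raise ValueError("mean fraction undefined: no samples with hydrogen bonds")
    n_by_sample = fractions.drop_duplicates("sample").set_index("sample")["n_sample"]
    total_n = float(n_by_sample.sum())
    # sum_i F_j^i N_i = sum_i x_j^i  (since F = x/N), so the weighted mean
    # is the total count of type j over the total count of bonds
    sums = fractions.groupby("hb_type")["count"].sum()
    return sums / total_n


def mean_fraction_unweighted(fractions: pd.DataFrame) -> pd.Series:
    """Plain mean of F_j^i over samples (absent types count as 0)."""
    if fractions.empty:
        raise ValueError("mean fraction undefined: no samples with hydrogen bonds")
    m = fractions["sample"].nunique()
    return fractions.groupby("hb_type")["fraction"].sum() / m


def persistence_filter(
    mean_fractions: pd.Series, threshold: float = 0.60
) -> list[str]:
    """Types whose mean fraction strictly exceeds ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    keep = mean_fractions[mean_fractions > threshold]
    return sorted(keep.index.tolist())


def fraction_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-type summary: mean fraction, F_max + argmax sample, mean
    geometry -- one row per observed type."""
    fractions = sample_fractions(records)
    if fractions.empty:
        return pd.DataFrame(
            columns=["hb_type", "mean_fraction", "f_max", "argmax_sample",
                     "mean_oo_distance", "mean_dha_angle", "n_records"]
        )
    fbar = mean_fraction(fractions)
    rows = []
    for hb_type in sorted(fbar.index):
        fmax, argmax = max_fraction(fractions, hb_type)
        sub = records[records.hb_type == hb_type]
        rows.append(
            (
                hb_type, float(fbar[hb_type]), fmax, argmax,
                float(sub.oo_distance.mean()), float(sub.dha_angle.mean()),
                int(len(sub)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["hb_type", "mean_fraction", "f_max", "argmax_sample",
                 "mean_oo_distance", "mean_dha_angle", "n_records"],
    )
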