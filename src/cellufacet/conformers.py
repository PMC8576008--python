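"""Hydroxymethyl rotamer analysis of glucan trajectories.

The exocyclic hydroxymethyl group of each anhydroglucose is described by
the dihedral omega = O5-C5-C6-O6 and classified into the three staggered
rotamers:

* ``gt`` (gauche-trans), omega near +60 deg;
* ``gg`` (gauche-gauche), omega near -60 deg;
* ``tg`` (trans-gauche), omega near 180 deg.

Binning is by fixed 120-degree windows: gt = [0, 120), gg = [-120, 0),
tg = the rest.  Populations that drift toward ~20 deg (as chain-end
groups do) therefore still count as gt.

Residues are stratified into reporting classes by chain position and
orientation: chain-end residues whose hydroxymethyl bearing (C5 -> O5)
points radially outward from the bundle cross-section are ``omega1``,
chain-end residues pointing inward are ``omega2``, and all internal
residues are ``omega3``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import biotite.structure as struc

from .crystal import NanocrystalModel

__all__ = [
    "torsion_angle",
    "classify_conformer",
    "assign_omega_class",
    "torsion_table",
    "conformer_profile",
    "CONFORMERS",
    "OMEGA_ATOMS",
]

CONFORMERS = ("gt", "gg", "tg")
OMEGA_ATOMS = ("O5", "C5", "C6", "O6")


class DegenerateGeometryError(ValueError):
    """Torsion undefined: coincident or collinear defining points."""


def torsion_angle(p1, p2, p3, p4) -> np.ndarray | float:
    """Signed dihedral angle in degrees, range (-180, 180].

    Sign follows the right-hand rule about the p2->p3 axis (IUPAC
    convention: looking from p2 to p3, a clockwise rotation of p4
    relative to p1 is positive).  Accepts arrays with any number of
    leading batch dimensions.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.any(np.linalg.norm(b, axis=-1) < 1e-10):
            raise DegenerateGeometryError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-10) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-10
    ):
        raise DegenerateGeometryError("three consecutive points are collinear")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n2, b2u) * n1, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return float(ang) if ang.ndim == 0 else ang


def wrap_angle(omega):
    """Wrap any angle in degrees into (-180, 180]."""
    w = np.mod(np.asarray(omega, dtype=float) + 180.0, 360.0) - 180.0
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    return float(w) if w.ndim == 0 else w


def classify_conformer(omega):
    """Rotamer label for an omega angle (degrees, wrapped internally).

    gt for [0, 120), gg for [-120, 0), tg otherwise.  Vectorized.
    """
    w = np.atleast_1d(wrap_angle(omega))
    out = np.full(w.shape, "tg", dtype="<U2")
    out[(w >= 0.0) & (w < 120.0)] = "gt"
    out[(w >= -120.0) & (w < 0.0)] = "gg"
    if np.isscalar(omega) or np.ndim(omega) == 0:
        return str(out[0])
    return out


# --------------------------------------------------------------------------
# Residue classes
# --------------------------------------------------------------------------

def assign_omega_class(model: NanocrystalModel) -> pd.DataFrame:
    """Per-residue omega class from the reference model geometry.

    Chain-end residues are classed by the sign of the projection of the
    C5 -> O5 vector onto the outward radial direction (bundle centroid to
    the residue's C5, in the a-b plane): positive = outward = omega1,
    otherwise omega2.  Internal residues are omega3.  Both chain ends are
    classified; the ``end`` column records which (``top``/``bottom``,
    empty for internal residues; a single-residue chain is flagged
    ``both`` and classed by orientation).
    """
    atoms = model.atoms
    centroid = model.cross_section_centroid()
    rows = []
    for ci in range(model.n_chains):
        mask = model.chain_mask(ci)
        sub = atoms[mask]
        res_ids = np.unique(sub.res_id)
        z_by_res = {r: sub.coord[sub.res_id == r, 2].mean() for r in res_ids}
        top = max(z_by_res, key=z_by_res.get)
        bottom = min(z_by_res, key=z_by_res.get)
        for r in res_ids:
            c5 = sub.coord[(sub.res_id == r) & (sub.atom_name == "C5")][0]
            o5 = sub.coord[(sub.res_id == r) & (sub.atom_name == "O5")][0]
            if r == top and r == bottom:
                end = "both"
            elif r == top:
                end = "top"
            elif r == bottom:
                end = "bottom"
            else:
                end = ""
            if end:
                radial = c5[:2] - centroid
                nrm = np.linalg.norm(radial)
                if nrm < 1e-9:  # on-axis residue: orientation ill-defined
                    cls = "omega2"
                else:
                    outward = float((o5[:2] - c5[:2]) @ (radial / nrm))
                    cls = "omega1" if outward > 0 else "omega2"
            else:
                cls = "omega3"
            rows.append((ci, int(r), cls, end))
    return pd.DataFrame(rows, columns=["chain_index", "res_id", "omega_class", "end"])


# --------------------------------------------------------------------------
# Trajectory analysis
# --------------------------------------------------------------------------

def _omega_indices(atoms: struc.AtomArray) -> tuple[np.ndarray, pd.DataFrame]:
    """Atom index quadruples (n_res, 4) for O5,C5,C6,O6 of every residue."""
    keys = pd.DataFrame(
        {
            "chain_index": atoms.chain_index,
            "res_id": atoms.res_id,
            "atom_name": atoms.atom_name,
            "idx": np.arange(atoms.array_length()),
        }
    )
    sel = keys[keys.atom_name.isin(OMEGA_ATOMS)]
    pivot = sel.pivot_table(
        index=["chain_index", "res_id"], columns="atom_name", values="idx"
    )
    pivot = pivot.dropna()[list(OMEGA_ATOMS)].astype(int)
    quads = pivot.to_numpy()
    residues = pivot.index.to_frame(index=False)
    return quads, residues


def torsion_table(
    trajectory: struc.AtomArrayStack | struc.AtomArray,
    model: NanocrystalModel | None = None,
) -> pd.DataFrame:
    """Omega angle, conformer and omega class for every residue and frame.

    ``trajectory`` must carry ``chain_index``/``res_id`` annotations and
    canonical atom names.  The omega classes are taken from ``model`` if
    given, else from the first frame's geometry.
    """
    if isinstance(trajectory, struc.AtomArray):
        trajectory = struc.stack([trajectory])
    quads, residues = _omega_indices(trajectory)
    coord = trajectory.coord  # (n_frames, n_atoms, 3)
    p = coord[:, quads, :]  # (n_frames, n_res, 4, 3)
    omega = torsion_angle(p[..., 0, :], p[..., 1, :], p[..., 2, :], p[..., 3, :])
    n_frames, n_res = omega.shape

    if model is not None:
        classes = assign_omega_class(model)
    else:
        first = trajectory[0] if trajectory.stack_depth() else trajectory
        pseudo = _pseudo_model(first)
        classes = assign_omega_class(pseudo)
    merged = residues.merge(classes, on=["chain_index", "res_id"], how="left")

    table = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n_res),
            "chain_index": np.tile(merged.chain_index.to_numpy(), n_frames),
            "res_id": np.tile(merged.res_id.to_numpy(), n_frames),
            "omega": omega.ravel(),
            "omega_class": np.tile(merged.omega_class.to_numpy(), n_frames),
            "end": np.tile(merged.end.fillna("").to_numpy(), n_frames),
        }
    )
    table["conformer"] = classify_conformer(table.omega.to_numpy())
    return table


def _pseudo_model(frame: struc.AtomArray) -> NanocrystalModel:
    """Wrap a bare annotated frame so class assignment can run on it."""
    from .crystal import ChainSpec, FacetSpec, UnitCell

    n = len(np.unique(frame.chain_index))
    dummy = [ChainSpec("origin", 0, 0, int(frame.res_id.max()))] * n
    return NanocrystalModel(
        name="frame", cell=UnitCell(), facet=FacetSpec((0, 0, 1)),
        chains=dummy, atoms=frame,
    )


def conformer_profile(
    trajectory: struc.AtomArrayStack,
    model: NanocrystalModel | None = None,
    equilibration_cut: float | int = 0.5,
    histogram_bin_width: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conformer fractions per omega class over the equilibrated tail.

    ``equilibration_cut`` is either a fraction of frames to discard from
    the start (float < 1) or an absolute first-frame index (int).  Returns
    ``(profile, histogram)``: fractions per (omega_class, conformer)
    stratum summing to 1 within each stratum (strata with no residues are
    absent, not zero), and the raw omega histogram per class in
    ``histogram_bin_width``-degree bins.
    """
    n_frames = trajectory.stack_depth()
    if isinstance(equilibration_cut, float) and equilibration_cut < 1.0:
        cut = int(np.floor(n_frames * equilibration_cut))
    else:
        cut = int(equilibration_cut)
    if cut >= n_frames:
        raise ValueError(f"equilibration cut {cut} >= frame count {n_frames}")

    table = torsion_table(trajectory, model)
    tail = table[table.frame >= cut]

    counts = (
        tail.groupby(["omega_class", "conformer"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("omega_class")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    counts["n_frames"] = n_frames - cut
    counts["n_residues"] = tail.groupby("omega_class").res_id.count().reindex(
        counts.omega_class
    ).to_numpy() // max(n_frames - cut, 1)

    edges = np.arange(-180.0, 180.0 + histogram_bin_width, histogram_bin_width)
    hist_rows = []
    for cls, group in tail.groupby("omega_class"):
        h, _ = np.histogram(group.omega, bins=edges)
        hist_rows.append(
            pd.DataFrame(
                {
                    "omega_class": cls,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "count": h,
                }
            )
        )
    histogram = pd.concat(hist_rows, ignore_index=True) if hist_rows else pd.DataFrame(
        columns=["omega_class", "bin_left", "bin_right", "count"]
    )
    return counts, histogram
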