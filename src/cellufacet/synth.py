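"""Synthetic trajectories and energy tables with planted ground truth.

The generator emulates the *statistical* structure of an equilibrated
solvated-nanocrystal trajectory -- not its physics.  Per frame it

1. applies isotropic Gaussian jitter (sigma ``jitter_sigma``) to every
   atom,
2. rotates each residue's hydroxymethyl arm (O6, H61, H62, HO6 about the
   C5-C6 axis) to an omega angle drawn from a planted gt/gg/tg mixture
   (Gaussian around +60 / -60 / 180 deg, width ``sigma_omega``), and
3. realizes a roster of planted donor-acceptor contacts by placing each
   acceptor oxygen at the requested O...O distance and D-H...A angle
   (with small geometry noise) with the requested per-frame occupancy;
   when a contact is "off" the acceptor is parked well outside the
   detection cutoff.

Everything is driven by one integer seed fanned out to per-frame
substreams, so trajectories are bit-reproducible and frame order is
parallel-safe.  What a green recovery test establishes: the analysis
stack measures planted torsion mixtures and contact occupancies without
bias.  What it does not establish: anything about force-field physics,
water, or thermodynamically meaningful ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .crystal import NanocrystalModel
from .conformers import OMEGA_ATOMS, torsion_angle, wrap_angle
from .energetics import hb_energy_from_density

__all__ = [
    "PlantedContact",
    "SyntheticTrajectoryConfig",
    "generate_trajectory",
    "generate_energy_tables",
    "CONFORMER_CENTERS",
]

#: canonical omega centers of the three rotamers (degrees)
CONFORMER_CENTERS = {"gt": 60.0, "gg": -60.0, "tg": 180.0}

#: atoms rotated rigidly about the C5-C6 axis when setting omega
_ROTAMER_ARM = ("O6", "H61", "H62", "HO6")


@dataclass(frozen=True)
class PlantedContact:
    """One donor->acceptor contact to realize in the trajectory."""

    donor_chain: int
    donor_res: int
    donor_atom: str            # O2 | O3 | O6
    acceptor_chain: int
    acceptor_res: int
    acceptor_atom: str         # O2 | O3 | O4 | O5 | O6
    distance: float = 2.75     # target O...O, angstrom
    angle: float = 161.0       # target D-H...A, degrees
    occupancy: float = 1.0     # per-frame probability

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class SyntheticTrajectoryConfig:
    """Stated world of one synthetic trajectory."""

    n_frames: int = 500
    seed: int = 0
    jitter_sigma: float = 0.05           # angstrom, every atom
    sigma_omega: float = 15.0            # degrees around the rotamer center
    #: gt/gg/tg probabilities per omega class; "default" applies to
    #: classes without their own entry
    mixtures: dict = field(
        default_factory=lambda: {"default": (0.6, 0.3, 0.1)}
    )
    contacts: list = field(default_factory=list)
    contact_distance_sigma: float = 0.03  # angstrom
    contact_angle_sigma: float = 2.0      # degrees
    off_distance: float = 4.5             # parking distance for absent contacts

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0 or self.sigma_omega < 0:
            raise ValueError("noise widths must be non-negative")
        for key, mix in self.mixtures.items():
            m = np.asarray(mix, dtype=float)
            if m.shape != (3,) or np.any(m < 0) or not np.isclose(m.sum(), 1.0):
                raise ValueError(
                    f"mixture for {key!r} must be 3 non-negative probabilities summing to 1"
                )

    def mixture_for(self, omega_class: str) -> np.ndarray:
        mix = self.mixtures.get(omega_class, self.mixtures.get("default"))
        if mix is None:
            raise KeyError(f"no mixture for omega class {omega_class!r}")
        return np.asarray(mix, dtype=float)


def _frame_rng(seed: int, frame: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(frame)]))


def _rotation_matrices(axes: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices, (n, 3, 3), for unit ``axes``."""
    x, y, z = axes[:, 0], axes[:, 1], axes[:, 2]
    zero = np.zeros_like(x)
    K = np.stack(
        [
            np.stack([zero, -z, y], axis=-1),
            np.stack([z, zero, -x], axis=-1),
            np.stack([-y, x, zero], axis=-1),
        ],
        axis=-2,
    )
    eye = np.eye(3)[None]
    s = np.sin(angles_rad)[:, None, None]
    c = np.cos(angles_rad)[:, None, None]
    return eye + s * K + (1.0 - c) * (K @ K)


class _ResidueIndex:
    """Pre-gathered atom indices for fast per-frame edits."""

    def __init__(self, atoms: struc.AtomArray):
        keys = pd.DataFrame(
            {
                "chain_index": atoms.chain_index,
                "res_id": atoms.res_id,
                "atom_name": atoms.atom_name,
                "idx": np.arange(atoms.array_length()),
            }
        )
        need = set(OMEGA_ATOMS) | set(_ROTAMER_ARM)
        sel = keys[keys.atom_name.isin(need)]
        pivot = sel.pivot_table(
            index=["chain_index", "res_id"], columns="atom_name", values="idx"
        ).dropna().astype(int)
        self.residues = pivot.index.to_frame(index=False)
        self.quads = pivot[list(OMEGA_ATOMS)].to_numpy()
        self.arm = pivot[list(_ROTAMER_ARM)].to_numpy()
        self.c5 = pivot["C5"].to_numpy()
        self.c6 = pivot["C6"].to_numpy()
        self.lookup = {
            (c, r): i
            for i, (c, r) in enumerate(
                zip(self.residues.chain_index, self.residues.res_id)
            )
        }
        self.atom_lookup = {
            (c, r, n): i
            for c, r, n, i in zip(keys.chain_index, keys.res_id, keys.atom_name, keys.idx)
        }


def _set_omegas(coord: np.ndarray, index: _ResidueIndex, targets: np.ndarray) -> None:
    """Rotate every hydroxymethyl arm in-place to the target omegas."""
    p = coord[index.quads]  # (n_res, 4, 3)
    current = torsion_angle(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
    delta = np.deg2rad(wrap_angle(targets - current))
    axes = coord[index.c6] - coord[index.c5]
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    R = _rotation_matrices(axes, delta)
    pivots = coord[index.c6][:, None, :]
    arm = coord[index.arm]  # (n_res, 4, 3)
    coord[index.arm] = np.einsum("nij,nkj->nki", R, arm - pivots) + pivots


def _place_acceptor(
    donor_o: np.ndarray,
    donor_h: np.ndarray,
    distance: float,
    angle_deg: float,
) -> np.ndarray:
    """Acceptor-oxygen position with given O...O distance and D-H...A angle.

    The acceptor lies in the plane spanned by the O-H bond and a fixed
    perpendicular, at the unique radius from H that satisfies both
    constraints.
    """
    oh = donor_h - donor_o
    b = np.linalg.norm(oh)
    u = oh / b
    # deterministic unit vector perpendicular to the O-H bond
    r = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    w = r - (r @ u) * u
    w /= np.linalg.norm(w)
    theta = np.deg2rad(angle_deg)
    # direction of H->A at `angle` from H->D (= -u)
    d_ha = -np.cos(theta) * u + np.sin(theta) * w
    # |H + rho*d_ha - O| = distance  ->  rho^2 + 2 rho (b u . d_ha) + b^2 - dist^2 = 0
    p = b * (u @ d_ha)
    disc = p * p - (b * b - distance * distance)
    rho = -p + np.sqrt(disc)
    return donor_h + rho * d_ha


def generate_trajectory(
    model: NanocrystalModel,
    config: SyntheticTrajectoryConfig,
    omega_classes: pd.DataFrame | None = None,
) -> tuple[struc.AtomArrayStack, dict]:
    """Synthesize a trajectory for ``model``; returns (stack, truth).

    ``truth`` records the planted parameters and the realized per-frame
    draws (conformer counts per omega class; contact on/off realization),
    for recovery testing.
    """
    from .conformers import assign_omega_class

    atoms = model.atoms
    index = _ResidueIndex(atoms)
    n_res = len(index.quads)
    if omega_classes is None:
        omega_classes = assign_omega_class(model)
    merged = index.residues.merge(omega_classes, on=["chain_index", "res_id"], how="left")
    classes = merged.omega_class.fillna("omega3").to_numpy()
    mix_by_res = np.stack([config.mixture_for(c) for c in classes])
    centers = np.array([CONFORMER_CENTERS[c] for c in ("gt", "gg", "tg")])

    for contact in config.contacts:
        for which, (c, r, a) in (
            ("donor", (contact.donor_chain, contact.donor_res, contact.donor_atom)),
            ("acceptor", (contact.acceptor_chain, contact.acceptor_res, contact.acceptor_atom)),
        ):
            if (c, r, a) not in index.atom_lookup:
                raise KeyError(f"planted {which} atom {(c, r, a)} absent from model")

    n_frames = config.n_frames
    base = atoms.coord.astype(float)
    frames = np.empty((n_frames, atoms.array_length(), 3), dtype=np.float32)
    conformer_draws = np.empty((n_frames, n_res), dtype=np.int8)
    contact_on = np.zeros((n_frames, len(config.contacts)), dtype=bool)

    for f in range(n_frames):
        rng = _frame_rng(config.seed, f)
        coord = base.copy()
        if config.jitter_sigma > 0:
            coord += rng.normal(0.0, config.jitter_sigma, coord.shape)

        u = rng.random(n_res)
        cum = np.cumsum(mix_by_res, axis=1)
        draws = (u[:, None] > cum).sum(axis=1).astype(np.int8)
        targets = centers[draws]
        if config.sigma_omega > 0:
            targets = targets + rng.normal(0.0, config.sigma_omega, n_res)
        _set_omegas(coord, index, targets)
        conformer_draws[f] = draws

        for ci, contact in enumerate(config.contacts):
            d_o = index.atom_lookup[
                (contact.donor_chain, contact.donor_res, contact.donor_atom)
            ]
            d_h = index.atom_lookup[
                (contact.donor_chain, contact.donor_res, "H" + contact.donor_atom)
            ]
            a_o = index.atom_lookup[
                (contact.acceptor_chain, contact.acceptor_res, contact.acceptor_atom)
            ]
            on = rng.random() < contact.occupancy
            contact_on[f, ci] = on
            dist = contact.distance if on else config.off_distance
            ang = contact.angle
            if on and config.contact_distance_sigma > 0:
                dist += rng.normal(0.0, config.contact_distance_sigma)
            if on and config.contact_angle_sigma > 0:
                ang += rng.normal(0.0, config.contact_angle_sigma)
            coord[a_o] = _place_acceptor(coord[d_o], coord[d_h], dist, ang)

        frames[f] = coord

    stack = struc.AtomArrayStack(n_frames, atoms.array_length())
    for category in atoms.get_annotation_categories():
        stack.set_annotation(category, atoms.get_annotation(category))
    stack.coord = frames

    counts = {}
    for cls in np.unique(classes):
        sel = conformer_draws[:, classes == cls]
        counts[str(cls)] = {
            name: int((sel == k).sum()) for k, name in enumerate(("gt", "gg", "tg"))
        }
    truth = {
        "seed": config.seed,
        "n_frames": n_frames,
        "mixtures": {k: list(map(float, v)) for k, v in config.mixtures.items()},
        "conformer_counts": counts,
        "contacts": [
            {
                "donor": [c.donor_chain, c.donor_res, c.donor_atom],
                "acceptor": [c.acceptor_chain, c.acceptor_res, c.acceptor_atom],
                "distance": c.distance,
                "angle": c.angle,
                "occupancy": c.occupancy,
                "realized_occupancy": float(contact_on[:, i].mean()),
            }
            for i, c in enumerate(config.contacts)
        ],
    }
    return stack, truth


# --------------------------------------------------------------------------
# Synthetic energy tables
# --------------------------------------------------------------------------

def generate_energy_tables(
    n_rows: int,
    rho_range: tuple[float, float] = (0.018, 0.043),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random density and energy-ledger tables that satisfy the model
    identities by construction (round-trip test fixtures).

    Densities carry exact linear-map energies; the ledger satisfies
    dE_bind = E_total - E_i and dE_sheet = E_i + dE_bind row by row.
    """
    lo, hi = rho_range
    if not 0.0 < lo <= hi <= 0.06:
        raise ValueError("rho range must lie within (0, 0.06] a.u.")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    types = ["O2H..O6", "O6H..O6", "O6H..O2", "O3H..O5", "O2H..O2", "O6H..O3"]
    rho = rng.uniform(lo, hi, n_rows)
    densities = pd.DataFrame(
        {
            "model": ["synthetic"] * n_rows,
            "hb_type": [types[i % len(types)] for i in range(n_rows)],
            "f_max": rng.uniform(0.6, 1.0, n_rows),
            "oo_distance": rng.uniform(2.70, 2.80, n_rows),
            "dha_angle": rng.uniform(158.0, 165.0, n_rows),
            "rho": rho,
            "e_hb": hb_energy_from_density(rho) if n_rows else np.array([]),
        }
    )
    e_i = rng.uniform(-10.0, 0.0, n_rows)
    de_bind = rng.uniform(-8.0, -1.0, n_rows)
    ledger = pd.DataFrame(
        {
            "model": ["synthetic"] * n_rows,
            "family": [f"sheet-{i}" for i in range(n_rows)],
            "medium": ["vacuum"] * n_rows,
            "e_total": e_i + de_bind,
            "e_i": e_i,
            "bsse": rng.uniform(0.5, 1.5, n_rows),
            "de_bind": de_bind,
            "de_sheet": e_i + de_bind,
        }
    )
    return densities, ledger
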