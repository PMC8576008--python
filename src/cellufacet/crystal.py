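"""Atomistic cellulose II nanocrystal models with chosen exposed facets.

Cellulose II packs antiparallel glucan chains on a monoclinic lattice
(fiber axis *c*).  A nanocrystal model here is an ``i x i`` bundle of
chains, each a beta-1,4 glucan of a given degree of polymerization (DP),
whose chain ends tile a requested Miller-plane facet:

* ``O`` = (0 0 1): the flat facet, all chain ends level;
* ``A`` = (-1 1 2): a gently inclined facet;
* ``B`` = (-2 2 1): a steeply inclined facet.

Inclined facets are realized by staggering whole residues along the chain
axis so that one designated anchor atom per chain end lies (to within the
c/2 residue rise) on the plane ``h*x + k*y + l*z = m`` in fractional
coordinates.  Models are named ``iLj`` (e.g. ``6A12``): ``i x i`` chains,
facet ``L``, DP ``j``.

The provenance of a model (cell, facet, chain lattice positions and
polarities, staggers) travels with the coordinates so downstream analyses
can stratify residues by chain end and radial position.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc

__all__ = [
    "UnitCell",
    "GlucoseTemplate",
    "ChainSpec",
    "FacetSpec",
    "NanocrystalModel",
    "CoplanarityReport",
    "build_chain",
    "compute_stagger",
    "choose_plane_offset",
    "assemble_nanocrystal",
    "facet_coplanarity_check",
    "FACET_MILLER",
]


class BuildError(ValueError):
    """Raised when a nanocrystal cannot be assembled as specified."""


# --------------------------------------------------------------------------
# Lattice
# --------------------------------------------------------------------------

#: Facet labels and their fixed Miller indices.
FACET_MILLER = {"A": (-1, 1, 2), "B": (-2, 2, 1), "O": (0, 0, 1)}

#: Default glycosidic C1-O4' bond length (angstrom).
GLYCOSIDIC_BOND = 1.43

#: Default axial offset of center chains relative to origin chains,
#: as a fraction of c (conventional cellulose II packing).
CENTER_OFFSET_FRAC = 0.216

#: In-plane orientation of the residue ring relative to the a axis
#: (degrees).  A free packing convention; the default keeps neighbouring
#: chains' hydroxyl arms clear of each other at the half-cell chain
#: spacing.
RING_ORIENTATION_DEG = 5.0


@dataclass(frozen=True)
class UnitCell:
    """Monoclinic cellulose II cell; *c* is the chain (fiber) axis.

    Defaults are the conventional cellulose II cell.  ``residues_per_c``
    is fixed at 2: one cellobiose (two anhydroglucose residues related by
    the 2-fold screw) per c repeat.
    """

    a: float = 8.10
    b: float = 9.03
    c: float = 10.31
    gamma: float = 117.1
    residues_per_c: int = 2

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not 0.0 < self.gamma < 180.0:
            raise ValueError("gamma must be in (0, 180) degrees")
        if self.residues_per_c != 2:
            raise ValueError("cellulose chains have 2 residues per c repeat")

    @property
    def residue_rise(self) -> float:
        """Axial rise per residue, c/2 (angstrom)."""
        return self.c / self.residues_per_c

    def lattice_vectors(self) -> np.ndarray:
        """Row matrix [a_vec; b_vec; c_vec]; c along +z, a along +x."""
        g = np.deg2rad(self.gamma)
        return np.array(
            [
                [self.a, 0.0, 0.0],
                [self.b * np.cos(g), self.b * np.sin(g), 0.0],
                [0.0, 0.0, self.c],
            ]
        )

    def reciprocal_vectors(self) -> np.ndarray:
        """Row matrix of reciprocal vectors (no 2*pi factor)."""
        return np.linalg.inv(self.lattice_vectors()).T

    def miller_normal(self, miller: tuple[int, int, int]) -> np.ndarray:
        """Unit normal of the (h k l) plane family in Cartesian space."""
        n = np.asarray(miller, dtype=float) @ self.reciprocal_vectors()
        return n / np.linalg.norm(n)


# --------------------------------------------------------------------------
# Glucose template
# --------------------------------------------------------------------------

def _nerf_place(a, b, c, length, angle_deg, torsion_deg):
    """Place atom D given chain A-B-C, |C-D|, angle(B,C,D), torsion(A,B,C,D)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            length * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _tetrahedral_pair(p, n1, n2):
    """The two exocyclic bond directions at ring atom ``p`` with ring
    neighbours ``n1``, ``n2`` (ideal tetrahedral completion).

    Returns (equatorial, axial) unit vectors, distinguished by |z|.
    """
    u1 = (n1 - p) / np.linalg.norm(n1 - p)
    u2 = (n2 - p) / np.linalg.norm(n2 - p)
    w = np.cross(u1, u2)
    w /= np.linalg.norm(w)
    base = -(u1 + u2) / 2.0
    e1 = base + np.sqrt(2.0 / 3.0) * w
    e2 = base - np.sqrt(2.0 / 3.0) * w
    e1 /= np.linalg.norm(e1)
    e2 /= np.linalg.norm(e2)
    # axial direction is the more nearly vertical one in the template frame
    if abs(e1[2]) > abs(e2[2]):
        return e2, e1
    return e1, e2


@dataclass(frozen=True)
class GlucoseTemplate:
    """One anhydroglucose residue in a local frame.

    ``names`` and ``coord`` are parallel; elements derive from the first
    letter of each (stripped) atom name.  ``C1`` is the linkage head and
    ``O4`` the linkage tail: in an assembled chain the C1 of residue *n*
    bonds the O4 of residue *n+1*.
    """

    names: tuple[str, ...]
    coord: np.ndarray  # (n_atoms, 3)

    REQUIRED = ("C1", "C2", "C3", "C4", "C5", "O5", "O2", "O3", "O4", "O6",
                "HO2", "HO3", "HO6")

    def __post_init__(self):
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        missing = [n for n in self.REQUIRED if n not in self.names]
        if missing:
            raise ValueError(f"template missing atoms: {missing}")
        counts = {n: self.names.count(n) for n in ("C1", "C2", "C3", "C4", "C5", "O5")}
        if any(v != 1 for v in counts.values()):
            raise ValueError("template must contain exactly one of each ring atom")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def position(self, name: str) -> np.ndarray:
        return self.coord[self.index(name)]

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(n.strip("0123456789")[0] for n in self.names)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "GlucoseTemplate":
        return replace(self, coord=self.coord @ rotation.T + translation)

    # -- construction ------------------------------------------------------

    @classmethod
    def ideal(cls, omega: float = 60.0) -> "GlucoseTemplate":
        """Idealized 4C1 beta-D-glucopyranose.

        Ring atoms sit on an ideal chair (C-C 1.52 A, puckering +-0.25 A);
        hydroxyls are equatorial, ring hydrogens axial.  The hydroxymethyl
        O5-C5-C6-O6 torsion is set to ``omega`` (default gt, +60 deg).
        """
        bond = 1.52
        pucker = 0.25
        radius = np.sqrt(bond**2 - (2 * pucker) ** 2)
        ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]
        pos = {}
        for k, name in enumerate(ring_names):
            ang = np.deg2rad(60.0 * k)
            z = pucker if k % 2 == 0 else -pucker
            pos[name] = np.array([radius * np.cos(ang), radius * np.sin(ang), z])

        def neighbors(k):
            return ring_names[(k - 1) % 6], ring_names[(k + 1) % 6]

        def exo(k):
            a, b = neighbors(k)
            return _tetrahedral_pair(pos[ring_names[k]], pos[a], pos[b])

        # equatorial substituents, axial H on each ring carbon
        ch_bond, co_bond, oh_bond = 1.10, 1.43, 0.96
        for k, (sub, dist) in enumerate(
            [(None, None), ("O2", co_bond), ("O3", co_bond),
             ("O4", co_bond), ("C6", bond)]
        ):
            eq, ax = exo(k)
            carbon = ring_names[k]
            pos[f"H{k + 1}"] = pos[carbon] + ch_bond * ax
            if sub is not None:
                pos[sub] = pos[carbon] + dist * eq

        # hydroxyl hydrogens: bent off the C-O axis to ~109 deg C-O-H
        for o_name, c_name in [("O2", "C2"), ("O3", "C3")]:
            u = pos[o_name] - pos[c_name]
            u /= np.linalg.norm(u)
            d = u + 0.6 * np.array([0.0, 0.0, 1.0])
            d /= np.linalg.norm(d)
            pos[f"HO{o_name[1]}"] = pos[o_name] + oh_bond * d

        # hydroxymethyl arm: O6 placed by the omega torsion about C5-C6
        pos["O6"] = _nerf_place(pos["O5"], pos["C5"], pos["C6"],
                                co_bond, 109.5, omega)
        pos["H61"] = _nerf_place(pos["O5"], pos["C5"], pos["C6"],
                                 ch_bond, 109.5, omega - 120.0)
        pos["H62"] = _nerf_place(pos["O5"], pos["C5"], pos["C6"],
                                 ch_bond, 109.5, omega + 120.0)
        pos["HO6"] = _nerf_place(pos["C5"], pos["C6"], pos["O6"],
                                 oh_bond, 108.0, 180.0)

        names = tuple(
            ["C1", "C2", "C3", "C4", "C5", "C6", "O2", "O3", "O4", "O5", "O6",
             "H1", "H2", "H3", "H4", "H5", "H61", "H62", "HO2", "HO3", "HO6"]
        )
        coord = np.array([pos[n] for n in names])
        return cls(names=names, coord=coord)


def _oriented_template(cell: UnitCell, template: GlucoseTemplate) -> GlucoseTemplate:
    """Rigidly place the template so the 2-fold screw along c closes the
    glycosidic link.

    With the screw S(x) = Rz(pi) x + (0, 0, c/2), the placement solves
    |S(O4) - C1| = GLYCOSIDIC_BOND exactly by (i) rotating the C1->O4
    virtual bond so its z-component is -(c/2 - bond), with the mean ring
    plane kept parallel to the chain axis, and (ii) centering the C1/O4
    midpoint on the screw axis.
    """
    h = cell.residue_rise
    v = template.position("O4") - template.position("C1")
    L = np.linalg.norm(v)
    dz = h - GLYCOSIDIC_BOND
    if L <= dz:
        raise BuildError(
            f"template C1-O4 span {L:.2f} A too short for residue rise {h:.2f} A"
        )
    # source frame: virtual bond + ring normal
    f1 = v / L
    ring_idx = [template.index(n) for n in ("C1", "C2", "C3", "C4", "C5", "O5")]
    ring = template.coord[ring_idx]
    ring_c = ring - ring.mean(axis=0)
    # smallest principal axis of the ring = ring normal
    _, _, vt = np.linalg.svd(ring_c)
    n_ring = vt[2]
    f3 = n_ring - (n_ring @ f1) * f1
    f3 /= np.linalg.norm(f3)
    f2 = np.cross(f3, f1)
    F = np.column_stack([f1, f2, f3])
    # target frame: bond tilted to reach the next screw image, ring
    # normal along +y so the ring plane contains the chain axis
    cos_a = dz / L
    sin_a = np.sqrt(1.0 - cos_a**2)
    g1 = np.array([sin_a, 0.0, -cos_a])
    g3 = np.array([0.0, 1.0, 0.0])
    g2 = np.cross(g3, g1)
    G = np.column_stack([g1, g2, g3])
    R = G @ F.T
    placed = template.coord @ R.T
    mid = 0.5 * (placed[template.index("C1")] + placed[template.index("O4")])
    placed = placed - mid
    # in-plane ring orientation: a rotation about the screw axis commutes
    # with the screw, so glycosidic closure is preserved
    th = np.deg2rad(RING_ORIENTATION_DEG)
    rz = np.array(
        [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    return replace(template, coord=placed @ rz.T)


# --------------------------------------------------------------------------
# Chain and facet specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FacetSpec:
    """Exposed-facet request: Miller indices + integer plane offset m."""

    miller: tuple[int, int, int]
    plane_offset: int = 0

    def __post_init__(self):
        if self.miller[2] == 0:
            raise ValueError("facet plane parallel to the chain axis (l = 0) unsupported")

    @classmethod
    def from_label(cls, label: str, plane_offset: int = 0) -> "FacetSpec":
        try:
            return cls(FACET_MILLER[label.upper()], plane_offset)
        except KeyError:
            raise BuildError(f"unknown facet label {label!r}; expected A, B or O") from None

    @property
    def label(self) -> str:
        for lab, hkl in FACET_MILLER.items():
            if hkl == self.miller:
                return lab
        return "({} {} {})".format(*self.miller)


@dataclass(frozen=True)
class ChainSpec:
    """One glucan chain of the bundle.

    ``u``/``v`` are fractional lattice coordinates of the chain axis in
    the a-b plane: integer for origin chains, half-integer for center
    chains.  ``stagger`` is the whole-residue axial offset applied for
    the facet.
    """

    polarity: str  # "origin" | "center"
    u: float
    v: float
    dp: int
    stagger: int = 0

    def __post_init__(self):
        if self.dp < 1:
            raise ValueError("dp must be >= 1")
        if self.polarity not in ("origin", "center"):
            raise ValueError("polarity must be 'origin' or 'center'")
        half = (round(2 * self.u), round(2 * self.v))
        if self.polarity == "origin" and (half[0] % 2 or half[1] % 2):
            raise ValueError("origin chains sit at integer (u, v)")
        if self.polarity == "center" and not (half[0] % 2 and half[1] % 2):
            raise ValueError("center chains sit at half-integer (u, v)")


@dataclass
class NanocrystalModel:
    """An assembled nanocrystal: coordinates plus lattice provenance."""

    name: str
    cell: UnitCell
    facet: FacetSpec
    chains: list[ChainSpec]
    atoms: struc.AtomArray  # annotations: chain_index (0-based), res_id (1..dp)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def dp(self) -> int:
        return self.chains[0].dp

    @property
    def n_residues(self) -> int:
        return sum(c.dp for c in self.chains)

    def chain_mask(self, chain_index: int) -> np.ndarray:
        return self.atoms.chain_index == chain_index

    def chain_axis(self, chain_index: int) -> np.ndarray:
        """Unit vector of the chain's covalent direction (residue 1 -> dp),
        i.e. the mean C1 -> O4 virtual-bond direction."""
        mask = self.chain_mask(chain_index)
        sub = self.atoms[mask]
        c1 = sub.coord[sub.atom_name == "C1"]
        o4 = sub.coord[sub.atom_name == "O4"]
        d = (o4 - c1).mean(axis=0)
        return d / np.linalg.norm(d)

    def facet_end_residue(self, chain_index: int) -> int:
        """res_id of the residue at the exposed-facet (top, +z) end."""
        mask = self.chain_mask(chain_index)
        sub = self.atoms[mask]
        ids = np.unique(sub.res_id)
        mean_z = [sub.coord[sub.res_id == r, 2].mean() for r in ids]
        return int(ids[int(np.argmax(mean_z))])

    def cross_section_centroid(self) -> np.ndarray:
        """Centroid of all atoms projected on the a-b (xy) plane."""
        return self.atoms.coord[:, :2].mean(axis=0)


# --------------------------------------------------------------------------
# Construction operations
# --------------------------------------------------------------------------

def compute_stagger(u: float, v: float, facet: FacetSpec, cell: UnitCell) -> int:
    """Whole-residue axial offset placing a chain's end anchor on the
    Miller plane h*x + k*y + l*z = m (fractional coordinates).

    n = round(residues_per_c * (m - h*u - k*v) / l).  For the flat (0 0 1)
    facet this is the same constant for every chain.
    """
    h, k, l = facet.miller
    if l == 0:
        raise BuildError("facet plane parallel to the chain axis (l = 0) unsupported")
    return int(round(cell.residues_per_c * (facet.plane_offset - h * u - k * v) / l))


def choose_plane_offset(
    facet_miller: tuple[int, int, int],
    uv: list[tuple[float, float]],
    cell: UnitCell,
) -> int:
    """Integer plane offset m minimizing total |stagger| over the chains
    (model centered on the facet plane).  Ties break toward smaller m."""
    h, k, l = facet_miller
    raw = [cell.residues_per_c * (h * u + k * v) / l for u, v in uv]
    best_m, best_cost = 0, None
    lo = int(np.floor(min(raw))) - 1
    hi = int(np.ceil(max(raw))) + 1
    for m in range(lo, hi + 1):
        facet = FacetSpec(facet_miller, m)
        cost = sum(abs(compute_stagger(u, v, facet, cell)) for u, v in uv)
        if best_cost is None or cost < best_cost:
            best_m, best_cost = m, cost
    return best_m


def build_chain(
    spec: ChainSpec,
    cell: UnitCell | None = None,
    template: GlucoseTemplate | None = None,
    center_offset_frac: float = CENTER_OFFSET_FRAC,
) -> struc.AtomArray:
    """Assemble one glucan chain.

    Residues are stacked by the 2-fold screw along c (alternate residues
    rotated 180 deg about the chain axis, translated c/2), giving exact
    glycosidic C1->O4' closure.  Center chains are built identically and
    then flipped 180 deg about a transverse axis (antiparallel polarity)
    and shifted by the intrinsic center offset.  Finally the chain is
    translated by its lattice position and facet stagger.
    """
    if spec.dp < 1:
        raise BuildError("dp must be >= 1")
    cell = cell or UnitCell()
    template = template if template is not None else GlucoseTemplate.ideal()
    placed = _oriented_template(cell, template)
    h = cell.residue_rise
    n_at = len(placed.names)
    dp = spec.dp

    coord = np.empty((dp * n_at, 3))
    rz = np.diag([-1.0, -1.0, 1.0])
    for j in range(dp):
        block = placed.coord @ (rz.T if j % 2 else np.eye(3))
        block = block + np.array([0.0, 0.0, j * h])
        coord[j * n_at:(j + 1) * n_at] = block

    if spec.polarity == "center":
        # antiparallel: rotate the assembled chain 180 deg about the x
        # axis placed at the anchor (C1) height, so facet-anchor heights
        # are polarity-invariant, then restore the z span and apply the
        # intrinsic center offset
        c1z = float(placed.position("C1")[2])
        coord = coord @ np.diag([1.0, -1.0, -1.0])
        coord[:, 2] += 2.0 * c1z + (dp - 1) * h + center_offset_frac * cell.c

    # residue 1 sits at the exposed-facet (top, +z) end of every chain:
    # origin chains stack upward, so their z-slot order is reversed
    if spec.polarity == "origin":
        slot_order = np.arange(dp - 1, -1, -1)
    else:
        slot_order = np.arange(dp)
    reorder = np.concatenate([np.arange(s * n_at, (s + 1) * n_at) for s in slot_order])
    coord = coord[reorder]

    lat = cell.lattice_vectors()
    shift = spec.u * lat[0] + spec.v * lat[1] + np.array([0.0, 0.0, spec.stagger * h])
    coord += shift

    atoms = struc.AtomArray(dp * n_at)
    atoms.coord = coord
    atoms.atom_name = np.tile(np.array(placed.names), dp)
    atoms.element = np.tile(np.array(placed.elements), dp)
    atoms.res_name = np.full(dp * n_at, "BGC")
    atoms.res_id = np.repeat(np.arange(1, dp + 1), n_at)
    atoms.chain_id = np.full(dp * n_at, "A")
    atoms.hetero = np.zeros(dp * n_at, dtype=bool)
    atoms.set_annotation("chain_index", np.zeros(dp * n_at, dtype=int))
    return atoms


# single-character chain id cycle used in PDB output
_CHAIN_ID_CYCLE = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_id_label(index: int) -> str:
    return _CHAIN_ID_CYCLE[index % len(_CHAIN_ID_CYCLE)]


def assemble_nanocrystal(
    i: int,
    dp: int,
    facet: str | FacetSpec,
    cell: UnitCell | None = None,
    template: GlucoseTemplate | None = None,
    plane_offset: int | str = "auto",
    center_offset_frac: float = CENTER_OFFSET_FRAC,
    clash_threshold: float = 0.8,
) -> NanocrystalModel:
    """Assemble an ``i x i``-chain nanocrystal named ``iLj``.

    Chains tile the base plane along the (1 -1 0) and (1 1 0) lattice
    diagonals with half-cell spacing, which interleaves origin chains
    (integer u, v) and antiparallel center chains (half-integer u, v) in
    a checkerboard.  Each chain receives the whole-residue stagger that
    places its end anchor on the requested Miller plane.
    """
    if i < 1 or dp < 1:
        raise BuildError("cross-section size and dp must be >= 1")
    cell = cell or UnitCell()
    if isinstance(facet, str):
        facet_spec = FacetSpec.from_label(facet)
    else:
        facet_spec = facet

    # lattice positions: p(j, k) = j*(a-b)/2 + k*(a+b)/2
    grid = []
    for j in range(i):
        for k in range(i):
            u = (j + k) / 2.0
            v = (k - j) / 2.0
            polarity = "origin" if (j + k) % 2 == 0 else "center"
            grid.append((u, v, polarity))
    grid.sort(key=lambda t: (t[0], t[1]))

    if plane_offset == "auto":
        m = choose_plane_offset(facet_spec.miller, [(u, v) for u, v, _ in grid], cell)
    else:
        m = int(plane_offset)
    facet_spec = replace(facet_spec, plane_offset=m)

    chains: list[ChainSpec] = []
    parts: list[struc.AtomArray] = []
    for idx, (u, v, polarity) in enumerate(grid):
        stagger = compute_stagger(u, v, facet_spec, cell)
        spec = ChainSpec(polarity=polarity, u=u, v=v, dp=dp, stagger=stagger)
        chain = build_chain(spec, cell, template, center_offset_frac)
        chain.chain_index[:] = idx
        chain.chain_id[:] = chain_id_label(idx)
        chains.append(spec)
        parts.append(chain)

    atoms = struc.concatenate(parts) if len(parts) > 1 else parts[0]

    if atoms.array_length() > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(atoms.coord)
        pairs = tree.query_pairs(r=clash_threshold)
        if pairs:
            a, b = sorted(pairs)[0]
            raise BuildError(
                f"steric clash after assembly: atoms {a} ({atoms.atom_name[a]}, "
                f"chain {atoms.chain_index[a]}) and {b} ({atoms.atom_name[b]}, "
                f"chain {atoms.chain_index[b]}) closer than {clash_threshold} A"
            )

    name = f"{i}{facet_spec.label}{dp}"
    return NanocrystalModel(name=name, cell=cell, facet=facet_spec,
                            chains=chains, atoms=atoms)


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoplanarityReport:
    max_deviation: float        # angstrom, max orthogonal distance to LS plane
    normal_angle_deg: float     # angle between fitted normal and Miller normal
    n_anchors: int

    def passes(self, max_dev: float, max_angle: float) -> bool:
        return self.max_deviation <= max_dev and self.normal_angle_deg <= max_angle


def facet_coplanarity_check(
    model: NanocrystalModel, anchor_atom: str = "C1"
) -> CoplanarityReport:
    """Least-squares plane fit through one anchor atom per chain at the
    exposed-facet end; reports the worst orthogonal deviation and the
    angle between the fitted normal and the facet's Miller normal."""
    if model.n_chains < 3:
        raise BuildError("coplanarity undefined for fewer than 3 chains")
    anchors = []
    for ci in range(model.n_chains):
        res = model.facet_end_residue(ci)
        mask = (
            model.chain_mask(ci)
            & (model.atoms.res_id == res)
            & (model.atoms.atom_name == anchor_atom)
        )
        anchors.append(model.atoms.coord[mask][0])
    pts = np.array(anchors)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    dev = np.abs(centered @ normal).max()
    ref = model.cell.miller_normal(model.facet.miller)
    cosang = abs(float(normal @ ref))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return CoplanarityReport(max_deviation=float(dev), normal_angle_deg=angle,
                             n_anchors=len(pts))
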