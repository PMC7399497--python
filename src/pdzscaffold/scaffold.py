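"""Oligomer construction in the scaffolding space group and avidity accounting.

A ligand-stabilized tandem-PDZ monomer packs into a body-centred cubic
lattice (space group I2_1 3, 24 general positions, cell edge ~148 A) through
three interface types:

* ``AB_DE`` - the reciprocal PDZ2(alphaB) <-> PDZ1(betaD-betaE) double
  contact that defines the twofold dimer (two interactions per dimer pair);
* ``AA_BC`` - the directed PDZ2(alphaA) -> PDZ1(betaB-betaC) contact that
  closes cyclic trimers around the threefold axes (one interaction per edge);
* ``P1P1`` - a single PDZ1-PDZ1 contact across a second twofold.

A monomer interior to the full lattice therefore makes 2 + 2 + 1 = 5
interactions, and the number of interactions broken on removing a copy (the
dissociation cost) grows along the oligomer series - the avidity argument
for why large oligomers persist after dilution.

The module provides a reference monomer placement (two-domain dumbbell
centres derived once by constrained optimization so that exactly the five
designated contacts form and every other lattice image stays clear),
operator presets for the metastable oligomer series 1e...24e, interface
graphs computed either combinatorially (from exact operator relations, no
coordinates needed) or geometrically (from domain centroid or residue-range
contacts), and the trimer-of-dimers grid search that derives the cell edge
as a = 4 * dx.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .spacegroup import SymmetryOperation, UnitCell, general_positions
from .structures import CoordinateSet, radius_of_gyration, transform

__all__ = [
    "InterfaceType",
    "Interface",
    "Assembly",
    "ClashError",
    "LatticeDerivation",
    "RELATION_OPS",
    "OLIGOMER_PRESETS",
    "OCTAMER_CONFIGURATIONS",
    "REFERENCE_CELL",
    "reference_monomer",
    "preset_ops",
    "build_oligomer",
    "combinatorial_assembly",
    "interface_degree",
    "dissociation_cost",
    "assembly_delta",
    "full_lattice_degree",
    "identify_twofold_axis",
    "trimer_of_dimers_search",
]

_OP = SymmetryOperation.from_triplet


class InterfaceType(Enum):
    AB_DE = "AB_DE"   # alphaB(PDZ2)-betaD-betaE(PDZ1), reciprocal (weight 2)
    AA_BC = "AA_BC"   # alphaA(PDZ2)-betaB-betaC(PDZ1), directed (weight 1)
    P1P1 = "P1P1"     # PDZ1-PDZ1 (weight 1)


#: Interactions contributed by one edge of each type.  The twofold dimer
#: forms both reciprocal AB_DE contacts at once, hence weight 2.
EDGE_WEIGHT = {InterfaceType.AB_DE: 2, InterfaceType.AA_BC: 1, InterfaceType.P1P1: 1}

# ---------------------------------------------------------------------------
# Frozen lattice reference (derived, see docs/methods.md)
# ---------------------------------------------------------------------------

#: Cell edge of the scaffolding lattice in Angstrom.
REFERENCE_CELL = UnitCell(148.0)

#: Exact operator relations that generate each interface from a copy.  The
#: AB_DE and P1P1 relations are exact involutions (pure twofolds); AA_BC uses
#: the threefold about [111].  The P1P1 relation carries an explicit lattice
#: shift: only that translate of the coset touches the home copy.
RELATION_OPS = {
    InterfaceType.AB_DE: (_OP("x,-y,-z+1/2"),),
    InterfaceType.AA_BC: (_OP("z,x,y"), _OP("y,z,x")),
    InterfaceType.P1P1: (_OP("-x+1/2,y,-z").shifted((0, 0, 1)),),
}

#: Domain reference positions (Cartesian, A) of the placed monomer: PDZ1-like
#: domain centre and PDZ2-like domain centre.  Derived by constrained
#: optimization so the five designated contacts sit at 26.3-26.9 A between
#: domain centres while every other lattice image pair stays >= 32 A.
REFERENCE_P1 = np.array([31.996466151858613, 7.570746944926746, 61.81037223209246])
REFERENCE_P2 = np.array([48.98385100518, 11.48159495208018, 19.241204740993552])

#: Domain-centre distance at/below which two domains are in contact
#: (geometric interface detection for bead models).
DOMAIN_CONTACT_CUTOFF = 28.0

#: Minimum inter-copy bead distance accepted before a clash is declared.
CLASH_THRESHOLD = 3.0

# Metastable oligomer series ("e" = extended monomer conformation).  The
# tetramer is a cyclic trimer around the [111] threefold plus the twofold
# dimer partner of one ring member; octamer and larger are built by docking
# further tetramers through a free dimer arm.  Additions through the 20-mer
# each form three interactions (one reciprocal AB_DE pair + one P1P1); the
# 24-mer covers all 24 general-position cosets of the unit cell exactly once.
OLIGOMER_PRESETS: dict[str, tuple[str, ...]] = {
    "1e": ("x,y,z",),
    "2e": ("x,y,z", "x,-y,-z+1/2"),
    "4e": ("x,y,z", "z,x,y", "y,z,x", "x,-y,-z+1/2"),
    "8e": (
        "x,y,z", "z,x,y", "y,z,x", "x,-y,-z+1/2",
        "-z+1/2,x,-y", "-y+1/2,z,-x", "-x+1/2,y,-z", "-x+1/2,-y,z-1/2",
    ),
    "12e": (
        "x,y,z", "z,x,y", "y,z,x", "x,-y,-z+1/2",
        "-z+1/2,x,-y", "-y+1/2,z,-x", "-x+1/2,y,-z", "-x+1/2,-y,z-1/2",
        "-y,-z+1/2,x", "-x,-y+1/2,z", "-z,-x+1/2,y", "z-1/2,-x+1/2,-y",
    ),
    "16e": (
        "x,y,z", "z,x,y", "y,z,x", "x,-y,-z+1/2",
        "-z+1/2,x,-y", "-y+1/2,z,-x", "-x+1/2,y,-z", "-x+1/2,-y,z-1/2",
        "-y,-z+1/2,x", "-x,-y+1/2,z", "-z,-x+1/2,y", "z-1/2,-x+1/2,-y",
        "-x,y+1/2,-z+1/2", "-z,x+1/2,-y+1/2", "-y,z+1/2,-x+1/2", "y,-z+1,-x+1/2",
    ),
    "20e": (
        "x,y,z", "z,x,y", "y,z,x", "x,-y,-z+1/2",
        "-z+1/2,x,-y", "-y+1/2,z,-x", "-x+1/2,y,-z", "-x+1/2,-y,z-1/2",
        "-y,-z+1/2,x", "-x,-y+1/2,z", "-z,-x+1/2,y", "z-1/2,-x+1/2,-y",
        "-x,y+1/2,-z+1/2", "-z,x+1/2,-y+1/2", "-y,z+1/2,-x+1/2", "y,-z+1,-x+1/2",
        "z-1/2,x+1/2,y+1/2", "y-1/2,z+1/2,x+1/2", "x-1/2,y+1/2,z+1/2",
        "x-1/2,-y+1/2,-z+1",
    ),
    "24e": (
        "x,y,z", "z,x,y", "y,z,x", "x,-y,-z+1/2",
        "-z,-x+1/2,y", "-y,-z+1/2,x", "-x,-y+1/2,z", "z-1/2,-x+1/2,-y",
        "-y,z+1/2,-x+1/2", "-x,y+1/2,-z+1/2", "-z,x+1/2,-y+1/2", "y,-z+1,-x+1/2",
        "-y+1/2,z,-x", "-x+1/2,y,-z", "-z+1/2,x,-y", "y+1/2,-z+1/2,-x",
        "-z+1/2,-x,y-1/2", "-y+1/2,-z,x-1/2", "-x+1/2,-y,z-1/2", "z,-x,-y-1/2",
        "x-1/2,y+1/2,z+1/2", "z-1/2,x+1/2,y+1/2", "y-1/2,z+1/2,x+1/2",
        "x-1/2,-y+1/2,-z+1",
    ),
}

#: Tetramer + tetramer docking through one reciprocal AB_DE dimer.  Of the
#: lattice-consistent configurations exactly one also forms a P1P1 contact
#: (three interactions on assembly, the favored configuration); the others
#: form only the AB_DE pair (two interactions).
OCTAMER_CONFIGURATIONS: dict[str, tuple[str, ...]] = {
    "favored": OLIGOMER_PRESETS["8e"],
    "alt1": (
        # second tetramer docked through the same ring arm, other partner
        # choice: the AB_DE pair forms but no P1P1 contact
        "x,y,z", "z,x,y", "y,z,x", "x,-y,-z+1/2",
        "-y+1/2,z,-x", "-x+1/2,y,-z", "-z+1/2,x,-y", "y+1/2,-z+1/2,-x",
    ),
    "alt2": (
        # second tetramer docked at the other free ring arm: AB_DE only
        "x,y,z", "z,x,y", "y,z,x", "x,-y,-z+1/2",
        "-x,-y+1/2,z", "-z,-x+1/2,y", "-y,-z+1/2,x", "-x,y+1/2,-z+1/2",
    ),
}


def preset_ops(name: str) -> list[SymmetryOperation]:
    """Operator list of a named oligomer preset (1e, 2e, 4e, ..., 24e)."""
    try:
        triplets = OLIGOMER_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(OLIGOMER_PRESETS)}"
        ) from None
    return [_OP(t) for t in triplets]


# ---------------------------------------------------------------------------
# Assemblies and interface graphs
# ---------------------------------------------------------------------------


class ClashError(ValueError):
    def __init__(self, i: int, j: int, dist: float, threshold: float):
        self.pair = (i, j)
        self.min_distance = dist
        super().__init__(
            f"copies {i} and {j} clash: minimum distance {dist:.2f} A "
            f"< threshold {threshold:.2f} A"
        )


@dataclass(frozen=True)
class Interface:
    i: int
    j: int
    kind: InterfaceType

    @property
    def weight(self) -> int:
        return EDGE_WEIGHT[self.kind]


@dataclass
class Assembly:
    """Symmetry copies of a monomer plus their typed interface graph."""

    ops: list[SymmetryOperation]
    copies: list[CoordinateSet] | None
    interfaces: list[Interface]
    cell: UnitCell = REFERENCE_CELL
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.ops)

    def combined(self) -> CoordinateSet:
        if self.copies is None:
            raise ValueError("combinatorial assembly carries no coordinates")
        parts = self.copies
        return CoordinateSet(
            chain_ids=np.concatenate([c.chain_ids for c in parts]),
            res_seq=np.concatenate([c.res_seq for c in parts]),
            res_names=np.concatenate([c.res_names for c in parts]),
            atom_names=np.concatenate([c.atom_names for c in parts]),
            coords=np.vstack([c.coords for c in parts]),
            weights=np.concatenate([c.weights for c in parts]),
            label=self.label or f"assembly n={self.n}",
            cell=self.cell,
        )

    def edge_list(self) -> list[tuple[int, int, str, int]]:
        return [(e.i, e.j, e.kind.value, e.weight) for e in self.interfaces]

    def write_edges(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# i j interface weight\n")
            for i, j, k, w in self.edge_list():
                fh.write(f"{i} {j} {k} {w}\n")


def _relation_edges(ops: Sequence[SymmetryOperation]) -> list[Interface]:
    """Typed edges from exact operator relations (no coordinates needed).

    Copies g and h interact when the relative operation g^-1 h equals one of
    the frozen relation operators exactly (including its lattice shift); the
    contact geometry of a pair depends only on that relative operation.
    """
    edges = []
    for i, j in itertools.combinations(range(len(ops)), 2):
        rel = ops[i].inverse() @ ops[j]
        rel_inv = rel.inverse()
        for kind, rels in RELATION_OPS.items():
            hits = [r for r in rels if rel == r or rel_inv == r]
            if hits:
                edges.append(Interface(i, j, kind))
                break
    return edges


def _domain_centroids(cs: CoordinateSet) -> tuple[np.ndarray, np.ndarray]:
    """Centroids of the PDZ1-like and PDZ2-like halves of a model.

    Bead dumbbells tag domains with residue names DM1/DM2; anything else is
    split by the chain-order midpoint as a fallback.
    """
    m1 = cs.res_names == "DM1"
    m2 = cs.res_names == "DM2"
    if m1.any() and m2.any():
        return cs.coords[m1].mean(axis=0), cs.coords[m2].mean(axis=0)
    half = len(cs) // 2
    return cs.coords[:half].mean(axis=0), cs.coords[half:].mean(axis=0)


def _geometric_edges(
    copies: Sequence[CoordinateSet], cutoff: float = DOMAIN_CONTACT_CUTOFF
) -> list[Interface]:
    """Typed edges from domain-centroid contacts.

    A directed PDZ2(i) -> PDZ1(j) contact is an AA_BC-type interaction; when
    both directions are in contact for a pair it is the reciprocal AB_DE
    dimer; a PDZ1(i)-PDZ1(j) contact is the P1P1 interface.
    """
    cents = [_domain_centroids(c) for c in copies]
    edges = []
    for i, j in itertools.combinations(range(len(copies)), 2):
        c1i, c2i = cents[i]
        c1j, c2j = cents[j]
        fwd = np.linalg.norm(c2i - c1j) <= cutoff   # PDZ2_i -> PDZ1_j
        rev = np.linalg.norm(c2j - c1i) <= cutoff
        p11 = np.linalg.norm(c1i - c1j) <= cutoff
        if fwd and rev:
            edges.append(Interface(i, j, InterfaceType.AB_DE))
        elif fwd or rev:
            edges.append(Interface(i, j, InterfaceType.AA_BC))
        if p11:
            edges.append(Interface(i, j, InterfaceType.P1P1))
    return edges


def residue_range_edges(
    copies: Sequence[CoordinateSet],
    annotation: dict[str, tuple[int, int]],
    d_cut: float = 8.0,
    n_min: int = 3,
) -> list[Interface]:
    """Typed edges from Calpha contacts between annotated element ranges.

    ``annotation`` maps element names ('alphaA_PDZ2', 'betaB_betaC_PDZ1',
    'alphaB_PDZ2', 'betaD_betaE_PDZ1', 'PDZ1') to inclusive residue-number
    ranges in the model's own numbering.  An edge of a given type exists when
    at least ``n_min`` Calpha pairs from the two named ranges are within
    ``d_cut``.
    """
    def ca_range(cs, key):
        lo, hi = annotation[key]
        mask = (cs.atom_names == "CA") & (cs.res_seq >= lo) & (cs.res_seq <= hi)
        return cs.coords[mask]

    edges = []
    for i, j in itertools.combinations(range(len(copies)), 2):
        def npairs(a, b):
            if len(a) == 0 or len(b) == 0:
                return 0
            return int((cdist(a, b) <= d_cut).sum())

        fwd = npairs(ca_range(copies[i], "alphaB_PDZ2"),
                     ca_range(copies[j], "betaD_betaE_PDZ1")) >= n_min
        rev = npairs(ca_range(copies[j], "alphaB_PDZ2"),
                     ca_range(copies[i], "betaD_betaE_PDZ1")) >= n_min
        if fwd and rev:
            edges.append(Interface(i, j, InterfaceType.AB_DE))
        else:
            aabc = (npairs(ca_range(copies[i], "alphaA_PDZ2"),
                           ca_range(copies[j], "betaB_betaC_PDZ1")) >= n_min
                    or npairs(ca_range(copies[j], "alphaA_PDZ2"),
                              ca_range(copies[i], "betaB_betaC_PDZ1")) >= n_min)
            if aabc:
                edges.append(Interface(i, j, InterfaceType.AA_BC))
        if npairs(ca_range(copies[i], "PDZ1"), ca_range(copies[j], "PDZ1")) >= n_min:
            edges.append(Interface(i, j, InterfaceType.P1P1))
    return edges


def _check_clashes(
    copies: Sequence[CoordinateSet], threshold: float = CLASH_THRESHOLD
) -> None:
    for i, j in itertools.combinations(range(len(copies)), 2):
        d = float(cdist(copies[i].coords, copies[j].coords).min())
        if d < threshold:
            raise ClashError(i, j, d, threshold)


def reference_monomer(
    beads_per_domain: int = 60, seed: int = 0
) -> CoordinateSet:
    """A dumbbell bead monomer at the derived reference placement.

    The two domain centres sit at the frozen positions from which the
    scaffolding-lattice contacts were derived; domain separation is 46 A and
    the radius of gyration falls in the 21-25 A band of the extended
    conformation.
    """
    from .synthetic_data import DumbbellSpec, make_dumbbell

    sep = float(np.linalg.norm(REFERENCE_P2 - REFERENCE_P1))
    spec = DumbbellSpec(separation=sep, beads_per_domain=beads_per_domain)
    generic = make_dumbbell(spec, seed=seed, label="reference monomer")
    # rigid map: x axis -> (p2 - p1) direction, centre -> midpoint
    u = (REFERENCE_P2 - REFERENCE_P1) / sep
    ref = np.array([1.0, 0.0, 0.0])
    v = np.cross(ref, u)
    c = float(ref @ u)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    mid = (REFERENCE_P1 + REFERENCE_P2) / 2.0
    out = generic.with_coords(generic.coords @ rot.T + mid)
    out.cell = REFERENCE_CELL
    return out


def build_oligomer(
    monomer: CoordinateSet,
    ops: Sequence[SymmetryOperation] | str,
    cell: UnitCell = REFERENCE_CELL,
    clash_threshold: float = CLASH_THRESHOLD,
    graph: str = "relations",
    label: str = "",
) -> Assembly:
    """Apply operator tags to a placed monomer and compute the interface graph.

    ``ops`` may be a preset name.  ``graph`` selects 'relations' (typing from
    exact operator relations) or 'geometric' (domain-centroid contacts).  A
    clash (any inter-copy bead distance below the threshold) raises
    :class:`ClashError` naming the offending pair.
    """
    if isinstance(ops, str):
        label = label or ops
        ops = preset_ops(ops)
    ops = list(ops)
    copies = [transform(monomer, op, cell) for op in ops]
    _check_clashes(copies, clash_threshold)
    if graph == "relations":
        interfaces = _relation_edges(ops)
    elif graph == "geometric":
        interfaces = _geometric_edges(copies)
    else:
        raise ValueError("graph must be 'relations' or 'geometric'")
    return Assembly(ops, copies, interfaces, cell, label)


def combinatorial_assembly(
    ops: Sequence[SymmetryOperation] | str, label: str = ""
) -> Assembly:
    """Assembly with the interface graph from operator relations only.

    No coordinates are attached; this is the download-free mode in which the
    avidity arithmetic (degrees 5 = 2+2+1, dissociation costs, interactions
    formed on association) is exercised.
    """
    if isinstance(ops, str):
        label = label or ops
        ops = preset_ops(ops)
    ops = list(ops)
    return Assembly(ops, None, _relation_edges(ops), REFERENCE_CELL, label)


def interface_degree(assembly: Assembly, index: int) -> tuple[int, int, int, int]:
    """(AB_DE, AA_BC, P1P1, total) interaction counts of one copy."""
    if not 0 <= index < assembly.n:
        raise IndexError(f"copy index {index} out of range (n={assembly.n})")
    counts = {k: 0 for k in InterfaceType}
    for e in assembly.interfaces:
        if index in (e.i, e.j):
            counts[e.kind] += e.weight
    return (
        counts[InterfaceType.AB_DE],
        counts[InterfaceType.AA_BC],
        counts[InterfaceType.P1P1],
        sum(counts.values()),
    )


def dissociation_cost(assembly: Assembly, index: int) -> int:
    """Interactions broken to remove one copy (equals its total degree)."""
    return interface_degree(assembly, index)[3]


def assembly_delta(a: Assembly, b: Assembly) -> int:
    """Interactions formed when two assemblies associate.

    The union's edges minus the edges internal to each part; coordinates (if
    present) are clash-checked first.
    """
    ops = list(a.ops) + list(b.ops)
    if len({(op.rotation, tuple(op.translation)) for op in ops}) != len(ops):
        raise ClashError(0, 0, 0.0, CLASH_THRESHOLD)
    if a.copies is not None and b.copies is not None:
        _check_clashes(list(a.copies) + list(b.copies))
    union_edges = _relation_edges(ops)
    w_union = sum(e.weight for e in union_edges)
    w_parts = sum(e.weight for e in a.interfaces) + sum(e.weight for e in b.interfaces)
    return w_union - w_parts


def full_lattice_degree() -> tuple[int, int, int, int]:
    """Interaction degree of a copy interior to the full scaffolding lattice.

    Computed from the relation operators modulo lattice translations: each
    copy has one reciprocal AB_DE dimer partner, two AA_BC ring neighbours
    and one P1P1 partner, hence (2, 2, 1, 5).
    """
    home = SymmetryOperation.identity()
    cosets = {
        (op.rotation, tuple(op.translation)) for op in general_positions(199)
    }
    counts = {k: 0 for k in InterfaceType}
    for kind, rels in RELATION_OPS.items():
        partners = set()
        for r in rels:
            for rel in (r, r.inverse()):
                img = (home @ rel).reduced()
                key = (img.rotation, tuple(img.translation))
                if key not in cosets:  # pragma: no cover - table integrity
                    raise RuntimeError("relation operator leaves the group")
                partners.add(key)
        counts[kind] += EDGE_WEIGHT[kind] * (
            len(partners) if kind is InterfaceType.AA_BC else 1
        )
    return (
        counts[InterfaceType.AB_DE],
        counts[InterfaceType.AA_BC],
        counts[InterfaceType.P1P1],
        sum(counts.values()),
    )


# ---------------------------------------------------------------------------
# Trimer-of-dimers grid search
# ---------------------------------------------------------------------------


@dataclass
class LatticeDerivation:
    dx: float                  # displacement of the dimer from the z-y plane (A)
    rotation: float            # rotation about the dimer twofold (degrees)
    a: float                   # derived cell edge, a = 4 dx
    resolution_error: float    # (2 pi) / (2 q_max)
    contact_distance: float    # best inter-dimer contact distance found
    target_distance: float


def identify_twofold_axis(
    dimer: CoordinateSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Axis direction and centre of a symmetric two-chain dimer.

    The two chains are superposed by a Kabsch rotation; for a twofold dimer
    that rotation is a 180-degree turn whose +1 eigenvector is the axis.
    """
    chains = sorted(set(dimer.chain_ids))
    if len(chains) != 2:
        raise ValueError("dimer must contain exactly two chains")
    a = dimer.coords[dimer.chain_ids == chains[0]]
    b = dimer.coords[dimer.chain_ids == chains[1]]
    if len(a) != len(b):
        raise ValueError("dimer chains must be the same length, in the same order")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    evals, evecs = np.linalg.eigh((rot + rot.T) / 2.0)
    axis = evecs[:, np.argmax(evals)]
    centre = (ca + cb) / 2.0
    return axis / np.linalg.norm(axis), centre


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]
    ])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


_C3_111 = _rotation_about(np.array([1.0, 1.0, 1.0]), 120.0)


def trimer_of_dimers_search(
    dimer: CoordinateSet,
    target_distance: float,
    rot_step: float = 5.0,
    dx_step: float = 1.0,
    dx_range: tuple[float, float] = (20.0, 60.0),
    q_max: float = 0.4,
    clash_threshold: float = CLASH_THRESHOLD,
) -> LatticeDerivation:
    """Grid search for the dimer placement that closes the trimer of dimers.

    The dimer is oriented with its twofold along x (perpendicular to the z-y
    plane, intersecting the x axis) and displaced by dx; two further dimers
    are generated by +-120-degree rotation about [1,1,1].  The grid point
    whose closest inter-dimer contact best matches ``target_distance`` (the
    reference crystal-contact distance) is selected, ties broken toward
    smaller dx then smaller rotation.  The cell edge follows as a = 4 dx and
    the quoted positional error is the half-period (2 pi)/(2 q_max) of the
    highest momentum transfer used in refining the dimer.
    """
    if rot_step <= 0 or dx_step <= 0:
        raise ValueError("grid steps must be positive")
    axis, centre = identify_twofold_axis(dimer)
    # orient: axis -> x, centre -> origin
    xhat = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, xhat)
    c = float(axis @ xhat)
    if np.linalg.norm(v) < 1e-12:
        rot0 = np.eye(3) if c > 0 else _rotation_about(np.array([0.0, 1.0, 0.0]), 180.0)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot0 = np.eye(3) + vx + vx @ vx / (1.0 + c)
    base = (dimer.coords - centre) @ rot0.T

    rotations = np.arange(0.0, 180.0, rot_step)
    dxs = np.arange(dx_range[0], dx_range[1] + 0.5 * dx_step, dx_step)
    best = None
    best_clashing = None
    for dx in dxs:
        for ang in rotations:
            placed = base @ _rotation_about(xhat, ang).T + np.array([dx, 0.0, 0.0])
            d2 = placed @ _C3_111.T
            d3 = d2 @ _C3_111.T
            dmin12 = float(cdist(placed, d2).min())
            score = abs(dmin12 - target_distance)
            entry = (score, dx, ang, dmin12)
            if dmin12 < clash_threshold or float(cdist(placed, d3).min()) < clash_threshold:
                if best_clashing is None or score < best_clashing[0]:
                    best_clashing = entry
                continue
            if best is None or (score, dx, ang) < (best[0], best[1], best[2]):
                best = entry
    if best is None:
        if best_clashing is not None:
            raise ClashError(0, 1, best_clashing[3], clash_threshold)
        raise ValueError("empty search grid")
    score, dx, ang, dmin = best
    return LatticeDerivation(
        dx=float(dx),
        rotation=float(ang),
        a=4.0 * float(dx),
        resolution_error=float(2.0 * np.pi / (2.0 * q_max)),
        contact_distance=float(dmin),
        target_distance=float(target_distance),
    )
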