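"""Crystallographic symmetry engine for the chiral (Sohncke) cubic space groups.

Protein assemblies built from proper rotations only can pack in one of the 13
Sohncke cubic space groups (International Tables numbers 195-199 and 207-214).
This module provides exact operator tables for those groups, the
symmetry-element attribute table used to narrow a packing arrangement down to
a single group, and small lattice-geometry helpers (axis angles, fractional /
Cartesian conversion for a cubic cell).

Operators are stored with integer rotation matrices and exact rational
translations so that group-theoretic checks (closure, inverses, involutions)
are free of floating-point tolerances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SymmetryOperation",
    "SpaceGroupRecord",
    "UnitCell",
    "UnknownSpaceGroupError",
    "SOHNCKE_CUBIC_NUMBERS",
    "space_group",
    "general_positions",
    "apply_operation",
    "eliminate_space_groups",
    "axis_angle",
]

_IDENT_ROT = ((1, 0, 0), (0, 1, 0), (0, 0, 1))


class UnknownSpaceGroupError(KeyError):
    """Raised for a space-group number outside the tabulated Sohncke cubic set."""


@dataclass(frozen=True)
class SymmetryOperation:
    """A proper rotation plus a fractional translation: x' = R x + t.

    ``rotation`` is a 3x3 integer matrix (tuple of tuples); ``translation``
    holds exact :class:`fractions.Fraction` components in units of the cell
    edge.  Operators drawn from a group table have translations reduced into
    [0, 1); operators used to build finite assemblies may carry explicit
    lattice shifts outside that range.
    """

    rotation: tuple[tuple[int, int, int], ...]
    translation: tuple[Fraction, Fraction, Fraction]

    # -- construction ------------------------------------------------------
    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOperation":
        """Parse an 'x,y,z'-style coordinate triplet, e.g. ``-x+1/2,y,-z``."""
        rows: list[tuple[int, int, int]] = []
        trans: list[Fraction] = []
        parts = triplet.replace(" ", "").lower().split(",")
        if len(parts) != 3:
            raise ValueError(f"triplet must have three components: {triplet!r}")
        for part in parts:
            row = [0, 0, 0]
            t = Fraction(0)
            sign, i = 1, 0
            while i < len(part):
                c = part[i]
                if c == "+":
                    sign, i = 1, i + 1
                elif c == "-":
                    sign, i = -1, i + 1
                elif c in "xyz":
                    row["xyz".index(c)] += sign
                    sign, i = 1, i + 1
                elif c.isdigit():
                    j = i
                    while j < len(part) and (part[j].isdigit() or part[j] == "/"):
                        j += 1
                    t += sign * Fraction(part[i:j])
                    sign, i = 1, j
                else:
                    raise ValueError(f"unparseable triplet component {part!r}")
            rows.append(tuple(row))
            trans.append(t)
        return cls(tuple(rows), tuple(trans))

    @classmethod
    def identity(cls) -> "SymmetryOperation":
        return cls(_IDENT_ROT, (Fraction(0), Fraction(0), Fraction(0)))

    # -- representation ----------------------------------------------------
    def triplet(self) -> str:
        """Render as an 'x,y,z'-style string."""
        out = []
        for row, t in zip(self.rotation, self.translation):
            s = ""
            for coef, name in zip(row, "xyz"):
                if coef == 0:
                    continue
                s += ("-" if coef < 0 else ("+" if s else "")) + name
            if t != 0:
                s += ("+" if t > 0 else "-") + str(abs(t))
            out.append(s or "0")
        return ",".join(out)

    def matrix(self) -> np.ndarray:
        """3x4 float matrix [R | t]."""
        m = np.zeros((3, 4))
        m[:, :3] = np.asarray(self.rotation, dtype=float)
        m[:, 3] = [float(t) for t in self.translation]
        return m

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.triplet()

    # -- algebra -----------------------------------------------------------
    def __matmul__(self, other: "SymmetryOperation") -> "SymmetryOperation":
        """Exact composition self∘other (apply ``other`` first)."""
        ra, rb = self.rotation, other.rotation
        rot = tuple(
            tuple(sum(ra[i][k] * rb[k][j] for k in range(3)) for j in range(3))
            for i in range(3)
        )
        tr = tuple(
            sum(ra[i][k] * other.translation[k] for k in range(3)) + self.translation[i]
            for i in range(3)
        )
        return SymmetryOperation(rot, tr)

    def inverse(self) -> "SymmetryOperation":
        rinv = _int_inverse(self.rotation)
        tr = tuple(-sum(rinv[i][k] * self.translation[k] for k in range(3)) for i in range(3))
        return SymmetryOperation(rinv, tr)

    def reduced(self) -> "SymmetryOperation":
        """Translation reduced mod 1 (coset representative modulo the lattice)."""
        return SymmetryOperation(self.rotation, tuple(t % 1 for t in self.translation))

    def shifted(self, shift: Sequence[int]) -> "SymmetryOperation":
        """Compose with an integral lattice translation."""
        return SymmetryOperation(
            self.rotation, tuple(t + int(s) for t, s in zip(self.translation, shift))
        )

    @property
    def is_identity(self) -> bool:
        return self.rotation == _IDENT_ROT and all(t == 0 for t in self.translation)

    def rotation_order(self) -> int:
        """Order of the rotation part (1, 2, 3, 4 or 6 for crystallographic R)."""
        acc = _IDENT_ROT
        for n in range(1, 7):
            acc = _matmul_int(self.rotation, acc)
            if acc == _IDENT_ROT:
                return n
        raise ValueError("non-crystallographic rotation matrix")

    def determinant(self) -> int:
        r = self.rotation
        return (
            r[0][0] * (r[1][1] * r[2][2] - r[1][2] * r[2][1])
            - r[0][1] * (r[1][0] * r[2][2] - r[1][2] * r[2][0])
            + r[0][2] * (r[1][0] * r[2][1] - r[1][1] * r[2][0])
        )

    def intrinsic_translation(self) -> tuple[Fraction, Fraction, Fraction]:
        """Screw component: (1/n) sum_k R^k t for rotation order n.

        Zero (mod 1) for pure rotations; e.g. 1/2 along the axis for a 2_1
        screw.
        """
        n = self.rotation_order()
        acc = _IDENT_ROT
        total = [Fraction(0)] * 3
        for _ in range(n):
            for i in range(3):
                total[i] += sum(acc[i][k] * self.translation[k] for k in range(3))
            acc = _matmul_int(self.rotation, acc)
        return tuple(t / n for t in total)

    def rotation_axis(self) -> tuple[int, int, int]:
        """Integer axis direction of a non-identity proper rotation."""
        n = self.rotation_order()
        if n == 1:
            raise ValueError("identity has no axis")
        acc, total = _IDENT_ROT, np.zeros((3, 3), dtype=int)
        for _ in range(n):
            total += np.asarray(acc)
            acc = _matmul_int(self.rotation, acc)
        for col in total.T:
            if np.any(col != 0):
                g = np.gcd.reduce(np.abs(col[col != 0]))
                return tuple(int(v) for v in col // g)
        raise ValueError("no invariant axis found")


def _matmul_int(a, b):
    return tuple(
        tuple(sum(a[i][k] * b[k][j] for k in range(3)) for j in range(3)) for i in range(3)
    )


def _int_inverse(r):
    """Inverse of an integer rotation matrix with determinant +-1."""
    rn = np.asarray(r, dtype=float)
    inv = np.linalg.inv(rn)
    return tuple(tuple(int(round(v)) for v in row) for row in inv)


def apply_operation(op: SymmetryOperation, coords: np.ndarray) -> np.ndarray:
    """Apply an operator to fractional coordinates, x' = R x + t.

    No mod-1 wrapping is applied: assemblies of symmetry copies must remain
    contiguous in space, so atomic coordinates are never folded back into the
    unit cell.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    rot = np.asarray(op.rotation, dtype=float)
    t = np.array([float(x) for x in op.translation])
    return coords @ rot.T + t


# ---------------------------------------------------------------------------
# Group tables
# ---------------------------------------------------------------------------

#: Generator triplets for the 13 Sohncke cubic groups, International Tables
#: for Crystallography Vol. A, standard settings.  Each group is expanded by
#: closure; the expansion is validated against the expected group order at
#: import time.
_GENERATORS: dict[int, list[str]] = {
    195: ["-x,-y,z", "-x,y,-z", "z,x,y"],                                  # P23
    196: ["-x,-y,z", "-x,y,-z", "z,x,y",
          "x,y+1/2,z+1/2", "x+1/2,y,z+1/2"],                               # F23
    197: ["-x,-y,z", "-x,y,-z", "z,x,y", "x+1/2,y+1/2,z+1/2"],             # I23
    198: ["-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "z,x,y"],                  # P2_1 3
    199: ["-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "z,x,y",
          "x+1/2,y+1/2,z+1/2"],                                            # I2_1 3
    207: ["-x,-y,z", "-x,y,-z", "z,x,y", "y,x,-z"],                        # P432
    208: ["-x,-y,z", "-x,y,-z", "z,x,y", "y+1/2,x+1/2,-z+1/2"],            # P4_2 32
    209: ["-x,-y,z", "-x,y,-z", "z,x,y", "y,x,-z",
          "x,y+1/2,z+1/2", "x+1/2,y,z+1/2"],                               # F432
    210: ["-x,-y+1/2,z+1/2", "-x+1/2,y+1/2,-z", "z,x,y",
          "y+3/4,x+1/4,-z+3/4", "x,y+1/2,z+1/2", "x+1/2,y,z+1/2"],         # F4_1 32
    211: ["-x,-y,z", "-x,y,-z", "z,x,y", "y,x,-z",
          "x+1/2,y+1/2,z+1/2"],                                            # I432
    212: ["-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "z,x,y",
          "y+1/4,x+3/4,-z+3/4"],                                           # P4_3 32
    213: ["-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "z,x,y",
          "y+3/4,x+1/4,-z+1/4"],                                           # P4_1 32
    214: ["-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "z,x,y",
          "y+3/4,x+1/4,-z+1/4", "x+1/2,y+1/2,z+1/2"],                      # I4_1 32
}

_EXPECTED_ORDER = {
    195: 12, 196: 48, 197: 24, 198: 12, 199: 24,
    207: 24, 208: 24, 209: 96, 210: 96, 211: 48, 212: 24, 213: 24, 214: 48,
}

# Symmetry-element attributes per group, International Tables Vol. A symmetry
# diagrams.  Columns: symbol, centering, has_fourfold_axes (any 4/4_1/4_2/4_3),
# has_pure_twofold_rotation, has_21_screws, threefold_axes_intersect,
# has_31_screws.  Every row is re-derivable from the operator table (see
# ``_compute_flags``) and the two derivations are cross-checked in the tests.
_ATTRIBUTES: dict[int, tuple[str, str, bool, bool, bool, bool, bool]] = {
    195: ("P23",     "P", False, True,  False, True,  False),
    196: ("F23",     "F", False, True,  True,  True,  True),
    197: ("I23",     "I", False, True,  True,  True,  True),
    198: ("P2_1 3",  "P", False, False, True,  False, True),   # only 2_1 screws
    199: ("I2_1 3",  "I", False, True,  True,  False, True),   # centering adds pure 2s
    207: ("P432",    "P", True,  True,  False, True,  False),
    208: ("P4_2 32", "P", True,  True,  True,  True,  False),
    209: ("F432",    "F", True,  True,  True,  True,  True),
    210: ("F4_1 32", "F", True,  True,  True,  True,  True),
    211: ("I432",    "I", True,  True,  True,  True,  True),
    212: ("P4_3 32", "P", True,  True,  True,  False, True),
    213: ("P4_1 32", "P", True,  True,  True,  False, True),
    214: ("I4_1 32", "I", True,  True,  True,  False, True),
}

SOHNCKE_CUBIC_NUMBERS: tuple[int, ...] = tuple(sorted(_GENERATORS))


@dataclass(frozen=True)
class SpaceGroupRecord:
    it_number: int
    symbol: str
    centering: str
    has_fourfold_axes: bool
    has_pure_twofold_rotation: bool
    has_21_screws: bool
    threefold_axes_intersect: bool
    has_31_screws: bool
    general_positions: tuple[SymmetryOperation, ...] = field(repr=False)


def _closure(gens: Iterable[SymmetryOperation]) -> list[SymmetryOperation]:
    ident = SymmetryOperation.identity()
    ops = {ident}
    frontier = set(gens) | {ident}
    while frontier:
        new = set()
        for a in frontier:
            for b in list(ops):
                for c in ((a @ b).reduced(), (b @ a).reduced()):
                    if c not in ops:
                        new.add(c)
        ops |= new
        frontier = new
        if len(ops) > 200:  # pragma: no cover - guards table typos
            raise RuntimeError("group closure exceeded any cubic group order")
    ordered = sorted(ops, key=lambda o: (not o.is_identity, o.rotation, o.translation))
    return ordered


def _compute_flags(ops: Sequence[SymmetryOperation]) -> dict[str, bool]:
    """Re-derive the attribute flags from an operator table.

    Pure rotations vs screws are distinguished by the intrinsic (screw)
    translation; threefold-axis intersection is tested geometrically on the
    fixed lines of all pure threefold operators over neighbouring cells.
    """
    has4 = any(op.rotation_order() == 4 for op in ops)
    pure2 = screw21 = screw31 = False
    axes: list[tuple[np.ndarray, np.ndarray]] = []
    for op in ops:
        n = op.rotation_order()
        if n not in (2, 3):
            continue
        intr = op.intrinsic_translation()
        pure = all(t % 1 == 0 for t in intr)
        if n == 2:
            pure2, screw21 = pure2 or pure, screw21 or not pure
        else:
            screw31 = screw31 or not pure
            if pure:
                axes.extend(_fixed_lines(op))
    intersect = False
    for (p1, d1), (p2, d2) in itertools.combinations(axes, 2):
        if abs(abs(float(d1 @ d2)) - 1.0) < 1e-9:
            continue  # parallel axes
        nvec = np.cross(d1, d2)
        if abs(float((p2 - p1) @ nvec)) / np.linalg.norm(nvec) < 1e-9:
            intersect = True
            break
    return {
        "has_fourfold_axes": has4,
        "has_pure_twofold_rotation": pure2,
        "has_21_screws": screw21,
        "threefold_axes_intersect": intersect,
        "has_31_screws": screw31,
    }


def _fixed_lines(op: SymmetryOperation) -> list[tuple[np.ndarray, np.ndarray]]:
    rot = np.asarray(op.rotation, dtype=float)
    t = np.array([float(x) for x in op.translation])
    d = np.asarray(op.rotation_axis(), dtype=float)
    d /= np.linalg.norm(d)
    lines = []
    for m in itertools.product((-1, 0, 1), repeat=3):
        rhs = -(t + np.asarray(m, dtype=float))
        x, *_ = np.linalg.lstsq(rot - np.eye(3), rhs, rcond=None)
        if np.linalg.norm((rot - np.eye(3)) @ x - rhs) < 1e-9:
            lines.append((x, d))
    return lines


def _build_table() -> dict[int, SpaceGroupRecord]:
    table = {}
    for num, gens in _GENERATORS.items():
        ops = _closure(SymmetryOperation.from_triplet(g) for g in gens)
        if len(ops) != _EXPECTED_ORDER[num]:  # pragma: no cover
            raise RuntimeError(
                f"space group {num}: closure gave {len(ops)} operators, "
                f"expected {_EXPECTED_ORDER[num]}"
            )
        if any(op.determinant() != 1 for op in ops):  # pragma: no cover
            raise RuntimeError(f"space group {num}: improper operation in table")
        symbol, centering, *flags = _ATTRIBUTES[num]
        table[num] = SpaceGroupRecord(
            num, symbol, centering, *flags, general_positions=tuple(ops)
        )
    return table


_TABLE = _build_table()


def space_group(it_number: int) -> SpaceGroupRecord:
    """Look up a tabulated Sohncke cubic space group by IT number."""
    try:
        return _TABLE[it_number]
    except KeyError:
        raise UnknownSpaceGroupError(
            f"space group {it_number} is not a tabulated Sohncke cubic group; "
            f"supported numbers: {list(SOHNCKE_CUBIC_NUMBERS)}"
        ) from None


def general_positions(it_number: int) -> list[SymmetryOperation]:
    """Centering-expanded general-position operators, identity first."""
    return list(space_group(it_number).general_positions)


_PREDICATES = {
    "has_fourfold_axes": ("has_fourfold_axes", True),
    "no_fourfold_axes": ("has_fourfold_axes", False),
    "has_pure_twofold_rotation": ("has_pure_twofold_rotation", True),
    "no_pure_twofold_rotation": ("has_pure_twofold_rotation", False),
    "has_21_screws": ("has_21_screws", True),
    "no_21_screws": ("has_21_screws", False),
    "has_31_screws": ("has_31_screws", True),
    "no_31_screws": ("has_31_screws", False),
    "threefold_axes_intersect": ("threefold_axes_intersect", True),
    "threefold_axes_do_not_intersect": ("threefold_axes_intersect", False),
}


def eliminate_space_groups(constraints: Iterable[str] = ()) -> list[SpaceGroupRecord]:
    """Filter the Sohncke cubic groups by symmetry-element predicates.

    Each constraint names an attribute state, e.g. ``"no_fourfold_axes"``,
    ``"threefold_axes_do_not_intersect"``, ``"has_pure_twofold_rotation"``.
    With no constraints all 13 groups are returned in IT-number order.
    """
    checks = []
    for name in constraints:
        if name not in _PREDICATES:
            raise ValueError(
                f"unrecognized predicate {name!r}; supported: {sorted(_PREDICATES)}"
            )
        checks.append(_PREDICATES[name])
    return [
        rec
        for num, rec in sorted(_TABLE.items())
        if all(getattr(rec, attr) is want for attr, want in checks)
    ]


def axis_angle(dir1: Sequence[float], dir2: Sequence[float]) -> float:
    """Acute angle in degrees between two lattice directions.

    The angle between the [1,1,1] threefold and a [1,0,0] twofold of a cubic
    lattice is arccos(1/sqrt(3)) = 54.74 degrees, the fixed tilt of the
    tetramer symmetry elements in the scaffolding lattice.
    """
    d1 = np.asarray(dir1, dtype=float)
    d2 = np.asarray(dir2, dtype=float)
    n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
    if n1 == 0 or n2 == 0:
        raise ValueError("lattice directions must be nonzero")
    cosang = abs(float(d1 @ d2) / (n1 * n2))
    return float(np.degrees(np.arccos(min(1.0, cosang))))


@dataclass(frozen=True)
class UnitCell:
    """Cubic unit cell (b = c = a, all angles 90 degrees)."""

    a: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("cell edge must be positive")

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) * self.a

    def to_fractional(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) / self.a
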