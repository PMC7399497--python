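"""Coordinate sets, fixed-column PDB I/O and basic molecular geometry.

The in-memory container is a flat atom table (:class:`CoordinateSet`) carrying
a per-atom scattering weight.  For all-atom input the weight defaults to the
element electron count; bead/pseudo-atom models get a uniform weight.  The
forward scattering model downstream is coarse-grained, so no solvent or
displaced-volume terms are attached here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .spacegroup import SymmetryOperation, UnitCell, apply_operation

__all__ = [
    "CoordinateSet",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "radius_of_gyration",
    "transform",
    "symmetry_distance",
]

# Electron counts for the elements found in protein/peptide models; used as
# coarse scattering weights.  Unknown elements fall back to carbon.
ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34,
    "MG": 12, "NA": 11, "K": 19, "CL": 17, "CA": 20, "ZN": 30, "FE": 26,
}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


class PDBParseError(ValueError):
    """Malformed fixed-column PDB content; message names the offending line."""


@dataclass
class CoordinateSet:
    """A flat atom table with Cartesian coordinates in Angstrom.

    ``weights`` are scattering weights (electrons for all-atom models, a
    uniform weight for bead models).  ``cell`` carries the cubic unit cell
    parsed from CRYST1 when present.
    """

    chain_ids: np.ndarray          # dtype '<U4'
    res_seq: np.ndarray            # int
    res_names: np.ndarray          # '<U4'
    atom_names: np.ndarray         # '<U4'
    coords: np.ndarray             # (n, 3) float
    weights: np.ndarray            # (n,) float
    label: str = ""
    cell: UnitCell | None = None
    icodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.coords) == 0:
            raise ValueError("empty coordinate set")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.weights <= 0):
            raise ValueError("scattering weights must be positive")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, mask: np.ndarray, label: str | None = None) -> "CoordinateSet":
        return CoordinateSet(
            chain_ids=self.chain_ids[mask],
            res_seq=self.res_seq[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            coords=self.coords[mask],
            weights=self.weights[mask],
            label=self.label if label is None else label,
            cell=self.cell,
            icodes=None if self.icodes is None else self.icodes[mask],
        )

    def without_waters(self) -> "CoordinateSet":
        mask = ~np.isin(self.res_names, list(_WATER_NAMES))
        if not mask.any():
            raise ValueError("coordinate set contains only water")
        return self.select(mask)

    def ca_only(self) -> "CoordinateSet":
        return self.select(self.atom_names == "CA")

    def with_coords(self, coords: np.ndarray) -> "CoordinateSet":
        out = replace(self)
        out.coords = np.asarray(coords, dtype=float)
        return out

    def atom_index(self, chain: str, resseq: int, atom: str = "CA") -> int:
        hits = np.flatnonzero(
            (self.chain_ids == chain) & (self.res_seq == resseq) & (self.atom_names == atom)
        )
        if len(hits) == 0:
            raise KeyError(f"no atom {atom!r} in chain {chain!r} residue {resseq}")
        return int(hits[0])

    @classmethod
    def from_points(
        cls,
        coords: np.ndarray,
        weight: float = 1.0,
        label: str = "",
        chain: str = "A",
        res_names: Sequence[str] | None = None,
        cell: UnitCell | None = None,
    ) -> "CoordinateSet":
        """Build a bead model: one pseudo-residue per point, CA pseudo-atoms."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        n = len(coords)
        return cls(
            chain_ids=np.full(n, chain, dtype="<U4"),
            res_seq=np.arange(1, n + 1),
            res_names=np.asarray(
                ["DUM"] * n if res_names is None else list(res_names), dtype="<U4"
            ),
            atom_names=np.full(n, "CA", dtype="<U4"),
            coords=coords,
            weights=np.full(n, float(weight)),
            label=label,
            cell=cell,
        )


def _element_of(atom_name: str, element_field: str) -> str:
    el = element_field.strip().upper()
    if el in ELECTRONS:
        return el
    name = atom_name.strip().upper()
    if len(name) >= 2 and name[:2] in ELECTRONS and not name[0].isdigit():
        # two-letter elements only when the name cannot be a remoteness code
        if name[:2] in {"MG", "NA", "CL", "ZN", "FE", "SE"}:
            return name[:2]
    for c in name:
        if c.isalpha():
            return c if c in ELECTRONS else "C"
    return "C"


def read_pdb(
    path,
    label: str | None = None,
    include_waters: bool = True,
    uniform_weight: float | None = None,
) -> CoordinateSet:
    """Read ATOM/HETATM records from a fixed-column PDB file.

    Altloc handling keeps the highest-occupancy conformer (first wins on a
    tie).  A CRYST1 record with a cubic cell is attached as ``cell``.
    ``uniform_weight`` overrides per-element electron weights (for bead
    models).
    """
    chains, resseqs, resnames, atomnames, icodes = [], [], [], [], []
    xyz, weights = [], []
    seen_alt: dict[tuple, tuple[float, int]] = {}
    cell = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                except ValueError as exc:
                    raise PDBParseError(f"line {lineno}: malformed CRYST1: {exc}") from None
                if abs(a - b) < 1e-3 and abs(a - c) < 1e-3:
                    cell = UnitCell(a)
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: ATOM record shorter than 54 columns")
            try:
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21].strip() or "_"
                resseq = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_str = line[54:60].strip()
                occ = float(occ_str) if occ_str else 1.0
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed fixed columns: {exc}") from None
            if altloc not in (" ", ""):
                key = (chain, resseq, icode, name)
                prev = seen_alt.get(key)
                if prev is not None:
                    if occ > prev[0]:
                        # replace the previously kept conformer in place
                        idx = prev[1]
                        xyz[idx] = (x, y, z)
                        seen_alt[key] = (occ, idx)
                    continue
                seen_alt[key] = (occ, len(xyz))
            element = _element_of(name, line[76:78] if len(line) >= 78 else "")
            chains.append(chain)
            resseqs.append(resseq)
            resnames.append(resname)
            atomnames.append(name)
            icodes.append(icode)
            xyz.append((x, y, z))
            weights.append(
                uniform_weight if uniform_weight is not None else ELECTRONS.get(element, 6)
            )
    if not xyz:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    cs = CoordinateSet(
        chain_ids=np.asarray(chains, dtype="<U4"),
        res_seq=np.asarray(resseqs, dtype=int),
        res_names=np.asarray(resnames, dtype="<U4"),
        atom_names=np.asarray(atomnames, dtype="<U4"),
        coords=np.asarray(xyz, dtype=float),
        weights=np.asarray(weights, dtype=float),
        label=label if label is not None else str(path),
        cell=cell,
        icodes=np.asarray(icodes, dtype="<U2"),
    )
    return cs if include_waters else cs.without_waters()


_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def write_pdb(
    coordsets: CoordinateSet | Iterable[CoordinateSet],
    path,
    cell: UnitCell | None = None,
    space_group: str = "I 21 3",
    one_chain_per_copy: bool = True,
) -> None:
    """Write one or more coordinate sets as a fixed-column PDB file.

    With a cell, a CRYST1 record is emitted with a cubic cell and the given
    space-group symbol.  When several copies are written, each gets its own
    chain identifier (62 available).
    """
    if isinstance(coordsets, CoordinateSet):
        coordsets = [coordsets]
    copies = list(coordsets)
    if one_chain_per_copy and len(copies) > len(_CHAIN_ALPHABET):
        raise ValueError(
            f"{len(copies)} copies exceed the {len(_CHAIN_ALPHABET)}-chain alphabet; "
            "split the assembly across several files"
        )
    lines = []
    if cell is None and copies[0].cell is not None and len(copies) == 1:
        cell = copies[0].cell
    if cell is not None:
        lines.append(
            f"CRYST1{cell.a:9.3f}{cell.a:9.3f}{cell.a:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} {space_group:<11s}"
        )
    serial = 1
    for ci, cs in enumerate(copies):
        for i in range(len(cs)):
            chain = _CHAIN_ALPHABET[ci] if one_chain_per_copy and len(copies) > 1 \
                else str(cs.chain_ids[i])[:1]
            name = str(cs.atom_names[i])
            namef = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = cs.coords[i]
            lines.append(
                f"ATOM  {min(serial, 99999):5d} {namef}{'':1s}{str(cs.res_names[i]):<3s} "
                f"{chain}{int(cs.res_seq[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def radius_of_gyration(cs: CoordinateSet) -> float:
    """Weight-averaged root-mean-square distance from the weighted centroid."""
    w = cs.weights / cs.weights.sum()
    centroid = w @ cs.coords
    d2 = ((cs.coords - centroid) ** 2).sum(axis=1)
    return float(np.sqrt(w @ d2))


def transform(
    cs: CoordinateSet, op: SymmetryOperation, cell: UnitCell
) -> CoordinateSet:
    """Apply a symmetry operation (fractional convention) to Cartesian coords."""
    frac = cell.to_fractional(cs.coords)
    return cs.with_coords(cell.to_cartesian(apply_operation(op, frac)))


def symmetry_distance(
    cs: CoordinateSet,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
    op: SymmetryOperation,
    cell: UnitCell | None = None,
) -> float:
    """Cartesian distance between atom A and the symmetry image of atom B.

    ``atom_a``/``atom_b`` are (chain, residue number, atom name).  The cell is
    required to fractionalize coordinates before applying the operation.
    """
    cell = cell or cs.cell
    if cell is None:
        raise ValueError("a unit cell is required to apply a symmetry operation")
    ia = cs.atom_index(*atom_a)
    ib = cs.atom_index(*atom_b)
    b_frac = cell.to_fractional(cs.coords[ib])
    b_img = cell.to_cartesian(apply_operation(op, b_frac)[0])
    return float(np.linalg.norm(cs.coords[ia] - b_img))
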