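"""Structure parsing and dihedral-derived quantities.

Reads RNA 3D structures (PDB / mmCIF via gemmi), resolves altlocs, detects
chain breaks, and computes the full per-residue angle table: the backbone
torsions alpha..zeta, the glycosidic angle chi (N1/C2 for pyrimidines,
N9/C4 for purines), the five ribose ring torsions nu0..nu4 with the derived
pseudorotation phase P, and the pseudo-torsions eta/theta defined over the
C4'/P trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .angles import ANGLE_NAMES, AngleTable, N_ANGLES
from .errors import EmptyStructureError, StructureParseError

#: Collinearity guard: dihedral undefined if a plane normal is shorter than this (A^2).
COLLINEAR_TOL = 1e-9

#: O3'(i-1)-P(i) distances above this (A) mark a chain break.
CHAIN_BREAK_DISTANCE = 2.5

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CU")


@dataclass
class Atom:
    """A single atom: PDB-convention name, coordinates in Angstrom."""

    name: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")


@dataclass
class Residue:
    """One nucleotide with its atoms keyed by name."""

    chain_id: str
    seq_index: int
    residue_name: str
    atoms: dict[str, Atom]
    author_number: int = 0
    parent_base: str = "N"

    @property
    def is_purine(self) -> bool:
        if self.parent_base in _PURINES:
            return True
        if self.parent_base in _PYRIMIDINES:
            return False
        return "N9" in self.atoms

    def coords(self, name: str) -> np.ndarray | None:
        atom = self.atoms.get(name)
        return None if atom is None else atom.coords


@dataclass
class StructureModel:
    """First model of a structure file: residues grouped in chain order."""

    chains: list[list[Residue]]
    source_path: str = ""
    model_number: int = 1

    @property
    def residues(self) -> list[Residue]:
        return [r for chain in self.chains for r in chain]

    def __len__(self) -> int:
        return sum(len(c) for c in self.chains)


# ---------------------------------------------------------------------------
# parsing

def parent_base(residue_name: str) -> str:
    """Parent base letter (A/C/G/U) for a residue code, N when unknown.

    Modified residues resolve through gemmi's tabulated chemical-component
    data (e.g. PSU -> U, 1MA -> A); DNA bases map to their RNA parent.
    """
    info = gemmi.find_tabulated_residue(residue_name.strip().upper())
    if info is None or not info.is_nucleic_acid():
        return "N"
    letter = info.one_letter_code.upper()
    if letter == "T":
        letter = "U"
    return letter if letter in "ACGU" else "N"


def _is_rna_like(res: gemmi.Residue) -> bool:
    """Nucleotide-like: tabulated nucleic acid, or carries ribose atoms."""
    info = gemmi.find_tabulated_residue(res.name.strip().upper())
    if info is not None:
        if info.is_water() or info.is_amino_acid():
            return False
        if info.is_nucleic_acid():
            return True
    names = {a.name for a in res}
    return "C1'" in names and ("C4'" in names or "O4'" in names)


def _resolve_altlocs(res: gemmi.Residue) -> dict[str, Atom]:
    """Keep one atom per name: highest occupancy, ties to smallest altloc."""
    best: dict[str, Atom] = {}
    for a in res:
        cand = Atom(
            name=a.name,
            coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
            altloc=a.altloc if a.altloc != "\x00" else "",
            occupancy=a.occ,
        )
        prev = best.get(a.name)
        if (
            prev is None
            or cand.occupancy > prev.occupancy
            or (cand.occupancy == prev.occupancy and cand.altloc < prev.altloc)
        ):
            best[a.name] = cand
    return best


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is kept; waters, amino acids and non-nucleotide
    ligands are dropped.  Raises :class:`StructureParseError` on unreadable
    input and :class:`EmptyStructureError` when no RNA residue survives.
    """
    path = Path(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    model = st[0]
    chains: list[list[Residue]] = []
    idx = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if not _is_rna_like(res):
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_index=idx,
                    residue_name=res.name.strip(),
                    atoms=_resolve_altlocs(res),
                    author_number=res.seqid.num,
                    parent_base=parent_base(res.name),
                )
            )
            idx += 1
        if residues:
            chains.append(residues)
    if not chains:
        raise EmptyStructureError(f"{path}: no RNA residues found")
    return StructureModel(
        chains=chains, source_path=str(path), model_number=1
    )


def extract_sequence(model: StructureModel) -> str:
    """One letter per residue in chain order, over {A, C, G, U, N}."""
    return "".join(r.parent_base for r in model.residues)


# ---------------------------------------------------------------------------
# dihedrals

def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, in (-180, +180].

    Uses the two-argument arctangent convention.  Returns NaN when a
    consecutive atom triple is collinear within :data:`COLLINEAR_TOL`.
    """
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    if any(p.shape != (3,) or not np.all(np.isfinite(p)) for p in pts):
        raise ValueError("dihedral points must be finite 3-vectors")
    b1 = pts[1] - pts[0]
    b2 = pts[2] - pts[1]
    b3 = pts[3] - pts[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < COLLINEAR_TOL or np.linalg.norm(n2) < COLLINEAR_TOL:
        return float("nan")
    b2n = np.linalg.norm(b2)
    if b2n < COLLINEAR_TOL:
        return float("nan")
    y = np.dot(np.cross(n1, n2), b2 / b2n)
    x = np.dot(n1, n2)
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


# quadruple table: angle name -> list of (residue offset, atom name)
_QUADRUPLES: dict[str, list[tuple[int, str]]] = {
    "alpha":   [(-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")],
    "beta":    [(0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")],
    "gamma":   [(0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")],
    "delta":   [(0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")],
    "epsilon": [(0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")],
    "zeta":    [(0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")],
    "nu0":     [(0, "C4'"), (0, "O4'"), (0, "C1'"), (0, "C2'")],
    "nu1":     [(0, "O4'"), (0, "C1'"), (0, "C2'"), (0, "C3'")],
    "nu2":     [(0, "C1'"), (0, "C2'"), (0, "C3'"), (0, "C4'")],
    "nu3":     [(0, "C2'"), (0, "C3'"), (0, "C4'"), (0, "O4'")],
    "nu4":     [(0, "C3'"), (0, "C4'"), (0, "O4'"), (0, "C1'")],
    "eta":     [(-1, "C4'"), (0, "P"), (0, "C4'"), (1, "P")],
    "theta":   [(0, "P"), (0, "C4'"), (1, "P"), (1, "C4'")],
}

_CHI_PYRIMIDINE = [(0, "O4'"), (0, "C1'"), (0, "N1"), (0, "C2")]
_CHI_PURINE = [(0, "O4'"), (0, "C1'"), (0, "N9"), (0, "C4")]


def _chain_breaks(chain: list[Residue]) -> list[bool]:
    """breaks[i] is True when a break separates residue i from residue i+1."""
    breaks = []
    for prev, nxt in zip(chain, chain[1:]):
        o3 = prev.coords("O3'")
        p = nxt.coords("P")
        if o3 is None or p is None:
            dist_ok = False
        else:
            dist_ok = float(np.linalg.norm(o3 - p)) <= CHAIN_BREAK_DISTANCE
        numbering_ok = nxt.author_number == prev.author_number + 1
        breaks.append(not (dist_ok and numbering_ok))
    return breaks


def extract_angles(model: StructureModel) -> AngleTable:
    """Compute all 14 angle columns (plus derived P) for a parsed model.

    Missing atoms, chain ends and chain breaks degrade individual angles to
    undefined; the call never raises for incomplete residues.
    """
    residues = model.residues
    L = len(residues)
    values = np.full((L, N_ANGLES), np.nan)

    pos = 0
    for chain in model.chains:
        breaks = _chain_breaks(chain)
        for i, res in enumerate(chain):
            neighbours = {0: res}
            if i > 0 and not breaks[i - 1]:
                neighbours[-1] = chain[i - 1]
            if i < len(chain) - 1 and not breaks[i]:
                neighbours[1] = chain[i + 1]
            for name, quad in _QUADRUPLES.items():
                values[pos + i, AngleTable.column(name)] = _quad_dihedral(
                    neighbours, quad
                )
            chi_quad = _CHI_PURINE if res.is_purine else _CHI_PYRIMIDINE
            values[pos + i, AngleTable.column("chi")] = _quad_dihedral(
                neighbours, chi_quad
            )
        pos += len(chain)

    return AngleTable(
        sequence=extract_sequence(model),
        values=values,
        chain_ids=[r.chain_id for r in residues],
        author_numbers=[r.author_number for r in residues],
    )


def _quad_dihedral(
    neighbours: dict[int, Residue], quad: list[tuple[int, str]]
) -> float:
    pts = []
    for offset, atom_name in quad:
        res = neighbours.get(offset)
        if res is None:
            return float("nan")
        xyz = res.coords(atom_name)
        if xyz is None:
            return float("nan")
        pts.append(xyz)
    return compute_dihedral(*pts)
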