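"""Synthetic backbone construction from internal coordinates.

Chains are grown atom by atom with the standard natural-extension reference
frame (NeRF): each new atom is placed from the three preceding frame atoms
using a fixed bond length, a fixed bond angle, and the requested dihedral.
Bond lengths and angles come from standard nucleic-acid geometry tables and
never vary; only torsions do.  Besides the six backbone atoms per residue
(P, O5', C5', C4', C3', O3') the builder places O4', C1', C2' with a fixed
near-C3'-endo local ribose geometry and the two chi-defining base atoms, so
that chi and the nu angles are extractable (chi honours the requested value;
the nu angles follow from the fixed sugar geometry).
"""

from __future__ import annotations

import math

import numpy as np

from .angles import AngleTable, wrap_signed
from .errors import ContractError
from .geometry import Atom, Residue, StructureModel

# bond lengths, Angstrom (standard ribonucleotide geometry)
BOND_LENGTHS = {
    ("O3'", "P"): 1.607,
    ("P", "O5'"): 1.593,
    ("O5'", "C5'"): 1.440,
    ("C5'", "C4'"): 1.510,
    ("C4'", "C3'"): 1.524,
    ("C3'", "O3'"): 1.423,
    ("C4'", "O4'"): 1.453,
    ("O4'", "C1'"): 1.414,
    ("C1'", "C2'"): 1.528,
    ("C1'", "N"): 1.470,
    ("N", "C"): 1.370,
}

# bond angles, degrees (vertex atom in the middle)
BOND_ANGLES = {
    ("C4'", "C3'", "O3'"): 110.6,
    ("C3'", "O3'", "P"): 119.7,
    ("O3'", "P", "O5'"): 104.0,
    ("P", "O5'", "C5'"): 120.9,
    ("O5'", "C5'", "C4'"): 111.5,
    ("C5'", "C4'", "C3'"): 115.5,
    ("C5'", "C4'", "O4'"): 109.2,
    ("C4'", "O4'", "C1'"): 109.7,
    ("O4'", "C1'", "C2'"): 106.1,
    ("O4'", "C1'", "N"): 108.2,
    ("C1'", "N", "C"): 126.0,
}

# A-form-like fallbacks for torsions that are requested as undefined
DEFAULT_TORSIONS = {
    "alpha": -68.0, "beta": 178.0, "gamma": 54.0, "delta": 82.0,
    "epsilon": -153.0, "zeta": -71.0, "chi": -158.0,
}

# fixed local sugar torsions (near C3'-endo pucker)
_NU4_FIXED = 20.5     # C3'-C4'-O4'-C1'
_NU0_FIXED = 3.0      # C4'-O4'-C1'-C2'
_O4_OFFSET = -121.0   # dihedral(O5',C5',C4',O4') relative to gamma
_N_OFFSET = -120.0    # dihedral(C4',O4',C1',N) placing the base nitrogen

_PURINES = frozenset("AG")


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom D so that |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(tau),
         math.sin(theta) * math.sin(tau)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def build_backbone_from_torsions(
    sequence: str, angle_spec: AngleTable
) -> StructureModel:
    """Build a single-chain model realizing the requested backbone torsions.

    ``extract_angles`` on the result reproduces the requested alpha..zeta
    (and chi) at defined positions to well under 1e-4 degrees.  Raises
    :class:`ContractError` on a sequence/angle length mismatch.
    """
    L = len(sequence)
    if L == 0:
        raise ContractError("empty sequence")
    if len(angle_spec) != L:
        raise ContractError(
            f"sequence length {L} != angle table length {len(angle_spec)}"
        )

    def torsion(i: int, name: str) -> float:
        v = angle_spec.angle_column(name)[i]
        return float(v) if np.isfinite(v) else DEFAULT_TORSIONS[name]

    residues: list[Residue] = []
    prev: dict[str, np.ndarray] | None = None
    for i, base in enumerate(sequence):
        atoms: dict[str, np.ndarray] = {}
        if prev is None:
            # seed frame for the first residue: P, O5', C5' in the xy-plane
            atoms["P"] = np.zeros(3)
            atoms["O5'"] = np.array([BOND_LENGTHS[("P", "O5'")], 0.0, 0.0])
            ang = math.radians(BOND_ANGLES[("P", "O5'", "C5'")])
            atoms["C5'"] = atoms["O5'"] + BOND_LENGTHS[("O5'", "C5'")] * np.array(
                [-math.cos(ang), math.sin(ang), 0.0]
            )
        else:
            atoms["P"] = place_atom(
                prev["C4'"], prev["C3'"], prev["O3'"],
                BOND_LENGTHS[("O3'", "P")], BOND_ANGLES[("C3'", "O3'", "P")],
                torsion(i - 1, "epsilon"),
            )
            atoms["O5'"] = place_atom(
                prev["C3'"], prev["O3'"], atoms["P"],
                BOND_LENGTHS[("P", "O5'")], BOND_ANGLES[("O3'", "P", "O5'")],
                torsion(i - 1, "zeta"),
            )
            atoms["C5'"] = place_atom(
                prev["O3'"], atoms["P"], atoms["O5'"],
                BOND_LENGTHS[("O5'", "C5'")], BOND_ANGLES[("P", "O5'", "C5'")],
                torsion(i, "alpha"),
            )
        atoms["C4'"] = place_atom(
            atoms["P"], atoms["O5'"], atoms["C5'"],
            BOND_LENGTHS[("C5'", "C4'")], BOND_ANGLES[("O5'", "C5'", "C4'")],
            torsion(i, "beta"),
        )
        atoms["C3'"] = place_atom(
            atoms["O5'"], atoms["C5'"], atoms["C4'"],
            BOND_LENGTHS[("C4'", "C3'")], BOND_ANGLES[("C5'", "C4'", "C3'")],
            torsion(i, "gamma"),
        )
        atoms["O3'"] = place_atom(
            atoms["C5'"], atoms["C4'"], atoms["C3'"],
            BOND_LENGTHS[("C3'", "O3'")], BOND_ANGLES[("C4'", "C3'", "O3'")],
            torsion(i, "delta"),
        )
        # ribose ring (fixed local pucker) and chi-defining base atoms
        atoms["O4'"] = place_atom(
            atoms["O5'"], atoms["C5'"], atoms["C4'"],
            BOND_LENGTHS[("C4'", "O4'")], BOND_ANGLES[("C5'", "C4'", "O4'")],
            wrap_signed(torsion(i, "gamma") + _O4_OFFSET),
        )
        atoms["C1'"] = place_atom(
            atoms["C3'"], atoms["C4'"], atoms["O4'"],
            BOND_LENGTHS[("O4'", "C1'")], BOND_ANGLES[("C4'", "O4'", "C1'")],
            _NU4_FIXED,
        )
        atoms["C2'"] = place_atom(
            atoms["C4'"], atoms["O4'"], atoms["C1'"],
            BOND_LENGTHS[("C1'", "C2'")], BOND_ANGLES[("O4'", "C1'", "C2'")],
            _NU0_FIXED,
        )
        n_name, c_name = ("N9", "C4") if base in _PURINES else ("N1", "C2")
        atoms[n_name] = place_atom(
            atoms["C4'"], atoms["O4'"], atoms["C1'"],
            BOND_LENGTHS[("C1'", "N")], BOND_ANGLES[("O4'", "C1'", "N")],
            _N_OFFSET,
        )
        atoms[c_name] = place_atom(
            atoms["O4'"], atoms["C1'"], atoms[n_name],
            BOND_LENGTHS[("N", "C")], BOND_ANGLES[("C1'", "N", "C")],
            torsion(i, "chi"),
        )

        residues.append(
            Residue(
                chain_id="A",
                seq_index=i,
                residue_name={"A": "A", "C": "C", "G": "G", "U": "U"}.get(base, "N"),
                atoms={k: Atom(name=k, coords=v) for k, v in atoms.items()},
                author_number=i + 1,
                parent_base=base if base in "ACGU" else "N",
            )
        )
        prev = atoms

    return StructureModel(chains=[residues], source_path="<built>")
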