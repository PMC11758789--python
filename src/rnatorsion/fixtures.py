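"""Synthetic test-data generation.

Everything the test suite consumes is generated here: random sequences,
angle tables drawn from per-angle-type circular modes, decoy ensembles with
controlled wrapped-Gaussian divergence from a native table, and PDB fixture
files realized through the internal-coordinate builder.

The mode table below is a synthetic artifact: unimodal wrapped-normal
clusters centred on A-form-helix-like values, one per angle kind.  It
reproduces the qualitative shape of real per-angle distributions (a single
dominant conformer per angle) but none of their multi-modality or
sequence dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .angles import ANGLE_NAMES, AngleTable, N_ANGLES, wrap_signed
from .build import build_backbone_from_torsions
from .errors import ContractError
from .geometry import StructureModel

#: (centre, spread) in degrees of the wrapped-normal mode per angle kind.
#: Synthetic, A-form-like values; not measured from any structure database.
ANGLE_MODES: dict[str, tuple[float, float]] = {
    "alpha": (-68.0, 20.0),
    "beta": (178.0, 15.0),
    "gamma": (54.0, 20.0),
    "delta": (82.0, 10.0),
    "epsilon": (-153.0, 20.0),
    "zeta": (-71.0, 20.0),
    "chi": (-158.0, 15.0),
    "nu0": (3.0, 5.0),
    "nu1": (-25.0, 5.0),
    "nu2": (37.0, 5.0),
    "nu3": (-36.0, 5.0),
    "nu4": (21.0, 5.0),
    "eta": (166.0, 25.0),
    "theta": (-148.0, 25.0),
}

#: angles undefined at the first / last residue of a chain
_FIRST_UNDEFINED = ("alpha", "eta")
_LAST_UNDEFINED = ("epsilon", "zeta", "theta")


@dataclass
class FixtureSpec:
    """Parameters of one generated decoy-ranking scenario."""

    seed: int = 0
    length: int = 30
    n_decoys: int = 20
    noise_scales: tuple[float, ...] = (10.0, 20.0, 40.0)
    undefined_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ContractError("length must be >= 4")
        if list(self.noise_scales) != sorted(set(self.noise_scales)):
            raise ContractError("noise_scales must be strictly increasing")
        if not 0.0 <= self.undefined_rate <= 0.5:
            raise ContractError("undefined_rate must be in [0, 0.5]")


def random_sequence(length: int, seed: int) -> str:
    """Uniform random sequence over {A, C, G, U}."""
    if length < 1:
        raise ContractError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGU"), size=length))


def sample_angle_table(
    sequence: str, seed: int, undefined_rate: float = 0.0
) -> AngleTable:
    """Draw an angle table from the per-angle-type modes.

    Each angle kind is sampled from its wrapped-normal mode; the chain-end
    undefined rules are enforced, and additional entries are knocked out
    independently at ``undefined_rate``.
    """
    if not sequence:
        raise ContractError("empty sequence")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    values = np.empty((L, N_ANGLES))
    for j, name in enumerate(ANGLE_NAMES):
        centre, spread = ANGLE_MODES[name]
        values[:, j] = wrap_signed(rng.normal(centre, spread, size=L))
    for name in _FIRST_UNDEFINED:
        values[0, AngleTable.column(name)] = np.nan
    for name in _LAST_UNDEFINED:
        values[-1, AngleTable.column(name)] = np.nan
    if undefined_rate > 0:
        knockout = rng.random((L, N_ANGLES)) < undefined_rate
        values[knockout] = np.nan
    return AngleTable(sequence=sequence, values=values)


@dataclass
class DecoyRecord:
    table: AngleTable
    noise_scale: float
    structure: StructureModel | None = None
    path: str | None = None


@dataclass
class DecoySet:
    """A native angle table plus perturbed candidates with known quality
    (the true wrapped-noise scale used to generate each decoy)."""

    native: AngleTable
    decoys: list[DecoyRecord] = field(default_factory=list)


def make_decoys(
    native: AngleTable,
    noise_scales,
    n_per_scale: int,
    seed: int,
    build_structures: bool = False,
) -> DecoySet:
    """Perturb a native table with wrapped-Gaussian noise per scale.

    Each decoy adds independent N(0, scale) noise (wrapped back into
    (-180, 180]) to every defined angle; undefined entries stay undefined.
    The generating scale is recorded as ground-truth quality.  With
    ``build_structures`` each decoy is also realized as 3D coordinates via
    the internal-coordinate builder.
    """
    if not (native.defined.any() or native.pucker_defined.any()):
        raise ContractError("native table has no defined angle")
    rng = np.random.default_rng(seed)
    out = DecoySet(native=native)
    for scale in noise_scales:
        for _ in range(n_per_scale):
            values = native.values.copy()
            defined = np.isfinite(values)
            noise = rng.normal(0.0, scale, size=values.shape)
            values[defined] = wrap_signed(values[defined] + noise[defined])
            table = AngleTable(
                sequence=native.sequence,
                values=values,
                chain_ids=list(native.chain_ids),
                author_numbers=list(native.author_numbers),
            )
            structure = None
            if build_structures:
                structure = build_backbone_from_torsions(
                    native.sequence, table
                )
            out.decoys.append(
                DecoyRecord(table=table, noise_scale=float(scale),
                            structure=structure)
            )
    return out


_ELEMENTS = {"P": "P", "O": "O", "C": "C", "N": "N"}


def write_fixture_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a built model as standard-conformant PDB ATOM records."""
    st = gemmi.Structure()
    st.name = "synthetic"
    gm = gemmi.Model("1")
    for chain_residues in model.chains:
        chain = gemmi.Chain(chain_residues[0].chain_id or "A")
        for res in chain_residues:
            gr = gemmi.Residue()
            gr.name = res.residue_name
            gr.seqid = gemmi.SeqId(res.author_number, " ")
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = 0.0
                ga.element = gemmi.Element(_ELEMENTS.get(atom.name[0], "C"))
                gr.add_atom(ga)
            chain.add_residue(gr)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def generate_decoy_directory(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, DecoySet]:
    """Write a native PDB plus one PDB per decoy under ``out_dir``.

    Returns the native file path and the in-memory decoy set (decoy records
    carry their file paths).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequence = random_sequence(spec.length, spec.seed)
    native = sample_angle_table(
        sequence, spec.seed + 1, spec.undefined_rate
    )
    n_per_scale = max(1, spec.n_decoys // max(1, len(spec.noise_scales)))
    decoy_set = make_decoys(
        native, spec.noise_scales, n_per_scale, spec.seed + 2,
        build_structures=True,
    )
    native_structure = build_backbone_from_torsions(sequence, native)
    native_path = out_dir / "native.pdb"
    write_fixture_pdb(native_structure, native_path)
    for i, rec in enumerate(decoy_set.decoys):
        rec.path = str(out_dir / f"decoy_{i:03d}.pdb")
        write_fixture_pdb(rec.structure, rec.path)
    return native_path, decoy_set
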