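"""Structure parsing, dihedral computation, pucker phase, and the
builder <-> extractor round-trip."""

import math

import numpy as np
import pytest

from rnatorsion.angles import ANGLE_NAMES, AngleTable, N_ANGLES, compute_pucker_phase
from rnatorsion.build import build_backbone_from_torsions
from rnatorsion.errors import ContractError, EmptyStructureError
from rnatorsion.fixtures import sample_angle_table, write_fixture_pdb
from rnatorsion.geometry import (
    compute_dihedral,
    extract_angles,
    extract_sequence,
    parent_base,
    read_structure,
)

from conftest import full_random_table

BACKBONE = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


def circ_err(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


def dihedral_oracle(p1, p2, p3, p4):
    """Independent brute-force dihedral: angle between plane normals with
    the sign of the triple product."""
    n1 = np.cross(p2 - p1, p3 - p2)
    n2 = np.cross(p3 - p2, p4 - p3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), p3 - p2) < 0:
        ang = -ang
    return ang


# ---------------------------------------------------------------------------
# dihedrals

@pytest.mark.parametrize("points,expected", [
    (((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)), 0.0),
    (((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)), 180.0),
])
def test_dihedral_planar_cases(points, expected):
    got = compute_dihedral(*points)
    assert circ_err(got, expected) < 1e-12
    assert -180.0 < got <= 180.0


def test_dihedral_matches_bruteforce_oracle(rng):
    for _ in range(50):
        pts = rng.normal(0, 5, (4, 3))
        got = compute_dihedral(*pts)
        want = dihedral_oracle(*pts)
        assert circ_err(got, want) < 1e-9


def test_dihedral_collinear_is_undefined():
    assert math.isnan(
        compute_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))
    )


def test_dihedral_rejects_nonfinite():
    with pytest.raises(ValueError):
        compute_dihedral((0, 0, np.nan), (1, 0, 0), (1, 1, 0), (0, 1, 0))


# ---------------------------------------------------------------------------
# pucker phase

def pucker_oracle(nus):
    num = nus[1] + nus[4] - nus[0] - nus[3]
    den = 2 * nus[2] * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
    return math.degrees(math.atan2(num, den)) % 360.0


def test_pucker_phase_matches_formula_oracle(rng):
    for _ in range(100):
        nus = rng.uniform(-60, 60, 5)
        assert abs(compute_pucker_phase(nus) - pucker_oracle(nus)) < 1e-9
    # the spec'd hand case: negative numerator and denominator
    nus = np.array([0.0, 40.0, -40.0, 40.0, -40.0])
    p = compute_pucker_phase(nus)
    assert abs(p - pucker_oracle(nus)) < 1e-9
    assert 180.0 < p < 270.0  # third quadrant: both sums negative


@pytest.mark.parametrize("nus,expected", [
    ((10.0, 20.0, 30.0, 15.0, 5.0), None),    # nu1+nu4 == nu0+nu3, nu2 > 0
    ((0.0, 30.0, 0.0, 0.0, 0.0), 90.0),       # nu2 = 0, positive numerator
    ((0.0, -30.0, 0.0, 0.0, 0.0), 270.0),     # nu2 = 0, negative numerator
])
def test_pucker_phase_quadrant_limits(nus, expected):
    if expected is None:
        assert compute_pucker_phase(np.asarray(nus)) == pytest.approx(0.0)
    else:
        assert compute_pucker_phase(np.asarray(nus)) == pytest.approx(expected)


def test_pucker_phase_degenerate_and_missing():
    assert math.isnan(compute_pucker_phase(np.zeros(5)))
    assert math.isnan(
        compute_pucker_phase(np.array([np.nan, 1.0, 2.0, 3.0, 4.0]))
    )


# ---------------------------------------------------------------------------
# builder round-trip and invariances

def test_builder_roundtrip_planar():
    L = 5
    values = np.full((L, N_ANGLES), np.nan)
    for name in BACKBONE:
        values[:, AngleTable.column(name)] = 180.0
    values[0, AngleTable.column("alpha")] = np.nan
    values[-1, AngleTable.column("epsilon")] = np.nan
    values[-1, AngleTable.column("zeta")] = np.nan
    spec = AngleTable("GACUA", values)
    got = extract_angles(build_backbone_from_torsions("GACUA", spec))
    for name in BACKBONE:
        j = AngleTable.column(name)
        mask = np.isfinite(values[:, j])
        assert np.all(circ_err(got.values[mask, j], 180.0) < 1e-4)


def test_builder_roundtrip_random_torsions(rng):
    L = 20
    seq = "".join(rng.choice(list("ACGU"), L))
    values = np.full((L, N_ANGLES), np.nan)
    for name in BACKBONE + ("chi",):
        values[:, AngleTable.column(name)] = rng.uniform(-180, 180, L)
    values[0, AngleTable.column("alpha")] = np.nan
    values[-1, AngleTable.column("epsilon")] = np.nan
    values[-1, AngleTable.column("zeta")] = np.nan
    spec = AngleTable(seq, values)
    got = extract_angles(build_backbone_from_torsions(seq, spec))
    for name in BACKBONE + ("chi",):
        j = AngleTable.column(name)
        mask = np.isfinite(values[:, j])
        assert np.max(circ_err(got.values[mask, j], values[mask, j])) < 1e-4


def test_builder_length_mismatch_is_contract_error():
    spec = full_random_table("GAC", 0)
    with pytest.raises(ContractError):
        build_backbone_from_torsions("GACU", spec)


def _random_built_model(rng, L=12):
    seq = "".join(rng.choice(list("ACGU"), L))
    table = sample_angle_table(seq, int(rng.integers(2 ** 31)))
    return build_backbone_from_torsions(seq, table)


def _transform_model(model, fn):
    for res in model.residues:
        for atom in res.atoms.values():
            atom.coords = fn(atom.coords)
    return model


def test_rigid_body_invariance(rng):
    model = _random_built_model(rng)
    before = extract_angles(model).values
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.normal(0, 50, 3)
    _transform_model(model, lambda x: q @ x + shift)
    after = extract_angles(model).values
    both = np.isfinite(before) & np.isfinite(after)
    assert np.array_equal(np.isfinite(before), np.isfinite(after))
    assert np.max(circ_err(before[both], after[both])) < 1e-6


def test_mirror_reflection_negates_dihedrals(rng):
    model = _random_built_model(rng)
    before = extract_angles(model).values
    _transform_model(model, lambda x: x * np.array([1.0, 1.0, -1.0]))
    after = extract_angles(model).values
    both = np.isfinite(before) & np.isfinite(after)
    assert np.max(circ_err(after[both], -before[both])) < 1e-6


# ---------------------------------------------------------------------------
# extraction edge rules

def test_chain_end_angles_undefined(rng):
    model = _random_built_model(rng, L=6)
    table = extract_angles(model)
    for name in ("alpha", "eta"):
        assert not table.defined[0, AngleTable.column(name)]
    for name in ("epsilon", "zeta", "theta"):
        assert not table.defined[-1, AngleTable.column(name)]


def test_missing_o4_degrades_to_undefined(rng):
    model = _random_built_model(rng, L=5)
    del model.chains[0][2].atoms["O4'"]
    table = extract_angles(model)
    for name in ("nu0", "nu1", "nu3", "nu4", "chi"):
        assert not table.defined[2, AngleTable.column(name)]
    assert not table.pucker_defined[2]
    assert table.defined[2, AngleTable.column("beta")]


def test_chain_break_undefines_cross_residue_angles(rng):
    model = _random_built_model(rng, L=8)
    # move the second half far away: O3'(3)-P(4) >> 2.5 A
    for res in model.chains[0][4:]:
        for atom in res.atoms.values():
            atom.coords = atom.coords + np.array([500.0, 0.0, 0.0])
    table = extract_angles(model)
    for name, pos in (("epsilon", 3), ("zeta", 3), ("theta", 3),
                      ("alpha", 4), ("eta", 4)):
        assert not table.defined[pos, AngleTable.column(name)], name
    # angles away from the break survive
    assert table.defined[2, AngleTable.column("epsilon")]
    assert table.defined[5, AngleTable.column("alpha")]


def test_numbering_gap_is_a_break(rng):
    model = _random_built_model(rng, L=6)
    for res in model.chains[0][3:]:
        res.author_number += 10
    table = extract_angles(model)
    assert not table.defined[3, AngleTable.column("alpha")]
    assert not table.defined[2, AngleTable.column("epsilon")]


# ---------------------------------------------------------------------------
# parsing

def test_read_structure_roundtrips_fixture(tmp_path, rng):
    model = _random_built_model(rng, L=3)
    path = tmp_path / "tiny.pdb"
    write_fixture_pdb(model, path)
    back = read_structure(path, format="pdb")
    assert len(back) == 3
    assert extract_sequence(back) == extract_sequence(model)


def test_multi_model_file_keeps_first(tmp_path, rng):
    model = _random_built_model(rng, L=3)
    path = tmp_path / "m.pdb"
    write_fixture_pdb(model, path)
    body = path.read_text().replace("END\n", "")
    atoms = "".join(l + "\n" for l in body.splitlines()
                    if l.startswith(("ATOM", "TER")))
    path.write_text(f"MODEL        1\n{atoms}ENDMDL\n"
                    f"MODEL        2\n{atoms}ENDMDL\nEND\n")
    back = read_structure(path)
    assert back.model_number == 1
    assert len(back) == 3


def test_protein_only_file_is_empty_structure(tmp_path):
    path = tmp_path / "prot.pdb"
    path.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    with pytest.raises(EmptyStructureError):
        read_structure(path)


def test_altloc_keeps_highest_occupancy_then_smallest_code(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(
        "ATOM      1  P  A  G A   1       0.000   0.000   0.000  0.30  0.00           P\n"
        "ATOM      2  P  B  G A   1       9.000   0.000   0.000  0.70  0.00           P\n"
        "ATOM      3  C1'A  G A   1       1.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      4  C1'B  G A   1       8.000   0.000   0.000  0.50  0.00           C\n"
        "END\n"
    )
    model = read_structure(path)
    res = model.residues[0]
    assert res.atoms["P"].coords[0] == pytest.approx(9.0)    # occupancy wins
    assert res.atoms["C1'"].coords[0] == pytest.approx(1.0)  # tie -> altloc A


def test_sequence_mapping():
    assert parent_base("G") == "G"
    assert parent_base("PSU") == "U"   # pseudouridine -> parent base
    assert parent_base("DT") == "U"    # thymine treated as U
    assert parent_base("XYZ") == "N"


def test_tsv_round_trip(rng):
    seq = "".join(rng.choice(list("ACGU"), 7))
    table = sample_angle_table(seq, 5, undefined_rate=0.2)
    import io

    buf = io.StringIO()
    table.to_tsv(buf)
    buf.seek(0)
    back = AngleTable.from_tsv(buf)
    assert back.sequence == table.sequence
    assert np.array_equal(back.defined, table.defined)
    both = table.defined
    assert np.max(np.abs(back.values[both] - table.values[both])) < 1e-3
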