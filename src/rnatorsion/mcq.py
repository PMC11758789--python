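"""Mean of circular quantities (MCQ) between two angle tables.

The MCQ measures the deviation between two structures of the same RNA in
angle space, without any superposition.  Over the torsion set
T = {alpha, beta, gamma, delta, epsilon, zeta, P, chi} (or the
pseudo-torsion set PT = {eta, theta}) it is the circular mean of per-angle
deviations Delta:

    MCQ(S, S') = atan2( sum_i sum_j sin Delta_ij, sum_i sum_j cos Delta_ij )

with the case analysis for undefined angles: Delta = 0 when both sides are
undefined, Delta = 180 deg when exactly one side is undefined, and otherwise
the wrap-around minimum min(diff, 360 - diff).  Since every Delta lies in
[0, 180], the sine sum is nonnegative and the result lands in [0, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .angles import AngleTable, PSEUDO_TORSION_SET, TORSION_SET
from .errors import AlignmentError, NoOverlapError


def wrap_mod(t: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees into [0, 360); idempotent."""
    out = np.mod(np.asarray(t, dtype=float), 360.0)
    # mod of a tiny negative number can round up to exactly 360.0
    out = np.where(out >= 360.0, 0.0, out)
    if np.ndim(t) == 0:
        return float(out)
    return out


def circ_diff(t: float | None, t_prime: float | None) -> float:
    """Deviation Delta between two angles in degrees, in [0, 180].

    NaN/None stand for "undefined": both undefined -> 0, exactly one
    undefined -> 180, otherwise the minimal circular difference.
    """
    t_def = t is not None and math.isfinite(t)
    tp_def = t_prime is not None and math.isfinite(t_prime)
    if not t_def and not tp_def:
        return 0.0
    if t_def != tp_def:
        return 180.0
    diff = abs(wrap_mod(t) - wrap_mod(t_prime))
    return min(diff, 360.0 - diff)


@dataclass
class DeviationSummary:
    """MCQ of a structure pair: the total, per-angle-type break-down, and
    book-keeping on how many angle pairs fell into each defined/undefined
    branch of the case analysis."""

    mcq_total: float
    per_angle: dict[str, float]
    residue_count_r: int
    pair_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)


def _delta_matrix(
    reference: AngleTable, candidate: AngleTable, angle_set: tuple[str, ...]
) -> tuple[np.ndarray, dict[str, tuple[int, int, int]], int]:
    """(r, |set|) matrix of Delta values over the positional overlap."""
    r = min(len(reference), len(candidate))
    if r < 1:
        raise NoOverlapError("no aligned residues")
    for i, (a, b) in enumerate(
        zip(reference.sequence[:r], candidate.sequence[:r])
    ):
        if a != b and "N" not in (a, b):
            raise AlignmentError(
                f"sequence mismatch at position {i}: {a!r} vs {b!r}"
            )
    deltas = np.empty((r, len(angle_set)))
    counts: dict[str, tuple[int, int, int]] = {}
    for j, name in enumerate(angle_set):
        ref = reference.angle_column(name)[:r]
        cand = candidate.angle_column(name)[:r]
        ref_def = np.isfinite(ref)
        cand_def = np.isfinite(cand)
        both = ref_def & cand_def
        one = ref_def ^ cand_def
        col = np.zeros(r)
        col[one] = 180.0
        diff = np.abs(wrap_mod(ref[both]) - wrap_mod(cand[both]))
        col[both] = np.minimum(diff, 360.0 - diff)
        deltas[:, j] = col
        counts[name] = (
            int(both.sum()), int(one.sum()), int(r - both.sum() - one.sum())
        )
    return deltas, counts, r


def _circular_mean_of_deltas(deltas: np.ndarray) -> float:
    """atan2(sum sin, sum cos) of deviations, in degrees on [0, 180]."""
    rad = np.radians(deltas)
    s = float(np.sin(rad).sum())
    c = float(np.cos(rad).sum())
    angle = math.degrees(math.atan2(s, c))
    return angle % 360.0 if angle < 0 else angle


def mcq(
    reference: AngleTable,
    candidate: AngleTable,
    angle_set: tuple[str, ...] = TORSION_SET,
) -> DeviationSummary:
    """Total and per-angle-type MCQ between two aligned angle tables.

    Tables are aligned positionally on the 0-based index; sequences must
    agree over the overlap (N matches anything).  The pucker phase enters T
    as a single angle type; both-undefined pairs contribute Delta = 0 to the
    sums rather than being skipped.
    """
    deltas, counts, r = _delta_matrix(reference, candidate, angle_set)
    per_angle = {
        name: _circular_mean_of_deltas(deltas[:, j])
        for j, name in enumerate(angle_set)
    }
    return DeviationSummary(
        mcq_total=_circular_mean_of_deltas(deltas),
        per_angle=per_angle,
        residue_count_r=r,
        pair_counts=counts,
    )


def mcq_pt(reference: AngleTable, candidate: AngleTable) -> DeviationSummary:
    """MCQ restricted to the pseudo-torsion set PT = {eta, theta}."""
    return mcq(reference, candidate, PSEUDO_TORSION_SET)


def mcq_per_residue(
    reference: AngleTable,
    candidate: AngleTable,
    angle_set: tuple[str, ...] = TORSION_SET,
) -> np.ndarray:
    """Circular mean of Delta over the angle set, one value per residue."""
    deltas, _, r = _delta_matrix(reference, candidate, angle_set)
    return np.array(
        [_circular_mean_of_deltas(deltas[i]) for i in range(r)]
    )


def resolve_angle_set(label: str) -> tuple[str, ...]:
    """Map a user-facing label (``"T"`` or ``"PT"``) to an angle set."""
    label = label.upper()
    if label == "T":
        return TORSION_SET
    if label == "PT":
        return PSEUDO_TORSION_SET
    raise ValueError(f"unknown angle set {label!r}; expected 'T' or 'PT'")
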