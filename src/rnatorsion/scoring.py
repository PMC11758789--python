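"""Reference-free TB-MCQ scoring of RNA 3D structures.

A candidate structure is scored without any native reference: its sequence
and torsion angles are extracted, the sequence-based regressor predicts the
angles the sequence "should" have, and the score is the MCQ between the
predicted and the extracted angle tables.  Lower is better.  With an oracle
predictor that returns the native structure's own angles, the score
degenerates exactly to the reference-based MCQ — which is the design premise
of the approach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .angles import AngleTable, TORSION_SET
from .errors import NoOverlapError, TorsionError
from .geometry import StructureModel, extract_angles, extract_sequence
from .mcq import mcq

logger = logging.getLogger(__name__)

#: file suffixes tried when scanning a decoy directory
_STRUCTURE_SUFFIXES = {".pdb", ".ent", ".cif", ".mmcif"}


@dataclass
class StructureScore:
    tb_mcq: float
    per_angle: dict[str, float]
    sequence_length: int
    source: str


class OraclePredictor:
    """Stand-in predictor returning a fixed (e.g. native) angle table.

    Used for testing the degeneracy property and for oracle-mode scoring
    against a known native structure; it mimics the ``predict`` interface of
    :class:`~rnatorsion.model.TorsionPredictor`.
    """

    def __init__(self, table: AngleTable):
        self.table = table

    def predict(self, sequence: str, crop: bool = True) -> AngleTable:
        return self.table


def score_structure(
    predictor,
    structure: StructureModel,
    angle_set: tuple[str, ...] = TORSION_SET,
) -> StructureScore:
    """TB-MCQ of one structure: MCQ(predicted angles, extracted angles).

    ``predictor`` is anything exposing ``predict(sequence) -> AngleTable``.
    Raises :class:`NoOverlapError` when the structure yields no defined
    angle at all.
    """
    sequence = extract_sequence(structure)
    extracted = extract_angles(structure)
    if not (extracted.defined.any() or extracted.pucker_defined.any()):
        raise NoOverlapError(
            f"{structure.source_path}: no defined angle in structure"
        )
    predicted = predictor.predict(sequence)
    # positional alignment: restrict to the (possibly cropped) prediction
    summary = mcq(predicted, extracted, angle_set)
    return StructureScore(
        tb_mcq=summary.mcq_total,
        per_angle=summary.per_angle,
        sequence_length=len(sequence),
        source=structure.source_path,
    )


def score_decoy_set(
    predictor,
    decoy_dir: str | Path,
    angle_set: tuple[str, ...] = TORSION_SET,
) -> tuple[pd.DataFrame, list[str]]:
    """Score every parseable structure in a directory.

    Returns a table with one row per decoy sorted ascending by TB-MCQ
    (best first) and the list of skipped files.  The sequence-based
    prediction is computed once per unique sequence and reused.
    """
    from .geometry import read_structure

    decoy_dir = Path(decoy_dir)
    paths = sorted(
        p for p in decoy_dir.iterdir()
        if p.suffix.lower() in _STRUCTURE_SUFFIXES
    )
    prediction_cache: dict[str, AngleTable] = {}

    class _CachingPredictor:
        def predict(self, sequence: str, crop: bool = True) -> AngleTable:
            if sequence not in prediction_cache:
                prediction_cache[sequence] = predictor.predict(sequence)
            return prediction_cache[sequence]

    caching = _CachingPredictor()
    rows = []
    skipped: list[str] = []
    for path in paths:
        try:
            structure = read_structure(path)
            score = score_structure(caching, structure, angle_set)
        except TorsionError as exc:
            logger.warning("skipping %s: %s", path, exc)
            skipped.append(str(path))
            continue
        rows.append({
            "path": str(path),
            "tb_mcq": score.tb_mcq,
            "sequence_length": score.sequence_length,
            **{f"mcq_{k}": v for k, v in score.per_angle.items()},
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("tb_mcq", kind="stable").reset_index(drop=True)
    return df, skipped
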