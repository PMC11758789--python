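"""Scoring-function evaluation over decoy sets: Pearson correlation and
enrichment score.

Both statistics relate a scoring function (energies E_n, lower = better) to
a quality metric (R_n, lower = better) over N decoys of one target:

* PCC — the Pearson product-moment correlation between raw energies and raw
  metric values.
* ES — 100 * |E_top10% ∩ R_top10%| / N: the overlap between the best 10% of
  decoys by energy and by metric.  10 is perfect agreement, an independent
  random scoring function averages 1, below 1 is worse than random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError


def pcc(energies, metrics) -> float:
    """Pearson correlation of raw energy and metric values.

    Raises :class:`DegenerateInputError` for N < 2 or a zero-variance
    vector.
    """
    e = np.asarray(energies, dtype=float)
    r = np.asarray(metrics, dtype=float)
    if e.shape != r.shape or e.ndim != 1:
        raise ContractError("energies and metrics must be equal-length vectors")
    if len(e) < 2:
        raise DegenerateInputError("PCC needs at least two decoys")
    de = e - e.mean()
    dr = r - r.mean()
    denom = np.sqrt((de ** 2).sum() * (dr ** 2).sum())
    if denom == 0.0:
        raise DegenerateInputError("PCC undefined: zero variance input")
    return float((de * dr).sum() / denom)


def top_fraction_indices(values, fraction: float) -> np.ndarray:
    """Indices of the floor(fraction * N) lowest values; ties broken by
    stable input order."""
    values = np.asarray(values, dtype=float)
    n_top = int(np.floor(fraction * len(values)))
    order = np.argsort(values, kind="stable")
    return order[:n_top]


def enrichment_score(energies, metrics, fraction: float = 0.10) -> float:
    """ES = 100 * |top-fraction by energy ∩ top-fraction by metric| / N."""
    e = np.asarray(energies, dtype=float)
    r = np.asarray(metrics, dtype=float)
    if e.shape != r.shape or e.ndim != 1:
        raise ContractError("energies and metrics must be equal-length vectors")
    n = len(e)
    if fraction <= 0 or fraction > 1:
        raise ContractError(f"fraction {fraction} not in (0, 1]")
    if n < 1.0 / fraction:
        raise ContractError(
            f"need at least {int(np.ceil(1.0 / fraction))} decoys for "
            f"fraction={fraction}; got {n}"
        )
    top_e = set(top_fraction_indices(e, fraction).tolist())
    top_r = set(top_fraction_indices(r, fraction).tolist())
    return 100.0 * len(top_e & top_r) / n


@dataclass
class DecoyEvaluation:
    """PCC and ES of a scoring function against a metric on one decoy set."""

    energies: np.ndarray
    metrics: np.ndarray
    pcc: float
    es: float
    n_decoys: int
    dropped: list[str] = field(default_factory=list)


def evaluate(
    scores: pd.DataFrame,
    metrics: pd.DataFrame,
    join_key: str = "path",
    score_column: str = "tb_mcq",
    metric_column: str = "mcq",
    fraction: float = 0.10,
) -> DecoyEvaluation:
    """Inner-join score and metric tables on ``join_key`` and compute
    PCC and ES; unmatched rows are reported in ``dropped``."""
    joined = scores.merge(metrics, on=join_key, how="inner")
    if len(joined) < 2:
        raise ContractError(
            f"need at least 2 joined rows; got {len(joined)}"
        )
    all_keys = set(scores[join_key]) | set(metrics[join_key])
    dropped = sorted(all_keys - set(joined[join_key]))
    e = joined[score_column].to_numpy(dtype=float)
    r = joined[metric_column].to_numpy(dtype=float)
    return DecoyEvaluation(
        energies=e,
        metrics=r,
        pcc=pcc(e, r),
        es=enrichment_score(e, r, fraction),
        n_decoys=len(joined),
        dropped=dropped,
    )
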