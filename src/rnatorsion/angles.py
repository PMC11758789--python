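"""Per-residue angle tables.

The central container is :class:`AngleTable`: for each residue of a chain it
holds the six backbone torsions (alpha..zeta), the glycosidic angle chi, the
five endocyclic ribose torsions nu0..nu4, the two pseudo-torsions eta/theta,
and the derived sugar-pucker pseudorotation phase P.  All torsions live in
(-180, +180] degrees; P lives in [0, 360) by crystallographic convention.
Undefined entries are stored as NaN.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of the 14 directly measured angle kinds.
ANGLE_NAMES: tuple[str, ...] = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi",
    "nu0", "nu1", "nu2", "nu3", "nu4", "eta", "theta",
)

N_ANGLES = len(ANGLE_NAMES)

#: Torsion-angle set T used by the MCQ metric (P is the derived pucker phase).
TORSION_SET: tuple[str, ...] = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "P", "chi",
)
#: Pseudo-torsion set PT.
PSEUDO_TORSION_SET: tuple[str, ...] = ("eta", "theta")

_SIN36_SIN72 = math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))


def wrap_signed(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Map angles (degrees) into the canonical (-180, +180] interval."""
    a = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    # mod can return -0.0 / values equal to -180 via rounding
    a = np.where(a <= -180.0, a + 360.0, a)
    if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0:
        return float(a)
    return a


def compute_pucker_phase(nus: np.ndarray, tol: float = 1e-9) -> float:
    """Pseudorotation phase P from the five ribose ring torsions, degrees.

    P = atan2(nu1 + nu4 - nu0 - nu3, 2 * nu2 * (sin 36 + sin 72)), mapped to
    [0, 360).  Returns NaN if any nu is undefined or both numerator and
    denominator vanish.
    """
    nus = np.asarray(nus, dtype=float)
    if nus.shape != (5,) or not np.all(np.isfinite(nus)):
        return float("nan")
    num = nus[1] + nus[4] - nus[0] - nus[3]
    den = 2.0 * nus[2] * _SIN36_SIN72
    if abs(num) < tol and abs(den) < tol:
        return float("nan")
    return math.degrees(math.atan2(num, den)) % 360.0


@dataclass
class AngleTable:
    """Angles for one chain (or one concatenated structure), L residues.

    ``values`` is an (L, 14) array ordered as :data:`ANGLE_NAMES`, NaN where
    undefined.  ``pucker_P`` is derived from nu0..nu4 and kept separately
    because it lives on [0, 360).
    """

    sequence: str
    values: np.ndarray
    chain_ids: list[str] = field(default_factory=list)
    author_numbers: list[int] = field(default_factory=list)
    pucker_P: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        L = len(self.sequence)
        if self.values.shape != (L, N_ANGLES):
            raise ValueError(
                f"values shape {self.values.shape} != ({L}, {N_ANGLES})"
            )
        if not self.chain_ids:
            self.chain_ids = ["A"] * L
        if not self.author_numbers:
            self.author_numbers = list(range(1, L + 1))
        if self.pucker_P is None:
            self.pucker_P = self._derive_pucker()
        else:
            self.pucker_P = np.asarray(self.pucker_P, dtype=float)

    def _derive_pucker(self) -> np.ndarray:
        nu_block = self.values[:, self.column("nu0"): self.column("nu4") + 1]
        return np.array([compute_pucker_phase(row) for row in nu_block])

    # -- accessors ---------------------------------------------------------
    @staticmethod
    def column(name: str) -> int:
        return ANGLE_NAMES.index(name)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def defined(self) -> np.ndarray:
        """(L, 14) boolean mask of defined angles."""
        return np.isfinite(self.values)

    @property
    def pucker_defined(self) -> np.ndarray:
        return np.isfinite(self.pucker_P)

    def angle_column(self, name: str) -> np.ndarray:
        """Values of one angle kind; ``"P"`` returns the pucker phase."""
        if name == "P":
            return self.pucker_P
        return self.values[:, self.column(name)]

    def copy(self) -> "AngleTable":
        return AngleTable(
            sequence=self.sequence,
            values=self.values.copy(),
            chain_ids=list(self.chain_ids),
            author_numbers=list(self.author_numbers),
            pucker_P=self.pucker_P.copy(),
        )

    # -- TSV dialect -------------------------------------------------------
    _TSV_COLUMNS = (
        ["chain", "resi_author", "resi_0based", "base"]
        + list(ANGLE_NAMES[:7]) + list(ANGLE_NAMES[7:12]) + ["P"]
        + list(ANGLE_NAMES[12:])
    )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chain": self.chain_ids,
            "resi_author": self.author_numbers,
            "resi_0based": np.arange(len(self)),
            "base": list(self.sequence),
        })
        for name in ANGLE_NAMES[:12]:
            df[name] = self.values[:, self.column(name)]
        df["P"] = self.pucker_P
        for name in ANGLE_NAMES[12:]:
            df[name] = self.values[:, self.column(name)]
        return df

    def to_tsv(self, path_or_buf, header_comment: str | None = None) -> None:
        """Write the table in the TSV dialect; NaN is written as ``NA``."""
        df = self.to_frame()
        text = df.to_csv(sep="\t", index=False, na_rep="NA",
                         float_format="%.4f")
        if header_comment:
            text = f"# {header_comment}\n{text}"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "AngleTable":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        df = pd.read_csv(io.StringIO(text), sep="\t", comment="#",
                         na_values=["NA"])
        values = np.column_stack(
            [df[name].to_numpy(dtype=float) for name in ANGLE_NAMES]
        )
        return cls(
            sequence="".join(df["base"].astype(str)),
            values=values,
            chain_ids=[str(c) for c in df["chain"]],
            author_numbers=[int(i) for i in df["resi_author"]],
            pucker_P=df["P"].to_numpy(dtype=float),
        )
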