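"""Sequence-based torsion-angle regression.

An RNA sequence is converted to DNA alphabet (U -> T), tokenized into
overlapping k-mers (with a leading CLS token), and fed to a transformer
encoder.  A regression head — layer normalization, a linear layer from the
hidden size to 1024, a GELU, a linear layer down to 28, and a final Tanh —
emits, per nucleotide, a sine and a cosine for each of the 14 angle kinds
(alpha, beta, gamma, delta, epsilon, zeta, chi, nu0..nu4, eta, theta).  The
pucker phase P is not predicted directly; it is derived from the decoded
ribose ring angles.  Angles are recovered from the (sin, cos) pairs with the
two-argument arctangent, which removes the periodicity problem from the
regression target.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .angles import ANGLE_NAMES, AngleTable, N_ANGLES
from .errors import ContractError, DegenerateInputError
from .nn import Adam, TransformerEncoder, gelu, gelu_grad, layernorm_forward, \
    layernorm_backward, linear_forward, linear_backward

MAX_NUCLEOTIDES = 512

_SPECIAL_TOKENS = ("[PAD]", "[CLS]", "[UNK]")
PAD_ID, CLS_ID, UNK_ID = 0, 1, 2


def kmer_vocabulary(k: int) -> dict[str, int]:
    """Token vocabulary: 3 special tokens then all 4^k DNA k-mers."""
    vocab = {tok: i for i, tok in enumerate(_SPECIAL_TOKENS)}
    for i, kmer in enumerate(itertools.product("ACGT", repeat=k)):
        vocab["".join(kmer)] = len(_SPECIAL_TOKENS) + i
    return vocab


@dataclass
class TokenizedSequence:
    raw_sequence: str
    dna_sequence: str
    tokens: np.ndarray
    kmer_k: int

    @property
    def content_token_count(self) -> int:
        return len(self.raw_sequence) - self.kmer_k + 1


def preprocess_sequence(
    seq: str, k: int = 3, crop: bool = True,
    max_nt: int = MAX_NUCLEOTIDES,
) -> TokenizedSequence:
    """U->T conversion, optional cropping to ``max_nt``, k-mer tokenization.

    Overlapping k-mers are emitted left to right; a CLS token is prepended.
    K-mers containing a non-ACGT letter map to the unknown-token id.
    """
    seq = seq.strip().upper()
    if any(c not in "ACGUTN" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGUTN"})
        raise ContractError(f"invalid nucleotide(s) {bad} in sequence")
    if len(seq) > max_nt:
        if not crop:
            raise ContractError(
                f"sequence length {len(seq)} exceeds the {max_nt}-nt limit"
            )
        seq = seq[:max_nt]
    if len(seq) < k:
        raise ContractError(f"sequence length {len(seq)} < k={k}")
    dna = seq.replace("U", "T")
    vocab = kmer_vocabulary(k)
    tokens = [CLS_ID] + [
        vocab.get(dna[i: i + k], UNK_ID) for i in range(len(dna) - k + 1)
    ]
    return TokenizedSequence(
        raw_sequence=seq, dna_sequence=dna,
        tokens=np.asarray(tokens, dtype=np.int64), kmer_k=k,
    )


# ---------------------------------------------------------------------------
# sin/cos codec

@dataclass
class SinCosTensor:
    """(L, 28) matrix of (sin, cos) pairs in angle-kind order, with an
    (L, 14) mask marking defined targets."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        L = self.values.shape[0]
        if self.values.shape != (L, 2 * N_ANGLES) or self.mask.shape != (L, N_ANGLES):
            raise ValueError("SinCosTensor shape mismatch")

    @property
    def component_mask(self) -> np.ndarray:
        """Mask expanded to the 28 (sin, cos) components."""
        return np.repeat(self.mask, 2, axis=1)


def encode_angles(table: AngleTable) -> SinCosTensor:
    """Defined angles become exact (sin, cos) pairs; undefined become zeros
    with a false mask."""
    rad = np.radians(table.values)
    mask = table.defined
    values = np.zeros((len(table), 2 * N_ANGLES))
    values[:, 0::2] = np.where(mask, np.sin(rad), 0.0)
    values[:, 1::2] = np.where(mask, np.cos(rad), 0.0)
    return SinCosTensor(values=values, mask=mask)


def decode_angles(t: SinCosTensor, sequence: str) -> AngleTable:
    """Angles from (sin, cos) pairs via atan2, mapped to (-180, +180].

    The two-argument form is scale invariant, so unnormalized predictions
    decode correctly.  An exact (0, 0) pair — and any mask-false entry —
    decodes to undefined.  P is derived from the decoded nu angles.
    """
    s = t.values[:, 0::2]
    c = t.values[:, 1::2]
    angles = np.degrees(np.arctan2(s, c))
    angles = np.where(angles <= -180.0, angles + 360.0, angles)
    undefined = (~t.mask) | ((s == 0.0) & (c == 0.0))
    angles = np.where(undefined, np.nan, angles)
    return AngleTable(sequence=sequence, values=angles)


def map_tokens_to_nucleotides(
    token_outputs: np.ndarray, L: int, k: int
) -> np.ndarray:
    """Assign the output of the k-mer token starting at nucleotide i to the
    central nucleotide i + floor((k-1)/2); uncovered edge positions copy the
    nearest assigned prediction."""
    n_tok = token_outputs.shape[0]
    if n_tok != L - k + 1:
        raise ContractError(
            f"expected {L - k + 1} token outputs for L={L}, k={k}; got {n_tok}"
        )
    if k == 1:
        return token_outputs
    lead = (k - 1) // 2
    out = np.empty((L, token_outputs.shape[1]))
    out[lead: lead + n_tok] = token_outputs
    out[:lead] = token_outputs[0]
    out[lead + n_tok:] = token_outputs[-1]
    return out


def masked_circular_loss(
    pred: SinCosTensor, target: SinCosTensor
) -> float:
    """Mean squared error over (sin, cos) components at mask-true targets."""
    if pred.values.shape != target.values.shape:
        raise ContractError("prediction/target shape mismatch")
    m = target.component_mask
    if not m.any():
        raise DegenerateInputError("loss undefined: no defined target angle")
    diff = pred.values[m] - target.values[m]
    return float(np.mean(diff ** 2))


# ---------------------------------------------------------------------------
# model

@dataclass
class ModelConfig:
    """Hyperparameters of the angle regressor.

    Defaults mirror the reference architecture (hidden 768, head 1024,
    28 outputs, 512-token limit, 3-mers); encoder depth/heads default to a
    desk-scale setting and may be raised or shrunk freely.
    """

    kmer_k: int = 3
    hidden_size: int = 768
    head_hidden: int = 1024
    n_outputs: int = 2 * N_ANGLES
    max_tokens: int = MAX_NUCLEOTIDES
    encoder_depth: int = 2
    encoder_heads: int = 4
    seed: int = 0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_outputs != 2 * N_ANGLES:
            raise ValueError(f"n_outputs must be {2 * N_ANGLES}")


class TorsionPredictor:
    """Transformer encoder + regression head mapping sequence to angles."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.vocab = kmer_vocabulary(cfg.kmer_k)
        self.encoder = TransformerEncoder(
            vocab_size=len(self.vocab), hidden=cfg.hidden_size,
            depth=cfg.encoder_depth, n_heads=cfg.encoder_heads,
            max_tokens=cfg.max_tokens, rng=rng,
        )
        add = self.encoder.store.add
        add("head.ln_g", np.ones(cfg.hidden_size))
        add("head.ln_b", np.zeros(cfg.hidden_size))
        add("head.W1", rng.normal(0, 0.02, (cfg.hidden_size, cfg.head_hidden)))
        add("head.b1", np.zeros(cfg.head_hidden))
        add("head.W2", rng.normal(0, 0.02, (cfg.head_hidden, cfg.n_outputs)))
        add("head.b2", np.zeros(cfg.n_outputs))
        self.store = self.encoder.store

    # -- forward / backward ------------------------------------------------
    def forward(self, tokenized: TokenizedSequence, with_cache: bool = False):
        """Per-nucleotide-token (sin, cos) outputs in [-1, 1]: shape
        (content_token_count, 28).  Special tokens are excluded."""
        cfg = self.config
        if tokenized.kmer_k != cfg.kmer_k:
            raise ContractError(
                f"tokenized with k={tokenized.kmer_k}, model uses k={cfg.kmer_k}"
            )
        if len(tokenized.tokens) > cfg.max_tokens:
            raise ContractError(
                f"{len(tokenized.tokens)} tokens exceeds max_tokens={cfg.max_tokens}"
            )
        P = self.store.params
        hidden, enc_cache = self.encoder.forward(tokenized.tokens)
        h_ln, c_ln = layernorm_forward(hidden, P["head.ln_g"], P["head.ln_b"])
        z1, c_l1 = linear_forward(h_ln, P["head.W1"], P["head.b1"])
        a1 = gelu(z1)
        z2, c_l2 = linear_forward(a1, P["head.W2"], P["head.b2"])
        out_all = np.tanh(z2)
        out = out_all[1:]  # drop CLS
        if not with_cache:
            return out
        return out, (enc_cache, c_ln, c_l1, z1, c_l2, out_all)

    def backward(self, d_out: np.ndarray, cache) -> None:
        """Accumulate parameter gradients given d(loss)/d(content outputs)."""
        enc_cache, c_ln, c_l1, z1, c_l2, out_all = cache
        acc = self.store.accumulate
        dz2 = np.zeros_like(out_all)
        dz2[1:] = d_out
        dz2 *= 1.0 - out_all ** 2  # tanh'
        da1, dW2, db2 = linear_backward(dz2, c_l2)
        acc("head.W2", dW2)
        acc("head.b2", db2)
        dz1 = da1 * gelu_grad(z1)
        dh_ln, dW1, db1 = linear_backward(dz1, c_l1)
        acc("head.W1", dW1)
        acc("head.b1", db1)
        dhidden, dg, db = layernorm_backward(dh_ln, c_ln)
        acc("head.ln_g", dg)
        acc("head.ln_b", db)
        self.encoder.backward(dhidden, enc_cache)

    # -- prediction --------------------------------------------------------
    def predict(self, sequence: str, crop: bool = True) -> AngleTable:
        """Full pipeline: tokenize, forward, map token outputs to
        nucleotides, decode to an angle table (P derived from the nus)."""
        tok = preprocess_sequence(
            sequence, self.config.kmer_k, crop=crop,
            max_nt=min(MAX_NUCLEOTIDES, self.config.max_tokens - 1),
        )
        token_out = self.forward(tok)
        L = len(tok.raw_sequence)
        per_nt = map_tokens_to_nucleotides(token_out, L, tok.kmer_k)
        tensor = SinCosTensor(
            values=per_nt, mask=np.ones((L, N_ANGLES), dtype=bool)
        )
        return decode_angles(tensor, tok.raw_sequence)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"param:{k}": v for k, v in self.store.params.items()}
        arrays["config_json"] = np.array(json.dumps(asdict(self.config)))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TorsionPredictor":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig(**json.loads(str(data["config_json"])))
            model = cls(cfg)
            for key in data.files:
                if key.startswith("param:"):
                    model.store.params[key[6:]][...] = data[key]
        return model


# ---------------------------------------------------------------------------
# training

def _targets_for(
    table: AngleTable, k: int, L: int
) -> SinCosTensor:
    """Per-token regression targets: the target of a k-mer token is the
    encoded angle vector of its central nucleotide."""
    enc = encode_angles(table)
    lead = (k - 1) // 2
    n_tok = L - k + 1
    sl = slice(lead, lead + n_tok)
    return SinCosTensor(values=enc.values[sl], mask=enc.mask[sl])


def train(
    model: TorsionPredictor,
    dataset: list[tuple[str, AngleTable]],
    epochs: int = 50,
    learning_rate: float | None = None,
) -> list[float]:
    """Fit the regressor on (sequence, angle table) pairs.

    One Adam step per example, examples shuffled each epoch with the
    config seed; returns the per-epoch mean masked sin/cos MSE.  Raises
    :class:`ContractError` on an empty dataset.
    """
    if not dataset:
        raise ContractError("training dataset is empty")
    cfg = model.config
    lr = learning_rate if learning_rate is not None else cfg.learning_rate
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.store, lr=lr)

    prepared = []
    for seq, table in dataset:
        if len(seq) != len(table):
            raise ContractError("sequence/angle table length mismatch")
        tok = preprocess_sequence(seq, cfg.kmer_k, crop=True)
        target = _targets_for(table, cfg.kmer_k, len(tok.raw_sequence))
        prepared.append((tok, target))

    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(prepared))
        epoch_losses = []
        for idx in order:
            tok, target = prepared[idx]
            model.store.zero_grad()
            out, cache = model.forward(tok, with_cache=True)
            pred = SinCosTensor(values=out, mask=target.mask)
            loss = masked_circular_loss(pred, target)
            m = target.component_mask
            d_out = np.zeros_like(out)
            d_out[m] = 2.0 * (out[m] - target.values[m]) / m.sum()
            model.backward(d_out, cache)
            optimizer.step()
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return history
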