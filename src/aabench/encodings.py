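"""Amino-acid encoding matrices and sequence encoding.

Every encoding is a 21 x d real matrix: one row per token of the
:class:`Alphabet` (padding symbol at index 0, then the 20 canonical amino
acids in alphabetical one-letter order).  Classical schemes (one-hot,
BLOSUM62, VHSE8) and random-frozen matrices are immutable; learned matrices
are trainable model parameters initialised uniformly on [-0.05, +0.05].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._tables import AMINO_ACIDS, PAD_TOKEN, blosum62_conditional, vhse8_values

N_TOKENS = 21  # 20 amino acids + padding symbol

SCHEMES = ("one_hot", "blosum62", "vhse8", "random_frozen", "learned")

UNIFORM_INIT_BOUND = 0.05  # embedding init: uniform on [-0.05, +0.05]


class UnknownTokenError(KeyError):
    """A residue or token index outside the 21-symbol alphabet."""


class EncodingFormatError(ValueError):
    """A serialized encoding matrix that violates the file contract."""


@dataclass(frozen=True)
class Alphabet:
    """Token <-> index bijection: padding at 0, amino acids at 1..20."""

    tokens: tuple[str, ...] = (PAD_TOKEN,) + tuple(AMINO_ACIDS)

    def __post_init__(self) -> None:
        if len(self.tokens) != N_TOKENS:
            raise ValueError(f"alphabet must have {N_TOKENS} tokens, got {len(self.tokens)}")
        if len(set(self.tokens)) != N_TOKENS:
            raise ValueError("alphabet tokens must be distinct")

    @property
    def pad_token(self) -> str:
        return self.tokens[0]

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise UnknownTokenError(token) from None

    def token(self, index: int) -> str:
        if not 0 <= index < N_TOKENS:
            raise UnknownTokenError(index)
        return self.tokens[index]


#: Module-level default alphabet used throughout the package.
ALPHABET = Alphabet()


class EncodingMatrix:
    """A named 21 x d encoding matrix with a trainable flag.

    Non-trainable matrices are made immutable at construction time
    (``values.flags.writeable`` is cleared) so that frozen schemes are
    byte-identical before and after any training run that consumes them.
    """

    def __init__(
        self,
        scheme: str,
        values: np.ndarray,
        trainable: bool,
        seed: int | None = None,
    ) -> None:
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != N_TOKENS:
            raise ValueError(f"encoding matrix must have {N_TOKENS} rows, got shape {values.shape}")
        if values.shape[1] < 1:
            raise ValueError("encoding dimension must be >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("encoding matrix entries must be finite")
        if not trainable:
            values = values.copy()
            values.flags.writeable = False
        self.scheme = scheme
        self.values = values
        self.trainable = bool(trainable)
        self.seed = seed

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"EncodingMatrix(scheme={self.scheme!r}, dim={self.dim}, "
            f"trainable={self.trainable}, seed={self.seed})"
        )


def build_one_hot(alphabet: Alphabet = ALPHABET) -> EncodingMatrix:
    """20-dimensional orthonormal encoding; the pad row is all zeros."""
    values = np.zeros((N_TOKENS, 20))
    values[1:, :] = np.eye(20)
    return EncodingMatrix("one_hot", values, trainable=False)


def build_blosum62() -> EncodingMatrix:
    """Row-stochastic (frequency-normalised) BLOSUM62 encoding, 20-dim."""
    values = np.zeros((N_TOKENS, 20))
    values[1:, :] = blosum62_conditional()
    return EncodingMatrix("blosum62", values, trainable=False)


def build_vhse8() -> EncodingMatrix:
    """Published 8-component physicochemical VHSE descriptors."""
    values = np.zeros((N_TOKENS, 8))
    values[1:, :] = vhse8_values()
    return EncodingMatrix("vhse8", values, trainable=False)


def _uniform_init(dim: int, seed: int) -> np.ndarray:
    if dim < 1:
        raise ValueError(f"encoding dimension must be >= 1, got {dim}")
    rng = np.random.default_rng(seed)
    return rng.uniform(-UNIFORM_INIT_BOUND, UNIFORM_INIT_BOUND, size=(N_TOKENS, dim))


def build_random_frozen(dim: int, seed: int) -> EncodingMatrix:
    """Fixed random embedding: every entry i.i.d. uniform on [-0.05, +0.05].

    The pad row is drawn like any other row (it is a real, analysable
    vector, not a masked placeholder).
    """
    return EncodingMatrix("random_frozen", _uniform_init(dim, seed), trainable=False, seed=seed)


def init_learned(dim: int, seed: int) -> EncodingMatrix:
    """Trainable embedding with the same initialisation law as random_frozen."""
    return EncodingMatrix("learned", _uniform_init(dim, seed), trainable=True, seed=seed)


def encode_sequence(tokens: Sequence[int] | np.ndarray, matrix: EncodingMatrix) -> np.ndarray:
    """Map a token-index sequence to an (L, d) real matrix by row lookup."""
    idx = np.asarray(tokens, dtype=int)
    if idx.ndim != 1:
        raise ValueError("token sequence must be one-dimensional")
    if idx.size and (idx.min() < 0 or idx.max() >= N_TOKENS):
        bad = idx[(idx < 0) | (idx >= N_TOKENS)][0]
        raise UnknownTokenError(int(bad))
    return np.asarray(matrix.values)[idx]


def save_matrix(matrix: EncodingMatrix, path: str | Path) -> None:
    """Write an encoding matrix as a TSV with a metadata header line."""
    path = Path(path)
    seed = "NA" if matrix.seed is None else str(matrix.seed)
    lines = [
        f"#scheme={matrix.scheme} dim={matrix.dim} "
        f"trainable={int(matrix.trainable)} seed={seed}"
    ]
    for tok, row in zip(ALPHABET.tokens, matrix.values):
        lines.append(tok + "\t" + "\t".join(f"{v:.15g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def load_matrix(path: str | Path) -> EncodingMatrix:
    """Read a matrix written by :func:`save_matrix`; validates the layout."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#scheme="):
        raise EncodingFormatError(f"{path}: line 1: missing '#scheme=' header")
    header: dict[str, str] = {}
    for item in lines[0][1:].split():
        if "=" not in item:
            raise EncodingFormatError(f"{path}: line 1: malformed header field {item!r}")
        key, _, val = item.partition("=")
        header[key] = val
    try:
        scheme = header["scheme"]
        dim = int(header["dim"])
        trainable = bool(int(header["trainable"]))
        seed = None if header["seed"] == "NA" else int(header["seed"])
    except (KeyError, ValueError) as exc:
        raise EncodingFormatError(f"{path}: line 1: bad header ({exc})") from exc
    body = lines[1:]
    if len(body) != N_TOKENS:
        raise EncodingFormatError(
            f"{path}: expected {N_TOKENS} matrix rows, found {len(body)} (line {len(lines)})"
        )
    values = np.empty((N_TOKENS, dim))
    for i, line in enumerate(body):
        parts = line.split("\t")
        if parts[0] != ALPHABET.tokens[i]:
            raise EncodingFormatError(
                f"{path}: line {i + 2}: expected token {ALPHABET.tokens[i]!r}, got {parts[0]!r}"
            )
        if len(parts) != dim + 1:
            raise EncodingFormatError(
                f"{path}: line {i + 2}: expected {dim} values, got {len(parts) - 1}"
            )
        try:
            values[i] = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise EncodingFormatError(f"{path}: line {i + 2}: {exc}") from exc
    return EncodingMatrix(scheme, values, trainable=trainable, seed=seed)
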