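"""Dataset preparation: tokenisation, padding, affinity transforms and the
PPI construction pipeline (length filter, protein-level split, k-mer
homology removal, 1:1 negative balancing, fraction subsetting)."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .encodings import ALPHABET, Alphabet, N_TOKENS
from .synthetic import PairRecord, PeptideRecord, SyntheticProtein

PEPTIDE_LENGTH = 26
PROTEIN_LENGTH = 1000
IC50_MAX_NM = 50000.0
BINDER_THRESHOLD = 0.426


class PreparationError(ValueError):
    pass


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[int, ...]
    original_length: int

    def __post_init__(self) -> None:
        if any(t < 0 or t >= N_TOKENS for t in self.tokens):
            raise PreparationError("token outside alphabet range")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class PreparedDataset:
    """Model-ready inputs/targets with provenance metadata.

    ``inputs`` is an (n, L) integer token array, or a pair of such arrays
    for the two-protein task.
    """

    inputs: np.ndarray | tuple[np.ndarray, np.ndarray]
    targets: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if len(self.targets) != self.n:
            raise PreparationError("inputs and targets must have equal length")

    @property
    def paired(self) -> bool:
        return isinstance(self.inputs, tuple)

    @property
    def n(self) -> int:
        return (self.inputs[0] if self.paired else self.inputs).shape[0]

    def take(self, idx: np.ndarray, **meta) -> "PreparedDataset":
        inputs = (
            (self.inputs[0][idx], self.inputs[1][idx]) if self.paired else self.inputs[idx]
        )
        return PreparedDataset(inputs, self.targets[idx], {**self.metadata, **meta})


def tokenize(sequence: str, alphabet: Alphabet = ALPHABET) -> TokenSequence:
    """Residue string -> integer tokens (A=1 .. Y=20 in alphabet order)."""
    if not sequence:
        raise PreparationError("empty sequence")
    tokens = []
    for pos, ch in enumerate(sequence, start=1):
        try:
            tokens.append(alphabet.index(ch))
        except KeyError:
            raise PreparationError(
                f"unknown residue {ch!r} at position {pos}"
            ) from None
    return TokenSequence(tuple(tokens), len(tokens))


def detokenize(tokens: Sequence[int], alphabet: Alphabet = ALPHABET) -> str:
    seq = tokens.tokens if isinstance(tokens, TokenSequence) else tokens
    return "".join(alphabet.token(t) for t in seq)


def _token_tuple(tokens) -> tuple[int, ...]:
    return tokens.tokens if isinstance(tokens, TokenSequence) else tuple(tokens)


def pad_trim_peptide(tokens, target_length: int = PEPTIDE_LENGTH) -> TokenSequence:
    """Left-pad with zeros or trim from the head end to ``target_length``."""
    toks = _token_tuple(tokens)
    if not toks:
        raise PreparationError("empty token list")
    original = len(toks)
    if original >= target_length:
        toks = toks[original - target_length:]  # head-end trimming keeps the tail
    else:
        toks = (0,) * (target_length - original) + toks
    return TokenSequence(toks, original)


def pad_protein(tokens, target_length: int = PROTEIN_LENGTH) -> TokenSequence:
    """Left-pad with zeros to ``target_length``; over-long input is an error
    (the length filter must run upstream)."""
    toks = _token_tuple(tokens)
    if not toks:
        raise PreparationError("empty token list")
    if len(toks) > target_length:
        raise PreparationError(
            f"protein of length {len(toks)} exceeds {target_length}; apply length_filter first"
        )
    return TokenSequence((0,) * (target_length - len(toks)) + toks, len(toks))


def normalize_ic50(ic50_nm: float) -> float:
    """IC50 (nM) -> [0, 1] affinity: clip(1 - log(IC50)/log(50000), 0, 1)."""
    if ic50_nm <= 0:
        raise PreparationError(f"IC50 must be positive, got {ic50_nm}")
    return float(np.clip(1.0 - math.log(ic50_nm) / math.log(IC50_MAX_NM), 0.0, 1.0))


def binarize_affinity(score: float, threshold: float = BINDER_THRESHOLD) -> int:
    """1 iff score >= threshold (a tie at the threshold counts as binder)."""
    return int(score >= threshold)


def _seq_of(protein) -> str:
    return protein.sequence if hasattr(protein, "sequence") else protein


def length_filter(proteins: Iterable, min_len: int = 100, max_len: int = 1000) -> list:
    """Keep proteins with min_len <= length <= max_len, preserving order."""
    return [p for p in proteins if min_len <= len(_seq_of(p)) <= max_len]


def split_proteins(proteins: Sequence, train_frac: float = 0.9,
                   seed: int = 0) -> tuple[list, list]:
    """Disjoint, exhaustive protein-level split; ceil(frac * n) in train."""
    if len(proteins) < 2:
        raise PreparationError("need at least 2 proteins to split")
    n_train = math.ceil(train_frac * len(proteins))
    order = np.random.default_rng(seed).permutation(len(proteins))
    train = [proteins[i] for i in sorted(order[:n_train])]
    test = [proteins[i] for i in sorted(order[n_train:])]
    return train, test


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_identity(seq_a: str, seq_b: str, k: int = 5) -> float:
    """Shared distinct k-mers over the smaller distinct-k-mer count."""
    if len(seq_a) < k or len(seq_b) < k:
        raise PreparationError(f"sequences must be at least {k} residues for k={k}")
    ka, kb = _kmer_set(seq_a, k), _kmer_set(seq_b, k)
    return len(ka & kb) / min(len(ka), len(kb))


def homology_filter(test_proteins: Sequence, train_proteins: Sequence,
                    threshold: float = 0.40, k: int = 5) -> list:
    """Drop test proteins whose k-mer identity to any training protein
    strictly exceeds ``threshold`` (desk-scale stand-in for an alignment
    identity filter)."""
    train_kmers = [_kmer_set(_seq_of(p), k) for p in train_proteins]
    kept = []
    for p in test_proteins:
        kp = _kmer_set(_seq_of(p), k)
        hit = any(
            len(kp & kt) / min(len(kp), len(kt)) > threshold for kt in train_kmers
        )
        if not hit:
            kept.append(p)
    return kept


def balance_negatives(positive_pairs: Sequence[PairRecord],
                      protein_ids: Sequence[str], seed: int = 0,
                      exclude: set[frozenset[str]] | None = None) -> list[PairRecord]:
    """Positives plus an equal number of uniformly sampled negative pairs.

    Negatives are unordered pairs over ``protein_ids`` that are not
    self-pairs, not in the positive set and not duplicated.  ``exclude``
    optionally bars further pairs from being drawn as negatives (e.g. all
    latently interacting pairs known to a synthetic generator).
    """
    ids = list(protein_ids)
    n = len(ids)
    n_pos = len(positive_pairs)
    positive_keys = {p.key for p in positive_pairs} | (exclude or set())
    n_possible = n * (n - 1) // 2 - len(positive_keys)
    if n_possible < n_pos:
        raise PreparationError(
            f"cannot sample {n_pos} negatives: only {n_possible} candidate pairs exist"
        )
    rng = np.random.default_rng(seed)
    negatives: list[PairRecord] = []
    seen: set[frozenset[str]] = set(positive_keys)
    while len(negatives) < n_pos:
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        if i == j:
            continue
        key = frozenset((ids[i], ids[j]))
        if key in seen:
            continue
        seen.add(key)
        a, b = sorted((ids[i], ids[j]))
        negatives.append(PairRecord(a, b, 0))
    return [PairRecord(p.id_a, p.id_b, p.label) for p in positive_pairs] + negatives


def subset_fraction(dataset: PreparedDataset, fraction: float,
                    seed: int = 0) -> PreparedDataset:
    """Seeded uniform subset of size round(fraction * n); fraction 1.0
    returns the full dataset in original order."""
    if not 0.0 < fraction <= 1.0:
        raise PreparationError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return dataset.take(np.arange(dataset.n), fraction=1.0)
    size = round(fraction * dataset.n)
    idx = np.random.default_rng(seed).choice(dataset.n, size=size, replace=False)
    return dataset.take(np.sort(idx), fraction=fraction, subset_seed=seed)


# ---------------------------------------------------------------------------
# End-to-end preparation helpers.


def prepare_peptide_dataset(records: Sequence[PeptideRecord],
                            target_length: int = PEPTIDE_LENGTH,
                            **meta) -> PreparedDataset:
    """Tokenise + pad/trim peptides; targets are observed affinities."""
    inputs = np.array(
        [pad_trim_peptide(tokenize(r.sequence), target_length).tokens for r in records],
        dtype=int,
    )
    targets = np.array([r.observed_affinity for r in records])
    return PreparedDataset(inputs, targets, dict(meta))


def prepare_ppi_dataset(proteins: Sequence[SyntheticProtein],
                        pairs: Sequence[PairRecord],
                        target_length: int = PROTEIN_LENGTH,
                        **meta) -> PreparedDataset:
    """Tokenise + zero-pad both proteins of every pair; targets are labels."""
    padded = {
        p.id: np.array(pad_protein(tokenize(p.sequence), target_length).tokens)
        for p in proteins
    }
    missing = [p for pr in pairs for p in (pr.id_a, pr.id_b) if p not in padded]
    if missing:
        raise PreparationError(f"pairs reference unknown proteins, e.g. {missing[0]!r}")
    tokens_a = np.stack([padded[p.id_a] for p in pairs])
    tokens_b = np.stack([padded[p.id_b] for p in pairs])
    targets = np.array([p.label for p in pairs], dtype=float)
    return PreparedDataset((tokens_a, tokens_b), targets, dict(meta))


def save_prepared(dataset: PreparedDataset, prefix: str | Path) -> None:
    """TSV of token rows + JSON sidecar with the provenance metadata."""
    prefix = Path(prefix)
    if dataset.paired:
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            fh.write("tokens_a\ttokens_b\ttarget\n")
            for a, b, t in zip(*dataset.inputs, dataset.targets):
                fh.write(
                    ",".join(map(str, a)) + "\t" + ",".join(map(str, b)) + f"\t{t:g}\n"
                )
    else:
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            fh.write("tokens\ttarget\n")
            for row, t in zip(dataset.inputs, dataset.targets):
                fh.write(",".join(map(str, row)) + f"\t{t:g}\n")
    prefix.with_suffix(".json").write_text(
        json.dumps({"paired": dataset.paired, "n": int(dataset.n),
                    **dataset.metadata}, indent=2, default=str) + "\n"
    )


def load_prepared(prefix: str | Path) -> PreparedDataset:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    paired = meta.pop("paired")
    meta.pop("n", None)
    lines = prefix.with_suffix(".tsv").read_text().splitlines()[1:]
    if paired:
        ta, tb, targets = [], [], []
        for line in lines:
            a, b, t = line.split("\t")
            ta.append([int(x) for x in a.split(",")])
            tb.append([int(x) for x in b.split(",")])
            targets.append(float(t))
        return PreparedDataset(
            (np.array(ta), np.array(tb)), np.array(targets), meta
        )
    tokens, targets = [], []
    for line in lines:
        row, t = line.split("\t")
        tokens.append([int(x) for x in row.split(",")])
        targets.append(float(t))
    return PreparedDataset(np.array(tokens), np.array(targets), meta)
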