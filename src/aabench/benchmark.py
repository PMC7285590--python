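"""Experiment orchestration: the encoding x dimension x architecture x
data-fraction benchmark grid, the per-figure experiment wrappers, and the
post-training embedding-space analysis.

Every grid cell derives its seeds deterministically from the base seed and
its own coordinates, runs independently, and writes one tidy CSV fragment;
an interrupted grid resumes by skipping completed cells.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import prep
from .evaluation import (
    aggregate_repetitions,
    distance_matrix_to_tsv,
    group_cohesion_test,
    hierarchical_cluster_order,
    linkage_to_newick,
    pairwise_distance_matrix,
)
from .encodings import EncodingMatrix, load_matrix
from .models import (
    CNNLSTMModelConfig,
    EmbeddingSpec,
    LSTMModelConfig,
    SiamesePPIConfig,
    build_cnn_lstm_model,
    build_lstm_model,
    build_siamese_ppi_model,
    train_model,
)
from .synthetic import (
    PHYSICOCHEMICAL_GROUPS,
    compatible_pair_keys,
    generate_motif_library,
    generate_peptide_dataset,
    generate_ppi_dataset,
)

CLASSICAL_SCHEMES = ("one_hot", "blosum62", "vhse8")
ALL_DIMS = (1, 2, 4, 8, 16, 32)
ALL_FRACTIONS = (0.25, 0.5, 0.75, 1.0)


def derive_seed(base_seed: int, *parts) -> int:
    """Stable per-cell seed: hash of the base seed and the coordinates."""
    key = "|".join([str(base_seed), *map(str, parts)])
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big")


@dataclass
class HLADataConfig:
    n_peptides: int = 2000
    noise_sd: float = 0.05
    length_range: tuple[int, int] = (13, 25)
    val_fraction: float = 0.2


@dataclass
class PPIDataConfig:
    n_proteins: int = 300
    length_range: tuple[int, int] = (100, 200)
    n_motifs: int = 4
    motif_length: int = 12
    n_positive: int = 800
    target_length: int = 200
    val_fraction: float = 0.2


@dataclass
class GridConfig:
    task: str = "hla"  # "hla" | "ppi"
    architectures: tuple[str, ...] = ("lstm",)
    schemes: tuple[str, ...] = ("one_hot", "learned")
    dims: tuple[int, ...] = (8,)
    fractions: tuple[float, ...] = (1.0,)
    repetitions: int = 1
    epochs: int = 120
    base_seed: int = 0
    hla_data: HLADataConfig = field(default_factory=HLADataConfig)
    ppi_data: PPIDataConfig = field(default_factory=PPIDataConfig)
    batch_size: int | None = None
    data_files: dict | None = None  # optional: peptides / proteins+pairs TSVs

    def __post_init__(self) -> None:
        if self.task not in ("hla", "ppi"):
            raise ValueError(f"unknown task {self.task!r}")
        if not (self.architectures and self.schemes and self.fractions):
            raise ValueError("architectures, schemes and fractions must be non-empty")
        for f in self.fractions:
            if not 0 < f <= 1:
                raise ValueError(f"fraction {f} outside (0, 1]")

    def cells(self) -> list[dict]:
        out = []
        for arch in self.architectures:
            for scheme in self.schemes:
                # classical schemes have a native dimension; the dims axis
                # only applies to learned / random_frozen embeddings
                dims = [0] if scheme in CLASSICAL_SCHEMES else list(self.dims)
                for dim in dims:
                    for fraction in self.fractions:
                        for rep in range(self.repetitions):
                            out.append(dict(task=self.task, architecture=arch,
                                            scheme=scheme, dim=dim,
                                            fraction=fraction, repetition=rep))
        return out


def _cell_id(cell: dict, base_seed: int, epochs: int) -> str:
    key = json.dumps({**cell, "base_seed": base_seed, "epochs": epochs}, sort_keys=True)
    return hashlib.sha256(key.encode()).hexdigest()[:16]


def _log(out_dir: Path | None, event: str, **fields) -> None:
    if out_dir is None:
        return
    with open(out_dir / "events.jsonl", "a") as fh:
        fh.write(json.dumps({"time": time.time(), "event": event, **fields}) + "\n")


def _prepare_hla(config: GridConfig):
    data_seed = derive_seed(config.base_seed, "hla", "data")
    if config.data_files and "peptides" in config.data_files:
        from .synthetic import read_peptide_tsv

        records = read_peptide_tsv(config.data_files["peptides"])
    else:
        hc = config.hla_data
        records = generate_peptide_dataset(
            hc.n_peptides, length_range=hc.length_range,
            noise_sd=hc.noise_sd, seed=data_seed,
        )
    ds = prep.prepare_peptide_dataset(records, data_seed=data_seed)
    split_rng = np.random.default_rng(derive_seed(config.base_seed, "hla", "split"))
    order = split_rng.permutation(ds.n)
    n_val = int(round(config.hla_data.val_fraction * ds.n))
    return ds.take(order[n_val:], split="train"), ds.take(order[:n_val], split="val")


def _prepare_ppi(config: GridConfig):
    data_seed = derive_seed(config.base_seed, "ppi", "data")
    pc = config.ppi_data
    if config.data_files and "proteins" in config.data_files:
        from .synthetic import read_pairs_tsv, read_proteins_fasta

        proteins = read_proteins_fasta(config.data_files["proteins"])
        pairs = read_pairs_tsv(config.data_files["pairs"])
    else:
        library = generate_motif_library(pc.n_motifs, pc.motif_length, seed=data_seed)
        proteins, positives = generate_ppi_dataset(
            pc.n_proteins, pc.length_range, library, pc.n_positive, seed=data_seed,
        )
        exclude = compatible_pair_keys(proteins, library)
        pairs = prep.balance_negatives(
            positives, [p.id for p in proteins],
            seed=derive_seed(config.base_seed, "ppi", "negatives"), exclude=exclude,
        )
    ds = prep.prepare_ppi_dataset(proteins, pairs, target_length=pc.target_length,
                                  data_seed=data_seed)
    split_rng = np.random.default_rng(derive_seed(config.base_seed, "ppi", "split"))
    order = split_rng.permutation(ds.n)
    n_val = int(round(pc.val_fraction * ds.n))
    return ds.take(order[n_val:], split="train"), ds.take(order[:n_val], split="val")


def _embedding_spec(cell: dict, seed: int) -> EmbeddingSpec:
    scheme, dim = cell["scheme"], cell["dim"]
    if scheme == "learned":
        return EmbeddingSpec("learned", dim=dim, seed=seed)
    if scheme == "random_frozen":
        return EmbeddingSpec("frozen", "random_frozen", dim=dim, seed=seed)
    return EmbeddingSpec("frozen", scheme)


def _build_model(cell: dict, spec: EmbeddingSpec, config: GridConfig, seed: int):
    arch = cell["architecture"]
    batch = config.batch_size
    if arch == "lstm":
        cfg = LSTMModelConfig(epochs=config.epochs)
        if batch:
            cfg.batch_size = batch
        return build_lstm_model(spec, cfg, seed=seed)
    if arch == "cnn_lstm":
        cfg = CNNLSTMModelConfig(epochs=config.epochs)
        if batch:
            cfg.batch_size = batch
        return build_cnn_lstm_model(spec, cfg, seed=seed)
    if arch == "siamese_cnn":
        pc = config.ppi_data
        cfg = SiamesePPIConfig(
            conv_filters=(8, 12, 16, 24), conv_kernels=(9, 7, 5, 3), pool_width=3,
            hidden_units=32, input_length=pc.target_length,
            batch_size=batch or 256, epochs=config.epochs, learning_rate=3e-3,
        )
        return build_siamese_ppi_model(spec, cfg, seed=seed)
    raise ValueError(f"unknown architecture {arch!r}")


def run_cell(cell: dict, config: GridConfig, train_ds, val_ds) -> pd.DataFrame:
    """Train one grid cell and return its tidy per-epoch metric rows."""
    seed = derive_seed(config.base_seed, *(cell[k] for k in
                                           ("task", "architecture", "scheme", "dim",
                                            "fraction", "repetition")))
    sub = prep.subset_fraction(train_ds, cell["fraction"], seed=seed)
    spec = _embedding_spec(cell, seed)
    model = _build_model(cell, spec, config, seed)
    history = train_model(model, (sub.inputs, sub.targets), (val_ds.inputs, val_ds.targets),
                          epochs=config.epochs, seed=seed)
    frame = history.to_frame()
    for key, value in cell.items():
        frame[key] = value
    frame["seed"] = seed
    return frame


def run_grid(config: GridConfig, out_dir: str | Path | None = None,
             resume: bool = False) -> pd.DataFrame:
    """Execute every cell of the grid; returns the combined tidy table.

    With ``out_dir`` each finished cell is written to ``cells/<id>.csv``;
    ``resume`` skips cells whose fragment already exists.  Cell failures
    are recorded in ``failures.json`` and do not abort the grid.
    """
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        (out_path / "cells").mkdir(parents=True, exist_ok=True)
        (out_path / "manifest.json").write_text(
            json.dumps(asdict(config), indent=2, default=str) + "\n"
        )
    if config.task == "hla":
        train_ds, val_ds = _prepare_hla(config)
    else:
        train_ds, val_ds = _prepare_ppi(config)
    frames, failures = [], []
    for cell in config.cells():
        cid = _cell_id(cell, config.base_seed, config.epochs)
        cell_file = out_path / "cells" / f"{cid}.csv" if out_path else None
        if resume and cell_file and cell_file.exists():
            frames.append(pd.read_csv(cell_file))
            _log(out_path, "cell_skipped", cell=cell, id=cid)
            continue
        t0 = time.time()
        try:
            frame = run_cell(cell, config, train_ds, val_ds)
        except Exception as exc:  # noqa: BLE001 - cell isolation by design
            failures.append({"cell": cell, "error": repr(exc)})
            _log(out_path, "cell_failed", cell=cell, id=cid, error=repr(exc))
            continue
        if cell_file:
            frame.to_csv(cell_file, index=False)
        _log(out_path, "cell_done", cell=cell, id=cid, seconds=round(time.time() - t0, 2))
        frames.append(frame)
    result = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out_path:
        result.to_csv(out_path / "results.csv", index=False)
        (out_path / "failures.json").write_text(json.dumps(failures, indent=2) + "\n")
    if failures:
        raise GridFailure(failures, result)
    return result


class GridFailure(RuntimeError):
    """One or more grid cells failed; carries the partial result table."""

    def __init__(self, failures: list[dict], result: pd.DataFrame):
        super().__init__(f"{len(failures)} grid cell(s) failed")
        self.failures = failures
        self.result = result


def _best_auc_table(result: pd.DataFrame) -> pd.DataFrame:
    vals = result[(result["split"] == "val") & (result["metric"] != "loss")]
    return (vals.groupby(["scheme", "dim", "fraction", "repetition"])["value"]
            .max().reset_index(name="best"))


def experiment_fig1(config: GridConfig | None = None, dims: Sequence[int] = (1, 2, 4, 8),
                    epochs: int = 120, seed: int = 0,
                    out_dir: str | Path | None = None) -> pd.DataFrame:
    """LSTM classical-vs-learned comparison: per-epoch val AUC curves."""
    config = config or GridConfig()
    config = GridConfig(task="hla", architectures=("lstm",),
                        schemes=("one_hot", "blosum62", "vhse8", "learned"),
                        dims=tuple(dims), fractions=(1.0,), repetitions=1,
                        epochs=epochs, base_seed=seed, hla_data=config.hla_data)
    return run_grid(config, out_dir=out_dir)


def experiment_fig4(config: GridConfig | None = None,
                    dims: Sequence[int] = ALL_DIMS, seeds: Sequence[int] = (0, 1, 2),
                    epochs: int = 120,
                    out_dir: str | Path | None = None) -> pd.DataFrame:
    """Random-frozen embeddings across dimensions; one run per seed."""
    config = config or GridConfig()
    frames = []
    for s in seeds:
        gc = GridConfig(task="hla", architectures=("lstm",), schemes=("random_frozen",),
                        dims=tuple(dims), fractions=(1.0,), repetitions=1,
                        epochs=epochs, base_seed=s, hla_data=config.hla_data)
        sub_dir = Path(out_dir) / f"seed{s}" if out_dir else None
        frame = run_grid(gc, out_dir=sub_dir)
        frame["base_seed"] = s
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def experiment_fig2(config: GridConfig | None = None,
                    fractions: Sequence[float] = ALL_FRACTIONS, repetitions: int = 5,
                    schemes: Sequence[str] = ("one_hot", "blosum62", "vhse8", "learned"),
                    dims: Sequence[int] = (8,), epochs: int = 20, seed: int = 0,
                    out_dir: str | Path | None = None) -> pd.DataFrame:
    """Siamese-CNN accuracy vs training-data fraction, mean +/- sd."""
    config = config or GridConfig()
    gc = GridConfig(task="ppi", architectures=("siamese_cnn",), schemes=tuple(schemes),
                    dims=tuple(dims), fractions=tuple(fractions),
                    repetitions=repetitions, epochs=epochs, base_seed=seed,
                    ppi_data=config.ppi_data)
    result = run_grid(gc, out_dir=out_dir)
    best = _best_auc_table(result)
    rows = []
    for (scheme, dim, fraction), grp in best.groupby(["scheme", "dim", "fraction"]):
        summary = aggregate_repetitions(grp["best"], metric="accuracy")
        rows.append(dict(scheme=scheme, dim=dim, fraction=fraction,
                         mean=summary.mean, sd=summary.sd, n=summary.n_repetitions))
    table = pd.DataFrame(rows)
    if out_dir:
        table.to_csv(Path(out_dir) / "fraction_summary.csv", index=False)
    return table


def analyze_embedding(matrix: EncodingMatrix | str | Path,
                      n_permutations: int = 1000, seed: int = 0,
                      out_dir: str | Path | None = None) -> dict:
    """Distance matrix + dendrogram + physicochemical cohesion report."""
    if not isinstance(matrix, EncodingMatrix):
        matrix = load_matrix(matrix)
    dm = pairwise_distance_matrix(matrix)
    leaf_order, linkage_matrix = hierarchical_cluster_order(dm)
    newick = linkage_to_newick(linkage_matrix, dm.labels)
    statistic, p_value = group_cohesion_test(
        dm, PHYSICOCHEMICAL_GROUPS, n_permutations=n_permutations, seed=seed
    )
    report = {
        "scheme": matrix.scheme,
        "dim": matrix.dim,
        "tokens": list(dm.labels),
        "leaf_order": [dm.labels[i] for i in leaf_order],
        "cohesion_statistic": statistic,
        "cohesion_p_value": p_value,
        "n_permutations": n_permutations,
    }
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "distances.tsv").write_text(distance_matrix_to_tsv(dm))
        (out / "dendrogram.nwk").write_text(newick + "\n")
        (out / "cohesion.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def desk_profile() -> GridConfig:
    """Scaled-down defaults that run on one CPU in minutes."""
    return GridConfig(epochs=120)


def full_profile() -> GridConfig:
    """Paper-scale settings (GPU-scale; hours to days on one CPU)."""
    return GridConfig(
        epochs=3000,
        hla_data=HLADataConfig(n_peptides=3900),
        ppi_data=PPIDataConfig(n_proteins=2000, length_range=(100, 1000),
                               n_positive=5000, target_length=1000),
    )
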