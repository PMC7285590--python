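# aabench

A benchmark of amino-acid encoding schemes for sequence models: classical
encodings (one-hot, row-stochastic BLOSUM62, VHSE8), end-to-end learned
embeddings, and random frozen embeddings, compared across three
architectures (LSTM, CNN-LSTM, siamese CNN) on two tasks — peptide binding
affinity regression and protein–protein interaction (PPI) classification —
with seeded synthetic data generators so everything runs offline on one CPU.

## What is in here

| Module | Purpose |
| --- | --- |
| `aabench.encodings` | 21 × d encoding matrices (pad token at index 0 + 20 amino acids in alphabetical order), construction, sequence encoding, TSV serialization |
| `aabench.synthetic` | synthetic peptide-affinity data (physicochemical-group 9-mer binding core + Gaussian noise) and motif-driven protein-pair data, homolog injection |
| `aabench.prep` | tokenization, pad/trim to 26 (peptides) and zero-pad to 1000 (proteins), IC50 normalization `1 − log(IC50)/log(50000)` with binder threshold 0.426, length filter 100–1000, 90/10 protein split, k-mer homology filter (40 %), 1:1 negative balancing, fraction subsetting |
| `aabench.nn` | minimal NumPy neural-net engine (embedding, LSTM, Conv1D, batch norm, average/global pooling, dense; Adam; MAE and BCE losses) — no deep-learning framework is assumed to be installed |
| `aabench.models` | the three architectures (LSTM-12; CNN(36×9) + LSTM-12; 4-module siamese CNN with shared weights), training loop, embedding extraction |
| `aabench.evaluation` | rank-based AUC, accuracy, mean ± sd over repetitions, 21 × 21 pairwise-distance matrices, average-linkage clustering/Newick export, group-cohesion permutation test |
| `aabench.benchmark` | the scheme × dimension × architecture × fraction grid with derived per-cell seeds, resumable cell-by-cell execution, figure-style experiments, embedding analysis |
| `aabench.cli` | `aabench` command-line entry point |

All frozen matrices are immutable (byte-identical before/after training);
learned embeddings initialize uniformly on [−0.05, +0.05]. Every generator
and training run is deterministic given its seed.

## CLI

```bash
aabench simulate-hla --n 2000 --seed 1 --out peptides.tsv
aabench simulate-ppi --n-proteins 300 --n-positive 800 --seed 1 --out-dir ppi/
aabench prepare --proteins ppi/proteins.fasta --pairs ppi/pairs.tsv --out-dir prep/
aabench train --data prep/train --arch siamese_cnn --scheme learned --dim 8 --out-dir run/
aabench grid --profile desk --seed 0 --out-dir grid/ [--resume]
aabench fig1 --dims 1,2,4,8 --out-dir fig1/     # classical vs learned (LSTM)
aabench fig2 --out-dir fig2/                    # accuracy vs data fraction (PPI)
aabench fig4 --dims 1,2,4,8,16,32 --out-dir fig4/  # random frozen embeddings
aabench analyze-embedding --matrix run/embedding.tsv --out-dir analysis/
```

Grid results are tidy CSVs keyed by
(task, architecture, scheme, dim, fraction, repetition, epoch, metric);
each cell's seed is a stable hash of the base seed and its coordinates, so
interrupted grids resume (`--resume`) to bit-identical tables.

The `desk` profile is deliberately scaled down (e.g. 120 epochs instead of
3000, proteins of length 100–200 instead of 100–1000) so that full
experiments finish in minutes on one CPU; `--profile full` restores
paper-scale settings.

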