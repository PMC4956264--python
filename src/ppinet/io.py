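"""Standard-format readers and writers.

FASTA for sequences (via Biopython), TSV for feature tables, edge lists,
adjacency matrices, kernel matrices (17-significant-digit round-trip),
expression matrices, pair datasets and MKL weights; JSON manifests for
benchmark bundles.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .kernels import FeatureTable, InteractionNetwork, KernelMatrix
from .mkl import MKLWeights
from .netvalidate import ExpressionMatrix
from .pairwise import PairDataset
from .seqsim import ProteinSequence, SyntheticBenchmark

logger = logging.getLogger("ppinet")

__all__ = [
    "read_fasta", "write_fasta",
    "read_network", "write_edge_list",
    "read_feature_table", "write_feature_table",
    "read_kernel", "write_kernel",
    "read_expression",
    "read_pair_dataset", "write_pair_dataset",
    "write_weights",
    "write_benchmark_bundle",
]


def read_fasta(path) -> list[ProteinSequence]:
    """Read protein sequences; ids are the first whitespace token of headers.

    Sequences are uppercased and trailing '*' stop symbols stripped.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    out, seen = [], set()
    for rec in records:
        pid = rec.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate id {pid!r}")
        seen.add(pid)
        out.append(ProteinSequence(pid, str(rec.seq).upper().rstrip("*")))
    return out


def write_fasta(sequences: list[ProteinSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_network(path) -> InteractionNetwork:
    """Read a network from a 2-column TSV edge list or a labeled square matrix.

    Duplicate and reversed edges are merged; self-loops dropped with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] == 2:
        ids: list[str] = []
        seen = set()
        for a, b in zip(df[0], df[1]):
            for v in (a, b):
                if v not in seen:
                    seen.add(v)
                    ids.append(v)
        idx = {v: i for i, v in enumerate(ids)}
        A = np.zeros((len(ids), len(ids)), dtype=np.int8)
        n_self = 0
        for a, b in zip(df[0], df[1]):
            if a == b:
                n_self += 1
                continue
            A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1
        if n_self:
            warnings.warn(f"{path}: dropped {n_self} self-loop(s)", stacklevel=2)
            logger.warning("%s: dropped %d self-loop(s)", path, n_self)
        return InteractionNetwork(ids, A)
    # square labeled matrix: header row + header column
    dfm = pd.read_csv(path, sep="\t", index_col=0)
    if dfm.shape[0] != dfm.shape[1] or list(dfm.index) != [str(c) for c in dfm.columns]:
        raise ValueError(f"{path}: unknown network format")
    A = dfm.to_numpy()
    if np.any(np.diag(A) != 0):
        warnings.warn(f"{path}: nonzero diagonal dropped", stacklevel=2)
        A = A.copy()
        np.fill_diagonal(A, 0)
    return InteractionNetwork([str(i) for i in dfm.index], A)


def write_edge_list(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in net.edges():
            fh.write(f"{a}\t{b}\n")


def read_feature_table(path) -> FeatureTable:
    """TSV with header row; first column = protein id.

    Missing values are imputed to the column median (count logged).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%s: imputed %d missing values to column medians", path, n_missing)
        df = df.fillna(df.median())
    return FeatureTable([str(i) for i in df.index], df.to_numpy(dtype=float))


def write_feature_table(table: FeatureTable, path, columns=None) -> None:
    cols = columns or [f"f{i}" for i in range(table.n_features)]
    pd.DataFrame(table.values, index=table.protein_ids, columns=cols).to_csv(
        path, sep="\t", index_label="id"
    )


def write_kernel(K: KernelMatrix, path) -> None:
    """Kernel TSV with id header row/column; 17 significant digits."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(K.entity_ids) + "\n")
        for i, pid in enumerate(K.entity_ids):
            fh.write(pid + "\t" + "\t".join(f"{v:.17g}" for v in K.values[i]) + "\n")


def read_kernel(path) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: kernel row/column ids disagree")
    return KernelMatrix(ids, df.to_numpy(dtype=float), check_psd=False)


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))


def write_pair_dataset(ds: PairDataset, path) -> None:
    with open(path, "w") as fh:
        for (a, b), t in zip(ds.pairs, ds.labels):
            fh.write(f"{a}\t{b}\t{int(t)}\n")


def read_pair_dataset(path) -> PairDataset:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 1: str, 2: int})
    return PairDataset(list(zip(df[0], df[1])), df[2].to_numpy())


def write_weights(weights: MKLWeights, path) -> None:
    with open(path, "w") as fh:
        for name, mu in zip(weights.names, weights.mu):
            fh.write(f"{name}\t{mu:.17g}\n")


def write_benchmark_bundle(bench: SyntheticBenchmark, outdir) -> None:
    """Bundle = FASTA per sequence set + features TSV + edge list + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bench.sequences, outdir / "sequences.fasta")
    for name, seqs in bench.perturbed.items():
        write_fasta(seqs, outdir / f"sequences_{name.lower()}.fasta")
    write_feature_table(bench.features, outdir / "features.tsv")
    write_edge_list(bench.network, outdir / "edges.tsv")
    manifest = {
        "n_proteins": bench.config.n_proteins,
        "n_modules": bench.config.n_modules,
        "seq_len": bench.config.seq_len,
        "levels": bench.config.levels,
        "deletion_fraction": bench.config.deletion_fraction,
        "seed": bench.config.seed,
        "modules": {pid: int(mod) for pid, mod in zip(bench.protein_ids, bench.modules)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
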