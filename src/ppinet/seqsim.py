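"""Synthetic sequence and benchmark generation.

Emulates genetic distance by perturbing protein sequences according to a
BLOSUM-derived substitution model: a configurable fraction of positions is
altered (deleted or substituted), with the four standard presets pairing
perturbation level with matrix (70%/BLOSUM30, 60%/BLOSUM40, 38%/BLOSUM62,
20%/BLOSUM80). Smith-Waterman percent identity provides the calibration
measure, and :func:`make_benchmark` assembles a full transfer-learning
benchmark: modular interaction network, module-informative features, and
perturbed sequence sets per level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .kernels import FeatureTable, InteractionNetwork

__all__ = [
    "AMINO_ACIDS",
    "ProteinSequence",
    "BlosumMatrix",
    "SubstitutionModel",
    "SyntheticBenchmark",
    "BenchmarkConfig",
    "load_blosum",
    "packaged_blosum",
    "substitution_model",
    "perturb_sequence",
    "sw_identity",
    "composition_features",
    "make_benchmark",
    "BLOSUM_LEVELS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: perturbation level (fraction of positions altered) paired with each matrix
BLOSUM_LEVELS = {
    "BLOSUM30": 0.70,
    "BLOSUM40": 0.60,
    "BLOSUM62": 0.38,
    "BLOSUM80": 0.20,
}


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class BlosumMatrix:
    """Integer substitution score matrix in NCBI text format."""

    name: str
    symbols: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.symbols)
        if self.scores.shape != (n, n):
            raise ValueError("score matrix shape must match symbol count")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError(f"{self.name}: score matrix is not symmetric")
        self._index = {s: i for i, s in enumerate(self.symbols)}

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self._index[a], self._index[b]])

    def to_aligner_matrix(self) -> substitution_matrices.Array:
        arr = substitution_matrices.Array(alphabet="".join(self.symbols), dims=2)
        for i, a in enumerate(self.symbols):
            for j, b in enumerate(self.symbols):
                arr[a, b] = self.scores[i, j]
        return arr


def load_blosum(path) -> BlosumMatrix:
    """Parse an NCBI-format substitution matrix ('#' comments, symbol header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no matrix content")
    header = lines[0].split()
    if any(len(s) != 1 for s in header):
        raise ValueError(f"{path}: malformed header row {header!r}")
    n = len(header)
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1 or parts[0] != header[len(rows)]:
            raise ValueError(f"{path}: malformed matrix row {ln!r}")
        rows.append([int(x) for x in parts[1:]])
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} rows, got {len(rows)}")
    return BlosumMatrix(name=path.stem, symbols=header, scores=np.array(rows, dtype=int))


def packaged_blosum(name: str) -> BlosumMatrix:
    """Load one of the packaged matrices: BLOSUM30, BLOSUM40, BLOSUM62, BLOSUM80."""
    ref = resources.files("ppinet") / "data" / f"{name.upper()}.txt"
    with resources.as_file(ref) as p:
        return load_blosum(p)


@dataclass
class SubstitutionModel:
    """Row-stochastic amino-acid replacement probabilities (zero diagonal)."""

    probabilities: np.ndarray
    alphabet: str = AMINO_ACIDS
    source: str = ""

    def __post_init__(self) -> None:
        P = np.asarray(self.probabilities, dtype=float)
        n = len(self.alphabet)
        if P.shape != (n, n):
            raise ValueError("probability matrix must match the alphabet")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows must sum to 1")
        if np.any(np.diag(P) != 0):
            raise ValueError("diagonal must be zero: a mutation changes the residue")
        self.probabilities = P
        self._index = {s: i for i, s in enumerate(self.alphabet)}

    def draw(self, residue: str, rng: np.random.Generator) -> str:
        i = self._index[residue]
        return self.alphabet[rng.choice(len(self.alphabet), p=self.probabilities[i])]


def substitution_model(B: BlosumMatrix) -> SubstitutionModel:
    """Replacement probabilities from BLOSUM scores.

    P(b | a) proportional to 2^(s(a, b) / 2) over b != a (half-bit
    back-transform with uniform background), row-normalized over the 20
    standard amino acids.
    """
    n = len(AMINO_ACIDS)
    P = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                P[i, j] = 2.0 ** (B.score(a, b) / 2.0)
        P[i] /= P[i].sum()
    return SubstitutionModel(P, AMINO_ACIDS, source=B.name)


def perturb_sequence(
    seq: ProteinSequence,
    level: float,
    model: SubstitutionModel,
    deletion_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
    *,
    detail: bool = False,
):
    """Alter exactly round(level * len) positions of the sequence.

    Of the altered positions, round(deletion_fraction * level * len) are
    deleted and the remainder substituted by model draws (always a different
    residue). Position choice is uniform without replacement.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    if not 0.0 <= deletion_fraction <= 1.0:
        raise ValueError("deletion_fraction must be in [0, 1]")
    rng = rng or np.random.default_rng()
    L = len(seq)
    n_alter = int(round(level * L))
    if n_alter < 1:
        if level > 0:
            warnings.warn(
                f"level {level} alters fewer than one position of a length-{L} "
                "sequence; returning an unchanged copy",
                stacklevel=2,
            )
        out = ProteinSequence(seq.id, seq.residues)
        return (out, {"substituted": [], "deleted": []}) if detail else out
    n_del = min(int(round(deletion_fraction * level * L)), n_alter)
    chosen = rng.choice(L, size=n_alter, replace=False)
    deleted = set(chosen[:n_del].tolist())
    substituted = sorted(set(chosen[n_del:].tolist()))
    residues = []
    for pos, res in enumerate(seq.residues):
        if pos in deleted:
            continue
        if pos in set(substituted):
            residues.append(model.draw(res, rng))
        else:
            residues.append(res)
    out = ProteinSequence(seq.id, "".join(residues))
    if detail:
        return out, {"substituted": substituted, "deleted": sorted(deleted)}
    return out


def sw_identity(
    s1: ProteinSequence | str,
    s2: ProteinSequence | str,
    B: BlosumMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Smith-Waterman percent identity under affine gaps.

    A gap of length k costs gap_open + k * gap_extend. Identity = identical
    aligned positions / alignment length (gaps included) * 100; a best local
    score of zero (no positive-scoring alignment) gives 0.
    """
    r1 = s1.residues if isinstance(s1, ProteinSequence) else str(s1)
    r2 = s2.residues if isinstance(s2, ProteinSequence) else str(s2)
    if not r1 or not r2:
        raise ValueError("sequences must be nonempty")
    B = B or packaged_blosum("BLOSUM62")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = B.to_aligner_matrix()
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if aligner.score(r1, r2) <= 0:
        return 0.0
    aln = aligner.align(r1, r2)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    if length == 0:
        return 0.0
    return 100.0 * counts.identities / length


def composition_features(
    sequences: list[ProteinSequence], k: int = 1, normalize: bool = True
) -> FeatureTable:
    """k-mer composition features (k = 1: amino-acid frequencies)."""
    kmers = [""]
    for _ in range(k):
        kmers = [p + a for p in kmers for a in AMINO_ACIDS]
    index = {km: i for i, km in enumerate(kmers)}
    X = np.zeros((len(sequences), len(kmers)))
    for row, seq in enumerate(sequences):
        s = seq.residues
        for i in range(len(s) - k + 1):
            X[row, index[s[i : i + k]]] += 1.0
        if normalize and len(s) >= k:
            X[row] /= len(s) - k + 1
    return FeatureTable([s.id for s in sequences], X)


@dataclass
class BenchmarkConfig:
    n_proteins: int = 160
    n_modules: int = 16
    seq_len: int = 240
    n_informative: int = 8
    n_noise_features: int = 8
    feature_noise_sd: float = 0.5
    deletion_fraction: float = 0.1
    levels: dict = field(default_factory=lambda: dict(BLOSUM_LEVELS))
    dirichlet_alpha: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules > self.n_proteins:
            raise ValueError("more modules than proteins")
        if self.n_modules < 1 or self.n_proteins < 1 or self.seq_len < 1:
            raise ValueError("invalid benchmark configuration")


@dataclass
class SyntheticBenchmark:
    protein_ids: list[str]
    modules: np.ndarray                       # planted module index per protein
    network: InteractionNetwork               # within-module cliques
    features: FeatureTable                    # informative + noise columns
    sequences: list[ProteinSequence]          # originals ("source species")
    perturbed: dict[str, list[ProteinSequence]]  # per BLOSUM level
    config: BenchmarkConfig


def make_benchmark(config: BenchmarkConfig | None = None, **kwargs) -> SyntheticBenchmark:
    """Generate a reproducible transfer-learning benchmark.

    Proteins are partitioned into modules forming cliques in the interaction
    network. Numeric features are a module prototype plus Gaussian noise with
    extra pure-noise columns. Each module draws an amino-acid frequency
    profile; member sequences are sampled from it, then perturbed copies are
    produced at every configured BLOSUM level (labels carry over to the
    perturbed sets by id).
    """
    if config is None:
        config = BenchmarkConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword arguments, not both")
    rng = np.random.default_rng(config.seed)
    m = config.n_proteins
    ids = [f"P{i:04d}" for i in range(m)]
    modules = np.sort(np.arange(m) % config.n_modules)

    A = (modules[:, None] == modules[None, :]).astype(np.int8)
    np.fill_diagonal(A, 0)
    network = InteractionNetwork(ids, A)

    prototypes = rng.normal(size=(config.n_modules, config.n_informative))
    X_inf = prototypes[modules] + config.feature_noise_sd * rng.normal(
        size=(m, config.n_informative)
    )
    X_noise = rng.normal(size=(m, config.n_noise_features))
    features = FeatureTable(ids, np.hstack([X_inf, X_noise]))

    profiles = rng.dirichlet(
        np.full(len(AMINO_ACIDS), config.dirichlet_alpha), size=config.n_modules
    )
    aa = np.array(list(AMINO_ACIDS))
    sequences = [
        ProteinSequence(
            ids[i], "".join(aa[rng.choice(20, size=config.seq_len, p=profiles[modules[i]])])
        )
        for i in range(m)
    ]

    perturbed: dict[str, list[ProteinSequence]] = {}
    for name, level in config.levels.items():
        model = substitution_model(packaged_blosum(name))
        perturbed[name] = [
            perturb_sequence(s, level, model, config.deletion_fraction, rng)
            for s in sequences
        ]
    return SyntheticBenchmark(
        protein_ids=ids, modules=modules, network=network, features=features,
        sequences=sequences, perturbed=perturbed, config=config,
    )
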