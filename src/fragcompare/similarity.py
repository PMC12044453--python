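"""Binary fingerprints, Tanimoto similarity and library diversity profiles.

Supported fingerprints: 166-bit structural keys (``maccs166``) and hashed
circular fingerprints of radius 2 or 3 folded to 1024 bits
(``morgan2_1024``/``morgan3_1024``).

Exhaustive pairwise similarity is computed for small libraries; above a
configurable trigger size, ten subsets of 5000 structures (defaults) are
drawn without replacement and pairwise similarities are computed within
each subset.  Subset ``i`` uses ``seed + i`` so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

logger = logging.getLogger(__name__)

FINGERPRINT_KINDS = ("maccs166", "morgan2_1024", "morgan3_1024")

_CDF_GRID_POINTS = 201
_VALUE_KEEP_LIMIT = 5_000_000
_HIST_BINS = 2048


@dataclass(frozen=True)
class FingerprintSpec:
    kind: str = "morgan2_1024"

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_KINDS:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")

    @property
    def n_bits(self) -> int:
        return 166 if self.kind == "maccs166" else 1024


@dataclass(frozen=True)
class SubsampleScheme:
    n_subsets: int = 10
    subset_size: int = 5000
    seed: int = 0
    trigger_size: int = 20_000


_generators: dict[int, object] = {}


def _morgan_generator(radius: int):
    if radius not in _generators:
        _generators[radius] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=1024
        )
    return _generators[radius]


def fingerprint(mol: Chem.Mol, spec: FingerprintSpec) -> np.ndarray:
    """Deterministic 0/1 vector of the spec's length.

    The structural-key variant drops the unused bit 0 of the toolkit's
    167-bit vector so the advertised 166-bit length holds.
    """
    if spec.kind == "maccs166":
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(167, dtype=np.uint8)
        for bit in bv.GetOnBits():
            arr[bit] = 1
        return arr[1:]
    radius = 2 if spec.kind == "morgan2_1024" else 3
    bv = _morgan_generator(radius).GetFingerprint(mol)
    arr = np.zeros(1024, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(mols: list[Chem.Mol], spec: FingerprintSpec) -> np.ndarray:
    return np.vstack([fingerprint(mol, spec) for mol in mols])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; defined as 1.0 when both vectors are all-zero."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    intersection = int(np.count_nonzero(np.logical_and(a, b)))
    union = int(np.count_nonzero(np.logical_or(a, b)))
    if union == 0:
        return 1.0
    return intersection / union


def pairwise_tanimoto(matrix: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle Tanimoto values for the rows of ``matrix``."""
    x = matrix.astype(np.int32)
    inter = x @ x.T
    pop = x.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    iu = np.triu_indices(len(x), k=1)
    numerator = inter[iu].astype(float)
    denominator = union[iu].astype(float)
    out = np.ones_like(numerator)
    nz = denominator > 0
    out[nz] = numerator[nz] / denominator[nz]
    return out


@dataclass
class SimilarityDistribution:
    fingerprint: FingerprintSpec
    mode: str  # "exhaustive" | "subsample"
    n_molecules: int
    n_values: int
    median: float
    q1: float
    q3: float
    min: float
    max: float
    cdf_similarity: np.ndarray
    cdf_fraction: np.ndarray
    per_subset_medians: list[float] = field(default_factory=list)
    values: np.ndarray | None = None


def _summarize(chunks: list[np.ndarray], spec, mode, n_mols, medians) -> SimilarityDistribution:
    counts = np.zeros(_HIST_BINS, dtype=np.int64)
    n_values = 0
    vmin, vmax = np.inf, -np.inf
    total = sum(chunk.size for chunk in chunks)
    keep = total <= _VALUE_KEEP_LIMIT
    kept = [] if keep else None
    edges = np.linspace(0.0, 1.0, _HIST_BINS + 1)
    for chunk in chunks:
        counts += np.histogram(chunk, bins=edges)[0]
        n_values += chunk.size
        vmin = min(vmin, float(chunk.min()))
        vmax = max(vmax, float(chunk.max()))
        if keep:
            kept.append(chunk)
    if keep:
        pooled = np.concatenate(kept)
        q1, med, q3 = np.percentile(pooled, [25, 50, 75])
        values = pooled
    else:  # stream quantiles off the fine histogram
        cum = np.cumsum(counts) / n_values
        centers = 0.5 * (edges[:-1] + edges[1:])
        q1, med, q3 = (centers[np.searchsorted(cum, q)] for q in (0.25, 0.5, 0.75))
        values = None
    cum = np.cumsum(counts) / n_values
    grid = np.linspace(0.0, 1.0, _CDF_GRID_POINTS)
    cdf = np.interp(grid, edges[1:], cum)
    cdf[-1] = 1.0
    return SimilarityDistribution(
        fingerprint=spec,
        mode=mode,
        n_molecules=n_mols,
        n_values=n_values,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(vmin),
        max=float(vmax),
        cdf_similarity=grid,
        cdf_fraction=cdf,
        per_subset_medians=medians,
        values=values,
    )


def diversity_distribution(
    mols: list[Chem.Mol],
    spec: FingerprintSpec,
    scheme: SubsampleScheme = SubsampleScheme(),
) -> SimilarityDistribution:
    """Pairwise-similarity distribution of a library under one fingerprint.

    Exhaustive below the trigger size (exactly n(n-1)/2 values); otherwise
    the subset protocol pools within-subset pairwise values and retains the
    per-subset medians for dispersion.
    """
    if len(mols) < 2:
        raise ValueError("diversity distribution needs at least 2 molecules")
    matrix = fingerprint_matrix(mols, spec)
    if len(mols) <= scheme.trigger_size:
        values = pairwise_tanimoto(matrix)
        return _summarize([values], spec, "exhaustive", len(mols), [])
    chunks = []
    medians = []
    size = min(scheme.subset_size, len(mols))
    for i in range(scheme.n_subsets):
        rng = np.random.default_rng(scheme.seed + i)
        idx = rng.choice(len(mols), size=size, replace=False)
        chunk = pairwise_tanimoto(matrix[idx])
        medians.append(float(np.median(chunk)))
        chunks.append(chunk)
    return _summarize(chunks, spec, "subsample", len(mols), medians)
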