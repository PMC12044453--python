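"""Synthetic-accessibility scoring (fragment contributions minus a
structural-complexity penalty, scaled into [1, 10]; 1 = easy).

The fragment score is the count-weighted mean log-frequency contribution of
the molecule's radius-2 circular substructures, looked up in the published
frequency table; environments absent from the table contribute the default
value of -4.  The complexity penalty sums size, stereo, spiro, bridgehead
and macrocycle terms; a symmetry correction (fingerprint density) rewards
molecules with few distinct environments.  The raw difference is mapped to
the [1, 10] scale with the published piecewise smoothing at the hard end.

The frequency table ships with the reference distribution
(``fpscores.pkl.gz``); it is located via the ``FRAGCOMPARE_FPSCORES``
environment variable or the RDKit contrib directory.
"""

from __future__ import annotations

import gzip
import math
import os
import pickle
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

#: Score above which a structure is conventionally read as hard to make.
EASY_SYNTHESIS_THRESHOLD = 6.0

_MISSING_CONTRIBUTION = -4.0

_fscores: dict[int, float] | None = None
_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=2)


def _default_table_path() -> str:
    env = os.environ.get("FRAGCOMPARE_FPSCORES")
    if env:
        return env
    return os.path.join(RDConfig.RDContribDir, "SA_Score", "fpscores.pkl.gz")


def load_fragment_scores(path: str | None = None) -> dict[int, float]:
    """Load (and cache) the circular-substructure frequency table."""
    global _fscores
    if _fscores is not None and path is None:
        return _fscores
    table_path = path or _default_table_path()
    if not os.path.exists(table_path):
        raise FileNotFoundError(
            f"fragment frequency table not found at {table_path}; set "
            "FRAGCOMPARE_FPSCORES to the fpscores.pkl.gz location"
        )
    with gzip.open(table_path) as handle:
        data = pickle.load(handle)
    scores: dict[int, float] = {}
    for row in data:
        contribution = float(row[0])
        for bit_id in row[1:]:
            scores[bit_id] = contribution
    _fscores = scores
    return scores


@dataclass(frozen=True)
class SABreakdown:
    """Score components: ``raw = fragment_score - complexity_penalty``;
    ``score`` is the [1, 10]-scaled final value."""

    fragment_score: float
    complexity_penalty: float
    raw: float
    score: float


def sa_breakdown(mol: Chem.Mol) -> SABreakdown:
    scores = load_fragment_scores()

    counts = _fpgen.GetSparseCountFingerprint(mol).GetNonzeroElements()
    total = 0
    fragment_sum = 0.0
    for bit_id, count in counts.items():
        total += count
        fragment_sum += scores.get(bit_id, _MISSING_CONTRIBUTION) * count
    fragment_score = fragment_sum / total

    n_atoms = mol.GetNumAtoms()
    n_chiral = len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=True)
    )
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    n_macro = sum(1 for ring in mol.GetRingInfo().AtomRings() if len(ring) > 8)

    size_penalty = n_atoms**1.005 - n_atoms
    stereo_penalty = math.log10(n_chiral + 1)
    spiro_penalty = math.log10(n_spiro + 1)
    bridge_penalty = math.log10(n_bridge + 1)
    macrocycle_penalty = math.log10(2) if n_macro > 0 else 0.0
    complexity_penalty = (
        size_penalty + stereo_penalty + spiro_penalty + bridge_penalty + macrocycle_penalty
    )

    # symmetry correction: many repeats of few environments -> easier
    if n_atoms > len(counts):
        fragment_score += math.log(float(n_atoms) / len(counts)) * 0.5

    raw = fragment_score - complexity_penalty

    low, high = -4.0, 2.5
    score = 11.0 - (raw - low + 1.0) / (high - low) * 9.0
    if score > 8.0:
        score = 8.0 + math.log(score + 1.0 - 9.0)
    score = min(10.0, max(1.0, score))
    return SABreakdown(
        fragment_score=fragment_score,
        complexity_penalty=complexity_penalty,
        raw=raw,
        score=score,
    )


def sa_score(mol: Chem.Mol) -> float:
    return sa_breakdown(mol).score


@dataclass
class SASummary:
    mean: float
    threshold: float
    n_above_threshold: int
    fraction_above_threshold: float
    hist_density: np.ndarray
    hist_edges: np.ndarray
    scores: np.ndarray


def library_sa_summary(
    mols: list[Chem.Mol], threshold: float = EASY_SYNTHESIS_THRESHOLD, bins: int = 36
) -> SASummary:
    """Mean score, fraction above ``threshold`` and a density histogram on
    [1, 10] over unique structures."""
    if not mols:
        raise ValueError("SA summary of an empty collection")
    values = np.array([sa_score(mol) for mol in mols])
    density, edges = np.histogram(values, bins=bins, range=(1.0, 10.0), density=True)
    n_above = int((values > threshold).sum())
    return SASummary(
        mean=float(values.mean()),
        threshold=threshold,
        n_above_threshold=n_above,
        fraction_above_threshold=n_above / len(values),
        hist_density=density,
        hist_edges=edges,
        scores=values,
    )
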