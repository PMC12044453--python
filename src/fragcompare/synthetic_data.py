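"""Generation of toy compound libraries with controllable composition.

Molecules are assembled from a fixed set of ring/chain building blocks
joined through linker groups that are cleavable by the decomposition rules
(amide, ester, ether, amine, sulfonamide, urea, biaryl bond), so every
multi-block molecule is guaranteed to fragment.  Two built-in population
profiles mirror the contrast the comparative analysis assumes:

* ``np_like`` -- oxygen-rich, sp3-rich, chiral, fused/bridged/spiro ring
  systems, almost no nitrogen;
* ``synthetic_like`` -- nitrogen-rich, aromatic-ring-rich, flat and achiral.

Elemental-composition targets are hit by reweighting block and linker
choices while a molecule is being assembled (the sampler tilts towards
blocks that move the running library composition towards the target), not
by post-hoc filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .chem_io import MoleculeRecord

RDLogger.DisableLog("rdApp.warning")


@dataclass(frozen=True)
class Block:
    """A building block: SMILES plus two attachment atom indices (atoms
    that carry at least one hydrogen in the block)."""

    name: str
    smiles: str
    attach_in: int
    attach_out: int
    kind: str  # ring-system family or "chain"


BLOCKS: dict[str, Block] = {
    block.name: block
    for block in [
        Block("benzene", "c1ccccc1", 0, 3, "aromatic_carbocycle"),
        Block("toluene_core", "Cc1ccccc1", 2, 5, "aromatic_carbocycle"),
        Block("pyridine", "c1ccncc1", 0, 2, "aromatic_N_heterocycle"),
        Block("pyrimidine", "c1cncnc1", 0, 1, "aromatic_N_heterocycle"),
        Block("methylpyrazole", "Cn1cccn1", 0, 3, "aromatic_N_heterocycle"),
        Block("oxane", "C1CCOCC1", 0, 5, "saturated_O_heterocycle"),
        Block("oxolane", "C1CCOC1", 0, 1, "saturated_O_heterocycle"),
        Block("dioxolane", "C1OCCO1", 2, 3, "saturated_O_heterocycle"),
        Block("pyranose_triol", "CCC1OCC(O)C(O)C1O", 0, 0, "saturated_O_heterocycle"),
        Block("furan", "c1ccoc1", 0, 1, "aromatic_O_heterocycle"),
        Block("benzodioxole", "c1ccc2c(c1)OCO2", 0, 1, "aromatic_O_heterocycle"),
        Block("naphthalene", "c1ccc2ccccc2c1", 0, 5, "fused_bicycle"),
        Block("indane", "C1Cc2ccccc2C1", 0, 4, "fused_bicycle"),
        Block("decalin", "C1CCC2CCCCC2C1", 0, 5, "fused_bicycle"),
        Block("norbornane", "C1CC2CCC1C2", 0, 4, "bridged_bicycle"),
        Block("oxanorbornane", "C1CC2CCC1O2", 0, 4, "bridged_bicycle"),
        Block("spirononane", "C1CCC2(C1)CCCC2", 0, 6, "spiro_pair"),
        Block("oxaspiro", "C1CCC2(C1)CCOC2", 0, 6, "spiro_pair"),
        Block("methyl", "C", 0, 0, "chain"),
        Block("isopropyl", "CC(C)C", 0, 3, "chain"),
        Block("chiral_ol", "C[C@@H](O)CC", 0, 4, "chain"),
        Block("diol_chain", "OCC(O)CC", 4, 4, "chain"),
        Block("piperidine", "C1CCNCC1", 0, 2, "saturated_N_heterocycle"),
        Block("morpholine", "C1COCCN1", 0, 1, "saturated_N_heterocycle"),
    ]
}

#: Linker templates: SMILES inserted between two blocks, with the atom
#: bonded to the left block and the atom bonded to the right block.  Each
#: produces at least one rule-cleavable acyclic bond.
LINKERS: dict[str, tuple[str, int, int]] = {
    "ether": ("O", 0, 0),
    "ester": ("C(=O)O", 0, 2),
    "amide": ("C(=O)N", 0, 2),
    "amine": ("N", 0, 0),
    "sulfonamide": ("S(=O)(=O)N", 0, 3),
    "urea": ("NC(=O)N", 0, 3),
    "biaryl": ("", -1, -1),  # direct bond, aromatic carbons only
}

_PROFILE_BLOCK_WEIGHTS = {
    "np_like": {
        "aromatic_carbocycle": 1.2,
        "aromatic_N_heterocycle": 0.02,
        "aromatic_O_heterocycle": 1.8,
        "saturated_O_heterocycle": 2.4,
        "saturated_N_heterocycle": 0.0,
        "fused_bicycle": 1.0,
        "bridged_bicycle": 0.8,
        "spiro_pair": 0.8,
        "chain": 1.6,
    },
    "synthetic_like": {
        "aromatic_carbocycle": 2.0,
        "aromatic_N_heterocycle": 2.5,
        "aromatic_O_heterocycle": 0.35,
        "saturated_O_heterocycle": 0.25,
        "saturated_N_heterocycle": 0.8,
        "fused_bicycle": 0.7,
        "bridged_bicycle": 0.05,
        "spiro_pair": 0.05,
        "chain": 0.6,
    },
}

_PROFILE_LINKER_WEIGHTS = {
    "np_like": {
        "ether": 3.0,
        "ester": 2.0,
        "amide": 0.05,
        "amine": 0.02,
        "sulfonamide": 0.0,
        "urea": 0.0,
        "biaryl": 0.8,
    },
    "synthetic_like": {
        "ether": 0.5,
        "ester": 0.4,
        "amide": 2.5,
        "amine": 1.2,
        "sulfonamide": 0.8,
        "urea": 0.4,
        "biaryl": 1.5,
    },
}

_PROFILE_TARGETS = {
    "np_like": {"frac_O": 0.22, "frac_N": 0.01, "frac_sp3": 0.68},
    "synthetic_like": {"frac_O": 0.10, "frac_N": 0.15, "frac_sp3": 0.30},
}


@dataclass(frozen=True)
class GeneratorParams:
    n: int = 100
    profile: str = "np_like"
    target_frac_O: float | None = None
    target_frac_N: float | None = None
    target_frac_sp3: float | None = None
    ring_block_weights: dict = field(default_factory=dict)
    linker_weights: dict = field(default_factory=dict)
    mean_blocks: float = 3.0
    planted_duplicates: tuple = ()  # (smiles, multiplicity) pairs
    seed: int = 0

    def resolved(self) -> "GeneratorParams":
        if self.profile not in ("np_like", "synthetic_like", "custom"):
            raise ValueError(f"unknown profile {self.profile!r}")
        base = self.profile if self.profile != "custom" else "np_like"
        targets = _PROFILE_TARGETS[base]
        block_weights = dict(_PROFILE_BLOCK_WEIGHTS[base])
        block_weights.update(self.ring_block_weights)
        linker_weights = dict(_PROFILE_LINKER_WEIGHTS[base])
        linker_weights.update(self.linker_weights)
        return replace(
            self,
            target_frac_O=(
                self.target_frac_O if self.target_frac_O is not None else targets["frac_O"]
            ),
            target_frac_N=(
                self.target_frac_N if self.target_frac_N is not None else targets["frac_N"]
            ),
            target_frac_sp3=(
                self.target_frac_sp3
                if self.target_frac_sp3 is not None
                else targets["frac_sp3"]
            ),
            ring_block_weights=block_weights,
            linker_weights=linker_weights,
        )


def _composition(smiles: str) -> tuple[int, int, int, int, int]:
    """(heavy, C, O, N, sp3 C) of a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    heavy = mol.GetNumHeavyAtoms()
    n_c = n_o = n_n = n_sp3 = 0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 6:
            n_c += 1
            if atom.GetHybridization() == Chem.HybridizationType.SP3:
                n_sp3 += 1
        elif z == 8:
            n_o += 1
        elif z == 7:
            n_n += 1
    return heavy, n_c, n_o, n_n, n_sp3


_BLOCK_COMPOSITION = {name: _composition(b.smiles) for name, b in BLOCKS.items()}
_LINKER_COMPOSITION = {
    name: _composition(smiles) if smiles else (0, 0, 0, 0, 0)
    for name, (smiles, _, _) in LINKERS.items()
}

_STEER_GAIN = 25.0


class _RunningComposition:
    def __init__(self):
        self.heavy = 0
        self.carbon = 0
        self.oxygen = 0
        self.nitrogen = 0
        self.sp3 = 0

    def add(self, comp: tuple[int, int, int, int, int]) -> None:
        heavy, c, o, n, sp3 = comp
        self.heavy += heavy
        self.carbon += c
        self.oxygen += o
        self.nitrogen += n
        self.sp3 += sp3

    def fracs(self) -> tuple[float, float, float]:
        if self.heavy == 0:
            return 0.0, 0.0, 0.0
        sp3_frac = self.sp3 / self.carbon if self.carbon else 0.0
        return self.oxygen / self.heavy, self.nitrogen / self.heavy, sp3_frac


def _steered_weights(
    names: list[str],
    base: dict[str, float],
    compositions: dict[str, tuple],
    running: _RunningComposition,
    params: GeneratorParams,
) -> np.ndarray:
    cur_o, cur_n, cur_sp3 = running.fracs()
    weights = np.zeros(len(names))
    for i, name in enumerate(names):
        w = base.get(name, 0.0)
        if w <= 0:
            continue
        heavy, c, o, n, sp3 = compositions[name]
        if heavy:
            tilt = (
                (params.target_frac_O - cur_o) * (o / heavy - params.target_frac_O)
                + (params.target_frac_N - cur_n) * (n / heavy - params.target_frac_N)
                + (params.target_frac_sp3 - cur_sp3)
                * ((sp3 / c if c else 0.0) - params.target_frac_sp3)
            )
        else:
            tilt = 0.0
        weights[i] = w * math.exp(_STEER_GAIN * tilt)
    return weights


def _choose(rng: np.random.Generator, names: list[str], weights: np.ndarray) -> str:
    total = weights.sum()
    if total <= 0:
        raise ValueError("no candidate has positive weight")
    return names[rng.choice(len(names), p=weights / total)]


def _attach(mol: Chem.RWMol, a: int, b: int, aromatic_only_ok: bool) -> None:
    mol.AddBond(a, b, Chem.BondType.SINGLE)
    for idx in (a, b):
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetNumExplicitHs() > 0:
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)


def _join(left: Chem.Mol, left_attach: int, right: Chem.Mol, right_attach: int,
          linker_name: str) -> Chem.Mol:
    """Join two pieces through a linker (or directly for the biaryl bond)."""
    smiles, link_in, link_out = LINKERS[linker_name]
    combined = Chem.RWMol(Chem.CombineMols(left, right))
    offset = left.GetNumAtoms()
    if linker_name == "biaryl":
        _attach(combined, left_attach, offset + right_attach, True)
    else:
        linker = Chem.MolFromSmiles(smiles)
        combined = Chem.RWMol(Chem.CombineMols(combined.GetMol(), linker))
        linker_offset = offset + right.GetNumAtoms()
        _attach(combined, left_attach, linker_offset + link_in, False)
        _attach(combined, linker_offset + link_out, offset + right_attach, False)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return out


def _block_mol(block: Block) -> Chem.Mol:
    mol = Chem.MolFromSmiles(block.smiles)
    # make attachment hydrogens explicit so bookkeeping in _attach works
    for idx in {block.attach_in, block.attach_out}:
        atom = mol.GetAtomWithIdx(idx)
        atom.SetNumExplicitHs(atom.GetTotalNumHs())
        atom.SetNoImplicit(True)
    return mol


def _check_feasible(params: GeneratorParams) -> None:
    names = [n for n, w in params.ring_block_weights.items() if w > 0]
    blocks = [b for b in BLOCKS.values() if b.kind in names]
    if not blocks:
        raise ValueError("no building block has positive weight")
    best_o = max(
        _BLOCK_COMPOSITION[b.name][2] / _BLOCK_COMPOSITION[b.name][0] for b in blocks
    )
    if params.target_frac_O > best_o + 0.1:
        raise ValueError(
            f"target_frac_O={params.target_frac_O} infeasible: the richest "
            f"available block reaches only {best_o:.2f}"
        )


def generate_molecule(
    rng: np.random.Generator, params: GeneratorParams, running: _RunningComposition
) -> str:
    """Assemble one molecule; returns its canonical SMILES."""
    block_names = [
        name
        for name, block in BLOCKS.items()
        if params.ring_block_weights.get(block.kind, 0.0) > 0
    ]
    base_block = {
        name: params.ring_block_weights[BLOCKS[name].kind] for name in block_names
    }
    linker_names = [n for n, w in params.linker_weights.items() if w > 0]

    n_blocks = max(1, 1 + rng.poisson(max(0.0, params.mean_blocks - 1)))
    weights = _steered_weights(block_names, base_block, _BLOCK_COMPOSITION, running, params)
    first = BLOCKS[_choose(rng, block_names, weights)]
    mol = _block_mol(first)
    attach_out = first.attach_out
    running.add(_BLOCK_COMPOSITION[first.name])
    for _ in range(n_blocks - 1):
        weights = _steered_weights(
            block_names, base_block, _BLOCK_COMPOSITION, running, params
        )
        nxt = BLOCKS[_choose(rng, block_names, weights)]
        link_weights = _steered_weights(
            linker_names,
            {n: params.linker_weights[n] for n in linker_names},
            _LINKER_COMPOSITION,
            running,
            params,
        )
        out_aromatic = mol.GetAtomWithIdx(attach_out).GetIsAromatic()
        in_aromatic = (
            Chem.MolFromSmiles(nxt.smiles).GetAtomWithIdx(nxt.attach_in).GetIsAromatic()
        )
        if "biaryl" in linker_names and not (out_aromatic and in_aromatic):
            link_weights[linker_names.index("biaryl")] = 0.0
        if link_weights.sum() <= 0:
            link_weights = np.array(
                [1.0 if n != "biaryl" else 0.0 for n in linker_names]
            )
        linker = _choose(rng, linker_names, link_weights)
        right = _block_mol(nxt)
        offset = mol.GetNumAtoms()
        mol = _join(mol, attach_out, right, nxt.attach_in, linker)
        attach_out = offset + nxt.attach_out
        running.add(_BLOCK_COMPOSITION[nxt.name])
        running.add(_LINKER_COMPOSITION[linker])
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(False)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_library(params: GeneratorParams) -> list[MoleculeRecord]:
    """Generate a deterministic library of pending molecule records."""
    params = params.resolved()
    if params.n < 1:
        raise ValueError("n must be >= 1")
    _check_feasible(params)
    rng = np.random.default_rng(params.seed)
    running = _RunningComposition()
    records = []
    for i in range(params.n):
        smiles = generate_molecule(rng, params, running)
        records.append(MoleculeRecord(source_id=f"gen{i + 1}", raw_smiles=smiles))
    for smiles, multiplicity in params.planted_duplicates:
        for j in range(multiplicity):
            records.append(
                MoleculeRecord(
                    source_id=f"planted{len(records) + 1}", raw_smiles=smiles
                )
            )
    return records


# ---------------------------------------------------------------------------
# benchmark suite

#: Hand-audited decomposition cases: input SMILES -> expected leaf SMILES
#: (derived by manual application of the cleavage rules; hydrogens cap the
#: cut bonds).  Frozen here as generator ground truth.
AUDITED_DECOMPOSITIONS: dict[str, set[str]] = {
    # biaryl bond -> two benzenes
    "c1ccc(-c2ccccc2)cc1": {"c1ccccc1"},
    # amide C-N -> acetaldehyde + aniline
    "CC(=O)Nc1ccccc1": {"CC=O", "Nc1ccccc1"},
    # ester C-O -> acetaldehyde + phenol
    "CC(=O)Oc1ccccc1": {"CC=O", "Oc1ccccc1"},
    # ether (aliphatic side cleaved) -> phenol + methane
    "COc1ccccc1": {"C", "Oc1ccccc1"},
    # aromatic N - aliphatic C -> pyrrole + methane
    "Cn1cccc1": {"C", "c1cc[nH]c1"},
    # sulfonamide N-S first; the released dimethylamine then dissolves
    # under the amine rule -> methane + ammonia + capped sulfonyl
    "CN(C)S(=O)(=O)c1ccccc1": {"C", "N", "O=[SH](=O)c1ccccc1"},
    # urea: both N-C(=O) bonds -> formaldehyde + 2 anilines
    "O=C(Nc1ccccc1)Nc1ccccc1": {"C=O", "Nc1ccccc1"},
    # olefin -> two ethanes (from 2-butene)
    "C/C=C/C": {"CC"},
    # lactam N - aliphatic C -> caprolactam + toluene
    "O=C1CCCCCN1Cc1ccccc1": {"Cc1ccccc1", "O=C1CCCCCN1"},
    # tertiary amine: all three N-C bonds -> ammonia + ethane x2 + toluene
    "CCN(CC)Cc1ccccc1": {"N", "CC", "Cc1ccccc1"},
}


@dataclass
class BenchmarkSuite:
    libraries: dict  # name -> list[MoleculeRecord]
    ground_truth: dict


def generate_benchmark_suite(seed: int = 0, n: int = 250) -> BenchmarkSuite:
    """Paired NP-like and synthetic-like libraries plus an RO3-enriched
    vendor-like library, with planted cross-library duplicates and a
    machine-readable ground-truth sheet."""
    planted_everywhere = ("c1ccccc1", "Oc1ccccc1", "c1ccncc1")
    np_params = GeneratorParams(
        n=n,
        profile="np_like",
        seed=seed,
        planted_duplicates=tuple((s, 2) for s in planted_everywhere),
    )
    syn_params = GeneratorParams(
        n=n,
        profile="synthetic_like",
        seed=seed + 1,
        planted_duplicates=tuple((s, 1) for s in planted_everywhere),
    )
    vendor_params = GeneratorParams(
        n=max(10, n // 2),
        profile="synthetic_like",
        mean_blocks=1.3,
        seed=seed + 2,
        planted_duplicates=tuple((s, 1) for s in planted_everywhere),
    )
    libraries = {
        "np_like": generate_library(np_params),
        "synthetic_like": generate_library(syn_params),
        "vendor_like": generate_library(vendor_params),
    }
    # make the cross-library intersection exactly the planted set: drop
    # incidental collisions from every library after the first that has them
    planted_canonical = {
        Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in planted_everywhere
    }
    seen: dict[str, str] = {}
    for name, records in libraries.items():
        kept = []
        for record in records:
            canonical = Chem.MolToSmiles(Chem.MolFromSmiles(record.raw_smiles))
            if canonical in planted_canonical:
                kept.append(record)
                continue
            if seen.get(canonical, name) != name:
                continue
            seen[canonical] = name
            kept.append(record)
        libraries[name] = kept
    ground_truth = {
        "planted_overlap": {
            ("np_like", "synthetic_like"): set(planted_everywhere),
            ("np_like", "vendor_like"): set(planted_everywhere),
            ("synthetic_like", "vendor_like"): set(planted_everywhere),
        },
        "composition_targets": {
            "np_like": _PROFILE_TARGETS["np_like"],
            "synthetic_like": _PROFILE_TARGETS["synthetic_like"],
        },
        "audited_decompositions": AUDITED_DECOMPOSITIONS,
        "params": {
            "np_like": np_params,
            "synthetic_like": syn_params,
            "vendor_like": vendor_params,
        },
    }
    return BenchmarkSuite(libraries=libraries, ground_truth=ground_truth)
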