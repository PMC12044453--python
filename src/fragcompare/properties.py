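"""Rule-of-three profiles and the constitutional/complexity descriptor panel.

The rule-of-three filter keeps fragments with MW <= 300 Da, rotatable
bonds <= 3, TPSA <= 60 A^2, logP <= 3, H-bond acceptors <= 3 and H-bond
donors <= 3 (all thresholds inclusive and configurable).

Conventions:

* logP is the Crippen atomic-contribution estimate;
* HBA counts N and O atoms, HBD counts N-H and O-H hydrogens;
* a rotatable bond is an acyclic single bond between two non-terminal
  heavy atoms, amide C-N excluded;
* TPSA is the classic Ertl topological variant (no S/P contributions);
* molecular weight includes implicit hydrogens, average atomic masses;
* the chiral-carbon fraction counts assigned and unassigned potential
  tetrahedral stereocenters over all carbons.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .recap import FragmentRecord

RO3_DEFAULTS = {
    "mw": 300.0,
    "rb": 3,
    "tpsa": 60.0,
    "logp": 3.0,
    "hba": 3,
    "hbd": 3,
}


@dataclass(frozen=True)
class Ro3Profile:
    mw: float
    rb: int
    tpsa: float
    logp: float
    hba: int
    hbd: int
    passes: bool


@dataclass(frozen=True)
class DescriptorProfile:
    """The 18-descriptor constitutional/complexity panel.

    Ring counts use the smallest set of smallest rings; an aromatic ring is
    one whose every bond is aromatic, and a heterocycle is a ring containing
    at least one non-carbon ring atom.
    """

    n_C: int
    n_O: int
    n_N: int
    frac_C: float
    frac_O: float
    frac_N: float
    frac_sp3_C: float
    frac_chiral_C: float
    mw: float
    n_heavy: int
    n_rings: int
    n_aliphatic_rings: int
    n_aromatic_rings: int
    n_heterocycles: int
    n_aliphatic_heterocycles: int
    n_aromatic_heterocycles: int
    n_spiro_atoms: int
    n_bridgehead_atoms: int


DESCRIPTOR_ORDER = [f.name for f in fields(DescriptorProfile)]


def ro3_profile(mol: Chem.Mol, thresholds: dict | None = None) -> Ro3Profile:
    """Compute the six fragment-likeness properties and the pass flag."""
    limits = dict(RO3_DEFAULTS)
    if thresholds:
        limits.update(thresholds)
    mw = Descriptors.MolWt(mol)
    rb = Lipinski.NumRotatableBonds(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    logp = Crippen.MolLogP(mol)
    hba = Lipinski.NOCount(mol)
    hbd = Lipinski.NHOHCount(mol)
    passes = (
        mw <= limits["mw"]
        and rb <= limits["rb"]
        and tpsa <= limits["tpsa"]
        and logp <= limits["logp"]
        and hba <= limits["hba"]
        and hbd <= limits["hbd"]
    )
    return Ro3Profile(mw=mw, rb=rb, tpsa=tpsa, logp=logp, hba=hba, hbd=hbd, passes=passes)


def filter_ro3(
    fragments: list[FragmentRecord], thresholds: dict | None = None
) -> tuple[list[FragmentRecord], float | None]:
    """Keep fragments passing the rule of three, preserving occurrence data.

    Returns the passing subset and the pass rate as a percentage rounded to
    one decimal (``None`` on empty input).
    """
    passing = []
    for fragment in fragments:
        mol = Chem.MolFromSmiles(fragment.canonical_smiles)
        if mol is None:
            continue
        if ro3_profile(mol, thresholds).passes:
            passing.append(fragment)
    if not fragments:
        return [], None
    return passing, round(100.0 * len(passing) / len(fragments), 1)


def descriptor_profile(mol: Chem.Mol) -> DescriptorProfile:
    n_heavy = mol.GetNumHeavyAtoms()
    n_c = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    n_o = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8)
    n_n = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7)
    chiral_centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    n_chiral_c = sum(
        1 for idx, _ in chiral_centers if mol.GetAtomWithIdx(idx).GetAtomicNum() == 6
    )
    return DescriptorProfile(
        n_C=n_c,
        n_O=n_o,
        n_N=n_n,
        frac_C=n_c / n_heavy if n_heavy else 0.0,
        frac_O=n_o / n_heavy if n_heavy else 0.0,
        frac_N=n_n / n_heavy if n_heavy else 0.0,
        frac_sp3_C=rdMolDescriptors.CalcFractionCSP3(mol),
        frac_chiral_C=n_chiral_c / n_c if n_c else 0.0,
        mw=Descriptors.MolWt(mol),
        n_heavy=n_heavy,
        n_rings=rdMolDescriptors.CalcNumRings(mol),
        n_aliphatic_rings=rdMolDescriptors.CalcNumAliphaticRings(mol),
        n_aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        n_heterocycles=rdMolDescriptors.CalcNumHeterocycles(mol),
        n_aliphatic_heterocycles=rdMolDescriptors.CalcNumAliphaticHeterocycles(mol),
        n_aromatic_heterocycles=rdMolDescriptors.CalcNumAromaticHeterocycles(mol),
        n_spiro_atoms=rdMolDescriptors.CalcNumSpiroAtoms(mol),
        n_bridgehead_atoms=rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
    )


def library_descriptor_summary(mols: list[Chem.Mol]) -> pd.Series:
    """Arithmetic mean of each descriptor over unique structures.

    The input is taken as-is (deduplicate upstream); means are not
    occurrence-weighted.
    """
    if not mols:
        raise ValueError("descriptor summary of an empty collection")
    rows = [descriptor_profile(mol).__dict__ for mol in mols]
    frame = pd.DataFrame(rows, columns=DESCRIPTOR_ORDER)
    return frame.mean(axis=0)
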