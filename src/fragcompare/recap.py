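"""Retrosynthetic decomposition by eleven named bond-cleavage rules.

Each rule matches an acyclic bond in a defined chemical environment and
cleaves it; the two open valences are capped with hydrogen.  Decomposition
is hierarchical: all matching bonds of the current structure are broken at
once, the pieces are separated, and the rules are re-applied to each piece
until nothing matches.  Only leaf fragments are returned; a structure with
no cleavable bond yields no fragments.

Cleaving bonds (rather than deleting linker heteroatoms, as some toolkit
reaction sets do) keeps the heavy atoms of the leaves an exact partition of
the parent's heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem_io import STATUS_STANDARDIZED, MoleculeRecord
from .standardize import standardize_molecule

logger = logging.getLogger(__name__)

_ORIG_IDX = "_fc_orig_idx"


@dataclass(frozen=True)
class RecapRule:
    """One named cleavage rule.

    ``patterns`` are SMARTS whose atom maps 1 and 2 mark the bond to break.
    A rule never cleaves a ring bond (every pattern requires ``!@``).
    """

    name: str
    patterns: tuple[str, ...]

    def compiled(self):
        return [Chem.MolFromSmarts(p) for p in self.patterns]


# Environments follow the published retrosynthetic rule set; the amine rule
# covers both acyclic and ring (non-aromatic) nitrogens.  Amide/sulfonamide
# nitrogens and ester oxygens are excluded from the amine/ether rules so each
# bond is attributed to its most specific rule.
RECAP_RULES: tuple[RecapRule, ...] = (
    RecapRule("amide", ("[C;!$(C([#7])[#7]):1](=!@[O])!@[#7;+0;!D1:2]",)),
    RecapRule("ester", ("[C;$(C(=O)[#6,#1]):1](=!@[O])!@[O;+0;D2:2]",)),
    RecapRule(
        "amine",
        (
            "[N;!D1;+0;!R;!$(N-C=[#7,#8,#15,#16]);!$(N-[S,P]=O):1]-!@[#6:2]",
            "[N;R;D3;+0;!$(N-C=[#7,#8,#15,#16]);!$(N-[S,P]=O):1]-!@[#6:2]",
        ),
    ),
    RecapRule("urea", ("[#7;+0;D2,D3:1]!@[C:2](!@=O)!@[#7;+0;D2,D3]",)),
    RecapRule(
        "ether",
        ("[#6:1]-!@[O;+0;D2;$(O([#6])[#6]);!$(O-C=[O,S,N,P]):2]",),
    ),
    RecapRule("olefin", ("[C:1]=!@[C:2]",)),
    RecapRule("aromatic_N_aliphatic_C", ("[n;+0:1]-!@[C:2]",)),
    RecapRule("lactam_N_aliphatic_C", ("[O]=[C]-@[N;+0:1]-!@[C:2]",)),
    RecapRule("aromatic_C_aromatic_C", ("[c:1]-!@[c:2]",)),
    RecapRule("quaternary_N", ("[N;D4;+:1]-!@[C:2]",)),
    RecapRule("sulfonamide", ("[#7;+0;D2,D3:1]-!@[S:2](=[O])=[O]",)),
)

RULE_NAMES = tuple(rule.name for rule in RECAP_RULES)

_COMPILED = [(rule.name, rule.compiled()) for rule in RECAP_RULES]


@dataclass
class FragmentRecord:
    """A unique standardized fragment aggregated over a library."""

    canonical_smiles: str
    occurrence: int = 0
    parents: set = field(default_factory=set)
    rules_applied: set = field(default_factory=set)
    site_count: int = 0


def _mapped_bond(mol: Chem.Mol, pattern: Chem.Mol, match: tuple[int, ...]):
    """Map a substructure match back to the (begin, end) atoms of the
    bond marked by atom maps 1 and 2."""
    a1 = a2 = None
    for query_atom in pattern.GetAtoms():
        num = query_atom.GetAtomMapNum()
        if num == 1:
            a1 = match[query_atom.GetIdx()]
        elif num == 2:
            a2 = match[query_atom.GetIdx()]
    if a1 is None or a2 is None:  # pragma: no cover - rule definition bug
        raise ValueError("rule pattern lacks atom maps 1 and 2")
    return a1, a2


def find_cleavable_bonds(mol: Chem.Mol) -> list[tuple[int, str]]:
    """Return ``(bond_index, rule_name)`` pairs for every cleavable bond.

    The list is deterministic in canonical atom order regardless of the
    input atom numbering.  For an ether oxygen flanked by two eligible
    carbons only one of the two C-O bonds is cleaved (preferring the
    aliphatic carbon, then the lower canonical rank), so the oxygen stays
    attached to one side instead of leaving as water.
    """
    Chem.GetSymmSSSR(mol)  # ring perception may be missing after renumbering
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    hits: list[tuple[int, str, int, int]] = []
    ether_by_oxygen: dict[int, list[tuple[int, int]]] = {}
    for rule_name, patterns in _COMPILED:
        for pattern in patterns:
            # uniquify=False: symmetry-equivalent bonds must all be found
            for match in mol.GetSubstructMatches(pattern, uniquify=False):
                a1, a2 = _mapped_bond(mol, pattern, match)
                bond = mol.GetBondBetweenAtoms(a1, a2)
                if bond is None or bond.IsInRing():
                    continue
                if rule_name == "ether":
                    ether_by_oxygen.setdefault(a2, []).append((a1, bond.GetIdx()))
                else:
                    hits.append((bond.GetIdx(), rule_name, ranks[a1], ranks[a2]))
    for oxygen_idx, candidates in ether_by_oxygen.items():
        candidates = sorted(set(candidates))

        def ether_key(item):
            carbon_idx, bond_idx = item
            aromatic = mol.GetAtomWithIdx(carbon_idx).GetIsAromatic()
            return (aromatic, ranks[carbon_idx])

        carbon_idx, bond_idx = sorted(candidates, key=ether_key)[0]
        hits.append((bond_idx, "ether", ranks[carbon_idx], ranks[oxygen_idx]))
    seen = set()
    ordered = []
    for bond_idx, rule_name, r1, r2 in sorted(
        hits, key=lambda h: (min(h[2], h[3]), max(h[2], h[3]), h[1])
    ):
        if (bond_idx, rule_name) in seen:
            continue
        seen.add((bond_idx, rule_name))
        ordered.append((bond_idx, rule_name))
    return ordered


def find_cleavage_sites(mol: Chem.Mol) -> list[tuple[str, tuple[int, ...]]]:
    """Group cleavable bonds into application sites.

    Amine and quaternary-nitrogen cleavages act on the whole nitrogen
    centre: all its matched bonds form one site and are broken together
    (cleaving them one at a time would change the nitrogen's degree and
    silence the rule midway).  Every other rule cleaves one bond per site.
    """
    grouped: dict[tuple, list[int]] = {}
    for bond_idx, rule_name in find_cleavable_bonds(mol):
        if rule_name in ("amine", "quaternary_N"):
            bond = mol.GetBondWithIdx(bond_idx)
            nitrogen = (
                bond.GetBeginAtomIdx()
                if bond.GetBeginAtom().GetAtomicNum() == 7
                else bond.GetEndAtomIdx()
            )
            key = (rule_name, nitrogen)
        else:
            key = (rule_name, -1, bond_idx)
        grouped.setdefault(key, []).append(bond_idx)
    return [(key[0], tuple(bonds)) for key, bonds in grouped.items()]


def _break_bonds(mol: Chem.Mol, bond_idxs: list[int]) -> Chem.Mol:
    """Break the given bonds, capping each open valence with hydrogens."""
    rw = Chem.RWMol(mol)
    pairs = []
    for bond_idx in dict.fromkeys(bond_idxs):
        bond = mol.GetBondWithIdx(bond_idx)
        order = int(round(bond.GetBondTypeAsDouble()))
        pairs.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    for begin, end, order in pairs:
        rw.RemoveBond(begin, end)
        for atom_idx in (begin, end):
            atom = rw.GetAtomWithIdx(atom_idx)
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() + order)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _tag_atoms(mol: Chem.Mol) -> Chem.Mol:
    tagged = Chem.Mol(mol)
    for atom in tagged.GetAtoms():
        atom.SetIntProp(_ORIG_IDX, atom.GetIdx())
    return tagged


def _decompose(mol: Chem.Mol, rule_trail: dict[int, set]) -> list[Chem.Mol]:
    cleavable = find_cleavable_bonds(mol)
    if not cleavable:
        return [mol]
    for bond_idx, rule_name in cleavable:
        bond = mol.GetBondWithIdx(bond_idx)
        for atom in (bond.GetBeginAtom(), bond.GetEndAtom()):
            rule_trail.setdefault(atom.GetIntProp(_ORIG_IDX), set()).add(rule_name)
    broken = _break_bonds(mol, [b for b, _ in cleavable])
    leaves = []
    for piece in Chem.GetMolFrags(broken, asMols=True, sanitizeFrags=True):
        leaves.extend(_decompose(piece, rule_trail))
    return leaves


def recap_decompose(
    mol: Chem.Mol, return_rules: bool = False
) -> list[Chem.Mol] | list[tuple[Chem.Mol, set]]:
    """Hierarchically decompose a molecule into its leaf fragments.

    Returns an empty list when nothing is cleavable (the undecomposable
    parent itself is not a fragment).  With ``return_rules`` each leaf is
    paired with the set of rule names on its cleavage boundary.
    """
    tagged = _tag_atoms(mol)
    rule_trail: dict[int, set] = {}
    if not find_cleavable_bonds(tagged):
        return []
    leaves = _decompose(tagged, rule_trail)
    if not return_rules:
        return leaves
    out = []
    for leaf in leaves:
        rules = set()
        for atom in leaf.GetAtoms():
            rules |= rule_trail.get(atom.GetIntProp(_ORIG_IDX), set())
        out.append((leaf, rules))
    return out


def recap_smiles(mol: Chem.Mol) -> set[str]:
    """Canonical SMILES of the deduplicated leaf fragments."""
    return {Chem.MolToSmiles(leaf) for leaf in recap_decompose(mol)}


@dataclass
class FragmentationStats:
    n_parents: int = 0
    n_skipped_mw: int = 0
    n_fragmented: int = 0
    n_unique_fragments: int = 0


def fragment_library(
    records: list[MoleculeRecord],
    mw_cutoff: float = 1000.0,
    count_sites: bool = False,
) -> tuple[list[FragmentRecord], FragmentationStats]:
    """Decompose a standardized library into aggregated fragment records.

    Parents at or above ``mw_cutoff`` daltons are skipped and counted.
    Each leaf is re-standardized and aggregated by canonical SMILES;
    ``occurrence`` counts each parent once per unique fragment (set
    ``count_sites`` to also tally per-site multiplicity).
    """
    stats = FragmentationStats()
    fragments: dict[str, FragmentRecord] = {}
    for record in records:
        if record.status != STATUS_STANDARDIZED:
            continue
        mol = Chem.MolFromSmiles(record.canonical_smiles)
        if mol is None:
            continue
        stats.n_parents += 1
        if Descriptors.MolWt(mol) >= mw_cutoff:
            stats.n_skipped_mw += 1
            continue
        leaves = recap_decompose(mol, return_rules=True)
        if not leaves:
            continue
        stats.n_fragmented += 1
        per_parent: dict[str, tuple[set, int]] = {}
        for leaf, rules in leaves:
            leaf_record = MoleculeRecord(
                source_id=record.source_id, raw_smiles=Chem.MolToSmiles(leaf)
            )
            leaf_record = standardize_molecule(leaf_record)
            if leaf_record.status != STATUS_STANDARDIZED:
                logger.warning(
                    "fragment of %s failed standardization", record.source_id
                )
                continue
            key = leaf_record.canonical_smiles
            old_rules, count = per_parent.get(key, (set(), 0))
            per_parent[key] = (old_rules | rules, count + 1)
        for key, (rules, count) in per_parent.items():
            fragment = fragments.setdefault(key, FragmentRecord(canonical_smiles=key))
            fragment.occurrence += count if count_sites else 1
            fragment.site_count += count
            fragment.parents.add(record.source_id)
            fragment.rules_applied |= rules
    stats.n_unique_fragments = len(fragments)
    return list(fragments.values()), stats
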