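"""Structure curation: element whitelist, largest component, reionization,
neutralization, canonical tautomer, deduplication.

The protocol is applied in a fixed order to each record:

1. element whitelist check on the molecule as read (before any splitting);
2. split multi-component inputs, keeping the component with the most heavy
   atoms (ties: higher molecular weight, then lexicographically smallest
   canonical SMILES);
3. reionize;
4. neutralize charges (quaternary nitrogens keep their charge);
5. generate a canonical tautomer (deterministic scored enumeration, capped
   at 1000 tautomers);
6. emit the canonical SMILES.

Stereochemistry is preserved throughout and participates in the canonical
key, so two enantiomers deduplicate to two records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem_io import (
    REASON_ELEMENT,
    REASON_EMPTY,
    REASON_PARSE,
    STATUS_REJECTED,
    MoleculeRecord,
)

logger = logging.getLogger(__name__)

#: Allowed elements (plus implicit/explicit hydrogen, atomic number 1).
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)
_ALLOWED_Z = frozenset({1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53})

MAX_TAUTOMERS = 1000

FLAG_TAUTOMER_FALLBACK = "tautomer_fallback"


@dataclass
class StandardizationReport:
    """Attrition accounting for one standardization run."""

    n_input: int = 0
    n_rejected_elements: int = 0
    n_rejected_parse: int = 0
    n_accepted: int = 0
    n_after_dedup: int = 0
    stage_log: list = field(default_factory=list)

    def validate(self) -> None:
        assert self.n_after_dedup <= (
            self.n_input - self.n_rejected_elements - self.n_rejected_parse
        )
        assert min(
            self.n_input,
            self.n_rejected_elements,
            self.n_rejected_parse,
            self.n_after_dedup,
        ) >= 0


def check_elements(mol: Chem.Mol) -> bool:
    """True iff every atom's element is in the 13-element whitelist.

    Applied to the molecule as read, before component splitting.
    """
    return all(atom.GetAtomicNum() in _ALLOWED_Z for atom in mol.GetAtoms())


def _largest_component(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]

    def key(fragment: Chem.Mol):
        return (
            -fragment.GetNumHeavyAtoms(),
            -Descriptors.MolWt(fragment),
            Chem.MolToSmiles(fragment),
        )

    return sorted(frags, key=key)[0]


_reionizer = rdMolStandardize.Reionizer()
_uncharger = rdMolStandardize.Uncharger()


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    params = rdMolStandardize.CleanupParameters()
    params.maxTautomers = MAX_TAUTOMERS
    enumerator = rdMolStandardize.TautomerEnumerator(params)
    return enumerator


_tautomerizer = _tautomer_enumerator()


def standardize_molecule(
    record: MoleculeRecord, element_filter_first: bool = True
) -> MoleculeRecord:
    """Run the full curation protocol on one record.

    ``element_filter_first`` switches whether the whitelist is applied to the
    whole multi-component input (default, matching the stated protocol
    order) or to the largest component only.
    """
    if record.status == STATUS_REJECTED:
        return record
    mol = Chem.MolFromSmiles(record.raw_smiles)
    if mol is None:
        return record.rejected(REASON_PARSE)
    if mol.GetNumAtoms() == 0:
        return record.rejected(REASON_EMPTY)
    if element_filter_first and not check_elements(mol):
        return record.rejected(REASON_ELEMENT)
    mol = _largest_component(mol)
    if not element_filter_first and not check_elements(mol):
        return record.rejected(REASON_ELEMENT)
    try:
        Chem.SanitizeMol(mol)
        mol = _reionizer.reionize(mol)
        mol = _uncharger.uncharge(mol)
    except Exception:
        return record.rejected(REASON_PARSE)
    pre_tautomer = Chem.MolToSmiles(mol)
    try:
        mol = _tautomerizer.Canonicalize(mol)
        canonical = Chem.MolToSmiles(mol)
    except Exception:
        # tautomer enumeration blew up: keep the pre-tautomer form, flagged
        out = record.standardized(pre_tautomer)
        out.flags.add(FLAG_TAUTOMER_FALLBACK)
        logger.warning("tautomer fallback for %s", record.source_id)
        return out
    return record.standardized(canonical)


def standardize_library(
    records: list[MoleculeRecord], element_filter_first: bool = True
) -> tuple[list[MoleculeRecord], StandardizationReport]:
    """Standardize and deduplicate a record collection.

    Returns unique records keyed on canonical SMILES; each surviving record
    carries the multiplicity of accepted inputs that collapsed onto it.
    """
    report = StandardizationReport(n_input=len(records))
    unique: dict[str, MoleculeRecord] = {}
    for record in records:
        out = standardize_molecule(record, element_filter_first=element_filter_first)
        report.stage_log.append((out.source_id, out.status, out.rejection_reason))
        if out.status == STATUS_REJECTED:
            if out.rejection_reason == REASON_ELEMENT:
                report.n_rejected_elements += 1
            else:
                report.n_rejected_parse += 1
            continue
        report.n_accepted += 1
        key = out.canonical_smiles
        if key in unique:
            unique[key].multiplicity += 1
        else:
            out.multiplicity = 1
            unique[key] = out
    deduped = list(unique.values())
    report.n_after_dedup = len(deduped)
    report.validate()
    return deduped, report
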