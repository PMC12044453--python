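"""Library comparison products: unique/overlap tables, most-frequent
fragment tables with an optional molecular-weight window, and ring-scaffold
censuses.

Overlap is keyed on the standardized stereo-aware canonical SMILES;
``stereo_sensitive=False`` strips stereo annotations before matching (the
two matchings are reported separately, never mixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .recap import FragmentRecord


def _canonical_set(library, stereo_sensitive: bool = True) -> set[str]:
    """Accepts FragmentRecords, MoleculeRecords or plain SMILES strings."""
    out = set()
    for item in library:
        smiles = getattr(item, "canonical_smiles", None) or item
        if not stereo_sensitive:
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            Chem.RemoveStereochemistry(mol)
            smiles = Chem.MolToSmiles(mol)
        out.add(smiles)
    return out


@dataclass(frozen=True)
class OverlapResult:
    name_a: str
    name_b: str
    n_a: int
    n_b: int
    n_shared: int
    unique_a: int
    unique_b: int
    pct_unique_a: float
    pct_unique_b: float
    pct_shared_a: float
    pct_shared_b: float
    shared: frozenset = field(repr=False, default=frozenset())


def overlap(
    lib_a, lib_b, name_a: str = "A", name_b: str = "B", stereo_sensitive: bool = True
) -> OverlapResult:
    """Intersection of two deduplicated libraries on canonical strings.

    Percentages are computed against the owning library's size (0.0 when
    the library is empty).
    """
    set_a = _canonical_set(lib_a, stereo_sensitive)
    set_b = _canonical_set(lib_b, stereo_sensitive)
    shared = set_a & set_b
    n_a, n_b, n_shared = len(set_a), len(set_b), len(shared)

    def pct(count, total):
        return 100.0 * count / total if total else 0.0

    return OverlapResult(
        name_a=name_a,
        name_b=name_b,
        n_a=n_a,
        n_b=n_b,
        n_shared=n_shared,
        unique_a=n_a - n_shared,
        unique_b=n_b - n_shared,
        pct_unique_a=pct(n_a - n_shared, n_a),
        pct_unique_b=pct(n_b - n_shared, n_b),
        pct_shared_a=pct(n_shared, n_a),
        pct_shared_b=pct(n_shared, n_b),
        shared=frozenset(shared),
    )


@dataclass
class FrequencyTable:
    """Fragments ranked by their share of the library.

    ``denominator`` is ``"occurrences"`` (each entry's percentage is its
    occurrence count over the library's total occurrences) or
    ``"unique_fragments"`` (over the number of unique fragments).  The
    denominator always covers the whole collection; the optional MW window
    only restricts which fragments are listed.
    """

    entries: list  # (canonical_smiles, percentage, occurrence)
    denominator: str
    mw_window: tuple[float, float] | None = None


def _mw(smiles: str) -> float:
    mol = Chem.MolFromSmiles(smiles)
    return Descriptors.MolWt(mol) if mol is not None else float("nan")


def frequency_table(
    fragments: list[FragmentRecord],
    top_k: int | None = None,
    mw_window: tuple[float, float] | None = None,
    denominator: str = "occurrences",
) -> FrequencyTable:
    if denominator not in ("occurrences", "unique_fragments"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if denominator == "occurrences":
        total = sum(f.occurrence for f in fragments)
    else:
        total = len(fragments)
    rows = []
    for fragment in fragments:
        if mw_window is not None:
            mw = _mw(fragment.canonical_smiles)
            if not (mw_window[0] <= mw <= mw_window[1]):
                continue
        weight = fragment.occurrence if denominator == "occurrences" else 1
        pct = 100.0 * weight / total if total else 0.0
        rows.append((fragment.canonical_smiles, pct, fragment.occurrence))
    rows.sort(key=lambda r: (-r[1], r[0]))
    if top_k is not None:
        rows = rows[:top_k]
    return FrequencyTable(entries=rows, denominator=denominator, mw_window=mw_window)


@dataclass
class PairedFrequencyTable:
    """Shared fragments with both libraries' percentages (library A first)."""

    entries: list  # (canonical_smiles, pct_a, pct_b)
    denominator: str
    mw_window: tuple[float, float] | None = None


def common_frequency_table(
    frags_a: list[FragmentRecord],
    frags_b: list[FragmentRecord],
    top_k: int | None = None,
    mw_window: tuple[float, float] | None = None,
    denominator: str = "occurrences",
) -> PairedFrequencyTable:
    table_a = frequency_table(frags_a, mw_window=mw_window, denominator=denominator)
    table_b = frequency_table(frags_b, mw_window=mw_window, denominator=denominator)
    pct_a = {smiles: pct for smiles, pct, _ in table_a.entries}
    pct_b = {smiles: pct for smiles, pct, _ in table_b.entries}
    shared = sorted(
        set(pct_a) & set(pct_b),
        key=lambda s: (-(pct_a[s] + pct_b[s]), s),
    )
    if top_k is not None:
        shared = shared[:top_k]
    return PairedFrequencyTable(
        entries=[(s, pct_a[s], pct_b[s]) for s in shared],
        denominator=denominator,
        mw_window=mw_window,
    )


@dataclass
class ScaffoldSummary:
    n_molecules: int
    n_with_scaffold: int
    n_distinct: int
    frequencies: dict  # scaffold canonical smiles -> molecule count
    n_nonheterocyclic: int
    n_nitrogen_containing: int
    n_fused: int
    n_ortho_fused: int


def murcko_scaffold(mol: Chem.Mol) -> str | None:
    """Canonical SMILES of the ring-systems-plus-linkers core, or None for
    acyclic molecules.  Idempotent: the scaffold of a scaffold is itself."""
    if mol.GetRingInfo().NumRings() == 0:
        return None
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(core)


def _rings_share_atoms(mol: Chem.Mol, min_shared: int) -> bool:
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if len(rings[i] & rings[j]) >= min_shared:
                return True
    return False


def scaffold_summary(mols: list[Chem.Mol]) -> ScaffoldSummary:
    """Ring-scaffold census of a standardized collection.

    Classifications (per distinct scaffold): nonheterocyclic = no ring atom
    is a heteroatom; nitrogen-containing = at least one nitrogen anywhere in
    the scaffold (ring or linker); fused = two rings sharing at least one
    atom (covers ortho-fused, bridged and spiro unions); ortho-fused is the
    stricter bond-sharing count.
    """
    frequencies: dict[str, int] = {}
    n_with = 0
    for mol in mols:
        scaffold = murcko_scaffold(mol)
        if scaffold is None:
            continue
        n_with += 1
        frequencies[scaffold] = frequencies.get(scaffold, 0) + 1
    n_nonhet = n_nitrogen = n_fused = n_ortho = 0
    for scaffold in frequencies:
        core = Chem.MolFromSmiles(scaffold)
        ring_atoms = [a for a in core.GetAtoms() if a.IsInRing()]
        if all(a.GetAtomicNum() == 6 for a in ring_atoms):
            n_nonhet += 1
        if any(a.GetAtomicNum() == 7 for a in core.GetAtoms()):
            n_nitrogen += 1
        if _rings_share_atoms(core, 1):
            n_fused += 1
        if _rings_share_atoms(core, 2):
            n_ortho += 1
    return ScaffoldSummary(
        n_molecules=len(mols),
        n_with_scaffold=n_with,
        n_distinct=len(frequencies),
        frequencies=frequencies,
        n_nonheterocyclic=n_nonhet,
        n_nitrogen_containing=n_nitrogen,
        n_fused=n_fused,
        n_ortho_fused=n_ortho,
    )
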