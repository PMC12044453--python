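"""Reading and writing compound libraries, plus a registry of named libraries.

Libraries live in two plain-text formats:

* ``smiles_table`` -- delimited text (``.smi``/``.csv``/``.tsv``) with a
  structure column and an optional identifier column.  The delimiter is
  auto-detected among tab, comma and generic whitespace; a header row naming
  a ``smiles`` column is honoured when present.
* ``sdf`` -- MDL SD files (V2000); molecules are converted to canonical
  SMILES at read time and 3D coordinates are discarded.

Every downstream stage keys on canonical SMILES strings, never on file row
indices.
"""

from __future__ import annotations

import csv
import io
import logging
import os
from dataclasses import dataclass, field, replace

from rdkit import Chem

logger = logging.getLogger(__name__)

VALID_ROLES = frozenset(
    {"natural_product", "synthetic_fragment", "vendor_fragment", "generated"}
)
VALID_FORMATS = frozenset({"smiles_table", "sdf"})

STATUS_PENDING = "pending"
STATUS_STANDARDIZED = "standardized"
STATUS_REJECTED = "rejected"

REASON_PARSE = "parse_error"
REASON_ELEMENT = "element_not_allowed"
REASON_EMPTY = "empty_structure"


class LibraryFormatError(ValueError):
    """Raised for unknown formats or malformed registry files."""


@dataclass(frozen=True)
class LibrarySpecEntry:
    """One named library in a registry."""

    name: str
    role: str
    path: str
    format: str

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise LibraryFormatError(
                f"unknown role {self.role!r}; expected one of {sorted(VALID_ROLES)}"
            )
        if self.format not in VALID_FORMATS:
            raise LibraryFormatError(
                f"unknown format {self.format!r}; expected one of {sorted(VALID_FORMATS)}"
            )


@dataclass
class MoleculeRecord:
    """One input structure and its per-stage standardization status.

    ``canonical_smiles`` is present iff ``status == "standardized"``;
    ``rejection_reason`` is present iff ``status == "rejected"``.
    ``multiplicity`` counts how many accepted inputs collapsed onto this
    record during deduplication (1 before deduplication).
    """

    source_id: str
    raw_smiles: str
    canonical_smiles: str | None = None
    status: str = STATUS_PENDING
    rejection_reason: str | None = None
    multiplicity: int = 1
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.canonical_smiles is not None) != (self.status == STATUS_STANDARDIZED):
            raise ValueError(
                "canonical_smiles must be present iff status == 'standardized'"
            )
        if (self.rejection_reason is not None) != (self.status == STATUS_REJECTED):
            raise ValueError(
                "rejection_reason must be present iff status == 'rejected'"
            )

    def rejected(self, reason: str) -> "MoleculeRecord":
        return replace(
            self,
            canonical_smiles=None,
            status=STATUS_REJECTED,
            rejection_reason=reason,
        )

    def standardized(self, canonical: str) -> "MoleculeRecord":
        return replace(
            self,
            canonical_smiles=canonical,
            status=STATUS_STANDARDIZED,
            rejection_reason=None,
        )


class LibraryRegistry:
    """A mapping of unique library names to :class:`LibrarySpecEntry`."""

    def __init__(self, entries: list[LibrarySpecEntry] | None = None):
        self._entries: dict[str, LibrarySpecEntry] = {}
        for entry in entries or []:
            self.add(entry)

    def add(self, entry: LibrarySpecEntry) -> None:
        if entry.name in self._entries:
            raise LibraryFormatError(f"duplicate library name {entry.name!r}")
        self._entries[entry.name] = entry

    def __getitem__(self, name: str) -> LibrarySpecEntry:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def names(self) -> list[str]:
        return list(self._entries)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "LibraryRegistry":
        """Read a registry from a flat key-value config file.

        The file holds one ``[name]`` section per library with ``role``,
        ``path`` and ``format`` keys.  Relative paths are resolved against
        the registry file's directory.
        """
        import configparser

        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)
        base = os.path.dirname(os.path.abspath(path))
        entries = []
        for name in parser.sections():
            section = parser[name]
            try:
                lib_path = section["path"]
            except KeyError as exc:
                raise LibraryFormatError(f"registry entry {name!r} lacks a path") from exc
            if not os.path.isabs(lib_path):
                lib_path = os.path.join(base, lib_path)
            entries.append(
                LibrarySpecEntry(
                    name=name,
                    role=section.get("role", "generated"),
                    path=lib_path,
                    format=section.get("format", "smiles_table"),
                )
            )
        return cls(entries)

    def save(self, path: str | os.PathLike) -> None:
        import configparser

        parser = configparser.ConfigParser()
        for entry in self:
            parser[entry.name] = {
                "role": entry.role,
                "path": entry.path,
                "format": entry.format,
            }
        with open(path, "w") as handle:
            parser.write(handle)


def _sniff_dialect(sample_lines: list[str]) -> str:
    """Pick a delimiter among tab, comma, whitespace from a few data lines."""
    if any("\t" in line for line in sample_lines):
        return "\t"
    if any("," in line for line in sample_lines):
        return ","
    return " "


def _parse_header(fields: list[str]) -> tuple[int, int | None] | None:
    """Return (smiles_col, id_col) if the row looks like a header, else None."""
    lowered = [f.strip().lower() for f in fields]
    smiles_names = {"smiles", "structure", "canonical_smiles"}
    id_names = {"id", "name", "identifier", "source_id", "compound_id"}
    smiles_col = next((i for i, f in enumerate(lowered) if f in smiles_names), None)
    if smiles_col is None:
        return None
    id_col = next((i for i, f in enumerate(lowered) if f in id_names), None)
    return smiles_col, id_col


def _records_from_rows(rows: list[list[str]]) -> list[MoleculeRecord]:
    if not rows:
        return []
    header = _parse_header(rows[0])
    if header is not None:
        smiles_col, id_col = header
        data_rows = rows[1:]
    else:
        smiles_col, id_col = 0, 1
        data_rows = rows
    records = []
    for i, row in enumerate(data_rows):
        if not row or all(not f.strip() for f in row):
            continue
        smiles = row[smiles_col].strip() if smiles_col < len(row) else ""
        if id_col is not None and id_col < len(row) and row[id_col].strip():
            source_id = row[id_col].strip()
        else:
            source_id = f"row{i + 1}"
        record = MoleculeRecord(source_id=source_id, raw_smiles=smiles)
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            record = record.rejected(REASON_PARSE)
        records.append(record)
    return records


def _read_smiles_table(path: str) -> list[MoleculeRecord]:
    with open(path, newline="") as handle:
        text = handle.read()
    lines = [line for line in text.splitlines() if line.strip()]
    if not lines:
        logger.warning("library file %s is empty", path)
        return []
    delim = _sniff_dialect(lines[:20])
    if delim == " ":
        rows = [line.split() for line in lines]
    else:
        rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    return _records_from_rows(rows)


def _read_sdf(path: str) -> list[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(path, sanitize=True, removeHs=True)
    records = []
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(
                MoleculeRecord(source_id=f"sdf{i + 1}", raw_smiles="").rejected(
                    REASON_PARSE
                )
            )
            continue
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        smiles = Chem.MolToSmiles(mol)
        records.append(
            MoleculeRecord(source_id=name or f"sdf{i + 1}", raw_smiles=smiles)
        )
    return records


def read_library(entry: LibrarySpecEntry) -> list[MoleculeRecord]:
    """Read a library file into pending/rejected molecule records.

    Unparsable rows are returned as rejected records (reason
    ``parse_error``), never silently dropped; row order is preserved.
    """
    if not os.path.exists(entry.path):
        raise FileNotFoundError(entry.path)
    if entry.format == "smiles_table":
        return _read_smiles_table(entry.path)
    if entry.format == "sdf":
        return _read_sdf(entry.path)
    raise LibraryFormatError(f"unknown format {entry.format!r}")  # pragma: no cover


def write_library(
    records: list[MoleculeRecord],
    path: str | os.PathLike,
    format: str = "smiles_table",
) -> None:
    """Write records to ``path``.

    For ``smiles_table`` the output is a tab-separated file with a header;
    embedded delimiters in identifiers are protected by csv quoting, so
    ``read_library(write_library(x))`` round-trips canonical strings and ids.
    Standardized records are written with their canonical string, other
    records with their raw string.
    """
    if format == "smiles_table":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(["smiles", "id", "status"])
            for record in records:
                smiles = (
                    record.canonical_smiles
                    if record.status == STATUS_STANDARDIZED
                    else record.raw_smiles
                )
                writer.writerow([smiles, record.source_id, record.status])
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for record in records:
                smiles = (
                    record.canonical_smiles
                    if record.status == STATUS_STANDARDIZED
                    else record.raw_smiles
                )
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    continue
                mol.SetProp("_Name", record.source_id)
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise LibraryFormatError(f"unknown format {format!r}")
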