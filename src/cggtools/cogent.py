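"""Deterministic re-encoding of genome collections into structured identifiers.

Public sequence repositories hand out identifier spaces that are
inconsistent across sources and unstable across releases. The encoding
here replaces each record id with a structured token

    ``Code-tag-vv-nnnnnn``

(4-letter species code with initial capital, free-form assembly tag,
2-digit collection version starting at 01, 6-digit serial starting at
000000 and incremented in input order), while preserving the complete
original header as the new description so nothing is lost. Encoded
collections can be concatenated into a single reference database with a
manifest, ready for indexing by any search tool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import SequenceRecord, read_fasta, write_fasta

SERIAL_WIDTH = 6
VERSION_WIDTH = 2
MAX_SERIAL = 10**SERIAL_WIDTH - 1

_SPECIES_RE = re.compile(r"^[A-Z][A-Za-z]{3}$")
_TAG_RE = re.compile(r"^[A-Za-z0-9]+$")


class CogentIDError(ValueError):
    """An identifier or catalog entry violates the encoding schema."""


@dataclass(frozen=True)
class CogentID:
    species_code: str
    assembly_tag: str
    version: int
    serial: int

    def __post_init__(self) -> None:
        if not _SPECIES_RE.match(self.species_code):
            raise CogentIDError(
                f"species code {self.species_code!r} must be 4 letters, initial capital"
            )
        if not _TAG_RE.match(self.assembly_tag):
            raise CogentIDError(
                f"assembly tag {self.assembly_tag!r} must be alphanumeric "
                "(the '-' delimiter is reserved)"
            )
        if not (0 < self.version < 10**VERSION_WIDTH):
            raise CogentIDError(f"version {self.version} out of range 01-99")
        if not (0 <= self.serial <= MAX_SERIAL):
            raise CogentIDError(f"serial {self.serial} out of range")

    def render(self) -> str:
        return (
            f"{self.species_code}-{self.assembly_tag}-"
            f"{self.version:0{VERSION_WIDTH}d}-{self.serial:0{SERIAL_WIDTH}d}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class CatalogEntry:
    """One genome collection to encode: source file plus its id fields."""

    source_path: str
    species_code: str
    assembly_tag: str
    version: int = 1

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.species_code, self.assembly_tag, self.version)


def suggest_species_code(genus: str, species: str) -> str:
    """Advisory 4-letter code: first 3 letters of the genus + first of the
    species epithet, title-cased (*Taeniopygia guttata* → ``Taeg``).
    Collisions across large taxonomies are the caller's policy to resolve;
    the catalog always supplies the code explicitly."""
    code = (genus[:3] + species[:1]).capitalize()
    if not _SPECIES_RE.match(code):
        raise CogentIDError(f"cannot derive a 4-letter code from {genus!r}/{species!r}")
    return code


def encode_collection(
    records: Sequence[SequenceRecord], entry: CatalogEntry
) -> list[SequenceRecord]:
    """Re-identify a collection with consecutive serials from 000000.

    The original header (id plus description) becomes the new description;
    residues are untouched; order is preserved.
    """
    if not records:
        raise CogentIDError(f"collection {entry.source_path!r} is empty")
    if len(records) > MAX_SERIAL + 1:
        raise CogentIDError(
            f"collection has {len(records)} records; serial space allows "
            f"{MAX_SERIAL + 1}"
        )
    out = []
    for serial, rec in enumerate(records):
        cid = CogentID(entry.species_code, entry.assembly_tag, entry.version, serial)
        original_header = f"{rec.id} {rec.description}".rstrip()
        out.append(SequenceRecord(cid.render(), original_header, rec.residues))
    return out


def decode_id(identifier: str) -> CogentID:
    """Parse a rendered identifier back into its fields.

    ``decode_id(cid.render()) == cid`` for every valid :class:`CogentID`.
    """
    parts = identifier.split("-")
    if len(parts) != 4:
        raise CogentIDError(
            f"identifier {identifier!r} has {len(parts)} '-'-separated fields, expected 4"
        )
    code, tag, version, serial = parts
    if len(version) != VERSION_WIDTH or not version.isdigit():
        raise CogentIDError(f"version field {version!r} must be {VERSION_WIDTH} digits")
    if len(serial) != SERIAL_WIDTH or not serial.isdigit():
        raise CogentIDError(f"serial field {serial!r} must be {SERIAL_WIDTH} digits")
    return CogentID(code, tag, int(version), int(serial))


def read_catalog(path: str | Path) -> list[CatalogEntry]:
    """Catalog TSV: ``source_path species_code assembly_tag version``."""
    entries: list[CatalogEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise CogentIDError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields"
                )
            src, code, tag, version = fields
            try:
                entries.append(CatalogEntry(src, code, tag, int(version)))
            except ValueError as exc:
                raise CogentIDError(f"{path}: line {lineno}: {exc}") from exc
    return entries


@dataclass
class ManifestRow:
    species_code: str
    assembly_tag: str
    version: int
    record_count: int
    source_path: str


def build_reference(
    catalog: Sequence[CatalogEntry],
    out_fasta: str | Path,
    out_manifest: str | Path | None = None,
) -> list[ManifestRow]:
    """Concatenate encoded collections into one reference database.

    Collections are encoded and appended in catalog order. Catalog keys
    and rendered ids must be globally unique; a duplicate rendered id
    aborts naming both source files.
    """
    seen_keys: set[tuple[str, str, int]] = set()
    for entry in catalog:
        if entry.key in seen_keys:
            raise CogentIDError(
                f"catalog entry {entry.key} listed more than once"
            )
        seen_keys.add(entry.key)

    manifest: list[ManifestRow] = []
    all_records: list[SequenceRecord] = []
    id_source: dict[str, str] = {}
    for entry in catalog:
        records = read_fasta(entry.source_path)
        encoded = encode_collection(records, entry)
        for rec in encoded:
            if rec.id in id_source:
                raise CogentIDError(
                    f"duplicate identifier {rec.id!r} from {entry.source_path!r} "
                    f"and {id_source[rec.id]!r}"
                )
            id_source[rec.id] = entry.source_path
        all_records.extend(encoded)
        manifest.append(
            ManifestRow(
                entry.species_code,
                entry.assembly_tag,
                entry.version,
                len(encoded),
                str(entry.source_path),
            )
        )
    write_fasta(all_records, out_fasta)
    if out_manifest is not None:
        with open(out_manifest, "wt") as fh:
            for row in manifest:
                fh.write(
                    f"{row.species_code}\t{row.assembly_tag}\t{row.version:02d}\t"
                    f"{row.record_count}\t{row.source_path}\n"
                )
    return manifest
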