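"""Sequence, manifest and report-table I/O.

Defines the core record types used by every other module and the plain-text
formats the pipeline reads and writes: multi-entry FASTA (via Bio.SeqIO),
TSV group manifests mapping sequence ids to one of the four study groups
(*Ampelomyces* sensu stricto, putative groups 1 and 2, outgroup), and TSV
report tables with per-column decimal rendering.

Sequences are normalized to an uppercase DNA alphabet on input (U -> T,
lowercase folded); folding code converts back to RNA internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "GROUP_LABELS",
    "SeqRecord",
    "GroupManifest",
    "SequenceIOError",
    "ManifestError",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "write_manifest",
    "write_table",
    "read_table",
]

#: The four study groups.
GROUP_LABELS = ("AMPELOMYCES", "PUTATIVE_G1", "PUTATIVE_G2", "OUTGROUP")

_DNA_ALPHABET = set("ACGTN")
# IUPAC ambiguity codes are retained but excluded from content statistics.
_IUPAC_EXTRA = set("RYSWKMBDHV")
_ALLOWED = _DNA_ALPHABET | _IUPAC_EXTRA


class SequenceIOError(ValueError):
    """Malformed sequence input (bad FASTA, bad alphabet, duplicate ids)."""


class ManifestError(ValueError):
    """Malformed group manifest (unknown labels, missing columns)."""


@dataclass
class SeqRecord:
    """One ITS sequence with id, free-text description and group label.

    ``seq`` is always uppercase DNA ({A,C,G,T,N} plus IUPAC ambiguity);
    ``rna_origin`` records whether the source used U instead of T.
    """

    id: str
    seq: str
    description: str = ""
    group: str | None = None
    rna_origin: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceIOError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALLOWED
        if bad:
            raise SequenceIOError(
                f"record {self.id!r}: characters outside alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _normalize_seq(raw: str) -> tuple[str, bool]:
    up = raw.upper()
    rna = "U" in up
    return up.replace("U", "T"), rna


@dataclass
class GroupManifest:
    """Mapping id -> group label plus a free-text provenance note per id."""

    groups: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in GROUP_LABELS}
        if bad:
            raise ManifestError(f"unknown group labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, rec_id: str) -> str:
        return self.groups[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self.groups

    def members(self, group: str) -> list[str]:
        return [i for i, g in self.groups.items() if g == group]

    def missing_from(self, records: Sequence[SeqRecord]) -> list[str]:
        """Manifest ids absent from *records* (reported, never dropped)."""
        have = {r.id for r in records}
        return [i for i in self.groups if i not in have]

    def label_records(self, records: Iterable[SeqRecord]) -> None:
        for rec in records:
            if rec.id in self.groups:
                rec.group = self.groups[rec.id]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-entry FASTA file into :class:`SeqRecord` objects.

    U and lowercase are folded to the uppercase DNA alphabet; records whose
    source contained U carry ``rna_origin=True``.  Duplicate ids and empty
    files are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SequenceIOError(f"{path}: empty dataset")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        lineno = 1 + text[: text.index(first)].count("\n")
        raise SequenceIOError(f"{path}: malformed header at line {lineno}: {first!r}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(io.StringIO(text), "fasta"):
        seq, rna = _normalize_seq(str(bio.seq))
        if bio.id in seen:
            raise SequenceIOError(f"{path}: duplicate id {bio.id!r}")
        seen.add(bio.id)
        records.append(
            SeqRecord(id=bio.id, seq=seq, description=bio.description, rna_origin=rna)
        )
    if not records:
        raise SequenceIOError(f"{path}: empty dataset")
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapped at *wrap* columns (>= 60)."""
    path = Path(path)
    bios = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        bios.append(_BioRecord(Seq(rec.seq), id=rec.id, description=desc))
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=max(wrap, 60))
        writer.write_file(bios)


def read_manifest(path: str | Path) -> GroupManifest:
    """Read a TSV manifest with columns ``id`` and ``group`` (+ optional note).

    Labels are case-folded to the canonical upper-case form; unknown labels
    raise :class:`ManifestError` listing the offending rows.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ManifestError(f"{path}: empty manifest")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    try:
        id_col, grp_col = header.index("id"), header.index("group")
    except ValueError as exc:
        raise ManifestError(f"{path}: need columns 'id' and 'group', got {header}") from exc
    note_col = header.index("note") if "note" in header else None
    groups: dict[str, str] = {}
    notes: dict[str, str] = {}
    bad_rows: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        rid, grp = cells[id_col].strip(), cells[grp_col].strip().upper()
        if grp not in GROUP_LABELS:
            bad_rows.append(f"line {lineno}: {cells[grp_col]!r}")
            continue
        if rid in groups:
            raise ManifestError(f"{path}: duplicate id {rid!r} at line {lineno}")
        groups[rid] = grp
        if note_col is not None and len(cells) > note_col:
            notes[rid] = cells[note_col].strip()
    if bad_rows:
        raise ManifestError(f"{path}: unknown group labels: " + "; ".join(bad_rows))
    return GroupManifest(groups=groups, provenance=notes)


def write_manifest(manifest: GroupManifest, path: str | Path) -> None:
    rows = [
        (rid, grp, manifest.provenance.get(rid, ""))
        for rid, grp in manifest.groups.items()
    ]
    write_table(rows, path, header=("id", "group", "note"))


def write_table(
    rows: Sequence[Sequence[object]],
    path: str | Path,
    header: Sequence[str],
    decimals: Mapping[str, int] | Sequence[int | None] | None = None,
) -> None:
    """Write rectangular *rows* as TSV with a header line.

    *decimals* fixes the rendered precision per column (by name or position);
    columns without a spec render floats at full repr precision.  Ragged rows
    are rejected.
    """
    path = Path(path)
    ncol = len(header)
    if isinstance(decimals, Mapping):
        dec_by_pos: list[int | None] = [decimals.get(h) for h in header]
    elif decimals is None:
        dec_by_pos = [None] * ncol
    else:
        dec_by_pos = list(decimals) + [None] * (ncol - len(decimals))

    def render(value: object, dec: int | None) -> str:
        if isinstance(value, float) and dec is not None:
            return f"{value:.{dec}f}"
        return str(value)

    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, row in enumerate(rows):
            if len(row) != ncol:
                raise ValueError(
                    f"ragged row {i}: expected {ncol} cells, got {len(row)}"
                )
            fh.write("\t".join(render(v, d) for v, d in zip(row, dec_by_pos)) + "\n")


def read_table(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a TSV written by :func:`write_table`; returns (header, rows)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty table")
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:] if ln]
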