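"""Protein sequence and localization-annotation I/O with dataset-construction filters.

The dataset filters mirror standard proteome pre-processing: drop fragments
shorter than 50 residues and collapse near-identical sequences (>90% identity)
so that large paralog families do not dominate the pI statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ParameterError, ValidationError

#: The 20 canonical residues plus the ambiguity/rare letters B, Z, X, U.
ALLOWED_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXU")

#: Controlled vocabulary of compartment labels.
LOCALIZATIONS = frozenset(
    {
        "cytoplasm",
        "nucleus",
        "membrane",
        "mitochondria",
        "lysosome",
        "cytoskeleton",
        "er",
        "peroxisome",
        "golgi",
        "extracellular",
        "multi",
    }
)

#: Synonym map normalising WoLF-PSORT-style and free-text labels to the
#: controlled vocabulary.  Keys are matched case-insensitively after
#: stripping surrounding whitespace.
LOCALIZATION_SYNONYMS: Mapping[str, str] = {
    "cyto": "cytoplasm",
    "cytosol": "cytoplasm",
    "cytoplasmic": "cytoplasm",
    "nucl": "nucleus",
    "nuclear": "nucleus",
    "plas": "membrane",
    "plasma membrane": "membrane",
    "mito": "mitochondria",
    "mitochondrion": "mitochondria",
    "mitochondrial": "mitochondria",
    "mx": "mitochondria",
    "lyso": "lysosome",
    "lysosomal": "lysosome",
    "cysk": "cytoskeleton",
    "cytoskeletal": "cytoskeleton",
    "e.r.": "er",
    "endoplasmic reticulum": "er",
    "reticular": "er",
    "pero": "peroxisome",
    "peroxisomal": "peroxisome",
    "golg": "golgi",
    "golgi apparatus": "golgi",
    "extr": "extracellular",
    "secreted": "extracellular",
}


@dataclass
class ProteinRecord:
    """One protein: accession, sequence, and (optionally) computed pI and label."""

    id: str
    sequence: str
    pi: float | None = None
    localization: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record requires a non-empty id")
        validate_sequence(self.sequence, entry=self.id)
        if self.pi is not None and not 0.0 <= self.pi <= 14.0:
            raise ValidationError(
                f"record {self.id!r}: pI {self.pi} outside [0, 14]"
            )
        if self.localization is not None and self.localization not in LOCALIZATIONS:
            raise ValidationError(
                f"record {self.id!r}: unknown localization {self.localization!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_pi(self, pi: float) -> "ProteinRecord":
        return replace(self, pi=pi)

    def with_localization(self, label: str) -> "ProteinRecord":
        return replace(self, localization=label)


def validate_sequence(sequence: str, entry: str = "<sequence>") -> None:
    """Raise :class:`ValidationError` unless *sequence* is a valid residue string."""
    if not sequence:
        raise ValidationError(f"entry {entry!r}: empty sequence")
    bad = set(sequence) - ALLOWED_LETTERS
    if bad:
        raise ValidationError(
            f"entry {entry!r}: illegal character(s) {sorted(bad)!r} in sequence"
        )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are uppercased and trailing stop symbols (``*``) stripped; the
    record id is the first whitespace-delimited token of the header line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with path.open() as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            seq = str(entry.seq).upper().rstrip("*")
            validate_sequence(seq, entry=entry.id)
            records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with fixed line wrapping (deterministic output)."""
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def filter_by_length(
    records: list[ProteinRecord], min_len: int = 50
) -> list[ProteinRecord]:
    """Keep records whose sequence length is at least *min_len* (default 50)."""
    if min_len < 1:
        raise ParameterError(f"min_len must be >= 1, got {min_len}")
    return [r for r in records if len(r) >= min_len]


def _kmer_set(sequence: str, k: int) -> frozenset[str]:
    return frozenset(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def kmer_identity(a: str, b: str, k: int = 5) -> float:
    """Fraction of the shorter sequence's distinct k-mers shared with the other.

    A cheap stand-in for alignment identity used by the redundancy screen.
    Sequences shorter than *k* have no k-mers and score 0 against anything
    but an exact copy.
    """
    if a == b:
        return 1.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    kmers_short = _kmer_set(short, k)
    if not kmers_short:
        return 0.0
    shared = len(kmers_short & _kmer_set(long_, k))
    return shared / len(kmers_short)


def redundancy_screen(
    records: list[ProteinRecord],
    identity_threshold: float = 0.9,
    k: int = 5,
) -> list[ProteinRecord]:
    """Greedy redundancy removal: drop records >*identity_threshold* identical
    to an already-kept longer (or equal-length, earlier) record.

    Records are considered in decreasing-length order (ties break by input
    order), compared by :func:`kmer_identity`; exact duplicates always drop.
    The returned list preserves the input's relative order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ParameterError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    kept_idx: list[int] = []
    kept_kmers: dict[int, frozenset[str]] = {}
    kept_seqs: set[str] = set()
    # inverted k-mer index over kept records keeps the screen near-linear:
    # only records sharing at least one k-mer are ever compared
    index: dict[str, list[int]] = {}
    for i in order:
        seq = records[i].sequence
        kmers = _kmer_set(seq, k)
        redundant = seq in kept_seqs
        if not redundant and kmers:
            shared: dict[int, int] = {}
            for km in kmers:
                for j in index.get(km, ()):
                    shared[j] = shared.get(j, 0) + 1
            for j, n_shared in shared.items():
                other = records[j].sequence
                denom = kmers if len(seq) <= len(other) else kept_kmers[j]
                if denom and n_shared / len(denom) > identity_threshold:
                    redundant = True
                    break
        if not redundant:
            kept_idx.append(i)
            kept_kmers[i] = kmers
            kept_seqs.add(seq)
            for km in kmers:
                index.setdefault(km, []).append(i)
    return [records[i] for i in sorted(kept_idx)]


def normalize_localization(label: str) -> str:
    """Map a raw label to the controlled vocabulary; raise if unknown."""
    raw = label.strip()
    key = raw.lower()
    if key in LOCALIZATIONS:
        return key
    if key in LOCALIZATION_SYNONYMS:
        return LOCALIZATION_SYNONYMS[key]
    raise ValidationError(f"unknown localization label {raw!r}")


def read_localization_table(path: str | Path) -> dict[str, str]:
    """Read a TSV of (id, localization) into an id -> compartment-label map.

    Labels pass through :func:`normalize_localization`; duplicate ids are an
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id", "localization"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"localization table {path}: missing column(s) {sorted(missing)}"
        )
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        pid = str(row.id)
        if pid in mapping:
            raise ValidationError(f"duplicate id {pid!r} in localization table")
        mapping[pid] = normalize_localization(str(row.localization))
    return mapping


def write_localization_table(mapping: Mapping[str, str], path: str | Path) -> None:
    """Write an id -> label map as a two-column TSV (insertion order preserved)."""
    with Path(path).open("w") as handle:
        handle.write("id\tlocalization\n")
        for pid, label in mapping.items():
            handle.write(f"{pid}\t{label}\n")


def attach_localizations(
    records: list[ProteinRecord], mapping: Mapping[str, str]
) -> tuple[list[ProteinRecord], list[str]]:
    """Attach labels to records; returns (labelled records, ids without a label)."""
    labelled: list[ProteinRecord] = []
    unlabelled: list[str] = []
    for rec in records:
        label = mapping.get(rec.id)
        if label is None:
            unlabelled.append(rec.id)
        else:
            labelled.append(rec.with_localization(label))
    return labelled, unlabelled


def read_xlsx_sequences(
    path: str | Path,
    id_column: str = "id",
    sequence_column: str = "sequence",
) -> list[ProteinRecord]:
    """Read protein records from a spreadsheet with id and sequence columns.

    Convenience loader for published supplementary protein tables distributed
    as XLSX.  Column matching is case-insensitive on the header row.
    """
    df = pd.read_excel(path, dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        id_col = cols[id_column.lower()]
        seq_col = cols[sequence_column.lower()]
    except KeyError as exc:
        raise ValidationError(
            f"spreadsheet {path}: expected columns {id_column!r} and "
            f"{sequence_column!r}, found {list(df.columns)}"
        ) from exc
    records = []
    for pid, seq in zip(df[id_col], df[seq_col]):
        records.append(
            ProteinRecord(id=str(pid), sequence=str(seq).upper().rstrip("*"))
        )
    return records
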