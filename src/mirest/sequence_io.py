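"""Sequence and fixture I/O.

The pipeline works on a single canonical alphabet internally: RNA
(A, C, G, U, uppercase).  DNA input is converted on read and can be
converted back on write.  Gap characters ('-') are stripped from
residues but their count is retained, because the printed reference
tables use gaps to mark indels against the reference miRNA.

Coordinates everywhere in this package are 1-based and inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "AnnotationRow",
    "TargetRow",
    "normalize_sequence",
    "gc_content",
    "read_fasta",
    "write_fasta",
    "load_annotation_table",
    "load_table1",
    "load_table2",
    "reverse_complement",
]

_RNA = set("ACGU")
_ALLOWED = set("ACGTUacgtu-")

#: canonical function vocabulary of the target table
FUNCTION_CATEGORIES = (
    "Metabolism",
    "Transcription factor",
    "Transporter",
    "Stress related",
    "Signal transduction",
    "Growth and development",
    "Structural protein",
    "Disease related",
    "Hypothetical protein",
)


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside A/C/G/T/U/-."""


@dataclass
class SequenceRecord:
    """A normalized sequence with provenance metadata.

    ``residues`` is always uppercase RNA; ``alphabet_origin`` records
    whether the source file was DNA or RNA so round-trips are lossless.
    """

    id: str
    description: str
    residues: str
    alphabet_origin: str = "DNA"
    gap_count: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _RNA
        if bad:
            raise AlphabetError(f"record {self.id!r}: non-RNA residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def normalize_sequence(raw: str, policy: str = "DNA->RNA") -> str:
    """Uppercase, strip gaps, and map T<->U according to *policy*.

    policy is ``"DNA->RNA"`` (T becomes U) or ``"RNA->DNA"`` (U becomes T).
    Characters outside ``{A,C,G,T,U,-}`` (case-insensitive) raise
    :class:`AlphabetError`; IUPAC ambiguity codes are deliberately rejected
    rather than guessed at.
    """
    bad = set(raw) - _ALLOWED
    if bad:
        raise AlphabetError(f"characters outside sequence alphabet: {sorted(bad)}")
    s = raw.upper().replace("-", "")
    if not s:
        raise ValueError("sequence empty after gap stripping")
    if policy == "DNA->RNA":
        return s.replace("T", "U")
    if policy == "RNA->DNA":
        return s.replace("U", "T")
    raise ValueError(f"unknown policy {policy!r}")


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (A<->U, C<->G)."""
    return seq.translate(str.maketrans("ACGU", "UGCA"))[::-1]


def gc_content(seq: str) -> float:
    """G+C percentage of *seq*, truncated (not rounded) to 2 decimals.

    Truncation toward zero reproduces the printed reference values
    (e.g. 9/21 = 42.857 is printed as 42.85).
    """
    if not seq:
        raise ValueError("gc_content of empty sequence")
    frac = 100.0 * sum(c in "GC" for c in seq) / len(seq)
    return math.floor(frac * 100 + 1e-9) / 100


def read_fasta(path, policy: str = "DNA->RNA") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized :class:`SequenceRecord`\\ s.

    Order is preserved.  An empty file yields an empty list with a warning.
    Gap characters are stripped and counted per record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        origin = "RNA" if ("U" in raw.upper() and "T" not in raw.upper()) else "DNA"
        residues = normalize_sequence(raw, "RNA->DNA")  # to DNA first
        residues = residues.replace("T", "U")  # then canonical RNA
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                residues=residues,
                alphabet_origin=origin,
                gap_count=raw.count("-"),
            )
        )
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, alphabet: str = "RNA") -> None:
    """Write records to FASTA, as RNA or converted back to DNA."""
    out = []
    for r in records:
        seq = r.residues if alphabet == "RNA" else r.residues.replace("U", "T")
        desc = r.description if r.description != r.id else ""
        out.append(_BioSeqRecord(Seq(seq), id=r.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


# --------------------------------------------------------------------------
# reference-table fixtures
# --------------------------------------------------------------------------

@dataclass
class AnnotationRow:
    """One characterized mature miRNA (a row of the discovery table)."""

    family: str
    ref_id: str
    precursor_length: int
    mfe: float
    mature_seq: str          # as printed (DNA, may contain gaps)
    n_mismatch: int
    mature_length: int
    source_est: str
    arm: str                 # "5'" or "3'"
    gc_percent: float
    strand: str              # "+" or "-"
    organ: str
    discrepancies: list = field(default_factory=list)

    @property
    def mature_rna(self) -> str:
        """Gap-stripped mature in canonical RNA."""
        return normalize_sequence(self.mature_seq, "DNA->RNA")

    def check(self) -> list:
        """Recompute derivable columns; return (not raise) discrepancies."""
        notes = []
        seq = self.mature_seq.replace("-", "")
        if len(seq) != self.mature_length:
            notes.append(f"{self.family}: ML {self.mature_length} != len {len(seq)}")
        gc = gc_content(seq)
        if abs(gc - self.gc_percent) > 0.005:
            notes.append(f"{self.family}: GC% {self.gc_percent} != recomputed {gc}")
        if not 0 <= self.n_mismatch <= 4:
            notes.append(f"{self.family}: NM {self.n_mismatch} outside 0-4")
        self.discrepancies = notes
        return notes


@dataclass
class TargetRow:
    """One predicted miRNA:mRNA target (a row of the target table)."""

    mirna_family: str
    target_acc: str
    description: str
    function_label: str
    duplex_text: str

    @property
    def category(self) -> str:
        return canonical_category(self.function_label)


def canonical_category(label: str) -> str:
    """Map printed function labels (case/pluralization variants) onto the
    closed category vocabulary."""
    key = label.strip().lower().replace("&", "and").rstrip("s").strip()
    for cat in FUNCTION_CATEGORIES:
        if cat.lower().rstrip("s") == key:
            return cat
    raise ValueError(f"function label {label!r} outside category vocabulary")


def _data_path(name: str) -> Path:
    return Path(resources.files("mirest") / "data" / name)


def load_annotation_table(path, schema: str) -> list:
    """Load a TSV fixture with the given schema (``table1`` or ``table2``).

    Rows failing an internal-consistency check are flagged (the note is
    attached to the row) but never dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty annotation table")
    if schema == "table1":
        rows = []
        for rec in df.to_dict("records"):
            row = AnnotationRow(
                family=rec["family"],
                ref_id=rec["ref_id"],
                precursor_length=int(rec["precursor_length"]),
                mfe=float(rec["mfe"]),
                mature_seq=rec["mature_seq"],
                n_mismatch=int(rec["n_mismatch"]),
                mature_length=int(rec["mature_length"]),
                source_est=rec["source_est"],
                arm=rec["arm"],
                gc_percent=float(rec["gc_percent"]),
                strand=rec["strand"],
                organ=rec["organ"],
            )
            row.check()
            rows.append(row)
        return rows
    if schema == "table2":
        return [
            TargetRow(
                mirna_family=rec["mirna_family"],
                target_acc=rec["target_acc"],
                description=rec["description"],
                function_label=rec["function_label"],
                duplex_text=rec["alignment"],
            )
            for rec in df.to_dict("records")
        ]
    raise ValueError(f"unknown schema {schema!r}")


def load_table1() -> list:
    """The packaged 46-mature discovery fixture."""
    return load_annotation_table(_data_path("table1_mirnas.tsv"), "table1")


def load_table2() -> list:
    """The packaged 138-row target fixture."""
    return load_annotation_table(_data_path("table2_targets.tsv"), "table2")
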