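"""Sequence and annotation input/output.

Reads protein and nucleotide FASTA files, translates EST nucleotide
sequences into the three forward reading frames, extracts candidate open
reading frames, and loads per-sequence secretion/GPI annotation tables
produced by external signal-peptide and GPI-anchor predictors.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the twenty standard residues plus 'X' (unknown) and '*' (stop)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X*")
NT_ALPHABET = frozenset("ACGTN")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


class SourceTier(str, Enum):
    """Sequence provenance tier (EST assemblies, transcript assemblies,
    curated proteins, or other)."""

    TC = "TC"
    TA = "TA"
    NR = "NR"
    OTHER = "OTHER"


class FastaFormatError(ValueError):
    """Raised for a malformed FASTA record; carries record id and line."""

    def __init__(self, message: str, record_id: str | None = None,
                 line: int | None = None):
        self.record_id = record_id
        self.line = line
        loc = []
        if record_id is not None:
            loc.append(f"record {record_id!r}")
        if line is not None:
            loc.append(f"line {line}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)


@dataclass
class SequenceRecord:
    """A protein or translated-EST sequence.

    Parameters
    ----------
    id : str
        Unique sequence identifier.
    sequence : str
        Uppercase amino-acid string; may contain ``X`` and ``*``.
    source_tier : SourceTier
        Provenance of the sequence.
    species : str, optional
        Species key for taxonomy joins.
    frame : int, optional
        Forward reading frame (1-3) for translated ESTs; ``None`` for
        native protein sequences.
    """

    id: str
    sequence: str
    source_tier: SourceTier = SourceTier.OTHER
    species: str | None = None
    frame: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)}")
        if self.frame is not None and self.frame not in (1, 2, 3):
            raise ValueError(f"record {self.id!r}: frame must be 1-3")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Orf:
    """A candidate open reading frame on a translated sequence."""

    parent_id: str
    start: int
    end: int
    sequence: str
    has_stop: bool

    def __post_init__(self) -> None:
        if not self.sequence.startswith("M"):
            raise ValueError("ORF must begin with 'M'")
        if "*" in self.sequence:
            raise ValueError("ORF may not contain a stop character")
        if self.end - self.start != len(self.sequence):
            raise ValueError("ORF coordinates inconsistent with sequence")


@dataclass
class SecretionAnnotation:
    """External predictor output for one sequence.

    ``hmm_sp_probability`` is the HMM signal-peptide probability in
    [0, 1]; ``nn_components_yes`` holds the five neural-network component
    calls (max C, max Y, max S, mean S, D); ``gpi_specificity`` is the
    GPI-anchor prediction specificity in [0, 100], or ``None`` when no
    GPI prediction exists.
    """

    id: str
    hmm_sp_probability: float
    nn_components_yes: tuple[bool, bool, bool, bool, bool]
    gpi_specificity: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.hmm_sp_probability <= 1.0:
            raise ValueError(
                f"annotation {self.id!r}: hmm_sp_probability "
                f"{self.hmm_sp_probability} outside [0, 1]")
        if len(self.nn_components_yes) != 5:
            raise ValueError(
                f"annotation {self.id!r}: exactly five NN flags required")
        if self.gpi_specificity is not None and not (
                0.0 <= self.gpi_specificity <= 100.0):
            raise ValueError(
                f"annotation {self.id!r}: gpi_specificity outside [0, 100]")


def read_fasta(path: str | Path,
               source_tier: SourceTier = SourceTier.OTHER,
               alphabet: frozenset[str] = PROTEIN_ALPHABET,
               ) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and line wrapping is collapsed.  Empty
    sequences raise :class:`FastaFormatError` with the record id and the
    line number of the offending header.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header_lines = _header_line_numbers(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError("empty sequence", record_id=rec.id,
                                   line=header_lines.get(rec.id))
        bad = set(seq) - alphabet
        if bad:
            raise FastaFormatError(
                f"invalid characters {sorted(bad)}", record_id=rec.id,
                line=header_lines.get(rec.id))
        records.append(SequenceRecord(id=rec.id, sequence=seq,
                                      source_tier=source_tier))
    return records


def _header_line_numbers(path: Path) -> dict[str, int]:
    """Map record id -> 1-based line number of its FASTA header."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            if line.startswith(">"):
                rid = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                out.setdefault(rid, n)
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records to FASTA with fixed line wrapping."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="")
            for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def translate_forward_frames(nt: str) -> tuple[str, str, str]:
    """Translate a nucleotide string in the three forward reading frames.

    Uses the standard genetic code; stop codons are rendered ``*``,
    codons containing ``N`` become ``X``, and trailing partial codons are
    dropped.  Reverse-complement frames are never translated: EST
    orientation is taken as given.
    """
    nt = nt.upper()
    bad = [(pos, c) for pos, c in enumerate(nt) if c not in NT_ALPHABET]
    if bad:
        pos, c = bad[0]
        raise ValueError(
            f"invalid nucleotide {c!r} at position {pos}")
    frames = []
    for offset in range(3):
        aa = []
        for j in range(offset, len(nt) - 2, 3):
            codon = nt[j:j + 3]
            aa.append("X" if "N" in codon else _CODON_TABLE[codon])
        frames.append("".join(aa))
    return frames[0], frames[1], frames[2]


def extract_orf(aa: str, parent_id: str = "") -> Orf | None:
    """Extract the longest Met-initiated stretch ending just before a stop.

    Stretches with a downstream stop take precedence; when no
    Met-initiated stretch has one, the longest Met-to-end stretch is
    returned with ``has_stop=False`` so downstream filters can demand
    complete ORFs.  Returns ``None`` when no methionine exists.  Ties are
    broken by smallest start.
    """
    best: Orf | None = None
    seg_start = 0
    n = len(aa)
    for seg, stopped in _segments(aa):
        m = aa.find("M", seg_start, seg_start + len(seg))
        if m != -1:
            end = seg_start + len(seg)
            cand = Orf(parent_id=parent_id, start=m, end=end,
                       sequence=aa[m:end], has_stop=stopped)
            best = _better_orf(best, cand)
        seg_start += len(seg) + 1  # skip the '*'
        if seg_start > n:
            break
    return best


def _segments(aa: str):
    """Yield (segment, has_downstream_stop) for stop-delimited segments."""
    parts = aa.split("*")
    for k, part in enumerate(parts):
        yield part, k < len(parts) - 1


def _better_orf(current: Orf | None, cand: Orf) -> Orf:
    if current is None:
        return cand
    # complete ORFs always beat incomplete ones; then longest, then leftmost
    key = (cand.has_stop, len(cand.sequence), -cand.start)
    cur = (current.has_stop, len(current.sequence), -current.start)
    return cand if key > cur else current


_REQUIRED_ANNOTATION_COLUMNS = (
    "id", "hmm_sp_probability",
    "nn_max_C", "nn_max_Y", "nn_max_S", "nn_mean_S", "nn_D",
)


def load_annotations(path: str | Path) -> dict[str, SecretionAnnotation]:
    """Load a tab-separated secretion/GPI annotation table.

    The table must have a header with columns ``id``,
    ``hmm_sp_probability``, the five NN flag columns (``nn_max_C``,
    ``nn_max_Y``, ``nn_max_S``, ``nn_mean_S``, ``nn_D``, values Y/N) and
    optionally ``gpi_specificity``.  Duplicate ids keep the last row with
    a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    out: dict[str, SecretionAnnotation] = {}
    flags = _REQUIRED_ANNOTATION_COLUMNS[2:]
    for _, row in df.iterrows():
        rid = str(row["id"])
        if rid in out:
            logger.warning("duplicate annotation for %r: keeping last", rid)
        gpi = None
        if "gpi_specificity" in df.columns and pd.notna(row.get("gpi_specificity")):
            gpi = float(row["gpi_specificity"])
        out[rid] = SecretionAnnotation(
            id=rid,
            hmm_sp_probability=float(row["hmm_sp_probability"]),
            nn_components_yes=tuple(
                str(row[c]).strip().upper() in ("Y", "YES", "TRUE", "1")
                for c in flags),
            gpi_specificity=gpi,
        )
    return out


def load_species_table(path: str | Path) -> pd.DataFrame:
    """Load the optional species/taxonomy table (id, species, family,
    division)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "species"):
        if col not in df.columns:
            raise ValueError(f"species table missing column {col!r}")
    return df
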