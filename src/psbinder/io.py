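"""Peptide sequence input, validation, and hygiene.

Peptides are short sequences over the 20 canonical one-letter amino-acid
codes. Input arrives either as FASTA or as plain text with one sequence per
line (the formats biopanning result lists are shared in). Ambiguous residue
codes (B, J, O, U, X, Z) and non-alphabetic characters are rejected because
composition features are undefined for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

#: The 20 canonical residues, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Ambiguity codes that disqualify a peptide outright.
AMBIGUOUS_CODES = frozenset("BJOUXZ")


class SequenceError(ValueError):
    """Raised when a sequence or record cannot be parsed or validated."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide: an identifier plus a canonical-residue sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        reason = validate_sequence(self.sequence)
        if reason is not None:
            raise SequenceError(f"invalid sequence for {self.id!r}: {reason}")
        if self.sequence != self.sequence.upper():
            object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str) -> Optional[str]:
    """Check a sequence against the 20-letter alphabet.

    Returns ``None`` if the (uppercased) sequence is acceptable, otherwise a
    human-readable rejection reason naming the first offending character and
    its 1-based position. Rejection is a return value, not an exception, so
    batch pipelines can log and continue.
    """
    if not sequence:
        return "empty sequence"
    upper = sequence.upper()
    for pos, ch in enumerate(upper, start=1):
        if ch not in _ALPHABET_SET:
            kind = "ambiguous residue" if ch in AMBIGUOUS_CODES else (
                "invalid residue" if ch.isalpha() else "nonalphabetic character"
            )
            return f"{kind} {ch!r} at position {pos}"
    return None


def trim_flanking_cysteines(sequence: str) -> str:
    """Remove the terminal cysteine pair of a disulfide-constrained peptide.

    Circular (cyclic) phage-display peptides are flanked by a C...C pair that
    forms the constraining disulfide bond and is not part of the displayed
    variable region. If the sequence both starts and ends with ``C`` and has
    at least 3 residues, the two flanking residues are removed; otherwise the
    sequence is returned unchanged. Applied once, never recursively.
    """
    if len(sequence) >= 3 and sequence[0] == "C" and sequence[-1] == "C":
        return sequence[1:-1]
    return sequence


def parse_fasta(text: str) -> List[Peptide]:
    """Parse FASTA text into peptides.

    Record ids are the first whitespace-delimited token after ``>``;
    multi-line sequence bodies are concatenated and uppercased before
    validation. ``;`` comment lines are not part of the accepted dialect.
    """
    if not text.strip():
        raise SequenceError("empty FASTA input")
    peptides: List[Peptide] = []
    current_id: Optional[str] = None
    chunks: List[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise SequenceError(f"empty sequence in record {current_id}")
        peptides.append(Peptide(id=current_id, sequence=seq))

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(";"):
            raise SequenceError("';' comment lines are not supported")
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            current_id = header.split()[0] if header else "unnamed"
            chunks = []
        else:
            if current_id is None:
                raise SequenceError("sequence data before first '>' header")
            chunks.append(line)
    flush()
    if not peptides:
        raise SequenceError("no FASTA records found")
    return peptides


def parse_plain(text: str) -> List[Peptide]:
    """Parse plain text, one sequence per non-blank line.

    Ids are auto-generated as ``seq1``, ``seq2``, ... in input order.
    Validation errors cite the offending line number.
    """
    peptides: List[Peptide] = []
    counter = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        seq = raw.strip()
        if not seq:
            continue
        counter += 1
        reason = validate_sequence(seq)
        if reason is not None:
            raise SequenceError(f"line {lineno}: {reason}")
        peptides.append(Peptide(id=f"seq{counter}", sequence=seq.upper()))
    return peptides


def render_fasta(peptides: Iterable[Peptide]) -> str:
    """Serialize peptides as FASTA (inverse of :func:`parse_fasta`)."""
    return "".join(f">{p.id}\n{p.sequence}\n" for p in peptides)


def render_plain(peptides: Iterable[Peptide]) -> str:
    """Serialize peptides as plain text (inverse of :func:`parse_plain`)."""
    return "".join(f"{p.sequence}\n" for p in peptides)


def read_raw_records(path: str) -> List[tuple]:
    """Read (id, sequence) pairs without validation.

    Used by batch prediction, where an invalid sequence must become a
    per-row error annotation rather than abort the whole file. Sequences
    are uppercased; FASTA bodies are concatenated; plain-text ids are
    auto-generated.
    """
    with open(path) as fh:
        text = fh.read()
    records: List[tuple] = []
    if text.lstrip().startswith(">"):
        current: Optional[str] = None
        chunks: List[str] = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    records.append((current, "".join(chunks).upper()))
                header = line[1:].strip()
                current = header.split()[0] if header else "unnamed"
                chunks = []
            elif current is not None:
                chunks.append(line)
        if current is not None:
            records.append((current, "".join(chunks).upper()))
    else:
        n = 0
        for line in text.splitlines():
            seq = line.strip()
            if seq:
                n += 1
                records.append((f"seq{n}", seq.upper()))
    return records


def read_peptides(path: str) -> List[Peptide]:
    """Read peptides from a file, sniffing FASTA vs plain-text format."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith(">"):
        return parse_fasta(text)
    return parse_plain(text)
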