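"""Training-set curation for peptide binding classification.

Negative peptides (biopanning hits against targets other than polystyrene)
may hide undiscovered plastic binders. Curation therefore removes, from the
negative side only, exact duplicates of positive sequences and any negative
whose composition is too similar to a positive, measured by the Generalized
Jaccard similarity on residue-count multisets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

from .io import Peptide, trim_flanking_cysteines, validate_sequence

#: Default cross-set similarity ceiling: negatives at or above this
#: Generalized Jaccard similarity to any positive are discarded.
DEFAULT_SIMILARITY_THRESHOLD = 0.90


def _residue_counts(sequence: str) -> Counter:
    return Counter(sequence)


def _dipeptide_counts(sequence: str) -> Counter:
    return Counter(sequence[i : i + 2] for i in range(len(sequence) - 1))


_REPRESENTATIONS: dict = {
    "residue": _residue_counts,
    "dipeptide": _dipeptide_counts,
}


def generalized_jaccard(
    a: str, b: str, representation: str = "residue"
) -> float:
    """Generalized (multiset) Jaccard similarity of two sequences.

    With count vectors ``x`` and ``y`` over the chosen token set,
    returns ``sum_i min(x_i, y_i) / sum_i max(x_i, y_i)``. Symmetric, in
    [0, 1], and exactly 1 iff the two token multisets are identical.

    ``representation`` selects the token multiset: ``"residue"`` (default,
    single amino-acid counts) or ``"dipeptide"`` (overlapping 2-mer counts).
    """
    if not a or not b:
        raise ValueError("generalized_jaccard requires non-empty sequences")
    try:
        count = _REPRESENTATIONS[representation]
    except KeyError:
        raise ValueError(f"unknown representation {representation!r}") from None
    xa, xb = count(a), count(b)
    keys = set(xa) | set(xb)
    num = sum(min(xa[k], xb[k]) for k in keys)
    den = sum(max(xa[k], xb[k]) for k in keys)
    return num / den


def remove_exact_duplicates(
    negatives: Sequence[Peptide], positives: Sequence[Peptide]
) -> List[Peptide]:
    """Drop negatives whose sequence exactly matches any positive, and
    within-negative exact duplicates (first occurrence kept)."""
    positive_seqs = {p.sequence for p in positives}
    seen: set = set()
    kept: List[Peptide] = []
    for pep in negatives:
        if pep.sequence in positive_seqs or pep.sequence in seen:
            continue
        seen.add(pep.sequence)
        kept.append(pep)
    return kept


def filter_by_similarity(
    negatives: Sequence[Peptide],
    positives: Sequence[Peptide],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    representation: str = "residue",
) -> List[Peptide]:
    """Keep only negatives strictly below ``threshold`` similarity to every
    positive (strict ``<``: a similarity equal to the threshold is removed)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    kept = []
    for neg in negatives:
        if all(
            generalized_jaccard(neg.sequence, pos.sequence, representation)
            < threshold
            for pos in positives
        ):
            kept.append(neg)
    return kept


@dataclass
class CurationRecord:
    """One logged curation action: which sequence, at which stage, and why."""

    sequence: str
    stage: str
    action: str
    reason: str


@dataclass
class LabeledDataset:
    """A curated, labeled peptide training set.

    Invariants (enforced by :func:`assemble_dataset`): no sequence appears in
    both classes, and every negative is below the similarity threshold to
    every positive.
    """

    positives: List[Peptide]
    negatives: List[Peptide]
    report: List[CurationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)

    def peptides(self) -> List[Peptide]:
        return list(self.positives) + list(self.negatives)

    def labels(self) -> List[int]:
        """1 for positives (binders), 0 for negatives."""
        return [1] * len(self.positives) + [0] * len(self.negatives)

    def report_tsv(self) -> str:
        lines = ["sequence\tstage\taction\treason"]
        lines += [
            f"{r.sequence}\t{r.stage}\t{r.action}\t{r.reason}"
            for r in self.report
        ]
        return "\n".join(lines) + "\n"


def _hygiene(
    raw: Sequence[Peptide],
    side: str,
    trim: bool,
    log: List[CurationRecord],
) -> List[Peptide]:
    out: List[Peptide] = []
    seen: set = set()
    for pep in raw:
        seq = pep.sequence
        if trim:
            trimmed = trim_flanking_cysteines(seq)
            if trimmed != seq:
                log.append(
                    CurationRecord(seq, f"{side}/trim", "trimmed",
                                   "flanking-cysteines-removed")
                )
                seq = trimmed
        reason = validate_sequence(seq)
        if reason is not None or len(seq) < 2:
            log.append(
                CurationRecord(seq, f"{side}/validate", "dropped",
                               reason or "shorter than one dipeptide")
            )
            continue
        if seq in seen:
            log.append(
                CurationRecord(seq, f"{side}/dedup", "dropped",
                               "within-set-duplicate")
            )
            continue
        seen.add(seq)
        out.append(Peptide(id=pep.id, sequence=seq))
    return out


def assemble_dataset(
    raw_positives: Sequence[Peptide],
    raw_negatives: Sequence[Peptide],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    trim: bool = True,
    representation: str = "residue",
) -> LabeledDataset:
    """Build a curated :class:`LabeledDataset` from candidate lists.

    Stages, in order, with every drop logged:

    1. flanking-cysteine trimming (both sides, when ``trim``),
    2. validation (invalid or sub-dipeptide sequences dropped),
    3. exact-duplicate removal — negatives matching a positive, plus
       within-set duplicates,
    4. composition-similarity filtering of the negative side only.

    Positives are never filtered against negatives: the asymmetry exists
    because a too-similar negative may be an unlabeled binder, while a
    positive is experimentally confirmed.
    """
    log: List[CurationRecord] = []
    positives = _hygiene(raw_positives, "positive", trim, log)
    negatives = _hygiene(raw_negatives, "negative", trim, log)

    pos_seqs = {p.sequence for p in positives}
    deduped = []
    for neg in negatives:
        if neg.sequence in pos_seqs:
            log.append(
                CurationRecord(neg.sequence, "negative/cross-dedup", "dropped",
                               "duplicate-of-positive")
            )
        else:
            deduped.append(neg)

    surviving = []
    for neg in deduped:
        sims = [
            generalized_jaccard(neg.sequence, pos.sequence, representation)
            for pos in positives
        ]
        if sims and max(sims) >= threshold:
            log.append(
                CurationRecord(
                    neg.sequence, "negative/similarity", "dropped",
                    f"generalized-jaccard {max(sims):.3f} >= {threshold:g}",
                )
            )
        else:
            surviving.append(neg)

    if not positives or not surviving:
        raise ValueError(
            "curation produced an empty class "
            f"({len(positives)} positives, {len(surviving)} negatives)"
        )
    return LabeledDataset(positives=positives, negatives=surviving, report=log)
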