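"""Synthetic labeled peptide datasets with the signal structure reported
for polystyrene binders.

Positives are enriched in the benzene-ring aromatics W, Y and F, and a
configurable fraction carry one of the recurrent plastic-binding motifs
WXXW, FHXXW or WXXWXXXW (X = any residue). Negatives are i.i.d. draws from
a documented background distribution at matched lengths, emulating panning
hits against unrelated targets. Motif wildcard positions are drawn from the
*background* (unenriched) distribution so the sequence-order signal and the
composition signal can be switched independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .curation import LabeledDataset, assemble_dataset
from .io import ALPHABET, Peptide

#: Residue background options. "natural" uses rounded vertebrate-proteome
#: frequencies; "uniform" is the simplest documented null.
NATURAL_FREQUENCIES = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

AROMATIC = ("W", "Y", "F")

DEFAULT_MOTIFS = ("WXXW", "FHXXW", "WXXWXXXW")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; a spec (seed included) fully determines the
    dataset.

    Lengths 7 and 12 mirror the commonest phage-display random-library
    sizes. ``motif_fraction`` of positives carry one explicitly planted
    motif; the rest rely on aromatic enrichment alone. The enrichment
    multiplier scales the W/Y/F background weights before renormalizing.
    """

    n_per_class: int = 104
    length_distribution: Tuple[Tuple[int, float], ...] = ((7, 0.5), (12, 0.5))
    motif_set: Tuple[str, ...] = DEFAULT_MOTIFS
    motif_fraction: float = 0.7
    aromatic_enrichment: float = 3.0
    background: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_fraction <= 1.0:
            raise ValueError("motif_fraction must be in [0, 1]")
        if self.aromatic_enrichment <= 0:
            raise ValueError("aromatic_enrichment must be positive")
        if not self.length_distribution:
            raise ValueError("length_distribution is empty")
        if self.motif_fraction > 0:
            shortest = min(len(m) for m in self.motif_set)
            max_len = max(l for l, _ in self.length_distribution)
            if max_len < shortest:
                raise ValueError(
                    "no generated length can accommodate any motif"
                )

    def background_probs(self) -> np.ndarray:
        if self.background == "uniform":
            return np.full(20, 0.05)
        if self.background == "natural":
            p = np.array([NATURAL_FREQUENCIES[a] for a in ALPHABET])
            return p / p.sum()
        raise ValueError(f"unknown background {self.background!r}")

    def enriched_probs(self) -> np.ndarray:
        p = self.background_probs().copy()
        for a in AROMATIC:
            p[ALPHABET.index(a)] *= self.aromatic_enrichment
        return p / p.sum()


_RESIDUES = np.array(list(ALPHABET))


def _draw(rng: np.random.Generator, probs: np.ndarray, n: int) -> str:
    return "".join(rng.choice(_RESIDUES, size=n, p=probs))


def _draw_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    lengths, weights = zip(*spec.length_distribution)
    w = np.asarray(weights, dtype=float)
    return int(rng.choice(lengths, p=w / w.sum()))


def generate_positive(
    spec: SyntheticSpec, rng: np.random.Generator, id: str = "pos"
) -> Peptide:
    """One synthetic binder.

    With probability ``motif_fraction`` a motif is planted at a uniform
    random offset: the motif is drawn uniformly among those that fit the
    drawn length (lengths too short for a given motif simply never receive
    it), its X wildcards come from the background distribution, and the
    residual positions come from the aromatic-enriched distribution.
    Otherwise the whole sequence is drawn from the enriched distribution.
    """
    length = _draw_length(spec, rng)
    enriched = spec.enriched_probs()
    background = spec.background_probs()
    if rng.random() < spec.motif_fraction:
        fitting = [m for m in spec.motif_set if len(m) <= length]
        if fitting:
            motif = fitting[int(rng.integers(len(fitting)))]
            offset = int(rng.integers(length - len(motif) + 1))
            chars = list(_draw(rng, enriched, length))
            for i, ch in enumerate(motif):
                chars[offset + i] = (
                    _draw(rng, background, 1) if ch == "X" else ch
                )
            return Peptide(id=id, sequence="".join(chars))
    return Peptide(id=id, sequence=_draw(rng, enriched, length))


def generate_negative(
    spec: SyntheticSpec, rng: np.random.Generator, id: str = "neg"
) -> Peptide:
    """One synthetic non-binder: i.i.d. background residues at a length
    drawn from the same length distribution as the positives."""
    length = _draw_length(spec, rng)
    return Peptide(id=id, sequence=_draw(rng, spec.background_probs(), length))


def generate_dataset(
    spec: SyntheticSpec, max_rounds: int = 50
) -> LabeledDataset:
    """A curated balanced dataset of exactly ``n_per_class`` per class.

    Generated candidates are passed through the standard curation pipeline
    (duplicate and cross-set-similarity filters); shortfalls are topped up
    by further sampling from the same stream, bounded by ``max_rounds``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    positives: List[Peptide] = []
    negatives: List[Peptide] = []
    dataset = None
    for _ in range(max_rounds):
        while len(positives) < n:
            positives.append(
                generate_positive(spec, rng, id=f"pos{len(positives) + 1}")
            )
        while len(negatives) < n:
            negatives.append(
                generate_negative(spec, rng, id=f"neg{len(negatives) + 1}")
            )
        dataset = assemble_dataset(positives, negatives, trim=False)
        if len(dataset.positives) >= n and len(dataset.negatives) >= n:
            return LabeledDataset(
                positives=dataset.positives[:n],
                negatives=dataset.negatives[:n],
                report=dataset.report,
            )
        # keep the survivors, resample the shortfall
        positives = list(dataset.positives)
        negatives = list(dataset.negatives)
    raise RuntimeError(
        f"could not assemble {n}+{n} curated peptides in {max_rounds} rounds"
    )
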