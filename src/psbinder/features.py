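"""Composition feature encodings.

A peptide of length L is represented by its amino-acid composition (AAC,
20 residue frequencies, counts divided by L) concatenated with its dipeptide
composition (DPC, 400 overlapping 2-mer frequencies, counts divided by
L - 1). Dipeptides are overlapping windows, so the DPC denominator is L - 1
and each block independently sums to 1.

The feature index convention is fixed and load-bearing (feature subsets and
persisted models refer to it): indices 0-19 are AAC in alphabetical residue
order A..Y; indices 20-419 are DPC in row-major order, first residue varying
slowest, both alphabetical ("AA", "AC", ..., "YY").
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np

from .io import ALPHABET, Peptide

AA: List[str] = list(ALPHABET)
DIPEPTIDES: List[str] = [a + b for a in AA for b in AA]
FEATURE_NAMES: List[str] = AA + DIPEPTIDES

N_AAC = 20
N_DPC = 400
N_FEATURES = N_AAC + N_DPC

AAC_INDICES = np.arange(N_AAC)
DPC_INDICES = np.arange(N_AAC, N_FEATURES)

_AA_INDEX = {a: i for i, a in enumerate(AA)}
_DP_INDEX = {d: i for i, d in enumerate(DIPEPTIDES)}


def _seq(peptide: Union[Peptide, str]) -> str:
    return peptide.sequence if isinstance(peptide, Peptide) else peptide


def aac(peptide: Union[Peptide, str]) -> np.ndarray:
    """20-component amino-acid composition; sums to 1."""
    seq = _seq(peptide)
    if not seq:
        raise ValueError("AAC undefined for an empty sequence")
    vec = np.zeros(N_AAC)
    for ch in seq:
        vec[_AA_INDEX[ch]] += 1.0
    return vec / len(seq)


def dpc(peptide: Union[Peptide, str]) -> np.ndarray:
    """400-component overlapping dipeptide composition; sums to 1."""
    seq = _seq(peptide)
    if len(seq) < 2:
        raise ValueError("DPC undefined for length-1 peptide")
    vec = np.zeros(N_DPC)
    for i in range(len(seq) - 1):
        vec[_DP_INDEX[seq[i : i + 2]]] += 1.0
    return vec / (len(seq) - 1)


def encode(
    peptide: Union[Peptide, str],
    subset: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Full 420-dimensional AAC∥DPC vector, optionally projected onto a
    feature-index subset (order of ``subset`` preserved)."""
    if subset is not None and len(subset) > 0:
        idx = np.asarray(subset, dtype=int)
        needs_dpc = bool(np.any(idx >= N_AAC))
    else:
        idx = None
        needs_dpc = True
    seq = _seq(peptide)
    if needs_dpc and len(seq) < 2:
        raise ValueError("DPC undefined for length-1 peptide")
    if needs_dpc:
        full = np.concatenate([aac(seq), dpc(seq)])
    else:
        full = np.concatenate([aac(seq), np.zeros(N_DPC)])
    return full if idx is None else full[idx]


def feature_matrix(
    peptides: Sequence[Union[Peptide, str]],
    subset: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Stack :func:`encode` over peptides into an (n, d) matrix."""
    return np.vstack([encode(p, subset) for p in peptides])


def block_indices(block: str) -> np.ndarray:
    """Feature indices for a named block: ``"aac"``, ``"dpc"`` or ``"both"``."""
    if block == "aac":
        return AAC_INDICES.copy()
    if block == "dpc":
        return DPC_INDICES.copy()
    if block == "both":
        return np.arange(N_FEATURES)
    raise ValueError(f"unknown feature block {block!r}")


def matrix_tsv(
    peptides: Sequence[Peptide], subset: Optional[Sequence[int]] = None
) -> str:
    """Feature matrix as TSV with an id column and per-feature name header."""
    idx = np.arange(N_FEATURES) if subset is None else np.asarray(subset, int)
    names = [FEATURE_NAMES[i] for i in idx]
    X = feature_matrix(peptides, idx)
    lines = ["id\t" + "\t".join(names)]
    for pep, row in zip(peptides, X):
        lines.append(pep.id + "\t" + "\t".join(f"{v:.10g}" for v in row))
    return "\n".join(lines) + "\n"


def matrix_svmlight(
    peptides: Sequence[Peptide],
    labels: Sequence[int],
    subset: Optional[Sequence[int]] = None,
) -> str:
    """Sparse "label index:value" lines, 1-based ascending feature indices,
    the file convention of common SVM training tools."""
    X = feature_matrix(peptides, subset)
    lines = []
    for label, row in zip(labels, X):
        nz = np.nonzero(row)[0]
        parts = [str(int(label))] + [f"{j + 1}:{row[j]:.10g}" for j in nz]
        lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"
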