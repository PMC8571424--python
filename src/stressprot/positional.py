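"""Composition and positional descriptors over the 20 standard amino acids.

All structures here are indexed by the alphabetically ordered standard
amino-acid list (A..Y). Non-standard symbols (X, O, U and normalized
ambiguity codes) are ignored — they contribute to none of these counts.

* frequency vector: 20 occurrence counts tau_i.
* AAPIV: accumulative absolute position incidence vector — mu_i is the sum
  of the 1-based positions at which amino acid i occurs. RAAPIV is the same
  on the reversed sequence.
* PRIM: 20x20 position relative incidence matrix — M[i, j] is the sum of
  signed offsets of every occurrence of amino acid j relative to the first
  occurrence of amino acid i (occurrences preceding it contribute negative
  offsets). Rows for absent amino acids are zero. RPRIM is PRIM of the
  reversed sequence.
"""

from __future__ import annotations

import numpy as np

from .sequence_io import STANDARD_AMINO_ACIDS, STANDARD_INDEX, ProteinSequence

N_STANDARD = len(STANDARD_AMINO_ACIDS)


def frequency_vector(seq: ProteinSequence) -> np.ndarray:
    """Count each standard amino acid; length-20 integer vector."""
    tau = np.zeros(N_STANDARD, dtype=np.int64)
    for c in seq.residues:
        i = STANDARD_INDEX.get(c)
        if i is not None:
            tau[i] += 1
    return tau


def aapiv(seq: ProteinSequence) -> np.ndarray:
    """Sum of 1-based positions of each standard amino acid."""
    mu = np.zeros(N_STANDARD, dtype=np.int64)
    for pos, c in enumerate(seq.residues, 1):
        i = STANDARD_INDEX.get(c)
        if i is not None:
            mu[i] += pos
    return mu


def raapiv(seq: ProteinSequence) -> np.ndarray:
    """AAPIV of the character-reversed sequence."""
    return aapiv(seq.reversed())


def prim(seq: ProteinSequence) -> np.ndarray:
    """20x20 matrix of summed signed offsets relative to first occurrences.

    M[i, j] = sum over occurrences p of amino acid j of (p - f_i), where
    f_i is the 1-based first-occurrence position of amino acid i. Using the
    per-acid position sums mu_j and counts c_j this is mu_j - c_j * f_i.
    """
    mu = aapiv(seq)
    counts = frequency_vector(seq)
    first = np.zeros(N_STANDARD, dtype=np.int64)
    for pos, c in enumerate(seq.residues, 1):
        i = STANDARD_INDEX.get(c)
        if i is not None and first[i] == 0:
            first[i] = pos
    m = np.zeros((N_STANDARD, N_STANDARD), dtype=np.int64)
    present = first > 0
    m[present, :] = mu[np.newaxis, :] - counts[np.newaxis, :] * first[present, np.newaxis]
    return m


def rprim(seq: ProteinSequence) -> np.ndarray:
    """PRIM of the character-reversed sequence."""
    return prim(seq.reversed())
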