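"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively — explicit Python loops, Gram-Schmidt
via QR — and deliberately shares no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np

from stressprot.moments import MOMENT_ORDERS
from stressprot.sequence_io import STANDARD_AMINO_ACIDS, ENCODING_ALPHABET

AA20 = STANDARD_AMINO_ACIDS


def random_sequences(rng: np.random.Generator, n: int, min_len=5, max_len=120,
                     alphabet: str = ENCODING_ALPHABET):
    """Random residue strings over the full 23-symbol alphabet."""
    letters = list(alphabet)
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(letters, size=length)))
    return out


def brute_raw_moments(grid: np.ndarray) -> np.ndarray:
    n = grid.shape[0]
    vals = []
    for x, y in MOMENT_ORDERS:
        s = 0.0
        for l in range(1, n + 1):
            for m in range(1, n + 1):
                s += (l ** x) * (m ** y) * grid[l - 1, m - 1]
        vals.append(s)
    return np.array(vals)


def brute_central_moments(grid: np.ndarray) -> np.ndarray:
    n = grid.shape[0]
    g00 = float(grid.sum())
    if g00 == 0:
        return np.zeros(10)
    xbar = sum(l * grid[l - 1, m - 1] for l in range(1, n + 1)
               for m in range(1, n + 1)) / g00
    ybar = sum(m * grid[l - 1, m - 1] for l in range(1, n + 1)
               for m in range(1, n + 1)) / g00
    vals = []
    for x, y in MOMENT_ORDERS:
        s = 0.0
        for l in range(1, n + 1):
            for m in range(1, n + 1):
                s += ((l - xbar) ** x) * ((m - ybar) ** y) * grid[l - 1, m - 1]
        vals.append(s)
    return np.array(vals)


def gram_schmidt_basis(n: int) -> np.ndarray:
    """Orthonormal polynomial basis over x=0..n-1 via QR of the Vandermonde
    matrix, sign-fixed so every leading coefficient is positive."""
    x = np.arange(n, dtype=float)
    v = np.column_stack([x ** k for k in range(min(4, n))])
    q, r = np.linalg.qr(v)
    q = q * np.sign(np.diag(r))  # leading coefficients positive
    basis = np.zeros((4, n))
    basis[: q.shape[1]] = q.T
    return basis


def brute_hahn_moments(grid: np.ndarray) -> np.ndarray:
    n = grid.shape[0]
    basis = gram_schmidt_basis(n)
    vals = []
    for x, y in MOMENT_ORDERS:
        s = 0.0
        for a in range(n):
            for b in range(n):
                s += grid[a, b] * basis[x, a] * basis[y, b]
        vals.append(s)
    return np.array(vals)


def brute_frequency(residues: str) -> np.ndarray:
    return np.array([residues.count(aa) for aa in AA20], dtype=np.int64)


def brute_aapiv(residues: str) -> np.ndarray:
    out = np.zeros(20, dtype=np.int64)
    for i, aa in enumerate(AA20):
        for pos in range(len(residues)):
            if residues[pos] == aa:
                out[i] += pos + 1
    return out


def brute_raapiv(residues: str) -> np.ndarray:
    return brute_aapiv(residues[::-1])


def brute_prim(residues: str) -> np.ndarray:
    m = np.zeros((20, 20), dtype=np.int64)
    for i, aa_i in enumerate(AA20):
        if aa_i not in residues:
            continue
        f_i = residues.index(aa_i) + 1
        for j, aa_j in enumerate(AA20):
            for pos in range(len(residues)):
                if residues[pos] == aa_j:
                    m[i, j] += (pos + 1) - f_i
    return m


def brute_rprim(residues: str) -> np.ndarray:
    return brute_prim(residues[::-1])
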