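"""Independent brute-force global-alignment oracle.

Enumerates every possible set of aligned residue pairs (a strictly
increasing match chain in the n x m grid) and scores each with the
closed-form minimal affine gap cost for that chain; every global
alignment corresponds to a chain plus a gap arrangement, and no
arrangement beats the minimal one, so the best chain gives the optimal
alignment.  The oracle optimizes the same deterministic tuple as the
package aligner — (score, identical columns, -alignment length) — but by
exhaustive enumeration rather than dynamic programming.

Scores are kept at 2x scale in exact integer arithmetic.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

OPEN2, EXT2 = 20, 1  # 2x scale: gap open 10, extend 0.5


@lru_cache(maxsize=4)
def scores2(matrix_name: str = "BLOSUM62") -> np.ndarray:
    mat = substitution_matrices.load(matrix_name)
    out = np.full((26, 26), -(10**9), dtype=np.int64)
    for a in mat.alphabet:
        if not a.isalpha():
            continue
        for b in mat.alphabet:
            if not b.isalpha():
                continue
            out[ord(a) - 65, ord(b) - 65] = int(round(2 * mat[a][b]))
    return out


@lru_cache(maxsize=64)
def match_chains(n: int, m: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All strictly increasing chains of (i, j) match positions."""
    out: list[tuple[tuple[int, int], ...]] = []

    def rec(chain: list[tuple[int, int]], i0: int, j0: int) -> None:
        out.append(tuple(chain))
        for i in range(i0, n):
            for j in range(j0, m):
                chain.append((i, j))
                rec(chain, i + 1, j + 1)
                chain.pop()

    rec([], 0, 0)
    return tuple(out)


def gap_cost2(k: int) -> int:
    return 0 if k == 0 else OPEN2 + (k - 1) * EXT2


def chain_gap_cost2(chain, n: int, m: int) -> int:
    """Minimal affine gap cost (2x) over all arrangements of a chain."""
    cost = 0
    prev_i = prev_j = -1
    for i, j in chain:
        cost += gap_cost2(i - prev_i - 1) + gap_cost2(j - prev_j - 1)
        prev_i, prev_j = i, j
    return cost + gap_cost2(n - prev_i - 1) + gap_cost2(m - prev_j - 1)


def oracle_stats(seq_a: str, seq_b: str) -> tuple[float, int, int]:
    """(score, identities, columns) of the best alignment of one pair."""
    S = scores2()
    a = [ord(c) - 65 for c in seq_a]
    b = [ord(c) - 65 for c in seq_b]
    n, m = len(a), len(b)
    best = None
    for chain in match_chains(n, m):
        score = -chain_gap_cost2(chain, n, m)
        ident = 0
        for i, j in chain:
            score += S[a[i], b[j]]
            ident += a[i] == b[j]
        length = n + m - len(chain)
        key = (score, ident, -length)
        if best is None or key > best:
            best = key
    return best[0] / 2.0, best[1], -best[2]


def oracle_pid(seq_a: str, seq_b: str) -> float:
    _score, ident, length = oracle_stats(seq_a, seq_b)
    return 100.0 * ident / length


def oracle_all_pairs(n: int, m: int, letters: str):
    """Vectorised oracle over every pair of length-n x length-m sequences.

    Returns (score2, identities, columns) arrays of shape (|letters|^n,
    |letters|^m), sequence order = itertools.product over ``letters``.
    """
    S = scores2()
    codes = np.array([ord(c) - 65 for c in letters], dtype=np.int64)
    A = codes[
        np.array(list(itertools.product(range(len(letters)), repeat=n)), dtype=np.int64)
    ]
    B = codes[
        np.array(list(itertools.product(range(len(letters)), repeat=m)), dtype=np.int64)
    ]
    sub = {}
    eq = {}
    for i in range(n):
        for j in range(m):
            sub[(i, j)] = S[A[:, i][:, None], B[None, :, j]]
            eq[(i, j)] = (A[:, i][:, None] == B[None, :, j]).astype(np.int64)
    shape = (A.shape[0], B.shape[0])
    best_s = np.full(shape, -(10**9), np.int64)
    best_i = np.zeros(shape, np.int64)
    best_l = np.zeros(shape, np.int64)
    for chain in match_chains(n, m):
        score = np.full(shape, -chain_gap_cost2(chain, n, m), np.int64)
        ident = np.zeros(shape, np.int64)
        for i, j in chain:
            score = score + sub[(i, j)]
            ident = ident + eq[(i, j)]
        length = n + m - len(chain)
        upd = (score > best_s) | (
            (score == best_s)
            & ((ident > best_i) | ((ident == best_i) & (length < best_l)))
        )
        best_s = np.where(upd, score, best_s)
        best_i = np.where(upd, ident, best_i)
        best_l = np.where(upd, length, best_l)
    return A, B, best_s, best_i, best_l
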