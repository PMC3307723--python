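"""Pairwise edit distance and optimal alignment under an affine gap cost.

The edit cost between two gap-free sequences is the minimum, over all
monotone alignments, of the summed substitution costs of the base/base
columns plus ``gap_cost(l)`` for every maximal run of ``l`` gap columns in
either row.  This is computed by the standard three-state (match / gap-in-a /
gap-in-b) Gotoh dynamic program, run on integer-rescaled costs so the result
is exact.  Traceback is deterministic with tie order: diagonal, then gap in
sequence b's row, then gap in sequence a's row — determinism here is what
makes implied alignments reproducible downstream.

:func:`enumerate_alignments_cost` is a brute-force oracle (exhaustive
enumeration of all alignments of short sequences) kept independent of the DP
so the two can be checked against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .cost_model import INT_INF, Cost, CostScheme
from .formats import GAP

_M, _X, _Y = 0, 1, 2  # match column, gap in row_b (consumes a), gap in row_a


def _check_input(seq: str) -> None:
    for ch in seq:
        if ch not in "ACGTN":
            raise ValueError(f"illegal character {ch!r} in unaligned sequence")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length rows realizing the optimal alignment, plus its cost."""

    row_a: str
    row_b: str
    cost: Cost

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        for x, y in zip(self.row_a, self.row_b):
            if x == GAP and y == GAP:
                raise ValueError("gap/gap column in pairwise alignment")

    def columns(self):
        return list(zip(self.row_a, self.row_b))


def score_alignment(row_a: str, row_b: str, scheme: CostScheme) -> Cost:
    """Recompute the cost of a two-row alignment from its columns and gap runs."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    total: Cost = Fraction(0)
    run_a = run_b = 0
    for x, y in zip(row_a, row_b):
        if x == GAP and y == GAP:
            raise ValueError("gap/gap column")
        if x == GAP:
            run_a += 1
        else:
            if run_a:
                total += scheme.gap_cost(run_a)
                run_a = 0
        if y == GAP:
            run_b += 1
        else:
            if run_b:
                total += scheme.gap_cost(run_b)
                run_b = 0
        if x != GAP and y != GAP:
            total += scheme.substitution_cost(x, y)
    if run_a:
        total += scheme.gap_cost(run_a)
    if run_b:
        total += scheme.gap_cost(run_b)
    return total


def _dp_tables(a: str, b: str, scheme: CostScheme):
    table, scale = scheme.integerized()
    sub = table
    open1 = table["open1"]
    ext = table["extend"]
    n, m = len(a), len(b)
    INF = INT_INF
    # Plain integer arithmetic throughout: INF is a large sentinel, additions
    # on top of it stay >= INF and are filtered by the final threshold check.
    M = [[INF] * (m + 1) for _ in range(n + 1)]
    X = [[INF] * (m + 1) for _ in range(n + 1)]
    Y = [[INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = open1 + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = open1 + (j - 1) * ext
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[("sub", ai, b[j - 1])]
            Mi[j] = min(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = min(Mp[j] + open1, Xp[j] + ext, Yp[j] + open1)
            Yi[j] = min(Mi[j - 1] + open1, Xi[j - 1] + open1, Yi[j - 1] + ext)
    return M, X, Y, scale


def edit_distance(a: str, b: str, scheme: CostScheme) -> Cost:
    """Minimum edit cost between two gap-free sequences (no traceback)."""
    _check_input(a)
    _check_input(b)
    if not a and not b:
        return Fraction(0)
    M, X, Y, scale = _dp_tables(a, b, scheme)
    best = min(M[len(a)][len(b)], X[len(a)][len(b)], Y[len(a)][len(b)])
    if best >= INT_INF:
        return math.inf
    return Fraction(best, scale)


def align_pair(a: str, b: str, scheme: CostScheme) -> PairwiseAlignment:
    """Optimal pairwise alignment with deterministic traceback."""
    _check_input(a)
    _check_input(b)
    if not a and not b:
        return PairwiseAlignment("", "", Fraction(0))
    M, X, Y, scale = _dp_tables(a, b, scheme)
    n, m = len(a), len(b)
    finals = (M[n][m], X[n][m], Y[n][m])
    best = min(finals)
    if best >= INT_INF:
        raise ValueError("no finite-cost alignment under this scheme (gaps forbidden, lengths differ)")
    state = finals.index(best)  # priority M, X, Y at ties
    i, j = n, m
    cols_a: list[str] = []
    cols_b: list[str] = []
    table, _ = scheme.integerized()
    open1, ext = table["open1"], table["extend"]

    while i > 0 or j > 0:
        if state == _M:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            target = M[i][j] - table[("sub", a[i - 1], b[j - 1])]
            i, j = i - 1, j - 1
            cands = (M[i][j], X[i][j], Y[i][j])
            state = cands.index(target)
        elif state == _X:
            cols_a.append(a[i - 1])
            cols_b.append(GAP)
            val = X[i][j]
            i -= 1
            if M[i][j] + open1 == val:
                state = _M
            elif X[i][j] + ext == val:
                state = _X
            else:
                state = _Y
        else:  # _Y
            cols_a.append(GAP)
            cols_b.append(b[j - 1])
            val = Y[i][j]
            j -= 1
            if M[i][j] + open1 == val:
                state = _M
            elif X[i][j] + open1 == val:
                state = _X
            else:
                state = _Y
    row_a = "".join(reversed(cols_a))
    row_b = "".join(reversed(cols_b))
    return PairwiseAlignment(row_a, row_b, Fraction(best, scale))


def enumerate_alignments_cost(a: str, b: str, scheme: CostScheme, max_len: int = 8) -> Cost:
    """Brute-force minimum alignment cost by exhaustive enumeration.

    Test-support oracle: generates every monotone alignment of ``a`` and
    ``b`` (including ones with adjacent insert/delete columns, which can
    never beat the DP when costs are positive) and scores each from its
    columns.  Only usable for short sequences.
    """
    if len(a) > max_len or len(b) > max_len:
        raise ValueError(f"enumeration oracle limited to sequences of length <= {max_len}")
    _check_input(a)
    _check_input(b)

    best: Cost = math.inf

    def rec(i: int, j: int, ra: list[str], rb: list[str]) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            cost = score_alignment("".join(ra), "".join(rb), scheme)
            if cost < best:
                best = cost
            return
        if i < len(a) and j < len(b):
            ra.append(a[i]); rb.append(b[j])
            rec(i + 1, j + 1, ra, rb)
            ra.pop(); rb.pop()
        if i < len(a):
            ra.append(a[i]); rb.append(GAP)
            rec(i + 1, j, ra, rb)
            ra.pop(); rb.pop()
        if j < len(b):
            ra.append(GAP); rb.append(b[j])
            rec(i, j + 1, ra, rb)
            ra.pop(); rb.pop()

    rec(0, 0, [], [])
    if not a and not b:
        return Fraction(0)
    return best
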