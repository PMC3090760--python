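"""Brutally simple ground-truth implementations, for certification only.

Nothing here shares code with the DP engine: alignments are enumerated as
monotone edit paths over explicitly chosen substring pairs and scored with
:func:`rsalign.core.reference_score`.  Exponential in the input sizes, hence
the hard ``max_size`` bound.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterator, List, Optional, Tuple

from .core import (
    Alignment,
    RnaSequence,
    ScoringScheme,
    SecondaryStructure,
    reference_score,
)

MAX_ORACLE_SIZE = 8


@lru_cache(maxsize=256)
def _paths(a: int, b: int) -> Tuple[Tuple[str, ...], ...]:
    """All gapped column-type sequences aligning a query chars to b target chars.

    Column types: 'M' consumes one of each, 'S' consumes a query char against
    a space, 'T' consumes a target char against a space.  No space-vs-space
    columns exist by construction.
    """
    if a == 0 and b == 0:
        return ((),)
    out = []
    if a > 0 and b > 0:
        out.extend(path + ("M",) for path in _paths(a - 1, b - 1))
    if a > 0:
        out.extend(path + ("S",) for path in _paths(a - 1, b))
    if b > 0:
        out.extend(path + ("T",) for path in _paths(a, b - 1))
    return tuple(out)


def _alignments_between(
    qsub: str, tsub: str, x: int, x2: int
) -> Iterator[Tuple[str, str, Tuple[int, int], Tuple[int, int]]]:
    a, b = len(qsub), len(tsub)
    qr = (x, x + a - 1) if a else (1, 0)
    tr = (x2, x2 + b - 1) if b else (1, 0)
    for path in _paths(a, b):
        s_chars: List[str] = []
        t_chars: List[str] = []
        i = j = 0
        for col in path:
            if col == "M":
                s_chars.append(qsub[i])
                t_chars.append(tsub[j])
                i += 1
                j += 1
            elif col == "S":
                s_chars.append(qsub[i])
                t_chars.append("-")
                i += 1
            else:
                s_chars.append("-")
                t_chars.append(tsub[j])
                j += 1
        yield "".join(s_chars), "".join(t_chars), qr, tr


def _check_size(query: RnaSequence, target: RnaSequence, max_size: int) -> None:
    if max_size > MAX_ORACLE_SIZE:
        raise ValueError(f"max_size {max_size} exceeds hard bound {MAX_ORACLE_SIZE}")
    if len(query) > max_size or len(target) > max_size:
        raise ValueError(
            f"oracle inputs too large: m={len(query)}, n={len(target)}, bound={max_size}"
        )


def brute_force_local(
    query: RnaSequence,
    structure: SecondaryStructure,
    target: RnaSequence,
    scheme: ScoringScheme,
    max_size: int = 6,
) -> Tuple[float, Alignment]:
    """Exact local optimum by enumerating every substring pair and alignment."""
    _check_size(query, target, max_size)
    best = 0.0
    best_aln = Alignment.empty()
    m, n = len(query), len(target)
    for x in range(1, m + 2):
        for y in range(x - 1, m + 1):
            qsub = query.substring(x, y)
            for x2 in range(1, n + 2):
                for y2 in range(x2 - 1, n + 1):
                    tsub = target.substring(x2, y2)
                    for s_p, t_p, qr, tr in _alignments_between(qsub, tsub, x, x2):
                        aln = Alignment(s_p, t_p, qr, tr, 0.0)
                        sc = reference_score(aln, structure, scheme)
                        if sc > best:
                            best = sc
                            best_aln = Alignment(s_p, t_p, qr, tr, sc)
    return best, best_aln


def brute_force_global(
    query: RnaSequence,
    structure: SecondaryStructure,
    target: RnaSequence,
    scheme: ScoringScheme,
    max_size: int = 6,
) -> float:
    """Exact global optimum: whole query against whole target."""
    _check_size(query, target, max_size)
    best = None
    for s_p, t_p, qr, tr in _alignments_between(
        query.residues, target.residues, 1, 1
    ):
        aln = Alignment(s_p, t_p, qr, tr, 0.0)
        sc = reference_score(aln, structure, scheme)
        if best is None or sc > best:
            best = sc
    return best if best is not None else 0.0


def brute_force_semiglobal(
    query: RnaSequence,
    structure: SecondaryStructure,
    target: RnaSequence,
    scheme: ScoringScheme,
    max_size: int = 6,
) -> float:
    """Exact semi-global optimum: best query substring against ALL of target."""
    _check_size(query, target, max_size)
    best = None
    m = len(query)
    for x in range(1, m + 2):
        for y in range(x - 1, m + 1):
            qsub = query.substring(x, y)
            for s_p, t_p, qr, tr in _alignments_between(qsub, target.residues, x, 1):
                aln = Alignment(s_p, t_p, qr, tr, 0.0)
                sc = reference_score(aln, structure, scheme)
                if best is None or sc > best:
                    best = sc
    return best if best is not None else 0.0


def brute_force_local_iterative(
    query: RnaSequence,
    structure: SecondaryStructure,
    target: RnaSequence,
    scheme: ScoringScheme,
    max_size: int = 6,
) -> float:
    """Second, independent enumerator (explicit stack) for cross-checking."""
    _check_size(query, target, max_size)
    best = 0.0
    m, n = len(query), len(target)
    for x in range(1, m + 2):
        for y in range(x - 1, m + 1):
            qsub = query.substring(x, y)
            for x2 in range(1, n + 2):
                for y2 in range(x2 - 1, n + 1):
                    tsub = target.substring(x2, y2)
                    stack: List[Tuple[int, int, str, str]] = [(0, 0, "", "")]
                    while stack:
                        i, j, s_p, t_p = stack.pop()
                        if i == len(qsub) and j == len(tsub):
                            qr = (x, y) if x <= y else (1, 0)
                            tr = (x2, y2) if x2 <= y2 else (1, 0)
                            aln = Alignment(s_p, t_p, qr, tr, 0.0)
                            sc = reference_score(aln, structure, scheme)
                            if sc > best:
                                best = sc
                            continue
                        if i < len(qsub) and j < len(tsub):
                            stack.append((i + 1, j + 1, s_p + qsub[i], t_p + tsub[j]))
                        if i < len(qsub):
                            stack.append((i + 1, j, s_p + qsub[i], t_p + "-"))
                        if j < len(tsub):
                            stack.append((i, j + 1, s_p + "-", t_p + tsub[j]))
                    del stack
    return best


def gotoh_local(query_seq: str, target_seq: str, scheme: ScoringScheme) -> float:
    """Textbook three-matrix Smith-Waterman with affine gaps (h + s*L).

    Structure-free: used for the M = empty-set reduction of the engine.
    """
    m, n = len(query_seq), len(target_seq)
    NEG = float("-inf")
    h, s = scheme.h, scheme.s
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target string (query char vs -)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query string (- vs target char)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - (h + s), E[i - 1][j] - s)
            F[i][j] = max(H[i][j - 1] - (h + s), F[i][j - 1] - s)
            diag = H[i - 1][j - 1] + scheme.gamma_of(query_seq[i - 1], target_seq[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def gotoh_global(query_seq: str, target_seq: str, scheme: ScoringScheme) -> float:
    """Textbook global (Needleman-Wunsch/Gotoh) affine-gap score."""
    m, n = len(query_seq), len(target_seq)
    NEG = float("-inf")
    h, s = scheme.h, scheme.s
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    for i in range(1, m + 1):
        E[i][0] = -(h + s * i)
        H[i][0] = E[i][0]
    for j in range(1, n + 1):
        F[0][j] = -(h + s * j)
        H[0][j] = F[0][j]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - (h + s), E[i - 1][j] - s)
            F[i][j] = max(H[i][j - 1] - (h + s), F[i][j - 1] - s)
            diag = H[i - 1][j - 1] + scheme.gamma_of(query_seq[i - 1], target_seq[j - 1])
            H[i][j] = max(diag, E[i][j], F[i][j])
    return H[m][n]
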