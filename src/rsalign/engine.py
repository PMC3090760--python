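"""The DP engine: table filling, traceback and the public alignment API.

Scores live in the tables filled by :mod:`rsalign._dp`; this module builds
the node metadata, owns the workspace, and reconstructs explicit alignments
by re-deriving the argmax at every cell (no backpointers are stored).  All
comparisons during traceback are exact float equalities, which is sound
because every score is a sum of dyadic-grid scheme values (see
:mod:`rsalign.core`).

Tie-breaking is deterministic and documented: table preference A1 > A2 > A3
> A4; within A1 the lower of the nine case indices; within a SPLIT join the
smaller target split point k; within a cell, an aligned column is preferred
over a query-char-vs-space column, which is preferred over a
target-char-vs-space column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _dp
from ._dp import AL, EE, KIND_EMPTY, KIND_PAIRED, KIND_SPLIT, KIND_UNPAIRED, SG, TG
from .core import Alignment, RnaSequence, ScoringScheme, SecondaryStructure
from .decompose import IntervalNode, decompose

Column = Tuple[Optional[int], Optional[int]]

#: The nine A1 boundary cases in their canonical order (case 1..9).
A1_CASES: Tuple[Tuple[int, int], ...] = tuple((l, r) for l in (AL, SG, TG) for r in (AL, SG, TG))


class TracebackError(RuntimeError):
    """Internal consistency failure: no candidate reproduces a cell's score."""


@dataclass(frozen=True)
class Cell:
    """Address of one DP entry, for use with :func:`traceback`.

    ``table`` is one of ``"A", "A1", "A2", "A3", "A4"``; ``case`` is a
    ``(left, right)`` pair or 1-based case index for A1, a boundary case for
    A2/A3, and ignored for A/A4.
    """

    table: str
    p: int
    q: int
    e: int
    f: int
    case: Optional[Union[int, Tuple[int, int]]] = None


class DPWorkspace:
    """Filled score tables for one (query, structure, target, scheme) run."""

    def __init__(self, query, structure, target, scheme, nodes, arrays):
        self.query: RnaSequence = query
        self.structure: SecondaryStructure = structure
        self.target: RnaSequence = target
        self.scheme: ScoringScheme = scheme
        self.nodes: List[IntervalNode] = nodes
        self.A1, self.P, self.Q, self.A4t, self.At = arrays
        self._by_interval = {(nd.p, nd.q): nd for nd in nodes}
        self.m = len(query)
        self.n = len(target)
        self.root = nodes[-1]

    # -- table accessors (1-based coordinates; e == f + 1 is the empty slice)

    def node(self, p: int, q: int) -> IntervalNode:
        key = (1, 0) if p > q else (p, q)
        nd = self._by_interval.get(key)
        if nd is None:
            raise KeyError(f"interval ({p}, {q}) is not part of the decomposition")
        return nd

    def _closed(self, e: int, f: int) -> float:
        return _closed_py(e, f, self.scheme.h, self.scheme.s)

    def a(self, p: int, q: int, e: int, f: int) -> float:
        """Semi-global: best substring of S[p..q] vs all of T[e..f]."""
        return float(self.At[self.node(p, q).index, e, f])

    def a1(self, p: int, q: int, e: int, f: int, case=None) -> float:
        """Global score of S[p..q] vs T[e..f]; ``case`` picks a boundary pair."""
        i = self.node(p, q).index
        if case is None:
            sub = self.A1[i, :, :, e, f]
            return float(sub.max())
        if isinstance(case, int):
            case = A1_CASES[case - 1]
        return float(self.A1[i, case[0], case[1], e, f])

    def a2(self, p: int, q: int, e: int, f: int, case: Optional[int] = None) -> float:
        """Prefix-global on S[p..q-1] (includes the empty-prefix closed form)."""
        i = self.node(p, q).index
        if case is not None:
            return float(self.P[i, case, e, f])
        return float(max(self.P[i, 0, e, f], self.P[i, 1, e, f], self.P[i, 2, e, f], self._closed(e, f)))

    def a3(self, p: int, q: int, e: int, f: int, case: Optional[int] = None) -> float:
        """Suffix-global on S[p+1..q] (includes the empty-suffix closed form)."""
        i = self.node(p, q).index
        if case is not None:
            return float(self.Q[i, case, e, f])
        return float(max(self.Q[i, 0, e, f], self.Q[i, 1, e, f], self.Q[i, 2, e, f], self._closed(e, f)))

    def a4(self, p: int, q: int, e: int, f: int) -> float:
        """Semi-global on S[p+1..q-1]."""
        return float(self.A4t[self.node(p, q).index, e, f])

    def best_local(self) -> Tuple[float, int, int]:
        """Best ``(score, e, f)`` over all target slices of the root interval.

        Ties prefer the empty slice, then smaller e, then smaller f.
        """
        sub = self.At[self.root.index]
        flat = int(np.argmax(sub))  # first occurrence: smallest e, then f
        v = float(sub.flat[flat])
        if v <= 0.0:
            return 0.0, 1, 0
        e, f = divmod(flat, sub.shape[1])
        return v, e, f


def _closed_py(e: int, f: int, h: float, s: float) -> float:
    if f < e:
        return 0.0
    return -(h + s * (f - e + 1))


class StructuralAligner:
    """Reusable aligner for one (query, structure, scheme) triple.

    Table buffers are reused across targets of equal length, which matters
    when scanning a genome window by window.  A returned workspace aliases
    those buffers and is invalidated by the next :meth:`fill` call.
    """

    def __init__(self, query: RnaSequence, structure: SecondaryStructure, scheme: ScoringScheme):
        if structure.seq_length != len(query):
            raise ValueError(
                f"structure length {structure.seq_length} != query length {len(query)}"
            )
        self.query = query
        self.structure = structure
        self.scheme = scheme
        self.nodes = decompose(structure, len(query))
        nn = len(self.nodes)
        self._kind = np.empty(nn, dtype=np.int64)
        self._c1 = np.zeros(nn, dtype=np.int64)
        self._c2 = np.zeros(nn, dtype=np.int64)
        self._pbeg = np.empty(nn, dtype=np.int64)
        self._qend = np.empty(nn, dtype=np.int64)
        for nd in self.nodes:
            i = nd.index
            self._kind[i] = nd.case_tag
            self._pbeg[i] = nd.p
            self._qend[i] = nd.q
            if nd.children:
                self._c1[i] = nd.children[0].index
                if len(nd.children) > 1:
                    self._c2[i] = nd.children[1].index
        self._sq = self.query.codes
        self._buf_n: Optional[int] = None
        self._bufs = None

    def _buffers(self, n: int):
        if self._buf_n != n:
            nn = len(self.nodes)
            self._bufs = (
                np.empty((nn, 4, 4, n + 2, n + 1), dtype=np.float64),
                np.empty((nn, 3, n + 2, n + 1), dtype=np.float64),
                np.empty((nn, 3, n + 2, n + 1), dtype=np.float64),
                np.empty((nn, n + 2, n + 1), dtype=np.float64),
                np.empty((nn, n + 2, n + 1), dtype=np.float64),
            )
            self._buf_n = n
        for arr in self._bufs:
            arr.fill(-np.inf)
        return self._bufs

    def fill(self, target: RnaSequence) -> DPWorkspace:
        """Fill every table for ``target`` and return the workspace."""
        n = len(target)
        arrays = self._buffers(n)
        _dp.fill_tables(
            self._kind,
            self._c1,
            self._c2,
            self._pbeg,
            self._qend,
            self._sq,
            target.codes,
            self.scheme.gamma,
            self.scheme.delta,
            self.scheme.h,
            self.scheme.s,
            *arrays,
        )
        return DPWorkspace(
            self.query, self.structure, target, self.scheme, self.nodes, arrays
        )

    def local_score(self, target: RnaSequence) -> float:
        return self.fill(target).best_local()[0]


# ---------------------------------------------------------------------------
# Traceback: re-derive the argmax at each cell using exact score equalities
# ---------------------------------------------------------------------------


class _Tracer:
    def __init__(self, ws: DPWorkspace):
        self.ws = ws
        self.A1 = ws.A1
        self.P = ws.P
        self.Q = ws.Q
        self.A4t = ws.A4t
        self.At = ws.At
        self.nodes = ws.nodes
        self.h = ws.scheme.h
        self.s = ws.scheme.s
        self.gamma = ws.scheme.gamma
        self.delta = ws.scheme.delta
        self.sq = ws.query.codes
        self.tg = ws.target.codes

    def closed(self, e: int, f: int) -> float:
        return _closed_py(e, f, self.h, self.s)

    @staticmethod
    def gap_t(e: int, f: int) -> List[Column]:
        return [(None, t) for t in range(e, f + 1)]

    @staticmethod
    def gap_q(p: int, q: int) -> List[Column]:
        return [(x, None) for x in range(p, q + 1)]

    def fail(self, what: str) -> None:
        raise TracebackError(f"no candidate reproduces {what}")

    # -- A1 -----------------------------------------------------------------

    def a1(self, i: int, l: int, r: int, e: int, f: int) -> List[Column]:
        nd = self.nodes[i]
        p, q = nd.p, nd.q
        if nd.case_tag == KIND_EMPTY:
            if l == EE:
                return []
            return self.gap_t(e, f)
        if f < e:
            return self.gap_q(p, q)
        target = self.A1[i, l, r, e, f]
        h, s = self.h, self.s
        if nd.case_tag == KIND_UNPAIRED:
            c = nd.children[0].index
            if l == AL:
                rest = target - self.gamma[self.sq[p - 1], self.tg[e - 1]]
                for l2 in (AL, SG, TG):
                    if self.A1[c, l2, r, e + 1, f] == rest:
                        return [(p, e)] + self.a1(c, l2, r, e + 1, f)
                if r == AL and self.A1[c, EE, EE, e + 1, f] == rest:
                    return [(p, e)]
            elif l == SG:
                rest = target + s
                if self.A1[c, SG, r, e, f] == rest:
                    return [(p, None)] + self.a1(c, SG, r, e, f)
                for l2 in (AL, TG):
                    if self.A1[c, l2, r, e, f] == rest + h:
                        return [(p, None)] + self.a1(c, l2, r, e, f)
            else:  # l == TG
                rest = target + s
                if self.A1[i, TG, r, e + 1, f] == rest:
                    return [(None, e)] + self.a1(i, TG, r, e + 1, f)
                for l2 in (AL, SG):
                    if self.A1[i, l2, r, e + 1, f] == rest + h:
                        return [(None, e)] + self.a1(i, l2, r, e + 1, f)
        elif nd.case_tag == KIND_PAIRED:
            c = nd.children[0].index
            u1, u2 = self.sq[p - 1], self.sq[q - 1]
            if l == AL and r == AL:
                rest = target - self.delta[u1, u2, self.tg[e - 1], self.tg[f - 1]]
                for l2 in (AL, SG, TG, EE):
                    for r2 in (AL, SG, TG, EE):
                        if self.A1[c, l2, r2, e + 1, f - 1] == rest:
                            return [(p, e)] + self.a1(c, l2, r2, e + 1, f - 1) + [(q, f)]
            elif l == AL and r == SG:
                rest = target - self.gamma[u1, self.tg[e - 1]] + s
                for l2 in (AL, SG, TG):
                    if self.A1[c, l2, SG, e + 1, f] == rest:
                        return [(p, e)] + self.a1(c, l2, SG, e + 1, f) + [(q, None)]
                for l2 in (AL, SG, TG):
                    for r2 in (AL, TG):
                        if self.A1[c, l2, r2, e + 1, f] == rest + h:
                            return [(p, e)] + self.a1(c, l2, r2, e + 1, f) + [(q, None)]
                if self.A1[c, EE, EE, e + 1, f] == rest + h:
                    return [(p, e), (q, None)]
            elif l == SG and r == AL:
                rest = target - self.gamma[u2, self.tg[f - 1]] + s
                for r2 in (AL, SG, TG):
                    if self.A1[c, SG, r2, e, f - 1] == rest:
                        return [(p, None)] + self.a1(c, SG, r2, e, f - 1) + [(q, f)]
                for l2 in (AL, TG):
                    for r2 in (AL, SG, TG):
                        if self.A1[c, l2, r2, e, f - 1] == rest + h:
                            return [(p, None)] + self.a1(c, l2, r2, e, f - 1) + [(q, f)]
                if self.A1[c, EE, EE, e, f - 1] == rest + h:
                    return [(p, None), (q, f)]
            elif l == SG and r == SG:
                rest = target + s + s
                for l2 in (AL, SG, TG):
                    for r2 in (AL, SG, TG):
                        adj = (0.0 if l2 == SG else h) + (0.0 if r2 == SG else h)
                        if self.A1[c, l2, r2, e, f] == rest + adj:
                            return [(p, None)] + self.a1(c, l2, r2, e, f) + [(q, None)]
            elif r == TG:  # l in (AL, SG): trailing target gap
                rest = target + s
                if self.A1[i, l, TG, e, f - 1] == rest:
                    return self.a1(i, l, TG, e, f - 1) + [(None, f)]
                for r2 in (AL, SG):
                    if self.A1[i, l, r2, e, f - 1] == rest + h:
                        return self.a1(i, l, r2, e, f - 1) + [(None, f)]
            else:  # l == TG: leading target gap
                rest = target + s
                if self.A1[i, TG, r, e + 1, f] == rest:
                    return [(None, e)] + self.a1(i, TG, r, e + 1, f)
                for l2 in (AL, SG):
                    if self.A1[i, l2, r, e + 1, f] == rest + h:
                        return [(None, e)] + self.a1(i, l2, r, e + 1, f)
        else:  # KIND_SPLIT
            cl = nd.children[0].index
            cr = nd.children[1].index
            for k in range(e - 1, f + 1):
                for rm in (AL, SG, TG):
                    for lm in (AL, SG, TG):
                        bonus = self.h if (rm == lm and rm != AL) else 0.0
                        if self.A1[cl, l, rm, e, k] + self.A1[cr, lm, r, k + 1, f] + bonus == target:
                            return self.a1(cl, l, rm, e, k) + self.a1(cr, lm, r, k + 1, f)
        self.fail(f"A1[{p},{q}][{l},{r}]({e},{f})")

    # -- P (prefix-global) --------------------------------------------------

    def p_(self, i: int, l: int, e: int, f: int) -> List[Column]:
        nd = self.nodes[i]
        p, q = nd.p, nd.q
        if f < e:
            return [(p, None)]
        target = self.P[i, l, e, f]
        h, s = self.h, self.s
        if l == TG:
            rest = target + s
            if self.P[i, TG, e + 1, f] == rest:
                return [(None, e)] + self.p_(i, TG, e + 1, f)
            for l2 in (AL, SG):
                if self.P[i, l2, e + 1, f] == rest + h:
                    return [(None, e)] + self.p_(i, l2, e + 1, f)
            self.fail(f"P[{p},{q}][TG]({e},{f})")
        if nd.case_tag == KIND_UNPAIRED:
            c = nd.children[0].index
            if l == AL:
                rest = target - self.gamma[self.sq[p - 1], self.tg[e - 1]]
                for l2 in (AL, SG, TG):
                    if self.P[c, l2, e + 1, f] == rest:
                        return [(p, e)] + self.p_(c, l2, e + 1, f)
                if self.closed(e + 1, f) == rest:
                    return [(p, e)] + self.gap_t(e + 1, f)
            else:  # l == SG
                rest = target + s
                if self.P[c, SG, e, f] == rest:
                    return [(p, None)] + self.p_(c, SG, e, f)
                for l2 in (AL, TG):
                    if self.P[c, l2, e, f] == rest + h:
                        return [(p, None)] + self.p_(c, l2, e, f)
                if self.closed(e, f) == rest + h:
                    return [(p, None)] + self.gap_t(e, f)
        elif nd.case_tag == KIND_PAIRED:
            c = nd.children[0].index
            if l == AL:
                rest = target - self.gamma[self.sq[p - 1], self.tg[e - 1]]
                for l2 in (AL, SG, TG, EE):
                    for r2 in (AL, SG, TG, EE):
                        if self.A1[c, l2, r2, e + 1, f] == rest:
                            return [(p, e)] + self.a1(c, l2, r2, e + 1, f)
                for l2 in (AL, SG, TG):
                    if self.P[c, l2, e + 1, f] == rest:
                        return [(p, e)] + self.p_(c, l2, e + 1, f)
                if self.closed(e + 1, f) == rest:
                    return [(p, e)] + self.gap_t(e + 1, f)
            else:  # l == SG
                rest = target + s
                for r2 in (AL, SG, TG):
                    if self.A1[c, SG, r2, e, f] == rest:
                        return [(p, None)] + self.a1(c, SG, r2, e, f)
                for l2 in (AL, TG):
                    for r2 in (AL, SG, TG):
                        if self.A1[c, l2, r2, e, f] == rest + h:
                            return [(p, None)] + self.a1(c, l2, r2, e, f)
                if self.P[c, SG, e, f] == rest:
                    return [(p, None)] + self.p_(c, SG, e, f)
                for l2 in (AL, TG):
                    if self.P[c, l2, e, f] == rest + h:
                        return [(p, None)] + self.p_(c, l2, e, f)
                if self.closed(e, f) == rest + h:
                    return [(p, None)] + self.gap_t(e, f)
        else:  # KIND_SPLIT
            cl = nd.children[0].index
            cr = nd.children[1].index
            if self.P[cl, l, e, f] == target:
                return self.p_(cl, l, e, f)
            for rm in (AL, SG, TG):
                if self.A1[cl, l, rm, e, f] == target:
                    return self.a1(cl, l, rm, e, f)
            for k in range(e - 1, f + 1):
                for rm in (AL, SG, TG):
                    for lm in (AL, SG, TG):
                        bonus = h if (rm == lm and rm != AL) else 0.0
                        if self.A1[cl, l, rm, e, k] + self.P[cr, lm, k + 1, f] + bonus == target:
                            return self.a1(cl, l, rm, e, k) + self.p_(cr, lm, k + 1, f)
        self.fail(f"P[{p},{q}][{l}]({e},{f})")

    # -- Q (suffix-global) --------------------------------------------------

    def q_(self, i: int, r: int, e: int, f: int) -> List[Column]:
        nd = self.nodes[i]
        p, q = nd.p, nd.q
        if f < e:
            return [(q, None)]
        target = self.Q[i, r, e, f]
        h, s = self.h, self.s
        if nd.case_tag == KIND_UNPAIRED:
            c = nd.children[0].index
            for l2 in (AL, SG, TG):
                if self.A1[c, l2, r, e, f] == target:
                    return self.a1(c, l2, r, e, f)
            if self.Q[c, r, e, f] == target:
                return self.q_(c, r, e, f)
        elif nd.case_tag == KIND_PAIRED:
            c = nd.children[0].index
            u2 = self.sq[q - 1]
            if r == AL:
                rest = target - self.gamma[u2, self.tg[f - 1]]
                for l2 in (AL, SG, TG, EE):
                    for r2 in (AL, SG, TG, EE):
                        if self.A1[c, l2, r2, e, f - 1] == rest:
                            return self.a1(c, l2, r2, e, f - 1) + [(q, f)]
                for r2 in (AL, SG, TG):
                    if self.Q[c, r2, e, f - 1] == rest:
                        return self.q_(c, r2, e, f - 1) + [(q, f)]
                if self.closed(e, f - 1) == rest:
                    return self.gap_t(e, f - 1) + [(q, f)]
            elif r == SG:
                rest = target + s
                for l2 in (AL, SG, TG):
                    if self.A1[c, l2, SG, e, f] == rest:
                        return self.a1(c, l2, SG, e, f) + [(q, None)]
                for l2 in (AL, SG, TG):
                    for r2 in (AL, TG):
                        if self.A1[c, l2, r2, e, f] == rest + h:
                            return self.a1(c, l2, r2, e, f) + [(q, None)]
                if self.Q[c, SG, e, f] == rest:
                    return self.q_(c, SG, e, f) + [(q, None)]
                for r2 in (AL, TG):
                    if self.Q[c, r2, e, f] == rest + h:
                        return self.q_(c, r2, e, f) + [(q, None)]
                if self.closed(e, f) == rest + h:
                    return self.gap_t(e, f) + [(q, None)]
            else:  # r == TG
                rest = target + s
                if self.Q[i, TG, e, f - 1] == rest:
                    return self.q_(i, TG, e, f - 1) + [(None, f)]
                for r2 in (AL, SG):
                    if self.Q[i, r2, e, f - 1] == rest + h:
                        return self.q_(i, r2, e, f - 1) + [(None, f)]
        else:  # KIND_SPLIT
            cl = nd.children[0].index
            cr = nd.children[1].index
            if self.Q[cr, r, e, f] == target:
                return self.q_(cr, r, e, f)
            for lm in (AL, SG, TG):
                if self.A1[cr, lm, r, e, f] == target:
                    return self.a1(cr, lm, r, e, f)
            for k in range(e - 1, f + 1):
                for rm in (AL, SG, TG):
                    for lm in (AL, SG, TG):
                        bonus = h if (rm == lm and rm != AL) else 0.0
                        if self.Q[cl, rm, e, k] + self.A1[cr, lm, r, k + 1, f] + bonus == target:
                            return self.q_(cl, rm, e, k) + self.a1(cr, lm, r, k + 1, f)
        self.fail(f"Q[{p},{q}][{r}]({e},{f})")

    # -- A4 and A -----------------------------------------------------------

    def a4(self, i: int, e: int, f: int) -> List[Column]:
        nd = self.nodes[i]
        if f < e:
            return []
        target = self.A4t[i, e, f]
        if nd.case_tag == KIND_EMPTY:
            return self.gap_t(e, f)
        if nd.case_tag == KIND_UNPAIRED:
            c = nd.children[0].index
            for l2 in (AL, SG, TG):
                if self.P[c, l2, e, f] == target:
                    return self.p_(c, l2, e, f)
            if self.closed(e, f) == target:
                return self.gap_t(e, f)
            if self.A4t[c, e, f] == target:
                return self.a4(c, e, f)
        elif nd.case_tag == KIND_PAIRED:
            return self.a(nd.children[0].index, e, f)
        else:  # KIND_SPLIT
            cl = nd.children[0].index
            cr = nd.children[1].index
            if self.A4t[cl, e, f] == target:
                return self.a4(cl, e, f)
            for r2 in (AL, SG, TG):
                if self.Q[cl, r2, e, f] == target:
                    return self.q_(cl, r2, e, f)
            for l2 in (AL, SG, TG):
                if self.P[cr, l2, e, f] == target:
                    return self.p_(cr, l2, e, f)
            if self.closed(e, f) == target:
                return self.gap_t(e, f)
            if self.A4t[cr, e, f] == target:
                return self.a4(cr, e, f)
            for k in range(e - 1, f + 1):
                for rm in (AL, SG, TG):
                    for lm in (AL, SG, TG):
                        bonus = self.h if (rm == lm and rm != AL) else 0.0
                        if self.Q[cl, rm, e, k] + self.P[cr, lm, k + 1, f] + bonus == target:
                            return self.q_(cl, rm, e, k) + self.p_(cr, lm, k + 1, f)
        self.fail(f"A4[{nd.p},{nd.q}]({e},{f})")

    def a(self, i: int, e: int, f: int) -> List[Column]:
        if f < e:
            return []
        target = self.At[i, e, f]
        for l in (AL, SG, TG):
            for r in (AL, SG, TG):
                if self.A1[i, l, r, e, f] == target:
                    return self.a1(i, l, r, e, f)
        for l in (AL, SG, TG):
            if self.P[i, l, e, f] == target:
                return self.p_(i, l, e, f)
        if self.closed(e, f) == target:
            return self.gap_t(e, f)
        for r in (AL, SG, TG):
            if self.Q[i, r, e, f] == target:
                return self.q_(i, r, e, f)
        if self.A4t[i, e, f] == target:
            return self.a4(i, e, f)
        nd = self.nodes[i]
        self.fail(f"A[{nd.p},{nd.q}]({e},{f})")


def _columns_to_alignment(
    cols: Sequence[Column], query: RnaSequence, target: RnaSequence, score: float
) -> Alignment:
    s_chars = []
    t_chars = []
    qpos = []
    tpos = []
    for qp, tp in cols:
        s_chars.append(query.base(qp) if qp is not None else "-")
        t_chars.append(target.base(tp) if tp is not None else "-")
        if qp is not None:
            qpos.append(qp)
        if tp is not None:
            tpos.append(tp)
    qr = (min(qpos), max(qpos)) if qpos else (1, 0)
    tr = (min(tpos), max(tpos)) if tpos else (1, 0)
    return Alignment(
        s_prime="".join(s_chars),
        t_prime="".join(t_chars),
        query_range=qr,
        target_range=tr,
        score=float(score),
    )


def traceback(workspace: DPWorkspace, cell: Cell) -> Alignment:
    """Reconstruct the alignment realizing ``cell``'s score exactly."""
    tr = _Tracer(workspace)
    i = workspace.node(cell.p, cell.q).index
    table = cell.table.upper()
    if table == "A":
        score = workspace.At[i, cell.e, cell.f]
        cols = tr.a(i, cell.e, cell.f)
    elif table == "A1":
        case = cell.case
        if case is None:
            sub = workspace.A1[i, :, :, cell.e, cell.f]
            best = None
            for l, r in A1_CASES:
                if best is None or sub[l, r] > sub[best]:
                    best = (l, r)
            if sub[EE, EE] > sub[best]:
                best = (EE, EE)
            case = best
        elif isinstance(case, int):
            case = A1_CASES[case - 1]
        score = workspace.A1[i, case[0], case[1], cell.e, cell.f]
        cols = tr.a1(i, case[0], case[1], cell.e, cell.f)
    elif table == "A2":
        if cell.case is None:
            score = workspace.a2(cell.p, cell.q, cell.e, cell.f)
            cols = None
            for l in (AL, SG, TG):
                if workspace.P[i, l, cell.e, cell.f] == score:
                    cols = tr.p_(i, l, cell.e, cell.f)
                    break
            if cols is None:
                cols = tr.gap_t(cell.e, cell.f)
        else:
            score = workspace.P[i, cell.case, cell.e, cell.f]
            cols = tr.p_(i, cell.case, cell.e, cell.f)
    elif table == "A3":
        if cell.case is None:
            score = workspace.a3(cell.p, cell.q, cell.e, cell.f)
            cols = None
            for r in (AL, SG, TG):
                if workspace.Q[i, r, cell.e, cell.f] == score:
                    cols = tr.q_(i, r, cell.e, cell.f)
                    break
            if cols is None:
                cols = tr.gap_t(cell.e, cell.f)
        else:
            score = workspace.Q[i, cell.case, cell.e, cell.f]
            cols = tr.q_(i, cell.case, cell.e, cell.f)
    elif table == "A4":
        score = workspace.A4t[i, cell.e, cell.f]
        cols = tr.a4(i, cell.e, cell.f)
    else:
        raise ValueError(f"unknown table {cell.table!r}")
    if not np.isfinite(score):
        raise ValueError(f"cell {cell} holds no finite score")
    return _columns_to_alignment(cols, workspace.query, workspace.target, score)


# ---------------------------------------------------------------------------
# Public alignment operations
# ---------------------------------------------------------------------------


def align_semiglobal_tables(
    query: RnaSequence,
    structure: SecondaryStructure,
    target: RnaSequence,
    scheme: ScoringScheme,
) -> DPWorkspace:
    """Fill all DP tables for the given instance and return the workspace."""
    return StructuralAligner(query, structure, scheme).fill(target)


def align_local(
    query: RnaSequence,
    structure: SecondaryStructure,
    target: RnaSequence,
    scheme: ScoringScheme,
    workspace: Optional[DPWorkspace] = None,
) -> Alignment:
    """Optimal local structural alignment; score is never below zero.

    The zero floor is realized by the empty-vs-empty alignment.
    """
    ws = workspace or align_semiglobal_tables(query, structure, target, scheme)
    score, e, f = ws.best_local()
    if score <= 0.0 and f < e:
        return Alignment.empty()
    cols = _Tracer(ws).a(ws.root.index, e, f)
    return _columns_to_alignment(cols, ws.query, ws.target, score)


def align_global(
    query: RnaSequence,
    structure: SecondaryStructure,
    target: RnaSequence,
    scheme: ScoringScheme,
    workspace: Optional[DPWorkspace] = None,
) -> Alignment:
    """Optimal global structural alignment: whole S against whole T."""
    ws = workspace or align_semiglobal_tables(query, structure, target, scheme)
    i = ws.root.index
    e, f = 1, ws.n
    sub = ws.A1[i, :, :, e, f]
    best = None
    for l, r in A1_CASES:
        if best is None or sub[l, r] > sub[best]:
            best = (l, r)
    if sub[EE, EE] > sub[best]:
        best = (EE, EE)
    score = sub[best]
    cols = _Tracer(ws).a1(i, best[0], best[1], e, f)
    return _columns_to_alignment(cols, ws.query, ws.target, score)


def align_semiglobal(
    query: RnaSequence,
    structure: SecondaryStructure,
    target: RnaSequence,
    scheme: ScoringScheme,
    workspace: Optional[DPWorkspace] = None,
) -> Alignment:
    """Best substring of S against ALL of T."""
    ws = workspace or align_semiglobal_tables(query, structure, target, scheme)
    i = ws.root.index
    score = ws.At[i, 1, ws.n]
    cols = _Tracer(ws).a(i, 1, ws.n)
    return _columns_to_alignment(cols, ws.query, ws.target, score)


def global_score(workspace: DPWorkspace) -> float:
    """Global alignment score straight from a filled workspace."""
    i = workspace.root.index
    sub = workspace.A1[i, :, :, 1, workspace.n]
    v = sub[:3, :3].max()
    if sub[EE, EE] > v:
        v = sub[EE, EE]
    return float(v)


def audit_lemma1(workspace: DPWorkspace) -> float:
    """Max absolute residual of A - max(A1, A2, A3, A4) over all cells."""
    worst = 0.0
    ws = workspace
    for nd in ws.nodes:
        i = nd.index
        for e in range(1, ws.n + 2):
            for f in range(e - 1, ws.n + 1):
                parts = [
                    ws.a1(nd.p, nd.q, e, f) if nd.case_tag != KIND_EMPTY else ws.A1[i, :, :, e, f].max(),
                    ws.a2(nd.p, nd.q, e, f),
                    ws.a3(nd.p, nd.q, e, f),
                    ws.a4(nd.p, nd.q, e, f),
                ]
                expect = max(parts)
                worst = max(worst, abs(float(ws.At[i, e, f]) - float(expect)))
    return worst
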