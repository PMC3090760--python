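"""Table-filling kernel for the structural alignment DP.

Compiled with numba when available (set ``RSALIGN_DISABLE_JIT=1`` to force the
pure-Python path).  All recurrences work on dense float64 tables indexed by
``[node, case(s), e, f]`` with ``e in 1..n+1`` and ``f in 0..n``; the column
``f = e - 1`` holds the empty target slice.

Boundary-case encoding for a (sub)alignment of S[p..q] vs T[e..f]:

* ``AL = 0`` - endpoint query char aligned to the endpoint target char
* ``SG = 1`` - endpoint query char aligned to a space (gap in T')
* ``TG = 2`` - endpoint target char aligned to a space (gap in S')
* ``EE = 3`` - the empty alignment (no columns); only the [EE, EE] cell of an
  empty query interval against an empty target slice is ever finite.

Tables per node:

* ``A1[node, l, r, e, f]`` - optimal *global* alignment of S[p..q] vs T[e..f]
  with left/right boundary cases ``l``/``r`` (nine finite combinations).
* ``P[node, l, e, f]``  - optimal *prefix-global*: a nonempty prefix of
  S[p..q-1] vs all of T[e..f], split by left boundary case.  The empty-prefix
  closed form ``-h - s*(f-e+1)`` is added at aggregation time.
* ``Q[node, r, e, f]``  - mirror *suffix-global* on S[p+1..q].
* ``A4[node, e, f]``    - semi-global on S[p+1..q-1] (best substring vs all
  of the target slice).
* ``A[node, e, f]``     - semi-global on S[p..q]; equals the four-way maximum
  of A1/A2/A3/A4 aggregates at every cell.

A gap of length L costs ``h + s*L``.  Appending a gap column to an alignment
charges ``s`` when it extends a same-string gap run (the adjacent boundary
case matches) and ``h + s`` when it opens a new run.  Concatenations at SPLIT
nodes charge ``h`` back when the two pieces' facing boundary cases are the
same gap type (the two runs merge into one).
"""

from __future__ import annotations

import os

import numpy as np

AL = 0
SG = 1
TG = 2
EE = 3

KIND_EMPTY = 0
KIND_UNPAIRED = 1
KIND_PAIRED = 2
KIND_SPLIT = 3

NEG = -np.inf


if os.environ.get("RSALIGN_DISABLE_JIT"):  # pragma: no cover - env-dependent
    njit = None
else:
    try:
        from numba import njit  # type: ignore
    except ImportError:  # pragma: no cover - numba is an optional extra
        njit = None

JIT_ENABLED = njit is not None


def _closed(e, f, h, s):
    """Score of aligning T[e..f] entirely to spaces (0 for the empty slice)."""
    if f < e:
        return 0.0
    return -(h + s * (f - e + 1))


def fill_tables(kind, c1, c2, pbeg, qend, sq, tg, gamma, delta, h, s, A1, P, Q, A4, A):
    n = tg.shape[0]
    nnodes = kind.shape[0]

    for i in range(nnodes):
        kd = kind[i]
        p = pbeg[i]
        q = qend[i]

        if kd == KIND_EMPTY:
            for e in range(1, n + 2):
                A1[i, EE, EE, e, e - 1] = 0.0
                A4[i, e, e - 1] = 0.0
                A[i, e, e - 1] = 0.0
            for ln in range(1, n + 1):
                for e in range(1, n - ln + 2):
                    f = e + ln - 1
                    v = A1[i, TG, TG, e + 1, f]
                    alt = A1[i, EE, EE, e + 1, f] - h
                    if alt > v:
                        v = alt
                    A1[i, TG, TG, e, f] = v - s
                    cl = -(h + s * ln)
                    A4[i, e, f] = cl
                    A[i, e, f] = cl
            continue

        qlen = q - p + 1
        has_pq = q > p  # prefix/suffix domains are nonempty

        # empty target slices: the only global alignment is all-query-gap
        for e in range(1, n + 2):
            A1[i, SG, SG, e, e - 1] = -(h + s * qlen)
            if has_pq:
                P[i, SG, e, e - 1] = -(h + s)
                Q[i, SG, e, e - 1] = -(h + s)
            A4[i, e, e - 1] = 0.0
            A[i, e, e - 1] = 0.0

        c = c1[i]
        cc = c2[i]
        u1 = sq[p - 1]
        u2 = sq[q - 1]

        for ln in range(1, n + 1):
            for e in range(1, n - ln + 2):
                f = e + ln - 1
                te = tg[e - 1]
                tf = tg[f - 1]

                # ---------------- A1 ----------------
                if kd == KIND_UNPAIRED:
                    ga = gamma[u1, te]
                    for r in range(3):
                        v = A1[c, AL, r, e + 1, f]
                        if A1[c, SG, r, e + 1, f] > v:
                            v = A1[c, SG, r, e + 1, f]
                        if A1[c, TG, r, e + 1, f] > v:
                            v = A1[c, TG, r, e + 1, f]
                        if r == AL and A1[c, EE, EE, e + 1, f] > v:
                            v = A1[c, EE, EE, e + 1, f]
                        A1[i, AL, r, e, f] = ga + v
                    for r in range(3):
                        v = A1[c, SG, r, e, f]
                        alt = A1[c, AL, r, e, f]
                        if A1[c, TG, r, e, f] > alt:
                            alt = A1[c, TG, r, e, f]
                        if r == SG and A1[c, EE, EE, e, f] > alt:
                            alt = A1[c, EE, EE, e, f]
                        alt -= h
                        if alt > v:
                            v = alt
                        A1[i, SG, r, e, f] = v - s
                    for r in range(3):
                        v = A1[i, TG, r, e + 1, f]
                        alt = A1[i, AL, r, e + 1, f]
                        if A1[i, SG, r, e + 1, f] > alt:
                            alt = A1[i, SG, r, e + 1, f]
                        alt -= h
                        if alt > v:
                            v = alt
                        A1[i, TG, r, e, f] = v - s

                elif kd == KIND_PAIRED:
                    # both endpoints aligned: the pair scores delta
                    if f > e:
                        g = NEG
                        for l2 in range(4):
                            for r2 in range(4):
                                if A1[c, l2, r2, e + 1, f - 1] > g:
                                    g = A1[c, l2, r2, e + 1, f - 1]
                        A1[i, AL, AL, e, f] = delta[u1, u2, te, tf] + g
                    # S[q] gapped: broken pair, S[p] scores gamma
                    v = NEG
                    alt = NEG
                    for l2 in range(3):
                        if A1[c, l2, SG, e + 1, f] > v:
                            v = A1[c, l2, SG, e + 1, f]
                        if A1[c, l2, AL, e + 1, f] > alt:
                            alt = A1[c, l2, AL, e + 1, f]
                        if A1[c, l2, TG, e + 1, f] > alt:
                            alt = A1[c, l2, TG, e + 1, f]
                    if A1[c, EE, EE, e + 1, f] > alt:
                        alt = A1[c, EE, EE, e + 1, f]
                    alt -= h
                    if alt > v:
                        v = alt
                    A1[i, AL, SG, e, f] = gamma[u1, te] + v - s
                    # S[p] gapped: broken pair, S[q] scores gamma
                    v = NEG
                    alt = NEG
                    for r2 in range(3):
                        if A1[c, SG, r2, e, f - 1] > v:
                            v = A1[c, SG, r2, e, f - 1]
                        if A1[c, AL, r2, e, f - 1] > alt:
                            alt = A1[c, AL, r2, e, f - 1]
                        if A1[c, TG, r2, e, f - 1] > alt:
                            alt = A1[c, TG, r2, e, f - 1]
                    if A1[c, EE, EE, e, f - 1] > alt:
                        alt = A1[c, EE, EE, e, f - 1]
                    alt -= h
                    if alt > v:
                        v = alt
                    A1[i, SG, AL, e, f] = gamma[u2, tf] + v - s
                    # both endpoints gapped
                    v = NEG
                    for l2 in range(3):
                        for r2 in range(3):
                            val = A1[c, l2, r2, e, f]
                            if l2 != SG:
                                val -= h
                            if r2 != SG:
                                val -= h
                            if val > v:
                                v = val
                    A1[i, SG, SG, e, f] = v - s - s
                    # trailing target gap (right peel)
                    for l2 in range(2):
                        v = A1[i, l2, TG, e, f - 1]
                        alt = A1[i, l2, AL, e, f - 1]
                        if A1[i, l2, SG, e, f - 1] > alt:
                            alt = A1[i, l2, SG, e, f - 1]
                        alt -= h
                        if alt > v:
                            v = alt
                        A1[i, l2, TG, e, f] = v - s
                    # leading target gap (left peel)
                    for r in range(3):
                        v = A1[i, TG, r, e + 1, f]
                        alt = A1[i, AL, r, e + 1, f]
                        if A1[i, SG, r, e + 1, f] > alt:
                            alt = A1[i, SG, r, e + 1, f]
                        alt -= h
                        if alt > v:
                            v = alt
                        A1[i, TG, r, e, f] = v - s

                else:  # KIND_SPLIT: concatenate L = (p, q') and R = (q'+1, q)
                    for l2 in range(3):
                        for r2 in range(3):
                            best = NEG
                            for k in range(e - 1, f + 1):
                                lany = A1[c, l2, AL, e, k]
                                if A1[c, l2, SG, e, k] > lany:
                                    lany = A1[c, l2, SG, e, k]
                                if A1[c, l2, TG, e, k] > lany:
                                    lany = A1[c, l2, TG, e, k]
                                rany = A1[cc, AL, r2, k + 1, f]
                                if A1[cc, SG, r2, k + 1, f] > rany:
                                    rany = A1[cc, SG, r2, k + 1, f]
                                if A1[cc, TG, r2, k + 1, f] > rany:
                                    rany = A1[cc, TG, r2, k + 1, f]
                                v = lany + rany
                                alt = A1[c, l2, SG, e, k] + A1[cc, SG, r2, k + 1, f] + h
                                if alt > v:
                                    v = alt
                                alt = A1[c, l2, TG, e, k] + A1[cc, TG, r2, k + 1, f] + h
                                if alt > v:
                                    v = alt
                                if v > best:
                                    best = v
                            A1[i, l2, r2, e, f] = best

                # ---------------- P (prefix-global, by left case) ----------
                if has_pq:
                    if kd == KIND_UNPAIRED:
                        a2c = _closed(e + 1, f, h, s)
                        for l2 in range(3):
                            if P[c, l2, e + 1, f] > a2c:
                                a2c = P[c, l2, e + 1, f]
                        P[i, AL, e, f] = gamma[u1, te] + a2c
                        v = P[c, SG, e, f]
                        alt = P[c, AL, e, f]
                        if P[c, TG, e, f] > alt:
                            alt = P[c, TG, e, f]
                        clo = _closed(e, f, h, s)
                        if clo > alt:
                            alt = clo
                        alt -= h
                        if alt > v:
                            v = alt
                        P[i, SG, e, f] = v - s
                    elif kd == KIND_PAIRED:
                        g = NEG
                        for l2 in range(4):
                            for r2 in range(4):
                                if A1[c, l2, r2, e + 1, f] > g:
                                    g = A1[c, l2, r2, e + 1, f]
                        for l2 in range(3):
                            if P[c, l2, e + 1, f] > g:
                                g = P[c, l2, e + 1, f]
                        clo = _closed(e + 1, f, h, s)
                        if clo > g:
                            g = clo
                        P[i, AL, e, f] = gamma[u1, te] + g
                        v = NEG
                        alt = NEG
                        for r2 in range(3):
                            if A1[c, SG, r2, e, f] > v:
                                v = A1[c, SG, r2, e, f]
                            if A1[c, AL, r2, e, f] > alt:
                                alt = A1[c, AL, r2, e, f]
                            if A1[c, TG, r2, e, f] > alt:
                                alt = A1[c, TG, r2, e, f]
                        if P[c, SG, e, f] > v:
                            v = P[c, SG, e, f]
                        if P[c, AL, e, f] > alt:
                            alt = P[c, AL, e, f]
                        if P[c, TG, e, f] > alt:
                            alt = P[c, TG, e, f]
                        clo = _closed(e, f, h, s)
                        if clo > alt:
                            alt = clo
                        alt -= h
                        if alt > v:
                            v = alt
                        P[i, SG, e, f] = v - s
                    else:  # SPLIT
                        for l2 in range(3):
                            best = P[c, l2, e, f]
                            for r2 in range(3):
                                if A1[c, l2, r2, e, f] > best:
                                    best = A1[c, l2, r2, e, f]
                            for k in range(e - 1, f + 1):
                                lany = A1[c, l2, AL, e, k]
                                if A1[c, l2, SG, e, k] > lany:
                                    lany = A1[c, l2, SG, e, k]
                                if A1[c, l2, TG, e, k] > lany:
                                    lany = A1[c, l2, TG, e, k]
                                pany = P[cc, AL, k + 1, f]
                                if P[cc, SG, k + 1, f] > pany:
                                    pany = P[cc, SG, k + 1, f]
                                if P[cc, TG, k + 1, f] > pany:
                                    pany = P[cc, TG, k + 1, f]
                                v = lany + pany
                                alt = A1[c, l2, SG, e, k] + P[cc, SG, k + 1, f] + h
                                if alt > v:
                                    v = alt
                                alt = A1[c, l2, TG, e, k] + P[cc, TG, k + 1, f] + h
                                if alt > v:
                                    v = alt
                                if v > best:
                                    best = v
                            P[i, l2, e, f] = best

                    # P[TG]: leading target gap, same for every node kind
                    v = P[i, TG, e + 1, f]
                    alt = P[i, AL, e + 1, f]
                    if P[i, SG, e + 1, f] > alt:
                        alt = P[i, SG, e + 1, f]
                    alt -= h
                    if alt > v:
                        v = alt
                    P[i, TG, e, f] = v - s

                # ---------------- Q (suffix-global, by right case) ----------
                if has_pq:
                    if kd == KIND_UNPAIRED:
                        for r2 in range(3):
                            v = Q[c, r2, e, f]
                            for l2 in range(3):
                                if A1[c, l2, r2, e, f] > v:
                                    v = A1[c, l2, r2, e, f]
                            Q[i, r2, e, f] = v
                    elif kd == KIND_PAIRED:
                        g = NEG
                        for l2 in range(4):
                            for r2 in range(4):
                                if A1[c, l2, r2, e, f - 1] > g:
                                    g = A1[c, l2, r2, e, f - 1]
                        for r2 in range(3):
                            if Q[c, r2, e, f - 1] > g:
                                g = Q[c, r2, e, f - 1]
                        clo = _closed(e, f - 1, h, s)
                        if clo > g:
                            g = clo
                        Q[i, AL, e, f] = gamma[u2, tf] + g
                        v = NEG
                        alt = NEG
                        for l2 in range(3):
                            if A1[c, l2, SG, e, f] > v:
                                v = A1[c, l2, SG, e, f]
                            if A1[c, l2, AL, e, f] > alt:
                                alt = A1[c, l2, AL, e, f]
                            if A1[c, l2, TG, e, f] > alt:
                                alt = A1[c, l2, TG, e, f]
                        if Q[c, SG, e, f] > v:
                            v = Q[c, SG, e, f]
                        if Q[c, AL, e, f] > alt:
                            alt = Q[c, AL, e, f]
                        if Q[c, TG, e, f] > alt:
                            alt = Q[c, TG, e, f]
                        clo = _closed(e, f, h, s)
                        if clo > alt:
                            alt = clo
                        alt -= h
                        if alt > v:
                            v = alt
                        Q[i, SG, e, f] = v - s
                        v = Q[i, TG, e, f - 1]
                        alt = Q[i, AL, e, f - 1]
                        if Q[i, SG, e, f - 1] > alt:
                            alt = Q[i, SG, e, f - 1]
                        alt -= h
                        if alt > v:
                            v = alt
                        Q[i, TG, e, f] = v - s
                    else:  # SPLIT
                        for r2 in range(3):
                            best = Q[cc, r2, e, f]
                            for l2 in range(3):
                                if A1[cc, l2, r2, e, f] > best:
                                    best = A1[cc, l2, r2, e, f]
                            for k in range(e - 1, f + 1):
                                qany = Q[c, AL, e, k]
                                if Q[c, SG, e, k] > qany:
                                    qany = Q[c, SG, e, k]
                                if Q[c, TG, e, k] > qany:
                                    qany = Q[c, TG, e, k]
                                rany = A1[cc, AL, r2, k + 1, f]
                                if A1[cc, SG, r2, k + 1, f] > rany:
                                    rany = A1[cc, SG, r2, k + 1, f]
                                if A1[cc, TG, r2, k + 1, f] > rany:
                                    rany = A1[cc, TG, r2, k + 1, f]
                                v = qany + rany
                                alt = Q[c, SG, e, k] + A1[cc, SG, r2, k + 1, f] + h
                                if alt > v:
                                    v = alt
                                alt = Q[c, TG, e, k] + A1[cc, TG, r2, k + 1, f] + h
                                if alt > v:
                                    v = alt
                                if v > best:
                                    best = v
                            Q[i, r2, e, f] = best

                # ---------------- A4 and A ----------------
                clo = _closed(e, f, h, s)
                if kd == KIND_UNPAIRED:
                    a2c = clo
                    for l2 in range(3):
                        if P[c, l2, e, f] > a2c:
                            a2c = P[c, l2, e, f]
                    a4 = A4[c, e, f]
                    if a2c > a4:
                        a4 = a2c
                    A4[i, e, f] = a4
                elif kd == KIND_PAIRED:
                    A4[i, e, f] = A[c, e, f]
                else:  # SPLIT
                    best = A4[c, e, f]
                    if A4[cc, e, f] > best:
                        best = A4[cc, e, f]
                    v = clo
                    for r2 in range(3):
                        if Q[c, r2, e, f] > v:
                            v = Q[c, r2, e, f]
                    if v > best:
                        best = v
                    v = clo
                    for l2 in range(3):
                        if P[cc, l2, e, f] > v:
                            v = P[cc, l2, e, f]
                    if v > best:
                        best = v
                    for k in range(e - 1, f + 1):
                        qany = Q[c, AL, e, k]
                        if Q[c, SG, e, k] > qany:
                            qany = Q[c, SG, e, k]
                        if Q[c, TG, e, k] > qany:
                            qany = Q[c, TG, e, k]
                        pany = P[cc, AL, k + 1, f]
                        if P[cc, SG, k + 1, f] > pany:
                            pany = P[cc, SG, k + 1, f]
                        if P[cc, TG, k + 1, f] > pany:
                            pany = P[cc, TG, k + 1, f]
                        v = qany + pany
                        alt = Q[c, SG, e, k] + P[cc, SG, k + 1, f] + h
                        if alt > v:
                            v = alt
                        alt = Q[c, TG, e, k] + P[cc, TG, k + 1, f] + h
                        if alt > v:
                            v = alt
                        if v > best:
                            best = v
                    A4[i, e, f] = best

                a1b = NEG
                for l2 in range(3):
                    for r2 in range(3):
                        if A1[i, l2, r2, e, f] > a1b:
                            a1b = A1[i, l2, r2, e, f]
                a2 = clo
                a3 = clo
                for l2 in range(3):
                    if P[i, l2, e, f] > a2:
                        a2 = P[i, l2, e, f]
                    if Q[i, l2, e, f] > a3:
                        a3 = Q[i, l2, e, f]
                best = a1b
                if a2 > best:
                    best = a2
                if a3 > best:
                    best = a3
                if A4[i, e, f] > best:
                    best = A4[i, e, f]
                A[i, e, f] = best


if JIT_ENABLED:
    _closed = njit(cache=True)(_closed)
    fill_tables = njit(cache=True)(fill_tables)
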