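"""Structure-guided interval decomposition of the query.

The DP only needs tables for query intervals reachable from ``(1, m)`` by
repeatedly applying the case function below; there are at most ``2m + 1``
such intervals:

* PAIRED:   ``(p, q)`` is itself a base pair -> child ``(p+1, q-1)``
* SPLIT:    ``p`` pairs with some ``q' < q``  -> children ``(p, q')`` and
            ``(q'+1, q)`` (``q'`` is unique: one partner per position)
* UNPAIRED: ``p`` pairs with nothing inside ``[p, q]`` -> child ``(p+1, q)``
* EMPTY:    ``p > q`` (base case; materialized explicitly and deduplicated)

PAIRED takes precedence over SPLIT when ``(p, q)`` is itself a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .core import SecondaryStructure

EMPTY = 0
UNPAIRED = 1
PAIRED = 2
SPLIT = 3

_TAG_NAMES = {EMPTY: "EMPTY", UNPAIRED: "UNPAIRED", PAIRED: "PAIRED", SPLIT: "SPLIT"}


@dataclass
class IntervalNode:
    """One query interval ``(p, q)`` the DP must fill.

    ``p == q + 1`` encodes the empty interval.  ``children`` are listed in
    the order the recurrences consume them (SPLIT: left part then right
    part); ``split`` holds ``q'`` for SPLIT nodes.
    """

    p: int
    q: int
    case_tag: int
    children: List["IntervalNode"] = field(default_factory=list)
    split: Optional[int] = None
    index: int = -1  # position in the dependency-ordered node list

    @property
    def tag_name(self) -> str:
        return _TAG_NAMES[self.case_tag]

    @property
    def size(self) -> int:
        return self.q - self.p + 1

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        extra = f", q'={self.split}" if self.split is not None else ""
        return f"IntervalNode({self.p}, {self.q}, {self.tag_name}{extra})"


def decompose(structure: SecondaryStructure, m: int) -> List[IntervalNode]:
    """Return the interval nodes needed for ``S[1..m]`` in dependency order.

    Every child precedes its parent; the last node is ``(1, m)``.  Nodes are
    deduplicated by ``(p, q)`` and all empty intervals collapse onto a single
    EMPTY node.  Node count is at most ``2m + 1``.
    """
    if structure.seq_length != m:
        raise ValueError(f"structure length {structure.seq_length} != m={m}")
    partner = structure.partner
    memo: Dict[Tuple[int, int], IntervalNode] = {}
    order: List[IntervalNode] = []

    def build(p: int, q: int) -> IntervalNode:
        if p > q:
            key = (1, 0)  # canonical empty interval
        else:
            key = (p, q)
        if key in memo:
            return memo[key]
        if p > q:
            node = IntervalNode(key[0], key[1], EMPTY)
            memo[key] = node
            order.append(node)
            return node
        mate = partner.get(p)
        if mate is not None and p < mate <= q:
            if mate == q:
                node = IntervalNode(p, q, PAIRED)
                memo[key] = node
                node.children = [build(p + 1, q - 1)]
            else:
                node = IntervalNode(p, q, SPLIT, split=mate)
                memo[key] = node
                node.children = [build(p, mate), build(mate + 1, q)]
        else:
            node = IntervalNode(p, q, UNPAIRED)
            memo[key] = node
            node.children = [build(p + 1, q)]
        order.append(node)
        return node

    build(1, m)
    for idx, node in enumerate(order):
        node.index = idx
    return order
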