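"""Domain types and the reference (non-DP) alignment scorer.

The reference scorer in this module is the ground truth: every score the
dynamic-programming engine reports must be realized by an explicit alignment
that :func:`reference_score` evaluates to exactly the same number.

Scoring values are snapped to a dyadic grid (multiples of ``2**-20``) when a
:class:`ScoringScheme` is constructed.  Sums of such values are exact in IEEE
double precision regardless of accumulation order, which is what makes
bit-exact agreement between the DP, the traceback and the reference scorer
possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np

ALPHABET = "ACGU"
_CODE: Dict[str, int] = {c: i for i, c in enumerate(ALPHABET)}

#: Watson-Crick plus wobble pairs, as ordered (5', 3') character tuples.
COMPLEMENTARY_PAIRS: FrozenSet[Tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)

GAP = "-"

#: Quantum used to snap scoring values to a dyadic grid (see module docstring).
SCORE_QUANTUM_BITS = 20


def snap(x: float) -> float:
    """Round ``x`` to the nearest multiple of ``2**-SCORE_QUANTUM_BITS``."""
    scale = float(1 << SCORE_QUANTUM_BITS)
    return round(float(x) * scale) / scale


def encode(residues: str) -> np.ndarray:
    """Encode an A/C/G/U string as an int8 array (A=0, C=1, G=2, U=3)."""
    return np.array([_CODE[c] for c in residues], dtype=np.int8)


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map T->U and reject anything outside the 4-letter alphabet."""
    out = []
    for pos, ch in enumerate(raw, start=1):
        c = ch.upper()
        if c == "T":
            c = "U"
        if c not in _CODE:
            raise ValueError(
                f"illegal character {ch!r} at position {pos} in {context}"
            )
        out.append(c)
    return "".join(out)


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U} with a text identifier.

    All external coordinates are 1-based inclusive; ``seq[i]`` on this type is
    therefore exposed through :meth:`base` rather than raw indexing.
    """

    id: str
    residues: str

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        """Build a sequence from raw text, normalizing case and T->U."""
        return cls(id=id, residues=normalize_residues(raw, context=f"record {id!r}"))

    def __post_init__(self) -> None:
        for pos, c in enumerate(self.residues, start=1):
            if c not in _CODE:
                raise ValueError(
                    f"illegal character {c!r} at position {pos} in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Return the residue at 1-based position ``i``."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} out of range 1..{len(self.residues)}")
        return self.residues[i - 1]

    def substring(self, x: int, y: int) -> str:
        """Return ``S[x..y]`` (1-based inclusive); empty when ``x > y``."""
        if x > y:
            return ""
        return self.residues[x - 1 : y]

    @cached_property
    def codes(self) -> np.ndarray:
        return encode(self.residues)


class StructureError(ValueError):
    """Raised for irregular structures (crossing or position-sharing pairs)."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A regular (non-crossing) set of base pairs over positions ``1..m``.

    Crossing pairs or pairs sharing a position violate regularity and are a
    hard construction error.
    """

    pairs: FrozenSet[Tuple[int, int]]
    seq_length: int

    def __init__(self, pairs: Iterable[Tuple[int, int]], seq_length: int):
        norm = frozenset((int(i), int(j)) for i, j in pairs)
        object.__setattr__(self, "pairs", norm)
        object.__setattr__(self, "seq_length", int(seq_length))
        self._validate()

    def _validate(self) -> None:
        seen: Dict[int, Tuple[int, int]] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= self.seq_length):
                raise StructureError(
                    f"pair ({i}, {j}) out of bounds for length {self.seq_length}"
                )
            for pos in (i, j):
                if pos in seen:
                    raise StructureError(
                        f"position {pos} occurs in two pairs {seen[pos]} and ({i}, {j})"
                    )
                seen[pos] = (i, j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for b in range(a + 1, len(ordered)):
                k, l = ordered[b]
                if k >= j:
                    break
                if i < k < j < l:
                    raise StructureError(
                        f"crossing pairs ({i}, {j}) and ({k}, {l})"
                    )

    @cached_property
    def partner(self) -> Dict[int, int]:
        """Map each paired position to its partner."""
        out: Dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def restrict(self, x: int, y: int) -> FrozenSet[Tuple[int, int]]:
        """``M_{x,y}``: the pairs with both endpoints inside ``[x, y]``.

        Pairs with exactly one endpoint inside are dropped; that endpoint
        remains an unpaired character of the substring.
        """
        return frozenset((i, j) for i, j in self.pairs if x <= i and j <= y)

    def __len__(self) -> int:
        return len(self.pairs)


def validate_structure(
    structure: SecondaryStructure,
    seq: RnaSequence,
    strict_complementarity: bool = False,
) -> List[str]:
    """Check that every pair of ``structure`` is complementary in ``seq``.

    Returns a list of warnings (one per offending pair).  Raises only when
    ``strict_complementarity`` is set.  Irregular structures never get this
    far: they fail at :class:`SecondaryStructure` construction.
    """
    if structure.seq_length != len(seq):
        raise ValueError(
            f"structure length {structure.seq_length} != sequence length {len(seq)}"
        )
    warnings = []
    for i, j in sorted(structure.pairs):
        duo = (seq.base(i), seq.base(j))
        if duo not in COMPLEMENTARY_PAIRS:
            warnings.append(
                f"pair ({i}, {j}) is non-complementary: {duo[0]}-{duo[1]}"
            )
    if warnings and strict_complementarity:
        raise ValueError("; ".join(warnings))
    return warnings


def _default_gamma(match: float = 1.0, mismatch: float = -1.0) -> np.ndarray:
    g = np.full((4, 4), mismatch, dtype=np.float64)
    np.fill_diagonal(g, match)
    return g


def _default_delta(gamma: np.ndarray, bonus: float = 2.0) -> np.ndarray:
    """delta(u1,u2,v1,v2) = gamma(u1,v1) + gamma(u2,v2) +/- bonus.

    The bonus is added when the target duo (v1, v2) is complementary and
    subtracted otherwise, rewarding conserved or compensatory pairing.
    """
    comp = np.zeros((4, 4), dtype=bool)
    for a, b in COMPLEMENTARY_PAIRS:
        comp[_CODE[a], _CODE[b]] = True
    d = np.zeros((4, 4, 4, 4), dtype=np.float64)
    for u1 in range(4):
        for u2 in range(4):
            for v1 in range(4):
                for v2 in range(4):
                    base = gamma[u1, v1] + gamma[u2, v2]
                    d[u1, u2, v1, v2] = base + (bonus if comp[v1, v2] else -bonus)
    return d


@dataclass(frozen=True)
class ScoringScheme:
    """Bundle of character scores, pair scores and affine gap penalties.

    ``gamma[u1, u2]`` scores a query character against a target character and
    ``delta[u1, u2, v1, v2]`` scores a query base pair against a target duo
    (indices follow A=0, C=1, G=2, U=3).  A gap of length L costs exactly
    ``h + s*L``; both penalties must be nonnegative.  All values are snapped
    to the dyadic grid on construction.
    """

    gamma: np.ndarray
    delta: np.ndarray
    h: float
    s: float

    def __init__(self, gamma, delta, h: float, s: float):
        g = np.asarray(gamma, dtype=np.float64)
        d = np.asarray(delta, dtype=np.float64)
        if g.shape != (4, 4):
            raise ValueError(f"gamma must be 4x4, got {g.shape}")
        if d.shape != (4, 4, 4, 4):
            raise ValueError(f"delta must be 4x4x4x4, got {d.shape}")
        if h < 0 or s < 0:
            raise ValueError("gap penalties h and s must be nonnegative")
        scale = float(1 << SCORE_QUANTUM_BITS)
        g = np.round(g * scale) / scale
        d = np.round(d * scale) / scale
        g.setflags(write=False)
        d.setflags(write=False)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "h", snap(h))
        object.__setattr__(self, "s", snap(s))

    @classmethod
    def default(
        cls,
        h: float = 5.0,
        s: float = 0.1,
        match: float = 1.0,
        mismatch: float = -1.0,
        pair_bonus: float = 2.0,
    ) -> "ScoringScheme":
        gamma = _default_gamma(match, mismatch)
        return cls(gamma=gamma, delta=_default_delta(gamma, pair_bonus), h=h, s=s)

    def gamma_of(self, u: str, v: str) -> float:
        return float(self.gamma[_CODE[u], _CODE[v]])

    def delta_of(self, u1: str, u2: str, v1: str, v2: str) -> float:
        return float(self.delta[_CODE[u1], _CODE[u2], _CODE[v1], _CODE[v2]])


EMPTY_RANGE = (1, 0)


@dataclass(frozen=True)
class Alignment:
    """A gapped alignment between a query substring and a target substring.

    ``s_prime`` and ``t_prime`` are equal-length strings over {A,C,G,U,-};
    no column may hold ``-`` in both.  ``query_range``/``target_range`` are
    1-based inclusive coordinates of the aligned substrings; an empty
    substring is encoded with start > end.
    """

    s_prime: str
    t_prime: str
    query_range: Tuple[int, int]
    target_range: Tuple[int, int]
    score: float

    def __post_init__(self) -> None:
        if len(self.s_prime) != len(self.t_prime):
            raise ValueError("aligned strings must have equal length")
        for col, (a, b) in enumerate(zip(self.s_prime, self.t_prime), start=1):
            if a == GAP and b == GAP:
                raise ValueError(f"column {col} is a gap in both strings")
            if a != GAP and a not in _CODE:
                raise ValueError(f"illegal query character {a!r} in column {col}")
            if b != GAP and b not in _CODE:
                raise ValueError(f"illegal target character {b!r} in column {col}")
        x, y = self.query_range
        nq = sum(1 for c in self.s_prime if c != GAP)
        if (y - x + 1 if x <= y else 0) != nq:
            raise ValueError("query_range does not match the number of query characters")
        x2, y2 = self.target_range
        nt = sum(1 for c in self.t_prime if c != GAP)
        if (y2 - x2 + 1 if x2 <= y2 else 0) != nt:
            raise ValueError("target_range does not match the number of target characters")

    def __len__(self) -> int:
        return len(self.s_prime)

    @cached_property
    def eta(self) -> Dict[int, int]:
        """Map 1-based column index (non-gap in s_prime) -> query position."""
        x = self.query_range[0]
        out: Dict[int, int] = {}
        k = 0
        for col, c in enumerate(self.s_prime, start=1):
            if c != GAP:
                out[col] = x + k
                k += 1
        return out

    @cached_property
    def _gap_runs(self) -> List[int]:
        runs: List[int] = []
        for row in (self.s_prime, self.t_prime):
            run = 0
            for c in row:
                if c == GAP:
                    run += 1
                elif run:
                    runs.append(run)
                    run = 0
            if run:
                runs.append(run)
        return runs

    @property
    def gap_count(self) -> int:
        """k: the number of maximal gap runs across both strings."""
        return len(self._gap_runs)

    @property
    def gap_total(self) -> int:
        """l: the total number of ``-`` characters across both strings."""
        return sum(self._gap_runs)

    @classmethod
    def empty(cls) -> "Alignment":
        return cls("", "", EMPTY_RANGE, EMPTY_RANGE, 0.0)


def reference_score(
    alignment: Alignment,
    structure: SecondaryStructure,
    scheme: ScoringScheme,
) -> float:
    """Score an alignment directly from its columns (the ground truth).

    A query base pair ``(i, j)`` restricted to the aligned query substring
    contributes ``delta`` iff both endpoint columns align query characters to
    target characters.  Every other query character aligned to a target
    character contributes ``gamma`` -- including pair endpoints whose partner
    faces a gap or lies outside the chosen substring (broken pairs).  Gaps
    cost ``k*h + l*s`` over the maximal gap runs of both strings.
    """
    x, y = alignment.query_range
    eta_inv: Dict[int, int] = {q: col for col, q in alignment.eta.items()}
    pairs = structure.restrict(x, y) if x <= y else frozenset()

    t_chars: Dict[int, str] = {}
    for col, (a, b) in enumerate(zip(alignment.s_prime, alignment.t_prime), start=1):
        if a != GAP and b != GAP:
            t_chars[col] = b

    score = 0.0
    in_pair_col: set = set()
    for i, j in sorted(pairs):
        ci, cj = eta_inv[i], eta_inv[j]
        if ci in t_chars and cj in t_chars:
            score += scheme.delta_of(
                alignment.s_prime[ci - 1],
                alignment.s_prime[cj - 1],
                t_chars[ci],
                t_chars[cj],
            )
            in_pair_col.add(ci)
            in_pair_col.add(cj)
    for col, b in t_chars.items():
        if col not in in_pair_col:
            score += scheme.gamma_of(alignment.s_prime[col - 1], b)
    score -= alignment.gap_count * scheme.h + alignment.gap_total * scheme.s
    return score
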