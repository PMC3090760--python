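"""Genome scanning, threshold/ROC evaluation, and synthetic fixtures.

The scanning protocol mirrors the experiment design: a window of length
``max(member lengths) + 20`` slides along the genome, each window is scored
by the local structural aligner, and score lists of real vs decoy windows
are turned into zero-false-positive / fixed-FPR thresholds and a normalized
partial AUC (FPR <= 0.1).

Fixtures embed mutated copies of a structured family into an i.i.d. uniform
random genome roughly ten times the total member length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ALPHABET,
    COMPLEMENTARY_PAIRS,
    Alignment,
    RnaSequence,
    ScoringScheme,
    SecondaryStructure,
)
from .engine import StructuralAligner, align_local, global_score


@dataclass
class ScanRecord:
    """Score of one genome window (1-based inclusive coordinates)."""

    window_start: int
    window_end: int
    score: float
    global_score: float = float("-inf")
    q_begin: int = 1
    q_end: int = 0
    t_begin: int = 1  # genome coordinates of the best local hit
    t_end: int = 0
    is_real_hit: Optional[bool] = None


def window_length_rule(member_lengths: Sequence[int], pad: int = 20) -> int:
    """The scanning window length: maximum member length plus ``pad``."""
    lengths = list(member_lengths)
    if not lengths:
        raise ValueError("member_lengths must be nonempty")
    return max(lengths) + pad


def scan(
    query: RnaSequence,
    structure: SecondaryStructure,
    genome: RnaSequence,
    window_len: int,
    scheme: ScoringScheme,
    step: int = 1,
    with_coords: bool = True,
) -> List[ScanRecord]:
    """Score every window of ``genome`` with the local structural aligner.

    Windows start at 1, 1+step, ...; when the genome is shorter than the
    window a single truncated window is scored (with a warning).  Each
    record also carries the global alignment score of the same window, read
    from the same DP fill.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(genome)
    aligner = StructuralAligner(query, structure, scheme)
    if window_len > n:
        warnings.warn(
            f"window length {window_len} exceeds genome length {n}; "
            "scoring one truncated window"
        )
        starts = [1]
        window_len = n
    else:
        starts = list(range(1, n - window_len + 2, step))
    records: List[ScanRecord] = []
    for start in starts:
        end = start + window_len - 1
        window = RnaSequence(id=f"{genome.id}:{start}-{end}", residues=genome.substring(start, end))
        ws = aligner.fill(window)
        score, _, _ = ws.best_local()
        gscore = global_score(ws)
        rec = ScanRecord(window_start=start, window_end=end, score=score, global_score=gscore)
        if with_coords and score > 0.0:
            aln = align_local(query, structure, window, scheme, workspace=ws)
            rec.q_begin, rec.q_end = aln.query_range
            tb, te = aln.target_range
            if tb <= te:
                rec.t_begin, rec.t_end = tb + start - 1, te + start - 1
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Threshold / ROC evaluation
# ---------------------------------------------------------------------------


def _roc_points(real: Sequence[float], false: Sequence[float]) -> List[Tuple[float, float]]:
    """Operating points (FPR, TPR) sweeping thresholds over observed scores.

    A score counts as positive at threshold t when it is strictly greater
    than t (so a real hit scoring <= t is missed), matching the miss rule.
    """
    nr, nf = len(real), len(false)
    pts = [(0.0, 0.0)]
    for t in sorted(set(real) | set(false), reverse=True):
        fpr = sum(1 for v in false if v > t) / nf
        tpr = sum(1 for v in real if v > t) / nr
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    return pts


def partial_auc(real: Sequence[float], false: Sequence[float], fpr_max: float = 0.1) -> float:
    """Trapezoidal area under the ROC for FPR <= fpr_max, normalized to [0, 1]."""
    pts = _roc_points(real, false)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if x0 >= fpr_max:
            break
        if x1 <= fpr_max:
            area += (x1 - x0) * (y0 + y1) / 2.0
        else:
            # linear interpolation at the cut
            yc = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
            area += (fpr_max - x0) * (y0 + yc) / 2.0
            break
    return area / fpr_max


def evaluate_thresholds(
    real_scores: Sequence[float],
    false_scores: Sequence[float],
    fpr_levels: Sequence[float] = (0.05, 0.10),
) -> Dict:
    """Threshold metrics: zero-FP threshold, misses, FPR-level thresholds, pAUC.

    The zero-false-positive threshold is the largest false score; a real hit
    scoring less than or equal to a threshold is a miss.  For an FPR level
    ``a`` the threshold is the smallest observed score t with
    ``#{false > t} / #false <= a``.
    """
    real = [float(v) for v in real_scores]
    false = [float(v) for v in false_scores]
    if not real or not false:
        raise ValueError("real_scores and false_scores must both be nonempty")
    zero_fp = max(false)
    misses0 = sum(1 for v in real if v <= zero_fp)
    nf = len(false)
    candidates = sorted(set(real) | set(false))
    sentinel = candidates[0] - 1.0
    out = {
        "zero_fp_threshold": zero_fp,
        "misses_zero_fp": misses0,
        "miss_rate_zero_fp": misses0 / len(real),
        "n_real": len(real),
        "n_false": nf,
        "levels": {},
        "pauc": partial_auc(real, false, 0.1),
        "pauc_fpr_max": 0.1,
    }
    for level in fpr_levels:
        thr = None
        for t in [sentinel] + candidates:
            if sum(1 for v in false if v > t) / nf <= level:
                thr = t
                break
        misses = sum(1 for v in real if v <= thr)
        out["levels"][float(level)] = {
            "threshold": thr,
            "misses": misses,
            "miss_rate": misses / len(real),
        }
    return out


def label_records(
    records: Sequence[ScanRecord],
    truth: Sequence[Tuple[int, int]],
    min_overlap_frac: float = 0.5,
) -> None:
    """Mark each window a real hit iff it overlaps a truth interval by at
    least ``min_overlap_frac`` of that member's length (in place)."""
    for rec in records:
        hit = False
        for a, b in truth:
            lo = max(rec.window_start, a)
            hi = min(rec.window_end, b)
            if hi - lo + 1 >= min_overlap_frac * (b - a + 1):
                hit = True
                break
        rec.is_real_hit = hit


def attribute_scores(
    records: Sequence[ScanRecord],
    truth: Sequence[Tuple[int, int]],
    min_overlap_frac: float = 0.5,
    use_global: bool = False,
) -> Tuple[List[float], List[float]]:
    """Per-member hit scores and decoy-window scores.

    Each member's score is the maximum window score over windows overlapping
    it; windows overlapping no member by >= ``min_overlap_frac`` of the
    member length contribute their scores to the false list.
    """
    label_records(records, truth, min_overlap_frac)
    real: List[float] = []
    for a, b in truth:
        best = None
        for rec in records:
            if min(rec.window_end, b) >= max(rec.window_start, a):
                v = rec.global_score if use_global else rec.score
                if best is None or v > best:
                    best = v
        if best is None:
            best = 0.0
        real.append(best)
    false = [
        (rec.global_score if use_global else rec.score)
        for rec in records
        if not rec.is_real_hit
    ]
    return real, false


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Recipe for one synthetic scanning fixture."""

    members: List[RnaSequence]
    genome_length_factor: float = 10.0
    max_members: int = 100
    seed: int = 0


def _random_bases(rng: np.random.Generator, k: int) -> str:
    return "".join(ALPHABET[c] for c in rng.integers(0, 4, size=k))


def make_fixture(spec: FixtureSpec) -> Tuple[RnaSequence, List[Tuple[int, int]]]:
    """Embed the members in a uniform random genome at arbitrary positions.

    Returns the genome and the 1-based inclusive, non-overlapping truth
    intervals of the embedded members, ordered along the genome.
    Reproducible for a fixed seed.
    """
    if not spec.members:
        raise ValueError("fixture needs at least one member")
    rng = np.random.default_rng(spec.seed)
    members = list(spec.members)
    if len(members) > spec.max_members:
        idx = rng.choice(len(members), size=spec.max_members, replace=False)
        members = [members[i] for i in sorted(idx)]
    total = sum(len(m) for m in members)
    background = int(round(spec.genome_length_factor * total)) - total
    if background < 0:
        raise ValueError(
            f"genome_length_factor {spec.genome_length_factor} leaves no room "
            f"for {total} member bases"
        )
    # split the background into len(members)+1 chunks via sorted cut points
    cuts = np.sort(rng.integers(0, background + 1, size=len(members)))
    chunks = []
    prev = 0
    for c in cuts:
        chunks.append(int(c) - prev)
        prev = int(c)
    chunks.append(background - prev)
    parts: List[str] = []
    truth: List[Tuple[int, int]] = []
    pos = 0
    for gap_len, member in zip(chunks, members):
        parts.append(_random_bases(rng, gap_len))
        pos += gap_len
        parts.append(member.residues)
        truth.append((pos + 1, pos + len(member)))
        pos += len(member)
    parts.append(_random_bases(rng, chunks[-1]))
    genome = RnaSequence(id=f"fixture-seed{spec.seed}", residues="".join(parts))
    return genome, truth


def mutate_member(
    seq: RnaSequence,
    structure: SecondaryStructure,
    point_rate: float,
    loop_indel_max: int,
    seed: int,
) -> RnaSequence:
    """Mutated family member: substitutions anywhere, indels only in loops.

    Positions that open a base pair mutate compensatorily (both partners are
    replaced by a random complementary duo), keeping the donor structure
    interpretable; unpaired positions substitute to a random other base.
    At most one insertion or deletion of up to ``loop_indel_max`` nt is
    applied at an unpaired position.
    """
    if not 0.0 <= point_rate <= 1.0:
        raise ValueError("point_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    partner = structure.partner
    chars = list(seq.residues)
    comp = sorted(COMPLEMENTARY_PAIRS)
    for pos in range(1, len(chars) + 1):
        mate = partner.get(pos)
        if mate is not None and mate < pos:
            continue  # closing endpoint: handled with its opener
        if rng.random() >= point_rate:
            continue
        if mate is not None:
            duo = comp[rng.integers(0, len(comp))]
            chars[pos - 1] = duo[0]
            chars[mate - 1] = duo[1]
        else:
            options = [c for c in ALPHABET if c != chars[pos - 1]]
            chars[pos - 1] = options[rng.integers(0, 3)]
    if loop_indel_max > 0:
        unpaired = [i for i in range(1, len(chars) + 1) if i not in partner]
        if unpaired:
            k = int(rng.integers(1, loop_indel_max + 1))
            anchor = unpaired[rng.integers(0, len(unpaired))]
            if rng.random() < 0.5:
                insert = _random_bases(rng, k)
                chars[anchor - 1] = chars[anchor - 1] + insert
            else:
                removed = 0
                pos = anchor
                while pos <= len(chars) and removed < k and pos not in partner:
                    chars[pos - 1] = ""
                    removed += 1
                    pos += 1
    return RnaSequence(id=f"{seq.id}|mut{seed}", residues="".join(chars))


def random_regular_structure(
    m: int, rng: np.random.Generator, pair_prob: float = 0.4, min_loop: int = 0
) -> SecondaryStructure:
    """Sample a random non-crossing structure over ``1..m``.

    Walks left to right keeping a stack of open positions; each position
    opens, closes (if allowed) or stays unpaired with probabilities driven
    by ``pair_prob``.  ``min_loop`` forces hairpin loops of at least that
    many unpaired bases (0 permits adjacent pairs, exercising corner cases).
    """
    pairs = []
    stack: List[int] = []
    for pos in range(1, m + 1):
        r = rng.random()
        closable = bool(stack) and pos - stack[-1] - 1 >= min_loop
        if closable and r < pair_prob / 2:
            pairs.append((stack.pop(), pos))
        elif r < pair_prob and pos < m:
            stack.append(pos)
    # unmatched opens stay unpaired
    return SecondaryStructure(pairs=pairs, seq_length=m)


def random_hairpin_family(
    n_members: int,
    stem: int,
    loop: int,
    seed: int,
    point_rate: float = 0.1,
    loop_indel_max: int = 5,
    tail: int = 4,
) -> Tuple[RnaSequence, SecondaryStructure, List[RnaSequence]]:
    """A structured family: query + mutated members sharing one hairpin fold.

    The fold is ``tail . stem ( loop . stem ) tail .``; pair regions are
    filled with complementary duos, loops with random bases.
    """
    rng = np.random.default_rng(seed)
    comp = sorted(COMPLEMENTARY_PAIRS)
    left = []
    right = []
    for _ in range(stem):
        duo = comp[rng.integers(0, len(comp))]
        left.append(duo[0])
        right.append(duo[1])
    seq = (
        _random_bases(rng, tail)
        + "".join(left)
        + _random_bases(rng, loop)
        + "".join(reversed(right))
        + _random_bases(rng, tail)
    )
    m = len(seq)
    pairs = [
        (tail + i + 1, tail + stem + loop + (stem - i)) for i in range(stem)
    ]
    structure = SecondaryStructure(pairs=pairs, seq_length=m)
    query = RnaSequence(id=f"family-seed{seed}", residues=seq)
    members = [
        mutate_member(query, structure, point_rate, loop_indel_max, seed=seed * 1000 + i)
        for i in range(n_members)
    ]
    for i, mem in enumerate(members):
        object.__setattr__(mem, "id", f"member{i}")
    return query, structure, members
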