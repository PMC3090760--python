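"""Readers and writers: FASTA, dot-bracket structures, scoring config, results.

Structure input accepts either a sidecar file whose single non-comment line
is a dot-bracket string, or a two-line "FASTA-like" file (sequence line then
structure line).  Only round brackets are recognized; pseudoknot bracket
types are rejected, consistent with the regular-structure scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .core import (
    ALPHABET,
    RnaSequence,
    ScoringScheme,
    SecondaryStructure,
    _default_delta,
    _default_gamma,
    normalize_residues,
)

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> List[RnaSequence]:
    """Read and normalize (T->U, uppercase) all records of a FASTA file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: List[RnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(RnaSequence.from_raw(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def parse_dot_bracket(db: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a pair set (innermost-first matching).

    Dot-bracket over ``( ) .`` cannot encode crossing pairs, so the result is
    regular by construction.  Unbalanced strings raise with the index of the
    first violation.
    """
    stack: List[int] = []
    pairs = []
    for idx, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(
                f"illegal structure character {ch!r} at position {idx} "
                "(only '.', '(' and ')' are supported)"
            )
    if stack:
        raise ValueError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(pairs=pairs, seq_length=len(db))


def write_dot_bracket(structure: SecondaryStructure) -> str:
    """Inverse of :func:`parse_dot_bracket`."""
    chars = ["."] * structure.seq_length
    for i, j in structure.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def read_structure_file(path: PathLike, seq_length: Optional[int] = None) -> SecondaryStructure:
    """Read a structure from a sidecar or two-line FASTA-like file.

    The structure line is the first non-comment line made of ``. ( )``; in
    the two-line dialect the first non-comment line is the sequence and the
    second is the structure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith(("#", ";", ">"))
    ]
    if not lines:
        raise ValueError(f"no structure line found in {path}")
    db = None
    for ln in lines:
        if set(ln) <= set(".()"):
            db = ln
            break
    if db is None:
        raise ValueError(f"no dot-bracket line found in {path}")
    structure = parse_dot_bracket(db)
    if seq_length is not None and structure.seq_length != seq_length:
        raise ValueError(
            f"structure length {structure.seq_length} != sequence length {seq_length}"
        )
    return structure


# ---------------------------------------------------------------------------
# Scoring configuration (JSON)
# ---------------------------------------------------------------------------

def scheme_to_config(scheme: ScoringScheme) -> dict:
    """Serialize a scheme to a plain JSON-able document."""
    return {
        "alphabet": ALPHABET,
        "gamma": np.asarray(scheme.gamma).tolist(),
        "delta": np.asarray(scheme.delta).tolist(),
        "h": scheme.h,
        "s": scheme.s,
    }


def scheme_from_config(doc: Mapping) -> ScoringScheme:
    """Build a scheme from a config document; absent keys fall back to defaults.

    ``gamma`` may be a dense 4x4 table or ``{"match": x, "mismatch": y}``;
    ``delta`` may be a dense 4^4 table or ``{"pair_bonus": b}`` selecting the
    parameterized default built on top of gamma.
    """
    h = float(doc.get("h", 5.0))
    s = float(doc.get("s", 0.1))
    g = doc.get("gamma")
    if g is None:
        gamma = _default_gamma()
    elif isinstance(g, Mapping):
        gamma = _default_gamma(float(g.get("match", 1.0)), float(g.get("mismatch", -1.0)))
    else:
        gamma = np.asarray(g, dtype=np.float64)
    d = doc.get("delta")
    if d is None:
        delta = _default_delta(gamma)
    elif isinstance(d, Mapping):
        delta = _default_delta(gamma, float(d.get("pair_bonus", 2.0)))
    else:
        delta = np.asarray(d, dtype=np.float64)
    return ScoringScheme(gamma=gamma, delta=delta, h=h, s=s)


def read_scoring_config(path: PathLike) -> ScoringScheme:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scoring config not found: {path}")
    return scheme_from_config(json.loads(path.read_text()))


def write_scoring_config(scheme: ScoringScheme, path: PathLike) -> None:
    Path(path).write_text(json.dumps(scheme_to_config(scheme), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "query_id",
    "target_id",
    "window_start",
    "window_end",
    "score",
    "q_begin",
    "q_end",
    "t_begin",
    "t_end",
)


def write_results(records: Sequence[Mapping], path: PathLike, header_lines: Sequence[str] = ()) -> None:
    """Write scan/alignment records as a TSV table with 1-based coordinates.

    Records are emitted sorted by (target_id, window_start).  ``header_lines``
    are written first as ``#``-prefixed provenance comments.
    """
    ordered = sorted(
        records, key=lambda r: (str(r.get("target_id", "")), int(r.get("window_start", 0)))
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for rec in ordered:
            fh.write("\t".join(_fmt(rec.get(c)) for c in RESULT_COLUMNS) + "\n")


def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, float):
        return repr(v)
    return str(v)


def read_results(path: PathLike) -> List[dict]:
    """Read a TSV written by :func:`write_results`."""
    rows: List[dict] = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = line.split("\t")
            row: dict = dict(zip(header, vals))
            for key in ("window_start", "window_end", "q_begin", "q_end", "t_begin", "t_end"):
                if row.get(key) not in (None, "."):
                    row[key] = int(row[key])
            if row.get("score") not in (None, "."):
                row["score"] = float(row["score"])
            rows.append(row)
    return rows
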