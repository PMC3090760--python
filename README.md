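# rsalign

Local structural alignment of RNA with an affine gap model.

Given a **query** RNA whose secondary structure is known (and regular, i.e.
pseudoknot-free) and a **target** sequence of unknown structure, `rsalign`
computes the optimal local structural alignment under an affine gap penalty
(`h + s·L` per gap of length `L`), along with the global, semi-global and
prefix/suffix-global variants it is built from.  Columns that align both
endpoints of a query base pair to target characters score with a base-pair
similarity function δ; all other aligned columns score with a character
similarity γ.  The DP runs in `O(m·n³)` over a structure-guided interval
decomposition of the query (at most `2m+1` intervals), with per-interval
tables split by boundary case so gap openings are charged exactly once per
maximal run.

Also included:

* a traceback that reconstructs explicit alignments whose independently
  recomputed score equals the DP score **bit-exactly** (scheme values are
  snapped to a dyadic grid so float sums are order-independent),
* a genome-scanning mode (window = longest member + 20 by default),
* threshold / miss-rate metrics and normalized partial AUC (FPR ≤ 10%),
* a synthetic fixture generator (mutated structured families embedded in a
  ~10× random decoy genome),
* brute-force oracles used to certify the engine on small inputs.

## Library quick start

```python
from rsalign import (RnaSequence, ScoringScheme, parse_dot_bracket,
                     align_local)

query = RnaSequence("q", "GGGAAACCC")
structure = parse_dot_bracket("(((...)))")
target = RnaSequence("t", "UUGGGAAACCCUU")
aln = align_local(query, structure, target, ScoringScheme.default())
print(aln.score, aln.s_prime, aln.t_prime, aln.query_range, aln.target_range)
```

`ScoringScheme.default()` uses γ(match)=+1, γ(mismatch)=−1,
δ(u₁,u₂,v₁,v₂)=γ(u₁,v₁)+γ(u₂,v₂)±2 (plus when the target duo is
complementary), h=5, s=0.1.  Everything is overridable via a JSON scoring
config or constructor arguments.

## Command line

```sh
# alignment modes
rsalign align-local  --query q.fa --structure q.db --target t.fa --out out.tsv
rsalign align-global --query q.fa --structure q.db --target t.fa --h 5 --s 0.1

# scan a genome with the l+20 window rule (step configurable)
rsalign scan --query q.fa --structure q.db --target genome.fa \
             --window 114 --step 1 --out scan.tsv

# generate a synthetic fixture, then evaluate a scan against its truth
rsalign fixture --seed 7 --members 20 --out-prefix fx
rsalign scan --query fx.query.fa --structure fx.query.db \
             --target fx.genome.fa --pad 20 --out fx.scan.tsv
rsalign eval --scan-tsv fx.scan.tsv --truth fx.truth.tsv --out metrics.json
```

Structures are dot-bracket files (sidecar line, or sequence+structure two-
line files).  All user-facing coordinates are 1-based inclusive; empty
ranges are encoded with start > end.  Outputs carry provenance headers and
are byte-identical across reruns with the same inputs and seed.

## Layout

| module                 | purpose                                               |
|------------------------|-------------------------------------------------------|
| `rsalign.core`         | domain types, validation, reference (non-DP) scorer   |
| `rsalign.io`           | FASTA / dot-bracket / scoring config / TSV results    |
| `rsalign.decompose`    | structure-guided interval decomposition               |
| `rsalign.engine`,`_dp` | DP tables, traceback, public alignment API            |
| `rsalign.oracle`       | brute-force enumerators + textbook Gotoh (test-only)  |
| `rsalign.scan`         | scanning, thresholds/pAUC, synthetic fixtures         |
| `rsalign.cli`          | `rsalign` command-line front end                      |
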