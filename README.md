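# swsearch

Exact Smith-Waterman protein database search, built around three
**score-equivalent** alignment engines:

1. a **scalar reference engine** — the literal affine-gap dynamic program;
2. a **striped vectorized engine** — the striped SIMD formulation with the
   lazy-F correction loop, executed on an emulated virtualized SIMD lane
   machine (any lane count `VL >= 1`);
3. a **partitioned vectorized engine** — the query is cut into `PL`-residue
   partitions, each aligned by the striped engine, with per-column H/F
   boundary values carried exactly between partitions.

The vectorized formulations are how fast SW implementations actually work on
SIMD units and GPUs; their correctness rests on two non-obvious claims — that
the lazy-F loop's early exit never leaves a wrong H or E cell behind, and
that the partition boundary carry is exact even though the engine's running
F vector is usually stale. This package makes both claims *executable*: every
engine is tested cell-for-cell and score-for-score against the scalar
reference, for power-of-two and non-power-of-two lane counts alike.

## The model

For sequences $S_1, S_2$ and substitution matrix $sbt$, with gap open
penalty $\rho$ and extension penalty $\sigma$ (a gap of length $k$ costs
$\rho + k\sigma$):

```
H(i,j) = max( 0, H(i-1,j-1) + sbt(S1[i], S2[j]), E(i,j), F(i,j) )
E(i,j) = max( H(i,j-1) - rho - sigma, E(i,j-1) - sigma )
F(i,j) = max( H(i-1,j) - rho - sigma, F(i-1,j) - sigma )
```

initialized to zero on the boundary row/column; the reported score is the
maximum over H. The striped engine reorders the query into `VL` interleaved
segments (lane `v`, segment `s` holds query position `v*T + s`,
`T = ceil(l/VL)`), computes each subject column assuming F contributes
nothing, then repairs the assumption in the lazy-F loop until a lane-vote
says no cell can change. The partitioned engine additionally hands
`F_first_next = max(H_last - rho - sigma, F_last - sigma)` from each
partition's last row to the next partition's first row, per subject column.

Gap penalties use the field's `"10-2k"` shorthand (open 10, extend 2).
Substitution matrices: built-in BLOSUM62/BLOSUM50 or any NCBI-format score
table file. Scores are reported without statistical significance (no
E-values/Z-values) — ranking is by raw optimal alignment score.

## Worked example

Generate a 5-record synthetic database, make the query a mutated homolog of
record `synth_2`, and search with the partitioned engine at the tuned
defaults (`VL=16`, `PL=256`):

```
$ swsearch-fixtures --n 5 --lengths uniform:80:120 --seed 42 --out demo_db.fasta
wrote 5 records to demo_db.fasta
$ swsearch --query query.fasta --db demo_db.fasta --matrix BLOSUM62 \
           --gap "10-2k" --engine partitioned --vl 16 --pl 256 --topk 3 --seed-check
# self-check ok: top hit synth_2 score 468 confirmed by scalar engine
# engine=partitioned
# matrix=BLOSUM62 gap=10-2k VL=16 PL=256
# cells=42680 elapsed=0.131s gcups=0.000325
rank	subject_id	subject_length	score
1	synth_2	89	468
2	synth_3	111	30
3	synth_4	96	28
```

The homolog's source sequence ranks first with an optimal local alignment
score of 468 — and `--seed-check` re-scores that hit with the scalar
reference engine to confirm the vectorized engine computed the exact score.
`cells` is query length × total subject residues; `gcups` (billions of DP
cell updates per second) is informational and machine-dependent.

The same search is available as a library call:

```python
from swsearch import ScoringScheme, load_matrix, parse_gap_spec, GapPenalty, search, read_fasta

scheme = ScoringScheme(load_matrix("BLOSUM62"), parse_gap_spec("10-2k"))
result = search(read_fasta("query.fasta")[0], read_fasta("demo_db.fasta"),
                scheme, engine="partitioned", VL=16, PL=256, topk=3)
print(result.to_frame())
```

A classic small check, identical from all three engines:

```python
from swsearch import sw_score, striped_sw_score, partitioned_sw_score
scheme = ScoringScheme(load_matrix("BLOSUM50"), GapPenalty(0, 8))
sw_score("HEAGAWGHEE", "PAWHEAE", scheme)          # 28
striped_sw_score("HEAGAWGHEE", "PAWHEAE", scheme, VL=4)   # 28
partitioned_sw_score("HEAGAWGHEE", "PAWHEAE", scheme)     # 28
```

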