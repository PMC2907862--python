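# Methods

## Scope and model

`swsearch` computes optimal local alignment scores of protein sequences
under the affine-gap Smith-Waterman recurrence (see README for the
equations) and ranks database subjects by that score. Traceback/alignment
strings, banded or linear-space variants, and score statistics (E-values,
Z-values) are out of scope: the tool reports scores only. All three engines
compute the *same* integer score by construction; the vectorized engines
exist to make the striped and partitioned formulations — the ones used on
real SIMD/accelerator hardware — testable as ordinary sequential code.

## Scoring

* **Alphabet**: taken from the substitution matrix (BLOSUM built-ins carry
  A..V plus B, Z, X; a `*` row, if present in a matrix file, is dropped).
  One extra *dummy* code is reserved; it scores 0 against everything and is
  used exclusively for padding, which is why padding can never change a
  score. Unknown input characters map to X (lenient default) or raise
  (strict mode).
* **Matrices** are validated square, integral and symmetric; asymmetric
  tables are rejected naming the offending pair. Scores are held as 64-bit
  signed integers; a guard rejects inputs whose worst-case score bound
  exceeds 2^31 − 1 (unreachable for real protein data).
* **Gap penalties**: `"q-rk"` means open q, extend r; a length-k gap costs
  q + k·r and the first gapped cell costs q + r. `extend >= 1` is enforced
  globally — the vectorized engines' fill-value safety argument (below)
  needs strictly decaying F values, and `extend = 0` is rejected rather
  than silently mishandled.

## Scalar reference engine

A literal row-major transcription of the recurrence, numba-compiled for
speed (the compiled code is the same statement of the algorithm; numba only
removes interpreter overhead). Only H is clamped at zero; E and F are plain
signed integers, exactly as the recurrence dictates, so `sw_full` can serve
as a cell-level oracle. Tests cross-check it against Biopython's
`PairwiseAligner` (an independent implementation; `open_gap_score =
−(ρ+σ)`, `extend_gap_score = −σ`) and against a hand-written
minor-diagonal-order evaluation, which also certifies the data-dependency
claim that anti-diagonal scheduling cannot change any table entry.

## Virtualized SIMD lane machine

`simd_model` emulates a fixed-width integer vector of `VL` lanes with
lane 0 the logical rightmost element: leftward shifts (toward higher lane
indices) with explicit fill, all/any lane votes, and saturating add/sub
built from max/min against a configurable score range. The emulation is
sequential, so no synchronization is modeled, and `VL` is any integer
≥ 1 — deliberately wider than the sub-warp sizes real hardware allows,
because engine correctness must not depend on the lane count and
non-power-of-two `VL` widens the test space. With the default 32-bit score
range, saturation is unreachable at the score magnitudes this package
produces, and the saturating ops reduce to plain arithmetic.

## Striped engine and the lazy-F loop

Per subject column: the inner loop walks the `T = ceil(l/VL)` striped
segments computing H from the diagonal term, E, and a postulated `vecF`
that ignores cross-segment vertical gaps; the lazy-F loop then shifts
`vecF` one lane left (wrapping segment T−1 to segment 0, the striped
layout's row adjacency) and re-applies it segment by segment.

Design choices that were genuinely open:

* **E ordering.** E(·, j) is computed at the *start* of column j from the
  finalized column j−1 state, rather than speculatively at the end of
  column j−1. Since E depends only on previous-column values, this makes
  E exactness structural: the lazy loop only ever corrects H. (The
  classical unsigned-saturating formulation computes E at column end and
  must patch it during lazy correction.)
* **Exit vote.** The loop continues while any lane has
  `F > max(H − open, 0)`. An H update is needed iff `F > H`; a larger F can
  still propagate downstream iff `F > H − open`. The clamp at zero mirrors
  the saturating arithmetic of hardware implementations and is essential
  in signed arithmetic: the zero fill shifted into lane 0 at every wrap
  would otherwise keep the vote true wherever `H < open`, and the loop
  would never terminate. It is score-safe because `H >= 0` everywhere and
  an `F <= 0` can neither raise an H nor survive decay with
  `extend >= 1`.
* **Fill values.** The diagonal shift fills lane 0 with the boundary (or
  partition-carried) H; lazy-F shifts fill with 0. Every lazy update is a
  max with a valid lower bound of the true value, so extra iterations are
  harmless; the vote only has to guarantee the loop never stops too early.
* **Termination.** Each lazy visit decays F by `extend >= 1` while H is
  bounded, so the loop terminates without an iteration cap.

Guarantees (all asserted by tests): after finalization, de-striped H and E
equal the scalar tables cell-for-cell for every column; predicate-driven
early exit yields columns identical to exhaustive full correction; scores
are identical across `VL ∈ {1,…,64}` including non-powers-of-two. No
guarantee is made (or asserted) about the raw `vecF` contents — that is
the point of the boundary-carry construction below.

## Partitioned engine and the boundary carry

The query is split into consecutive `PL`-residue partitions (`PL` a
multiple of `VL`; default `PL=256`, `VL=16`, the configuration tuned for
half-warp hardware vectors), each with its own striped profile, aligned
partition by partition. Between partitions, two subject-length arrays are
carried: the previous partition's last-row H per column (exact, feeds the
diagonal), and the next partition's first-row F per column, computed as

    F_first_next(j) = max(H_last(j) − ρ − σ, F_last(j) − σ).

Storing the *next* partition's first-cell F rather than the raw last-cell
F matters because the lazy loop usually exits leaving the running `vecF`
stale. The carry is nevertheless exact in both lazy-F outcomes: when the
loop ran to full correction, the last-cell F is true; when it exited
early, every skipped correction was dominated by the H path, and H_last is
always exact.

One signed-arithmetic subtlety: the raw `vecF` chain is effectively a
*saturated* quantity — negative F chains never cross a lane boundary,
because the wrap happens only while the (zero-clamped) vote holds — so the
raw observed last-cell F can understate truly negative F values that no
score could ever feel. To keep the carried value equal to the true signed
F in *all* regimes, the engine reconstructs the exact last-cell F from its
own exact post-lazy H column via the unrolled recurrence

    F_last(j) = max( max_r [ H(r,j) − ρ − σ − (PL−2−r)·σ ],  F_in(j) − (PL−1)·σ )

(one vectorized max per column; `r` ranges over partition rows above the
last). The raw chain value is still recorded per column, so tests can
demonstrate that it really is stale in early-exit columns while the carry
stays exact. Consistently, the first partition's F boundary is the true
first-row value `−σ`, not 0. E needs no carry at all (it depends only on
same-row cells), which tests confirm at partition-first rows.

## Search driver

Every subject is scored by the selected engine (query profiles and
partition plans are built once per search); results are ranked with stable
ties (database input order), so runs are reproducible. The reported cell
count is query length × total subject residues; GCUPS = cells / seconds /
10^9, timed over scoring only (no file I/O), reported for information and
never asserted in tests. The CLI exits 0 on success, 2 on usage errors, 3
on input-format errors; `--seed-check` re-scores the top hit with the
scalar reference and fails loudly on any mismatch.

## Synthetic data

The fixture generator draws residues i.i.d. from a composition over the 20
standard amino acids — uniform by default (no composition model is implied
by the search algorithm itself; a Swiss-Prot-like frequency table is
available for realism but required by nothing). Homologs are derived by
independent point substitutions (always to a different residue) at a given
rate plus insertion/deletion events started at a given per-position rate
with geometric lengths (p = 0.5, mean 2). Each database record uses an
independent child seed stream, so outputs are byte-reproducible and
insensitive to record count. What this emulates — and what it does not:
i.i.d. sequences have no domain structure, repeats, or biased local
composition, so passing tests certify *algorithmic exactness* of the
engines on arbitrary integer score landscapes (including adversarial
low-complexity inputs, which the test generators add deliberately), not
retrieval sensitivity on real proteomes.

## Test and verification sizes

The randomized equivalence suite uses 500 pairs with lengths 1–300 drawn
across both BLOSUM matrices, three gap penalties, `VL ∈ {1,2,3,4,7,8,16,
32}` and `PL ∈ {VL, 4·VL, 256}`; column-exactness and boundary-carry
properties are each checked over ≥1000 columns, with instrumentation
verifying that both lazy-F outcomes (full correction / early exit) actually
occur so the carry theorem is not vacuously tested. The long-query search
check uses a 5,478-residue query — the scale of the largest real protein
queries the tuned `PL=256`/`VL=16` configuration targets — against a
50-record database with lengths uniform on [100, 300] (typical protein
lengths, ~10k residues total). `scripts/acceptance.py` re-runs scaled versions of the same
computations (400 pairs, ≥1000 columns each) from a single seed.

## Known limitations

* The engines are exact but deliberately un-optimized emulations; GCUPS on
  a CPU interpreter is orders of magnitude below hardware implementations
  of the same algorithms.
* Raw scores are length- and composition-biased; without E/Z statistics,
  cross-query comparisons of scores are not meaningful.
* DNA scoring, PSSMs, and match/mismatch schemes are unsupported by
  design; the alphabet always comes from a protein substitution matrix.
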