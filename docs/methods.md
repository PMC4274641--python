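# Methods

This note records the model implemented by `ffgc`, the algorithmic and
numerical choices made, the semantics of every user-facing parameter, and the
known limitations. Empirical statements are restricted to what the test suite
and `scripts/acceptance.py` actually compute.

## Model and definitions

An indeterminate string `S` is a sequence of non-empty character sets;
`|S|` is its length and `‖S‖ = Σᵢ |S[i]|` its cardinality. `C(S[i,j])` is the
union of the position sets over the 1-based inclusive interval `[i,j]`.

For intervals `[i,j]` of `S` and `[k,l]` of `T`, with
`C = C(S[i,j]) ∩ C(T[k,l])`:

- **weak common interval pair**: every position of both intervals intersects
  `C`;
- **indel**: a position inside either interval whose set has empty
  intersection with `C`; an **approximate** weak pair tolerates at most `δ`
  indels in total over both intervals;
- **C-closed interval**: both borders intersect `C` and neither neighbour
  does (maximality on both sides);
- **mutually-closed pair**: `[i,j]` is `C(T[k,l])`-closed on `S` *and* `[k,l]`
  is `C(S[i,j])`-closed on `T`. Note that closedness is taken with respect to
  the partner interval's full character set, not the intersection `C`; the
  two notions differ on indeterminate strings and the former is the one that
  makes mutual closedness symmetric and the candidate enumerations complete.

Only mutually-closed pairs with `C ≠ ∅` are reported. Counting arguments give
at most `n·m` reported weak pairs and at most `(δ+1)²·n·m` approximate pairs;
both bounds are asserted over the randomized test battery.

### Index-mapping reduction

All solvers operate on the index string `I_S = {1}…{n}` and the index mapping
`T_S` with `T_S[y] = {x : S[x] ∩ T[y] ≠ ∅}`, or `{∞}` when empty. The
sentinel `∞` is ordered above every character, matches nothing, and never
enters a common set. Weak status, indel counts, mutual closedness and
empty-`C` status are identical between `(S, T)` and `(I_S, T_S)` interval for
interval; the test suite checks this equivalence exhaustively on randomized
instances (`tests/test_core.py::TestReductionEquivalence`). Reported pairs are
restated over the original alphabet by re-classifying their coordinates on
`(S, T)`.

Derived structures: the `i`-reduced string `T_S^i[y] = min {c ∈ T_S[y] : c ≥ i}`
(else `∞`); the min-rank interval of character `j` at `y` (maximal run of
entries ≤ `j`); the min-rank distance `d(k,l) = max T_S^i[k..l]`; and the
rank-nearest successor (position of the next character `j+1` with minimal
min-rank distance, leftmost on ties, none if the minimum is `∞`).

## Algorithms

**Oracle** (`ffgc.oracle`). Literal evaluation of the definitions on all
`O(n²m²)` interval pairs, vectorized with numpy (interval character sets via
cumulative unions, indel counts via prefix sums, closedness via padded
boolean occurrence matrices). A second, loop-based transcription of the
definitions lives in the test suite and cross-checks the vectorized oracle on
small instances, so the reference itself is verified by two independent
routes.

**WCII** (δ = 0). For each left bound `i`, paths of rank-nearest successors
are walked level by level (one level per right bound `j`), maintaining for
each reached position the antichain of minimal path bounds. A pair
`([i,j], [k,l])` is reported when the min-rank interval `[k,l]` of `j` at the
current position encloses some path bound and neither `i−1` nor `j+1` occurs
in `T_S[k..l]`. Min-rank intervals are maintained incrementally with a
union-find over activation levels. Design choice: paths arriving at the same
position are pruned to the antichain of bounds-minimal paths. This rule is
provably lossless (a path whose bounds contain another's can never report a
pair the tighter one does not, as both share all future successors), and the
implementation asserts that each `(position, character)` pair is processed at
most once per left bound.

**AWCII** (any δ). For each `(i, j)` and each occurrence `y` of `j`, at most
`(δ+1)²` candidate intervals are generated: for each left budget the farthest
left endpoint whose set meets `[i,j]` reachable with that many interior
indels, combined with the symmetric right endpoints. A candidate `[k,l]` is
reported when `i` occurs in it, neither `i−1` nor `j+1` occurs in it, and
(missing characters of `[i,j]`) + (interior indels) ≤ δ. Character
containment and closedness queries are answered with binary searches over
per-character position lists. Right bounds are abandoned as soon as more than
δ characters of `[i,j]` are globally absent from `T_S`.

**ACSI** (any δ). For each occurrence of the left bound `i` and each
candidate right bound `j`, a recursive EXTEND procedure grows the window
while neighbours meet `[i,j]`, aborts when `i−1` or `j+1` enters the window,
reports when the missing characters fit the remaining budget and both `i` and
`j` occur in the window, and recurses across indel gaps on both sides with
the budget reduced by the gap length. Each recursive call consumes budget, so
the depth is bounded by δ + 2 (asserted). A sound pre-scan discards right
bounds that cannot occur in the maximal window reachable from the seed;
`prune=False` disables it and must produce identical output (tested).

All three solvers are exact; `tests/test_acceptance.py` verifies exact result
set equality against the oracle for δ ∈ {0,1,2,3} over a fixed battery of
215 seeded instances with `n, m ≤ 25` (210 random, 5 adversarial fixtures
with identical-set runs, reversals and near-disjoint alphabets).

## Family-free layer

Chromosomes are sequences of unique gene identifiers; `σ` is a sparse
symmetric non-negative similarity (entries given in both orientations are
averaged; absent means 0). `B_A[y]` lists the `A`-positions with `σ > 0` to
gene `y` of `B`. Parameters of `discover_clusters` / `compare_genomes`:

- `delta` (δ ≥ 0): maximum indels per reported pair; `wcii` requires δ = 0.
- `min_size` (s ≥ 1, default 3): minimum positions per interval on both sides.
- `f` ∈ [0,1]: stringency. Edge `(a,b)` is kept iff
  `σ(a,b) ≥ f · min(best(a), best(b))` (rule `"min"`, default) or with `max`
  aggregation (rule `"max"`). `f = 0` keeps all positive edges; the kept set
  shrinks monotonically in `f`.
- `algorithm`: `wcii`, `awcii` or `acsi` (default); all produce identical
  cluster sets at matching parameters.

Scores: `μ(x → R) = max_{y∈R} σ(x,y) / max_{z∈B} σ(x,z)` (0 when the gene has
no positive similarity into the partner genome), and the pair score sums `μ`
over both sides. Consequences asserted in tests: `0 ≤ μ ≤ 1` with `μ = 1`
exactly when a globally best hit lies inside the interval,
`score ≤ |L| + |R|`, invariance under global rescaling of `σ`, and side-swap
symmetry of the discovered coordinate sets. With family-indicator
similarities (σ = 1 iff same family) the pipeline reduces to classic
mutually-closed common-interval detection on the family strings; this is
checked against a direct set-equality oracle. Multi-chromosome genomes are
compared chromosome pair by chromosome pair; clusters never span chromosomes.

## Synthetic generators

All generators are driven by a single integer seed through Python's
`random.Random`; identical configurations reproduce identical datasets.

- `random_indeterminate_pair`: position sets are uniform samples of the
  configured size range (default 1–3) from a shared alphabet (default 8
  characters); `disjoint_alphabets=True` gives the two strings disjoint
  alphabets, producing all-`∞` index mappings.
- `planted_cluster_dataset`: two genomes (default 40 genes each) with
  `n_clusters` (default 3) planted blocks of `cluster_size` (default 4)
  genes. Block genes are matched one-to-one with similarities drawn from
  `cluster_score_range` (default 0.5–1.0), making them mutual best hits.
  `cluster_indels` extra genes per block are inserted strictly inside the
  `B`-side block with no similarity to anything, so the planted pair has
  exactly that many indels and needs a matching δ to be discovered. Blocks
  are placed uniformly with at least one gene between consecutive blocks, and
  the `B`-side block order is shuffled.
- **Noise semantics**: `noise_rate` is the number of spurious similarity
  edges per gene; `round(noise_rate · (|A| + |B|) / 2)` random non-planted
  gene pairs receive scores from `noise_score_range` (default 0.05–0.2),
  strictly below the cluster scores so best hits are never displaced. Noise
  harms discovery only by breaking closedness near a block boundary —
  mirroring the effect of spurious similarities in real data. These defaults
  are the study conditions for the recovery checks: 100% recall without
  noise, and recall ≥ 95% over 50 fixed-seed replicates at `noise_rate =
  0.05`.
- `random_family_genomes`: uniform family labels (default 8 families) with
  the indicator similarity, used for the reduction and symmetry checks.

## Numerical choices

- Characters are arbitrary hashable values; index-mapping characters are
  Python ints and `∞` is `math.inf`, so ordering comparisons are exact. No
  floating-point arithmetic enters any combinatorial predicate.
- Scores are IEEE doubles; `μ` is a single division by a positive maximum.
  Score-based assertions in tests compare with relative tolerance ~1e-6;
  coordinate assertions are exact.
- The oracle uses `int16` prefix sums, sufficient for `n, m ≤ 25` batteries
  (counts ≤ 50) with ample margin.

## Limitations

- The oracle is `O(n²m²·(n+m+|Σ|))` in time and memory and is meant for
  verification at battery scale (`n, m ≲ 60`), not production use.
- AWCII is quadratic in `n` per seed position in the worst case; ACSI is the
  recommended solver for genome-scale inputs.
- Reported clusters from overlapping or nested genomic segments are not
  post-processed (no merging, no containment filtering); consumers see every
  mutually-closed pair above the size threshold.
- The stringency filter and score use each gene's global best hit within the
  supplied similarity table; genes missing from the table simply contribute
  `μ = 0`.
- Statistical significance of discovered clusters is out of scope; scores
  rank candidates but carry no p-value semantics.
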