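# ffgc — family-free gene cluster discovery via weak common intervals

`ffgc` detects conserved gene clusters between two genomes **without assigning
genes to families first**. Raw pairwise gene similarities (e.g. normalized
reciprocal BLAST scores) turn one genome into an *indeterminate string* over
the positions of the other; candidate clusters are then the mutually-closed
(approximate) weak common intervals of that representation. The package
provides three exact discovery algorithms, a brute-force oracle used to verify
them, a scoring and filtering layer for the genomic use case, synthetic data
generators, plain-TSV file formats, and a command-line interface.

## The model

An **indeterminate string** `S` of length `n = |S|` is a sequence of non-empty
character sets over an alphabet Σ; its **cardinality** `‖S‖ = Σᵢ |S[i]|` is
the total element count. `C(S[i,j])` denotes the union of the position sets of
the substring `S[i]…S[j]`. All coordinates are 1-based and inclusive.

Given two indeterminate strings `S`, `T` and intervals `[i,j]` in `S`, `[k,l]`
in `T`, let `C = C(S[i,j]) ∩ C(T[k,l])`:

- `([i,j], [k,l])` is a **weak common interval pair** if every position of
  both intervals intersects `C`.
- It is an **approximate weak common interval pair** with at most `δ`
  **indels** if at most `δ` positions (counted over both intervals) have empty
  intersection with `C`.
- An interval is **C-closed** if both of its border positions intersect `C`
  and neither neighbouring position does. A pair is **mutually closed** when
  `[i,j]` is `C(T[k,l])`-closed on `S` and `[k,l]` is `C(S[i,j])`-closed on
  `T`. Only mutually-closed pairs with non-empty `C` are reported; the number
  of such weak pairs is at most `n·m`, and at most `(δ+1)²·n·m` in the
  approximate case.

Discovery runs on an equivalent reduced instance: the **index string**
`I_S = {1}{2}…{n}` and the **index mapping** `T_S`, where `T_S[y]` is the set
of positions `x` of `S` with `S[x] ∩ T[y] ≠ ∅` (or `{∞}` if none). Weakness,
indel counts and mutual closedness transfer interval-for-interval between
`(S, T)` and `(I_S, T_S)`.

**Family-free layer.** Each chromosome is a string of unique gene identifiers;
a symmetric similarity `σ ≥ 0` between genes of genomes `A` and `B` induces
the index mapping `B_A` (position `y` lists the `A`-positions with positive
similarity to gene `y` of `B`). Gene clusters are the mutually-closed
(approximate) weak common intervals of `(I_A, B_A)` with at least `s`
positions per side. Each reported pair gets the best-hit score

```
score(L, R) = Σ_{x ∈ L} μ(x → R)  +  Σ_{y ∈ R} μ(y → L),
μ(x → R)    = max_{y ∈ R} σ(x, y) / max_{z ∈ B} σ(x, z)   (0 if no positive σ),
```

so `0 ≤ μ ≤ 1`, `score ≤ |L| + |R|`, and the score is invariant under global
rescaling of σ. An optional **stringency filter** `f ∈ [0,1]` discards edges
with `σ(a,b) < f · min(best(a), best(b))` before discovery.

### Algorithms

| name | problem | idea |
| --- | --- | --- |
| `wcii` | δ = 0 | per left bound `i`, walk rank-nearest-successor paths through `T_S` and report min-rank intervals that enclose the path bounds |
| `awcii` | any δ | per `(i, j)` and seed occurrence of `j`, enumerate ≤ (δ+1)² budget-bounded candidate intervals |
| `acsi` | any δ | per seed occurrence of `i`, recursive EXTEND: grow, abort on border characters, jump indel gaps |

All three are **exact** and verified against the brute-force oracle
(`ffgc.oracle.enumerate_bruteforce`), which applies the definitions to all
O(n²m²) interval pairs.

## Worked example

`S = {a,d,g}{c}{a,d}{e,f}{b}{c,g}` and `T = {c}{a,d}{g}{b}{e}`:

```python
from ffgc import IndeterminateString, index_mapping, wcii, awcii

S = IndeterminateString([{"a","d","g"}, {"c"}, {"a","d"}, {"e","f"}, {"b"}, {"c","g"}])
T = IndeterminateString([{"c"}, {"a","d"}, {"g"}, {"b"}, {"e"}])

print("len(S) =", len(S), " cardinality =", S.cardinality())
print("C(S[2,4]) =", sorted(S.character_set(2, 4)))
print("T_S =", index_mapping(S, T))

for pair in wcii(S, T):
    print(pair.coords(), sorted(pair.common_set), "indels:", pair.indels)
```

prints

```
len(S) = 6  cardinality = 11
C(S[2,4]) = ['a', 'c', 'd', 'e', 'f']
T_S = IndexMapping({2,6}{1,3}{1,6}{5}{4}, n=6)
(1, 1, 2, 3) ['a', 'd', 'g'] indels: 0
(1, 3, 1, 3) ['a', 'c', 'd', 'g'] indels: 0
(1, 6, 1, 5) ['a', 'b', 'c', 'd', 'e', 'g'] indels: 0
(2, 2, 1, 1) ['c'] indels: 0
(3, 3, 2, 2) ['a', 'd'] indels: 0
(4, 4, 5, 5) ['e'] indels: 0
(4, 5, 4, 5) ['b', 'e'] indels: 0
(4, 6, 3, 5) ['b', 'e', 'g'] indels: 0
(5, 5, 4, 4) ['b'] indels: 0
(5, 6, 3, 4) ['b', 'g'] indels: 0
(6, 6, 1, 1) ['c'] indels: 0
(6, 6, 3, 3) ['g'] indels: 0
```

Allowing one indel and requiring at least two positions per side
(`awcii(S, T, delta=1, min_size=2)`) adds exactly one pair:
`(5, 6, 1, 4) ['b', 'c', 'g'] indels: 1`, which absorbs the unmatched
position `T[2] = {a,d}` inside `T[1..4]`.

### Command line

```bash
ffgc synth --seed 7 --noise 0 --out-dir demo   # planted dataset + ground truth
ffgc discover demo/orders_a.tsv demo/orders_b.tsv demo/similarity.tsv -o demo/clusters.tsv
```

prints `9 clusters written to demo/clusters.tsv`; the top rows recover all
three planted clusters exactly (compare `demo/truth.tsv`):

```
chrA  loA  hiA  chrB  loB  hiB  size_A  size_B  indels  score   genesA           genesB
chr1  5    8    chr1  8    11   4       4       0       8.0000  a5,a6,a7,a8      b8,b9,b10,b11
chr1  16   19   chr1  2    5    4       4       0       8.0000  a16,a17,a18,a19  b2,b3,b4,b5
chr1  23   26   chr1  31   34   4       4       0       8.0000  a23,a24,a25,a26  b31,b32,b33,b34
```

`ffgc wci` and `ffgc oracle` expose the string-level solvers; see
`ffgc --help` for all options and `docs/methods.md` for format details.

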