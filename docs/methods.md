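# Methods

## The model

DNA storage systems encode binary data into synthetic DNA. Synthesis and
sequencing chemistry constrain which sequences are usable: the GC content
should sit near 50%, long homopolymer runs (AAAA…) inflate error rates, and
technology- or application-specific motifs (restriction sites, primer
targets) must not occur at all. This package enumerates, for a fixed word
length `n`, *every* word satisfying such constraints, and turns the result
into a codebook for a lexicographic binary→DNA code.

The central object is the matrix chaos-game representation (mCGR): a
`2^n × 2^n` grid whose cells are in bijection with the `4^n` DNA words of
length `n`. Each nucleotide owns one quadrant of the 2×2 unit cell
(default layout `[[A,T],[G,C]]`; the alternate `[[A,C],[G,T]]` is provided
because the two orderings produce different GC patterns). A word's cell is
obtained by interleaving its characters' `(row_bit, col_bit)` pairs: bit
`i` of row and column belongs to character `i+1` counted from the start of
the word. The first character therefore controls the finest subdivision
and the last character the coarsest quadrant — every quadrant shares its
final letter, which is the self-similarity that makes constraint
propagation a fractal recursion. The inverse mapping (grid cell → word) is
a bit-deinterleave, so allowed words are recovered from coordinates without
storing any strings.

### Constraint propagation (tile + stretch + add)

A forbidden motif of length `L` starts as a single 1 at its own cell in the
order-`L` grid. One doubling step to order `n+1` uses two sparse maps that
mirror the Kronecker products with the 2×2 all-ones matrix:

* tiling (`1 ⊗ M`): entry `(r, q)` reappears at `(r + b·2^n, q + c·2^n)`
  for `b, c ∈ {0,1}` — the word gains one arbitrary character at the end;
* stretching (`M ⊗ 1`): entry `(r, q)` reappears at `(2r + b, 2q + c)` —
  the word gains one arbitrary character at the start.

**Counting convention.** Tiling and stretching the *same* count matrix at
every step counts derivation paths, not occurrences: an occurrence strictly
inside a longer word is reached once per interleaving of prepend/append
steps (one `CC` inside `ACCA` would be counted twice). The flagged *set*
is unaffected, which is all a 0/1 formulation needs, but this package keeps
exact counts. It therefore carries a companion suffix indicator `S`
(cells of words that *end* with the motif) and iterates

    S^(n+1) = stretch(S^n)
    M^(n+1) = tile(M^n) + S^(n+1)

i.e. occurrences of the extended word = occurrences of its length-`n`
prefix + one more if the appended character completes the motif at the end.
On the first step from the motif's own order this coincides with the plain
tile+stretch+add; at every order the count at a cell equals the number of
possibly-overlapping occurrences of the motif in that cell's word (verified
exhaustively against string scans for all motifs of length ≤ 4 up to
`n = 8`). Matrices for several motifs are combined by entrywise addition
(both components add — the operator is linear).

Only affected cells are stored (a dict keyed by `(row, col)`); the allowed
set is the complement and is never materialised sparsely. Homopolymer
limits are not a separate mechanism: a maximum run of `r` is exactly the
four forbidden motifs `X^(r+1)`, `X ∈ {A,C,G,T}` (forbidding the shortest
overlong run forbids all longer ones).

### GC content

GC constraints use a dense integer matrix built by the same doubling
recursion, `D^n = 1^(2^(n-1)) ⊗ D^1 + D^(n-1) ⊗ 1^2`, whose 2×2 generator
holds a 1 in each quadrant owned by G or C (`[[0,0],[1,1]]` for the default
layout, `[[0,1],[1,0]]` for the alternate). The cell of a word then holds
its G+C count; under the default layout this equals the bit count of the
row index, which serves as the closed-form oracle in the tests. Bounds are
inclusive and evaluated on exact rationals (`gc_min ≤ k/n ≤ gc_max`).
Float inputs are interpreted through their decimal representation, so a
bound written `0.4` means exactly 2/5 — the nearest binary float is
slightly larger and would silently exclude a GC count of exactly 40%.
A fixed ("strong") GC content is expressed as `gc_min = gc_max`.

### Hamming matrices

The distance from one word `s` to all words of the same length follows
`H(s)^n = 1^2 ⊗ H(s)^(n-1) + B^1(s_n) ⊗ 1^(2^(n-1))`, with `B^1(x)` the
2×2 single-character mismatch matrix (0 at `x`'s quadrant, 1 elsewhere) and
`s_n` the last character. The all-pairs table uses the 4×4
all-ones-minus-identity generator in the same doubling scheme. The raw
Kronecker recursion indexes words by their base-4 character digits
(coarse → fine); that index is incompatible with the grid coordinate index
`k = row·2^n + col` used everywhere else, so the table is computed in the
recursion's natural index and then permuted. This keeps both properties:
the recursion is the construction, and the table row of word `s` equals the
flattened single-word grid of `s`.

### Codebook assembly and concatenation safety

`build_codebook` sums the motif matrices of all forbidden motifs (explicit
plus homopolymer), masks the dense GC-allowed grid with the flagged cells,
back-calculates the surviving coordinates to sequences in a vectorised
pass, and sorts lexicographically (A<C<G<T, plain ASCII order; any fixed
order yields the same code rate and a self-consistent codec).

Code words drawn independently can still create a forbidden motif across a
junction. The concatenation-safe filter removes, for each motif `m` of
length `L` and each `k` from `ceil(L/2)` to `L−1`, every word whose
length-`k` suffix equals `m[:k]` or whose length-`k` prefix equals
`m[L−k:]`. This suffices: a junction occurrence splits `m` into a suffix
part of length `k` and a prefix part of length `L−k`, and
`max(k, L−k) ≥ ceil(L/2)`, so at least one participant was removed. The
junction property is tested exhaustively over all ordered pairs at small
`n`. `ceil` (not `floor`) is fixed by the canonical homopolymer example:
for the run `AAA`, words ending with `AA` and words starting with `AA` are
removed. Both removal conditions are a union; requiring both would break
the junction guarantee.

The code rate is `log2(|C|)/n` bits per nucleotide (maximum 2).

### Lexicographic codec

The sorted codebook carries `b = floor(log2 |C|)` bits per word (computed
by integer bit length, never floating point); only the first `2^b` words
are addressable. The bit stream is MSB-first at both byte and block level;
the final partial block is zero-padded on the right. Termination is not
part of the published scheme, so the package prepends a 64-bit big-endian
payload-bit-length header carried through the same block mechanism
(`with_header=False` is available for worked examples and rate
experiments). Decoding splits the DNA into `n`-mers, maps them through a
word→index hash map, rejects unknown words (with the nucleotide offset),
indices ≥ `2^b` (the encoder never emits them), and declared lengths that
exceed the bits present. The realized rate reported is payload bits over
*total* nucleotides, so the header counts against it; it approaches `b/n`
as the payload grows. Whether the published end-to-end figure includes
framing overhead is not stated, so the asymptotic `b/n` and the realized
rate are reported separately.

## Defaults and parameters

| parameter | default | why |
| --- | --- | --- |
| layout | `[[A,T],[G,C]]` | the standard corner assignment; alternate preset `[[A,C],[G,T]]` |
| word length cap | 12 (hard cap 14 with override) | full 4^n enumeration; ~12 nt is the practical limit, and beyond 10 nt the rate gain is marginal |
| GC bounds | unset | inclusive, exact-rational when set |
| max homopolymer | unset | expressed internally as 4 motifs of length r+1 |
| pairwise Hamming cap | n ≤ 6 | dense 4^n × 4^n table |
| single-word Hamming cap | n ≤ 10 | dense 2^n × 2^n grid |
| dense export cap | n ≤ 8 | CSV/PGM stay human-sized |
| codec header | 64-bit big-endian bit length | self-delimiting streams; off for experiments |

## Benchmark conditions

The headline configuration is word length 10, GC 40–60% inclusive (counts
4–6 of 10), homopolymer runs ≤ 3, no additional motifs, with the
concatenation-safe filter. The enumeration yields 653,896 words, pruning
leaves 395,272, hence code rate log2(395272)/10 = 1.8592 and block size 18,
so a large payload encodes at 18/10 = 1.8 bits/nt. The package reports the
code rate as computed; note that the pruning rule as documented above (its
only self-consistent reading, matching the `AAA` → remove-`AA`-at-either-end
example) determines the 395,272 count exactly, and the suffix-only pruning
variant it improves upon gives 508,080 (rate 1.90) under the same
constraints.

## What the synthetic data does and does not emulate

The fixture generator produces seeded random motif sets, the corresponding
codebooks, and seeded random byte payloads whose default sizes span the
300 kB–1.7 MB range of the original jpg benchmark corpus. Payload *content*
is irrelevant to a lossless fixed-rate codec — random bytes exercise it
fully — but the fixtures do not emulate synthesis/sequencing error
processes (the code here contains no error correction by design), nor real
motif catalogues from specific platforms. Passing tests therefore
demonstrate combinatorial and codec correctness, not wet-lab viability of
any particular codebook.

## Numerical choices and degenerate inputs

* All coordinate arithmetic is integer; the classic CGR uses
  `fractions.Fraction`, so denominators divide `2^k` exactly.
* Contradictory constraint sets produce an *empty* codebook with a warning,
  not an error (an empty result is informative); the code rate and codec
  then refuse to run on fewer than 2 words.
* Motifs longer than the word length cannot occur and are skipped during
  enumeration; they still participate in concatenation-safety only if a
  codebook explicitly passes them (the filter rejects motifs longer than
  the word length).
* Matrix extension aggregates duplicate cells with `np.unique` on packed
  64-bit keys; at the default caps all indices fit comfortably.

## Known limitations

* Full enumeration is exponential in `n`; the caps are guards, not
  optimisations. Codebooks beyond `n = 12` need a different algorithmic
  approach (e.g. per-prefix dynamic exclusion, which the grid structure
  would support but which is out of scope here).
* Minimum-pairwise-distance codebook *selection* is not implemented; the
  Hamming module computes distances only.
* Reverse-complement constraints and thermodynamic measures (melting
  temperature, secondary structure) are out of scope.
* The codec provides no error correction; it is a constrained-code layer
  intended to sit beneath any ECC.
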