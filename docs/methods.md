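# Methods

## Model and procedure

`minicount` counts the exact multiplicity of every k-mer (or canonical
k-mer) of a set of sequencing reads. It assumes reads over the alphabet
{A,C,G,T,N,...}: runs of non-ACGT symbols split a read into fragments, and
only fragments of length ≥ k contribute windows. No quality filtering or
abundance thresholding is applied by default (a `min_count` output filter
exists as plumbing).

The computation has two phases.

**Phase one — distribution.** Every fragment is scanned once. For each
k-mer window the *minimizer* is the m-mer occurrence of minimal rank under
the selected total ordering; in canonical mode the minimum is taken over
the m-mer windows of both strands, with ties preferring the forward
strand, then the leftmost position. Minimizer identity is positional: a
super-mer ends exactly when the minimal occurrence (position + strand)
moves, even if the new occurrence spells the same m-mer. This makes the
decomposition maximal and makes window conservation exact: the k-mer
windows of the super-mers, concatenated in order, equal the fragment's
window scan. Super-mers are appended to bin file `rank % F`. Records are
bit-exact (u16 length, u32 rank, 2-bit packed bases, little-endian), so a
rerun produces byte-identical bins.

The bin-assignment map is a plain modulus rather than a mixed integer
hash: with the default F = 512 dividing 4^m it spreads ranks perfectly
evenly (enumerating all 4^7 ranks gives max/mean occupancy 1.0), whereas a
scrambling hash would add ~60% skew at these bin sizes with no
correctness benefit. Frequency-aware balancing driven by runtime
throughput measurements is deliberately out of scope.

**Phase two — counting.** Bins are processed in file order. The bin's
k-mer total n is known from the phase-one manifest. If n exceeds the table
budget T_max the bin is processed in p = ⌈n/T_max⌉ passes, pass i keeping
the k-mers with partHash(x) ≡ i (mod p); within a pass, k-mers are routed
to N logical shard tables by partHash(x) mod N, so all occurrences of a
k-mer meet in one table. Each shard table is sized ⌈α·n_shard/β⌉.
Insertion probes slots (h₀(x) + i(i+1)/2) mod |T| for i < i_max; a probe
sequence that sees only foreign keys fails, and the k-mer spills with its
multiplicity to a file-backed failure buffer. After the pass the buffer is
drained into a dedicated power-of-two table (first with a doubled probe
cap, then, on repeated failure, doubling capacity with an exhaustive probe
schedule, which must terminate). Exactness therefore never depends on the
probing ever succeeding.

The per-bin implementation deduplicates each pass/shard's k-mers and
inserts every distinct key once with its multiplicity. This is equivalent
to inserting occurrences one by one: a slot on a key's probe path can
never become empty again, and can never come to hold the key unless the
key was inserted, so success/failure is all-or-nothing per key and
counters are additive. The public `CountTable.insert` keeps per-occurrence
semantics for direct use.

## Hash functions

Two independent functions, with deliberately different cost contracts:

* `probe_hash(x, i)` folds each 64-bit block (32 bases) of the packed
  k-mer through a splitmix64 finalizer chain (constants fixed in code),
  then adds the triangular offset i(i+1)/2. Cost is linear in k. For
  power-of-two capacities the triangular schedule visits every slot;
  capacities produced by the sizing formula are *not* rounded to powers of
  two (see below), so full coverage is only guaranteed for the drain
  tables, which are power-of-two by construction.
* `part_hash(x)` mixes exactly the first four 16-bit blocks (8 bases
  each), giving a constant-cost value in [0, 2^16) used for both pass
  selection and sharding. Independence from the probing hash is checked
  by a chi-square test in the suite.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | required | k-mer length; any k ≥ 1 (slot key uses ⌈2k/64⌉ words) |
| m | 7 | minimizer length; larger m → more, shorter super-mers |
| ordering | `kmc2` | minimizer ranking strategy |
| canonical | on | merge each k-mer with its reverse complement |
| F | 512 | temporary bin files |
| memory_cap | 1 GiB | T_max = memory_cap / slot bytes (key words + u32 counter) |
| i_max | 30 | probe cap per insertion (≈ log₂ n for realistic n) |
| β | 0.4 | target table fill level; lower = fewer probes, more memory |
| α₀ | 0.5 | bootstrap distinct/total ratio for the first bin |
| shards N | 1 | logical tables per pass; results invariant to N |

α is refreshed to the observed d/n after each non-empty bin. Counters
saturate at 2^32 − 1. Output is sorted lexicographically so identical
inputs yield byte-identical files.

Orderings follow their published definitions: `cgat` (lexicographic
C<G<A<T), `roberts` (complement even positions, then C<A<T<G), `kmc2`
(A<C<G<T with m-mers starting AAA or ACA demoted after all others —
exactly the named exceptions, nothing more), `random` (seeded
permutation), and `dfp(p)` (ascending sampled frequency, re-sorted by
distance to pivot position 4^m·p, lexicographic ties). A plain `lex`
ordering is included as the baseline used in worked examples. `dfp`
samples frequencies from the first 100,000 read fragments — cheap and
deterministic given input order.

## Synthetic data

The simulator draws a uniform random genome, then fixed-length reads from
uniform positions and strands with independent substitution errors
(default 1%) and N-masking (default 0.1%), at coverage 10 of a 100 kb
genome — large enough that stressed configurations exercise multi-pass
splitting and failure draining. It does not model indels, coverage bias,
repeats or quality-correlated errors, so passing tests demonstrate
counting correctness and robustness of the machinery, not instrument
realism; correctness on real data follows because the counter never
inspects anything but the base strings.

## Numerical and design choices

* Base codes A=0, C=1, G=2, T=3 make integer order equal lexicographic
  order, so canonicalization is a word-vector comparison.
* Table capacity is exactly ⌈α·n/β⌉ (granularity 1). Rounding to powers
  of two would guarantee probe-schedule coverage but would make the
  realized fill level drift anywhere in (β/2, β]; the expected-fill
  contract was judged more important, and exactness is carried by the
  drain path regardless.
* Ties in minimizer rank cannot occur between different m-mer values
  (ranks are bijective); between occurrences, leftmost wins, forward
  strand before reverse.
* Degenerate inputs: empty bins produce empty output; n = 0 leaves α
  unchanged; i_max = 0 makes every insertion fail (and is therefore not a
  supported operating point, though the drain still yields exact counts).
* Reported test problem sizes (100 kb genome, coverage 10, k up to 200,
  60 k-key fill experiments) were chosen as the smallest sizes that
  exercise every code path — multi-pass, spilling, sharding, both strand
  modes — while keeping the whole suite comfortably interactive.

## Known limitations

* Single-process, sequential phases; shards are logical, not threads.
  Concurrency is an implementation freedom the contracts deliberately
  leave open.
* The u16 record length caps super-mers at 65,535 bases; reads above that
  length would need record chunking.
* GPU tables, throughput-adaptive shard rebalancing and the sort-compress
  counting alternative are out of scope.
* `evaluate_ordering` keeps exact per-minimizer distinct sets in memory;
  it is meant for desk-scale inputs, not full genomes.
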