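# minicount

Exact k-mer counting for DNA sequencing data via minimizer-partitioned,
two-phase hashing — a library with a thin command-line front end.

Counting the occurrences of every length-k substring (k-mer) of a read set
is a primitive behind genome assembly, error correction and abundance
estimation. Whole data sets rarely fit in memory, so `minicount` follows
the disk-based two-phase design used by the fastest CPU counters:

1. **Distribution.** Each read fragment is decomposed into *super-mers*:
   maximal substrings whose k-mer windows all share the same *minimizer*
   (the m-mer, m ≪ k, that is minimal under a chosen total ordering of all
   4^m m-mers). Super-mers sharing a minimizer are appended to the same
   temporary bin file, so all occurrences of any k-mer land in one bin and
   the bins can be counted independently.
2. **Counting.** Each bin is re-read, split back into k-mers (canonicalized
   to min(x, revcomp(x)) unless disabled) and inserted into an
   open-addressing hash table with quadratic probing. Probing stops after
   i_max trials; failed k-mers spill to failure buffers that are drained
   exactly afterwards. Tables are sized |T| = α·n/β, where n is the bin's
   k-mer total (known from phase one), α the estimated distinct/total
   ratio carried over from the previous bin, and β the target fill level.
   A bin with n > T_max is processed in p = ⌈n/T_max⌉ passes, pass i
   taking the k-mers with partHash(x) ≡ i (mod p).

Counts are exact for every configuration — stress knobs change performance,
never results — and k is unbounded in principle (tested to k = 200).
Six minimizer orderings are provided (`lex`, `cgat`, `roberts`, `kmc2`,
`random`, `dfp`), plus an evaluation module scoring them by total
super-mer count versus maximal distinct k-mers per minimizer.

## Worked example

The string `CAAGAACAGTG` at k = 4, m = 3 under the plain lexicographic
ordering (A<C<G<T, forward strand):

```python
from minicount import build_ordering, encode, super_mers

ordering = build_ordering("lex", 3)
for sm in super_mers(encode("CAAGAACAGTG"), 4, ordering, canonical_mode=False):
    print(sm.bases, sm.minimizer_rank, sm.kmer_count)
```

```
CAAGA 2 2
AGAA 8 1
GAACA 1 2
ACAG 4 1
CAGTG 11 2
```

Five super-mers — `CAAGA, AGAA, GAACA, ACAG, CAGTG` — whose window counts
(2+1+2+1+2) recover all 8 k-mer windows of the string exactly once each.

End-to-end, from the shell:

```sh
minicount simulate -o reads.fastq --genome-length 20000 --coverage 5 --seed 7
minicount count reads.fastq -o counts.tsv -k 25
```

prints a run report such as

```
k=25 ordering=kmc2 canonical=True
total k-mers     74181
distinct k-mers  35187
written (>= min) 35187
passes used      512
failures spilled 102
mean probes      1.463
```

and writes one `<k-mer>\t<count>` line per distinct canonical 25-mer,
sorted, with exact counts (`examples/count_simulated_reads.py` verifies a
stressed version of this run against a brute-force dictionary oracle).
The `examples/` directory holds one short narrative script per capability.

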