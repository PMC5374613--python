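"""Scoring minimizer ordering strategies on a simulated read set.

An ordering is judged by two opposing metrics: the total number of
super-mers (less is less temporary disk) and the maximal number of distinct
k-mers sharing one minimizer (less is a flatter bin-size distribution).
The distance-from-pivot family interpolates between favouring rare
minimizers (pivot 0) and frequent ones (pivot 1).
"""

import tempfile
from pathlib import Path

from minicount import SimSpec, build_ordering, compare_orderings, simulate_genome, simulate_reads
from minicount.dna_codec import read_sequences
from minicount.minimizers import sample_frequencies

tmp = Path(tempfile.mkdtemp())
spec = SimSpec(genome_length=50_000, read_length=100, coverage=3.0, seed=23)
reads_path = simulate_reads(simulate_genome(spec), spec, tmp / "reads.fastq")

M, K = 6, 28
freqs = sample_frequencies(read_sequences(reads_path), M)
orderings = [
    build_ordering("cgat", M),
    build_ordering("roberts", M),
    build_ordering("kmc2", M),
    build_ordering("random", M, seed=23),
] + [
    build_ordering("dfp", M, frequencies=freqs, pivot=p) for p in (0.0, 0.5, 0.8, 1.0)
]

df = compare_orderings(reads_path, K, orderings)
print(df.to_string(index=False))
# Lower total_supermers means better disk compression of the bins; lower
# max_distinct_per_minimizer means no single bin dominates peak memory.
# The two pull against each other, which is the whole trade-off.
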