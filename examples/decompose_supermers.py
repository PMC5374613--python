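"""Super-mer decomposition of a single DNA string, step by step.

Builds the plain lexicographic ordering on 3-mers and decomposes an 11-base
string into super-mers at k=4: maximal substrings whose k-mer windows all
share one minimizer occurrence.  Each super-mer is printed with its
minimizer and the number of k-mer windows it carries.
"""

from minicount import build_ordering, encode, minimizer_of, super_mers

SEQ = "CAAGAACAGTG"
K, M = 4, 3

ordering = build_ordering("lex", M)  # lexicographic A<C<G<T
fragment = encode(SEQ)

print(f"sequence {SEQ}  (k={K}, m={M}, forward strand)")
for i in range(len(SEQ) - K + 1):
    kmer = encode(SEQ[i : i + K])
    mmer, rank = minimizer_of(kmer, ordering)
    print(f"  k-mer {kmer}  minimizer {mmer} (rank {rank})")

sms = super_mers(fragment, K, ordering, canonical_mode=False)
print(f"\n{len(sms)} super-mers:")
for sm in sms:
    print(f"  {sm.bases}  minimizer rank {sm.minimizer_rank}  windows {sm.kmer_count}")

# The window counts add up to the fragment's k-mer count: nothing is lost,
# nothing is counted twice, while repeated minimizers compress the windows
# into far fewer records than one per k-mer.
total = sum(sm.kmer_count for sm in sms)
print(f"\nwindows covered: {total} = {len(SEQ)}-{K}+1 = {len(SEQ) - K + 1}")
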