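"""K-mer composition: local sequence composition as frequency vectors.

Builds a short DNA sequence, computes its 2-mer frequencies and the
strand-collapsed (reverse-complement) variant, and prints the nonzero
features.  Frequencies are counts over the L-k+1 overlapping windows
divided by the window total, so each vector sums to 1.
"""

from pseqfeat import Alphabet, Sequence, kmer_vector, revkmer_vector, validate_alphabet

seq = validate_alphabet(Sequence("demo", "ACGTACGTTTGCA"), Alphabet.DNA)

v = kmer_vector(seq, k=2)
print(f"Kmer k=2: {len(v)} features, sum = {v.values.sum():.3f}")
for label, x in zip(v.labels, v.values):
    if x:
        print(f"  {label}: {x:.4f}")

rv = revkmer_vector(seq, k=2)
print(f"\nRevKmer k=2: {len(rv)} strand-independent classes (16 dimers collapse to 10)")
for label, x in zip(rv.labels, rv.values):
    if x:
        print(f"  {label}(+rc): {x:.4f}")
# Each class pools a k-mer with its reverse complement, so the same vector
# is produced whichever genome strand the sequence was read from.
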