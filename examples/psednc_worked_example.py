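"""PseDNC: dinucleotide composition plus sequence-order correlation tiers.

With lambda = 10 tiers and weight w = 0.05 the vector has 16 + 10 = 26
components: the 16 dinucleotide frequencies (scaled by 1/(1+w*Phi)) and
10 pseudo components w*theta_j/(1+w*Phi) that summarize how the six
dinucleotide structural properties (Twist, Tilt, Roll, Shift, Slide,
Rise) differ between positions j steps apart.  The whole vector sums
to 1 by construction.
"""

from pseqfeat import Alphabet, ParameterSet, Sequence, run_mode, validate_alphabet

seq = validate_alphabet(
    Sequence("demo", "GCGGCGGGCGCCACCGCCGGGCCGGCATCGGCGC"), Alphabet.DNA
)

(vec,) = run_mode("PseDNC", [seq], ParameterSet(lamada=10, weight=0.05))
print(f"mode={vec.mode}  dimension={len(vec)}  sum={vec.values.sum():.12f}")

print("\ntop 3 dinucleotide components (composition part):")
comp = sorted(zip(vec.labels[:16], vec.values[:16]), key=lambda t: -t[1])
for label, x in comp[:3]:
    print(f"  {label}: {x:.4f}")

print("\npseudo components (one per correlation tier):")
for label, x in zip(vec.labels[16:], vec.values[16:]):
    print(f"  {label}: {x:.5f}")
# A large theta1 component means neighbouring dinucleotides differ
# strongly in their structural properties; GC-rich sequences typically
# put their largest composition mass on GC/CG/GG, as here.
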