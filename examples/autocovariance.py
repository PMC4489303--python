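"""Auto/cross covariance: long-range correlation of physicochemical tracks.

Reads a protein sequence through two standardized amino-acid indices
(hydrophobicity and hydrophilicity), then reports the auto covariance of
each track and the cross covariance between them for lags 1..4.  A
positive AC at lag 2 means residues two positions apart tend to deviate
from the sequence mean in the same direction for that property.
"""

from pseqfeat import (
    Alphabet,
    ParameterSet,
    Sequence,
    run_mode,
    validate_alphabet,
)

seq = validate_alphabet(
    Sequence("demo", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"), Alphabet.PROTEIN
)
params = ParameterSet(lag=4, properties=("Hydrophobicity", "Hydrophilicity"))

(acc,) = run_mode("ACC", [seq], params)
print(f"ACC: {len(acc)} features = 2 properties^2 x 4 lags")
for label, x in zip(acc.labels, acc.values):
    print(f"  {label}: {x:+.4f}")
# The first 8 features are the two auto-covariance blocks; the last 8 the
# ordered cross pairs.  Hydrophobicity and hydrophilicity are inversely
# related, so their cross covariances tend to mirror the auto terms.
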