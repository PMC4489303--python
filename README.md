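# pseqfeat

Fixed-dimension numeric feature vectors from DNA, RNA and protein
sequences, for building machine-learning predictors in sequence biology.
Most classifiers (SVMs, trees, neural networks) consume vectors, not
sequences; `pseqfeat` converts a FASTA file into vectors through **28
published feature modes** — 14 for DNA, 6 for RNA, 8 for protein —
spanning three categories:

| category | modes | what it captures |
|---|---|---|
| composition | `Kmer`, `RevKmer` | local composition: frequencies of the `L−k+1` overlapping k-mers (RevKmer pools each k-mer with its reverse complement for strand-independent DNA features) |
| autocorrelation | `DAC`/`DCC`/`DACC` (di-), `TAC`/`TCC`/`TACC` (trinucleotide), `AC`/`CC`/`ACC` (protein) | long-range order: covariance of physicochemical tracks at lags 1..*lag* |
| pseudo composition | `PseDNC`, `PseKNC`, `PC-/SC-PseDNC/TNC-General`, `PC-/SC-PseAAC(-General)` | composition plus λ sequence-order correlation tiers mixed with weight *w* |

## The model

A sequence `S = R₁R₂…R_L` is read through one or more physicochemical
indices `P_u` (each z-scored to mean 0, population SD 1 over its complete
oligomer set), giving numeric tracks `P_u(1..T)`, `T = L − g + 1` for
oligomer length `g`. The engines compute:

- **auto covariance** `AC(u,ℓ) = (1/(T−ℓ)) Σᵢ (P_u(i)−P̄_u)(P_u(i+ℓ)−P̄_u)`
  and the **cross covariance** analog for ordered property pairs;
- **parallel correlation** tiers
  `θ_j = (1/(T−j)) Σᵢ Θ(i,i+j)` with coupling
  `Θ(i,j) = (1/Λ) Σ_u [P_u(i)−P_u(j)]²`;
- **series correlation** values `τ = (1/(T−j)) Σᵢ P_u(i)·P_u(i+j)`,
  one per (lag, property) pair;
- the **pseudo-composition vector** `d_u = f_u/(1+wΦ)` for the `Aᵏ`
  k-tuple frequencies and `d = w·c_v/(1+wΦ)` for each correlation value
  `c_v` (`Φ = Σ c_v`), which sums to 1 exactly.

Property tables: 148 DNA dinucleotide, 12 DNA trinucleotide, 22 RNA
dinucleotide and 547 amino-acid built-in indices, plus user-defined index
files that can drive any property-based mode (see
`examples/user_defined_properties.py`). The curated entries — the six DNA
structural properties `Twist/Tilt/Roll/Shift/Slide/Rise` and the classic
`Hydrophobicity/Hydrophilicity/SideChainMass` — are real published
values; the remaining catalogue slots are deterministic synthetic
placeholders (`SYNTH-*`) documented in `docs/methods.md`.

## Worked example

```python
from pseqfeat import Alphabet, ParameterSet, Sequence, run_mode, validate_alphabet

seq = validate_alphabet(
    Sequence("demo", "GCGGCGGGCGCCACCGCCGGGCCGGCATCGGCGC"), Alphabet.DNA)
(vec,) = run_mode("PseDNC", [seq], ParameterSet(lamada=10, weight=0.05))
```

prints (via `python examples/psednc_worked_example.py`):

```
mode=PseDNC  dimension=26  sum=1.000000000000

top 3 dinucleotide components (composition part):
  GC: 0.1440
  CG: 0.1280
  GG: 0.1120

pseudo components (one per correlation tier):
  theta1: 0.06370
  theta2: 0.05560
  ...
```

26 = 16 dinucleotide frequencies + λ = 10 correlation tiers; the large
GC/CG/GG components reflect the GC-rich input, and `theta1` being the
largest tier says neighbouring dinucleotides differ most in their
structural properties. The same computation from a shell:

```sh
printf '>demo\nGCGGCGGGCGCCACCGCCGGGCCGGCATCGGCGC\n' \
  | pseqfeat dna -m PseDNC --lamada 10 -w 0.05 -f csv
```

Output formats: sparse LIBSVM (`label index:value …`), CSV and
tab-delimited tables, and heat-map matrices (data only). See
`pseqfeat list-modes` and the `examples/` directory — one short script
per capability.

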