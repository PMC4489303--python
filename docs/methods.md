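# Methods

## Scope and model

`pseqfeat` converts DNA, RNA and protein sequences into fixed-dimension
feature vectors through 28 registered modes in three categories:
composition, autocorrelation and pseudo composition. A sequence
`S = R₁…R_L` is treated as a string over a strict alphabet
(DNA `{A,C,G,T}`, RNA `{A,C,G,U}`, the 20 standard amino acids).
Ambiguity codes and gaps are rejected with a positioned error rather
than skipped: every feature indexes exact oligomers, so one unresolvable
position would silently corrupt every window containing it. Lowercase
input is uppercased; this changes no semantics.

### Composition

`Kmer` counts the `T = L − k + 1` overlapping windows (step 1) and emits
frequencies (count / T) over all `Aᵏ` k-mers in lexicographic order
(`A<C<G<T`, `A<C<G<U`, alphabetical amino acids), so vectors are
non-negative and sum to 1. `RevKmer` (DNA) maps each k-mer to the
lexicographic minimum of itself and its reverse complement before
tallying; normalization by the total window count happens after
collapsing (equivalent to normalizing before, since classes partition
the windows). Class counts follow the closed form `4ᵏ/2` (odd k) and
`(4ᵏ + 4^{k/2})/2` (even k).

### Physicochemical tracks

Property-based modes read the sequence through indices defined on
oligomers of length g (dinucleotides g=2, trinucleotides g=3, residues
g=1), producing tracks `P_u(1..T)`, `T = L − g + 1`. Every index is
standardized to mean 0 and unit **population** SD (divide by N) over its
complete oligomer set before use — the oligomer set is the whole
population, not a sample — making magnitudes comparable across
properties. Standardization is idempotent and fails loudly on constant
indices. The shipped six-structural-property table is already a z-scored
published table (2-decimal values); re-standardizing it is a no-op to
within rounding and keeps all indices on one convention.

### Autocorrelation

With deviations taken from each track's own mean, and the number of
summed pairs as denominator:

    AC(u,ℓ)     = (1/(T−ℓ)) Σ_{i=1}^{T−ℓ} (P_u(i)−P̄_u)(P_u(i+ℓ)−P̄_u)
    CC(u1,u2,ℓ) = (1/(T−ℓ)) Σ (P_{u1}(i)−P̄_{u1})(P_{u2}(i+ℓ)−P̄_{u2})

The `T−ℓ` (pairs-count) denominator is a deliberate fixed convention —
published variants of these descriptors differ between `T−ℓ` and
`T−ℓ−1`, and downstream values are convention-sensitive, so it is stated
here prominently. Cross covariance enumerates ordered pairs of distinct
properties in input order; labels are property-major with lag innermost;
ACC is the exact concatenation of AC then CC. One engine, parameterized
by g, serves DAC/DCC/DACC (g=2), TAC/TCC/TACC (g=3) and AC/CC/ACC (g=1).

### Pseudo composition

Two coupling conventions, both pluggable behind the correlation-profile
abstraction:

- parallel: `θ_j = (1/(T−j)) Σ_i Θ(i,i+j)`,
  `Θ(i,j) = (1/Λ) Σ_u [P_u(i)−P_u(j)]²` (squared differences averaged
  over the Λ selected properties; θ_j ≥ 0);
- series: `τ_{(j−1)Λ+u} = (1/(T−j)) Σ_i P_u(i)·P_u(i+j)`, ordered
  lag-major / property-minor (the ordering is unstated in the source
  literature; lag-major is this package's recorded choice).

The final vector normalizes the k-tuple frequencies `f` to sum 1 and sets
`d_u = f_u/(1+wΦ)` and `d = w·c_v/(1+wΦ)` with `Φ = Σ c_v`, so every
vector sums to exactly 1 and the pseudo mass is `wΦ/(1+wΦ)` — strictly
increasing in w whenever Φ > 0. This is algebraically identical to the
published form in which unnormalized frequencies appear in both
numerator and denominator. λ = 0 (and w = 0) degenerate to the bare
composition vector; λ = 0 is permitted as a useful limiting case.

Named modes are fixed engine configurations: PseDNC = (k=2, g=2,
parallel, six structural properties); PseKNC keeps **dinucleotide**
correlations (g=2) for any composition k, following the formulation that
extends PseDNC — a `corr_g` argument keeps a `corr_g = k` variant
available; PC-/SC-PseTNC-General = (k=3, g=3); PC-PseAAC = (k=1, g=1,
parallel, hydrophobicity/hydrophilicity/side-chain mass, dimension
20+λ); SC-PseAAC = (k=1, g=1, series, hydrophobicity/hydrophilicity,
dimension 20+2λ). The protein `-General` modes differ from PC-/SC-PseAAC
only in the allowed property universe (the full 547-slot catalogue or
user files); richer channels such as functional-domain or GO information
are out of scope — user-defined indices are the single extension point.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| k | k-tuple length | required (PseKNC: 3) | capped at 6 (nucleic) / 3 (protein) unless `allow_unsafe_k`; protein k=3 already gives 8000 dims |
| lag | max correlation distance | required | needs `lag ≤ T − 1` |
| λ (`lamada`) | highest correlation tier | **required** | legality depends on L (`λ ≤ T − 1`), so there is no silent default |
| w (`weight`) | pseudo-component weight | 0.05 | the value used by the standard worked configurations |
| properties | index names | mode-specific | PseDNC/PseKNC → the 6 structural; PC-/SC-PseAAC(-General) → the classic 3/2; autocorrelation and nucleotide `-General` modes require explicit selection (no canonical default exists) |

Batch semantics are all-or-nothing: any invalid sequence aborts the run
naming the sequence id, because a partially generated feature matrix
corrupts downstream ML silently.

## Built-in property tables

Catalogue sizes are fixed at 148 (DNA dinucleotide), 12 (DNA
trinucleotide), 22 (RNA dinucleotide) and 547 (amino acid). Two curated
plain-text tables ship in `src/pseqfeat/data/`: the six DNA structural
properties (Twist, Tilt, Roll, Shift, Slide, Rise — standardized,
2-decimal published values) and the three classic amino-acid properties
(hydrophobicity, hydrophilicity, side-chain mass). The remaining
catalogue slots are **synthetic placeholders** — standard-normal draws
from fixed seeds, named `SYNTH-<alphabet>-<g>-<nnn>` — generated
deterministically at load time. They keep the catalogue at its
documented size and exercise every selection/normalization/formula path,
but carry no physical meaning: analyses that need real values for those
slots should supply a user-defined index file, which shadows built-ins
by name. Filler is generated in code rather than shipped as files purely
to keep the source tree small; determinism is identical either way.

## Synthetic data and what tests show

`pseqfeat.testkit.random_sequences` draws residues i.i.d.-uniform over
the alphabet with seeded generators (fixed seeds recorded in the tests,
so failures replay exactly). Uniform sequences probe the algebra — label
order, dimensions, normalization, engine/oracle agreement — under the
documented conditions; they do not emulate compositional bias, repeats
or phylogenetic correlation of real genomes and proteomes, so green
tests certify formula correctness, not biological discriminative power.
Oracles (`testkit.oracle_suite`) are deliberately naive re-derivations —
dictionary tallies, explicit double loops, explicit normalization — that
share no code with the engines, keeping engine-vs-oracle equality a
meaningful cross-check. Test problem sizes (sequences of tens to a few
hundred residues, ≥100 instances per mode family) were chosen as
desk-scale checks that complete in seconds.

## Numerical choices

- Covariance deviations use shifted-data centering (anchor at the first
  track value before subtracting the mean): a constant track then yields
  exactly zero features instead of ~1 ulp residue, and conditioning
  improves for offset-heavy tracks.
- Engine/oracle comparisons assert `|diff| < 1e-10`; sum-to-one and
  z-score invariants use 1e-12 and 1e-9 respectively.
- Emitted numbers default to 8 significant digits (configurable): below
  formula tolerance, above float noise.
- LIBSVM export omits zero features (1-based, strictly increasing
  indices); default class label `+1` for unlabeled feature-generation
  runs.
- Heat maps are exported as row-major NaN-padded grids with an aligned
  label grid; no graphics.

## Known limitations

- Synthetic catalogue filler (above) means selections outside the
  curated nine properties are reproducible but physically meaningless
  without user-supplied tables.
- No support for ambiguity codes, gapped or aligned input, FASTQ, or
  mismatch/gapped k-mer variants.
- Single-threaded; protein `Kmer` beyond k=4 (160 000+ dims) is memory-
  rather than CPU-bound and is gated behind `allow_unsafe_k`.
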