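# Methods

## Model

The predictor is a graph transformer over atom tokens. A
*microenvironment* around a target residue is the closed ball of atoms
within radius r (default 16 Å) of the residue's Cα with every atom of the
residue itself removed; the Cα coordinate is retained as the geometric
center. Each token is the concatenation of a learned embedding of its
chemical element (vocabulary {C, N, O, S, P, H, other} plus padding,
embedding width E = 20) with two physical features — partial charge
(elementary charges) and solvent-accessible surface area (Å²) — projected
to the hidden width H.

Geometry enters only through the pairwise Euclidean distance matrix D.
Two featurizations of D are concatenated per atom pair: K = 16 Gaussian
radial basis channels exp(−D²/2σ_k²) with bandwidths σ_k log-spaced over
[0.5, 20] Å, and a C = 4 one-hot distance category with boundaries
{2.2, 4.0, 8.0} Å (covalent / first shell / mid-range / long-range;
distances exactly at a boundary fall in the lower bin). A linear map of
the 20 pair features yields one additive bias per attention head, applied
to the pre-softmax logits of every attention layer. An attention block is
two biased self-attention layers followed by one MLP, each sublayer with
pre-layer-norm residual wiring and dropout (default 0.1). With H = 128,
8 heads, 4 blocks and MLP width 5H, the backbone plus classifier totals
1,213,684 parameters (reported at runtime by `n_parameters()`).

Because there is no positional encoding and coordinates appear only
through D, token states are permutation-equivariant, the pooled outputs
permutation-invariant, and everything is invariant under rigid motions of
the input structure. Both properties are asserted numerically (≤1e−5
over 100 random rigid motions; the measured deviation is ~1e−17).

**Masked-amino-acid pretraining.** The final-layer states of all tokens
within 8 Å of the masked Cα (the first contact shell) are mean-pooled and
decoded by Linear(H→128) → ReLU → Linear(128→20); softmax gives the
amino-acid likelihoods and the loss is cross-entropy. E is the embedding
width of the *element* vocabulary; the value 20 coincides with the number
of amino acid types but plays no amino-acid role in the backbone.

**ΔΔG head.** The weight vectors of the 20 classifier output neurons are
the *structural amino-acid embeddings* (20×H; this requires the
classifier hidden width to equal H, which the default configuration
satisfies). A mutation (from, to) is modeled by running the shared-weight
(Siamese) head attention blocks twice over the token states with the
respective embedding appended as a CLS token — the CLS token has no
coordinates, so its pair-feature rows and columns are zero, and the two
branches never co-attend. The decoded prediction is ΔΔG = w·(u_to −
u_from), kcal/mol, positive destabilizing.

Numerical consequences of the zero-bias subtraction decoder, all tested:
self-mutations decode to exactly 0.0, predictions are exactly
antisymmetric, and any thermodynamic cycle closes to floating-point
precision. A configuration switch restores a decoder bias for
experiments that want one; the zero-bias form is the default because it
is the cleaner inductive bias for a state function. The head's attention
blocks (default 2) are fresh parameters; the backbone is loaded
pretrained. Structural embeddings are *live* — fine-tuning moves them
with the classifier weights — unless frozen by configuration.

A deep mutational scan builds one microenvironment per residue, runs the
backbone once, contextualizes all 20 amino-acid embeddings once each, and
recombines cached branch states into the 19 substitutions — 20 branch
evaluations per residue, not 380.

## Thermodynamic augmentation

Gibbs free energy is a state function, so, at one position with a single
wild type, n distinct measured mutants imply all n(n−1) ordered mutations
among them: ΔΔG(aᵢ→aⱼ) = ΔΔG(wt→aⱼ) − ΔΔG(wt→aᵢ) (thermodynamic
permutations, TP). TP records never involve the wild type, are closed
under reversal (the ΔΔG multiset mean is exactly zero), and satisfy
triple additivity by construction. Thermodynamic reversibility (TR)
contributes one wild-type-targeted reversal per original. Duplicate
mutations are collapsed to the measurement with largest |ΔΔG| (stable
tie-break: first in input order) *before* TP so that n counts distinct
mutant amino acids; conflicting wild-type claims at one position abort
with a data-quality error rather than being resolved silently, because
thermodynamic validity depends on a single reference state. Generated
records colliding with existing ones are dropped in favor of the
existing measurement and counted.

## Curation

The leakage barrier removes every candidate protein whose sequence
identity to any reference (test) protein reaches 30% — inside the
"twilight zone" below which most pairs fold differently. Identity is
computed either by the external MMseqs2 binary (`easy-search -c 0.3
-s 7.5 --seq-id-mode 1`) when it is on PATH, or by the built-in global
aligner (BLOSUM62, affine gaps 11/1, identity = matches / alignment
length). The built-in definition is the audit's reference behavior; the
coverage flag of the external tool can treat short local overlaps
differently, which the report records by naming its backend. A
post-split audit always recomputes all cross-split identities with the
built-in aligner and fails the split at ≥30%.

## Features

Partial charges come from a bundled AMBER-style (residue, atom-name)
lookup — a stand-in for a published force-field assignment, swappable via
the `charge_table` argument; atoms without an entry get 0.0 and are
counted. SASA is Shrake–Rupley with a deterministic golden-spiral point
set (default 960 points, probe 1.4 Å) on the full unmasked structure,
since the features describe the native environment before masking.
Hydrogens are kept when present and never added. Relative solvent
accessibility divides residue SASA by the Tien et al. (2013) theoretical
maxima, capped at 1.

## Training

Reference recipe: Huber loss with δ = 1 kcal/mol; AdamW (β = 0.9/0.999,
ε = 1e−8 — unspecified upstream, standard values) with learning rate
5e−5 on head parameters and 2e−5 on backbone parameters; effective batch
960 as micro-batch 240 × 4 accumulation steps; weight decay 0.1; weight
EMA with η = 0.99; 750 iterations at constant learning rate. The
small-dataset recipe freezes the backbone (bit-identical parameters
after the run, asserted) and uses lr 5e−7 resuming from a large-scale
run or 5e−5 from scratch, batch 1024, 500 iterations. Mixed precision
is off; all arithmetic is float64, which lets the analytic gradients be
checked against central differences (≤1e−4 relative on a 10-token
environment; observed agreement is far tighter).

The desk preset (batch 16, 150–200 iterations, lr 3e−3/1e−3,
H = 32, 1 block) exists so the loops run in seconds to minutes on one
CPU. Desk-scale benchmarks evaluate the live weights rather than the EMA
shadow: at toy iteration counts the η = 0.99 shadow has only partially
converged toward the trained weights, so the shadow is kept available on
the returned model (`model._ema`) for longer runs instead of being
swapped in automatically.

## Synthetic study conditions

The generators emulate the statistical shape of curated stability data,
not its physics. Structures are parametric α-helices (rise 1.5 Å, twist
100°, Cα radius 2.3 Å, consecutive Cα–Cα ≈ 3.8 Å) with backbone N, CA,
C, O and one side-chain pseudo-atom per non-glycine residue whose element
encodes the residue's chemical class; there are no rotamers, no packing
optimization, and no real tertiary contacts. ΔΔG tables come from a
planted per-amino-acid potential g: ddg(wt→a) = g(a) − g(wt) +
Normal(0, 0.3) kcal/mol — the noise default matches the ±0.5 kcal/mol
experimental-error convention that also defines the
stabilizing/neutral/destabilizing class boundaries. Drawing g with
positive mean and building sequences from low-g amino acids reproduces
the >70% destabilizing skew of experimental tables (measured ~82% under
the default seed conditions).

The planted regression task adds a structure-dependent term:
ΔΔG = w*·(φ(to) − φ(from)) + γ·density(position)·(φ_vol(to) − φ_vol(from))
+ noise, with φ a fixed property embedding (normalized Kyte–Doolittle
hydropathy, side-chain volume, formal charge), density the centered atom
count within 8 Å of the Cα, and γ = 0.4. The target is exactly
antisymmetric; train and test positions are disjoint. A closed-form
linear probe on φ differences alone reaches Pearson ≥ 0.8; the density
term is the headroom a microenvironment-aware model can close. Passing
these benchmarks shows the architecture can recover an additive,
structure-modulated antisymmetric signal at desk scale — it says nothing
about accuracy on real proteins, which requires large-scale pretraining
and experimental data.

The toy pretraining set plants the label in the element composition of
the pooling shell (2 + 7k nitrogen atoms among 24 atoms for class k), so
a mean-pooling classifier can solve it exactly; it exercises the
pretraining loop, not representation learning.

## Problem sizes and numerics

Acceptance-style runs use: 15 originals over positions with n = 1…5
mutants for the combinatorics (TP = 40); a 300-residue helix at 6 Å
environment radius with a 16-wide single-block model for the 5700-row
scan; 200 random queries for the exactness checks; 100 rigid motions for
invariance; 2 structures × 20 positions × 8 pairs (224 train / 96 test
records) and 150 desk iterations for the planted task; 90 environments
and 60 iterations for toy pretraining; 8 candidate proteins with 3
planted ~65%-identity homologs for the split audit. These sizes were
chosen so the whole suite completes in minutes on one CPU while every
check remains statistically unambiguous.

Known limitations: no protonation or charge assignment beyond the lookup
table; no multi-point mutations; no mutant-structure generation; the
built-in aligner is quadratic and meant for fixture-scale audits, not
proteome-scale clustering; training is single-process CPU and not meant
for the full ~2.6M-microenvironment pretraining regime.
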