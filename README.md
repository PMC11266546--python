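# ddgformer

Structure-based prediction of the thermodynamic stability change of a
protein point mutation — ΔΔG in kcal/mol, positive meaning destabilizing —
from a single masked-residue microenvironment, together with the
thermodynamic data-augmentation and leakage-aware dataset-curation tooling
that such a predictor needs. The intended users are protein engineers and
computational biologists who want to rank candidate stabilizing mutations
or run full computational deep mutational scans from one structure.

## The model

Atoms are tokens. A microenvironment is every atom within a radius
(default 16 Å) of a target residue's Cα, with the target residue's own
atoms removed. Each token starts as the concatenation of a learned
element embedding (E = 20) with two physical features — an AMBER-style
partial charge and Shrake–Rupley SASA — projected to hidden width H = 128.
Pairwise distances D enter the transformer as an additive attention bias:
K = 16 Gaussian radial basis channels plus a C = 4 one-hot distance
category are mapped linearly to one bias per attention head and added to
the pre-softmax logits of every attention layer. An attention block is
two biased attention layers plus an MLP with pre-layer-norm residuals;
four blocks give ≈1.2 M parameters. Because geometry enters only through
D, the network is invariant under rigid motions and equivariant under
token permutation by construction.

**Pretraining** is masked-amino-acid recovery: the final states of all
tokens within 8 Å of the masked Cα are mean-pooled and passed through a
Linear(128)–ReLU–Linear(20) classifier; softmax gives the 20 amino-acid
likelihoods.

**ΔΔG regression** represents a mutation by two *structural amino-acid
embeddings* — the weight vectors of the "from" and "to" output neurons of
that classifier. Each embedding is appended as a CLS token to the
microenvironment's token states and contextualized by the regression
head's own attention blocks (Siamese: shared weights, branches never
co-attend). The decoded prediction is

    ΔΔG = w · (u_to − u_from)

with a zero decoder bias, which enforces the state-function property of
Gibbs free energy exactly: self-mutations are 0, predictions are
antisymmetric, and thermodynamic cycles close. Since the mutation enters
only through the CLS embeddings, one microenvironment serves all 380
mutation types at a position, and a deep mutational scan costs one
environment build plus 20 contextualizations per residue.

**Thermodynamic augmentation.** From n distinct mutant amino acids
measured at one position, thermodynamic permutations (TP) generate all
n(n−1) ordered mutations among them with
ΔΔG(aᵢ→aⱼ) = ΔΔG(wt→aⱼ) − ΔΔG(wt→aᵢ); the result never involves the wild
type and is balanced between stabilizing and destabilizing (its ΔΔG
multiset has mean exactly zero). Thermodynamic reversibility (TR) adds
the reverse of each measurement with negated ΔΔG. Duplicates across
source tables are resolved by largest |ΔΔG|, and train/test splits are
audited against a 30% sequence-identity leakage barrier (MMseqs2 when
available, a built-in BLOSUM62 global aligner otherwise).

## Worked example

```python
from ddgformer import (BackboneConfig, GraphTransformerBackbone,
                       StabilityModel)
from ddgformer.microenv import build_masked_microenv
from ddgformer.structure_io import (assign_partial_charges, compute_sasa)
from ddgformer.synthetic import SyntheticSpec, make_helix_structure

st = make_helix_structure(SyntheticSpec(seed=7, n_residues=20))
assign_partial_charges(st)
compute_sasa(st)
env = build_masked_microenv(st, "A", 10)

model = StabilityModel(
    GraphTransformerBackbone(BackboneConfig.desk(), seed=0),
    n_head_blocks=1, seed=0)
model.eval()
print(model.predict_ddg(env, "A", "V").ddg)   # -0.1293286513357185
print(model.predict_ddg(env, "V", "A").ddg)   # 0.1293286513357185
print(model.predict_ddg(env, "A", "A").ddg)   # 0.0
```

The three numbers are the predicted ΔΔG (kcal/mol) of A→V at residue 10
of a 20-residue synthetic helix under an untrained desk-scale model, its
exact negation for the reverse mutation, and the exact zero for a
self-mutation — the two identities the subtraction architecture
guarantees regardless of training.

The same model object runs a scan (19 substitutions per residue):

```python
table = model.dms_scan(st)     # 20 residues -> 380 rows
```

A command-line interface mirrors the library
(`ddgformer simulate|featurize|pretrain|finetune|predict|dms|augment|split|eval`);
see `ddgformer --help`.

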