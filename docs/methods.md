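# Methods

## Problem and model

`microrank` prioritizes candidate pathogenic microbes for human diseases
from three inputs: a binary microbe–disease association network
ℛ ∈ {0,1}^{nm×nd}, marker-gene (16S rRNA) sequences per microbe, and
hierarchical tree codes per disease. The working assumption is the standard
one in this literature: functionally similar microbes tend to interact with
similar diseases, so known associations plus sequence- and hierarchy-based
similarities carry signal about unknown associations.

The core is an implicit-feedback latent-factor ranker. Microbe *i* carries
a latent vector U_i ∈ ℝ^z, disease *d* a vector V_d ∈ ℝ^z and a bias b_d,
and the raw preference is

    r̂_di = V_d·U_i + b_d.

Training follows the Bayesian personalized ranking recipe with *group
preference*. Each SGD draw samples a known association (i, d), a negative
disease b unknown for i, and a group 𝒢 ⊆ ℳ_d (microbes known-associated
with d, i ∈ 𝒢, |𝒢| capped at the configured group size). The group
preference r̂_𝒢d is the arithmetic mean of the members' raw scores — the
construction used throughout the group-BPR lineage; the blend

    r̂_𝒢id = ρ·r̂_𝒢d + (1−ρ)·r̂_id

is pushed above r̂_ib by the logistic pairwise loss

    ℱ = ln(1 + exp(−(r̂_𝒢id − r̂_ib)))
        + (α_u/2)Σ_{j∈𝒢}‖U_j‖² + (α_v/2)(‖V_d‖² + ‖V_b‖²)
        + (β_v/2)(b_d² + b_b²),

minimized by SGD with learning rate γ. The softplus is evaluated through
`log1p`/`logaddexp`, so large margins cannot overflow. Gradients are exact
and are continuously checked against central finite differences in the test
suite (relative error < 1e-4 over randomized configurations).

Two ablation variants exist. `group_axis="none"` forces 𝒢 = {i}, which
reduces the model to plain pairwise ranking. `group_axis="disease"` is the
mirror image — the group is drawn from the diseases known for the sampled
microbe (containing d), the blended score ρ·mean_{d′∈𝒢} r̂_{d′i} +
(1−ρ)·r̂_{di} is compared against r̂_{dj} for a negative microbe j, and the
regularization mirrors accordingly (α_v/β_v on the grouped disease
parameters, α_u on both microbe vectors). The mirror construction is our
design; only the microbe-grouped form is canonical.

Negative candidates are drawn from the full roster: any disease (microbe)
without a known association to the anchor is treated as unlabeled. A draw
whose anchor is associated with every item on the negative side is
resampled, with a bounded retry budget.

After training, scores are optionally *augmented* with similarity
evidence. For a pair (d_i, m_j),

    r̂_{d_i m_j} += (α_d/|𝒟_{m_j}|) Σ_{d′∈𝒟_{m_j}} S_d(d_i, d′)
                  + (α_m/|ℳ_{d_i}|) Σ_{m′∈ℳ_{d_i}} S_m(m_j, m′),

where neighbor sets come from *training* positives only and an empty set
contributes zero. Augmentation is additive and order-independent; no score
normalization is applied afterwards.

## Similarity matrices

**Disease semantic similarity S_d.** Dot-delimited tree codes (e.g.
`C18.654.726`) place each disease in a taxonomy; prefix nesting defines
ancestry. Each disease d gets a weight vector over the nd studied diseases:
V_d(d)=1, V_d(t)=1/(len(d,t)+1) for descendants t, else 0, where len(d,t)
is the difference in dot-segment depth along the codes (minimized over code
pairs for multi-code diseases). Depth is counted on the codes themselves,
not on hops through studied diseases, because the taxonomy exists
independently of the studied subset. Weights are exact rationals up to the
final cosine; S_d is the cosine of these vectors with the diagonal pinned
to 1.

**Microbe sequence similarity (MSS).** Percent identity of an optimal
global alignment (match +1, mismatch −1, linear gap −2 by default;
identity = 100·matches/columns), computed with Biopython's pairwise
aligner, or ingested from a BLAST-tabular file (symmetrized by the maximum
of the two directions; absent pairs default to identity 0 on the grounds
that a missing alignment carries no evidence of similarity). The identity
matrix is min–max normalized over *all* entries, diagonal included — the
normalization notation carries no exclusion, so none is applied. A constant
matrix normalizes to zeros with a warning rather than NaN.

**Evolutionary-distance similarity (MES).** From a multiple alignment the
pipeline first trims terminal columns covered by any row's leading or
trailing gap run, then applies complete deletion: every remaining column
containing a gap or `N` (treated as missing data) is dropped. On the clean
block the p-distance p̂ = mismatched sites / compared sites is computed per
pair, ED = 1 − p̂, and ED is min–max normalized like MSS. When no multiple
alignment is supplied, each pair is globally aligned on the fly and complete
deletion applied per pair. No substitution-model correction (Jukes–Cantor,
Kimura) is applied: the p-distance is the intended statistic.

**Imputation and fusion.** Microbes without an available sequence are
filled in both MSS and MES with the mean of the available off-diagonal
similarities (diagonal 1), including the cells between two missing
microbes. The final microbe similarity is the elementwise mean
S_m = (MSS + MES)/2.

## Evaluation protocol

Evaluation is disease-oriented ("local"): for a disease d with held-out
positives, AUC_d is the fraction of (test-positive, unlabeled) pairs in
which the positive outscores the unlabeled microbe. Unlabeled means: not a
positive of d in either the training or the test partition. Ties count ½ —
the indicator in the definition is strict, but the ½ convention is what
makes a constant scorer score exactly 0.5, which the tests assert. The
aggregate AUC is the unweighted mean over evaluable diseases; diseases with
no unlabeled microbes are skipped with a warning.

*Leave-one-out*: every known association is held out in turn, the model is
retrained from scratch on the remainder, and the singleton-test AUC_d
values are averaged over held-out instances. *Repeated k-fold*: per repeat
the positives are reshuffled into k folds; a repeat's value is the mean
aggregate AUC over its folds, and the report is mean ± standard deviation
across repeats (the repeats are the only population the ± can refer to).
Similarity matrices are computed once from the full sequence/hierarchy
inputs — they are not derived from associations, so this leaks nothing —
while the augmentation neighbor sets always use training positives only.
A leakage test verifies that no test positive ever reaches the trainer.

## Synthetic data generator

The generator builds coupled test worlds. Microbes and diseases are
partitioned into blocks; associations appear with probability p_in within a
block and p_out across. Every microbe and disease is guaranteed at least
one positive (empty rows/columns are resampled). Each block gets a random
ancestral sequence; members diverge by i.i.d. substitutions at rate μ
(substituted sites take one of the other three bases uniformly), so the
expected within-block p-distance is the two-branch mismatch probability
≈ 2μ(1−μ) and between-block sequences are unrelated. Disease tree codes
grow as a random rooted forest; when block labels are supplied, each block
grows one subtree, so hierarchy relatedness mirrors the planted structure.

Defaults are fixed once: nm=60, nd=12, two blocks, p_in=0.5, p_out=0.02,
sequence length 300, μ=0.05 (a realistic within-genus marker-gene
divergence), branching 3, depth 3. Synthetic-study evaluations train for 50
epochs — the budget paired with this world size throughout the package —
while the model default remains 100 epochs. What the generator does *not*
emulate: the hypervariable-region architecture of real 16S genes,
non-star phylogenies within a block, the extreme microbe/disease aspect
ratio of curated catalogues, and annotation noise. Passing recovery tests
therefore demonstrates that the machinery extracts planted signal, not that
real-data AUC levels are reproduced.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| z | latent dimension | 30 | performance is flat in a wide range |
| \|𝒢\| | group size | 5 | capped at \|ℳ_d\| per draw |
| ρ | group-preference weight | 0.5 | blend of group vs individual |
| γ | SGD learning rate | 0.01 | 0.001 also reasonable; both supported |
| α_u, α_v, β_v | L2 weights | 0.01 | admissible 0.0001–0.1 |
| α_d, α_m | augmentation weights | 0.5 | equal weighting, matching ρ |
| T | training epochs | 100 | one draw per known positive per epoch |
| init scale | Gaussian init s.d. | 0.01 | keeps initial softplus near ln 2 |

The α_d = α_m = 0.5 equal weighting is our choice (the augmentation weights
are otherwise unconstrained); both are exposed on the CLI. Biases start at
zero; U, V start as zero-mean Gaussians at scale 0.01 so early margins are
tiny and the loss starts near ln 2 per sample.

## Numerical and degenerate-input choices

- Softplus via `logaddexp`; sigmoid split by sign: no overflow at any margin.
- Ranking ties break lexicographically by microbe name (stable two-pass sort).
- Name order everywhere is lexicographic; association loaders are
  row-order-insensitive and collapse duplicate pairs with a logged count.
- Constant similarity matrices min–max to zeros with a warning.
- Complete deletion that removes every column raises, directing the caller
  to the pairwise fallback.
- An anchor saturating its negative side is resampled; a dataset where all
  anchors saturate raises.
- All randomness flows through NumPy generators seeded from the
  configuration; cross-validation spawns independent child streams per
  fold/repeat, so runs are reproducible end to end.

## Known limitations

- The internal global aligner is a stated stand-in for BLAST-style local
  alignment; word-size/E-value heuristics and multi-HSP reduction are not
  reproduced, so identities from real BLAST runs will differ slightly
  (precomputed identity tables can be supplied instead).
- Multiple-sequence alignment is consumed, not produced; unaligned inputs
  fall back to per-pair global alignments.
- LOOCV retrains per held-out association (the faithful reading of the
  protocol), which is the dominant cost at catalogue scale; the k-fold
  protocol is the practical choice for large rosters.
- Scores are unnormalized preferences: comparable within a disease row,
  not calibrated probabilities across diseases.
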