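# Methods

## Model

`trimda` scores miRNA–disease pairs on a tripartite graph whose three binary
bipartite layers — miRNA–disease (MD), miRNA–lncRNA (ML) and disease–lncRNA
(DL) — share entity sets. The method assumes associations are unweighted and
that co-membership in lncRNA/disease neighbourhoods is informative about
unobserved miRNA–disease edges; it uses no sequence, expression or semantic
similarity information.

**Stage 1 — collaborative filtering.** miRNAs are items; lncRNAs and diseases
are users. The spliced matrix A⁰_MLD = [A⁰_ML, A⁰_MD] gives each miRNA a
combined binary neighbourhood vector. Similarity between miRNAs is the cosine
of these vectors, equivalently |N∩N′|/√(|N||N′|); pairs where either
neighbourhood is empty get similarity 0 (the global 0/0 := 0 convention). The
recommender matrix Rⁿᵒʳ·A⁰_MLD aggregates, for each (miRNA, user) cell, the
user's known miRNAs weighted by their similarity to the candidate. A column is
eligible for recommendations only if it already has at least one known miRNA
(a user with no history has no collaborative signal); within an eligible
column, candidates scoring *strictly* above the column's averaged value P are
added as new **binary** edges. Ties at exactly P are not added. Recommended
edges are unweighted because the allocation stage consumes binary adjacency
and integer degrees. The update is a single pass — similarity is computed once
from G⁰, and recommendations never delete an edge, so Gᵘ ≥ G⁰ elementwise.
The DL layer is never updated, and the updated ML layer is not consumed
downstream; it is produced for completeness and auditing.

**Stage 2 — consistence-based resource allocation.** Each known or
recommended MD edge carries one unit of initial resource (the initial
resource vector is exactly a row of Aᵘ_MD, so no separate state is kept).
The M→D→M two-step allocation yields the miRNA–miRNA transfer matrix W; each
hop divides by the sending node's degree, so every row of W belonging to a
miRNA with at least one disease link sums to 1 (an algebraic identity the
tests assert numerically). The diagonal self-transfer term is included. The
consistence correction w′_kt = w_kt + w_tk/Σ_s w_sk rewards pairs whose
resource flow is mutually consistent; when a column sum is zero the ratio is
dropped. Rscore₁ = W′·Aᵘ_MD. Independently, the D→L→D allocation through the
DL layer gives Rscore₂ = Aᵘ_MD·D_d⁻¹·A⁰_DL·D_l⁻¹·A⁰_DLᵀ, using pseudo-inverse
degree matrices (zero-degree rows/columns contribute nothing). Because
Rscore₂ depends only on the DL layer's structure around a disease, diseases
with no known miRNA still receive nonzero scores — the "new disease" use
case. The final score is the convex blend γ·Rscore₁ + (1−γ)·Rscore₂ and is
affine in γ cell by cell.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `gamma` | 0.9 | weight of the miRNA-side allocation; 1.0 ignores the lncRNA route, 0.0 uses it exclusively. 0.9 is the operating point at which the method reports its best performance. |
| `p_denominator` | `all_rows` | the P threshold is the column sum divided by n_m (all rows). The literal reading of "sum of all elements … averaged" admits a nonzero-rows variant, kept as a config option for sensitivity analysis; the default is the all-rows reading. |
| `use_cf` | True | False gives the allocation-only baseline on G⁰ (known positives only). |
| `ordering` | lexicographic | entity index order; lexicographic makes outputs byte-reproducible across input orderings. `input` preserves first-seen order. |

## Cross-validation protocol

Positives are the 1-cells of the scored MD matrix — known plus recommended
edges for the full model, known only for the baseline — and negatives are
*all* remaining cells (no subsampling). Both classes are shuffled and split
into five near-equal folds (sizes differ by at most one). The
collaborative-filtering stage is run once, before splitting: the positive set
is fixed, and only the allocation (W, W′, Rscore₁, Rscore₂, blend) is
recomputed per fold on a copy with the test positives masked to 0. A masked
positive's score therefore never reads its own edge (asserted by a
perturbation test). AUC is the trapezoid area of the tie-grouped ROC sweep
(equal to the concordant-pair statistic with half credit for ties) and AUPR
is the area under the precision–recall step curve; both are computed via
scikit-learn and cross-checked in the tests against an exhaustive
pair-counting oracle. Results are reported as mean ± sd over repeats, with
the per-repeat maximum also recorded since "achieves the value X over 10
runs" can be read either way.

## Synthetic data generator

The generator emulates the structure of curated miRNA/disease/lncRNA
association collections: three sparse coupled binary layers. It is a planted
block model: entities of each role are partitioned into `n_blocks` blocks;
within-block MD edges are drawn at `within_block_prob`, all others at
`background_prob`; the ML and DL layers echo the same blocks with
within-block probability `layer_coupling × within_block_prob`, so lncRNA
co-neighbourhoods carry genuine signal about held-out MD edges — exactly the
co-occurrence structure both stages exploit. `holdout_frac` of the realised
within-block MD edges are removed from the returned graph and serve as
recoverable ground truth. A block model was chosen over degree-matched
rewiring because shared-neighbour co-occurrence is the method's premise;
blocks create that signal directly. All randomness flows from one
`numpy.random.Generator` seeded by the config, with no global state.

The standard benchmark is 60 miRNAs × 40 diseases × 20 lncRNAs, 4 blocks,
within/background probabilities 0.5/0.02, coupling 0.7, holdout 0.3, sizes
chosen so the whole suite runs in seconds while keeping per-fold positive
counts in the hundreds. What the generator does **not** emulate: the heavy-
tailed degree distributions, hub miRNAs, and correlated curation biases of
real databases. Passing the recovery benchmark shows the pipeline extracts
planted co-occurrence signal; it does not certify performance on real
association data, whose degree structure can inflate AUC for degree-driven
scorers.

## Numerical choices

- **Zero degrees / empty columns:** every division guards with 0/0 := 0
  (pseudo-inverse of the degree diagonal, dropped consistency ratio, zero
  similarity). This keeps all scores finite and lets isolated entities ride
  through the pipeline with zero or lncRNA-only scores.
- **Ties:** ranking ties are broken by miRNA index order (stable argsort);
  ROC/PR sweeps group equal scores at one threshold.
- **Strict threshold:** recommendation requires score > P, never ≥.
- **Determinism:** the predict path has no randomness at all; CV and the
  generator derive every stream from explicit seeds via `SeedSequence`.
- **Dense matrices:** layers at the intended scale (hundreds × hundreds) fit
  comfortably dense; no sparse representations are used.

## Known limitations

- The allocation stage consumes the updated MD layer and the original DL
  layer only; recommended ML edges influence nothing downstream.
- Associations are unweighted; confidence weighting of edges is out of scope.
- One densification pass, not an iteration to a fixpoint.
- The D→L→D allocation is one reading of an ambiguously indexed formula; the
  interpretation (resource to lncRNAs and back, each hop degree-normalised)
  follows the surrounding prose and is what the loop oracle encodes.
- Disease/miRNA identifiers are compared verbatim after whitespace trimming;
  no fuzzy or ontology-based name merging is attempted, so inputs must be
  pre-harmonised.
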