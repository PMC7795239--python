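# Methods

This note documents the models the package implements, the choices made
where the methods literature leaves them open, what the synthetic data
emulate, and the known limits of both.

## 1. Interactive and regulatory models

A genome-wide genetic and epigenetic network (GWGEN) couples a
protein–protein interaction network (PPIN) with a gene regulatory network
(GRN) over five entity classes: proteins, genes, TFs, lncRNAs and miRNAs.
Expression data (entity × sample, nonnegative; a TF row is the expression of
its gene/protein) are modeled per target entity:

* **protein** q:  `p_q[n] = Σ_r κ_qr · p_q[n]·p_r[n] + λ_q + ε[n]` over its
  interactors r — the interaction term is bilinear in the two partners;
* **gene** x:  `g_x[n] = Σ_u α_xu·t_u[n] + Σ_v β_xv·l_v[n]
  − Σ_w γ_xw·m_w[n]·g_x[n] + λ_x + ε[n]` with TF regulators t, lncRNA
  regulators l and miRNA repressors m; `γ_xw ≥ 0` so miRNA regulation is
  repressive by convention;
* **lncRNA** and **miRNA** targets follow the same form as genes (abilities
  σ/ς/τ and ω/ξ/ψ respectively), again with nonnegative miRNA-repression
  abilities entering negatively.

`λ` is a basal production level absorbing unmodeled regulation
(methylation, histone modification); `ε` is zero-mean Gaussian data noise.

### Identification

Each target defines one linear regression `y = Φθ + ε`: protein rows use
product columns `p_q·p_r`, gene/lncRNA/miRNA rows use plain TF/lncRNA
expression columns plus self-multiplied miRNA product columns `m_w·y`, and a
trailing all-ones column carries `λ`. The fit minimizes `½‖Φθ − y‖²`
subject to `θ_j ≤ 0` on miRNA columns — a convex box-constrained least
squares problem. Implementation: ordinary least squares when no constraint
is active, otherwise `scipy.optimize.lsq_linear` (BVLS, tolerance 1e-12).
Rank-deficient designs return the minimum-norm solution with a warning
flag. When a target has ≥ N−1 candidate regulators (the overfit regime),
candidates are pre-truncated to the N−2 most absolutely correlated with the
response, with a logged warning.

### Order detection and pruning

The number of genuine regulators (the system order) is detected by
minimizing `AIC(k) = log(SSE/N) + 2(k+1)/N` (natural log; SSE floored at
1e-12·N for perfect fits). The search removes regulators one at a time —
always the one with the smallest standardized coefficient magnitude
(|coefficient| × column standard deviation) in the *current refit* — down
to the empty model, and returns the AIC-minimizing member of that nested
family, resolving ties toward fewer parameters. Refitting after each
removal matters because regressor columns are correlated in these designs
(the miRNA product columns all contain the response as a factor); a
one-shot ranking from the full fit misattributes near-collinear columns.
On candidate sets of ≤ 8 regulators the backward search reproduces the
exhaustive-subset AIC minimum in ≈ 96% of random instances (the remainder
are near-ties among statistically equivalent subsets).

Pruning applies order detection to every entity. A directed edge survives
if its target's detected model retains it. An undirected ppi edge makes a
claim about *both* endpoint models, so it survives only when both retain
it; the stored ability is the mean of the two endpoint estimates. This
AND-rule is deliberately conservative: each protein regression contains the
response as a factor of every regressor column, which makes single-endpoint
support weak evidence.

### What the AIC can and cannot deliver

With independent regressor columns, AIC retains a spurious candidate with
probability `P(χ²₁ > 2) ≈ 0.157` — that is the criterion's designed
operating point, not an implementation artifact. At 50% spurious
candidates, planted-edge precision is therefore capped near
`R/(R + 0.157) ≈ 0.86` even at full recall `R = 1`. Two structural
features of GWGEN designs push the realized null-retention rate to
0.2–0.3: lncRNA regulators are themselves linear composites of TFs (one
lncRNA column can compress several TF effects, and AIC sometimes prefers
the compact wrong model), and the miRNA/ppi product columns contain the
response's noise (a simultaneity effect that distorts the nested F
statistics of co-candidates). On the pruning benchmark below the package
measures recall ≈ 0.98 and precision ≈ 0.81. Users who need higher
precision should lower the admission rate by replacing the AIC penalty
with a BIC-style `log(N)·k/N` — at the cost of recall; the package keeps
the AIC form.

## 2. Principal network projection (PNP)

The identified abilities are assembled into the network matrix `H`
(rows: protein, gene, lncRNA, miRNA targets; columns: ppi-participating
proteins together with TFs, then lncRNAs, then miRNAs; an undirected κ̂
appears symmetrically at both ppi cells). `H = S·diag(v)·Dᵀ` by SVD;
singular-value energies `E_i = v_i²/Σv²`; the minimal leading set with
cumulative energy ≥ 85% (configurable) is retained; node a's score is
`S(a) = Σ_{b≤I} (h_a·d_b)²`, the squared norm of its row's projection onto
the retained right singular subspace (at full rank this is `‖h_a‖²`, by
Parseval). The core GWGEN is the subnetwork induced on the `top_k` nodes
by score (default 3000), with regulator-only nodes (e.g. pure TF columns)
ranking at score 0 and ties broken by node id.

## 3. Core-network comparison and over-representation

Two cores (disease vs control) are partitioned exactly by edge identity
(endpoints + mode) into common / disease-only / control-only sets; nodes
likewise. Expression direction per node is the pseudo-counted fold change
`log2((mean_disease + 1)/(mean_control + 1))`, labeled higher/lower in
disease when its magnitude reaches 0.5 (configurable) — a deliberately
simple monotone criterion. Gene-set over-representation of any node set
against user-supplied GMT collections uses the one-sided hypergeometric
tail `P(X ≥ k)` with Benjamini–Hochberg q-values across sets (raw p-values
are also reported). Biomarker choice itself is a user input, not computed.

## 4. The DTI classifier

Drug–target pairs arrive as concatenated descriptor vectors (363 drug +
996 target features by default). Features are standardized (per-feature
mean/sd from the training split only; zero-variance sd floored at 1e-8)
and PCA-reduced to 618 components — the classifier's input width — clipped
to the attainable rank on small data. The network is fully connected,
618 → 512 → 256 → 128 → 64 → 1: ReLU hidden activations each followed by
inverted dropout (rate 0.4, training only), a sigmoid output unit, binary
cross-entropy loss with probabilities clipped to [1e-7, 1−1e-7], Adam at
learning rate 1e-4, batches of 100, up to 100 epochs with early stopping
(validation loss, patience 10, best weights restored). Hidden layers use
He initialization; the output head starts at zero so the untrained
classifier emits exactly 0.5. Parameters and activations are float32 (the
sigmoid is evaluated in float64); all randomness — initialization, batch
order, dropout masks — flows from one seeded generator, so training is
bit-reproducible on a single thread.

Evaluation: a stratified quarter of the pairs is held out as the test set;
ten-fold stratified cross-validation runs on the remainder; the fold model
with the highest testing accuracy is retained. Metrics: confusion counts
at threshold 0.5, TPR, specificity, FPR = 1 − specificity, a
threshold-sweep ROC curve and trapezoidal AUC (equal to the normalized
Mann–Whitney U statistic). Binding prediction scores every drug × target
pair and keeps pairs with probability ≥ 0.5 (configurable).

## 5. Drug design specifications

Four screening axes: *regulation ability* (signed perturbation response
per (drug, gene); positive = upregulation; exactly zero cannot drive a
direction and counts as unwanted), *toxicity* (LD50 in mol/kg, larger =
safer), *sensitivity* (EC50, smaller = more potent), *side effect* (the
count of core-network binding targets other than the desired biomarkers).
`filter_candidates` removes drugs failing any threshold and sorts by LD50
descending, side effect, EC50, id. `select_combination` searches drug
subsets exhaustively (size ≤ 2 by default): a subset is feasible when every
biomarker is bound by ≥ 1 member *and the member-summed regulation* has the
desired sign for every biomarker — net-effect reasoning, so one member's
small unwanted regulation can be outweighed by another's strong desired
one. Among feasible subsets the winner has minimal size, then minimal
total side effect, then maximal minimum LD50, then minimal total EC50,
then lexicographic ids. On the bundled nine-compound T2D panel the unique
feasible pair is Sulforaphane + Biotin (net ETS1 regulation
0.089 − 0.986 = −0.897 < 0), reproduced by an independent brute-force
enumerator in the tests.

## 6. Synthetic data: what it emulates and what it does not

The generator plants a ground-truth subnetwork inside a candidate network
and emits expression that satisfies the model equations *identically* —
the residual of the true regression model equals the injected noise — so
noiseless identification is an exact oracle. Because the equations are
linear in the target's own expression they solve in closed form, e.g.
`g = (Σαt + Σβl + λ + ε)/(1 + Σγm)`; no fixed-point iteration is involved.

Design choices, in the package's own words:

* **Exogenous drivers.** TF expressions and a subset of proteins
  ("drivers", one third) are i.i.d. `|Normal(1, 0.5²)|` draws (drivers
  capped at 3). The protein equations are bilinear and mutually coupled;
  restricting ppi edges to responsive × driver pairs keeps them exactly
  solvable. Driver rows consequently follow no regression model of their
  own — one reason the ppi AND-rule exists.
* **Acyclic lncRNA/miRNA cross-regulation.** lncRNAs and miRNAs are
  generated in an interleaved order; within-class and cross-class edges
  run from earlier to later entities only.
* **Ability draws.** Uniform in [−2, 2] (miRNA repression in [0, 2]) with
  a minimum magnitude of 0.3 — an edge with near-zero ability is
  indistinguishable from no edge and would make the planted truth
  ill-posed. Each responsive protein's κ set is rescaled when needed so
  the closed-form denominator stays positive. Every lncRNA/miRNA receives
  at least one true TF regulator with |ability| ≥ 1, so every regulator
  varies even in the noiseless limit (identifiability).
* **Basal levels.** lncRNA/miRNA basal is U[0.5, 1.5] so transcriptional
  drive dominates their dynamic range; gene and protein basal is U[3, 6]
  (pure sinks — ample basal keeps additive noise a small fraction of even
  strongly repressed targets). Basal levels additionally carry a margin
  covering the worst case of the negative linear regulation, so simulated
  expression rarely goes negative; residual negatives are clipped to zero
  and counted in the log.
* **Noise** is `Normal(0, 0.1²)` by default, injected inside the model
  equation (so the regression residual is exactly the noise).

What passing these tests does **not** show about real data: real
expression is counts-based with mean-dependent (not additive Gaussian)
noise; real candidate networks have hub-dominated degree distributions and
feedback loops, not the acyclic generated topology; real protein rows all
follow the coupled bilinear system rather than splitting into drivers and
responders; and real regulation is time-dependent while the model is a
static regression across samples.

The DTI generator plants a linear rule in descriptor space: pairs are
scored by a latent weight vector and the benchmark keeps the
highest-scoring pairs as positives and lowest as negatives, discarding the
ambiguous middle band — mirroring how affinity databases are thresholded
into confident binders and non-binders. Clean labels are therefore
linearly separable with a margin; `label_noise` flips labels i.i.d.
Real descriptors are far from isotropic Gaussian and real binding is not
linear in them.

The bundled drug-screening panel carries the published values for the nine
T2D candidate compounds (biomarker bindings, side-effect counts,
regulation abilities, LD50, EC50). The published panel does not name the
off-target bindings behind each side-effect count, so those are synthetic
placeholder ids, one per counted binding.

## 7. Benchmark problem sizes

The shipped acceptance benchmarks use: identification/pruning networks of
10 proteins, 10–20 genes, 2–5 miRNAs, 4–5 lncRNAs, 14 TFs, N = 200
samples, noise sd 0.1, 50 seeds (≈ 10 candidate regulators per gene at
density 0.5, half spurious); exhaustive-AIC cross-checks on ≤ 8
candidates; PNP identities on random 30 × 20 matrices; DTI training on
5,000 pairs of full descriptor width with the training budget set to 50
epochs (accuracy on the separable benchmark plateaus well before);
enrichment oracles on universes of ≤ 25 nodes.

## 8. Known limitations

* The regression forms place the observed response inside the miRNA and
  ppi product regressors; estimates of those coefficients are therefore
  not consistent in the errors-in-variables sense, and co-candidate
  selection rates are mildly inflated (§1). This is a property of the
  model family, faithfully implemented.
* AIC order detection trades recall for a fixed ~16% per-candidate
  false-admission rate; see §1 for the precision ceiling this implies.
* The DNN is a single-threaded NumPy implementation: exactly reproducible
  and fast enough for the benchmark sizes, but not GPU-scalable.
* DTI model persistence is a plain ``.npz`` of weights and preprocessing
  statistics (``DTIResults.save`` / ``gwgenkit.dti.model.load_model``);
  no versioning or integrity checking is attempted.
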