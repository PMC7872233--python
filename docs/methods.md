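# Methods

This note documents the models, algorithms and design choices behind
`braflogic`: what is simulated, which parameters matter, what the synthetic
cohort does and does not emulate, and where the design was genuinely open.

## Stochastic semantics of multi-valued logical networks

A network is a set of nodes with discrete activity levels in
`[0, max_level]` (`max_level = 1` is Boolean).  Each non-input node carries
one logical expression per level over the `&`, `|`, `!` grammar with
threshold literals `node:l` (true iff the node's level is at least `l`);
its *target level* in a state is the largest level whose expression holds
(0 if none).  Expressions for consecutive levels must nest — satisfying the
level-`l+1` expression implies satisfying the level-`l` expression — so the
target is well defined; `validate_model` checks this by enumeration over
each rule's regulators (or seeded sampling when the product space exceeds
2^16).

Dynamics are a continuous-time Markov chain with asynchronous updating.
In any state, every node sitting below (above) its target contributes one
enabled transition moving it one level up (down) with propensity `k_up`
(`k_down`); both rates default to 1 per node.  Events are drawn with the
Gillespie direct method: exponential waiting time in the total propensity,
transition chosen proportionally to its rate.  Input nodes never
transition: their level is drawn once from the initial condition and held,
modeling environmental conditions.  A state with no enabled transition is
absorbing.

Initial conditions assign each node an activation probability `a`: the
node starts at `max_level` with probability `a` and at 0 otherwise,
independently across nodes and trajectories; unspecified nodes use
`a = 0.5`.  Mass on intermediate levels is not supported — it is not needed
by any analysis here, and the 0/max convention is the natural multi-valued
extension of the Boolean one.  Deterministic assignments (`a` of exactly 0
or 1, and forced nodes) consume no randomness, which makes structurally
extended models (e.g. with an inactive inhibitor node) reproduce the
original simulation bit-for-bit under the same seed.

An ensemble of `n_trajectories` independent trajectories (default 5000) is
summarized as (i) the mean stochastic trajectory — per-node expected
normalized level `E[level]/max_level` sampled on an evenly spaced grid of
`n_time_points` (default 100) from each piecewise-constant path — and
(ii) the empirical distribution over full model states at `t_end` (default
50 time units).  Phenotype scores are the expected normalized level of a
declared read-out node at `t_end`.

### Implementation and verification

The ensemble simulator compiles every rule into a target-level lookup
table indexed by the mixed-radix encoding of its regulators' levels and
runs the Gillespie loop in a numba-compiled kernel with incremental
propensity updates (the running total is refreshed every 4096 events to
bound floating-point drift).  Results are bit-reproducible given the
configuration seed.

Two independent implementations guard the semantics: a pure-Python
single-trajectory sampler built directly on `enabled_transitions`, and an
exact transient solver that assembles the master-equation generator over
the full state space (capped at 2^14 states) and computes
`pi(t) = exp(Q^T t) pi(0)` with SciPy's sparse matrix-exponential action.
The test suite checks the kernel against closed forms (`1 - e^{-t}`
activation curves) and against the exact solver on randomized small
models, and checks the exact solver itself against a hand-built ODE
integration on a mutual-repression pair.

## Model checking

Assertions compare the probability of a condition — a conjunction of
`node = level` or `node >= level` clauses evaluated on the `t_end` state
distribution — between a baseline and a perturbed simulation, with an
expected direction (`increase`, `decrease`, `unchanged`).  Perturbations
pin nodes to fixed levels; several assertions compare two perturbed
regimes via explicit baseline perturbations.

Because both probabilities are Monte-Carlo estimates, verdicts use a
significance guard: the assertion's tolerance (default 0.01, the minimum
change considered meaningful) is augmented by twice the combined binomial
standard error.  `increase` therefore requires
`delta > tolerance + 2*SE`, `decrease` the mirror image, and `unchanged`
`|delta| <= tolerance + 2*SE`.  Routine scoring uses the conventional 5000
trajectories, but suite verification defaults to larger ensembles (the
packaged checks run at 50000) purely to stabilize verdicts: every packaged
assertion's effect was measured at 30000-50000 trajectories and exceeds
the tolerance on its own; the larger ensemble narrows the estimator, it
does not create effects.

## The BRAF signaling model

The packaged network (30 nodes; MEK, ERK, p70 and Proliferation ternary)
covers the MAPK cascade (receptors EGFR/ERBB2/ERBB3/MET/FGFR2, GRB2-SOS,
RAS, the BRAF and CRAF isoforms, MEK, ERK), the PI3K/AKT axis (GAB1, PI3K,
PTEN, PDPK1, AKT, mTOR, p70), the SOX10/FOXD3/ERBB3 axis distinguishing
the melanoma context, a p53/p21 damage arm under the ATM input, and the
ERK-driven negative feedbacks.  MEK reaches level 2 only through BRAF,
which phosphorylates it more efficiently than CRAF; ERK mirrors MEK.

Rule choices that were genuinely open, and how they were resolved:

* **GAB1 = (EGFR | MET) & !ERK.**  The ERK feedback on PI3K signaling acts
  on the EGF-dependent GAB1/PI3K association, so GAB1 is driven by EGFR
  rather than by the whole GRB2 hub; MET is included because GAB1 is the
  principal direct effector of HGF/MET signaling.
* **PI3K = GAB1 | ERBB3.**  ERBB3 couples to the p85 subunit of PI3K
  directly — this is the biochemical basis of the NRG1/ERBB3 resistance
  axis.  A direct RAS→PI3K edge was considered and dropped: it saturates
  baseline PI3K activity, masking the pathway-switch behavior (AKT
  induction after BRAF or MEK inhibition) that the model must reproduce.
* **mTOR = AKT & !p70:2.**  The canonical S6K negative feedback
  (S6K-mediated IRS-1 degradation shuts down PI3K/mTORC1 signaling),
  modeled at the mTORC1 step.  It duty-limits the p70 arm so that a cell
  cannot sustain maximal proliferative signaling on the PI3K arm alone
  indefinitely — without it, low-MAPK states are fully compensated by the
  released PI3K arm and CRAF expression loses its effect on inhibition
  response, contradicting the CRAF-mediated resistance the model exists to
  capture.
* **p21 = p53 & !AKT.**  AKT phosphorylates and inactivates p21; this
  makes PI3K-axis lesions relieve the cell-cycle brake, which is how
  PTEN-loss resistance manifests in the damage-active half of the state
  space.
* **Proliferation: level 1 = !p21 & (ERK | p70:2); level 2 =
  !p21 & ERK:2 & p70.**  Any ERK signal, or a fully engaged p70, licenses
  proliferation; maximal proliferation requires maximal ERK with p70
  support.  The read-out is deliberately MAPK-weighted: sustained
  PI3K-only signaling yields at most moderate proliferation.
* **FOXD3 inhibition of EGFR** is retained (`EGFR = EGF & !ERK & !FOXD3`)
  even though the supporting evidence is from colorectal cells; in the
  melanoma context (EGF absent) the edge is inert anyway.

Three initial-condition profiles encode tissue context: `generic` (every
node at 0.5), `IC_CRC` (EGF = 1, SOX10 = NRG1 = 0) and `IC_melanoma`
(SOX10 = NRG1 = 1, EGF = 0).

Under the generic profile the model's mean Proliferation score over 100
replicate ensembles of 5000 trajectories is 0.184 with replicate standard
deviation 0.004, and the same mean at `t_end = 100` — the distribution is
asymptotic well before the scoring horizon.  The packaged assertion suite
(17 assertions encoding nine literature-reported behaviors: the
CRC-specific EGFR feedback, MEK-inhibition effects, HGF rescue, the
melanoma SOX10/FOXD3/ERBB3 axis, CRAF-mediated ERK reactivation, PI3K-axis
resistance and its reversal by combined inhibition, and AKT induction
independent of EGFR) passes at every tested seed.  The HGF-rescue
assertion runs in a ligand-free context (EGF = FGF = NRG1 = 0) supplied
inline, mirroring the ligand-controlled rescue experiments it encodes;
under the generic profile receptor redundancy leaves no headroom for any
single ligand.

## Personalization

Per-cell-line models are derived from two omics layers:

* **Mutations (discrete).**  Mutations are interpreted against a packaged
  OncoKB-style table (exact protein changes plus a `truncating` wildcard
  for nonsense/frameshift calls); annotated gain-of-function lesions force
  the mapped node to its maximum level, loss-of-function to 0, for the
  whole simulation.  Unannotated mutations are dropped.  GOF and LOF
  colliding on one node in one cell line is an error.
* **RNA (continuous).**  Expression is min-max normalized per gene across
  the cohort (constant genes map to 0.5; optional percentile winsorizing
  is available).  A mapped node with normalized value `x` starts active
  with probability `x` and has its rates skewed to
  `rate_up = A^(2x-1)`, `rate_down = A^(1-2x)` with amplification
  `A = 100`: the midpoint is exactly neutral, the product of the two rates
  is always 1, and the mapping is symmetric in `x <-> 1-x`.  Unmapped
  nodes keep defaults.
* **Combined.**  The continuous layer is applied first; mutation forcing
  then overrides rates and initial conditions on the forced nodes — a hard
  genetic lesion dominates a soft expression readout.

The packaged gene→node map is an editable TSV.  Family nodes pool
paralogs by averaging (RAS from NRAS/KRAS/HRAS: total isoform dosage).  A
`use_rna` flag marks genes whose transcript is *not* accepted as an
activity proxy — BRAF (activation is mutation-driven, not dosage-driven)
and the damage sensors ATM and TP53 (post-translationally controlled) —
these genes still feed mutation interpretation.  The flag matters because
min-max normalization stretches every gene to the full `[0, 1]` range, so
the per-gene extreme cell lines would otherwise receive 100-fold rate
distortions on channels where expression carries no signal.

## Synthetic cohort

No screening data are bundled; the generator emulates the statistical
structure of melanoma/colorectal cell-line panels so the pipeline's
recovery behavior has a known answer:

* Tissue-specific driver frequencies (BRAF 0.50/0.15 in melanoma/CRC,
  RAS family 0.25/0.40 — NRAS in melanoma, KRAS in CRC — TP53 0.20/0.60,
  PTEN 0.15/0.10, PIK3CA 0.05/0.20), with hotspot protein changes matching
  the packaged annotations.  BRAF V600 and RAS hotspot mutations are
  mutually exclusive, as in tumors.
* Expression with tissue shifts (SOX10 high in melanoma, EGFR high in
  CRC).  RAF1 and PDPK1 are drawn from a two-mode mixture (modes ±2 around
  the baseline, within-mode SD 0.8): the analysis this cohort feeds is
  about distinctly-low versus distinctly-high CRAF/PDPK1 lines, and a
  unimodal draw leaves most lines in an uninformative middle ground.
  Background genes receive Gaussian noise contaminated with 3% outliers at
  5x the gene SD — real expression matrices have heavy-tailed per-gene
  ranges, and under min-max normalization those outliers are what keep the
  bulk of the cohort away from the extreme rate regime.
* A latent sensitivity per line,
  `s = clip(0.15 + 0.55*BRAF - 0.25*RAS - 0.25*craf - 0.15*pdpk1
  - 0.25*(PTEN or PIK3CA) + N(0, 0.05), 0, 1)`
  with `craf`/`pdpk1` the cohort-normalized RAF1/PDPK1 expression: the
  narrated resistance logic (BRAF-mutant lines sensitive; RAS activation,
  high CRAF, high PDPK1 and PI3K-axis lesions resistant).  Observable
  metrics are derived from it: drug `AUC = clip(1 - 0.5 s + N(0, 0.04))`
  (low = sensitive) and CRISPR scaled Bayes factor `8 s - 2 + N(0, 0.4)`
  (high = sensitive), anti-correlated by construction.

What the cohort does **not** emulate: co-expression structure between
genes, copy-number and proteomic layers, dose-response measurement
artifacts, tissue-specific drug pharmacology (the inhibitor is modeled as
an unconditional on/off input), and the long tail of passenger mutations.
Passing recovery tests therefore show that the pipeline extracts the
signals this generative model plants — not that it would extract them from
any real panel.

## Validation pipeline

For each cell line and strategy, two simulations are run: untreated, and
with an inhibitor input grafted onto the target node (every level
expression becomes `old & !inhibitor`, so the active inhibitor forces the
target to decay to 0; on a mutation-forced target the inhibitor overrides
the forcing while preserving the forced initial level).  The two arms
share the configuration with deterministically split seeds.  The ratio of
inhibited to untreated Proliferation score is the sensitivity proxy; a
line whose untreated score is 0 cannot be further inhibited and reports
ratio 1 with a warning flag.  Ratios are min-max normalized across the
cohort (a bounded, cohort-relative score; constant vectors map to 0.5) and
correlated against each sensitivity metric with Pearson's r and the
two-sided t-transform p-value.  Informative models give positive
correlations against AUC and negative against Bayes factors.

Pipeline runs use 2000 trajectories per simulation: the quantity consumed
is a cohort-level correlation over 120+ ratio estimates, and the
Monte-Carlo error of each ratio (~0.03) is well below the cohort spread of
the ratios themselves (~0.15); the scoring-sensitive quantities (generic
score, assertion suite) keep their larger ensembles.

The CRAF-separation analysis — among BRAF-mutant lines, distinctly low
CRAF expression should yield lower normalized scores under the combined
strategy — is run on BRAF-mutant lines *without* PTEN/PIK3CA co-mutations
(PI3K-axis forcing is a separate, CRAF-independent resistance route that
would contaminate both arms) with a one-sided Mann-Whitney test at the
median RAF1 split, on a doubled (120+120) cohort so that each arm holds at
least 30 lines.

The learning baseline is a bootstrap ensemble of randomized regression
trees (scikit-learn) scored by out-of-bag explained variance
`1 - MSE_oob / Var(y)`, with permutation variable importance (mean
performance drop over repeated within-column shuffles).  It is comparison
plumbing: on the synthetic cohort it recovers BRAF mutation status as the
dominant predictor of drug sensitivity.

## Numerical and degenerate-input conventions

* Constant expression vectors normalize to 0.5 (both gene-wise expression
  and cohort score normalization).
* `t_end` distributions from the exact solver are clipped at 0 and
  renormalized (they sum to 1 within 1e-9 before clipping).
* Pearson correlation requires n >= 3 and non-zero variance in both
  vectors; degenerate inputs raise rather than return NaN.
* Assertion verdicts are monotone in tolerance by construction; identical
  seeds give identical verdicts.
* The simulator caps exact-solver state spaces at 2^14 states and rule
  lookup tables at 2^20 entries; larger models are rejected with a clear
  error rather than silently degraded.

## Known limitations

* The logical model is a reconstruction: it reproduces the published
  score, the literature-derived assertion suite and the narrated
  resistance mechanisms, but makes no claim of rule-level identity with
  the original curated network.
* Intermediate initial levels for multi-valued nodes are not expressible.
* The inhibitor model is unconditional (no mutant-selective or paradoxical
  pharmacology).
* RNA is an imperfect proxy for node activity; the per-gene `use_rna`
  flags are a coarse instrument for that judgment, and the combined
  strategy's gain over mutations-only varies with the cohort draw.
* No copy-number or (phospho)proteomic personalization; no temporal-logic
  model checking; no GINsim/SBML-qual import; no synchronous updating.
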