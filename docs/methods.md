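# Methods

## Model

A cell type is represented by a Boolean network: nodes are genes, proteins
or cytokine signals, each with one update rule over NOT/AND/OR, evaluated
**synchronously** (all nodes update simultaneously on the current state).
The synchronous scheme was chosen because the simulation protocol counts
discrete time steps uniformly across genes and because the minimal
master-regulator circuits this package targets are conventionally analysed
with synchronous fixed points; asynchronous and probabilistic-update
semantics are out of scope.

A **microenvironment** is a clamping of input nodes.  A clamped node's
value overrides its rule at every step and is exempt from noise: it is an
experimenter-imposed boundary condition, not an intracellular variable.
When a scenario fixes a chemical context, *every* declared input is
clamped — inputs the condition does not mention are clamped to 0 (absent),
never left free-running.

**Attractors** of the clamped dynamics (fixed points and cycles) are stable
gene-expression patterns and are read as cell phenotypes.  Exhaustive
enumeration encodes the free nodes of a state as an integer rank, computes
the successor of every state at once (rules evaluated vectorised over the
whole state space), and finds cycles by pointer doubling on the successor
array; basins follow from one gather.  The exhaustive cap is 20 free nodes
(~10^6 states) by default; beyond it, a seeded sampled mode relaxes random
initial states and reports estimated basin fractions (default 5000
samples).  Attractor ids are deterministic: ordered by the smallest state
rank each attractor contains.  Cycles are enumerated and reported even
though the marker schemes only define fixed-point phenotypes; by default a
cycle is labelled `unclassified-cycle` (a logged, explicit choice), with an
optional state-average labelling policy.

**Phenotype schemes** are ordered marker-pattern lists with first-match-wins
semantics.  Ordering resolves the overlaps the marker definitions leave
implicit: the TAM patterns (iNOS+ Arg1+) are checked before plain M1/M2,
M1-TAM (which additionally requires IL-12 or IFN-γ) before M2-TAM, and the
FoxP3-pinning regulatory CD4 patterns before the effector ones, iTreg
(three markers) first.  Th1 is identified by the lineage's intracellular
master regulator (T-bet) plus IFN-γ rather than by the input cytokine
IL-12; scheme node names are bound to a concrete network at load time
through a configurable alias map, so schemes survive reconstructions with
different node naming.  A pattern referencing a missing node is a
load-time configuration error, never a classify-time surprise.

## Stochastic protocol

At each step, after the synchronous rules fire, each free node's output is
complemented independently with probability `noise` (one uniform draw per
node per step).  Noise levels 0.03, 0.08 and 0.13 form the robustness set;
0.08 is the working default.  The full protocol runs 10000 steps and 30
trajectories per initial phenotype, repeated for 10 rounds; the per-round
row-normalised transition matrices are averaged (pooled-count estimation is
available behind a flag).  Tests and the acceptance script use a reduced
protocol — 2000 steps × 10 trajectories × 3 rounds — which leaves every
Monte-Carlo estimate with ≥ 6×10^4 observed transitions per chain state;
this is the package's own test-scale choice and the estimator is identical
at any protocol size.

Every sampled trajectory state is mapped to an attractor by **noise-free
relaxation** (basin membership, an O(1) lookup against the precomputed
label array) and thence to its phenotype label; consecutive label pairs are
accumulated into counts.  This is the standard construction for stochastic
discrete dynamical systems: it degenerates to "count how often the
attractor is conserved" when trajectories hug their attractors, and is
well defined for transient states.  Attractors sharing a phenotype label
are merged into one chain state *before* counting, so the chain is over
phenotypes.  Rows with zero observations become self-loops, which keeps the
matrix stochastic without inventing transitions.  `label_every` subsamples
the trajectory for coarser counting.

Randomness: a single root `SeedSequence` spawns one independent stream per
round; within a round all trajectories are batched (vectorised) on that
stream.  Identical protocol + seed gives bit-identical counts.

Declared input nodes that are left unclamped receive noise like any other
free node by default (`noisy_inputs=True`); setting the flag to False
exempts them.  The default keeps the single-bit fixture (`A, A`) a genuine
symmetric flip chain.

## Stationary distributions

Phenotype frequencies are π = lim (Pᵀ)ᵗ x₀, computed by power iteration
until the successive L1 change falls below `tol` (default 1e-12, max 10^6
steps), then cross-checked two ways: the fixed-point residual |πP − π|₁
must be below 1e-8, and for chains with a unique unit eigenvalue π must
match the dominant left eigenvector of P.  Reducibility (unit eigenvalue
multiplicity > 1) is detected and flagged — the limit then depends on x₀.
Periodic chains do not converge pointwise; the Cesàro flag returns the
running time-average instead, stopping on the stationarity residual
(Cesàro averages converge only as O(1/t), so successive-change stopping
would be misleading).

Scenario averages are uniform means of the per-microenvironment stationary
distributions (per insulin setting, then overall), mirroring the fact that
only the tissue-level mixture is observable.

## Validation statistics

Qualitative relations ("A > B", "A > others", "Others = 0 %") are evaluated
on stationary distributions with **strict** inequalities; ties score 0 with
a logged note.  Marker tokens such as `GLUT4+` aggregate every phenotype
label containing them.  The zero-assertion holds when every non-baseline
label has mass below 1e-9.  Pooled successes over all conditions and noise
levels feed an exact one-tailed binomial test against p₀ = 0.5 (tail sum,
no normal approximation); the reported bound is the one-sided exact
Clopper–Pearson lower limit, the Beta(α; s, n−s+1) quantile (0 when s = 0).

Quantitative validation correlates paired simulated/observed frequency
vectors: R² is the squared Pearson coefficient, R_xx its positive root,
adjusted R² uses one predictor, and the p-value comes from the F statistic
of the single-predictor regression.  This operation is validated by
construction (closed-form oracles in the tests), since no numeric reference
values exist for it.

## Bundled VAT models

The three rule files under `src/vatmarkov/data/` are clearly-versioned
reconstructions (`provenance: reconstructed-from-main-text`); every rule
block carries a comment naming the causal observation motivating it.  Their
acceptance contract is behavioral: under the qualitative-validation grid
the stationary distributions must satisfy the expected relations at all
three noise levels — at least 24/27 for CD4+ T cells (the "Others = 0 %"
row necessarily fails under any positive noise, because the multistable
unstimulated network keeps residual mass on non-Th0 attractors), 12/12 for
macrophages and 12/12 for adipocytes.

The adipocyte model encodes the causal spine of insulin resistance:
insulin → IRS → GLUT4 translocation; TNF/IL-6/IFN-γ (or the CoCl₂-type
inducer) → NF-κB → TNF/IL-1β secretion and intracellular ceramide;
ceramide blocks IRS and sustains itself unless degraded by
adiponectin-receptor signalling; PPARγ drives adiponectin and is repressed
by inflammation and ceramide; IL-10/IL-4 quench NF-κB except under severe
(triple-cytokine) inflammation; TNFR2 gates the autocrine amplification
loops and the hypertrophy marker CTGF.  Consequences the package verifies:
insulin alone → GLUT4+ dominance (the insulin-resistant, ceramide-on
attractor exists but has a small basin); insulin + TNF → GLUT4−;
adiponectin over-activation, PPARγ over-activation or intracellular
ceramide knockout restore GLUT4+ under severe inflammation, while single
anti-cytokine neutralisations and IL-10 alone do not.

Microenvironment catalogs for the lean/obese/diabetic contexts
(`data/scenarios.yaml`) binarise the documented cytokine profiles
(high/low → 1/0, the only representation a Boolean model admits); the
diabetic catalog is the obese one plus extracellular ceramide.  Four
microenvironments per cell type per context, each run with and without
insulin, is a deliberate default — the exact number and composition of
contexts is configuration, not biology, and users can supply their own
scenario files.

## Synthetic data

Random networks are truth-table based: each node draws a random k-input
table whose entries are 1 with probability `bias`, rendered to expressions
by minterm expansion (keeping the bias exact), emitted in the standard
dialect and round-tripping through the parser.  The toy fixtures have
closed-form behavior: the single-bit net's noisy chain is exactly
[[1−q, q], [q, 1−q]] with stationary (1/2, 1/2); the toggle switch has two
unit-basin fixed points and one 2-cycle of basin 2; the three-node relay
has exactly one attractor per input clamping; the mini-adipocyte realises
all eight marker combinations as fixed points.  Fixture truth tables are
asserted at import as a tamper check.

What the generator does *not* emulate: scale-free topology, critical-regime
tuning, or any transcriptome-like correlation structure.  Passing tests on
synthetic networks therefore demonstrate algorithmic correctness
(enumeration, labelling, estimation, statistics), not biological fidelity
of any particular network.

## Numerical choices and edge cases

* Row-stochasticity is enforced to 1e-12; distributions sum to 1 within
  1e-10.
* Discretisation of TPM matrices uses the ≥-row-mean rule; a constant gene
  row (value = mean) discretises to all ones.
* The Monte-Carlo tolerance for the analytic single-bit chain is three
  binomial standard errors per matrix entry; for its stationary vector the
  entry error is propagated by the delta method (sd(π) ≈ se·√2/(4q)).
* Exhaustive mode refuses > 20 free nodes with an explicit pointer to
  sampled mode.
* Empty qualitative trial lists are an error, never a vacuous pass.

## Known limitations

* Synchronous-only semantics; no multi-valued logic, no ODE refinement.
* The bundled networks are reconstructions: they satisfy the documented
  qualitative contract but make no claim of matching any particular
  published truth table, and figure-level bar heights of the original
  study are not reproduction targets.
* Phenotype classification of cycles is a convention (excluded by
  default), not biology.
* The quantitative correlation module treats each condition separately; no
  pooled multi-panel analysis or multiple-testing correction is provided.
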