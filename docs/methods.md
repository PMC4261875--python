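# Methods

This note documents the models, parameter choices and numerical conventions
behind `paleofv`, and what the synthetic-data generators do and do not
establish.

## Neutral decay model

Post-endogenisation sequence evolution is modelled as the equal-rates
single-site substitution chain (the Jukes–Cantor model): each site leaves
its current base at total rate *r* (substitutions/site/year) and the
replacement is uniform over the other three bases. This is the unique
Markov chain that is homogeneous, independent across sites, and symmetric
across base types, so a "neutral, homogeneous, independent" decay assumption
pins it down with no free parameters beyond the rate. Defaults:

* `MAMMAL_NEUTRAL_RATE = 2.2e-9` /site/year — the average neutral
  substitution rate of mammalian genomes; used for all dating.
* `OVERESTIMATE_RATE = 1.0e-8` /site/year — a deliberate overestimate used
  to stress-test whether neutral change alone can move a sequence's
  phylogenetic position (the "pseudogene effect" experiment). The value is
  read as ten × 10⁻⁹, consistent with its description as an overestimate of
  2.2×10⁻⁹.

Sequences are evolved by **endpoint sampling**: each site's state after *t*
years is drawn from the closed-form transition probabilities
P(unchanged) = ¼ + ¾·e^(−4rt/3), which is distributionally identical to
simulating individual substitution events and costs O(sites). Gap and
ambiguity symbols keep their positions, so mutated alignment members stay in
their original coordinates; no re-alignment is performed (re-aligning does
not change relative positions for the small divergences involved). The
independent correctness oracle is `analytic_stop_probability`, which sums
the exact per-codon probability of reading as TAA/TAG/TGA over the three
stop codons and averages over counted codons.

## Stop-codon census conventions

Counting operates on the caller-supplied reading frame: gaps are stripped,
`frame_offset` bases skipped, a trailing partial codon ignored. The
**terminal codon is excluded** by default, because an annotated frame's
natural stop carries no decay signal. Codons containing non-ACGT symbols
are excluded from both the stop count and the codon total; counting them in
either alone would bias the frequency, and the convention keeps frequency ×
total = count exactly. Frequencies display at 3 significant figures
(9/1163 → "0.00774"; 14/975 → "0.0144") but are carried at full precision.

## Monte-Carlo integration dating

For each intact model sequence, stop-codon frequencies are simulated on an
age grid (default 5–200 Myr, step 5, 1,000 independent replicates per age —
replicates are endpoint draws per age, not single trajectories). The age
CDF is the per-age **exceedance probability** q(t) = P(f_sim(t) ≥ f_obs),
read as the first-passage CDF of the time needed to reach the observed
frequency under a near-monotone accumulation process; a running maximum
absorbs Monte-Carlo noise. Summaries use the renormalised increments
Δq_k = q(t_k) − q(t_{k−1}): mean Σ t_k·Δq_k, median the smallest grid age
with q ≥ 0.5, mode the grid cell with the largest increment, and a central
95% interval from the 0.025/0.975 crossings. Renormalisation is refused
unless q(t_max) ≥ 0.99 — renormalising a visibly truncated tail would
silently bias every summary young.

Randomness: one master seed; per-(model-sequence, grid-age) generator
streams are spawned deterministically (the per-model component keyed by a
CRC of the sequence id, so identical inputs give identical outputs), and
replicates within an age are vectorised inside one stream.

What a green self-consistency test establishes: with f_obs set to the
analytic expected frequency at a planted age on the grid interior, the
median recovers the planted age within one grid step in ≥95% of seeded
runs. What it does not establish: agreement with the published age
estimates for the real elements, which depend on the codon usage of the six
real pol model sequences. Synthetic stand-ins (generic-protein codon usage,
uniform synonymous codons) place the 0.00774 frequency at a median of
~30 Myr rather than the published 35 Myr; stop-gain rates at small *t* are
dominated by the fraction of codons one substitution from a stop, which is
composition-specific.

## Cophylogeny reconciliation

An exact dynamic program replaces genetic-algorithm search: for every
(virus node, host node) pair the minimum cost of embedding the virus
subtree with its root at, or anywhere below, that host node is tabulated in
postorder. Event classes and costs follow the maximum-cospeciation setting:
cospeciation −1, duplication 0, duplication-and-host-switch 0, loss 0,
failure-to-diverge 0. Because only cospeciation is priced, the solver
requires zero loss cost (losses are then unconstrained and lineages may
slide down host paths freely) and reports implied losses post hoc under an
earliest-divergence convention.

Design choices:

* **Untimed switches.** The host tree carries no divergence times during
  reconciliation; a switch may land on any host edge that is neither the
  source position nor one of its ancestors (descendant edges included).
  This relaxation can only increase the attainable cospeciation count
  relative to a timed reconciliation; on the bundled 17-taxon system the
  exact solver nevertheless returns exactly the published count (14).
* **Determinism.** DP values are lexicographic tuples (cost,
  −cospeciations, switches), so ties prefer more cospeciations then fewer
  switches, and hosts are scanned in postorder with strict improvement —
  output is reproducible bit for bit.
* **Envelope.** Exact solving is restricted to ≤25 tips; heuristic search
  for larger trees is out of scope.

Significance uses **random tip mapping**: the tip bijection is replaced by
a uniform random bijection, the solver re-run, and the add-one permutation
p-value (1 + #{null ≥ observed})/(1 + N) reported. The observed count may
be supplied externally, e.g. a conservative manual re-count that discounts
a cospeciation requiring an unsampled host lineage (14 → 13 in the bundled
system). The test's p-value is super-uniform under the null by
construction; a simulation check is part of the suite.

The solver is verified against an independent brute-force enumerator over
all embeddings on small instances (exhaustively for 4-tip topology pairs,
randomly for 5–6 tips, including non-default costs).

## Codivergence regression and node dating

Branch pairs are extracted from a reconciliation wherever a virus branch
runs between two cospeciation events (or a cospeciation and an associated
tip): the virus branch length (aa substitutions/site) is paired with the
host duration (age difference of the mapped host nodes, from a `NodeAges`
table keyed by clade tip sets). Branches touching duplications or switches
do not track host time and are excluded, as is the virus root branch;
zero-duration pairs are dropped with a warning.

The fit is OLS of virus branch length on host duration, with intercept
(through-origin is not assumed). The regression is oriented this way so
that dating a node is classical inverse prediction: the duration implied by
a branch length y is d = (y − intercept)/slope, the node date is
calibration − d, and the 95% interval propagates the coefficient covariance
through d by the delta method with a t(df) quantile. The delta method was
chosen over Fieller's construction for robustness at small N; the interval
covers the regression's predicted-mean uncertainty, not the scatter of a
new observation.

**Outlier pruning and its behaviour.** Outliers are pruned iteratively:
compute Cook's distances on the current fit, and while the largest exceeds
`cook_factor` (default 3) times their mean, remove that one point and
refit. This is the common 3×-mean rule of thumb applied until convergence.
A caveat documented deliberately: the threshold is scale-free, and on clean
Gaussian data the largest Cook's distance exceeds 3× the mean in ≈99% of
samples (simulated, n = 23), so the default rule keeps pruning well past
any genuinely gross outliers (≈7 of 23 clean points on average) and the
post-pruning confidence intervals are anti-conservative (simulated slope
coverage ≈61% at nominal 95%, vs ≈94% with pruning disabled). Gross
planted outliers are always removed first; but for inference on data not
suspected of contamination, fit with `cook_factor=inf`.

## Synthetic data

* `make_coding_sequence` draws sense codons i.i.d. from a codon-usage
  profile (uniform over the 61 sense codons by default; a
  "fv-pol-like" preset uses a generic globular-protein amino-acid
  composition with uniform synonymous codon use — a stand-in, not an
  estimate of any real sequence), plants an exact number of stop codons at
  random positions and appends a terminal stop, so the census recovers the
  construction exactly.
* `make_cophylo_pair` simulates a Yule host tree (ultrametric; ages derive
  from depths), copies it as the virus tree, and applies tip
  subtree-prune-regraft moves to the virus tree only — host switching
  leaves the host tree untouched — recording each move in a truth ledger.
* `make_regression_pairs` draws host durations uniform on ~1–100 Myr and
  virus lengths on a line with Gaussian noise (defaults: slope 0.007
  subs/site/Myr, intercept 0.001, sd 0.01 — a mammal-scale codivergence
  world), appending verbatim outliers after the regular points.

Generators emulate the statistical structure the analyses assume —
clock-like decay, tree congruence, linearity — not the biology they omit:
no selection, recombination, indels, rate variation among sites or
lineages, or realistic codon usage. Green tests therefore establish
internal correctness and calibration of the methods, not the field accuracy
of any particular published estimate.

## Degenerate inputs and tie-breaks

* Empty reading frames (no countable codons) raise rather than return 0/0.
* A dating CDF that never reaches 0.99 refuses to summarise.
* Perfect regression fits (numerically zero residual variance) skip
  pruning; predictor variance of zero raises.
* Non-positive fitted slopes refuse inverse prediction.
* The modal grid cell and all CDF crossings resolve ties toward the
  earliest grid age.
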