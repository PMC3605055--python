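# Methods

## Model

An annotated global metabolic network is a triple (C, R, E): metabolites C,
reactions R (each an undirected hyperedge over ≥1 metabolites — no
stoichiometry, no direction, all reactions treated as reversible), and
enzymes E, each annotated to a non-empty set of reactions. Reactions with no
annotating enzyme are dropped at construction: the object of study is the
enzyme-supported network. An enzyme with ≥2 annotated reactions is
catalytically promiscuous; these are the only source of inferential
ambiguity.

A subnetwork is a subset N ⊆ R with induced metabolite set C(N) (union over
members) and induced enzymes. N is **valid** iff every enzyme of the parent
network intersects N. The full network is always valid. A reaction that is
the sole annotation of some enzyme is **forced**: it belongs to every valid
subnetwork and its marginal probability is exactly 1 under any distribution
on valid subnetworks. The number of valid subnetworks is bounded above by
∏ᵢ (2^{rᵢ} − 1) over enzymes i with rᵢ annotated reactions (map each valid
N to its per-enzyme intersections; the map is injective and each
intersection non-empty), with equality when no two enzymes share a
reaction.

The target law on valid subnetworks is

    π(N) ∝ exp(−λ · |C(N)|),    λ ≥ 0.

λ = 0 is the uniform law on valid subnetworks; larger λ concentrates mass
on metabolite-sparse subnetworks. λ = 1 is the default. The per-reaction
marginal P(r) = Σ_{N valid, r∈N} π(N) is the probability that r belongs to
the community's realized metabolism under parsimony.

## Sampler

One Metropolis–Hastings step: draw a reaction uniformly from the toggle
pool, toggle it (insert if absent, delete if present), redraw if the result
is invalid (invalid redraws are counted separately and are neither chain
steps nor acceptance-rate denominators), and accept with
min(1, exp(−λ·Δn)), where Δn is the metabolite-count change. Deletions
never increase the count, so parsimony-improving moves are always accepted.
Forced reactions are excluded from the toggle pool: deleting one is always
invalid and it is never absent, so exclusion is behaviour-preserving and
saves redraws. If the pool is empty (no promiscuous enzyme) the sampling
space is a single subnetwork and the chain raises a degenerate-space error
pointing at exact mode.

Chains start at the full network (always valid; `random_valid` mode instead
greedily deletes random non-forced reactions for dispersion diagnostics).
After a burn-in of `burn_in_steps` valid proposals, the current subnetwork
is stored every `batch_size` (B) valid proposals until `n_samples` (S)
subnetworks are stored. Marginals are estimated as inclusion frequencies
over stored samples; the ergodic average (running mean) is the convergence
monitor, and the minimum-metabolite subnetwork seen anywhere in the run is
tracked as the maximum-likelihood subnetwork (ties: earliest). A single
seeded generator drives toggle choice and accept/reject draws, so runs are
bit-reproducible given the seed.

**Proposal asymmetry.** Conditional on validity, the candidate is uniform
over the d(N) valid single-toggle neighbours of N, and d varies between
neighbouring states, so the retry-until-valid proposal is asymmetric. The
default `paper_faithful` mode applies the plain Metropolis rule anyway; its
stationary law therefore deviates from π by an amount that grows as d
varies more strongly — on the two-reaction fixture T1 the deviation reaches
0.057 in marginal probability, the largest we have observed, and small
generated networks sit at 0.01–0.05. `hastings_corrected` mode multiplies
the ratio by d(N)/d(N′) and is exact; d is maintained incrementally (a
toggle only changes the deletable status of reactions sharing an enzyme
whose coverage crosses 1↔2), so the correction costs O(local) per step.
Exactness is verified two ways: the corrected sampler against enumeration
marginals, and the uncorrected sampler against the *uncorrected chain's own
stationary law*, obtained by building the full transition matrix over the
enumerated universe and solving for its invariant vector.

**Defaults.** Production defaults are B = 10,000, burn-in 10⁷ steps,
S = 10,000 — appropriate for networks with hundreds of promiscuous-enzyme
reactions, where thinning at B = 10,000 makes stored samples effectively
independent. The test-suite and acceptance script use desk-scale settings
(B = 20–100, burn-in 10³–10⁴, S 1,500–20,000) chosen as the problem sizes
appropriate to toy networks of 2–60 reactions, where mixing times are tiny.
The realized acceptance rate is reported and a warning (not an error) is
emitted outside [0.10, 0.50]; the rate depends on λ and on how much
metabolite sharing the network has (λ = 1 on sparse toy networks gives
0.5–0.7).

**Effective sample size.** Tolerances for sampler-vs-oracle comparisons use
a binomial standard error with n replaced by an ESS from the
initial-positive-sequence estimator of the integrated autocorrelation time
(pair sums of autocorrelations accumulated while positive), which is robust
to correlation extending beyond lag 1 in thinned series.

## Exact oracle

For networks whose non-forced reaction count is within a cap (default 20),
the valid universe is enumerated by iterating subsets of non-forced
reactions with forced reactions pinned in, checking only enzymes that
contain no forced reaction. Weights are normalized in log-space with
max-subtraction so networks with hundreds of metabolites per subnetwork do
not underflow. The oracle supplies exact marginals, the exact
minimum-metabolite subnetwork with tie counts, and the uncorrected-chain
stationary law described above. It is deliberately capped: it is a test
oracle, not a counting algorithm.

## Comparative layer

Distances: Bray–Curtis on enzyme abundance vectors
(1 − 2·Σ min(xᵢ,yᵢ)/(Σx + Σy)); Jaccard on presence sets; Euclidean on
marginal-probability vectors. All pairwise comparisons align on the union
of keys; a reaction absent from a sample's annotated network has marginal 0
there — the only convention consistent with the estimator's support.
Clustering is agglomerative with Ward's minimum-variance criterion on the
precomputed distance matrix in the squared-distance (ward.D2) dialect:
the Lance–Williams recurrence operates on squared distances and reported
merge heights are on the input scale. Dendrograms export to Newick.

Differential reactions between two groups: per reaction, (i) Fisher's exact
test (two-sided by the point-probability rule) on presence/absence counts,
and (ii) the pooled-variance two-sample t-test (df = n₁+n₂−2) on marginal
probabilities, at raw α = 0.05 by default (Benjamini–Hochberg optional). A
zero pooled variance is returned as a flagged degenerate result, never a
silent p. Fold changes of group-mean marginals are reported per reaction.
The reaction graph joins reactions sharing ≥1 metabolite (an optional
currency-metabolite exclusion list is honoured); its connected components
are reported as chains annotated with which members were t-test-only versus
significant in both tests.

## Synthetic networks and cohorts

The generator is reaction-first with preferential metabolite reuse: each
new metabolite slot reuses an already-used compound with odds
`metabolite_sharing_bias` : 1 (degree-proportional choice), else draws a
fresh one. This matters: with disjoint reactions the parsimony law is
nearly uniform and the sampler untestable, so the bias knob directly
controls how discriminating π is. Enzyme assignment hits
round(`promiscuous_fraction` · n_enzymes) promiscuous enzymes exactly:
mono-functional enzymes take distinct reactions first, promiscuous enzymes
cover the remainder and fill to their target sizes; infeasible demands
(uncoverable reactions) raise an error. Defaults (250 reactions, 300
metabolites, 200 enzymes, 30% promiscuous, 2–4 reactions per promiscuous
enzyme, bias 2) emulate a modest real annotated network, in which roughly
30% of enzyme families are multi-functional.

Cohorts share one base topology per group. A **planted context effect**
replaces the metabolites of one reaction of a promiscuous enzyme with
compounds already used by forced reactions: in the effect group the
reaction costs no extra metabolites and its marginal rises, while enzyme
and reaction lists are identical in both groups — the constructed analogue
of reactions that differ between environments in likelihood but not in
occurrence. `design_context_effect` searches candidate targets and
verifies the marginal margin with the exact oracle at generation time.
An optional per-sample enzyme dropout (`nuisance_dropout`) models
detection failure; reactions left unannotated drop out of that sample's
network.

What the generator does **not** emulate: real KEGG degree distributions,
pathway/module structure, reaction directionality, and abundance-weighted
annotation confidence. Passing tests therefore demonstrate correctness of
the inference machinery under controlled promiscuity and sharing, not
biological fidelity of any particular network.

## Calibration of the null (design note)

Null cohorts for type-I checks use identical generators for both groups;
per-sample variation is the sampler's Monte-Carlo noise, which is
approximately normal, so the pooled t-test is calibrated (empirically
≈ 0.05 at 6-vs-6 over thousands of reaction tests). Two caveats are
intrinsic rather than implementation defects. First, Fisher's exact test at
6-vs-6 is conservative by discreteness: its rejection region at α = 0.05
contains only near-degenerate tables, and its exact size — computable by
enumeration for any iid presence probability — never exceeds ≈ 0.01. A
"rate ≈ α" expectation is unattainable for an exact conditional test at
this sample size; the correct property, type-I *control* (size ≤ α), holds
and is what the acceptance suite asserts. Second, with `nuisance_dropout`
enabled the per-sample nuisance is heavy-tailed (rare large context shifts
when an influential enzyme drops out), and the pooled t-test becomes
conservative (≈ 0.03 observed); users comparing real cohorts with
presence/absence variability should expect the same behaviour.

## Numerical and tie-breaking conventions

- Exact probabilities: log-space weights, max-subtracted; marginals clipped
  to [0, 1] against 1-ulp overshoot.
- Minimum-metabolite ties: lexicographic enumeration order (oracle),
  earliest occurrence (sampler); tie counts reported.
- Ward ties: scipy's deterministic nearest-neighbour-chain order.
- Degenerate inputs: empty subnetworks are invalid by definition (every
  enzyme uncovered); both-empty sets are rejected by Jaccard; zero total
  abundance is rejected by Bray–Curtis; constant inclusion series yield
  NaN autocorrelation flagged as degenerate.
- Marginal TSVs serialize 6 decimals; round-trips are exact to 5e-7.

## Limitations

- The parsimony exponent λ is a modelling choice, not an estimated
  quantity; results should be read as λ-conditional (the λ = 0 uniform law
  is a useful sensitivity anchor).
- The uncorrected proposal mode carries the documented asymmetry deviation
  (up to ~0.06 on two-reaction toys, smaller as networks grow); use
  `hastings_corrected` when exactness matters more than per-step cost.
- No flux-balance or thermodynamic viability constraints; no reaction
  directionality or compartments; no taxonomic (sequence-based) distance —
  the comparative layer starts from annotations and abundances.
- The exact oracle is exponential by design and capped at 20 free
  reactions.
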