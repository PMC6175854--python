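# Methods

## Model

### Node-wise Bayesian sparse regression (network estimation)

For each pathway and each protein *i*, the centered expression vector
y_i (length n) is regressed on

- **protein regulators**: proteins j with prior inclusion weight
  w_ji > 0 (the set upa(i)), restricted to the pathway's members;
- **upstream covariates** of the protein's own gene: the
  methylation-modulated component of its mRNA (least-squares fit of mRNA
  on the methylation probe), the methylation-independent component (the
  residual), and the expression of miRNAs annotated to the gene.

The coefficient prior is Zellner's g-prior, beta | g, sigma ~
N(0, sigma^2 g (Z'Z)^-1) with g = n by default (unit information), and
p(sigma) ∝ 1/sigma. All covariate columns are centered and unit-scaled so
that g = n carries the same meaning for every candidate; coefficients are
reported on the standardized scale. With R^2_M the coefficient of
determination of model M (k_M covariates), the marginal likelihood is

    log m(M) = -(n/2) log(2 pi) + log Gamma(n/2) + (n/2 - 1) log 2
               - (k_M/2) log(1+g) - (n/2) log Q_M,
    Q_M = y'y (1 + g (1 - R^2_M)) / (1 + g).

This exact form (constants included) is cross-checked in the test suite
against adaptive quadrature of the (beta, sigma) integral.

The model prior is independent Bernoulli over candidates: protein
regulators use w_ji, upstream covariates a configurable
`default_upstream_prior` (0.5, noninformative — the source procedure does
not state one). Posteriors are computed by exact enumeration of all 2^k
models when k <= `enumeration_limit` (default 12; 2^12 closed-form
evaluations per node keep enumeration sub-second, and the limit is a
config knob) and otherwise by an MC3 add/delete/swap Metropolis-Hastings
sampler (default 50,000 iterations, 10% burn-in, cached marginals,
seeded). The sampler is validated against enumeration at k = 10 (max
absolute pip difference <= 0.02).

The **median probability model** (pip strictly > 0.5) defines edges:
i selected for j only gives a regulatory edge i -> j; mutual selection
gives a single correlative edge storing max(pip_ij, pip_ji) with both raw
pips retained. C_i counts regulatory targets plus correlative partners;
upstream edges are reported but excluded from C_i and from connectivity
summaries, which weight protein network topology only.

### Prior calibration

The initial edge set Ê is one PC fit on the full data at `alpha_init`
(default 0.1; the source material also mentions 0.01, so the level is a
config knob, not a constant). Stability weights: 100 half-subsamples
(floor(n/2), without replacement), each analysed across a grid of 100
levels equally spaced strictly inside (0, 0.1); a directed edge occurrence
credits its direction with 1, an undirected occurrence credits both
directions with 0.5 (directions that the CPDAG cannot identify should not
be arbitrarily assigned). Per direction, the selection probability at each
level is the fraction of subsamples carrying it; the final weight is the
maximum over the grid, masked to pairs in Ê. The prior inclusion
probability is the edge-wise average w_ij = (causal_ij + ppi(i,j)) / 2,
with the undirected PPI score entering both directions and a missing
source contributing 0; pairs with no evidence from either source stay
exactly 0 and are excluded from upa.

The PC algorithm is implemented in-package (no supported environment
library provides it): Gaussian partial-correlation conditional-independence
tests with the Fisher z transform (p-values cached per subsample — they do
not depend on the level, which makes the 100-level grid cheap), the
order-independent "stable" skeleton phase, v-structure orientation, and
Meek rules R1–R3. Conflicting orientations leave an edge undirected rather
than deleting it.

### Patient-level deconvolution

Under the MPM with the g-prior, the posterior predictive of protein i at a
patient's own covariate row z* is Student-t with n degrees of freedom,
location (g/(1+g)) z*'beta_hat and scale^2 = (Q/n)(1 + (g/(1+g))
z*'(Z'Z)^-1 z*). An empty MPM falls back to the null-model predictive
centered at 0 with the marginal scale of y. The predictive conditions on
the full cohort (in-sample): the procedure deconvolves each patient's
status given the cancer-type fit, and nothing in the source suggests
leave-one-out; model averaging over the enumerated model space is
available behind a flag and agrees closely with the MPM predictive when
the posterior concentrates.

(p-, p0, p+) are the predictive masses below -delta, inside ±delta, above
+delta (delta = 0.5 on the centered protein scale). The per-protein status
is the argmax of the triple; **exact ties resolve to neutral** (they are
measure-zero on real data; the conservative call avoids fabricating
direction). Pathway scores are the out-degree-weighted averages

    kappa_j(+/-/0) = (1/p) sum_i p_ij(+/-/0) (C_i + 1),

whose sum is exactly (1/p) sum_i (C_i + 1) — enforced to 1e-10 in tests.
Pathway status is the argmax of the three kappas with the same tie rule.
Comparison scores: the naive score is the plain sum of member protein
values; the native score is the sign-weighted sum (positive regulatory
members minus negative ones).

### Stratification and summaries

The combined score kappa+ + kappa- per patient and pathway forms the
stratification matrix (patients missing any pathway are dropped). Ward
linkage on Euclidean distances; the number of clusters is chosen with the
gap statistic against B = 50 uniform reference datasets over each
feature's observed range (Tibshirani's simpler reference; the source cites
the method without parameters): the selected k is the smallest with
Gap(k) >= Gap(k+1) - s_{k+1}, where W_k is the total within-cluster sum of
squares of the dendrogram cut at k. A constant matrix returns k = 1 with a
warning; W_k is floored at a 1e-12 relative epsilon so degenerate
point-mass geometries stay finite.

Enrichment probability: with x_in of n_cat category members inside a
cluster and x_out of n_other non-members, EP = P(theta_cat > theta_other)
under independent Beta(1 + x, 1 + n - x) posteriors, by seeded Monte Carlo
(the published supplementary definition is unavailable; Beta(1,1) priors
are the minimal Bayesian model matching the "posterior probability"
language). NMI uses the sqrt normalization I/sqrt(H H) by default (the
variant is configurable for the same reason), with zero-entropy partitions
guarded to 0.

Connectivity score CS = realized unordered protein pairs / (p(p-1)/2),
counting regulatory and correlative edges once per pair. Its permutation
p-value permutes each protein column's sample order independently
(destroying inter-protein dependence, preserving marginals and the
upstream design), refits the full network with the same prior, and applies
add-one smoothing: p = (1 + #{null CS >= observed}) / (reps + 1). The
p-value is discrete and conservative under ties (independent data usually
give CS = 0 observed and null alike), which the calibration test treats as
a one-sided bound. Diversity is the sample SD of CS across lineages; edge
consistency counts, per unordered pair, the lineages holding any edge on
it (plus per-direction regulatory counts), flagged known when the PPI
score exceeds 0.5. Concordance is the predictive mass the patient's triple
assigns to the delta-category of the observed (cohort-centered) value.

## Synthetic cohorts

The generator emulates the data model the regression assumes: proteins
follow linear-Gaussian structural equations on an Erdos-Renyi-style DAG
(edges forward in a fixed topological order; coefficient magnitudes
uniform on [0.5, 1.0] with random signs — bounded away from zero so
structure recovery is feasible at n ≈ 500); per gene, methylation ~ N(0,1),
mRNA = 0.7 x methylation + N(0,1), miRNAs ~ N(0,1); each protein loads on
its own gene's mRNA (0.5) and miRNAs (0.3) plus structural noise (SD 0.3
by default). Lineages beyond the first rewire a stated fraction of edges
uniformly at random, preserving acyclicity via the fixed order.

Subgroup shifts are applied **after** the structural equations, to the
pathway's protein columns and the corresponding genes' mRNA columns, with
no propagation through the protein wiring: a propagated shift would cancel
through negative coefficients and make "every shifted protein is
activated" false by construction, while the post-hoc shift keeps the truth
status exactly the categorisation of the shift against delta and makes the
activation visible to the upstream covariates the predictive actually
uses. Subgroup sizes follow a minority-subtype design — the control group
takes two shares and each shifted subgroup one (one shift => one third of
patients) — because an activated molecular subtype is a minority of a real
cohort and a 50% shifted group would lose half its shift to cohort
centering.

What the generator does **not** emulate: RPPA antibody noise signatures,
copy-number or mutation data, platform batch effects, missingness
patterns, non-Gaussian marginals, or feedback loops. A green recovery test
therefore establishes that the estimator works when its model family is
correct at realistic signal-to-noise — not that it is robust to assay
artefacts.

## Numerical choices

- R^2 values are clamped to [0, 1 - 1e-12]; rank-deficient model
  submatrices fall back to the pseudo-inverse with a logged warning
  (simulated data can contain exact duplicates).
- Constant candidate columns are dropped (standardization would divide by
  zero) with a warning; constant features abort the PC fit with the
  feature named.
- Partial correlations are clipped to |r| <= 1 - 1e-7 before the Fisher z
  transform; tests with fewer than 1 effective degrees of freedom return
  p = 1 (never reject).
- Candidates with prior weight 1 are mandatory: models excluding them have
  prior probability zero, and the MC3 chain is initialised including them.
- Every stochastic stage (subsampling, MC3, gap references, enrichment
  Monte Carlo, permutation nulls) takes a numpy Generator or a seed from
  the analysis config; identical seeds give bit-identical results.

## Known limitations

- Node-wise regressions are not a joint graphical likelihood; mutual
  selections are reported as correlative edges rather than reconciled into
  a coherent joint model, matching the estimation procedure being
  reproduced.
- The MC3 pip estimates are visit frequencies; for very flat posteriors at
  large k they carry Monte Carlo error of order 1/sqrt(iterations).
- Enumeration beyond ~14 candidates is intentionally routed to MC3; the
  `enumeration_limit` default (12) trades exactness for runtime and is
  configurable.
- The permutation p-value refits the entire network per replicate; cost
  grows linearly in `permutation_reps` times the Step-1 cost.
- Antibody-level protein features mapping to multiple genes (e.g. pan-AKT)
  are matched to upstream features only through the explicit sidecar
  protein->gene mapping; no fuzzy matching is attempted.
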