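# Methods

## Model and hypotheses

`ordbf` evaluates *informed hypotheses* on the category proportions
**θ** = (θ₁, …, θ_K) of two conjugate count models:

- **Multinomial**: x ~ Multinomial(x₊, θ) with a Dirichlet(α) prior on the
  simplex;
- **Independent binomials**: x_k ~ Binomial(θ_k, n_k) with independent
  Beta(α_k, β_k) priors.

An informed hypothesis H_r constrains θ with equalities (θ₂ = θ₃),
inequalities (θ₁ < θ₂), free groups ((θ₈, θ₉): unordered among themselves
but jointly bounded by their chain neighbours), and independent sections
joined by `&`. Within a section the elements must form a linear chain — a
"stick" hypothesis. Partial orders ("branched" hypotheses, e.g. θ₁ < θ₂ and
θ₁ < θ₃ with θ₂, θ₃ unordered *and* separately bounded above) are not
expressible in the grammar and are rejected by the parser; this is a known
limitation of the stick-breaking transform underlying the estimator, not an
implementation shortcut. In the dialect, `=` binds tighter than `,`, so
`"4 , 5 = 6"` is the free pair {4, (5 = 6)}; a reading in which 5 is
simultaneously free against 4 and tied to 6 would be contradictory and is
not representable.

The central quantity is the Bayes factor of H_r against the encompassing
hypothesis H_e (all proportions free),

    BF_re = p(x | H_r) / p(x | H_e),

which by the Klugkist identity equals the ratio of posterior to prior mass
of the restricted region R_r under H_e — equivalently, the ratio of the
normalizing constants of the constrained posterior and constrained prior
densities. Mixed hypotheses factor as

    BF_re = BF_1e × BF_2e|1e,

an analytic Bayes factor for the equality constraints times a conditional
Bayes factor for the inequalities given the equalities. Sections are
mutually independent (for the Dirichlet this follows from neutrality: the
within-section composition is itself Dirichlet, independent of the rest)
and contribute additively on the log scale.

## Equality constraints (closed form)

All marginal likelihoods are computed in the natural-log domain with
log-gamma functions; the worked examples reach Bayes factors of order
e⁻⁴⁸⁰, so nothing is ever exponentiated before the API boundary.

- Multinomial point null θ = p₀:
  log BF_0e = log B(α) − log B(α + x) + Σ_k x_k log p₀k.
- Binomial "all equal" null: the K Beta(α_k, β_k) priors are collapsed onto
  a shared rate with parameters (α₊ − (K−1), β₊ − (K−1)) — subtracting K−1
  keeps a uniform prior uniform after collapsing — and the Bayes factor is
  the ratio of the collapsed to the product-form marginal likelihood.
- Binomial point null θ = θ₀: the prior degenerates to a point and the
  marginal likelihood reduces to the likelihood at θ₀. Only a single shared
  θ₀ is supported.
- Equality *groups* inside a larger hypothesis (BF_1e): for binomials, the
  all-equal formula restricted to the group; for multinomials, a
  Savage–Dickey ratio on the within-group composition φ ~ Dirichlet(α_g)
  evaluated at the uniform composition,
  log B(α_g) − log B(α_g + x_g) − x_g₊ log m for a group of size m. When
  the group spans all K categories this reduces exactly to the point-null
  formula with p₀ = (1/K, …, 1/K), which is verified in the tests.

After collapsing, a merged multinomial category carries the summed counts,
the summed concentrations minus (m − 1), and its multiplicity m; the
conditional inequality constraints compare merged categories through their
per-category mean (mass divided by m). Collapsing differs from adding
categories before the analysis: the former conditions a K-category model on
equality, the latter specifies a smaller model.

## Inequality constraints (bridge sampling)

The conditional inequality Bayes factor is the difference of two log
normalizing constants, each estimated by bridge sampling:

1. **Constrained Gibbs sampling.** Multinomial: the chain runs on
   independent Gamma(α_k, 1) variables; the constraints only involve the
   scale-free ratios g_k/(m_k Σg), so each full conditional is a Gamma
   truncated to the interval spanned by the chain neighbours (for free
   groups, the running max of the previous element and min of the next),
   and θ = g/Σg is the constrained Dirichlet. Binomial: truncated-beta full
   conditionals directly. Truncation is done by inverse-CDF on the
   regularized incomplete gamma/beta functions, guarded near vanishing
   interval mass. Several short chains run in parallel with vectorized
   updates (default 8 chains, 500 burn-in sweeps each, thinning 1, 12,000
   retained draws total); initialization projects the conjugate means onto
   the ordering, which is deterministic and always strictly feasible. The
   stationary law — not the particular sweep schedule — is the contract,
   and it is checked against a rejection oracle.

2. **Stick-breaking/probit transform.** Draws are mapped coordinate-wise to
   the real line through θ_k = (u_k − l_k)Φ(ξ_k) + l_k, processing elements
   from smallest to largest. Lower bounds: 0 for the first element,
   thereafter the largest per-category mean of the previous element. Upper
   bounds: 1 for binomials; for multinomials the exact feasibility bound —
   the largest value that still allows the remaining stick to be completed
   with unplaced free-group peers at their lower bound and all later
   elements above the element's running maximum, i.e. the solution of
   m_p t + M_peers·l + M_later·max(η_placed, t) = R, piecewise in t. For a
   plain ascending chain this reduces to (remaining stick)/(elements left),
   e.g. 1/3 for the smallest of three. The largest element is the remainder
   of the stick. Bounds depend only on earlier coordinates, so the Jacobian
   is triangular with log-determinant Σ log m_k + log(u_k − l_k) +
   log φ(ξ_k). Correctness of the free-group bound is established
   operationally: round-trip bijectivity to < 1e−8 and quadrature
   normalization of the transformed density are part of the test suite. At
   extremely large positive ξ the map approaches the corner of the closed
   region where adjacent elements tie at float resolution; this is harmless
   in practice because MCMC draws are interior.

3. **Bridge estimator.** The unnormalized target on ℝ^d is the encompassing
   conjugate density at θ(ξ) times the Jacobian; its normalizing constant is
   the constrained mass. The proposal is a multivariate normal
   moment-matched to the first half of each chain's transformed draws
   (jittered to positive definiteness if required, which is logged); the
   second half plus an equal number of fresh proposal draws enter the
   Meng–Wong optimal-bridge fixed-point iteration, run in log space with a
   median shift until the relative change falls below 1e−10 (cap 1,000
   iterations; non-convergence flags the result rather than failing
   silently). Draws from the proposal map back into the restricted region
   by construction, so the indicator never truncates them.

4. **Error measure.** The relative mean-squared error re² combines an iid
   variance term for the proposal draws with an autocorrelation-inflated
   term for the MCMC draws; the inflation factor is the integrated
   autocorrelation time of the target-side integrand, estimated per chain
   with Geyer's initial-positive-sequence truncation (our choice of
   spectral window). `percentage_error = 100·√re²` approximates the SD of
   the log marginal likelihood; independent bridge estimates are combined
   in quadrature and labelled approximate. Seed-to-seed spreads agree with
   the reported errors within a factor of three in the tests.

## Defaults and numerical choices

| parameter | default | rationale |
|---|---|---|
| retained draws | 12,000 | ≈1% log-scale error on the 9-category worked example; seconds of runtime |
| proposal split | 50/50 | fit on the first half of each chain, evaluate on the second |
| chains | 8 | vectorizes the truncated-CDF updates; burn-in is cheap |
| burn-in | 500 sweeps/chain | far beyond observed mixing times for K ≤ 10 |
| bridge tolerance | 1e−10 | relative change of the estimate |
| prior | all concentrations 1 | uniform over the (constrained) space |

Degenerate inputs: hypotheses with no inequalities skip the bridge entirely
(conditional BF ≡ 1); sections with a single element impose no ordering and
are likewise skipped; a collapsed concentration ≤ 0 (over-informative
equality collapse) is an error; draws on a transform boundary are rejected
with the offending row index.

Seeding: a single user seed feeds a `SeedSequence`; each section × target
sampling run and each proposal-draw stream gets an independent spawned
substream, so results are bit-reproducible and sections are statistically
independent.

## Synthetic data and what the tests show

`simulate_counts` draws multinomial or independent-binomial counts at
user-chosen θ and sample sizes — the only data-generating mechanism needed
for this method, since the model's sampling assumptions (independent trials,
fixed category structure) are exactly what the generator produces. It does
not emulate overdispersion, clustered or hierarchical sampling, or
model misspecification; passing consistency tests therefore show that the
estimator recovers the right Bayes factors *under the assumed models*, not
that those models fit any particular real dataset. The packaged worked
datasets (Greek fiscal first digits, N = 1,497; stochastic-dominance
violations, N = 1,212) tie the pipeline to published analyses: analytic
values are reproduced to 0.01 on the log scale and bridge-sampled values to
0.1 on the log scale at the default draw counts.

## Known limitations

- Branched (partial-order) hypotheses are out of scope (grammar and
  transform both exclude them); size-ratio and odds-ratio constraints are
  not supported.
- Binomial point nulls accept one shared θ₀ only.
- The re² error measure treats the proposal side as iid and the target side
  as stationary; it is an approximation, adequate at the default draw
  counts.
- Posterior summaries are numeric only (medians and central credible
  intervals per category); a minimal matplotlib plot is provided but
  figure styling is left to the user.
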