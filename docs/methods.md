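# Methods

## The diffusion model

Each experiment releases one piece of information (the location of a food
patch) into a troop. The discoverer is informed from the outset; everyone
else is naive. OADA treats the *order* in which naive individuals acquire
the information as the data — absolute times never enter — and models the
acquisition rate of naive individual *i* as

    additive        R_i = s · T_i + exp(Γ_i)
    multiplicative  R_i = exp(Γ_i) · (s · T_i + 1)
    asocial         R_i = exp(Γ_i)

with `T_i` the sum of *i*'s network connections to currently informed
individuals and `Γ_i = Σ_m β_m x_im` a linear predictor over
individual-level variables (ILVs). The observed order contributes, per
acquisition event, the factor `R_acquirer / Σ_naive R_i`. Because this is
a ratio within one diffusion, any per-task baseline rate cancels: "task
identity" is realized by treating each experiment as an independent
likelihood factor, and troop membership simply selects which matrix
supplies `T`. Under the additive and multiplicative forms the model is a
proper sequential distribution over orders — the probabilities of all
complete orders sum to one, which the test suite verifies by brute-force
enumeration on instances of up to five naive individuals.

Assumptions worth making explicit: connections act additively across
informed individuals; the network is static within the study; individuals
never forget; and the risk set at each event is every still-naive troop
member (individuals who never acquire are right-censored within the
experiment).

### The transmission parameter and its two scales

The likelihood is well-posed on the unbounded rate-ratio scale
`s ∈ [0, ∞)`: `s` multiplies the social term relative to an asocial
baseline of 1. Field reports often quote a bounded transmission strength
in [0, 1); we report both, related by the strictly monotone map
`s_bounded = s/(1+s)`. The optimizer works directly on the bounded-below
`s` axis (L-BFGS-B with `s ≥ 0`) from a fixed multi-start grid
(s₀ ∈ {0, 1, 10, 100, 1000}, ILV coefficients started at 0), so the
boundary `s = 0` — where both social forms collapse exactly onto the
asocial model — is attainable exactly, and refits are deterministic.
Convergence tolerance is 1e-8 on the log-likelihood; failure of every
start flags the fit rather than raising.

### Ties, unknowns, direction

Individuals observed acquiring simultaneously form a tie group. The
default Breslow treatment divides each tied acquirer's rate by the common
pre-event denominator; the exact treatment averages the
shrinking-denominator sequential probabilities over all orderings of the
tie (enumerated, tie groups of at most 6). Both treatments hold rates at
the pre-event state within a tie — simultaneous acquirers do not transmit
to each other.

Acquirers that could not be identified in the field are representable by
the reserved id `UNKNOWN`; they are dropped from tallies and likelihood
contributions with a logged warning. This is a package decision for an
edge case the field protocol leaves open; at the default rate (two events
in fifty experiments) it is numerically negligible.

For directed matrices, `T_i` defaults to *i*'s outgoing edges toward
informed individuals (attention: *i* watches those it associates to); a
`direction="incoming"` switch sums edges received instead. Directionality
of information flow is genuinely ambiguous, which is exactly why both
directed and symmetrized variants of the count networks sit in the
candidate set.

### Model selection

With `n` the total number of acquisition events (tied individuals each
count once) and `k = |ILVs| + 1[social]`,

    AICc = −2 logL + 2k + 2k(k+1)/(n − k − 1).

The network comparison fits one social model per (rule, form) plus an
asocial model, all sharing the same ILVs. The ILV search crosses every
subset of the four ILVs with both forms on the winning network. Effects
are model-averaged over the ΔAICc ≤ 2 set with renormalized Akaike
weights, substituting β = 0 where an ILV is absent (full-model averaging),
so weakly supported variables shrink toward zero. ILVs enter in raw units
(relative rank in [0,1], sex 0/1, age in years, boldness in seconds);
standardization is deliberately not applied by default so coefficient
magnitudes stay interpretable against the field tables.

## Networks

SRI uses sampling occasions, not raw rows: scan records sharing a
`scan_id` belong to one occasion, and member lists that overlap within an
occasion are merged transitively (chain groups may be recorded in parts;
merging never crosses occasions). For a dyad, the denominator counts
occasions where at least one member was observed. An individual never
observed under a rule has no defined index and is reported as an error
rather than silently zeroed.

Betweenness needs a weight→distance transform the field literature rarely
states; we use `distance = 1/weight` (strong associations are short
paths), unnormalized counts, endpoints excluded, fractional splitting
among equal-length geodesics, and zero-weight dyads as non-edges.
Strength for directed matrices sums edges given *and* received, which
makes strength invariant under symmetrization; an out-only variant is
available. Spearman screens report the tie-adjusted `S = Σd²`, ρ, and a
two-sided p-value from the t approximation — adequate at troop sizes of
~46–48, where the exact permutation null is unnecessary.

## Constraint count models

Counts of socially informed acquisition, application and exploitation
(occasions where the individual itself discovered the patch are excluded
and tallied separately) are modelled as log-link Poisson against six
predictors: relative rank, boldness, age, sex, 10 m proximity strength
and directed-grooming strength — the two strengths chosen because
betweenness is strongly rank-correlated with strength in these networks
and adds nothing independent.

With only two troops, a troop random intercept is weakly identified and
boundary-prone, so the default engine fits a fixed intercept per troop
(Poisson GLM with a troop factor) and reports Wald statistics on the
coefficient scale; a variational-Bayes Poisson mixed-model engine
(`engine="random"`) is available side-by-side and reports the posterior
SD of the troop intercept. Backward elimination drops the largest
p ≥ 0.05 term, refits, and repeats; every dropped term is then re-added
singly to the minimal model to confirm it stays non-significant, with any
inconsistency flagged in the trace rather than silently resolved. No
multiple-testing correction is applied across the three responses, and no
exposure offset is used (all individuals experienced the same 25 trials).

## The synthetic-data generator

The generator exists to make every pipeline stage testable with known
truth; its defaults are the field design scale, not free dials:

| quantity | default | note |
|---|---|---|
| troop sizes | 46, 48 | with the observed sex/age-class mix |
| scans per individual per rule | 24 | three proximity rules |
| grooming / dominance events per individual | 29 / 16 | totals ≈ 1330–1390 and ≈ 740–770 per troop |
| diffusions per troop | 25 | |
| informed per diffusion | lognormal, median 10, clipped to 2–27 | patch depletion as a random stopping count |
| true network | 10 m SRI | diffusion runs on the realized matrix |
| s (bounded) | 0.9 | identifiable interior value |
| ILV effects | rank 0.26, sex 0.15, age −0.01, boldness 0 | multiplicative form |
| unidentified acquirers | ~2 per 50 diffusions | |
| tie events | 5% of acquisition events | pairs |

Pairwise structure comes from a latent affinity — a Gaussian kernel over
2-D latent positions — shared by all proximity rules and grooming, so the
candidate matrices are mutually correlated as in field data while only
the designated true matrix drives the diffusion. The 10 m and 5 m rules
differ by inclusion scale and exponent (the tighter radius is a steeper
function of affinity); the per-scan inclusion scale for the 10 m rule
(0.15) was chosen so that typical SRI strengths land near 2, which puts
the Poisson count medians near the observed 6 / 2.5 / 1 under the default
count coefficients. Boldness is lognormal (median 15 s) and negatively
coupled to age through a Gaussian copula (ρ = −0.55); ranks are a uniform
random permutation per troop.

Two pieces have no quantitative field model and are plausible
constructions only: the discoverer is drawn with weight
`exp(1.5·relrank + 0.8·male − 0.08·age)` (dominant, young, male
individuals find patches first), and application/exploitation flags are
drawn with rank- and sex-dependent sigmoid probabilities, with co-feeding
at 4.8% of entries and protest at 5/14 of co-feeds. Count responses for
the constraint module are generated separately from log-link Poisson
truths over the realized strengths.

What the generator does **not** emulate: observability bias (the field
study made no correction either), demographic turnover within the season,
spatially explicit movement, repeated-discoverer structure, and any
dependence of asocial discovery on the network. Passing recovery tests
therefore show the estimators are correct *under the model's own
assumptions* at the study's scale — they cannot show the field data meet
those assumptions.

## Numerical choices and problem sizes

Linear predictors are clipped at ±50 before exponentiation; zero-weight
dyads are structural non-edges; CSV output is fixed at six significant
digits so reruns diff byte-identically; the pipeline is a pure function
of (inputs, config, seed). The heavy recovery checks run 100 synthetic
replicates at the full design scale in the test suite (with the 8-network
identification done at equal parameter count, i.e. without ILVs, and the
transmission estimate taken from the correctly specified multiplicative
ILV model), and 40 replicates in the acceptance script; both report the
replicate count alongside each number.

## Known limitations

- The exact tie method enumerates orderings and is limited to tie groups
  of six; larger simultaneous groups require Breslow.
- Standard errors for OADA parameters are not reported (model comparison
  and averaging are the inferential route, as in the field analysis);
  profile or bootstrap intervals would be a natural extension.
- The variational random-intercept engine gives approximate posterior
  SDs, not frequentist SEs; with two troops the fixed-intercept engine
  is the honest default.
- At `s` near 1 on the bounded scale the likelihood flattens in
  `log s`; estimates there are reported but their upper scale is weakly
  identified — one reason the generator's default sits at 0.9 rather
  than at the boundary.
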