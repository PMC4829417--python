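# socdiff

Social-information diffusion analysis for animal social networks.

When a wild primate discovers a hidden food patch, knowledge of that patch
spreads: groupmates watch the discoverer, approach, enter the patch, and —
rank and tolerance permitting — eat from it. `socdiff` implements the full
analysis chain for such field experiments on two troops of wild chacma
baboons, and a matching synthetic-data generator so every stage can be
exercised with known ground truth:

1. **Record handling** — validated tabular schemas for phenotypes, proximity
   scans, directed interactions and per-experiment diffusion logs; relative
   rank scaling `1 − (1 − r)/(1 − n)`; per-individual tallies of the
   three-step information-use sequence (acquisition → application →
   exploitation) and co-feeding summaries.
2. **Association networks** — per troop, five association rules giving eight
   candidate matrices: simple ratio index (SRI) networks for the 10 m and
   5 m-chain proximity rules, `SRI = x / (x + y_ab + y_a + y_b)`, and
   directed count networks (nearest neighbour, grooming, dominance) plus
   their symmetrized variants; weighted strength and betweenness, and
   Spearman correlation screens.
3. **Order-of-acquisition diffusion analysis (OADA)** — which network, if
   any, shaped the order in which individuals acquired the information?
   Each acquisition event contributes a partial-likelihood factor
   `R_acquirer / Σ_naive R_i`, where a naive individual's rate combines a
   social term `s·T_i` (`T_i` = summed connections to informed individuals)
   with an asocial baseline `exp(Γ_i)` over individual-level variables
   (rank, sex, age, boldness):

   * additive: `R_i = s·T_i + exp(Γ_i)`
   * multiplicative: `R_i = exp(Γ_i)·(s·T_i + 1)`
   * asocial: `R_i = exp(Γ_i)`

   Experiments enter as independent likelihood factors (task identity);
   troop membership selects the matrix; ties are handled by Breslow or
   exact averaging. Candidates are ranked by AICc, searched over all ILV
   subsets, and model-averaged over ΔAICc ≤ 2 with zero substitution.
   `s` is optimized on the unbounded rate scale and also reported on the
   bounded scale `s/(1+s) ∈ [0, 1)`.
4. **Phenotypic constraints** — Poisson count models of acquisition,
   application and exploitation counts against six predictors (relative
   rank, boldness, age, sex, 10 m proximity strength, grooming strength)
   with a per-troop intercept, backward elimination at α = 0.05 and a
   re-add check, plus collinearity screening.
5. **Synthetic studies** — populations, scans, interactions, diffusion
   experiments and count responses at the field design scale (troops of 46
   and 48, 24 scans per individual per rule, 25 diffusions per troop,
   diffusion sizes with median ≈ 10), generated from a latent-affinity
   model with the diffusion following the same acquisition-rate model the
   analysis fits — so transmission parameters, the true network and count
   coefficients are all recoverable quantities.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from socdiff import SimScenario, simulate_study, compare_networks

# a reduced synthetic study: two troops of 16 and 18, 8 diffusions each
study = simulate_study(SimScenario(seed=7, troop_sizes=(16, 18),
                                   n_diffusions_per_troop=8))
by_rule = study.networks_by_rule()

table = compare_networks(study.diffusions,
                         {r: by_rule[r] for r in ("ten_m", "groom_directed")},
                         study.phenotypes, forms=("multiplicative",), ilvs=("rank",))
print(table.frame()[["model", "df", "loglik", "aicc", "delta_aicc",
                     "s_bounded"]].round(2).to_string(index=False))
best = table.best()
print(f"\nbest model: {best.spec.label()}")
print(f"s (unbounded rate scale) = {best.s_unbounded:.2f}")
print(f"s (bounded [0,1) scale)  = {best.s_bounded:.3f}")
```

prints

```
                             model  df  loglik   aicc  delta_aicc  s_bounded
         multiplicative:ten_m:rank   2 -350.78 705.64        0.00       0.87
multiplicative:groom_directed:rank   2 -354.01 712.10        6.47       0.02
                    asocial:-:rank   1 -355.38 712.79        7.15        NaN

best model: multiplicative:ten_m:rank
s (unbounded rate scale) = 6.59
s (bounded [0,1) scale)  = 0.868
```

The study was simulated with information spreading on the 10 m proximity
network at a bounded transmission strength of 0.9. The comparison recovers
that: the 10 m model beats the grooming network and the asocial model by
more than 6 AICc units, and the bounded transmission estimate (0.868) sits
close to the generating value; the grooming model's near-zero `s` says that
network adds nothing once its rows are fit to a diffusion it did not drive.

A command-line interface mirrors the library
(`socdiff simulate | build-networks | fit-oada | compare-networks |
ilv-search | fit-constraints | report | run-all`); `run-all` drives the
whole pipeline from a YAML config and writes every table as CSV along with
a run log and a plain-text report.

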