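# wetlandnbn

Non-parametric (Gaussian-copula) Bayesian networks linking wetland traits
to waterbird alpha diversity: model calibration, direct/indirect effect
decomposition, copula validity testing, and what-if scenario simulation at
regional and single-wetland scale.

The package is written for wetland ecologists and conservation planners
who have (i) a small table of wetlands described by mixed
ordinal/continuous traits — spatial (size, isolation, distance to the
coastline), anthropic (tourism pressure, anthropization, scored 0–3), and
hydrological (mean water level, water level fluctuations, salinity,
discharges, diversions) — plus an observed species count per wetland, and
(ii) a causal hypothesis (a DAG) of how those traits drive diversity. It
answers questions like *"how many species per wetland should we expect if
water diversions became widespread everywhere?"* or *"what would this one
wetland gain if its water level fluctuations rose to 15 cm?"* — without
running field experiments.

## The model

Each variable keeps its empirical marginal distribution `F_i`; dependence
is carried by a normal copula over a directed acyclic metamodel:

    F_{1..n}(x_1..x_n) = C_R( F_1(x_1), ..., F_n(x_n) )

where `C_R` is the Gaussian copula with correlation matrix `R`. Each arc
`x_j -> x_c` carries the normal-score partial correlation of parent and
child given the child's earlier-listed parents; `R` is assembled from the
arc values by a vine construction, so it is positive definite for any arc
values in (−1, 1), and every non-adjacent dependence is the one implied by
the DAG factorization.

On top of the fitted network:

* **Effects** — direct effect `E_D = ρ_{i,AD}` (the arc to the diversity
  node), indirect effect `E_I = Σ_k Π ρ` over all directed multi-step
  paths, total `E_T = E_D + E_I`.
* **Validation** — `D_E`, the determinant of the data's Spearman rank
  correlation matrix, is compared against the central 90% band of `D_N`
  resampled from the fitted copula at the same sample size; inside the
  band, the copula assumption is not rejected at the 10% level.
* **Scenarios** — conditionalization: evidence values are mapped to normal
  scores through the empirical marginals, conditional multivariate-normal
  algebra propagates them, and the diversity node is mapped back to
  species units by Monte Carlo through its empirical quantile function.
  Evidence beyond a variable's observed range saturates (clamped to the
  extreme quantiles), so benefits plateau rather than extrapolate.

Latent correlations are estimated by Spearman's rho with the exact
normal-copula map `r = 2 sin(π ρ_s / 6)` for continuous pairs, and by
polyserial / polychoric maximum likelihood where 0–3 ordinal traits are
involved (coarse discretization attenuates rank correlations, which would
otherwise bias the fit).

A synthetic-data module generates trait tables from a fully known ground
truth emulating a 16-wetland coastal study design (overdispersed richness,
mean ≈ 19 species, SD ≈ 14), so the entire pipeline is testable end to end
with no external data.

## Worked example

```bash
python examples/validate_copula.py
```

```
D_E                    = 2.137e-04
90% band of D_N        = [6.245e-06, 6.059e-04]
D_E quantile position  = 0.77
normal copula          : not rejected at the 10% level
```

The synthetic 16-wetland table's rank-dependence determinant sits at the
0.77 quantile of the copula's own resampling distribution — comfortably
inside the 90% band, so the Gaussian-copula description of the data is
retained.

```bash
python examples/regional_scenarios.py
```

```
  id   mean     sd  delta  delta_pct
 S_0   20.3   14.6    0.0        0.0
 S_6    9.6    6.5  -10.7      -52.8
 S_7    7.5    5.0  -12.8      -63.0
S_13   32.4   21.6   12.1       59.7
S_14   37.5   24.3   17.2       84.5
```

(excerpt) — the baseline community of ~20 species per wetland would halve
if water level fluctuations vanished everywhere (S_6), collapse to ~7 if
every trait deteriorated at once (S_7), and could nearly double under the
best-case management scenario (S_14). The lever ranking printed below the
table orders single-trait interventions: fluctuations first, then
diversions, then salinity.

Other examples: `fit_and_decompose.py` (effect table at the study's
n = 16), `downscale_wetland.py` (single-wetland predictions under 30
scenario overrides), `parameter_recovery.py` (estimator bias/RMSE against
the known ground truth).

There is also a thin CLI: `nbn generate | validate-input | fit | effects |
validate | simulate` (`nbn --help` for usage); fitted models travel
between commands as JSON.

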