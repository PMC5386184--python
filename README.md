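# teadvice

Online forecasting of short, unstable time series by **temporal expert
advice**: prediction with expert advice whose per-step losses carry
exponentially *growing* coefficients, so the forecaster trusts whichever
reference trajectories agree with the target *right now*.  The intended
users are researchers in biostatistics and nonlinear time-series analysis
who need to predict a scalar signal — a tumor biomarker such as PSA, or a
chaotic observable — from a handful of observations plus a database of
longer series or a mechanistic model fitted to previous subjects.

## The method

Experts `i = 1..N` give advice `f_{i,t}`; after each observation `y_t` the
forecaster charges coefficient-weighted losses and predicts by weighted
averaging:

    L_{i,t} = Σ_{k≤t} a_k l(f_{i,k}, y_k),    w_{i,t} ∝ exp(−η L_{i,t}),
    p_{t+q} = Σ_i w_{i,t} f_{i,t+q},

with `a_k = 1` (the classical exponentially weighted average forecaster),
`a_k = λ^{k−1}` with `λ > 1` (the temporal scheme, TEA), or
`a_k(t) = ρ^{t−k−1}` with `0 < ρ < 1` (the discounted Chernov–Zhdanov
scheme).  The temporal regret obeys
`R̃_t ≤ ε sqrt(S ln N / 2)` with `S = (λ^{2t}−1)/(λ²−1)` at the
bound-optimal rate; normalized onto the discounted scale (multiply by
`ρ^{t−1}`, `λ = 1/ρ`) it is strictly smaller than the discounted bound,
by exactly a factor `ρ`.  A Gaussian-mixture layer turns the weighted
advice into a predictive distribution with quantile bands `u_t(Q)`, and an
expert-construction layer builds panels from sliding windows over a series
database or from a piecewise-linear model of prostate-cancer cell
populations fitted to the first K PSA measurements of a target patient.
See `docs/methods.md` for the full model description and design choices.

## Worked example

`examples/henon_point_prediction.py` builds 1000 expert orbits of the
Henon map with parameters drawn near — but not at — the target's
`(a, b) = (1.35, 0.15)`, then predicts the target orbit one step ahead:

```
experts: 1000, target length: 60
temporal (lambda=1/0.9)      accumulated |error| =  5.889
discounted (rho=0.9)         accumulated |error| = 11.815
standard                     accumulated |error| = 15.265
```

The numbers are the summed absolute one-step prediction errors over the 50
steps after the burn-in: recency weighting (temporal, discounted) tracks
the chaotic orbit far better than uniform-history weighting, and the
growing-coefficient temporal scheme tracks it best.  The other examples
cover the regret bounds (`examples/regret_bounds.py`), distribution
prediction of PSA for a synthetic patient
(`examples/psa_distribution_prediction.py`), and the pairwise win
tournament against persistence/average baselines
(`examples/baseline_tournament.py`).  A thin CLI mirrors these workflows
(`teadvice simulate | synth | build-experts | predict | predict-dist |
bounds | evaluate`).

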