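# unfoldirt

Unfolding (ideal-point) item response models for Likert-scale data.

Conventional (dominance) IRT models assume that the probability of a high
rating rises monotonically with the latent trait.  Attitude items often
violate this: a respondent can disagree with "capital punishment is
necessary but I wish it were not" from *either* side of the issue, so the
item characteristic curve is single-peaked — endorsement is most likely
when the person's position &theta; is close to the item location &delta;
and falls off with |&theta;&nbsp;&minus;&nbsp;&delta;|.  `unfoldirt` is a
toolkit for fitting this class of models to ordered categorical responses,
aimed at psychometricians and applied researchers working with attitude,
personality, vocational-interest or patient-reported-outcome scales.

## Models

* **GGUM family** (UM1–UM8).  The generalized graded unfolding model,

  P(z | θ) ∝ exp{α[z(θ−δ) − Σ<sub>k≤z</sub> τ<sub>k</sub>]} +
  exp{α[(M−z)(θ−δ) − Σ<sub>k≤z</sub> τ<sub>k</sub>]},   z = 0..C, M = 2C+1,

  plus its reductions: discrimination α fixed at 1, thresholds τ shared
  across items, and the unit-threshold (λ) variants.
* **Luo's general family.**  Category probability as a normalized product
  of binary operational probabilities
  P<sub>k</sub> = ψ(ρ<sub>k</sub>) / (ψ[α(θ−δ)] + ψ(ρ<sub>k</sub>)) with a
  choice of operational function ψ: exp|x| (ALM), exp(x²) (SSLM), x²
  (PARELLA), cosh x (HCM), or a category-indexed cosh ratio (GUM).  The
  thresholds ρ<sub>k</sub> have a direct interpretation as crossing
  distances from the item location.
* **Multidimensional unfolding** (between-item design): θ−δ replaced by the
  weighted Euclidean distance across dimensions, with equicorrelated-normal
  traits and free correlations.

Estimation is marginal maximum likelihood via EM on a fixed quadrature
grid (50 nodes on [−4, 4]; 15 per dimension in 3-D), with bounded
quasi-Newton M-steps using analytic gradients.  Standard errors come from
numerical differencing of the observed-data log-likelihood
(forward/central/Richardson); person scoring supports EAP, MAP and MLE,
plus empirical reliability.  A simulation harness generates data under the
standard recovery designs and summarizes bias, RMSE, Monte Carlo SD and
the SE calibration measure RM = mean(SE)/SD − 1.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate 1,500 persons answering 10 four-point items under the graded
unfolding model (GUM kernel, common thresholds), fit, and score:

```sh
unfoldirt simulate --design example2-gum --n 1500 --items 10 --seed 7 --out demo
unfoldirt fit --model GUM --data demo/responses.csv \
    --delta-signs=-1,-1,-1,-1,-1,1,1,1,1,1 --se --out demo_fit
unfoldirt score --model GUM --data demo/responses.csv \
    --params demo_fit/parameters.csv --out demo_scores.csv
```

The fit reports

```
loglik -17122.3822  iterations 35  converged True
```

and `demo_fit/parameters.csv` begins

```
parameter,estimate,family,se
delta_1,-1.995054881,delta,0.09291689988
delta_2,-1.46733952,delta,0.07179093185
delta_3,-1.120318571,delta,0.05965011136
```

— the generating locations for these items were −2.000, −1.556 and −1.111
(equally spaced on [−2, 2]; written to `demo/truth.csv`), so each estimate
sits within about one standard error of its truth.  `demo_scores.csv`
holds one EAP trait estimate and posterior SD per person:

```
person,theta_1,se_1,method,valid
1,-1.44599,0.361202,EAP,True
```

The same pipeline is available programmatically
(`unfoldirt.fit_mml_em`, `score_persons`, `run_study`, ...), and
`unfoldirt recover` runs a full parameter-recovery study from the command
line.

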