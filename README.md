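# msmiss

**Marginal structural models with partially observed time-varying
confounders.**

Longitudinal observational studies with a time-varying treatment need
marginal structural models (MSMs): when earlier treatment affects later
confounders, which in turn affect later treatment (treatment–confounder
feedback), ordinary regression adjustment is biased, and the standard remedy
is stabilized inverse-probability-of-treatment weighting followed by a
weighted regression of the outcome on treatment history only.  In registry
and electronic-health-record data, however, the confounders are routinely
*incomplete* — a value may simply not be recorded at a visit — and the
choice of missing-data strategy then determines whether the causal estimate
survives.

`msmiss` is a toolkit for exactly this problem, aimed at biostatisticians
and epidemiologists who want to (a) analyse a longitudinal panel with any of
five missing-confounder strategies behind one interface, and (b) stress-test
those strategies by simulation under explicitly parameterised missingness
mechanisms.

## The model

The analysis model is the additive MSM for a continuous end-of-study
outcome with binary treatments A_k at K = 3 time points,

    E[Y^(a0, a1, a2)] = β_int + β0·a0 + β1·a1 + β2·a2,

fitted by weighted least squares with stabilized weights

    sw_i = Π_k P(A_k = a_ik | A_{k-1}) / P(A_k = a_ik | L1_k, L2_k, A_{k-1}),

both sets of probabilities estimated by pooled logistic regression on
person-time rows.  Any static-regime contrast follows from the β's (e.g.
always- vs never-treated = β0 + β1 + β2).

## Strategies and mechanisms

| Strategy | Idea |
|---|---|
| `cc` | complete-case: drop subjects with any missing confounder cell |
| `locf` | last observation carried forward, then analyse as complete |
| `mpa` | missingness-pattern approach: pattern-specific weight models using only the observed confounders of each pattern |
| `mi` | multiple imputation by chained equations (PMM), Rubin's-rules pooling |
| `ipmw` | censor at first missing cell, reweight complete records by inverse probability of remaining observed |

The simulator overlays six missingness mechanisms on complete panels —
`MCAR`, `MAR_AL` (past treatment + confounders), `MAR_ALY` (… + outcome),
`MAR_ALV` (… + independent risk factor), `CONSTANT` (missing only when the
value exactly repeated the previous measurement), and `DIFFERENTIAL`
(missingness severs the link between the masked value and the contemporaneous
treatment decision) — each calibrated to a target missingness proportion
(40% main scenario, 5% secondary).  See `docs/methods.md` for the full
data-generating model and every numerical choice.

## Worked example

```python
import msmiss as mm

dgm = mm.default_dgm()
truth = mm.true_msm_coefficients(dgm, "gformula_mc", n_mc=400_000, seed=7)
print("true betas:", truth.betas.round(4))

panel = mm.simulate_full_data(dgm, n=10_000, seed=7)
mconfig = mm.default_missingness("MAR_AL", target=0.40, config=dgm)
masked = mm.apply_missingness(panel, mconfig, seed=7)
from msmiss.simulate import realized_missingness
print("missing fraction:", round(realized_missingness(masked, mconfig), 3))

res = mm.mi_estimate(masked, m=10, seed=7)
print("MI betas:  ", res.pooled.params[1:].round(4), " se:", res.pooled.se[1:].round(4))
w, est = mm.ipmw_estimate(masked)
print("IPMW betas:", est.betas.round(4), " se:", est.se[1:].round(4),
      " n_eff:", est.n_effective)
```

Output from this exact script:

```
true betas: [0.7063 0.6251 0.5   ]
missing fraction: 0.398
MI betas:   [0.7609 0.7009 0.5279]  se: [0.0599 0.061  0.062 ]
IPMW betas: [1.4089 0.2637 0.4453]  se: [0.3331 0.1978 0.2151]  n_eff: 1506
```

The truth oracle (counterfactual g-formula simulation) gives β = (0.706,
0.625, 0.500).  Under a missing-at-random mechanism both MI and IPMW are
consistent, but this single data set shows the efficiency gap the package
is built to expose: MI uses all 10,000 subjects and lands within about one
SE (~0.06) of the truth, while IPMW — which censors at the first missing
cell and keeps only 1,506 fully observed subjects, reweighted by two
estimated weights — has SEs of 0.20–0.33 and correspondingly scattered
point estimates (its β̂_0 here is about two SEs above the truth).  Averaged
over replications both are unbiased; `run_scenario` quantifies exactly
this, and the bias of genuinely invalid method/mechanism pairs (e.g.
carry-forward under anything but "constant" missingness) stands out
against it.

From the shell:

```bash
msmiss simulate --n 10000 --seed 1 --mechanism MAR_AL --target 0.4 --out panel.csv
msmiss analyze --panel panel.csv --method mi --imputations 10 --seed 1 --out result.json
msmiss experiment --scenario scenario.yaml --seed 1 --out results/
msmiss report --results results/ --out bias.png
```

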