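# capdce

A toolkit for discrete choice experiments (DCEs) on provider payment
preferences, built around a capitation pilot: attribute/level schemas,
D-efficient choice-design generation under point priors, random-utility
choice simulation, multinomial logit (MNL) and panel mixed logit (MMNL)
estimation with cluster-robust standard errors, and post-estimation
willingness-to-accept (WTA) and relative-importance scores.

## Pipeline

1. **Schema** (`capdce.schema`) — attributes with ordered numeric level
   codes, linear or indicator coding, expected signs, design priors and a
   cost flag; an optional opt-out alternative-specific constant (ASC).
   Two fixtures ship with the package: `pilot` (5 attributes, K = 6 with
   the opt-out ASC) and `final` (4 attributes). Load them with
   `capdce.load_fixture("pilot")` or any YAML file via
   `load_attribute_config` (schema documented in its docstring).
   The fixtures' priors are sign-consistent stand-ins (|prior| x range
   ~ 0.1), **not** values from any study.
2. **Design** (`capdce.design`) — multi-start coordinate exchange over the
   full-factorial candidate set minimizing the D-error
   `det(I(beta)^-1)^(1/K)` at the priors; the opt-out is held fixed.
   Diagnostics report level balance, within-task overlap and dominance.
3. **Simulation** (`capdce.simulate`) — utilities `X beta + Gumbel noise`,
   choices by utility argmax, full best-to-worst rankings, optional normal
   random-coefficient layer for panel heterogeneity.
4. **Estimation** (`capdce.estimate`) — MNL by Newton iterations with
   analytic gradient/Hessian (globally concave likelihood), classical and
   respondent-clustered sandwich covariance, forced-choice option (opt-out
   excluded), equal-shares or user-supplied adjusted-rho² baseline; panel
   MMNL by simulated maximum likelihood with Halton draws.
5. **Post-estimation** (`capdce.postest`) — WTA = `-b_k / b_cost` with
   delta-method standard errors through the robust covariance;
   relative importance as each attribute's `|b_k| x level span` share.

## CLI

```bash
capdce design   --config pilot.yaml --tasks 8 --alts 2 --seed 1 --out design.csv
capdce simulate --design design.csv --config pilot.yaml --n 31 --seed 2 --out choices.csv
capdce fit      --data choices.csv --out fit.json          # add --no-optout, --mmnl
capdce report   --results fit.json --config pilot.yaml --out report.json
capdce pipeline --config pipeline.yaml                     # all four stages + manifest
```

A pipeline config is a YAML mapping of `PipelineConfig` fields, e.g.

```yaml
attribute_config: pilot.yaml
out_dir: out/
n_tasks: 8
n_nonoptout_alts: 2
n_respondents: 31
beta_true: [-0.0895, 0.4808, 0.0003, -0.0360, 0.0540, -0.2319]
```

All CSV/JSON outputs embed the seed and a config hash; identical configs
produce identical artifacts.

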