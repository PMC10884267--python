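# comorbid

Model-based synthesis of pairwise multimorbidity prevalence from
heterogeneous study data.

## The problem

National estimates of how often two chronic conditions occur *together* are
hard to obtain directly: individual studies use different sampling frames
(household surveys, clinic attenders, insurance databases), different
condition definitions, and are rarely nationally representative. Standard
meta-analysis of association measures is also misleading here, because the
observed odds ratio between two conditions depends systematically on how
many "healthy" (no-condition) individuals the sampling frame retains —
facility-based samples compress or even reverse associations.

`comorbid` implements a three-stage statistical pipeline for this setting,
aimed at epidemiologists and health-systems modellers:

1. **Evidence synthesis.** For each condition pair, per-study unadjusted
   odds ratios are computed from 2×2 contingency tables (Woolf variance,
   Haldane–Anscombe correction for zero cells) and pooled by
   DerSimonian–Laird random-effects meta-analysis — or, when three or more
   study estimates exist, by a random-effects meta-regression (REML τ²) of
   the log OR on the product of the two study prevalences
   `log θ = c + m·PᵢPⱼ`. The product `PᵢPⱼ` is the expected prevalence of
   the combination under independence; regressing on it standardises the
   association for the healthy-fraction distortion.
2. **Joint prevalence.** Given national marginal prevalences `Pᵢ, Pⱼ` and
   an odds ratio `θᵢⱼ` (predicted at the national marginals for
   meta-regression pairs), the joint prevalence solves

   ```
   θᵢⱼ = Pᵢⱼ(1 − Pᵢ − Pⱼ + Pᵢⱼ) / [(Pᵢ − Pᵢⱼ)(Pⱼ − Pᵢⱼ)]
   ```

   in closed form: `Pᵢⱼ = [A − √(A² − 4θ(θ−1)PᵢPⱼ)] / (2(θ−1))` with
   `A = 1 + (θ−1)(Pᵢ + Pⱼ)`, the unique root inside the Fréchet bounds.
   Conditional comorbidity prevalences are `Pᵢⱼ/Pᵢ`, and the expected
   comorbidity count for index condition *i* is `Mᵢ = Σⱼ Pᵢⱼ/Pᵢ`.
3. **Uncertainty.** A parametric bootstrap resamples the marginals
   (independent normals from their 95% CIs), and the association (normal on
   the pooled log OR, or multivariate normal on `(m, c)` with their
   covariance), re-solving the quadratic each iteration; percentile CIs are
   reported, and `var(Mᵢ)` is approximated as the sum of the per-pair
   conditional variances.

A synthetic-data module generates study series from a known log-OR surface
(including the healthy-retention sampling distortion, which multiplies the
observed OR by exactly the retention factor φ), so every stage is testable
without any external data. The national South African prevalence table
(ages 15+) for ten conditions — arthritis, asthma, COPD, depression,
diabetes, HIV, hypertension, IHD, stroke, tuberculosis — is packaged as an
input fixture.

## Worked example

The strongest association in the packaged national tables is COPD–asthma
(OR 14.6, 95% CI 10.3–19.9), with marginals `P_COPD = 1.8%` and
`P_asthma = 3.5%`:

```python
from comorbid import (PrevalenceEstimate, PairAssociation, BootstrapConfig,
                      pair_prevalence, bootstrap_pair)
import math

copd = PrevalenceEstimate("COPD", 0.018, 0.015, 0.022)
asthma = PrevalenceEstimate("Asthma", 0.035, 0.031, 0.040)
assoc = PairAssociation("COPD", "Asthma", "fixed", k_studies=1,
                        pooled_log_or=math.log(14.6),
                        pooled_se=(math.log(19.9) - math.log(10.3)) / (2 * 1.959964))

pp = pair_prevalence(copd, asthma, assoc)
pb = bootstrap_pair(copd, asthma, assoc, BootstrapConfig(n_iter=10_000, seed=1))
print(f"joint prevalence P(COPD & asthma) = {pp.p_joint:.4%} "
      f"(95% CI {pb.ci_low:.4%} to {pb.ci_high:.4%})")
print(f"asthma among COPD patients      = {pp.p_b_given_a:.1%}")
print(f"COPD among asthma patients      = {pp.p_a_given_b:.1%}")
```

prints

```
joint prevalence P(COPD & asthma) = 0.5592% (95% CI 0.4119% to 0.7287%)
asthma among COPD patients      = 31.1%
COPD among asthma patients      = 16.0%
```

That is: although both conditions are individually uncommon, roughly one in
three people with COPD also has asthma, and one in six asthma patients has
COPD — the joint burden is concentrated in the rarer index condition.

The same pipeline runs end to end from the shell. `comorbid run-all` takes
a study CSV (2×2 counts or log-OR rows), a prevalence CSV, and optional
fixed ORs, and writes odds-ratio / joint-prevalence / conditional matrices,
a comorbidity table (`Mᵢ` with CIs) and a run manifest:

```bash
comorbid simulate -m -8 -c 1.0 --tau 0.1 -k 10 --study-size 2000 \
    --seed 2 --out studies.csv
comorbid synthesize --studies studies.csv --out assoc.csv
comorbid run-all --fixed-or fixed.csv --seed 1 --out results/
```

(Omitting `--prevalence` uses the packaged national table.)

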