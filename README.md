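# consafety

Statistical analysis of fatal construction-accident registries: severity
classification and descriptive characterization, regional severity ranking by
k-means with an ANOVA validity check, and GM(1,1) grey forecasting of annual
deaths.

Occupational-safety surveillance in the construction sector produces exactly
the kind of data classical methods struggle with: short annual series (a
decade of death counts), categorical registries (type, location, province,
date), and heavily skewed severity distributions in which ordinary accidents
(fewer than 3 deaths) dominate while rare collapses kill tens of workers at
once. `consafety` packages the standard analysis chain for such data, built
around a bundled reference study of China's 2010–2019 registry (6005 fatal
accidents, 7275 deaths across 31 provinces), and a seeded synthetic-registry
generator so every stage is testable without external data.

## The models

**Severity bands** (State Council Order No. 493): deaths in [0,3) → ordinary,
[3,10) → major, [10,30) → severe, ≥30 → extraordinarily severe.

**Relative mortality indexes** normalize each region's death toll by the size
of its construction sector: deaths per 10¹¹ CNY of production value, and
deaths per 10⁵ employees. Raw counts rank populous provinces worst; the
relative indexes expose small provinces with disproportionate mortality.

**K-means with ANOVA validity.** Regions are clustered by Lloyd's algorithm
(best of ≥50 k-means++ restarts, raw Euclidean features), labels are
severity-ordered so cluster 1 is the most critical group, and each feature is
checked with a one-way ANOVA across the final memberships:

    F = [Σₖ nₖ(x̄ₖ − x̄)² / (K−1)] / [Σₖ Σᵢ (xᵢₖ − x̄ₖ)² / (n−K)]

**GM(1,1) grey forecasting.** For a positive series x⁽⁰⁾(1..n), the 1-AGO
accumulation x⁽¹⁾(k) = Σᵢ≤ₖ x⁽⁰⁾(i) is modeled by the whitening equation
dx/dt + a·x = b. With background values z⁽¹⁾(k) = (x⁽¹⁾(k)+x⁽¹⁾(k−1))/2, the
parameters solve the least-squares system x⁽⁰⁾(k) = −a·z⁽¹⁾(k) + b, and the
restored (IAGO) prediction is

    x̂⁽⁰⁾(k+1) = (1 − eᵃ)(x⁽⁰⁾(1) − b/a) e⁻ᵃᵏ,  x̂⁽⁰⁾(1) = x⁽⁰⁾(1).

A model is accepted when the mean relative error of the in-sample fit
(averaged over all n points) is below 20%. A simple linear regression on
t = 1..n serves as the baseline.

## Worked example

Grey forecast of the bundled 10-year deaths series (772, 738, 624, 653, 648,
554, 735, 807, 840, 904):

```sh
$ consafety forecast --out out/fc
GM(1,1): a = -0.0424, b = 559.9831, MRE = 6.98% (valid)
next-step forecast: 886.8
```

The development coefficient a = −0.0424 is negative, so the restored series
grows ~4.3%/year; b = 559.98 is the grey input. The fit's mean relative
error, 6.98%, is under the 20% validity threshold (the linear baseline
manages only 11.01% with R² = 0.25), and the one-step-ahead forecast rounds
to 887 deaths for the next year. `out/fc/forecast_table.csv` holds the
per-year fitted values and relative errors for both models.

Cluster the provinces on the relative mortality rates:

```sh
$ consafety cluster --features relative --out out/cl
rate_production: F(2,28) = 159.558, p = 4.94e-16
rate_staff: F(2,28) = 69.423, p = 1.41e-11
```

Cluster 1 is {Hainan, Qinghai} — provinces whose death rates per unit
production value (252.78, 261.36) and per 10⁵ staff (151.67, 136.90) dwarf
those of high-count provinces like Jiangsu, which lands in the *least*
critical cluster once exposure is accounted for. Both F statistics far exceed
the F(2,28) critical value 3.34, so the clusters separate both features.

The same library calls are available in Python
(`consafety.fit_gm11`, `consafety.cluster_panel`, `consafety.aggregate`, …),
and `consafety simulate` draws synthetic registries with the reference
study's marginal structure (August peak, February trough, ~4.3% major+severe
share) for testing pipelines end to end. `consafety reproduce --out DIR`
recomputes all fourteen headline numbers of the bundled study and prints a
pass/fail line for each.

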