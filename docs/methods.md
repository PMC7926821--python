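# Methods

## Registry model and severity classification

A registry row is one fatal accident: date, region (closed list of the 31
mainland provinces/municipalities), accident type (five categories: falls
from height, struck-by, collapse, lifting injury, other), site location
(four categories, optional), deaths, and a serious-injury flag. Severity
bands partition the non-negative death tolls — [0,3) ordinary, [3,10) major,
[10,30) severe, ≥30 extraordinarily severe. The serious-injury flag is
stored but never escalates the band: the bands are defined on deaths alone,
and the flag only characterizes the floor of the ordinary class (an event
with serious injuries but no deaths is still a registrable ordinary
accident).

Two data-availability quirks of the underlying surveillance feed shape the
aggregation contract. Accident types are missing for one study year, so
type aggregations run on the type-annotated subset and report that subset's
size next to every percentage (in the bundled study the type base is 5500 =
2841+778+647+450+784, not the 6005 total). Location data exist only for the
first two study years; a location aggregation over a registry that mixes
annotated and non-annotated records raises instead of silently producing
percentages on an undeclared base.

Weekdays use the ISO convention (Monday = 1). Report display rounds
half-up at 2 decimals; all internal computation is full precision. Because
the upstream feed's own rounding convention is unknown, percentages are
reported at full precision rather than forced to any printed digit.

The bundled province panel is an independent dataset from the national
yearly series: its column sums (6028 accidents, 7296 deaths) exceed the
national headline totals (6005, 7275), presumably due to revision timing in
the underlying reports, and the two are deliberately never reconciled.
Raw production values and employee counts are not part of the panel; the
printed rate columns are primary, and `infer_denominators` can back-compute
denominators (flagged `inferred`) that reproduce the rates by construction.

## Relative indexes

death rate per unit production value = deaths / production value (10¹¹ CNY);
death rate of staff = deaths / employees (10⁵ persons). Both are linear in
deaths and inverse in the denominator (scale equivariance is property-
tested). Whether a source computed its printed rates from single-year or
decade-aggregated denominators cannot be recovered from the rates; the
panel treats them as given.

## K-means and the cluster-validity ANOVA

Lloyd's algorithm on raw (unstandardized) feature columns: assignment by
squared Euclidean distance, centroid update by cluster means, convergence
when assignments are stable, best of ≥50 k-means++ restarts by
within-cluster sum of squares (WSS). Features are deliberately not
standardized: the reference memberships are consistent with raw Euclidean
distance, and the two features in each set share units and scale. An empty
cluster is re-seeded at the point farthest from its assigned centroid.
WSS is non-increasing across Lloyd half-steps (recorded per iteration and
property-tested); on instances small enough to enumerate (n ≤ 8, K ≤ 3) the
best-of-restarts solution attains the exhaustive-partition optimum.

Final labels are severity-ordered: cluster 1 has the largest centroid norm
(or the largest centroid value on a chosen severity feature in
`rank_clusters`), ties broken by cluster size with the larger cluster taking
the more critical label.

Validity is assessed per feature by a one-way ANOVA across the final
memberships, SPSS quick-cluster style: between SS = Σ nₖ(meanₖ − grand
mean)², within SS = Σ squared deviations from cluster means, F = between
MS / within MS at df (K−1, n−K), upper-tail F p-value. The decomposition
conserves total SS to 1e-9 relative (tested). Because memberships are chosen
to separate the features, this F is a separation index, not a hypothesis
test of cluster existence; p-values are reported at full precision, and a
"Sig = 0" report convention is read as p < 0.0005.

Critical values come from the F distribution: for 3 clusters over 31
regions, F(2,28) at α = 0.05 is 3.340. A value of 4.196 sometimes quoted
for this layout is the F(1,28) critical value — a numerator-df slip — and is
documented here but not used.

On the bundled panel's relative rates, the reference partition
({Hainan, Qinghai} as the critical cluster) is a genuine Lloyd fixed point
(WSS 19671.8) but not the global optimum: best-of-restarts finds a strictly
better partition (WSS 18306.1) that moves Heilongjiang into the critical
cluster. The package reports the better-WSS solution; the validity ANOVA on
the reference memberships is still reproduced exactly when those memberships
are supplied, and the two extreme provinces are in the critical cluster
under either partition. On the absolute factors the reference partition
(Jiangsu as a singleton critical cluster, an 8-member second cluster) is
recovered exactly.

## GM(1,1)

Estimation: 1-AGO accumulation, background values with the standard
equal-weight coefficient 0.5 (this choice reproduces the bundled study's
coefficients; the coefficient is fixed, not exposed, because no alternative
weighting is in scope), least squares on the n−1 equations
x⁽⁰⁾(k) = −a·z⁽¹⁾(k) + b via `numpy.linalg.lstsq`. The initial condition
x̂⁽¹⁾(1) = x⁽⁰⁾(1) is the classical choice; the restored prediction for
observation k+1 is (1 − eᵃ)(x⁽⁰⁾(1) − b/a)e⁻ᵃᵏ, so a forecast for the
(n+j)-th calendar step evaluates the exponent at index n−1+j. The model
requires strictly positive series with n ≥ 4; |a| < 1e-12 is treated as the
a → 0 limit, in which every restored value equals b (a flat series fits
a = 0, b = level exactly). Mean relative error averages |actual −
fitted|/actual over *all* n points, including the structurally exact first
one; the acceptance threshold is 20% (configurable).

A subtlety documented because tests rely on it: the continuous restored
series is not an exact solution of the discrete background-value equations.
Substituting the exponential trajectory into x⁽⁰⁾(k) = −a·z⁽¹⁾(k) + b leaves
a relative residual of a³/12 — the trapezoid rule's error on an exponential —
so refitting a noise-free generated trajectory recovers the development
coefficient only up to a bias of |a|³/12 (measured at exactly that constant
across |a| ≤ 0.2), and the refit's in-sample mean relative error is O(|a|³)
rather than zero. Self-consistency tests therefore assert the analytic
bounds (|Δa| ≤ |a|³/6, MRE ≤ 100·|a|³) instead of machine precision. At the
bundled study's a ≈ −0.042 the bias is ~6e-6 — four orders of magnitude
below the parameter itself.

The standalone restored-series constant printed in the bundled study's
equation table (580.2671) is inconsistent with that study's own fitted
column, which pins the constant at 605.466·e⁻⁰·⁰⁴²⁴ ≈ 580.324; the
least-squares value 580.3282 reproduces every printed fitted value and the
887 forecast, so the printed constant is treated as a misprint.

The linear baseline is ordinary least squares of the series on t = 1..n
(via `scipy.stats.linregress`), with R² = 1 − SSE/SST and the same relative-
error report.

## Synthetic generators

`generate_registry` draws yearly accident counts from a Poisson law around a
(optionally trending) mean — default 600/year over 2010–2019, the order of
the bundled study's registry — then assigns each accident independently: a
calendar day drawn over all days of the year with weight month_weight ×
weekday_weight, a region (default proportional to the bundled panel's
accident counts), a type (default shares 51.66/14.15/11.76/8.18/14.25%),
and a death toll. Month and weekday defaults encode only ordinal facts
(August peak, February trough; Monday/Sunday high, Tuesday low); their
magnitudes are conventional because the underlying sources publish the
ordering, not calibrated intensities. The deaths-per-accident law is a
zero-truncated geometric (p = 0.79543) mixed with weight 0.0012 of
uniform{10..29}: the severe weight matches the observed severe share
(~7/6005 ≈ 0.12%) and the geometric decay solves
(1−w)q² + w = 0.043, making the major+severe share exactly 4.3%. The implied
mean of ~1.28 deaths/accident is slightly above the study's 1.21 — the tail
masses, not the mean, are the calibration targets. Every draw is recorded
in a ledger, and aggregation outputs are tested for exact equality against
ledger recounts.

The generator emulates categorical marginals only: no weather, holiday,
spatial, or serial correlation, no under-reporting, no within-year trend.
Passing tests therefore demonstrate correct counting, classification,
clustering, and fitting on data with the reference marginal structure — not
robustness to the dependence structure of real registries.

`generate_panel` jitters panel counts and rates by independent lognormal
factors exp(N(0, scale)); scale 0 returns the panel verbatim. At 5% jitter
the absolute-factor cluster structure (Jiangsu singleton) survives in ≥95 of
100 seeds; at scale 10 it is destroyed (both tested). `generate_gm_series`
emits the exact restored-series trajectory (a = 0 handled as the constant
limit) with optional lognormal multiplicative noise; at 2% noise the median
development-coefficient recovery error over 100 replicates is ~0.0014.

## Problem sizes

All bundled computations are desk-scale: a 10-point series, a 31×2 feature
matrix, registries of ~6000 records (50,000 in the law-of-large-numbers
tests). The full suite runs in a few seconds on one CPU.

## Known limitations

- GM(1,1) assumes quasi-exponential growth of the accumulated series; it
  cannot represent the U-shape of the bundled deaths series within-sample
  (its worst in-sample error, 29%, falls at the series minimum) and is only
  as good as the 20% mean-error criterion admits.
- The initial-condition convention x̂⁽¹⁾(1) = x⁽⁰⁾(1) is fixed; alternative
  initializations (e.g. last-point anchoring) are out of scope.
- K-means reports the best-WSS partition, which for near-tied structures may
  differ from a particular published local optimum (see above).
- The severity bands are jurisdiction-specific; other countries' injury
  classification schemes are not implemented.
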