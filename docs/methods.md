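# Methods

This note documents the models, algorithms, parameters, and design choices
behind `marshsim`, in the spirit of a package methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dimension system and unit conversions

The analysis runs over four fundamental dimensions (mass M, length L, time
T, temperature K) and seven variables: nee and par [M L⁻² T⁻¹], st [K],
ss [M L⁻³], pa [M L⁻¹ T⁻²], cp [L² T⁻² K⁻¹], and t [T]. Two conventions
are deliberate and load-bearing:

- µmol (gas amounts) and g (salinity, pressure) are both carried under the
  single M dimension with no mole↔gram conversion; the derived groups come
  out in their standard forms only under this bookkeeping.
- cp, the specific heat of wet soil, is a fixed constant (1.48 J/g/K,
  numerically identical to 1.48 kJ/kg/K) introduced solely to normalize
  the lone K-dimensioned variable st; it is stored as a `PhysicalVariable`
  and overridable in configuration.

Conversions are affine (`si = scale·x + offset`): st +273.15 (the only
offset permitted — validation rejects offsets elsewhere), ss ×1000,
pa ×100000, everything else ×1. The round-trip si→original is tested to
1e-12 relative tolerance rather than bit-exactness: IEEE-754 addition and
subtraction of 273.15 is not an exact involution, and the package does not
pretend otherwise. Dimension exponents, by contrast, are exact
`fractions.Fraction` values throughout.

The flux sign convention is uptake-positive. Negative values pass record
validation with a warning but are excluded from regime analysis, whose
log₁₀ transform requires positivity.

## The pi engine

A pi group is a monomial ∏ varᵉ with rational exponents. Construction
follows the classical recipe: pick r = 4 repeating variables that span
(M, L, T, K) without forming a dimensionless product among themselves
(checked by exact rank; when a set fails, the diagnostic exhibits a
null-space witness — the dimensionless combination it forms), fix the
target variable's exponent at +1, and solve the 4×4 homogeneity system by
exact Gaussian elimination over `Fraction`. Exactness is the point:
equality and uniqueness of groups must not depend on float tolerance, and
exponents like ½ arising from root-form iterations are represented
exactly.

Equivalence of groups is proportionality of exponent vectors (a group, its
powers, roots, and inverse are one similitude). The canonical form divides
by the exponent of the lexicographically first variable present, clears
denominators, and reduces, leaving a primitive integer vector with a
positive leading entry; deduplication compares canonical forms and keeps
first occurrences.

**Driver pool.** The response variable (nee) never repeats. Of the
C(6,4) = 15 candidate repeating sets over {par, st, ss, pa, cp, t}, 9 are
valid; their left-out-driver groups fall into 4 equivalence classes. The
full six-member driver pool is obtained by augmenting the iterated drivers
with the products and ratios of the first environmental number
(ss·pa/par²) against each unique iterated driver. This anchored
combination rule is a design choice: it is the smallest closure that
produces exactly the analysis' six unique drivers, whereas closing under
*all* pairwise products/ratios would manufacture additional classes (e.g.
st·cp·ss³·par⁻²·pa⁻¹-type composites) that belong to no iteration and add
no information — any driver group is already a rational-exponent monomial
of two basis groups, so "more combinations" only multiplies equivalent
decorations. The six canonical representatives carry labels lue, pi2, pi3,
pi4, bgc, pi6, pi7 (bgc = pi3/pi2 = st·cp·ss/pa).

A basis-change identity is enforced in tests: the groups derived from any
two valid repeating sets span the same exponent space, checked by solving
the exact linear system that expresses one basis in the other.

## Chamber fluxes

The molar amount of CO₂ in the closed chamber is
`ppm · P[Pa] · V / (R · T[K])` µmol with R = 8.314 J/mol/K, V = 0.216 m³;
air temperature (not soil temperature) enters the gas law. The flux is the
OLS slope of amount versus time divided by the 0.36 m² footprint,
sign-flipped once so uptake is positive. An equivalent
concentration-times-height route is available behind a flag and is
identical for a fixed chamber volume.

QC: R² ≥ 0.90, at least 10 points, at least a 60 s span (all
configurable). Failing series still report their flux, flagged with a
reason; constant series short-circuit to flux 0 with "R² undefined" (the
zero-variance case is detected explicitly rather than trusting the
regression routine's 0/0 behaviour). The daytime filter keeps records with
clock time in [08:00, 16:30] local EST — both boundaries inclusive, the
least surprising reading of an "between 8 a.m. and 4.30 p.m." window — and
PAR > 1.5 µmol/m²/s. Timestamps are treated as naive local EST (UTC−5, no
DST).

Out of scope by design: nonlinear chamber models (exponential/HMR) and
water-vapor dilution corrections.

## Regime pipeline

`evaluate_pis` computes LUE and the six drivers per record from SI values
(records with nonpositive nee/par/pa are excluded, logged). BGC equals
pi3/pi2 elementwise to machine precision because both sides are evaluated
from the same exponent maps.

**PCA driver selection.** All seven numbers are log₁₀-transformed and
z-standardized with the sample (n−1) standard deviation, then a joint PCA
is run (response and drivers together — the biplot construction). Loadings
are the unit eigenvector coordinates on (PC1, PC2); the sign indeterminacy
is fixed by making the response loading's PC1 coordinate positive. The
selected driver minimizes the angular distance to collinearity
(min(θ, 180°−θ)) with the response loading. Because every number is a
monomial over five base quantities, the log-space data matrix has rank at
most 5 — a structural fact the tests assert.

**Classification.** low if LUE < 0.002; high if LUE ≥ 0.002 and
BGC ≤ 0.13; transitional otherwise. Boundary ties go to high, matching
the regime definitions' weak inequalities. Thresholds are configuration,
defaulting to the published values; they are applied, not re-estimated
(estimating them, like fitting the diagram's "loop" curve or tipping
point, is outside the package's scope).

**ANOVA.** Pairwise one-way F statistics are computed from sums of squares
directly (df = 1, n₁+n₂−2), with p-values from `scipy.stats.f`;
`scipy.stats.f_oneway` serves as an independent cross-check in tests, not
as the implementation. No multiple-testing correction is applied across
the three pairs. Empty or singleton regimes skip their pairs with a
warning.

**Site summaries** use the ratio-of-means construction: seasonal mean
drivers are converted to SI and LUE/BGC computed from those means — not
the mean of per-record ratios. Report tables round LUE/BGC to 3 decimals
and temperatures to 1.

**Binning** pools all sites into left-closed right-open bins aligned at
zero with fixed widths 1 °C (st), 2 ppt (ss), 100 µmol/m²/s (par); empty
bins are omitted.

The air-temperature threshold utility fits AT ~ ST by OLS (or evaluates a
supplied coefficient pair) and reports the AT value at ST = 17 °C.

## Synthetic campaigns

The generator emulates the study design — 137 instantaneous daytime
observations, 4 sites, 25 sampling days across May–October — not any
particular dataset. Per record:

- **st**: seasonal sinusoid from 9 °C (season edges) to 26 °C (mid
  season) plus N(0, 1.5²) noise, clipped to the seasonal range;
- **ss**: truncated normal around per-site means (31, 26, 31, 34 ppt),
  sd 2 ppt, support [10, 40];
- **par**: 300 + 1800·Beta(2, 2) µmol/m²/s;
- **pa**: truncated normal (1013, 4²) mbar on [1004, 1027];
- **at**: 6.31 + 1.135·st + N(0, 1.5²);
- **nee** = α·par·exp(ε), ε ~ N(0, 0.1²) — a linear light response with
  multiplicative lognormal error (the response to light is linear; no
  light saturation is modelled, consistent with the absence of
  photoinhibition in the study data).

The efficiency α is drawn by condition tier: cold soil (st < 17 °C) is
temperature-limited regardless of salinity, α ~ U(0.0008, 0.0016); warm
and saline (ss > 30 ppt), α ~ U(0.0022, 0.003); warm and fresher,
α ~ U(0.003, 0.01). Configuration validation requires the cold band to
sit strictly below the LUE threshold and the favorable band above it.
The cold tier deliberately does not require high salinity: the low regime
reflects cold limitation of photosynthesis, so a cold, low-salinity record
is still inefficient.

The truth table records each record's α, its condition tier, and its
**generating regime** — the regime of the noiseless record, i.e.
classify(α, BGC) with the realized BGC. This is the label the classifier
should recover: at zero noise recovery is exact by construction (a
round-trip check of the whole evaluate→classify chain, including unit
conversion), and under the default 10% noise only records with α near the
0.002 boundary can flip. The condition breaks (17 °C, 30 ppt) do not map
exactly onto the diagram thresholds (0.002, 0.13) — BGC also involves Pa
and the full temperature–salinity product — which is why tier and regime
are distinct columns.

Distribution families (truncated normals, the sinusoid, the scaled beta)
are generator choices, not observed facts; the generator does not emulate
tidal dynamics, nitrogen-loading gradients, or spatial structure, nor the
empirical correlation between sampling day and site salinity. Passing
recovery tests on these campaigns therefore demonstrates the pipeline's
correctness under the stated statistical structure, not the field
behaviour of any real marsh.

Chamber-series generation inverts the flux estimator's model: a linear
molar-amount drawdown at flux·area µmol/s, converted to ppm and perturbed
with Gaussian noise at the analyzer precision (0.4 ppm). Noiseless
round-trips are exact; the Monte-Carlo bias over 200 replicates (default
300 s deployments) is within three standard errors of zero — the problem
sizes used in tests and the acceptance script (137-record campaigns, 200
flux replicates) match the study's scale and keep the checks cheap.

## Reproducibility and I/O

All randomness flows from one `numpy.random.Generator`; seeded runs are
bit-reproducible, and `run_report` logs the package version, a SHA-256
configuration digest, and the thresholds actually applied. Tabular I/O is
CSV; pi groups serialize to JSON with exponents as exact `"p/q"` strings.
The end-to-end order is: daytime filter → SI conversion → pi evaluation →
PCA → classification → ANOVA → site summary → binning → process-diagram
figure.

## Known limitations

- Only the study's (M, L, T, K) unit system is supported — no general
  unit ontology.
- Monomial similitudes only; no symbolic simplification beyond exponent
  arithmetic.
- The regime thresholds and the AT–ST regression coefficients are inputs,
  not estimates; reproducing the published F statistics or PCA variance
  on the deposited field data would require that dataset, which is not
  bundled.
- The linear chamber model assumes a well-mixed chamber and ignores
  water-vapor dilution.
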