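# Methods

This note records the statistical conventions the package fixes, why it
fixes them, and what the synthetic generator does and does not emulate.

## Data model

One catch record is one measured fish: site, season (wet/dry), species,
body length (cm, 0.1 precision) and body weight (g, 0.1 precision), both
strictly positive. Communities are groupings of records by site, season
or the whole survey; abundance is the record count per species and
biomass the summed weight. Species identifiers are case-sensitive exact
strings — fuzzy matching silently merges species and corrupts richness
S, so none is attempted. Percentages are carried at full precision and
only rounded for display.

## Diversity and dominance

Shannon diversity uses log base 2 (bits) as its default because the
evenness convention `J = H / log₂ S` pairs with it; a `base` argument
exists for cross-study comparison. Evenness is undefined at S = 1
(log 1 = 0) and raises rather than returning a sentinel.

The IRI is computed with N%, W% and F% all on the 0–100 scale and the
plain product `IRI = (N% + W%) × F%`, range [0, 20000]. Under the
alternative reading with F% as a fraction the index caps at 200 and the
conventional dominance cut-off of 1000 is unreachable, so that reading
is rejected; with the implemented convention `IRI ≥ 1000` is the
standard Pinkas-style threshold and is applied inclusively. Occurrence
units for F% default to site × season pairs; a parameter allows
occurrence over sites only, since field studies differ on this and
reported F% values depend on the choice.

## ABC curves and W

Both dominance curves are independent descending sorts (the abundance
curve sorted by abundance, the biomass curve by biomass); species
identity is not matched across ranks, per standard ABC methodology. Ties
sort by species identifier so output is reproducible. The W statistic
uses Clarke's normalization `W = Σ(Bᵢ − Aᵢ) / (50(S − 1))`, which bounds
W in [−1, 1] for every community. The classifier is exact, not
sign-based: undisturbed requires A ≤ B at every rank (strictly somewhere),
severe the mirror, and everything else — including curves identical at
every rank, where neither curve is "above" the other — is moderate.
Undisturbed therefore implies W > 0 and severe implies W < 0, but the
converse does not hold for crossing curves.

## Normalized biomass size spectrum

Size classes double: class k spans [V·2^(k−1), V·2^k), half-open so a
fish exactly at a boundary belongs to the upper class, with
`k = floor(log₂(w/V)) + 1`. V defaults to the per-community minimum
weight; an override forces a shared grid when spectra on different bin
grids would otherwise be compared. The spectrum point for a non-empty
class is x = log₂(upper limit in g) — the absolute upper limit, not a
class index — and y = log₂((class biomass / area) / class width).

`area` is the per-unit-effort normalization constant and defaults to 1:
sampled area per site is rarely known for electrofishing-style surveys,
and changing `area` (or rescaling every class's biomass by a constant)
shifts only the intercept, never slope or curvature, so all
curvature-based comparisons are unaffected. Empty interior classes are
omitted from the fit rather than imputed — log₂ 0 is undefined and
imputation would manufacture spectrum shape.

Fits are ordinary least squares via `numpy.polyfit`; the quadratic needs
≥ 3 points, the linear ≥ 2, and R² = 1 − SS_res/SS_tot requires
non-constant y. "Curvature" is the quadratic coefficient a; the dome
apex −b/(2a) is reported only when a < 0. A community with equal total
biomass per octave yields slope −1 and curvature 0 to machine precision
(this is the package's reference computation in `scripts/acceptance.py`).

Curvature groups are compared with a three-tier box-plot rule: boxes are
[Q1, Q3] with quartiles by linear interpolation (NumPy's default;
Tukey hinges were rejected so the rule is reproducible across software).
Disjoint boxes → very significant; both medians outside the other box →
significant; otherwise not significant. Each group needs ≥ 3 values.

## Transforms and statistics

lg(x+1) and Hellinger are the usual pre-ordination transforms for
abundance and biomass matrices; z-scoring uses the sample (n−1)
standard deviation, conventional at survey-sized n. Bray–Curtis and
Pearson are delegated to SciPy behind the module's validated surface.
NMDS stress bands are half-open and left-closed — the conventional
wording uses strict inequalities on both sides, which leaves the
boundary values unassigned, so 0.05 falls in "basically credible" and
0.20 in "untrustworthy", covering [0, ∞) without gaps. Ordination
fitting itself (NMDS optimization, RDA with permutation tests) is
deliberately out of scope: the module produces the standard inputs any
ordination package consumes.

## Synthetic generator

The generator emulates the *structure* the analyses assume: a species
pool with a faunal template (default five families in two orders, 14 +
9 + 3 + 1 + 1 = 28 species), per site × season catches with skewed
abundance, individual weights from per-species lognormals (σ = 0.4 on
the log scale, truncated at the 0.1 g measurement floor), and an
environment table with a downstream altitude gradient. Defaults are 21
sites × 2 seasons × 97 individuals, ~4074 fish per survey — the scale
of a two-season river campaign. Abundance defaults to a geometric
(niche-preemption) series with k = 0.4, a standard model for the
strongly skewed dominance such surveys report; a lognormal alternative
is provided.

Regimes control how body size pairs with abundance rank:

- *undisturbed* flattens abundances toward uniform while the size ladder
  spans 0.5–512 g, so biomass concentrates in large-bodied species and
  W > 0 by construction;
- *severe* sets median weights inversely proportional to abundance
  (clipped to the ladder range), so numbers concentrate in small fish,
  per-species biomass is near-flat, and W < 0;
- *moderate* shuffles size against abundance rank;
- *sheldon_ideal* places 2^(K−k+1) fish of weight 2^(k−1) g in class k —
  exactly 2^K g per class — so the NBSS is a line of slope exactly −1;
- a *dome* configuration targets y = a(x − apex)² + peak on the spectrum
  axes directly, filling each class with ~(target biomass / mid-weight)
  fish jittered within the class (the jitter of ±0.25 octaves cannot
  cross a bin boundary). Shallow (a = −0.08, tributary-like) and steep
  (a = −0.30, main-stream-like) presets are provided; per-site curvature
  jitter (sd 0.02) and an optional coupling to the site's dissolved
  oxygen allow curvature–environment correlations of known sign.

What the generator does **not** emulate: gear selectivity, spatial
autocorrelation between neighbouring sites, seasonal migration (the two
seasons are independent draws), length–weight scatter (lengths follow a
deterministic cubic allometry W = 0.01 L³), or mechanistic population
dynamics. Tests passing on synthetic data therefore certify the
*statistics*, not field realism.

## Problem sizes and numerics

Monte-Carlo checks use sizes at which their expectations are sharp but
cheap: 1000 random communities (S = 2–12) for the W oracle, 100 seeds
for regime W-signs at 2–3 sites per survey, and 500 replicate spectra
(10 points, noise σ = 0.1) for curvature recovery, asserting |bias| <
2 SE. Exactness claims (slope −1, W bounds, oracle agreement) are tested
at 1e−12; fitted-coefficient recovery without noise at 1e−9. All
randomness flows from explicit integer seeds; the analysis stages are
seed-free because the statistics are deterministic given data.

## Known limitations

- The NBSS x-axis uses absolute log₂ weight, so spectra built with
  different V sit on different grids; use the shared-V override when
  comparing communities.
- The box-plot significance tiers are a descriptive rule, not an
  inferential test; they carry no error rates.
- The IRI occurrence convention materially changes F% when effort is
  unbalanced across units; report which convention was used.
- With very small catches the quadratic fit can be rank-deficient or
  dominated by a single class; the pipeline skips fits with fewer than
  the required points and logs the group.
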