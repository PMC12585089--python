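# Methods

This note records the models, conventions, and numerical choices the
package implements, including the places where the underlying design
was genuinely open and a convention had to be fixed.

## Record curation

A record enters the analysis only with a collection date (ISO-8601),
latitude, longitude, depth, both isotope values, and a taxon name.
Isotope values are additionally screened against a sanity envelope —
δ¹³C in [−60, 0] ‰, δ¹⁵N in [−20, 40] ‰, both configurable — which is
generous relative to marine organic matter but catches unit and sign
errors.  Every exclusion is attributed to exactly one rule and
reported; unknown vocabulary terms raise instead of being coerced so
the accounting stays exact.

The Julian day of each record is the day count from the dataset-wide
earliest collection date.  It is recomputed on every load and after
every row-dropping operation; a stored `julian_day` column is never
trusted.

**Sectors.**  Six longitudinal sectors partition [−180°, 180°]:
Northern Bering/Chukchi Seas (west of 157°W), Beaufort Sea (157–123°W),
Canadian Arctic Archipelago (123–78°W), Baffin Bay (78–45°W), East
Greenland (45°W–0°), Svalbard (east of 0°).  The published boundaries
name the cut points but not which side owns them, so the package fixes
a half-open convention with the *western* bound inclusive (−157°
exactly → Beaufort Sea); the easternmost interval also contains +180°
so the partition is total.  The boundary list is a value object and
can be replaced wholesale.

**Depth rule.**  Collections strictly deeper than 45 m are dropped
only in the Northern Bering/Chukchi and Beaufort sectors, where the
shelf is broad and shallow and depth is a proxy for distance from the
coast.  Deep fjord, strait, and eastern-shelf sites are legitimate
coastal habitat and are never touched.  The retention of specific deep
shelf sites near Svalbard and the Canadian Archipelago was originally
a qualitative proximity judgment, which cannot be recovered from any
rule; it is therefore an explicit allow-list argument, empty by
default.

## Coastscape scoring

Four coastal archetypes (fjord, lagoon, shelf, strait) are
characterized by eight ordinal features graded on a four-level scale.
The original site assignments were a-priori expert judgment; the
package provides a reproducible proxy: grades are encoded
symmetrically as ++/+/−/−− → +2/+1/−1/−2, a site's feature states map
to +1 (present) / −1 (absent) / 0 (unknown), and each archetype's
score is the dot product of its weight column with the site vector.
The encoding was chosen for symmetry (flipping every feature negates
every score) and testability, and lives in a packaged CSV that can be
swapped.  Exact ties at the top are reported as `ambiguous` — breaking
them silently would fabricate information the features do not contain.

## Lipid correction

Corrections are derived from paired lipid-extracted / non-extracted
tissue samples, aggregated at the phylum level (with the pelagic
copepod *Calanus* split out from the otherwise benthic Arthropoda).
The procedure is screen-then-fit: a two-sided Wilcoxon signed-rank
test per taxon × isotope × treatment cell, a Bonferroni adjustment
across the tested family at α = 0.05, and an OLS regression of the
treated value on the untreated value only for significant cells.
The regression direction (treated on untreated) matters because the
published equations do not label axes; it matches the stated purpose
of mapping untreated measurements onto their lipid-free equivalents.
C:N ratios are deliberately not used: their observed range in the
calibration set was too narrow to carry information.

The signed-rank test drops zero differences (Wilcoxon's original
convention) and counts them.  For n ≤ 25 usable pairs the p-value is
exact, computed by convolution over the 2ⁿ sign assignments on
(doubled) midranks, which handles ties in |d| naturally; above 25 a
normal approximation with tie and continuity corrections is used.
The exact path is implemented in the package rather than delegated so
that its null distribution is enumerable and testable; an independent
library implementation serves as a cross-check in the tests.

At application time, each consumer record whose genus is routed to a
correction (and whose tissue was not already lipid-extracted at
measurement) has each isotope with an available model replaced by
`a·x + b`, and is flagged `lipid_corrected`; flagged records are never
corrected twice.  The model is selected by (taxon, isotope) alone:
the published bank contains exactly one treatment per pair, and the
acid-only ambiguity for calcifiers cannot be resolved from public
text.  The packaged genus→phylum routing table is a synthetic roster
of common Arctic genera (marked synthetic in its filename); the real
roster is not public, and any CSV of the same shape can replace it.

## Trends and group comparisons

Temporal change is estimated by OLS of the isotope value on Julian
day.  Significance is judged against a caller-supplied
Bonferroni-adjusted alpha, defaulting to 0.001/16 — the conservative
level for the standard 16-test family (8 group series × 2 isotopes).
Kendall's τ-b (tie-corrected) accompanies every fit because isotope
data are tied after rounding; the τ variant is a package choice, as
the plain name "Kendall's tau" underdetermines it.  A significant
per-day slope is expressed as a decadal change by multiplying by
3650; rounding to one decimal happens only in reports, never
internally.

Group comparisons use a tie-corrected Kruskal–Wallis test with Dunn's
(1964) post-hoc pairwise z-tests from joint mean ranks with tie
correction — the large-sample normal variant, as no exact variant is
standard — and Bonferroni adjustment across all pairs.  The compact
letter display is built by insert-and-absorb, which guarantees two
groups share a letter iff their adjusted p ≥ α; the constructor
audits this equivalence on every run and raises on violation.  Dunn's
test is implemented in the package because no installed library
provides it.

Depth–δ¹⁵N relationships are exposed as a thin chooser: Pearson on
(optionally log₁₀-transformed) depth where regression assumptions
hold, Spearman where they do not.  The choice is the caller's, since
it was made per habitat by residual inspection in the original
workflow.

## Isotopic niche regions and overlap

Each group's (δ¹³C, δ¹⁵N) cloud is modeled as bivariate normal.  The
α-level niche region N_R is the highest-density ellipse
`(x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₂(α)` (5.991 at α = 0.95); its area is
π·χ²₂(α)·√det Σ.  Elliptical regions are used rather than hulls or
kernel regions because the probabilistic overlap definition requires
a distributional niche.

Uncertainty in (μ, Σ) is handled with the conjugate
normal-inverse-Wishart family.  The noninformative prior is
operationalized as the (κ → 0, Ψ → 0, ν = −1) limit, giving
`Σ | data ~ Inverse-Wishart(S, n − 1)` with S the centered scatter
matrix and `μ | Σ ~ N(x̄, Σ/n)`; the general informative update is
implemented as well.  n ≥ 4 points are required so the posterior is
proper in two dimensions.  Inverse-Wishart draws come from scipy's
sampler (Bartlett-based, SPD by construction); a 10⁻¹⁰ diagonal
ridge is applied only if the scatter matrix is numerically singular.

Directional overlap of A onto B is, for each paired posterior draw,
the fraction of fresh Monte-Carlo points from `N(μ_A, Σ_A)` that land
inside B's α-ellipse; the per-draw fractions form the posterior of
the overlap probability, summarized by the mean and (2.5%, 97.5%)
quantiles.  Defaults are 10,000 posterior draws — the published
"random permutations" count, read here as posterior draws — and
1,000 points per draw, a separate knob; both are recorded in every
estimate.  Overlap matrices follow the row-onto-column convention.
All sampling is vectorized over draws in fixed-size chunks, and every
stochastic routine takes a seed or Generator; results are
bitwise-reproducible under a fixed integer seed.

Calibration facts the test suite verifies: for two large groups from
one distribution the posterior-mean overlap approaches α; overlap at
known parameters agrees with an independent grid-quadrature
integrator to within 0.005; estimates are insensitive to unequal
sample sizes (50 vs 500); and overlap decreases monotonically with
mean separation.

## Synthetic data

The generator exists so every stage is testable without any download.
Each group is a bivariate normal cloud with configurable mean, sd,
and inter-isotope correlation (default 0, because published summary
tables report only per-isotope mean ± sd; correlation is exposed
because ellipse orientation affects overlap).  Collection dates
default to a mid-July–mid-September window within each sampled year,
matching the summer concentration of Arctic field campaigns; metadata
(longitude, depth, genus/phylum) are drawn from per-coastscape
ranges.  The packaged study-like configuration reproduces the
compiled dataset's group structure — 16 consumer coastscape × habit
cells plus pPOM and sPOM per coastscape, parameterized from the
published per-cell summaries — at about one tenth of each cell's
sample size (985 records), which keeps the full pipeline and test
suite fast while leaving every per-cell n large enough for the niche
posterior.

What the generator does *not* emulate: spatial autocorrelation and
coastline geometry, non-normal (skewed or multimodal) isotope
distributions, unbalanced temporal coverage across habitats, and
taxonomic structure beyond genus/phylum labels.  Passing tests
therefore demonstrate that the estimators recover the structure they
assume, not that real Arctic data satisfy those assumptions.

## Pipeline

Stages run in a fixed order: parse → sector assignment → depth filter
→ habit/end-member harmonization → lipid correction → trends → group
comparisons → niche overlap.  Alphas default to the analysis values
(0.05 lipid screening family, 0.001/16 trend family, 0.95 niche
region).  Every run writes a manifest with the seed, a configuration
hash, per-stage in/out/excluded counts (which must reconcile), and
the output list.  The pipeline's default niche settings (1,000 draws
× 500 points) are reduced relative to the estimator defaults to keep
an end-to-end run interactive; report-quality runs should pass
`--n-draws 10000 --points-per-draw 1000`.

## Known limitations

- The coastscape scorer is a reproducible proxy for expert judgment,
  not a reconstruction of it; its encoded weights admit ties that the
  original assignments resolved by hand.
- The genus-level correction routing ships as a synthetic stand-in;
  results depending on *which* genera are corrected are not
  comparable to the original compilation without the real roster.
- No mixed-effects or spatial modeling: records are treated as
  exchangeable within groups, although campaigns cluster in space and
  time.
- Niches are strictly bivariate and normal; heavy-tailed or curved
  clouds will inflate the fitted ellipse.
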