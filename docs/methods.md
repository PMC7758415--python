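# Methods

## Scope and data model

The package evaluates tomato accession panels on two axes — taste chemistry
and volatile odor — and fuses them into a single multi-criteria flavor
ranking. The in-memory containers are plain pandas frames plus small typed
records: `CompoundRef` (per-volatile calibration, threshold, descriptors,
class labels), `PeakTable` (one GC-MS run: integrated areas, retention
times, match scores, internal-standard record), accession profile frames
(taste compounds, sensory scores, odor-category OAVs), and the
`TopsisModel`/`TopsisResults` pair for the ranking stage.

Analysis starts at integrated peak tables: raw-spectrum deconvolution,
library spectral matching, and instrument control are out of scope (match
scores are inputs).

## GC-MS quantification

**Retention index.** Kovats convention: each ladder n-alkane C_z anchors
RI = 100z; a query at retention time t_x strictly between consecutive
alkanes is interpolated as

    RI = 100z + 100 · (log t_x − log t_z) / (log t_{z+1} − log t_z)

(the classical logarithmic form, the package default) or with raw times in
place of logs (`mode="linear"`, the usual choice for temperature-programmed
runs; both are exposed because practice varies and the two differ by only a
few index units mid-bracket). No extrapolation: queries outside the ladder
span, or coinciding with an alkane's own retention time when the query is
not that alkane, are reported as unbracketed. A query equal to a ladder
alkane (the alkane itself) scores exactly 100z.

**Identification filter.** A peak is retained iff both the forward and the
reverse library match exceed 800 of 1000, strictly; missing scores reject
the peak with a logged reason. The retained set is order-invariant.

**Relative quantification.** With internal standard (3-nonanone) area S_t
and spiked concentration m_t, analyte area S_n and sample mass m_0 (kg),

    m_n = S_n · m_t / (S_t · m_0),

in 1e-9 kg L^-1 under the convention that 1 L of tomato homogenate weighs
about 1 kg. A zero internal-standard area invalidates the run (hard error).

**Calibration correction.** Each compound's calibration line y = a·x + b
maps true concentration x to measured relative concentration y (the axis
orientation that makes "correction" an inversion); the correction is
x = (y − b)/a. Because published intercepts can be negative, small signals
can invert below zero; these are floored at 0 and counted in the log.
Calibration fits use ordinary least squares (scipy's `linregress`) on ≥ 3
distinct levels; series with r² < 0.99 are flagged (every published curve
meets 0.99).

## Flavor metrics

**OAV.** OAV = concentration / olfactory threshold, dimensionless; OAV > 1
defines the odor-impact set. Compounds without a published threshold (nine
of the sixty) have an *undefined* OAV — excluded from every aggregate,
never counted as zero. The reporting form rounds half-up to an integer and
prints "<1" below one; this reproduces the published integer OAV column
for all 22 numeric rows of the shipped volatile table (machine-checked in
the test suite). The raw float is always retained internally.

**Odor categories.** Descriptor words map volatiles into six categories
(green, floral, fruity, vegetable, fatty, irritant). The map is shipped as
editable configuration, not ground truth, because no complete published
mapping exists; the default keyword table was built from the volatile
descriptors and extended (lilac, cinnamon, herbs, woody, metallic) so that
the five volatiles the source panel attributes to irritant odor all land in
the irritant bin. Category scores are *sums* of member OAVs (the published
per-accession totals, e.g. a maximum total OAV near 1,200, are consistent
only with summation); a volatile whose descriptors span categories
contributes its full OAV to each — the simplest defensible reading,
configurable by editing the keyword table.

**Taste metrics.** Sugar/acid ratio = (fructose + glucose)/(citric +
malic), reported to two decimals; descriptive summaries use the sample SD
(n − 1) and CV = SD/mean.

**Aggregates.** Functional-group and precursor-class summaries report the
member count and the sum of member mean concentrations. Two published
functional-group totals (ketones, phenols) do not reconcile with the sum
of the per-volatile means (gaps ≈ 122.4 and ≈ 101.5 × 1e-9 kg L^-1); the
package computes the direct sums and the discrepancies are asserted as
flagged in the tests rather than silently corrected. Per-volatile
metabolic-precursor labels are a curated chemistry-based assignment (31
lipid-derived, 18 carotenoid-derived, 8 phenylalanine-derived, 3
amino-acid-derived) because no per-compound table is published; precursor
aggregates therefore reproduce published group *structure* only
approximately and are not an acceptance surface.

## TOPSIS flavor ranking

Criteria are Z-score standardized (sample SD; zero-variance columns map to
zeros with a warning), weighted (uniform by default — no published weights
exist — and user-configurable), and given directions: sourness and
irritant odor are cost criteria, all others benefit. The ideal X+_j is the
column max (benefit) or min (cost), the anti-ideal X−_j the opposite, and

    S_i± = sqrt( Σ_j w_j² (R_ij − X_j±)² ),   C_i = S_i− / (S_i+ + S_i−).

C_i ∈ [0, 1] always, with C_i = 1 exactly at the ideal point. Direction
handling selects ideal/anti-ideal on the standardized matrix rather than
sign-flipping raw data (identical result, clearer audit trail). Published
per-accession closeness scores include negative values, which canonical
closeness cannot produce; the results object therefore also exposes a
Z-scored closeness for cross-run comparison, but numeric equality with
those published scores is not claimed — the raw sensory matrices behind
them are unpublished.

Three rankings are computed per panel: taste criteria only (sweetness,
sourness, sweetness/sourness ratio, characteristic flavor, overall
acceptability), odor categories only, and the concatenation. Class labels
I–IV come either from descending interval breaks or from fixed class sizes
(10, 20, 28, 13 reproduces the published partition cardinalities); ties
break by stable input order.

Degenerate input — all alternatives identical on every criterion — makes
closeness undefined and raises an error rather than returning a value.

## Association statistics

Pearson r with the two-sided t-test p and the two-level star convention
(\* p < 0.05, \*\* p < 0.01), per cell and uncorrected by default to match
the published table convention; Benjamini–Hochberg adjustment is available
(`adjust="bh"`). Zero-variance inputs leave cells undefined and unstarred.
One-way ANOVA across fruit types excludes groups with fewer than two
members (warning) and reports the zero-within-variance case as infinite F
with p = 0 instead of warning-and-NaN.

## Synthetic panel generator

The generator's defaults are the study conditions: 71 accessions
apportioned 8/11/15/37 over pink-cherry/red-cherry/pink-large/red-large
(largest-remainder apportionment of configurable proportions), 60
volatiles, 50 panelists, an 8-point hedonic scale, per-volatile
concentration CVs drawn uniformly from 0.3–2.5, calibration slopes from
0.02–5.0 (the span of the shipped reference curves, excluding zero so the
response is invertible), intercepts from ±0.5, thresholds log-uniform over
3.5–2e6 (the published threshold span), internal standard at 65.68 × 1e-9
kg L^-1 (10 µL of 3.284e-5 kg L^-1 3-nonanone in ~5 g homogenate).

Volatile concentrations are log-normal per compound (concentrations are
positive and span orders of magnitude), scaled by a shared per-accession
odor-richness factor (CV 0.3) to induce realistic covariance. Taste
chemistry centers on the panel means (fructose ≈ 1350·1.25^cherry mg
100 g^-1, glucose ≈ 0.62·fructose, citric ≈ 280, malic ≈ citric/1.77).
Latent sensory scores are affine in standardized drivers — sweetness is
planted on fructose + glucose (default effect 1.2 score units per SD),
sourness on total acid, characteristic flavor and overall acceptability on
a 0.6·sugar + 0.4·log-total-volatile latent — so correlation recovery is
testable. Panel scores add per-panelist Gaussian noise (default SD 0.8
score units; the source describes no panelist-noise distribution, so the
normal choice is a stand-in), average over panelists, clip to [0, 8], and
round to quarter points (the granularity of published panel scores). With
zero noise and one panelist the reported score is exactly the clipped,
quarter-rounded latent.

Peak areas are forward-simulated through the exact physics the
quantification stage inverts — S_n = (a·x + b)·S_t·m_0/m_t times
mean-one log-normal multiplicative noise (default CV 5%) — so the
zero-noise roundtrip is exact to floating point and the noisy roundtrip
error tracks the noise level. True concentrations are floored where needed
to keep a·x + b strictly positive (negative intercepts would otherwise
make tiny signals un-invertible). Two decoy peaks with sub-cutoff match
scores are planted per run to exercise the identification filter. One root
seed spawns independent per-stage substreams (library, concentrations,
taste, sensory, peaks), so each stage is reproducible in isolation.

What the simulator does **not** emulate: raw spectra, co-elution and peak
overlap, matrix effects on SPME partitioning, panelist bias/drift or
inter-panelist correlation, and missing volatiles (real panels detect some
phenols in a minority of accessions). Passing recovery tests therefore
show the pipeline's algebra and statistics are correct under the stated
generative assumptions, not that instrument- or panel-specific artifacts
are handled.

## Problem sizes and numerical choices

The test suite and acceptance checks run on the fixture tables (71 × 60)
and synthetic panels of 6–71 accessions and 6–20 volatiles — the full
published panel geometry where the check concerns it (type counts, class
partition, 1,000-query retention-index monotonicity), smaller panels where
only the algebra is at stake. TOPSIS is validated against an independently
coded brute-force evaluation on all matrix shapes up to 4 × 3 and all
direction combinations, to 1e-12. Retention-index bracketing requires
consecutive carbon numbers; gaps raise rather than interpolate across
missing alkanes. CSV outputs are UTF-8, comma-delimited, "." decimals,
with a provenance comment line (version, seed, config hash); thousands
separators and en-dash ranges from printed sources were normalized when
the fixtures were built.

## Known limitations

* Published per-accession closeness scores, correlation coefficients, and
  odor-category totals depend on unpublished supplementary matrices and
  are not reproduced numerically; the package reproduces every quantity
  computable from the printed tables and validates the rest by property.
* Whether published WAX retention indices used the log or linear form is
  indeterminate; both are provided.
* The descriptor→category map and precursor labels are curated
  configuration, not published ground truth.
* No posthoc structure beyond the one-way F-test; no odor-mixture
  psychophysics; no glycoside-bound volatile pool.
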