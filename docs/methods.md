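# Methods

`sulfomics` implements an untargeted, sulfate-focused metabolomics workflow
for distinguishing oral from intramuscular (IM) administration of the
progestin altrenogest in horses, working from negative-mode LC-HRMS/MS data:
an aligned feature × sample peak-area table plus DDA product-ion spectra.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Diagnostic-ion model and exact masses

Steroid sulfate esters fragment predictably in negative mode. Six diagnostic
signals are screened per spectrum: the product ions SO3⁻• (79.9574), HSO3⁻
(80.9652), SO4⁻• (95.9523) and HSO4⁻ (96.9601), and the neutral losses SO3
(79.9568 Da) and H2SO4 (97.9674 Da) computed as precursor-minus-fragment
differences. All values derive at run time from embedded NIST/CODATA
monoisotopic masses (C 12 exactly, H 1.0078250319, O 15.9949146,
S 31.9720707, e⁻ 5.4858×10⁻⁴), with anion m/z electron-inclusive — the
convention that reproduces the reference values for HSO3⁻, HSO4⁻ and SO4⁻• at
4 decimal places. SO3⁻• computes to 79.95736, which rounds to 79.9574;
screening listings sometimes print 79.9573, so equality for this one ion is
asserted within 0.0002 Da rather than at 4 d.p.

Two summary parameters per spectrum:

- **IR** = Σ(intensity of distinct peaks matched to any diagnostic) /
  Σ(all peak intensities) ∈ [0, 1]. A physical peak satisfying several
  diagnostics (possible at particular precursor masses) is counted once;
  whether the original scripts counted once or per-diagnostic is not
  documented, and distinct-peak counting was chosen because IR is then a
  true intensity fraction bounded by 1.
- **MA** = 100 × (largest diagnostic-matched intensity) / (base-peak
  intensity) ∈ [0, 100].

Fragment matching uses an absolute ±0.005 Da window by default
(`--frag-tol-da`). An absolute window was chosen because the diagnostics sit
at low m/z where a ppm window would be sub-millidalton and unrealistically
tight for QTOF product-ion spectra. Spectrum-to-feature alignment uses
±3 s RT and ±5 ppm precursor tolerance; among candidates the smallest
|Δppm| wins, ties broken by smaller |ΔRT| then lexicographic feature ID
(determinism); when several spectra map to one feature, the spectrum with
the largest base peak — a precursor-intensity proxy — is kept.

## Sulfate classification

Each feature contributes eight parameters (six diagnostic-channel
intensities, IR, MA), z-scored column-wise (constant columns left at 0;
whether the original analysis standardized the raw channels is unstated,
and z-scoring keeps the heterogeneous units commensurate). Features without
any MS/MS spectrum enter as all-zero rows rather than being dropped, so
downstream feature counts remain well-defined. Lloyd's k-means with k = 2,
10 random restarts and a fixed seed (default 1) partitions the features;
the cluster whose centroid has the larger mean of the standardized IR and
MA columns is labelled *sulfated* (cluster 1). The labelling depends only
on the centroids, so it is invariant to cluster relabelling, and under
fixed centroids raising a feature's IR and MA can never flip it from
sulfated to non-sulfated.

## QC-anchored normalization

Pooled-QC samples (aliquots of every sample of one designated horse)
injected at the start and after every 10 study injections anchor the drift
model. Per feature, a LOWESS curve (span 0.5, 2 robustifying iterations —
the upstream alignment software does not publish its parameters, so these
are this package's defaults) of QC area versus injection order is
interpolated to every injection position; each value is divided by the
curve and rescaled by the feature's raw QC median, so a drift-free feature
passes through unchanged to machine precision. Features with fewer than 4
positive QC values, or whose fitted curve touches zero, pass through
unchanged and are flagged in the normalization report (QC CV before/after
per feature).

Missing cells are imputed as 20% of the feature's minimum observed positive
area (the MetaboAnalyst default rule). Fill%-style presence filtering and
optional S/N / MS2-presence filters run before normalization; the original
cut-offs were manual and unpublished, so the defaults here are permissive
and configurable. PCA for QC assessment operates on log10(x+1),
feature-centered, with a deterministic sign convention (largest-magnitude
loading positive per component).

## Moderated differential analysis

Per feature, a two-group linear model on log2 areas contrasts
post-administration samples against the 0 h baseline of the same horse
(pooled residual variance, df = n1 + n2 − 2). Residual variances are shrunk
by empirical Bayes: (d0, s0²) estimated by matching the mean and variance of
log s² to the scaled-F implied moments via digamma/trigamma inversion
(Newton iteration for the trigamma inverse); posterior
s̃² = (d0·s0² + df·s²)/(d0 + df); moderated t on d0 + df degrees of freedom
(normal limit when d0 = ∞; when the log-variance spread does not exceed the
χ² sampling spread the prior is taken as infinite with s0² the arithmetic
mean of the variances). p-values are Benjamini–Hochberg adjusted — the
adjustment method used originally is unnamed, and BH is the standard default
for this analysis type.

Volcano tiers: *non-significant* if −log10(adj p) < 1; otherwise
*mid-significant* when |log2FC| < 3 and *significant* when |log2FC| ≥ 3
(fold change beyond ±8). Both boundaries count as passing, and the
significant tier requires the p criterion as well as the fold-change one
(plot descriptions sometimes mention only the fold change for the top tier,
but the geometry implies both). Class counts on any particular dataset are
data-specific and are not treated as reference values.

A caveat stated openly: technical triplicates share one biological draw,
so replicate-level baseline-vs-post contrasts are pseudo-replicated and
their p-values optimistic — in the original workflow as much as here. The
generator's calibration check therefore uses singleton replicates, where
every sample is an independent biological draw and the test is properly
calibrated.

## Steroid-sulfate searcher

Sulfate-labelled features are compared against a 26-entry theoretical list
at ±5 ppm (inclusive; "within ±5 ppm" is read inclusively). Each entry's
deprotonated m/z is computed from its formula, never stored. Only the five
confirmed compounds of the screening list are public — estrone sulfate
C18H22O5S, testosterone sulfate C19H28O5S, 2-methoxyestradiol sulfate
C19H26O6S, pregnenolone sulfate C21H32O5S, cortisol sulfate C21H30O8S — so
the remaining 21 entries are documented placeholder steroid sulfates
(common endogenous and doping-relevant conjugates); the default list is a
synthetic stand-in, not a reconstruction. All qualifying (feature,
compound) pairs are reported, sorted by |Δppm|; multiplicity is expected
and left to manual review. The consistency filter keeps compounds hit in at
least `min_datasets` of several per-horse batches.

## Biomarker evaluation

IM is the positive class, oral the negative class. Univariate: rank-based
AUC (Mann–Whitney U / n1·n2, ties half, oriented ≥ 0.5 with the direction
recorded), Welch t on log2 areas, log2FC of class means, and co-behaviour
clusters from average-linkage hierarchical clustering of 1 − |Spearman ρ|
(the clustering behind the original report's cluster column is unspecified;
|ρ| makes anti-correlated features co-cluster, which is the behaviour a
ratio-biomarker reviewer wants).

Multivariate: Monte-Carlo cross-validation with 30 stratified 2/3–1/3
splits, a 300-tree random forest per split (no scaling or transformation),
holdout class probabilities pooled into a single ROC whose trapezoidal area
is the headline AUC, and a 95% band from the 2.5/97.5 percentiles of
per-run holdout AUCs (the aggregation behind the original interval is
undocumented; a percentile band over runs is the natural MCCV analogue).
Importances are permutation importances (mean decrease in accuracy) on the
holdout. The confusion matrix takes each sample's majority vote over the
runs in which it was held out; a vote fraction of exactly 0.5 — or the
vanishingly rare sample never held out — counts as positive, a documented
deterministic tie-break. Sensitivity/specificity/accuracy are exact
percentages, rounded only for display.

## Synthetic study generator

The generator emulates the administration study the analysis assumes and is
the test bed for every stage. Defaults mirror the reported dataset shape:
two horses (one per route), 21 days of daily 8 am collections (0–504 h)
plus frequent-sampling days (+2/+4/+6/+8/+12 h) at day 0 for both routes
and at the final administration (day 14 oral, day 7 IM) — 32 time points —
with the oral horse's 480 h collection lost; technical triplicates give
(30 + 31) × 3 = 183 post-administration data points. Pooled QCs are
injected first and after every 10 study injections; two external controls
(baseline-like samples from unrelated horses) close the sequence.

Peak areas are log-normal (positivity guaranteed): one biological draw per
(feature, horse, time point) shared by the triplicates, technical noise per
replicate. Markers carry the observed between-route log2 effects
(2-methoxyestradiol sulfate +1.15, testosterone sulfate −0.936, estrone
sulfate −3.35, cortisol sulfate +0.109, pregnenolone sulfate −3.05, IM
minus oral) applied to IM post-administration samples, plus a
post-vs-baseline response shared by both routes (0.5–2 log2 units; this
extra field exists so the baseline-vs-post volcano stage has planted
signal while the group contrast stays exactly the planted effect).
Abundance distributions and CVs are not reported anywhere, so the defaults
are declared, not inferred: biological CV 0.6 and technical CV 0.1 for
markers (0.4/0.1 for background), base abundances log-uniform over
10⁴–10⁶ area units. A linear 0.8→1.2 sensitivity drift multiplies all
areas over the injection sequence — strong enough to confound a naive
group contrast between the two horses (they occupy different injection
blocks), and exactly what the LOWESS stage removes. Background features
(default 300, 20% sulfated, 20% carrying random N(0, 2) post responses,
2% missingness on study samples) populate the null and the volcano tiers.

Spectra: one per feature from its highest-area sample, diagnostic peaks
drawn Poisson around template counts, five decoy fragments uniform over
m/z 100–400 kept ≥ 0.05 Da from every diagnostic position (including the
feature's own neutral-loss positions), and background precursor m/z kept
≥ 0.06 Da from every searcher list entry — so no decoy can produce a
spurious diagnostic match or searcher hit, by construction. Marker
precursor m/z get a ±2 ppm observational error.

What the generator does **not** emulate: pharmacokinetic decay of the
response over time (the post response is a constant shift),
concentration-dependent missingness, RT drift, chimeric spectra, isotope
clusters, and realistic biological covariance between markers. Separation
between routes under the defaults is consequently much cleaner than on
real horses: the MCCV AUC here saturates near 1.0, whereas the real-data
figure (0.965 with a 0.931–0.995 band) reflects biology the simulation
does not model. Passing tests show the machinery is correct, not that the
markers would perform equally well in new animals.

## Problem sizes and numerical choices

Default synthetic runs use 305 features × 210 injections; tests use the
same study once (session fixture) plus smaller designs for replicated
calibration checks (50 replicate studies with markers only; 20 null
studies with 60 features and singleton replicates). The determinism check
runs the full pipeline twice at 60 background features, 10 MCCV runs, 100
trees, and compares outputs byte-for-byte. Plot files (volcano, MA-vs-IR,
ROC) are opt-in (`--plots`) because PNG encoding is not byte-stable across
matplotlib backends; the determinism guarantee covers all data outputs and
the manifest.

Other numerical conventions: k-means restarts 10 (seed 1); BH ties
preserved by stable sorting; trigamma inversion iterated to 1e-10 relative
change; zero-variance features get t = 0, p = 1 when the fold change is
also zero (±∞ otherwise, logged); constant features in univariate
statistics report AUC 0.5, p = 1 and are logged.
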