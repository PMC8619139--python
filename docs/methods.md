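# Methods

photonet re-implements, at desk scale, the analytical strategy used to spot
photosensitizer (PS) compound families in complex natural extracts: combine
feature-based molecular networking (FBMN) of LC-MS² data with two
photochemistry-aware overlays — a light-absorption flag and per-feature
extract specificity — and with extract-level photoactivity measurements, then
rank network clusters by how strongly they co-locate all lines of evidence.
This note documents the models, the numerical choices, and what the
synthetic study does and does not establish.

## Molecular networking

**Modified cosine.** Two MS² spectra are compared by cosine similarity in
which a fragment pair (i, j) may match either directly
(|mzᵢ − mzⱼ| ≤ τ, default τ = 0.02 Th) or offset by the precursor mass
difference Δ = M_b − M_a (|mzᵢ − (mzⱼ − Δ)| ≤ τ). Intensities are square-root
scaled (the GNPS convention; damps dominance of base peaks), candidate pair
weight is √Iᵢ·√Iⱼ, and the score is the *maximum-weight one-to-one
assignment* over candidates, normalized by the product of the Euclidean
norms of the √-scaled intensity vectors — hence bounded by 1 and symmetric.

The assignment is solved exactly as a rectangular linear-sum-assignment
problem restricted to candidate cells rather than greedily. Greedy
resolution is suboptimal precisely when one fragment holds both a direct and
a shifted candidate — the analog-pair situation the modified cosine exists
for. The exact optimum is verified in the test suite against brute-force
enumeration on small spectra and cross-checked against an independent
implementation (matchms, fed √-scaled intensities; being greedy, it can only
score lower or equal).

**Graph construction.** Edges with score ≥ 0.7 and ≥ 6 matched peaks are
kept, then pruned to the mutual top-10 of both endpoints; any connected
component larger than 100 nodes repeatedly sheds its lowest-scoring edge
(ties broken lexicographically by endpoint ids, components recomputed after
each removal). Edge-less features are singletons. These are GNPS-convention
defaults — the original study's job parameters are not published — and all
are overridable per run. Spectrum↔feature identity is by feature-id string
match (the MZmine FBMN convention tying SCANS to quant-table row ids);
unmatched spectra are logged and excluded.

## Photoactivity overlays

**Specificity.** For feature f and extract e, share(f,e) = area(f,e) /
Σₑ′ area(f,e′). Reporting levels are the conventional >60% (major
occurrence), >95% (virtual) and >99% (complete specificity), all strict
inequalities. All-zero features are flagged degenerate and never counted.

**VIS-Signal.** A feature is VIS-positive if a DAD trace at the configured
visible wavelength (default 468 nm) shows a peak at the feature's retention
time. Evidence: within ±0.1 min of the RT, peak height = window maximum
minus the local baseline (median of the surrounding ±0.5 min excluding the
window); noise = 1.4826 × MAD of the same baseline region; SNR = height /
noise; flag = 1 iff the best SNR across extracts ≥ 3 (the conventional
detection limit). The flag is scale-free, deterministic, and by design
conservative for low-abundance chromophores — matching the observed behavior
that trace-level pigments are not flagged.

A caveat worth stating: with hundreds of feature×extract windows, a 3σ
threshold against a *white-noise* baseline would produce occasional false
positives purely from the maximum statistic. The criterion behaves well
on real DAD data because baselines are drift-dominated — the local MAD then
reflects drift amplitude, against which window maxima of non-peaks are small.
The synthetic generator reproduces exactly this regime (below).

## Extract-level assays

**DMA singlet-oxygen assay.** ¹O₂ formation is quantified indirectly by the
photobleaching of 9,10-dimethylanthracene absorbance at 377 nm. The
bleaching rate k is the negative least-squares slope of A377 versus
cumulative irradiation time (blank-drift corrected when a blank well is
given); the relative yield is 100 × k_sample / k_control with berberine as
the blue-light control and rose bengal as the green-light control. Yields
above 100% mean the extract outbleaches its reference. The statistic is a
pluggable strategy (`dma_relative_yield(..., strategy=...)`); the slope
ratio is the package's definition of the assay's comparative semantics.
The linear slope slightly underestimates k for strongly bleaching wells
(first-order decay), biasing the strongest yields a few percent low; the
ratio form removes most of the common part of that bias. Radiant exposure
is irradiance × time (1.24 J cm⁻² min⁻¹ blue, 1.34 green; e.g. 7.5 min blue
→ 9.3 J cm⁻²).

The ascorbate co-incubation wells are summarized as a quench fraction
1 − k(DMA+AA)/k(DMA), clipped to [0,1]. Its mechanistic reading (Type I
contribution) is not settled; it is reported as a diagnostic only.

**Dose-response.** Viability follows the four-parameter logistic
v(c) = bottom + (top − bottom)/(1 + (c/EC50)^h), fitted by bounded nonlinear
least squares in log(EC50) (the GraphPad "relative Hill slope" convention),
initialized at top = 100, bottom = 0, h = 1, EC50 at the geometric mid-dose,
with three alternative restarts. The 95% CI is Wald on the log scale with a
t quantile at n − 4 degrees of freedom — with a six-dose ladder the normal
quantile undercovers noticeably, the t choice restores ~95% empirical
coverage (verified by simulation). If the fitted curve never reaches 50%
viability within (0, c_max] (c_max = 37.5 µg/mL, the top tested dose), the
EC50 is right-censored at c_max. With the standard ladder
(0.375–37.5 µg/mL) and 5% viability noise the estimator is median-unbiased
to within a few percent, but single-fit scatter is large (median absolute
deviation ≈ 15–25% even with replicates) — an information floor of fitting
four parameters to six doses, mirrored by the wide CIs such assays report.

**Selectivity and bands.** S.I. = EC50(dark) / EC50(irradiated); when the
dark arm is censored the index is a lower bound ("≥"), e.g. censored dark
37.5 over irradiated 0.8 → ≥ 46.9. Activity bands for irradiated EC50s:
> 20 µg/mL no/low, 5–20 µg/mL high (both boundaries inclusive — the verbal
rule leaves them ambiguous), < 5 µg/mL very high.

## Annotation

Library matching reuses the modified cosine, so derivatized analogs
(±14.0157 methylation, +15.9949 oxidation, +162.0528 glycosylation, +33.9610
H→Cl) hit their parent through shifted fragments. A marker entry (authentic
standard) whose precursor matches within tolerance yields identification
level 1; other spectral matches are level 2. Taxonomically informed
re-ranking adds a configurable boost per matching rank (defaults 0.05
family, 0.10 genus, 0.20 species on the [0,1] cosine) — a deliberately
simple, testable stand-in for published weighting schemes. Marker identities
propagate to every member of their cluster (no score change). In-silico
candidate lists are consumed as pre-scored tables, never computed.

## Prioritization

An extract is *active* iff any DMA yield ≥ 5% (the floor below which
formation is negligible) or any irradiated EC50 band is high / very high.
Cluster priority = number of member features that are simultaneously
VIS-positive and specific (share > level, default 0.99) to an active
extract — a numeric codification of the visual rule (node color =
specificity to an active extract, node size = VIS flag). Ranking is by
priority, ties by VIS-positive count then cluster id; priority-0 clusters
are unranked. Candidate features are the same conjunction, listed per
extract.

## Synthetic data: what it emulates, and what it does not

The generator emits a full input bundle (MGF, quant table, DAD traces, DMA
kinetics, dose-response tables, spectral library) with ground truth,
deterministically per seed:

* **Families.** 10 compound families (4–6 analogs) share a random fragment
  scaffold (8–15 peaks, log-normal intensities); each analog shifts the
  precursor and a fixed "mobile" scaffold subset by one derivatization
  delta, so within-family modified cosines stay ≥ 0.7 while independent
  scaffold draws keep between-family scores < 0.5.
* **Specificity plan.** The two pigment families plus standalone chromophore
  features are made completely specific (share drawn in 0.992–0.998) to the
  two active extracts: 9 for the *Dermocybe*-like and 52 for the
  *Phlegmacium*-like extract, the study-scale counts. Inactive extracts
  carry a few specific non-chromophore features; everything else draws
  Dirichlet shares capped below 0.99.
* **DAD traces.** Chromophores add a Gaussian peak (σ = 0.05 min) at their
  RT in their majority extract, amplitude 15–40× the baseline scale. The
  baseline is slow wander (three sinusoids, periods 1.2–8 min, marginal sd
  0.2 mAU) over a white floor at sd/100 — the drift-dominated regime of real
  detectors. Chromophore RTs sit on a 0.6-min grid with all other features
  at midpoints, i.e. the pigments are chromatographically resolved.
* **Assays.** DMA wells decay exponentially at control rate 0.006 min⁻¹
  scaled by the planted relative yield (study-scale values: 183.5% / 123.2%
  blue, ~10–11% green, < 2.5% for inactive extracts), OD noise 0.0005,
  technical duplicates; the ascorbate wells decay at 70% of the plain rate
  for active extracts. Viabilities follow the Hill model (h = 1.2, 5%
  noise, triplicates) at planted EC50s taken from the published green-light
  values for the strongly active extract; dark arms are censored-by-design
  (true EC50 75 µg/mL > 37.5).

**Limitations.** Passing the ground-truth tests shows the pipeline recovers
planted structure under these (favorable, realistic-but-clean) conditions;
it does not show robustness to what the generator deliberately omits:
co-eluting pigments (a non-chromophore eluting under a pigment's DAD peak
would be falsely flagged — the generator separates them), shared scaffolds
*across* families, adduct/isotope redundancy, missing MS² spectra,
retention-time misalignment between runs, and matrix effects in the assays.
Dataset-scale statistics (thousands of nodes) are likewise not reproduced —
the default bundle has ~130 features so the full suite runs in seconds.

## Reproducibility

All randomness flows through a single integer seed
(`numpy.random.default_rng`); identical seed and configuration give
byte-identical bundles and run summaries (no timestamps in any artifact).
The pipeline records a hash of its analysis parameters (I/O paths excluded)
in the run summary.
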