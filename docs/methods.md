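# Methods

This note records the models, conventions and numerical choices behind
`tsimquant`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Mass arithmetic

All masses come from one pinned table (`tsimquant/data/isotopes.tsv`,
IUPAC-CIAAW isotopic compositions with AME atomic masses; version string
`IUPAC-CIAAW-2013/AME2016` is exposed as `masses.MASS_TABLE_VERSION` and
recorded in CLI run logs). Monoisotopic mass is the sum of
most-abundant-isotope masses. The deprotonated m/z is computed as
*neutral mass − proton mass*, i.e. the electron stays with the anion. At a
5 ppm gate on a 129 Da ion the electron's 0.55 mDa is material, which is
why the convention is fixed here rather than left to rounding. The
hydrogen-atom binding energy (~1.5 × 10⁻⁸ Da) is below every tolerance
used and is ignored.

The eight panel precursor values recorded in the fingerprint table
(`tsimquant/data/panel.tsv`) are the published 3–4-decimal catalog values;
all agree with the computed exact masses within 5 ppm. Two entries of the
original inclusion-list catalog (FdUMP 325.0211, FdURD 245.0605) disagree
with both the exact masses and that catalog's own scan-filter centers by
~10 ppm and are treated as typographical; they are retained in the
`catalog_mz` column for provenance. One further inconsistency is inherent
to the source data: the published 5-FU scan filter (127.0090–131.0090) is
centered 1–2 mDa below every defensible precursor value, so window
reconstruction is exact to 3 decimals for seven of eight compounds and to
2 mDa for 5-FU.

**Extraction centering.** SIM windows and inclusion lists use the catalog
precursor values (they are the instrument-facing numbers). XIC extraction
in the detection/quantification pipeline centers its 5 ppm window on the
*computed* exact m/z: measured ions sit at the physical mass, and a window
centered on a 4-decimal rounding of it (up to 4.5 ppm off for 5-FU) would
clip its own analyte.

## Isotope envelopes

Per-element isotope distributions are convolved as sparse vectors keyed by
nucleon count, pruning terms below 10⁻¹² absolute probability; peaks
sharing a nucleon count merge into one centroid at their
abundance-weighted mean mass — what a centroided Orbitrap scan shows at
the resolutions involved (isotope fine structure is out of scope). The
`[M-H]-` adduct removes one hydrogen before convolving and adds the
electron mass. Truncation (default 10⁻³ of the base peak) drops
low-abundance peaks smallest-first while the total probability removed
stays below the threshold, so retained abundances always sum to within the
threshold of 1. Tests pin the engine peak-wise (≤ 10⁻⁶) to an exhaustive
isotopologue-enumeration oracle on small formulas.

## Fragment explanation

A fragment is explained when some elemental sub-multiset of the
deprotonated precursor composition has anion m/z (monoisotopic mass +
electron) within tolerance (default 10 ppm, accommodating 3–4-decimal
published fragment values) of the observation. The search is a
depth-first walk over per-element counts with mass-remaining pruning,
exhaustive within the window; candidates sort by |ppm deviation|, then
fewest heteroatoms, then formula string. The published validation tool for
this step scores fragmentation trees with proprietary formulas; the 0–100
scores reported here (fraction of fragments explained; isotope-envelope L1
agreement) are this package's own analogues, keeping the semantics (higher
is better, 5 ppm median-deviation gate) without claiming numerical
equivalence — they are labelled as such in output.

## Peak detection and integration

XICs take one point per qualifying scan (SIM scans whose isolation window
cannot see the requested m/z window are skipped, not zero-filled; MS2
extraction is precursor-filtered at 5 ppm). The noise floor is
1.4826 × MAD of the lowest intensity quartile — robust and parameter-free.
Apexes are local maxima above `min_snr` (default 3) times the floor;
bounds walk from the apex to the nearest valley or baseline return;
peaks spanning fewer than 3 samples are discarded. Integration is
trapezoidal after subtracting a straight baseline between the bound
endpoints, floored at zero. When several candidate peaks exist the one
nearest the expected RT is taken (largest area if no RT is known). The
boundary rule is deliberately simple and artifact-defined: the workflow
being automated delegated peak picking to interactive software whose
algorithm is not published. Fragment evidence integrates each fragment's
MS2 XIC over the *precursor's* bounds (shared bounds make the combined
"total area" well defined) and requires the fragment apex within `rt_tol`
(default 0.1 min — the source states co-elution without a number) of the
precursor apex.

## Detection rule

Detected ⇔ precursor peak found ∧ ≥ `min_fragments` (default 1)
fingerprint fragments co-elute ∧ no control veto. The veto fires when the
paired untreated control's XIC area over the same window and RT bounds
exceeds `veto_fraction` (default 0.1) of the treated area — a hard zero
would be untestable under noise. The veto applies only to drug-derived
compounds: the endogenous nucleotides dUMP and TMP are present in every
sample by nature (the emulated study reports them in treated and untreated
alike), so vetoing them against a control would eliminate every true
detection; the panel carries an `endogenous` flag for this.

## Calibration and group statistics

Calibration is ordinary least squares of area on concentration (≥ 3
distinct positive levels). LOD = 3 × SD and LOQ = 10 × SD with SD the
residual standard deviation of the fit divided by the slope — the source
defines the limits as 3×/10× an unnamed SD; the residual-based convention
is the default and a blank-based SD is accepted as an option. LOQ/LOD is
10/3 identically. Normalization divides every area by the 0.780 ng/µL
FdUMP reference area of the sample's replicate batch, making ratios
invariant to batch-wide response drift. Group comparison is a two-sided
two-sample t-test, equal-variance by default (Welch by flag), on the
normalized ratios of treated test samples; sem = sd/√n. Two degenerate
identical groups give t = 0, p = 1. Non-detects are excluded and counted,
never imputed as zero. No multiple-testing correction is applied by
default (six compounds × two matrices); Benjamini–Hochberg is available by
flag.

## The simulator: what it emulates and what it does not

Chromatographic peaks are Gaussian (closed-form area A·σ·√(2π) gives exact
oracles); elution order and RTs follow the panel (FdUMP/dUMP 1.4, TMP 1.5,
5-FU 1.6, FURD 1.9, FdURD 2.1 min), width σ = 0.03 min, RT jitter SD 0.01
min per run. The acquisition schedules one SIM scan per panel window per
0.015 min cycle over 0.8–2.6 min and fires an MS2 scan (≤ 4 per cycle,
mirroring the loop count) whenever the target's monoisotopic intensity
exceeds an absolute threshold (10⁴ counts) — the source gives instrument
settings, not trigger logic. Centroid m/z error is Gaussian with SD 1 ppm
(inside the instrument's <2 ppm claim); the `response_factor`
(2 × 10⁵ area per ng/µL) is defined on the monoisotopic trace; heavier
isotopologues ride on top at natural abundance, and the manifest's
`true_total_area` counts only envelope peaks inside the SIM window (the
FdUMP M+2 falls 5 mDa outside its ±2 window and is physically never
acquired). Matrix background adds near-isobaric Gaussian interferents
inside the SIM windows but outside the 5 ppm extraction windows, plus
additive chemical noise (Poisson-many exponential centroids per scan and
|N(0, noise)| on real centroids). Biological scatter is mean-preserving
log-normal with CV 20% — positive concentrations and exact configured
fold changes of expectations; the source reports "minor differences"
between replicates without a distribution, so the CV is an exposed
parameter, not an asserted value.

The default study design carries ten biological replicates per group,
treated and untreated, lysate and media; the resistant group has
FdUMP/FURD (and FdURD in media) at 0.4× parental; FdURD is absent from
lysate; FUTP/FdUTP are at concentration zero everywhere, reproducing the
below-detection outcome; calibrants run the two-fold series 100…0.195
ng/µL and each replicate batch carries one 0.780 ng/µL FdUMP QC injection.

Not emulated: retention modelling of the F5 column chemistry, ion
suppression/matrix-effect kinetics, profile peak shapes, co-eluting
isomers, saturation, and cross-run RT drift. Passing tests therefore
demonstrate the correctness of the *computation* — mass math, windowing,
integration, decision logic, statistics — under a faithful but idealized
signal model, not robustness to every pathology of real chromatography.

## Problem sizes and seeds

Tests and the acceptance suite use scaled designs chosen as the package's
own test sizes: detection logic runs 50 seeded one-replicate studies (9
runs each); fold-change recovery averages 8 seeded studies at the full
n = 10 on a five-compound sub-panel; the t-test's type-I error is measured
on 1000 draws from the biological-scatter model directly. All randomness
flows through explicit integer seeds (`numpy.random.default_rng`); a run
is bit-identical under the same seed.

## I/O formats

The lossless interchange of desk-scale work is a line-delimited JSON run
format (one header record, one record per spectrum, RT in minutes). mzML
is supported both ways by a compact serializer/parser for centroided data
(64-bit float arrays uncompressed on write; 32/64-bit and zlib accepted on
read; scan start time accepted in minutes or seconds; SIM windows carried
in scan-window metadata, MS2 precursors in selected-ion metadata). Output
mzML is verified in the test suite against an independent reader from
another ecosystem. Profile-mode spectra are rejected: the pipeline
consumes centroided peak lists only. The sample sheet is a CSV with
columns `sample_id, group, treatment, matrix, replicate, role,
calibrant_concentration`; calibrant rows must carry a concentration and
each test sample is normalized against the QC run sharing its replicate
number.
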