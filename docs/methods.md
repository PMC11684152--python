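# Methods

## Data model

A dataset pairs a **peak table** (intensities; rows = mass identifiers,
columns = samples) with a **molecular identification table** (one record per
mass: formula string and/or element counts C, H, N, O, S, P, an optional
isotope annotation, and any calculated-property columns).  The two tables
must carry the same set of unique mass identifiers, read as strings to avoid
floating-point key drift.  Any peak with a recorded formula must have
C ≥ 1 and H ≥ 1.

Missingness is two-level.  Input files encode "not observed" with a raw
code (typically 0); `encode_missing` replaces that code with NaN, a
dedicated not-a-value sentinel, so intensities and presence/absence can
never be conflated.  The raw code is kept as metadata and restored on
export, which makes the write→read round trip lossless (the CSV reader uses
round-trip float parsing for the same reason).  Every mutating operation
appends a provenance record (step name, parameters, peak/sample counts
before and after); the provenance log is append-only and feeds the HTML
report.

Scales: `abundance`, `log2`, `log10`, `ln`, `presence_absence`.  Log
transforms are only allowed from raw abundance (no double-log) and reject
non-positive observed values with a pointer to the missing-value code,
since a zero that should have been declared missing is the usual culprit.

## CoreMS-style ingest

Per-sample long-format files carry candidate formulas per calibrated m/z
with a confidence score (assumed in [0, 1]; out-of-range scores are
rejected), peak height, mass error (ppm) and isotope annotation.  Column
names are auto-detected against a synonym list; a user-supplied map always
wins.  `confidence_profile` tabulates retained records and mean/max |mass
error| over a threshold grid — the trade-off used to pick a cut-off.
`resolve_formulas` keeps one candidate per (sample, m/z), maximizing either
confidence or peak height, with a deterministic tie-break: smaller |mass
error| first, then lexicographically smallest formula.  Pivoting merges
peaks across samples **by resolved formula string** (isotope-annotated
formulas are distinct peaks); the mean calibrated m/z becomes the peak
mass.  Same-formula peaks within one sample — rare after calibration — are
merged by summing their heights.  m/z-bin matching across samples is
deliberately out of scope.

## Chemical properties

All properties are NaN whenever the peak lacks a formula or a denominator
is degenerate.

- **Elemental ratios**: O:C, H:C, N:C, P:C; N:P only when P ≥ 1.
- **Kendrick**: KM = mass · 14/14.01565 (CH₂ base only).  The defect
  convention is KMD = ⌈KM⌉ − KM, giving KMD ∈ [0, 1); the nearest-integer
  alternative is available behind `defect="round"`.  Members of a CH₂
  homologous series share KMD to well below 1e-9.
- **NOSC** = 4 − (4C + H − 3N − 2O − 2S + 5P)/C, the nominal oxidation
  state of carbon (−4 for methane, +4 for CO₂, 0 for glucose).
- **ΔG°Cox** = 60.3 − 28.5·NOSC, kJ per mol C: the linear relation between
  the standard-state Gibbs energy of the carbon-oxidation half reaction and
  NOSC.  The affinity is exact by construction, and the tests assert it
  column-wide.
- **DBE** = 1 + ½(2C − H + N + P).
- **AI** = (1 + C − O − S − 0.5H)/(C − O − S − N − P), clamped to 0 when
  the denominator is non-positive or the value is negative (the usual
  convention; `clamp=False` emits NaN instead).  AI_mod replaces O with
  0.5·O in both numerator and denominator.
- **Elemental-composition class**: symbols with non-zero counts
  concatenated in fixed C,H,N,O,S,P order ("CHO", "CHNOS", …).
- **Compound class**: position of (O:C, H:C) against a boundary table of
  axis-aligned rectangles, each half-open (min-inclusive, max-exclusive) so
  shared edges resolve deterministically.  All containing classes are
  reported, ";"-joined in precedence order; outside every rectangle the
  label is "Other".  The default table (shipped as an editable CSV)
  follows the common van Krevelen literature conventions: Lipid
  [0,0.3)×[1.5,2.5); Unsaturated hydrocarbon [0,0.125)×[0.8,1.5); Protein
  [0.3,0.55)×[1.5,2.3); Amino sugar [0.55,0.7)×[1.5,2.2); Carbohydrate
  [0.7,1.5)×[1.5,2.5); Lignin [0.125,0.65)×[0.8,1.5); Tannin
  [0.65,1.1)×[0.8,1.5); Condensed hydrocarbon [0,0.95)×[0.2,0.8).  Users
  needing a different convention load their own CSV.

## Filtering

Filters are set intersections over peaks (the sample-name filter acts on
columns instead), applied sequentially.  The final peak set is therefore
invariant under filter reordering; only the per-step retention counts
depend on order, and those counts are the data behind the filter bar
chart.  The per-group minimum-observation rule keeps a peak if **any**
group meets the minimum — the permissive reading, which retains peaks that
are well observed in one group but absent in the other (exactly the peaks
the uniqueness tests are about).  Custom filters accept an inclusive
numeric range or a categorical keep-set on any molecular or calculated
column.  An empty dataset after any step is an error naming the filter.
`reset_filters` restores the pre-chain dataset but never undoes
preprocessing columns or missing encoding.

## Two-group uniqueness

Both methods work on presence/absence per group, with group proportions
p_g = (samples observing the peak)/(group size).

**Thresholds.**  Unique to group 1 iff p₁ ≥ presence threshold and
p₂ ≤ absence threshold (symmetrically for group 2); observed-in-both iff
both p ≥ presence threshold; otherwise insufficient.  Defaults — presence
0.5, absence 0 — are deliberately strict: seen in at least half of one
group and never in the other.

**G-test.**  Per peak, the 2×2 table of (observed, missing) sample counts
per group gives G = 2 Σ O·ln(O/E) with expected counts from the margins;
zero cells contribute 0 (the x·ln x → 0 limit).  The Williams small-sample
factor q = 1 + [(n/r₁ + n/r₂ − 1)(n/c₁ + n/c₂ − 1)]/(6n) divides G, and
G/q is referred to χ² with 1 df.  Degenerate margins (peak observed in no
or every sample) give G = 0, p = 1.  Groups must have ≥ 3 samples each.
A peak is unique to the better-observed group when p ≤ α and that group's
proportion also clears the presence threshold; observed-in-both when
p > α and both proportions are positive; otherwise insufficient.  No
multiple-testing correction is applied by default; a Benjamini–Hochberg
adjusted-p column is available behind a flag (labels still use raw
p-values).

At 10 samples per group the Williams-corrected test is mildly
conservative: its exact size at α = 0.05, computable by enumerating the
11×11 table of per-group counts with binomial weights, is ≈ 0.043 rather
than 0.050.  The calibration check therefore estimates the rejection rate
by averaging many independent replicates of the null condition, so the
estimate reflects this true size rather than single-draw Monte-Carlo
noise.  Power at well-separated presence probabilities (0.9 vs 0.1,
10/group) is ≈ 0.99.

## Ordination and plot tables

Distances: euclidean, Manhattan, Bray–Curtis (missing treated as zero
abundance), and Jaccard on presence/absence, via scipy.  PCoA is classical
scaling: B = −½·J·D²·J, eigendecomposition, coordinates √λᵢ·vᵢ.  Negative
eigenvalues (possible for non-euclidean metrics) are dropped from both the
coordinates and the R² denominator — no Lingoes/Cailliez correction — so
R² per axis is the positive-eigenvalue proportion; at most five axes are
returned.  On euclidean distances of a known configuration the embedding
reproduces all pairwise distances to 1e-8.

Plot builders emit tidy tables, not pixels: van Krevelen (O:C, H:C),
Kendrick (KM, KMD), custom scatter, per-sample QC summaries, and kernel
densities.  Points lacking a required value are excluded, never
zero-filled, so every row count is derivable from the exclusion rules.
Densities use a Gaussian kernel with Silverman bandwidth on a shared
512-point grid; the grid is padded by five maximum bandwidths beyond the
pooled data range so that every curve integrates to 1 within 1e-3 on its
own grid (a grid clipped exactly to the data range would lose kernel tail
mass well above that tolerance).  Units with fewer than two distinct
values are skipped with a warning.  Optional matplotlib rendering lives in
a thin separate layer.

## Mapping and reporting

Formula-to-entry mapping uses local CSV tables (formula, database, entry
type, entry id, entry name) rather than live database queries, for
reproducibility and licensing reasons; a small fictional table ships for
tests (synthetic, as its filename states).  Matching is exact on the
formula string — isomers share formulas by design.  Per (database, entry
type) at most `max_records` (default 5) entries are returned, in ascending
entry-id order for determinism.  Wide (";"-joined cells) and long (row per
entry) layouts carry identical information.

The HTML report is rendered from an internal markdown template with a
small built-in converter (headings, lists, tables); equations appear as
plain text.  With a pinned timestamp the report is byte-identical across
runs.  The export bundle writes the processed data and molecular files
(restoring the raw missing code), an optional merged sheet joined on the
mass identifier, uniqueness-test CSVs per comparison, plot tables, and the
report.

## Synthetic data

The generator emulates a two-group study at the scale of a typical soil
organic-matter dataset.  Defaults: 2000 peaks, 10 samples per group, 90%
of peaks formula-assigned, 5% isotope-flagged, log-normal intensities
(meanlog 16, sdlog 1 — arbitrary instrument units).  Formulas are drawn by
rejection sampling — C uniform on [4, 40], H:C uniform on [0.2, 2.5], O:C
capped at 1.2, N/O/S/P entering with decreasing probabilities — which
populates the realistic region of the van Krevelen plane and keeps NOSC
within [−4, 4].  Peak masses are the monoisotopic masses of the generated
formulas.  Presence/absence: 15% of peaks are truly differential with
presence probabilities 0.9 vs 0.1 (direction randomized); the rest share a
per-peak probability drawn uniformly from [0.4, 0.95].  The truth table
returned alongside the data flags the differential peaks, making power and
type-I checks self-contained.  CoreMS mode writes per-sample files in
which each observed peak carries the true formula (confidence ∈
[0.7, 0.99]) plus decoy candidates (confidence ∈ [0.1, 0.69], perturbed
element counts, larger mass errors), with a truth sidecar mapping m/z to
the true formula.

What the generator does **not** emulate: peak shapes, resolution or m/z
noise, intensity correlation structure between peaks, batch effects, or
chemically coherent co-occurrence of compound classes.  Passing tests
therefore demonstrate correctness of the computations and calibration of
the statistics under independent Bernoulli presence — not robustness to
instrument artifacts.

## Numerical and design choices

- Canonical missing marker is NaN, never 0.
- Formula parsing: Hill-style element+count tokens, alphabet restricted to
  C,H,N,O,S,P with a strict flag; count absent = 1.
- Group detection: plain substring matching, first pattern wins,
  case-sensitive by default (regular expressions behind a flag).
- Tie-breaks are deterministic everywhere (formula resolution, mapping
  truncation, class precedence) so identical inputs give byte-identical
  outputs.
- Eigendecomposition symmetrizes the double-centered matrix and treats
  eigenvalues below 1e-12 of the spectral radius as zero.
- The end-to-end checks run at 2000 peaks × 20 samples, a scale at which
  the full pipeline (simulate → properties → filter → compare → PCoA →
  export) completes in a few seconds.

## Limitations

- Only pairwise (two-group) comparisons; no abundance-based differential
  tests — comparisons are about presence only.
- Single Kendrick base (CH₂); no isotope-resolved property variants.
- Cross-sample peak identity after CoreMS ingest is formula-string based;
  unassigned peaks cannot be matched across samples in that path.
- Compound-class boundaries are a convention, not a measurement; results
  near rectangle edges depend on the table chosen.
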