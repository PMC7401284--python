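# Methods

## Dietary scoring

**Inputs.** Three CSV dialects: a food composition table (`food_id, name,
iron_mg_per_100g, ascorbic_mg_per_100g, phytate_mg_per_100g`), item-level
recall records (`participant_id, day_index, food_id, grams_consumed`, one
row per eaten item), and hematology panels (`participant_id,
hemoglobin_g_dl, ferritin_ng_dl, absorption_pct`). Unresolvable food ids,
duplicate keys and out-of-range values are hard errors, never silent zeros
— a silently zeroed phytate entry would bias the phytate:iron ratio
downward, so missing composition data must be fixed upstream.

**Categorization.** A food is "high" density for a variable iff its
per-100 g value strictly exceeds the cutoff (defaults: iron 0.35, ascorbic
acid 24, phytate 50 mg/100 g, phytate:iron ratio 1); the boundary value is
"low". The per-food ratio is molar by default, using molar masses 660.04
g/mol (phytic acid) and 55.845 g/mol (Fe); a mass (mg/mg) convention is
available via `ratio_mode`. The molar default was chosen because cohort-
level mean molar ratios of ~4 are the plausible range for a mixed Western
diet, whereas the mass reading of the same intakes gives ~45; the two
conventions differ only by the constant factor M_Fe/M_phytate and therefore
rank foods identically. A food with phytate but zero iron is assigned ratio
+inf (maximally inhibitory); with neither, 0.

**MIE.** Daily nutrient totals are Σ grams × content/100 g over the day's
items, averaged across recall days; the participant ratio is the ratio of
the averaged phytate and iron intakes (undefined, and an error, at zero
mean iron). **FPM.** density = high foods / total foods, counting every
eaten item across all days by default (`counting_mode="instances"`);
`"unique_foods"` deduplicates by food id first, for the reading of a food
"inventory". Participants with fewer than `required_days` (default 3)
completed recall days are excluded, with logged counts.

## Diagnostic protocol

Outcome positivity is biomarker ≥ cutoff ("iron sufficient"), swept over
inclusive grids: hemoglobin 11.0–14.0 g/dL step 0.5 (7 cutoffs), ferritin
5–55 ng/dL step 5 (11), absorption 0–50 % step 5 (11). Ferritin units
follow the conventional assay label used for these panels and are treated
as opaque. Dietary variables are dichotomized at their cohort 25th/50th/
75th percentiles (linear interpolation between closest ranks; any
convention is defensible, this one is fixed and logged); absorption
enhancers (iron, ascorbic acid) test positive strictly above a threshold,
inhibitors (phytate, ratio) strictly below, and a tie is negative.
Directions are configurable per variable.

Each of the (cutoffs × 3 thresholds) cells yields a 2×2 table. Cells with
an empty margin (outcome or test all-positive/all-negative) are flagged
degenerate and excluded from all summaries — clamping them would
manufacture information. Per method/variable/outcome the summary is the
unweighted mean of each metric over retained cells, reported in percent;
cells where a single metric is undefined (zero denominator) are dropped
from that metric's mean only. The protocol reports one number per
method/variable/outcome because grid-cell metrics are strongly dependent
(they share participants), so averaging, not pooling, is the honest
collapse.

Fisher's exact test (two-sided) is computed by direct enumeration over the
hypergeometric support with exact integer comparisons: p = Σ probabilities
of tables (same margins) whose probability ≤ the observed table's. This
matches `scipy.stats.fisher_exact` (cross-checked in tests) while letting
the test suite sweep every small table quickly. Method comparison uses a
paired two-sided t-test across cells matched on (outcome cutoff, threshold
rank), restricted to pairs where both methods are defined; a zero-variance
difference vector (including exactly identical vectors) is reported as
p = 1.0 with a degenerate flag so that comparison reports always complete
rather than raising inside a sweep.

## Synthetic cohort generator

The generator is the package's test bed; its defaults are the study
conditions the analysis assumes.

* **Composition** (60 foods): per nutrient, a food is high-density with
  probability `high_fraction` (iron 0.55, ascorbic 0.10, phytate 0.20) and
  its content is `cutoff · exp(±|N(m, s)|)` — strictly above the cutoff in
  the high class, at or below in the low class, so the mixture and the
  categorization agree by construction. The high fractions were back-solved
  from the typical FPM density quartiles of a mixed diet (iron densities
  ~0.5–0.6, ascorbic ~0.03–0.14, phytate ~0.1–0.25), and the log-scale
  parameters chosen so cohort mean intakes land near 14–15 mg/d iron,
  ~90–130 mg/d ascorbic acid and ~500–700 mg/d phytate under the default
  portion model.
* **Recalls**: 27 participants × 3 days; items per day truncated-normal
  (9.6 ± 2.8, min 1); portions lognormal with mean 140 g, SD 100 g. Each
  participant has latent standard-normal pattern scores z_iron, z_ascorbic,
  z_phytate; the odds of choosing a high-density food scale as
  `exp(preference_strength · z)` with `preference_strength = 0.6` — one SD
  of pattern score multiplies the odds ~1.8×, a moderate degree of dietary
  patterning consistent with the narrow FPM density interquartile ranges
  seen in homogeneous cohorts. The ratio score is the standardized
  difference `(z_phytate − z_iron)/√2`.
* **Hematology**: each biomarker = baseline + noise_SD · Σ_v β_v z_v +
  N(0, noise_SD). Effect sizes β are expressed in units of the biomarker's
  noise SD so one β vector acts comparably on hemoglobin (13.1 ± 1.0
  g/dL), ferritin (30.3 ± 15.1 ng/dL) and absorption (14.4 ± 26.0 %,
  truncated to [0, 100]; ferritin floored at 0). Defaults are weak
  (β = ±0.25, negative for the inhibitors), matching the near-zero Youden
  indices typical of free-living cohorts; β = 0 gives exact independence
  and β = 2 a strong, recoverable signal.

**What the generator does not emulate:** repeated food habits (items are
drawn i.i.d. within a participant, so FPM densities carry binomial rather
than habit-structured noise), day-of-week and seasonal menu structure,
recall error (omissions, portion misreporting), heme vs non-heme iron,
inflammation effects on ferritin, and any nonlinearity or interaction in
the diet→biomarker link. Passing tests therefore show the *protocol* is
correct and well calibrated under a known generative model — not that
either assessment method is valid in real populations.

## Numerical and design notes

* Quartiles: `numpy.percentile(..., method="linear")`; degenerate
  (constant) inputs are flagged; fewer than 4 values is an error.
* Grid points are generated as `start + step·k` with an inclusive endpoint
  to avoid float-accumulation drift.
* Fisher enumeration compares exact integer numerators, so mathematically
  tied tables are always included regardless of float rounding.
* Problem sizes in the test suite — 200 random cohorts (n ≤ 30) for
  brute-force equivalence, all 2×2 tables with total ≤ 40 for Fisher, 20
  seeds × n = 500 for null calibration, 20 seeds × n = 200 per effect size
  for signal recovery — were chosen to make sampling error small relative
  to the asserted bands while keeping the default run fast on one core.
* The hemoglobin floor (0.1 g/dL) and biomarker clipping exist only to keep
  generated panels physically valid under extreme configured effects.

## Known limitations

* The grid-collapse rule (unweighted mean over retained cells) is one
  defensible reading of the protocol; alternatives (weighting by cell
  information, dropping extreme cutoffs) are not implemented.
* No AUC estimation or multiple-testing correction: the protocol reports
  per-cell Fisher tests and two paired t-tests per variable/outcome as is.
* `paired_compare` maps any zero-variance difference vector to p = 1.0;
  a constant non-zero shift between methods is thus reported as
  non-significant with a flag, which callers should inspect.
* The generator's dietary marginals are approximate (within ~20–30 % of
  the intended cohort means), adequate for protocol validation but not for
  nutrition surveillance realism.
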