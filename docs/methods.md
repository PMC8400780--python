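# Methods

## Scope and model

The package reproduces, as code, the desk half of a targeted LC-PRM-MS
assay for haptoglobin site-specific glycosylation: given a transition list
of glycopeptide targets and per-patient fragment chromatograms, it
integrates isomer peak areas, normalizes them within each glycosylation
site, and evaluates the resulting relative abundances as cirrhosis-vs-HCC
markers. The acquisition half (purification, digestion, the instrument
method) is out of scope; its parameters (25 eV collision energy, the
100-min gradient) are carried only as provenance metadata in `RunConfig`.

## Mass arithmetic

All masses are monoisotopic. Amino-acid residue masses come from
pyteomics; monosaccharide residue masses are HexNAc 203.079373, Hex
162.052824, Fuc 146.057909, Neu5Ac 291.095417; water 18.0105646863 and
proton 1.00727646677 Da. A glycopeptide's precursor m/z is
`(M_peptide + M_glycan + z·M_proton) / z`. The three site backbones are
MVSHHNLTTGATLINE (Asn184), NLFLNHSE (Asn207) and VVLHPNYSQVDIGLIK
(Asn241); none contains cysteine, so no fixed or variable modifications
apply. These constants reproduce the assay's printed precursor values
(1278.8295 for Asn207 + 5-6-0-3 at 3+, 1181.7977 for 5-6-0-2) to four
decimals.

The quantifier fragment set per target is the Y1 ion (peptide + HexNAc)
plus the five-step core ladder (+HexNAc, +Hex, +Hex, +Hex, +HexNAc+Hex),
all singly protonated — six ions for every composition in the packaged
table. Compositions too small for a step truncate the ladder. Oxonium
marker ions (HexNAc⁺ 204.0866, Neu5Ac⁺ 292.1027, and their water losses)
are emitted flagged non-quantifier. Reference fragment values printed for
the assay sit 1–5 mDa above theory while the precursors match exactly;
fragment identity is therefore asserted at 10 ppm rather than at fixed
decimal precision.

Charge states follow the observed-charge rule: 3+ everywhere except
tri/tetra-antennary sialylated compositions (HexNAc − 2 ≥ 3 antennae,
Neu5Ac ≥ 1) on the long Asn241 backbone, which are 4+.

## The packaged target table

The transition list transcribes the published site-by-site
microheterogeneity table: 72 isomer entries over 41 distinct
(site, composition) forms — 13/11 at Asn184, 43/18 at Asn207, 16/12 at
Asn241. (The source text variously states 73/42 and 44/19 for these
totals; the printed table is taken as authoritative.) Cross-site
composition overlaps computed from it: 10 (Asn184∩Asn207), 11
(Asn207∩Asn241), 7 (Asn184∩Asn241), 7 (triple).

Expected retention times are fixture conventions, not physical claims:
within each site's elution window (Asn184 42–54, Asn207 40–60, Asn241
61–88 min) glycoforms are placed evenly in elution order (fewer sialic
acids and smaller glycans first), and isomers of one composition are
spaced 2.0 min apart, isomer 1 earliest.

## Synthetic cohorts

The generator's defaults are the study conditions: 15 patients per arm;
genders 3M/12F (cirrhosis) and 7M/8F (HCC); HCC TNM stages allocated by
largest-remainder rounding of 47/0/40/13 % to 7/0/6/2 of 15; AFP
log-normal with distribution medians 2.9 and 6.0 ng/mL. The AFP log-scale
sd (natural log) defaults to 1.0 — the source reports only medians, so the
spread is a free parameter of the generator, not a cohort claim.

Glycoform abundances are compositional. Per site and group, class means
over (sialylated, sialylated-fucosylated, other) are split equally across
that class's isomer entries (per-target override weights are available),
multiplied by log-normal noise (logistic-normal model, sd 0.15 on the log
scale), and renormalized to sum to one within the site. Asn207 class means
are calibrated to the published group pies: (0.872, 0.121, 0.007) in
cirrhosis vs (0.775, 0.217, 0.008) in HCC. Asn184 and Asn241 showed no
group differences, so both groups share one profile there; the values
(0.85, 0.10, 0.05) and (0.88, 0.07, 0.05) are realistic
sialylated-dominated profiles chosen once as package defaults.

Chromatograms are rendered per (form, fragment) trace on a 40–90 min grid
at 0.02 min: each isomer entry contributes a Gaussian (σ = 0.3 min) at its
expected RT with amplitude `total_scale × abundance × fragment_split /
(σ√2π)`, so the noise-free trace area is exactly `total_scale × abundance
× split`. The fragment split (0.35, 0.20, 0.15, 0.12, 0.10, 0.08) sums to
one; a flat 50-count baseline and 5 % multiplicative Gaussian noise are
added on top. Traces are keyed by the form's `site|code` identifier
because PRM fragments are precursor-isolated — fragments of different
precursors never mix even when their m/z coincide.

What the generator does **not** emulate: isotope envelopes, co-isolation
interference, retention-time drift between runs, heteroscedastic
electrospray response, missingness, or any real patient-level biology
beyond the class-mean shifts. Passing recovery tests therefore show the
desk pipeline is self-consistent and unbiased under its own peak model,
not that it would produce these exact numbers on the deposited raw data.

## Quantitation conventions

Extraction windows are ±3 min around the expected RT (spanning all of a
form's isomers) with a 10 ppm fragment m/z tolerance; the acquisition-side
±2 Da precursor window is recorded but plays no role in desk quantitation.
The six fragment EICs are summed and the **composite** is integrated —
apexes and bounds then agree across fragments by construction; per-fragment
integration is available by calling `integrate_peak` on individual EICs.
Peaks are local maxima with prominence ≥ 5 % of the tallest apex and at
least `min_isomer_separation` (1.0 min) apart; adjacent peaks split at the
valley between them, outer bounds fall where the trace reaches 1 % of the
apex. Integration is trapezoidal above a local linear baseline drawn
between the bound intensities (the Xcalibur-like convention; the true
bounding rules of that software are unpublished, so this convention is
validated against synthetic truth only). Isomer identity is positional:
isomer 1 is the earliest peak in the window; undetected isomers report
area 0 with a missing flag; surplus apexes keep the tallest `n_isomers`
and are logged.

Numerical behavior: areas are linear in intensity, stable to ≤0.5 % under
grid halving, and the noise-free end-to-end chain returns true relative
abundances within 1 % per entry (observed maximum ≈ 0.25 %, dominated by
the 1 %-of-apex truncation of the Gaussian tails, which cancels in the
normalization).

## Normalization and summaries

Relative abundance divides each patient's area by that patient's total
over all 72-entry columns of the same site; a zero-total patient-site is
flagged, never silently dropped; the operation is idempotent. Group class
fractions are means of per-patient fractions (matching per-patient
normalization followed by averaging), not pooled-area ratios — the source
does not state which convention its pies use; a pooled-ratio switch exists.
Heat-map rows are per-feature z-scores across patients (zero-variance
features flagged as all-zero rows), columns ordered cirrhosis-then-HCC,
rows by average-linkage Euclidean clustering.

## Marker statistics

Gender balancing subsamples both arms, without replacement and seeded, to
the per-gender minimum counts across arms — 3M/12F vs 7M/8F becomes 3M/8F
in each arm (n = 22) — making the two ratios exactly equal; three such
subsets are drawn. Per feature and subset, a two-sided Welch *t*-test
(pooled-variance Student's *t* by config; Welch is the default because the
HCC arm is the more variable) and a Wilcoxon rank-sum test are computed;
*t* p-values are Bonferroni-corrected ×3 and a feature is significant only
when the corrected p beats α = 0.05 in **all three** subsets (any/majority
rules are available; the all-subsets reading is the strict interpretation
of "significant despite the gender factor"). This compound procedure is
conservative: on null features its realized type-I rate is far below α.

ROC-AUC is the Mann–Whitney statistic with half credit for ties, oriented
so larger scores indicate HCC (opposite-direction markers are flipped and
flagged). The default confidence interval is DeLong's nonparametric
variance (comparable to SPSS output); a seeded 2000-resample percentile
bootstrap is the alternative. Marker panels are combined by unpenalized
in-sample logistic regression on standardized features with AFP entered in
logs; the combined score is the linear predictor and its AUC is in-sample
— deliberately optimistic, matching the panel-building convention the
assay used, with a ridge fallback under perfect separation. PCA is
mean-centered and Pareto-scaled by default (the MarkerView convention;
autoscaling available), computed by SVD.

## Problem sizes and determinism

Every stochastic step consumes a `numpy` `default_rng` seeded from the
relevant config; identical configs and seeds give bit-identical datasets
and pipeline outputs. The recovery analyses use 20 replicate default
cohorts (15 + 15 patients each, full render→quantify chain); the
statistical property sweeps use 50 seeded cohorts evaluated on generator
truth tables, which is the statistics' actual input surface and keeps the
sweeps fast. Sample-median checks of the AFP model use 10,000 draws.

## Known limitations

- Isomer assignment is RT-positional; it would mislabel isomers under
  retention drift larger than the isomer spacing. No cross-run alignment
  is attempted (synthetic RTs are stable by construction).
- The in-sample panel AUC overstates out-of-sample discrimination;
  with ~20 correlated features on 30 patients it saturates near 1.0.
- Patient-level results of the original cohort (specific p-values, AUCs)
  are not reproducible here without the deposited raw data; the pipeline
  validates against its own generator truth and the printed, desk-scale
  reference values instead.
- The mzML adapter writes/reads chromatogram lists only (no spectra), with
  uncompressed 64-bit arrays.
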