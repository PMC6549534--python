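# Methods

## Problem and scope

`methcascade` implements an integrative screen for genes whose expression
changes during staged liver carcinogenesis (NAFL at 6 weeks, NASH-fibrosis
at 12 weeks, full-fledged HCC at 20 weeks; disease vs age-matched control,
n = 4 per arm and stage) are plausibly driven by promoter DNA methylation.
The screen combines five measurements per gene — promoter sequence,
log2-scale expression, MeDIP-style methylation (bound/input), H3K4me3
ChIP/input enrichment, and qPCR Ct values — and funnels them through two
filter cascades.  The package works on tables; no raw array, read-level
bisulfite or ChIP processing is in scope.  Because the screen is defined
by fixed thresholds rather than a fitted model, validation rests on a
synthetic cohort generator with planted, recoverable truth.

## CpG-island calling

A promoter is "epigenetically regulatable" when it contains a strong CpG
island: length > 500 bp, G+C fraction > 55 %, and observed/expected CpG
ratio > 0.65, where obs/exp = N_CpG · L / (N_C · N_G).  The criteria
define a segment but not an algorithm, so the scanner uses a deterministic
fixed-window construction: a window of exactly `min_length + 1` bases
(501 by default, realising the strict length inequality) slides with step
1; a window qualifies when it passes both composition thresholds strictly;
islands are maximal unions of overlapping qualifying windows.  Merged
islands are reported with their own recomputed statistics even if the
union's aggregate dips below a threshold — consumers can re-filter, and
the construction avoids under-specified trimming heuristics.  All
inequalities are strict, matching the wording of the criteria.  `N` bases
are excluded from counts and effective length; windows with more than 10 %
`N` are disqualified; a sequence lacking C or G has obs/exp defined as 0
(conservative, avoids 0/0).  Coordinates are 0-based half-open.  The
implementation uses cumulative-sum rolling counts; its contract is exact
equality with a naive per-window recomputation oracle, enforced by test.

## Differential expression

Expression is analysed on the log2 scale.  Per stage, the gene-level
statistic is mean(disease) − mean(control) (log2 fold change) with a
pooled-variance Student t-test (Welch available via `equal_var=False`;
Student is the default because that is the named test for the two-arm
comparisons).  P-values are Benjamini–Hochberg adjusted within stage
across all tested genes (statsmodels step-up).  The DEG rule is
|log2FC| ≥ 1 (inclusive — the boundary has to be fixed somewhere and the
fold-change criterion is stated as "a twofold change") and adjusted
p < 0.05 (strict, following the "<0.05" wording).  Degenerate genes with
zero variance in both arms get p = 1 when means agree, p = 0 otherwise.
The common-trend set is the intersection of per-stage DEG sets with
identical direction at every stage; the documented alternative
(intersecting genes significant anywhere) is not implemented.  The
HCC-unique set is the final-stage DEG set minus genes DE at any earlier
stage, mirroring "differentially expressed only in HCC".  Moderated
(array-style) variance estimators are deliberately absent: upstream array
preprocessing is out of scope and plain t-tests are the documented
stand-in on synthetic data.  Stage-dependence statistics are one-way
ANOVA with Tukey HSD plus OLS of value on stage rank (scipy).  Raw-scale
inputs can be natural-log transformed first via a preprocessing helper.

## Methylation

Percent methylation is 100 · bound/input (single-fraction elution against
total input).  Values above 100 % are flagged, not clipped.  The
functional-significance screen keeps genes with mean control-arm percent
methylation ≥ 20 % (inclusive).  Per-stage differential methylation is a
two-sample t-test against age-matched controls, reported both as
`delta_percent` = control − disease (percentage points, positive = loss)
and `relative_change` = 1 − disease/control, the scale on which a "45 %
decrease" is stated; both are always reported because the two readings of
a "percent decrease" differ.  Microarray-style DM calling standardises
per-gene log2 enrichment ratios across the gene set, z = (x − x̄)/s, and
calls a gene when BH-adjusted p < 0.05 and |z| ≥ 1.5.  The original
"Z-score fold-change" is defined in a prior methods paper not available
here; cross-gene standardisation is this package's explicit
interpretation.  RRBS-style region summaries reduce to percent methylated
CpGs of total CpGs in the region.

## Integration and the cascades

H3K4me3 enrichment per gene and stage is mean log2(chip/input) in the
disease arm minus the stage-matched control mean; the promoter-mark
filter keeps |log2FC| ≥ 1 (inclusive, the two-fold rule).  The
expression–methylation relationship is a Pearson correlation pairing
disease-arm samples' log2 expression with the same samples' percent
methylation.  Pooled mode (default) uses all disease samples across
stages (n = 12 under the default design); per-stage mode is available but
underpowered at n = 4 and therefore not the default.

The common-gene cascade applies, in order: (1) common-trend DEG;
(2) promoter CGI present; (3) control methylation ≥ 20 % (inclusive);
(4) DM (p < 0.05) at every stage (an any-stage relaxation is a config
switch); (5) inverse correlation (r < 0, p < 0.05).  The HCC-unique
cascade applies: (1) uniquely DE at the final stage; (2) DM-called by the
z-score rule; (3) inverse relationship — by default opposite signs of the
expression log2FC and the methylation change, since a single-stage
Pearson over four pairs carries almost no information (Pearson mode is
available); (4) tumour methylation strictly > 20 % (the two passages word
the threshold differently: "≥20 %" for the control screen, "greater than
20 %" here, and both readings are honoured).  Survivors are classified
(up, hypo) → hypomethylated_overexpressed, (down, hyper) →
hypermethylated_downregulated, otherwise discordant.  Each report row
records a monotone boolean trail — a filter is only evaluated when all
earlier ones passed — so funnel counts are nested by construction.

## Synthetic cohorts and what they do (and do not) show

The generator plants four gene roles: *drivers* (over-expressed at every
stage with progressive promoter hypomethylation, always CGI-positive),
*passengers* (over-expressed, methylation untouched), *late-DM* genes
(down-regulated and hypermethylated at the final stage only) and *nulls*.
Defaults encode the study design: 200 genes, 5 drivers, 10 passengers,
10 late-DM, 3 stages × 2 arms × 4 replicates.

Effect sizes and noise: expression is base 8.0 plus planted log2FC plus
Gaussian noise (sd 0.25).  Driver expression log2FC is (1.8, 2.8, 3.8) —
monotone, comfortably above the two-fold threshold at n = 4 so that
recovery measures the cascade, not marginal test power; passengers are
(1.8, 2.2, 2.6); late-DM genes −2.5 at the final stage.  Driver control
methylation is 0.60 with planted relative decreases (0.23, 0.31, 0.45),
the trajectory reported for the nominated driver gene; late-DM genes
shift +0.25 from a 0.30 baseline; null-gene baselines are drawn uniformly
over 4–90 %, the spread reported for control livers.  Methylation noise
is a Beta distribution reparameterised by mean and concentration
(default 2000, i.e. replicate CV ≈ 2–4 %, careful qPCR-grade precision);
bounded support keeps every fraction in [0, 1] without clipping.  No
replicate-level variance estimates are published for these assays, so
noise defaults are chosen for testability — sized by a-priori power
analysis so that planted effects are recoverable at n = 4 — rather than
fitted to data.  H3K4me3 planted log2 enrichment is (2.0, 1.0, 0.4) with
noise sd 0.2: maximal at the earliest stage, so the count of genes passing
the two-fold filter falls strictly across stages, reproducing the
direction (not magnitude) of the reported 27 → 9 → 5 decline.  qPCR Ct
tables are built so 2^−ΔΔCt recovers the planted fold change in
expectation, with a constant reference gene (endogenous-control design).

CGI-positive promoters carry a planted ≥ 650 bp segment built from a
token stream (25 % CG dinucleotides), giving G+C ≈ 0.70 and obs/exp ≈ 1.6,
verified post hoc; CGI-negative promoters are i.i.d. sequence with 90 %
of CpG dinucleotides ablated, verified to keep every 500 bp window at
obs/exp ≤ 0.4 and regenerated on failure (≤ 100 attempts).  Promoters are
standalone sequences; no genome coordinates or repeat structure are
simulated, and generation starts at per-gene quantities (no reads,
probes or capture chemistry).

All randomness flows from one root seed through fixed named substreams
(one per table), so outputs are byte-identical across runs and adding a
generator cannot perturb another's stream.  Sample names are
`<arm>_<stage>_<rep>` with controls first and stages ascending.

Passing tests on these cohorts demonstrate that the pipeline's decision
rules recover planted structure under idealised noise; they do not
demonstrate performance on real arrays, where probe effects, correlated
noise, batch structure and non-Beta methylation variability are all
absent from the simulation.

## Numerical and design choices

* Degenerate t-tests (zero variance both arms): p = 1 on equal means.
* BH family: all genes tested at one stage (per-contrast adjustment).
* ΔΔCt uses the arithmetic group mean of ΔCt, not per-sample pairing —
  the choice is not pinned down by the method's description; documented.
* Beta noise means are clipped to [1e−6, 1 − 1e−6] before drawing;
  planted means outside [0, 1] are clipped and counted in
  `TruthTable.table.attrs["clipped_cells"]`.
* The correlation threshold is P = 0.05 exactly; a figure legend
  elsewhere quotes it as log2 P = −4.13, which is not log2(0.05) ≈ −4.32,
  and the plain 0.05 is used.
* Configs with `cgi_promoter_fraction = 0` and planted drivers are
  rejected: drivers must be CGI-positive for the cascade to be meaningful.
* Problem sizes in the validation suite — 100 cohorts for recovery, 50
  for null calibration, 200 sequences for the scanner oracle — are the
  package's chosen desk-scale defaults; each completes in about a minute.

## Known limitations

* The z-score DM call is an interpretation of an inaccessible upstream
  definition; alternative standardisations would shift calls near |z| = 1.5.
* Per-stage Pearson correlations at n = 4 are implemented but essentially
  uninformative; conclusions should rest on the pooled mode.
* The generator plants monotone, stage-aligned effects only; it cannot
  probe robustness to non-monotone trajectories or partially penetrant
  effects.
* No moderated-variance testing, probe-level normalisation or RNA-seq
  count models; inputs are assumed already normalised on log2 scale.
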