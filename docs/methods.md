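# Methods

This note documents the statistical procedures, the synthetic-data
generative model, the parameter defaults and the design choices made where
the problem was genuinely open.

## DMR calling

**Region formation.** Per CpG site, Δβ is the difference of group means of
per-sample betas (NaN-skipping over uncovered samples). Candidate regions are
maximal runs of consecutive CpGs with the same Δβ sign and |Δβ| ≥
`min_site_delta` (default 0.1); a run breaks at a sign change, at Δβ = 0
(treated as a sign mismatch), at a chromosome change, or when consecutive
member CpGs lie more than `max_gap` (300 bp) apart. Runs with fewer than
`min_cpgs` (5) members are discarded. The region interval spans the first to
the last member CpG plus one (half-open), so its length is
`last − first + 1` bp.

**Region test.** Counts are pooled within group over the region's member
CpGs and samples into a 2×2 table (methylated/unmethylated × case/control),
tested with the two-sided Fisher exact test. Pooling trades the per-sample
hierarchy for determinism and power at n = 6 + 6; the pseudo-replication
this introduces is exactly what the permutation screen (below) guards
against. p-values are adjusted across all candidates with
Benjamini–Hochberg.

**Permutation type-I screen.** Pooled Fisher p-values are anticonservative
under sample-level variability, and candidate regions are *selected* as
extreme same-sign runs, so any per-region permutation of the region's own
statistic is biased: under a true null the observed labelling ranks at
~2/924 among the 6-vs-6 splits and a per-region test can never screen it at
the 0.01 level. The screen therefore compares each region's observed
statistic (|mean member-CpG Δβ|) against the *genome-wide maximum* candidate
run statistic over relabelled cohorts: for every group-label split (all
C(12,6) = 924 enumerated exactly when C(n, n_case) ≤ 1000, otherwise
`n_perm` = 200 seeded draws with the add-one estimator), the largest |mean
Δβ| over any same-sign run of ≥ `min_cpgs` sites anywhere in the genome is
recorded. This is a max-T (Westfall–Young) style null that accounts for the
genome-wide search. The member sites of the candidates under consideration
are excluded from the permutation scan: partially aligned relabellings
retain a fraction of any true effect, and without the exclusion strong true
regions inflate the null and mask weaker true regions. With it, the screen
leaves planted regions intact (measured recall 1.0 at the default effect
size) while null cohorts yield zero calls in 20/20 runs.

**Filters.** Retained DMRs satisfy length > 200 bp (strict), p < 0.05,
q < 0.05 and permutation p < 0.01. The effect size reported per DMR is the
fold difference score FDS = |log2((β_case + ε)/(β_ctrl + ε))| on the pooled
group betas with ε = 0.01; its attainable maximum is log2((1+ε)/ε) =
log2(101) ≈ 6.658, which brackets the score range seen in practice.

## Feature annotation

CpG-island context follows the standard geometry: island inside a CGI,
shore within 2 kb of an island boundary, shelf within 2–4 kb, open sea
beyond; the nearest island wins where flanks of two islands overlap, and an
exact-distance tie resolves upstream. Genic context uses a strand-aware
promoter window `[TSS − 1500, TSS + 500)` (a common convention; the window
is config-exposed), gene body = gene span minus promoter, intergenic
otherwise. Feature *pairs* are assigned per member CpG — the genic and CGI
label at the same position — so a DMR running from a promoter island into a
gene-body shore reports {(promoter, island), (genebody, shore)} rather than
the 4-pair cross product; this resolution matches how long DMRs actually
straddle features. Nearest TSS is chosen by absolute distance from the DMR
midpoint; ties prefer the lexicographically smaller gene id. Feature
summaries count a DMR once per label it carries, so fractions across labels
can exceed 1.

## Concordance integration

External cohorts enter as per-gene logFC tables. Thresholds are strict:
expression |FC| > 2 (interpreted on the linear scale, i.e. |logFC| > 1, with
a `log2` switch since every exemplar gene passes under either reading) and
methylation |Δ| > 0.1; p and adjusted-p filters (< 0.05) apply when provided.
A gene is robust iff (a) it carries a called DMR over its promoter or gene
body ("current" DMG; the DMR→gene map uses the annotation labels and the
nearest-TSS gene), (b) it passes the expression threshold with one consistent
direction in all provided expression tables, (c) it passes the methylation
threshold with the direction of the current call in all provided methylation
tables, and (d) the (methylation, expression) pair is functional: hyper/down
or hypo/up. Support defaults to *all* provided tables of each kind because
the biomarker question demands markers that replicate everywhere;
`min_*_support` relaxes this.

## MDM selection

Per-sample region methylation is the pooled beta over member CpGs. The four
criteria, all strict: FC = mean_case / max(mean_ctrl, 10⁻⁴) > 20 (the floor
prevents division blow-up when controls are fully unmethylated — the
criteria themselves force ctrl < 1%, where the ratio is intrinsically
unstable); AMD = mean_case − mean_ctrl > 0.10; rank AUC (Mann–Whitney U /
(n₁n₂), ties ½) > 0.80 with rank-test p < 0.01 (exact enumeration when
n ≤ 12 and tie-free, otherwise normal approximation with tie correction);
control mean methylation < 1%. Survivors rank by (AUC desc, FC desc, id
asc); the head of the list is the top MDM. The criteria as printed describe
a hypermethylated marker; a `mirror_hypo` flag evaluates the mirrored
criteria (1/FC, −AMD, 1−AUC, 1−ctrl) for hypomethylation candidates and is
off by default.

## Classification and clustering

Feature matrices hold per-sample pooled DMR betas restricted to one
(genic, CGI) class, imputing a sample's uncovered DMRs with the cross-sample
mean. The classifier is a linear SVM with C = 1 under stratified k-fold
(default 10, reduced with a warning to the minority class size — 6 folds for
the 6-vs-6 design); columns are standardized with training-fold statistics
only, and a pre-split train/test mode exists for external-cohort evaluation.
Clustering selects the most variable CpGs by cross-sample beta variance
(default: all), computes sample–sample Pearson correlations on mean-imputed
betas, and cuts an average-linkage tree on 1 − r at k = 3 among the case
samples (tumour subgrouping), cross-tabulated against KRAS/BRAF status.
Cluster labels are canonicalized by order of first appearance so the
assignment is invariant to sample input order.

## Cq diagnostics

Signals are quantification cycles, by default reference-normalized
(ΔCq = target − reference; undetermined references are an error). Lower
signal ⇒ more methylated, and a sample is positive iff signal ≤ threshold —
the direction in which tumour samples amplify earlier. Threshold candidates
are midpoints between adjacent sorted unique signals plus ±∞ sentinels; the
selected threshold maximizes sensitivity subject to specificity ≥ the
target, ties resolving to the smallest (most stringent) threshold. (The
vacuous target 0 therefore returns the smallest full-sensitivity midpoint,
not +∞.) Group comparison uses Welch's unequal-variance t-test on the
analysis-scale signals; group mean Cqs are reported on the raw cycle scale.
Relative expression uses 2^−ΔΔCt on group means, reported in both
orientations (their product is exactly 1). Plasma panels are re-scored with
the tissue-frozen threshold, never re-optimized. Undetermined target
reactions carry the `max_cycles` sentinel (default 40) so "no amplification"
ranks least methylated in the threshold search.

## Synthetic-data generative model

No generative model is canonical for this design, so the package fixes a
standard WGBS-like hierarchy:

- **Tracks.** One chromosome; `n_genes` = 200 gene models of 8 kb evenly
  spaced (≥ 20 kb apart, guarded), alternating strand; a 1 kb CGI centred on
  ~60% of TSSs; CpGs every 10 bp inside islands and every 100 bp elsewhere
  (~51k CpGs on the 4 Mb default).
- **Baselines by context:** island 0.08, shore 0.35, shelf 0.60, open sea
  0.75 — low promoter-island methylation and high open-sea methylation, so
  planted hypermethylation arises in islands/shores and hypomethylation in
  open sea, reproducing the observed feature asymmetry of tumour DMRs.
- **Planted effects.** 30 hyper DMRs in promoter islands (±400 bp around the
  TSS) and 20 hypo DMRs in open-sea gene bodies (4.6–5.4 kb past the TSS),
  shifting case-sample logit betas by ±`delta_logit` (2.5), i.e. realized
  |Δβ| ≈ 0.43 (hyper) and 0.55 (hypo). Five of the hyper DMRs are
  **marker-grade**: control baseline 0.004 with a logit shift of 5.0
  (case β ≈ 0.37), the regime MethyLight markers occupy — near-zero
  methylation in normal tissue with a deep tumour shift — without which no
  region could ever satisfy the FC > 20 and ctrl < 1% criteria. Setting
  `delta_logit = 0` silences *all* planted effects (marker shifts included),
  giving a true null cohort.
- **Counts.** β_site,sample = logistic(logit(β0) + effect·1[case] +
  Normal(0, `sample_sd` = 0.2)); depth ~ Poisson(`mean_coverage` = 20);
  methylated counts ~ BetaBinomial(depth, mean β, precision `dispersion` =
  50). The realized mean depth concentrates within ±15% of the target.
- **Expression and external cohorts.** Gene baselines ~ Normal(8, 1.5) on
  log2 scale; concordant genes (60% of planted, marker genes always
  included) receive case-vs-control logFC ∓(2 + U(0,1)) opposing their
  methylation direction; discordant genes alternate sign-violating and
  sub-threshold (U(−0.8, 0.8)) effects; non-planted genes are null. Each of
  the 4 expression and 4 methylation external tables reports the true
  per-gene effect (logFC, or Δβ for methylation) plus Normal(0,
  `external_noise_sd` = 0.05) with configurable dropout (default 0).
- **Cq panels.** Cq = C0 − log2(q) + Normal(0, 0.3) with C0 = 38 and q the
  methylated template quantity: q = copies·m in tissue (copies = 1000) and
  q = copies·(tf·m_case + (1−tf)·m_ctrl) for plasma cases (copies = 200,
  tumour fraction tf = 0.05 — a plausible cfDNA value; the real value is
  unknown). Quantities below 1 copy, or cycles past 40, come out
  undetermined. Reference Cq ~ Normal(25, 0.3) independent of group. With
  the default marker (m_case ≈ 0.4, m_ctrl ≈ 0.004) the model lands tissue
  group-mean Cqs near 29.5 (case) and 36.2 (control).

**What the simulation does not emulate:** read-level errors and bisulfite
conversion failure, sequence-dependent coverage bias, copy-number and purity
structure beyond the single tumour-fraction scalar, correlated methylation
between neighbouring CpGs beyond the planted blocks, batch effects across
external cohorts, and per-sample biological variation in marker methylation
for the Cq model (only cycle noise is simulated — tissue panels therefore
separate essentially perfectly, and the plasma sensitivity under 5% dilution
collapses rather than landing at an intermediate value). Passing recovery
tests therefore demonstrates the correctness of the algorithms under the
stated model, not the field performance of any marker.

## Problem sizes and numerical choices

Default desk-scale conditions: 6 + 6 samples, ~51k CpGs on 4 Mb, 50 planted
DMRs; the full caller runs in seconds and the 20-cohort null calibration in
about half a minute. Tests that exercise recovery use either these defaults
or a 50-gene/1.1 Mb reduction of the same geometry. Degenerate inputs are
errors, not silent results: zero-coverage betas, empty intersection
cohorts, single-class panels, constant-beta clustering input and absent
feature classes all raise with a message naming the offender. Permutation
p-values use ≥ comparisons with a 10⁻¹² slack against float jitter; BH
adjustment preserves input order; Fisher tables are rounded to integers
after NaN-aware pooling.

## Known limitations

- The permutation screen's site-exclusion step assumes screened candidates
  cover a negligible fraction of the genome; on cohorts where candidates
  cover most sites the null would be estimated from too little background
  (the degenerate extreme — a cohort that *is* one region — returns the
  unexcluded exact enumeration instead).
- The per-region Fisher test ignores the sample hierarchy by design; its
  p-values should be read as ranking scores gated by the permutation
  screen, not as calibrated per-region error rates.
- With 6-vs-6 designs the exact permutation floor is 1/924 ≈ 0.0011, so
  screen thresholds below that are unattainable.
- The AUC of the discovery stage is computed on sequencing betas; the Cq
  stage computes its own diagnostics and the two are not interchangeable.
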