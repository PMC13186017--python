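# Methods

## Data model

The compendium is long-format: one row is one phosphosite observation in
one experimental comparison ("condition"). A condition is identified by
(PMID, dataset id, condition id); the condition — not the dataset — is
the atomic unit of evidence, because one dataset may contain several
comparisons while the publication (PMID) is the unit of independence.
Sites are identified by HGNC symbol + residue (S/T/Y) + 1-based position
on the canonical sequence, rendered `GENE_R###` (e.g. `MELK_S356`).
Isoform-specific coordinates must be mapped to canonical positions
upstream; gene symbols are normalized through a user-supplied alias map
(case-insensitively) before any matching, and the same map is applied to
annotation resources so cross-matching cannot be broken by nomenclature
drift.

Two dataset kinds exist: `differential` rows carry fold change
(treatment/control) and p-value; `profile` rows are qualitative
detections with neither. Missing optional cells become missing values,
never zeros. Fold changes supplied as log2 ratios can be declared via
`FilterConfig.log2_fold` and are exponentiated on read.

## Quality filter and direction calling

Class-I filtering keeps rows with localization probability ≥ 0.75 and
A-score ≥ 13. Literature thresholds for the A-score are quoted both as
"≥ 13" and "> 13"; the filter defaults to ≥ 13 and the threshold is a
config field. A missing A-score passes by default — profiling sources
often omit it and localization probability alone is then the gate —
with `strict_ascore=True` rejecting such rows.

Direction calls: Up iff fc ≥ 1.3 and p < 0.05; Down iff fc ≤ 0.76 and
p < 0.05; Unchanged otherwise (including a missing p-value). When
several peptides report the same site in the same condition, a
significant call dominates Unchanged, agreement keeps the call, and an
Up/Down conflict yields Ambiguous, which is excluded from all event
counting. All three thresholds live in `FilterConfig`.

## Co-occurrence and co-regulation statistics

For a site pair, only conditions where both sites carry Up or Down
contribute; each contributes exactly one of the four joint events.
Unchanged is not a fifth event category — it simply removes the
condition — because only the four U/D event types are directional
evidence.

The positive co-regulation ratio is Σ(concordant)/Σ(discordant) and the
negative ratio its reciprocal. Zero denominators return an infinity
sentinel (perfect concordance or discordance); an all-zero tally returns
NaN (undefined, pair skipped). The heatmap statistic is
(concordant − discordant)/total, chosen for boundedness in [−1, 1] and
sign interpretability; raw counts are always exported alongside so any
alternative statistic can be recomputed.

The cross-protein gate uses the 2×2 table of m-direction × o-direction
over shared informative conditions. The two-sided Fisher's exact p is
the sum of hypergeometric probabilities of all tables with the observed
margins that are no more probable than the observed table (computed via
`scipy.stats.fisher_exact`; the test suite verifies agreement with an
independent exact-rational enumeration to 1e-9 relative error over the
full grid of tables with margins ≤ 12). Two-sided is used because the
test carries no directional claim — the sign comes from event-category
dominance.

A pair is high-confidence positive iff FET p < 0.05, ratio_pos ≥ 0.15,
concordant > discordant, ≥ 2 distinct conditions and ≥ 2 distinct PMIDs
among its events; negative is the mirrored test. The dominance condition
is added because 0.15 is permissive (a ratio of 0.15 means ~6.7-fold
more discordance): without it a mostly-discordant pair could pass the
positive ratio gate. Infinite ratios pass — zero opposing events is the
strongest evidence, and the evidence-count gates prevent
single-observation artifacts. Evidence counts default to all informative
events; `strict_evidence=True` counts only the sign-supporting
categories. No multiple-testing correction is applied by default (the
filter is on raw p, and the conservativeness of the exact test plus the
three further gates keeps the null call rate around 2% at α = 0.05, as
the calibration shows); `bh_correct=True` applies Benjamini–Hochberg
across a scan for users who want FDR semantics.

## Major sites, sharing and roles

Detection recurrence deduplicates at the dataset level (one dataset
counts once per site however many rows or conditions report it) and is
counted separately for profile and differential datasets; ranking uses
the combined count by default (differential-only is a flag), ties broken
by position ascending, k = 3 and minimum count 2 by default. Venn
partitions and core/pairwise/exclusive sharing operate on PsOP *sites*,
not proteins — two sites of one protein are distinct partners.

Roles are assigned from local TSV snapshots (no API calls, so runs are
reproducible and provenance-tagged): upstream kinase when the PsOP's
protein is a reported or predicted kinase of the target (restricted to
the matching m-site when the record names a target site), co-regulated
kinase / phosphatase by list membership, binary interactor by an
undirected interaction edge (kinase–substrate edges stay directed),
substrate when the target phosphorylates the PsOP's protein (respecting
the record's site when given). All applicable roles are emitted — there
is no precedence, matching the reality that a kinase can also be an
interactor.

## Synthetic compendium

The generator emulates the structural features of a curated multi-study
compendium: `n_studies` publications (distinct PMIDs, so the ≥ 2-PMID
gate is genuinely testable) × `conditions_per_study` comparisons; each
condition draws one latent regime direction (Up with probability
`p_up` = 0.5) shared by the target's sites — phosphosites of one protein
respond coherently within a comparison, mirroring the strong observed
concordance of major-site pairs. Planted positive partners copy the
regime with probability `concordance`, negative partners oppose it with
the same probability, background sites draw independent directions; a
partner is therefore genuinely co-regulated with every target site and
the truth assigns it to all of them. Sites are measured with probability
`detect_prob` (default 0.9) and informative with probability
`p_target_informative` (default 0.7 — comparisons in a target-focused
compendium are selected for responsiveness). Fold changes for intended
Up are log-uniform in [1.5, 4] and Down in [0.25, 0.67], keeping a
margin from the 1.3/0.76 calling boundaries so intent is unambiguous;
significant p ~ U(0, 0.01], unchanged rows fc ~ U[0.9, 1.1],
p ~ U[0.2, 1]. A 5% fraction of rows falls below the Class-I
localization threshold to exercise the filter. Default cohort: 15
positive, 15 negative, 15 background partner sites. All randomness flows
through one integer seed into `numpy.random.default_rng`.

What the generator does **not** emulate: peptide-level quantification
and multiply-phosphorylated peptides, batch effects beyond the
study/condition structure, correlated background modules, or realistic
fold-change/variance coupling. Passing recovery tests therefore
demonstrates the correctness and calibration of the counting and gating
machinery under the stated independence assumptions, not performance on
real compendia with structured confounding.

## Evaluation and problem sizes

Recovery is scored per sign at pair level: precision counts any call on
a pair that is not true-for-that-sign as a false positive; null FPR is
the fraction of background × m-site pairs called with any sign. The
recovery benchmark pools true/called/hit counts over five replicate
compendia (10 studies × 4 conditions, detection 0.9, concordance 1.0 —
225 true pairs per sign), measuring operating characteristics rather
than one noisy draw; null calibration uses ten replicates of 70
background sites × 3 target sites = 2,100 null pairs. These sizes give
binomial standard errors below 0.01 on the reported rates while keeping
the whole suite in the tens of seconds. Monotonicity of recall in
concordance and in conditions-per-study is checked on a 3-point grid
with 0.05 Monte-Carlo slack.

## Numerical and design notes

- Ratio sentinels: NaN = undefined (no events), inf = zero denominator
  with nonzero numerator; the product identity ratio_pos × ratio_neg = 1
  holds exactly whenever both are finite and nonzero.
- The analysis path is seed-free and fully deterministic: every table
  and network export is written in sorted (site-string) order, so
  repeated runs are byte-identical.
- The concordance-matrix diagonal is 1 where the site has at least one
  informative condition and 0 otherwise, so an all-Unchanged site is
  visibly inert rather than spuriously self-concordant.
- Network node identity is the rendered site string; a protein-level
  collapse (`collapse_to_proteins`, keeping the best-p edge per gene) is
  offered because published figures mix site- and protein-level
  rendering. Role-filtered subgraphs (`filter_by_role`) reproduce the
  per-role network views.
- Known limitations: no network-wide FDR by default; within-protein
  pairs are deliberately excluded from the PsOP scan (they belong to the
  co-occurrence module); the pipeline trusts upstream canonical-position
  mapping and does not re-localize sites.
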