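# Methods

## The problem

Esophageal sarcomatoid carcinoma is rare enough that cohorts are assembled
from archival FFPE tissue with no matched normal DNA. Somatic calls from a
targeted panel must therefore be separated from germline polymorphisms and
platform artifacts by deterministic rules over annotations and evidence
counts, not by paired subtraction. This package implements that rule set,
the surrounding summaries (copy number, mutation burden, cohort profiling,
actionability), and a synthetic cohort generator used to validate the rules
end-to-end.

## Filtering model

Five independent per-variant predicates are applied conjunctively. Because
each looks only at the variant itself (plus fixed context: blacklist,
repeat regions), the kept set is invariant under filter order; the printed
order is used only for trace readability and for attributing a removal to
the first failing filter in run manifests.

| filter | rule | boundary semantics |
|---|---|---|
| functional class | keep missense, stopgain, frameshift indel, non-frameshift indel | splice excluded by default (`keep_splice` widens it) |
| population frequency | remove if 1000 Genomes or ExAC frequency > 1% | strict; missing frequency treated as 0 (presumed rare) |
| panel-of-normals blacklist | remove blacklisted keys | key = (chrom, pos, ref, alt) after normalization |
| repeat regions | remove calls inside repeat-masked intervals | 1-based variant position converted to 0-based; intervals half-open |
| evidence tier | COSMIC: VAF > 1% and ≥ 5 mutant reads; otherwise VAF > 2% and ≥ 8 | VAF bounds strict ("above"), read minimums inclusive ("a minimum of") |

The blacklist detection rule (≥ 3 mutant reads and VAF > 1%) and the
recurrence rule (detected in > 20% of normals) are likewise strict/inclusive
exactly as stated; a variant appearing twice in one normal's table counts
once, since recurrence is across samples. Boundary cases for every
threshold are unit-tested exhaustively.

An optional `min_depth` pre-filter (default off) mirrors the upstream
caller's depth ≥ 20 requirement; depth filtering belongs to primary calling
rather than interpretation, so it is not part of the default cascade.

### Variant identity key

Blacklist matching across samples needs a normalized key. The key strips an
optional `chr` prefix and trims shared ref/alt suffixes then prefixes
(adjusting the position), collapsing equivalent indel spellings. Full
left-alignment against a reference genome is deliberately not performed:
the package consumes annotated tables, not sequence, and the generator and
tests exercise caller-consistent spellings.

## Copy number

Per bin, log2((T_i / median T) / (R_i / median R)) with genome-wide
per-sample medians; median normalization removes library-size differences
without modeling GC bias, which the consumed coverage tables cannot
support. Contiguous bins of one gene are averaged into a single per-gene
segment — the analysis only makes gene-level gain/loss statements, so no
HMM segmentation is used. A segment is called at |log2| ≥ 0.6, boundary
inclusive, because the cutoff value itself is equated with the reported
~1.5-fold change (2^0.6 = 1.516; 2^−0.6 = 0.660). Bins with zero or missing
coverage on either side are dropped with a warning.

## Mutation burden

TMB = (kept variants with class in the functional keep-list) / (merged
unique panel footprint in Mb). Stopgain counts as non-synonymous;
synonymous and splice calls and CNVs do not enter the numerator. TMB on
real data depends on the true panel footprint in Mb, which is not published
for this panel; synthetic-truth recovery is therefore the validation
target, not the cohort's absolute TMB values.

## Cohort profiling

The gene × patient matrix maps stopgain and frameshift calls to a
`truncating` category, CNV gain to `amplification` and loss to `loss`;
a cell is a *set* of categories. Rows cover observed genes plus the full
group catalog so unaltered catalog genes report 0%. "Altered" includes CNVs
for frequency purposes (amplifications count toward a gene's altered
cases). Pathway frequency counts a patient once regardless of how many
group genes are hit. No multiple-testing correction is applied anywhere;
the cohort-vs-reference comparison is a single two-sided Fisher exact test
taking the reference cohort size explicitly.

ClinVar triage of MMR/proofreading lesions counts a lesion as pathogenic
only when a pathogenic/likely-pathogenic assertion is present *and* no
benign-class assertion conflicts with it; a conflicting annotation such as
`Likely_benign;pathogenic` is not treated as a pathogenic identification.

## Actionability

Rules are (gene, pattern, therapy) triples in an editable flat TSV; pattern
kinds are amplification, exact protein change, truncation class (nonsense /
frameshift), splice disruption and any-deleterious. Protein notation is
normalized (drop `p.`, spaces, case) before comparison because published
tables mix spellings like `p.M1043 V`. Truncation rules are class-level
rather than per-variant since the underlying evidence is class-level.
Matching is per (patient, rule, alteration), so adding rules never removes
matches.

## Synthetic cohort generator

Defaults emulate the study conditions: 15 tumors at ~300× and 53 normals at
~700× on a 60-gene panel (50 bins × 100 bp per gene, 0.3 Mb footprint —
chosen as a desk-scale stand-in for a 416-gene panel; every rule is
footprint-independent except TMB's denominator, which scales trivially).
Per patient: somatic count ~ Poisson(12) with VAF ~ Beta(2, 8) (mean 0.2,
reflecting FFPE tumor content and subclonality) and 30% COSMIC-flagged;
germline count ~ Poisson(10) with heterozygous VAF ~ Beta(30, 30) and a
two-point population-frequency mixture (70% common at 5%, 30% rare at
0.01%) — a threshold filter only needs mass on both sides of 1%, not a
realistic site-frequency spectrum. Thirty artifact sites at VAF
0.015–0.04, half *recurrent* (planted in max(⌊0.2·n⌋+1, 30% of normals))
and half *sporadic* (min(⌊0.2·n⌋, 10%)), so the blacklist recovers exactly
the recurrent sites by construction; ~2 repeat-region false positives per
tumor; 3 genes per tumor with log2 shifts ±1 under multiplicative
lognormal coverage noise (sd 0.1). Read counts satisfy
alt = round(VAF·depth) with VAF stored as alt/depth.

Two construction guarantees matter for interpretation of the tests. First,
each gene span is partitioned into disjoint somatic / germline / artifact /
repeat position pools, so origins never collide at a site. Second, each
normal draws its private germline positions from its own stripe of the
germline pool, so no germline key recurs across normals and the blacklist
contains artifacts only (valid when the stripe width ⌊pool/n_normals⌋ ≥ 1
and 1/n_normals ≤ recurrence threshold, true for the defaults).

Random streams are split per component (somatic, germline, artifacts,
coverage, clinical) via seed-sequence spawning, so changing one knob does
not perturb the others; identical seed + config gives byte-identical files.
Clinical covariates are sampled to the cohort's margins (12/15 male, stage
I/II/III = 4/7/4, site 1/7/7, macroscopic type 10/1/4) purely for realistic
fixtures.

What the generator does *not* emulate: read-level errors and mapping
artifacts (artifacts are injected as calls, not simulated from base
errors), a realistic site-frequency spectrum, GC-dependent coverage bias,
purity/ploidy effects on CNV, and annotation noise (SIFT/ClinVar/COSMIC
labels are assigned, not predicted). Passing the end-to-end tests therefore
shows the rules are implemented and composed correctly under the stated
statistical structure — not that the thresholds are optimal for real FFPE
panel data.

## Curated tables

Two small tables ship with the package: the cohort's reported actionable
alterations (small variants plus amplifications, including the class-level
truncation entries) and its MMR/proofreading lesion table with SIFT and
ClinVar columns. Gene, patient, protein/cDNA notation and annotations
follow the published tables; genomic coordinates for entries reported
without a specific change are synthetic placeholders and are never used for
matching. These tables are loaded independently of the cascade — in
particular the NF1 splice-disruption entry is matched by the actionability
module regardless of the cascade's default exclusion of splice calls.

## Numerical and degenerate-input choices

Thresholds are compared in double precision exactly as written (0.01, 0.02,
0.2, 0.6); inputs are fractions with exact decimal spellings so no epsilon
is applied. Floats round-trip through TSVs via `repr` and
`float_precision="round_trip"`. Empty variant lists, empty repeat sets,
empty matrices and zero-mutation patients are all defined results rather
than errors; an empty normal cohort, an empty panel footprint and
non-finite log2 ratios are errors. Fisher's test delegates to
`scipy.stats.fisher_exact` and is cross-checked against exhaustive
hypergeometric enumeration in the test suite.

## Known limitations

- Rare germline variants (population frequency ≤ 1%) that pass the
  evidence tier are indistinguishable from somatic calls by construction;
  the evaluation reports them as leakage rather than pretending otherwise.
- The blacklist counting rule ignores depth differences between normals; a
  depth-aware error model is out of scope.
- CNV classification has no purity/ploidy correction, so the ±0.6 cutoff
  maps to integer copy numbers only in pure diploid tumors.
- The analysis drivers run on synthetic data sized for a desk-scale run
  (0.3 Mb panel); absolute TMB values are correspondingly larger than on a
  multi-Mb panel at equal mutation counts.
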