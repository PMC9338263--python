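# Methods

## Scope and data model

The package evaluates expanded carrier screening (ECS) on a cohort of
parental couples whose children have neurodevelopmental disorders, so
detected carrier constellations can be compared against the children's
actual diagnoses.  Sequencing, alignment, variant calling, annotation
(ClinVar, HGMD, gnomAD), in-silico missense scores (VIPUR, CADD, the
eight-tool ensemble) and ROH detection are all upstream of the package:
their outputs are inputs here.  The analysis consumes plain tables —
calls, annotations, couples/trios, diagnoses, ROH BED, SMN1 read counts,
FMR1 repeat lengths — bundled in a `CohortBundle`.

## Gene catalog

Inheritance annotations from several database exports are merged per
gene symbol (case-normalized, optional alias table).  Any X-linked
annotation yields consensus-XL; an autosomal gene is consensus-AR when
every listing database annotates AR, conflicting when AR/AD mix, and
queued for manual curation when AD-only in more than one database.
AD-only in exactly one database is kept as conflicting — the least
committal reading of a single-source claim; a curation override can
promote or exclude any gene, and excluded genes are retained with their
reason but dropped from every metric.  Genes that exomes cannot assess
reliably (paralog- or repeat-confounded: FMR1, SMN1, GBA, HBA1/2,
CYP21A2) are flagged non-capturable and handled by the dedicated
callers instead.

## Variant QC

Filters run in a fixed order with set semantics (idempotent, output ⊆
input): call quality ≥ 12; consequence filter for variants without a
ClinVar record (UTR, intronic beyond ±3 bp, synonymous); artifact rules
— heterozygous alt-read fraction < 28 % (single carrier), variant-wide
removal when ≥ 90 % of ≥ 2 heterozygous carriers sit below 28 %,
forward-strand fraction outside [0.2, 0.8], homology regions; then the
frequency filter for non-ClinVar variants (gnomAD MAF > 5 %, cohort
allele frequency > 5 %, or > 2 gnomAD homozygotes/hemizygotes).  The
alt-fraction rules deliberately skip homozygous and hemizygous calls,
whose alt fraction legitimately approaches 1.  The recurrence rule is
evaluated on the post-quality call set; the remaining artifact rules
commute with one another and with the frequency filter.

## Classification groups

Sixteen ordered groups combine three evidence axes: ClinVar P/LP with
≥ 1 review star (split by HGMD DM / non-DM / absent → groups 1–3),
ClinVar "conflicting" with ≥ 75 % P/LP entries (4–6), ClinVar P/LP with
zero stars (7–9), non-ClinVar HGMD-DM by functional class (truncating /
high-stringency missense / protein-length alteration → 10–12), and
non-ClinVar non-HGMD by class (truncating 13, high-stringency missense
14, non-canonical splice 15, protein-length alteration 16).  Cumulative
sets over the index k form the pathogenicity sweep; groups 15–16 are
computed but excluded from headline metrics (k runs 1–14 by default)
because they are dominated by benign variants.  Variants matching no
group drop out of the carrier analysis.  Canonical ±1/2 splice sites
count as truncating.  Design choices left open by the evidence: the
zero-star stratum is split three ways by HGMD state (a pooled variant
is configurable), and review stars gate only the P/LP records, not the
conflicting ones.

The high-stringency missense rule — VIPUR ≥ 0.85, CADD ≥ 20 and ≥ 85 %
deleterious votes — computes the vote fraction over non-missing
predictor calls (7/8 = 87.5 % passes; with six available tools all six
are needed); a variant with no available calls fails with a warning.
A benchmarking harness returns confusion-matrix sensitivity/specificity
for any decision rule against labelled scores.

Known hypomorphic alleles (common HFE, SERPINA1, BTD, FECH variants)
are kept in carrier frequencies but a gene in which **both** partners
carry only hypomorphic alleles is never an at-risk gene; a
keep-pathogenic override exists for conflicting-but-convincing variants
(e.g. the recurrent MMACHC insertion).

## Couple analysis

At-risk and risk-reduction definitions are given in the README.  Three
decisions deserve note.  (1) X-linked at-risk status counts carrier
*mothers* only; hemizygous paternal variants are never at-risk.  (2)
Diagnosis matching requires gene identity **and** that every inherited
causal allele is among the transmitting parent's qualifying variants at
the current threshold — a child with one qualifying and one filtered
allele is not matched, which is exactly what the filter-false-negative
accounting counts.  (3) The X-linked virtual-mating formula keeps the
displayed pair denominator C(N, 2) for fidelity even though it is not a
per-couple probability; a carrier-females-per-female alternative is
available under a flag.

The pragmatic screening policy re-derives at-risk couples without
in-silico missense modelling: ClinVar P/LP with ≥ 1 star auto-qualifies;
zero-star and conflicting records are retained as manual-review items
(they are rare — well below one per sample); unannotated truncating
variants qualify below 0.5 % MAF; unannotated missense/in-frame variants
are assessed only when the partner carries a firm variant in the same
gene.  Couples whose status rested on both partners' modelled missense
variants therefore drop.

Undetected-risk accounting categorizes every recessive/X-linked
diagnosis as detected, filtered-inherited (false negative of the
screen), de novo hemizygous, compound het inherited + de novo, or
CNV-involving; ECS sensitivity is detected / (detected +
filtered-inherited).

Tier sets follow the nested ACMG scheme (Tier-1 core set, default
{CFTR, SMN1}; Tier-2 ≥ 1/100; Tier-3 ≥ 1/200 plus X-linked; Tier-4
everything), assigned from *observed* carrier frequencies at the chosen
threshold; tier metrics restrict both the at-risk gene sets and the
diagnosis matching to the tier's genes, so nesting implies monotone
metrics.  Stratum comparisons use Welch's t-test and the two-tailed
Fisher exact test (significance at p ≤ 0.05), via scipy.

## SMN1 caller

Copy number is estimated from read counts at the three
paralog-differentiating positions.  The scale factor is the sample's
SMN-to-control depth ratio normalized by the run median — robust while
carriers are a run minority — so four total SMN copies is the run norm:
`est_total = 4f`, `est_SMN1 = 4f·p̄`, and the carrier boundary
`f·p̄ < 1/3` is the midpoint between one and two SMN1 copies.  The
per-position proportions are averaged unweighted (a read-count-weighted
mean is a config switch), and `p̄` is multiplied by `f` rather than
rescaling per position — both choices are undetermined by the
normalization idea itself and are fixed here for determinism.  On
noiseless counts proportional to the true copy state, calls are exact
for all states with c1 ≤ 3 when the run median is a 2+2 sample, and
scale-invariant under global depth changes.  The PCA + 2-means step is
an automatable, deterministic stand-in for visual candidate triage.
Silent (2+0) carriers are out of scope.

## F_ROH and consanguinity

Segments are merged per chromosome before the strict > 5 Mb threshold
(callers may fragment a run), summed over autosomes and divided by
2691 Mb (GRCh37).  Degree bins sit at the geometric midpoints of the
expected autozygosity ladder — ≥ 0.177 first, ≥ 0.0884 second,
≥ 0.0442 third degree — with an uncertain band [0.022, 0.0442) below
and non-consanguineous beneath it; the bins are config-overridable.
Couple status is classified from the **child's** F_ROH (parental
relatedness manifests as child autozygosity); a parental fallback
exists for childless couples.

## Synthetic cohorts and the reference fixture

The generator draws per-gene pathogenic allele frequencies log-uniform
on [5·10⁻⁴, 0.02] (the band where recessive carrier frequencies of
individually rare disease genes live), Hardy-Weinberg genotypes,
consanguineous allele sharing with probability ≈ 4F (the chance a
partner carries a given allele identical by descent, capped at 1),
Mendelian transmission, stratum-specific de novo dominant diagnosis
rates (0.50 outbred, 0.06 consanguineous — the reported NDD aetiology
split), binomial SMN read counts and exact-F ROH segments.  Truth
tables are exact, so at-risk recall is asserted at 100 % and sampled
quantities within binomial error.  What the generator does **not**
emulate: linkage between variants, annotation errors, coverage
variation, population structure — so passing tests demonstrate correct
arithmetic and logic under the stated model, not robustness to messy
real-world annotation.

The deterministic fixture encodes the study conditions as data: 350
trios in 23/293/34 consanguinity strata, 52 autosomal at-risk couples
(13 consanguineous, two of them dependent solely on modelled missense
variants), 20 X-linked carrier mothers, 27 matched transmissions (10/15/2
by stratum; 4 dependent on zero-star ClinVar records in CRADD, DPYS,
TRAPPC9, UFC1), 16 filter false negatives carrying 17 sub-threshold
missense alleles, 2 + 3 + 3 intrinsically undetectable diagnoses, 191
HFE hypomorphic carriers, 13 SMN1 carriers, 2 FMR1 premutation mothers,
and a per-individual qualifying-variant distribution with 25 zeros,
median 4 and maximum 12.  Counts only implied by published percentages
are back-solved from the percentage and its denominator; the analysis
recomputes everything from the constructed calls.

## Problem sizes and numerics

Default test/acceptance sizes: the 700-sample fixture (< 5 s end to
end), 120–200-couple synthetic cohorts for property suites, 1000
samples at 80× for the SMN1 performance check, 10,000 couples for the
Hardy–Weinberg recovery — sizes chosen so each check is statistically
meaningful at interactive runtimes.  All thresholds are closed on the
qualifying side exactly as stated (≥ 12, < 28 %, ≥ 75 %, ≥ 0.85, ≥ 20,
< 1/3, > 5 Mb strict); ties therefore never depend on float noise at
the printed precision.  Degenerate inputs (empty cohorts, zero-read SMN
positions, single-sample runs, zero-variance PCA features, empty
contingency margins) return explicit no-call/NaN results with warnings
rather than raising.

## Known limitations

No variant normalization beyond exact key matching; no CNV calling from
sequence data (CNV diagnoses enter only through the trio table); the
X-linked virtual formula is reported as displayed (see above); ancestry
estimation and structural missense modelling are out of scope; the
published ClinVar-scale missense benchmark (97 % specificity / 24 %
sensitivity) is replaced by a synthetic confusion-matrix property, as
the labelled ClinVar corpus is not shipped.
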