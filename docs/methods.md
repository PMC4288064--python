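# Methods

## Evidence grading

Each association candidate is scored on six criteria, every score in
{1, 2, 3}:

| criterion | 1 | 2 | 3 |
|---|---|---|---|
| citations of the source article | 1–15 | 16–50 | > 50 |
| study type × author count | research, < 10 authors | research 10–34, or meta-analysis < 7 | research ≥ 35, or meta-analysis ≥ 7 |
| study population | other races | mixed | Caucasian |
| sample size, min(cases, controls) | < 100 | 100–1000 | > 1000 |
| PubMed articles on the SNP–disease link | < 7 | 7–19 | ≥ 20 |
| cumulative models containing the SNP allele | none | 1–2 | ≥ 3 |

The *evidence degree* is the arithmetic mean of the six scores (range
[1, 3]), banded **weak** < 1.5 ≤ **moderate** < 2.3 ≤ **strong**. The
published band boundaries are typographically inconsistent; the half-open,
lower-inclusive reading used here is the only one that partitions [1, 3],
and both edges are covered by explicit tests. Two published bins leave a
single integer unassigned (sample size exactly 1000; PubMed count exactly
19); both are assigned to the middle bin, extending it rather than creating
a gap. "Sample size (each of case and controls)" is read conservatively as
min(cases, controls): both arms must clear a bin. Missing metadata scores
the lowest bin and the record is flagged (`imputed_fields`) rather than
dropped.

The *impact category* bands the odds ratio: strong ≥ 2.50, moderate
[2.00, 2.50), weak < 2.00.

## Redundancy resolution

Conflicting reports for one (rsID, forward allele) are resolved by
lexicographic preference: population (Caucasian > mixed > other, matching
the ancestry of the intended subjects), study type (meta-analysis >
research), citation count (descending), odds ratio (descending). Ties
surviving all four phases break on confidence-interval width (ascending,
narrower = more informative) and finally the source tag, so KB builds are
order-independent and reproducible; a permutation-invariance property test
enforces this. Before grouping, rsIDs are pushed through the dbSNP merge
map (iterated lookup, cycle-checked) and reverse-strand alleles are
complemented to the forward strand. A/T and C/G sites are inherently
strand-ambiguous under complementation; the per-record `reported_strand`
metadata is trusted, which is a documented limitation.

## Genotype handling

Raw files are matched by rsID only; positions are carried as opaque
metadata, so build-36 and build-37 files behave identically. `--` no-calls
at KB SNPs are distinguished from SNPs absent from the chip: both are
excluded from every score, but they are reported separately because model
abstention semantics depend on the difference. Duplicate rsID lines keep the
first occurrence (with a warning); vendor-internal `i`-prefixed IDs are
parsed and retained but never match the KB; D/I (indel) calls score as
no-risk with a warning.

Hemizygous calls — single-letter genotypes on X/Y/MT, e.g. males at the
X-linked rs5945572 — satisfy both dominant and recessive panel requirements
(every allele copy present is the risk allele) but weight 1 in additive
scores, since a single allele cannot count twice. This convention is
documented here because published panel evaluations include X-linked SNPs in
male subjects without comment.

## Independent association scores

Four scores summarize the knowledge-base hits: SNP count and evidence-impact
degree, each dominant (every hit weighs 1) and additive (homozygous-risk
hits weigh 2). The per-SNP evidence-impact term combines the evidence rank
and impact rank (weak/moderate/strong → 1/2/3); the combination operator is
not specified by the grading scheme's source, so the **product** (range 1–9)
is the default — it preserves the intent that one strong/strong SNP outweighs
several weak/weak SNPs — with the sum available via `combine="sum"`. Neither
operator is asserted to be the historical one.

## Cumulative models

Per-SNP impact: dominant SNPs score 1 for heterozygous or homozygous risk;
recessive SNPs only for homozygous risk; a positive family health history
adds 1 on supporting panels and switches the lookup to the with-FHH column.
Unknown family history evaluates the without-FHH column and flags the
result — positivity is never imputed. Model files are validated at load:
the reference table must cover every impact level 0..n (+1 with FHH) and
its ORs must be non-decreasing, so lookup can never fall off the table on
complete data.

Missing-data policy: the default **strict** mode returns *unknown* whenever
any panel SNP is unassayed or a no-call — an incomplete panel cannot index
the reference table honestly, and the three-way high / lower / unknown
verdict classification (OR ≥ 2.5 / OR < 2.5 / unknown) passes the
abstention through. The optional **bounds** mode instead scores missing
SNPs as 0 and 1 and reports the impact and OR brackets, for exploratory
use.

Of the six shipped panels only the five-SNP panel's reference table is
published; it is encoded verbatim (without-FHH ORs 1.00, 1.50, 1.96, 2.21,
4.47, 4.47 for impacts 0–5; with-FHH 1.00, 1.62, 2.07, 2.71, 4.76, 9.46,
9.46 for 0–6). The other five panels ship with their published SNP grids
but synthetic stand-in tables (35 % OR growth per impact unit, monotone by
construction) flagged `synthetic_reference: true`; conclusions should not
be drawn from their absolute ORs.

## Branch-set models

A branch is a conjunction of requirements — exact genotype
(order-insensitive), allele presence, or a clinical field value over
bmi_class / smoking / alcohol. Matching is three-valued per branch:
*matched* (all requirements satisfied), *contradicted* (at least one
definitively violated by available data), *indeterminate* (some requirement
touches missing data, none violated). The model verdict is *at risk* iff
any branch matched, *risk free* iff all branches are contradicted, else
*indeterminate*. Tri-state clinical fields default to unknown, never
negative, precisely so that absence of a smoking datum yields
indeterminacy, not a spurious risk-free verdict. Published model
performance metrics (accuracy/precision/recall) are display metadata only;
the models' training is out of scope, and the shipped branch sets are
synthetic stand-ins with the published shape.

## Polygenic scores

With cᵢ the risk-allele copies of hit i (het/hemizygous 1, hom 2) and ORᵢ
its allelic odds ratio: count = Σ cᵢ; log-odds = Σ cᵢ ln ORᵢ;
multiplicative OR = Π ORᵢ^cᵢ = exp(log-odds) — an algebraic identity the
suite checks to 1e-12 over random hit sets. Per-genotype weighting (every
hit once) is a switch. The multiplicative lifetime risk requires an
explicit average population risk in (0, 1) — there is no defensible
universal default — and is capped at 1.0 with a flag when the product
exceeds certainty, since odds-ratio multiplication under an independence
assumption is known to overshoot.

## Synthetic data

The generator plants chosen zygosities (hom / het / no_risk / absent /
no-call) at KB SNPs and pads with background markers whose rsIDs are
disjoint from the KB, writing standard raw-format files; identical seeds
give byte-identical files. It emulates the *structure* of consumer raw
data — no-calls, off-chip SNPs, irrelevant background markers — but not
linkage disequilibrium, allele-frequency spectra, chip-specific marker
panels or population structure; passing tests therefore demonstrate
correctness of the bookkeeping and arithmetic on known ground truth, not
calibration of risk estimates on real genomes. Cohort-scale checks in the
test suite use up to a few hundred randomized KBs/genomes of ≤ 20 SNPs and
≤ 30 background markers each, which exercises every code path while keeping
the whole suite under a few seconds.

## Numerical and degenerate-input choices

Category boundaries are closed on the left everywhere (1.5, 2.3 for
evidence; 2.00, 2.50 for impact; 2.5 for the high-risk verdict), tested at
the boundary values. Empty hit sets are valid and score 0 / 0.0 / OR 1.0.
Empty raw files, cyclic merge maps, non-positive ORs, reference-table gaps
and duplicate branch IDs raise validation errors at load rather than
propagating. Report assembly reuses a single hit-extraction pass so the
categorical grid, independent panel and polygenic scores always describe
the same hits (asserted by count equality in tests), and reports omit the
timestamp by default so identical inputs produce byte-identical output.
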