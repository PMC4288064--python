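# snprisk

Personal prostate-cancer risk assessment from direct-to-consumer genotype
files, backed by a curated, evidence-graded knowledge base of SNP–disease
associations.

GWAS repositories report many — often conflicting — odds ratios for the same
SNP allele, and raw consumer genotype files (23andMe-style TSV) carry hundreds
of thousands of markers of which only a handful are clinically relevant to any
one disease. `snprisk` addresses both ends of that gap for clinicians and
bioinformaticians building risk-reporting pipelines:

* **Knowledge-base curation** — candidate associations (rsID, risk allele,
  OR, study metadata) are graded on six 1–3 evidence sub-scores (citations,
  study type × authors, race/ethnicity, sample size, literature volume,
  cumulative-model membership); the *evidence degree* is their mean, banded
  weak < 1.5 ≤ moderate < 2.3 ≤ strong. The OR itself is banded into an
  *impact category* (strong ≥ 2.50, moderate ≥ 2.00, weak < 2.00). Redundant
  reports for one SNP allele are resolved by a four-phase preference
  (Caucasian > mixed > other population; meta-analysis > single study; more
  citations; higher OR), after dbSNP merge-chain resolution and
  forward-strand allele normalization.
* **Independent association scores** — a genome's knowledge-base hits are
  summarized four ways: SNP count and evidence×impact rank sum, each under a
  dominant (any carriage = 1) and an additive (homozygote = 2) weighting.
* **Cumulative models** — published small SNP panels (e.g. the five-SNP
  panel with dominant rs1447295-A, rs16901979-A, rs6983267-G and recessive
  rs1859962-G, rs4430796-A). Each panel SNP contributes one impact unit under
  its genetic model; positive family health history adds one more on panels
  that support it; the total impact indexes the published odds-ratio
  reference table. An incomplete panel (off-chip SNP or no-call) abstains
  with verdict *unknown* rather than guessing (a bounds mode brackets the
  impact instead).
* **Branch-set models** — decision-tree-derived disjunctions of conjunctive
  genotype(+clinical) requirements, matched three-valuedly: *at risk* (some
  branch fully satisfied), *risk free* (every branch contradicted),
  *indeterminate* (missing data blocks a decision).
* **Polygenic scores** — count of risk alleles; log-odds `Σ cᵢ·ln ORᵢ`;
  multiplicative OR `Π ORᵢ^cᵢ` (cᵢ = allele copies), optionally times an
  average population risk for a lifetime-risk estimate.

## Worked example

Build a tiny demonstration KB over the five-SNP panel, synthesize a raw
genotype file homozygous for every risk allele, and assess it with a positive
family history:

```python
from snprisk import AssociationCandidate, build_kb, save_kb, load_builtin_models
from snprisk.genotype_io import generate_synthetic_genome, save_genome

zheng = {m.name: m for m in load_builtin_models()}["5-SNP_Zheng"]
cands = [AssociationCandidate(
             rsid=s.rsid, risk_allele=s.risk_allele, odds_ratio=1.3,
             race_group="caucasian", study_type="meta_analysis",
             citation_count=60, author_count=12, sample_size_cases=2000,
             sample_size_controls=2000, pubmed_article_count=10,
             cumulative_model_count=2, source="demo")
         for s in zheng.snps]
kb = build_kb(cands, version="demo")
save_kb(kb, "kb.json")
genome = generate_synthetic_genome(
    kb, {a.rsid: "hom" for a in kb.associations},
    n_background=20, seed=7, subject_id="demo")
save_genome(genome, "demo.txt")
```

```sh
snprisk assess --genome demo.txt --kb kb.json \
    --fhh positive --avg-population-risk 0.125 --format text
```

prints (abridged):

```
Independent scores
  SNP count        dominant      5   additive     10
  evidence-impact  dominant   15.0   additive   30.0

Cumulative models
  5-SNP_Zheng      impact 6  OR 9.46  [high]
  17-SNP_Helfand   unknown (12 SNP(s) not on chip)

Polygenic scores
  risk-allele count   10
  log-odds            2.6236
  multiplicative OR   13.7858
  lifetime risk       1.0000  (capped at 1.0)
```

Reading it: all five panel SNPs are homozygous risk, so the dominant SNP
count is 5 and the additive count 10; every hit is evidence-strong
(rank 3) × impact-weak (rank 1), giving 5·3 = 15 and, with homozygote
weights, 30. The five-SNP panel scores 5 impact units plus 1 for family
history = 6, whose with-FHH reference-table entry is OR 9.46 — the *high*
(OR ≥ 2.5) band. The 17-SNP panel abstains because this toy genotype file
does not assay 12 of its SNPs. The multiplicative polygenic OR is
1.3¹⁰ ≈ 13.79 = exp(2.6236), and 13.79 × 0.125 exceeds 1, so the lifetime
risk is reported capped.

The other CLI verbs: `snprisk build-kb` (grade + deduplicate a candidate
file, write canonical JSON and a TSV export, print the impact×evidence
distribution), `snprisk simulate` (seeded cohorts of synthetic raw files
plus a planted-truth manifest) and `snprisk cohort-summary` (tally
cumulative-model verdicts over a set of reports).

## Scope notes

Only the five-SNP panel's odds-ratio reference table is published in full;
the other five shipped panels carry their published SNP/genetic-model grids
but synthetic monotone reference tables, flagged `synthetic_reference` in the
model file. The shipped branch-set models are likewise small synthetic
stand-ins with the published shape. VCF input, imputation, build liftover and
indel genotypes are out of scope; matching is by rsID on forward-strand
alleles.
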