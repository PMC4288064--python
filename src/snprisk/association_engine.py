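"""Matching personal genomes against the knowledge base; independent scores.

A knowledge-base SNP found in a genome with at least one risk allele becomes
a *personal association hit* (the genotype record is a clinically relevant
SNP, CR-SNP).  Four whole-genome summary scores are computed over the hits:

* SNP count, dominant — number of hits (any risk-allele carriage counts 1);
* SNP count, additive — homozygous-risk hits weighted 2, others 1;
* evidence-impact, dominant — sum over hits of evidence_rank x impact_rank
  (ranks weak=1, moderate=2, strong=3);
* evidence-impact, additive — the same with the zygosity weight applied.

The evidence-impact combination operator defaults to the rank product (a
strong/strong SNP contributes 9, outweighing several weak/weak SNPs); the
rank sum is available via ``combine="sum"``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Literal, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field

from .genotype_io import (
    RISK_ZYGOSITIES,
    PersonalGenome,
    Zygosity,
    genotype_zygosity,
    zygosity_weight,
)
from .knowledge_base import (
    Association,
    EvidenceCategory,
    ImpactCategory,
    KnowledgeBase,
    category_rank,
)

__all__ = [
    "PersonalAssociationHit",
    "ExtractionResult",
    "IndependentScorePanel",
    "CategoricalSummary",
    "extract_hits",
    "score_snp_count",
    "score_evidence_impact",
    "categorical_summary",
    "score_panel",
    "hits_to_dataframe",
    "export_hits",
]

CATEGORIES = ("strong", "moderate", "weak")


class PersonalAssociationHit(BaseModel):
    association: Association
    zygosity: Zygosity

    @property
    def zygosity_weight(self) -> int:
        return zygosity_weight(self.zygosity)

    @property
    def allele_count(self) -> int:
        """Risk-allele copies carried (hom=2, het/hemizygous=1)."""
        return self.zygosity_weight


class ExtractionResult(BaseModel):
    """Hits plus the assay-coverage bookkeeping Table-9-style reporting needs.

    ``nocall_rsids`` (assayed but uncalled) and ``missing_rsids`` (not on the
    chip) are reported separately: both exclude a SNP from every score, but
    they are different statements about the raw data.
    """

    hits: list[PersonalAssociationHit]
    no_risk_rsids: list[str]
    nocall_rsids: list[str]
    missing_rsids: list[str]

    @property
    def n_kb_snps_assayed(self) -> int:
        return len(self.hits) + len(self.no_risk_rsids) + len(self.nocall_rsids)

    @property
    def n_kb_snps_missing(self) -> int:
        return len(self.missing_rsids)


class IndependentScorePanel(BaseModel):
    snp_count_dominant: int = Field(ge=0)
    snp_count_additive: int = Field(ge=0)
    evidence_impact_dominant: float = Field(ge=0)
    evidence_impact_additive: float = Field(ge=0)
    n_kb_snps_assayed: int = Field(ge=0)
    n_kb_snps_missing: int = Field(ge=0)


class CategoricalSummary(BaseModel):
    """3x3 hit counts indexed by (impact category, evidence category)."""

    counts: dict[str, dict[str, int]]
    total: int

    @classmethod
    def empty(cls) -> "CategoricalSummary":
        return cls(
            counts={i: {e: 0 for e in CATEGORIES} for i in CATEGORIES}, total=0
        )

    def cell(
        self,
        impact: Union[ImpactCategory, str],
        evidence: Union[EvidenceCategory, str],
    ) -> int:
        return self.counts[str(getattr(impact, "value", impact))][
            str(getattr(evidence, "value", evidence))
        ]


def extract_hits(genome: PersonalGenome, kb: KnowledgeBase) -> ExtractionResult:
    """Match every KB association against the genome's genotype calls."""
    hits: list[PersonalAssociationHit] = []
    no_risk: list[str] = []
    nocalls: list[str] = []
    missing: list[str] = []
    for assoc in kb.associations:
        record = genome.records.get(assoc.rsid)
        if record is None:
            missing.append(assoc.rsid)
            continue
        zygosity = genotype_zygosity(record, assoc.risk_allele)
        if zygosity is Zygosity.NOCALL:
            nocalls.append(assoc.rsid)
        elif zygosity in RISK_ZYGOSITIES:
            hits.append(PersonalAssociationHit(association=assoc, zygosity=zygosity))
        else:
            no_risk.append(assoc.rsid)
    return ExtractionResult(
        hits=hits, no_risk_rsids=no_risk, nocall_rsids=nocalls, missing_rsids=missing
    )


Mode = Literal["dominant", "additive"]


def _weight(hit: PersonalAssociationHit, mode: Mode) -> int:
    if mode == "dominant":
        return 1
    if mode == "additive":
        return hit.zygosity_weight
    raise ValueError(f"unknown mode {mode!r}")


def score_snp_count(hits: Sequence[PersonalAssociationHit], mode: Mode) -> int:
    """Count of risk SNPs; additive mode weights homozygotes twice."""
    return sum(_weight(h, mode) for h in hits)


def score_evidence_impact(
    hits: Sequence[PersonalAssociationHit],
    mode: Mode,
    combine: Literal["product", "sum"] = "product",
) -> float:
    """Evidence-impact degree summed over hits.

    Per-SNP contribution combines the evidence rank and impact rank
    (weak/moderate/strong → 1/2/3); additive mode multiplies by the zygosity
    weight.
    """
    total = 0.0
    for h in hits:
        ev = category_rank(h.association.evidence_category)
        im = category_rank(h.association.impact_category)
        base = ev * im if combine == "product" else ev + im
        total += base * _weight(h, mode)
    return total


def categorical_summary(
    hits: Sequence[PersonalAssociationHit],
) -> CategoricalSummary:
    """Tally hits into the 3x3 impact-by-evidence grid."""
    summary = CategoricalSummary.empty()
    for h in hits:
        summary.counts[h.association.impact_category.value][
            h.association.evidence_category.value
        ] += 1
    summary.total = len(hits)
    return summary


def score_panel(
    extraction: ExtractionResult,
    combine: Literal["product", "sum"] = "product",
) -> IndependentScorePanel:
    """All four independent scores plus assay-coverage counts."""
    hits = extraction.hits
    return IndependentScorePanel(
        snp_count_dominant=score_snp_count(hits, "dominant"),
        snp_count_additive=score_snp_count(hits, "additive"),
        evidence_impact_dominant=score_evidence_impact(hits, "dominant", combine),
        evidence_impact_additive=score_evidence_impact(hits, "additive", combine),
        n_kb_snps_assayed=extraction.n_kb_snps_assayed,
        n_kb_snps_missing=extraction.n_kb_snps_missing,
    )


def hits_to_dataframe(hits: Sequence[PersonalAssociationHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        a = h.association
        rows.append(
            {
                "rsid": a.rsid,
                "risk_allele": a.risk_allele,
                "zygosity": h.zygosity.value,
                "odds_ratio": a.odds_ratio,
                "evidence_category": a.evidence_category.value,
                "impact_category": a.impact_category.value,
                "contribution": category_rank(a.evidence_category)
                * category_rank(a.impact_category)
                * h.zygosity_weight,
            }
        )
    columns = [
        "rsid", "risk_allele", "zygosity", "odds_ratio",
        "evidence_category", "impact_category", "contribution",
    ]
    return pd.DataFrame(rows, columns=columns)


def export_hits(
    hits: Sequence[PersonalAssociationHit],
    path: Union[str, Path, IO[str]],
    fmt: Literal["tsv", "json"] = "tsv",
) -> None:
    df = hits_to_dataframe(hits)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        payload = df.to_dict(orient="records")
        text = json.dumps(payload, indent=2) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            Path(path).write_text(text, encoding="utf-8")
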