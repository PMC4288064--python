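"""Curated SNP–disease association knowledge base.

Association candidates harvested from GWAS repositories come with study
metadata (race group, study type, citations, sample sizes ...). This module
grades each candidate's evidence quality on six 1–3 sub-scores, categorizes
the magnitude of impact from the odds ratio, resolves redundant candidates
for the same SNP allele through a four-phase selection, normalizes alleles to
the forward strand, follows dbSNP rsID merge chains, and serializes the
resulting knowledge base to JSON (canonical) and TSV (flat export).
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "RaceGroup",
    "StudyType",
    "Strand",
    "EvidenceCategory",
    "ImpactCategory",
    "AssociationCandidate",
    "EvidenceScores",
    "Association",
    "KnowledgeBase",
    "score_evidence",
    "categorize_evidence",
    "compute_evidence_degree",
    "categorize_impact",
    "select_association",
    "normalize_allele",
    "complement",
    "resolve_merged_rsid",
    "build_kb",
    "grade_candidate",
    "load_kb",
    "save_kb",
    "export_kb_tsv",
    "load_merge_map",
    "load_candidates",
]

NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Evidence-category cut points on the 1–3 degree scale: weak < 1.5 <= moderate
# < 2.3 <= strong.  The published table row is typographically inconsistent;
# this half-open reading is the only one that partitions [1, 3].
EVIDENCE_MODERATE_MIN = 1.5
EVIDENCE_STRONG_MIN = 2.3

# Impact-category cut points on the odds-ratio scale.
IMPACT_STRONG_MIN = 2.50
IMPACT_MODERATE_MIN = 2.00


class RaceGroup(str, Enum):
    CAUCASIAN = "caucasian"
    MIXED = "mixed"
    OTHER = "other"


class StudyType(str, Enum):
    META_ANALYSIS = "meta_analysis"
    RESEARCH = "research"


class Strand(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


class EvidenceCategory(str, Enum):
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"


class ImpactCategory(str, Enum):
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"


_CATEGORY_RANK = {"weak": 1, "moderate": 2, "strong": 3}


def category_rank(category: Union[EvidenceCategory, ImpactCategory, str]) -> int:
    """Numeric rank of a weak/moderate/strong category (1/2/3)."""
    return _CATEGORY_RANK[str(getattr(category, "value", category))]


class AssociationCandidate(BaseModel):
    """One literature report of a SNP-allele association with disease risk.

    ``risk_allele`` is interpreted on ``reported_strand``; candidates on the
    reverse strand are complemented to the forward strand during KB assembly.
    Optional metadata left as ``None`` is imputed to the lowest evidence bin
    and the record flagged.
    """

    rsid: str
    risk_allele: str
    odds_ratio: float = Field(gt=0)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    race_group: RaceGroup = RaceGroup.OTHER
    study_type: StudyType = StudyType.RESEARCH
    citation_count: Optional[int] = Field(default=None, ge=0)
    author_count: Optional[int] = Field(default=None, ge=1)
    sample_size_cases: Optional[int] = Field(default=None, ge=0)
    sample_size_controls: Optional[int] = Field(default=None, ge=0)
    pubmed_article_count: Optional[int] = Field(default=None, ge=0)
    cumulative_model_count: Optional[int] = Field(default=None, ge=0)
    source: str = ""
    reported_strand: Strand = Strand.FORWARD

    @field_validator("rsid")
    @classmethod
    def _check_rsid(cls, v: str) -> str:
        if not v.startswith("rs") or not v[2:].isdigit():
            raise ValueError(f"not a dbSNP rsID: {v!r}")
        return v

    @field_validator("risk_allele")
    @classmethod
    def _check_allele(cls, v: str) -> str:
        v = v.upper()
        if v not in NUCLEOTIDES:
            raise ValueError(f"risk allele must be one of A/C/G/T, got {v!r}")
        return v

    @model_validator(mode="after")
    def _check_ci(self) -> "AssociationCandidate":
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.odds_ratio <= self.ci_high):
                raise ValueError(
                    f"odds ratio {self.odds_ratio} outside its CI "
                    f"[{self.ci_low}, {self.ci_high}]"
                )
        return self

    @property
    def forward_allele(self) -> str:
        return normalize_allele(self.risk_allele, self.reported_strand)

    @property
    def ci_width(self) -> float:
        if self.ci_low is None or self.ci_high is None:
            return float("inf")
        return self.ci_high - self.ci_low


class EvidenceScores(BaseModel):
    """Six 1–3 sub-scores whose mean is the evidence degree."""

    citation_score: int = Field(ge=1, le=3)
    study_score: int = Field(ge=1, le=3)
    race_score: int = Field(ge=1, le=3)
    sample_score: int = Field(ge=1, le=3)
    pubmed_score: int = Field(ge=1, le=3)
    model_score: int = Field(ge=1, le=3)
    imputed_fields: tuple[str, ...] = ()

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.citation_score,
            self.study_score,
            self.race_score,
            self.sample_score,
            self.pubmed_score,
            self.model_score,
        )


class Association(BaseModel):
    """A graded, deduplicated KB entry: forward-strand allele, OR, grades."""

    rsid: str
    risk_allele: str
    odds_ratio: float = Field(gt=0)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    evidence_scores: EvidenceScores
    evidence_degree: float = Field(ge=1.0, le=3.0)
    evidence_category: EvidenceCategory
    impact_category: ImpactCategory
    source: str = ""

    @model_validator(mode="after")
    def _check_consistency(self) -> "Association":
        degree = sum(self.evidence_scores.as_tuple()) / 6
        if abs(degree - self.evidence_degree) > 1e-9:
            raise ValueError("evidence_degree is not the mean of the sub-scores")
        return self


class KnowledgeBase(BaseModel):
    disease_code: str = "C61"  # ICD-10: malignant neoplasm of prostate
    version: str = "0"
    associations: list[Association] = ()

    @model_validator(mode="after")
    def _check_unique(self) -> "KnowledgeBase":
        keys = [(a.rsid, a.risk_allele) for a in self.associations]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (rsid, risk_allele) in knowledge base")
        return self

    def __len__(self) -> int:
        return len(self.associations)

    def by_rsid(self) -> dict[str, Association]:
        """rsID -> association lookup (one risk allele per rsID post-selection)."""
        return {a.rsid: a for a in self.associations}


# ---------------------------------------------------------------------------
# Evidence grading


def _bin_citations(n: int) -> int:
    # (1-15)=1, (16-50)=2, (>50)=3
    if n <= 15:
        return 1
    if n <= 50:
        return 2
    return 3


def _bin_study(study_type: StudyType, authors: int) -> int:
    if study_type is StudyType.META_ANALYSIS:
        return 3 if authors >= 7 else 2
    if authors < 10:
        return 1
    if authors < 35:
        return 2
    return 3


_RACE_SCORE = {RaceGroup.OTHER: 1, RaceGroup.MIXED: 2, RaceGroup.CAUCASIAN: 3}


def _bin_sample(n: int) -> int:
    # (<100)=1; (>=100 and <=1000)=2; (>1000)=3 — 1000 assigned to the middle
    # bin, closing the gap the published criteria leave open.
    if n < 100:
        return 1
    if n <= 1000:
        return 2
    return 3


def _bin_pubmed(n: int) -> int:
    # (<7)=1; (>=7 and <=19)=2; (>=20)=3 — 19 assigned to the middle bin.
    if n < 7:
        return 1
    if n <= 19:
        return 2
    return 3


def _bin_models(n: int) -> int:
    if n == 0:
        return 1
    if n < 3:
        return 2
    return 3


def score_evidence(candidate: AssociationCandidate) -> EvidenceScores:
    """Assign the six evidence sub-scores for one candidate.

    Sample size is scored on ``min(cases, controls)`` so that both study arms
    must clear a bin.  Missing metadata scores the lowest bin (1) and the
    field is recorded in ``imputed_fields``.
    """
    imputed: list[str] = []

    def _or_impute(value, field: str, floor):
        if value is None:
            imputed.append(field)
            return floor
        return value

    citations = _or_impute(candidate.citation_count, "citation_count", 1)
    authors = _or_impute(candidate.author_count, "author_count", 1)
    cases = _or_impute(candidate.sample_size_cases, "sample_size_cases", 0)
    controls = _or_impute(candidate.sample_size_controls, "sample_size_controls", 0)
    articles = _or_impute(candidate.pubmed_article_count, "pubmed_article_count", 0)
    models = _or_impute(candidate.cumulative_model_count, "cumulative_model_count", 0)

    return EvidenceScores(
        citation_score=_bin_citations(citations),
        study_score=_bin_study(candidate.study_type, authors),
        race_score=_RACE_SCORE[candidate.race_group],
        sample_score=_bin_sample(min(cases, controls)),
        pubmed_score=_bin_pubmed(articles),
        model_score=_bin_models(models),
        imputed_fields=tuple(imputed),
    )


def categorize_evidence(degree: float) -> EvidenceCategory:
    """Category of an evidence degree: weak < 1.5 <= moderate < 2.3 <= strong."""
    if degree < EVIDENCE_MODERATE_MIN:
        return EvidenceCategory.WEAK
    if degree < EVIDENCE_STRONG_MIN:
        return EvidenceCategory.MODERATE
    return EvidenceCategory.STRONG


def compute_evidence_degree(
    scores: EvidenceScores,
) -> tuple[float, EvidenceCategory]:
    """Evidence degree = mean of the six sub-scores, categorized."""
    degree = sum(scores.as_tuple()) / 6
    return degree, categorize_evidence(degree)


def categorize_impact(odds_ratio: float) -> ImpactCategory:
    """Magnitude of impact from the OR: strong >=2.50, moderate [2.00, 2.50), weak <2.00."""
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    if odds_ratio >= IMPACT_STRONG_MIN:
        return ImpactCategory.STRONG
    if odds_ratio >= IMPACT_MODERATE_MIN:
        return ImpactCategory.MODERATE
    return ImpactCategory.WEAK


# ---------------------------------------------------------------------------
# Redundancy resolution

_RACE_RANK = {RaceGroup.CAUCASIAN: 2, RaceGroup.MIXED: 1, RaceGroup.OTHER: 0}
_STUDY_RANK = {StudyType.META_ANALYSIS: 1, StudyType.RESEARCH: 0}


def _selection_key(c: AssociationCandidate):
    # Four published phases, then two deterministic tie-breaks (narrower CI,
    # then source tag) so rebuilds are reproducible.
    return (
        -_RACE_RANK[c.race_group],
        -_STUDY_RANK[c.study_type],
        -(c.citation_count or 0),
        -c.odds_ratio,
        c.ci_width,
        c.source,
    )


def select_association(
    candidates: Iterable[AssociationCandidate],
) -> AssociationCandidate:
    """Resolve redundant reports of one SNP allele to a single candidate.

    Four-phase preference: Caucasian > mixed > other race; meta-analysis >
    research study; more citations; higher OR.  Residual ties break on CI
    width (ascending) then source tag, making the result order-independent.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to select from")
    keys = {(c.rsid, c.forward_allele) for c in candidates}
    if len(keys) > 1:
        raise ValueError(f"candidates span multiple SNP alleles: {sorted(keys)}")
    return min(candidates, key=_selection_key)


# ---------------------------------------------------------------------------
# Identifier normalization


def complement(allele: str) -> str:
    """Watson–Crick complement of a single nucleotide."""
    try:
        return _COMPLEMENT[allele.upper()]
    except KeyError:
        raise ValueError(f"not an unambiguous nucleotide: {allele!r}") from None


def normalize_allele(allele: str, reported_strand: Union[Strand, str]) -> str:
    """Express a reported risk allele on the forward genomic strand.

    Reverse-strand alleles are complemented; forward-strand input is returned
    unchanged.  A/T and C/G alleles are strand-ambiguous (the complement is
    the other allele of the pair), so the caller must trust
    ``reported_strand`` metadata; a warning is emitted for them.
    """
    allele = allele.upper()
    if allele not in NUCLEOTIDES:
        raise ValueError(f"not an unambiguous nucleotide: {allele!r}")
    strand = Strand(reported_strand)
    if strand is Strand.FORWARD:
        return allele
    return _COMPLEMENT[allele]


def resolve_merged_rsid(rsid: str, merge_map: Mapping[str, str]) -> str:
    """Follow dbSNP merge chains to the current identifier.

    dbSNP occasionally merges reference SNP IDs; an old ID then maps to a
    newer one, possibly through several hops.  IDs absent from the map are
    already current.  Raises on a cyclic map.
    """
    seen = {rsid}
    current = rsid
    while current in merge_map:
        current = merge_map[current]
        if current in seen:
            raise ValueError(f"cycle in rsID merge map involving {current}")
        seen.add(current)
    return current


# ---------------------------------------------------------------------------
# Assembly and serialization


def grade_candidate(candidate: AssociationCandidate) -> Association:
    """Grade one (already selected) candidate into a KB association."""
    scores = score_evidence(candidate)
    degree, evidence_cat = compute_evidence_degree(scores)
    return Association(
        rsid=candidate.rsid,
        risk_allele=candidate.forward_allele,
        odds_ratio=candidate.odds_ratio,
        ci_low=candidate.ci_low,
        ci_high=candidate.ci_high,
        evidence_scores=scores,
        evidence_degree=degree,
        evidence_category=evidence_cat,
        impact_category=categorize_impact(candidate.odds_ratio),
        source=candidate.source,
    )


def build_kb(
    candidates: Iterable[AssociationCandidate],
    merge_map: Optional[Mapping[str, str]] = None,
    disease_code: str = "C61",
    version: str = "0",
) -> KnowledgeBase:
    """Assemble a knowledge base: normalize IDs/alleles, deduplicate, grade.

    rsIDs are updated through ``merge_map`` and alleles flipped to the forward
    strand before grouping, so two reports of the same variant under an old ID
    or on opposite strands collapse into one group; each (rsid, allele) group
    is then resolved by :func:`select_association` and graded.
    """
    merge_map = merge_map or {}
    groups: dict[tuple[str, str], list[AssociationCandidate]] = {}
    for cand in candidates:
        resolved = resolve_merged_rsid(cand.rsid, merge_map)
        forward = cand.forward_allele
        if resolved != cand.rsid or forward != cand.risk_allele:
            cand = cand.model_copy(
                update={
                    "rsid": resolved,
                    "risk_allele": forward,
                    "reported_strand": Strand.FORWARD,
                }
            )
        groups.setdefault((cand.rsid, cand.risk_allele), []).append(cand)
    associations = [
        grade_candidate(select_association(group))
        for _, group in sorted(groups.items())
    ]
    return KnowledgeBase(
        disease_code=disease_code, version=version, associations=associations
    )


def save_kb(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    """Write the canonical JSON serialization."""
    Path(path).write_text(kb.model_dump_json(indent=2) + "\n", encoding="utf-8")


def load_kb(path: Union[str, Path]) -> KnowledgeBase:
    """Load and validate a canonical KB JSON file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return KnowledgeBase.model_validate(payload)


def export_kb_tsv(kb: KnowledgeBase, path: Union[str, Path, IO[str]]) -> None:
    """Flat one-row-per-association TSV export (header, UTF-8)."""
    rows = []
    for a in kb.associations:
        s = a.evidence_scores
        rows.append(
            {
                "rsid": a.rsid,
                "risk_allele": a.risk_allele,
                "odds_ratio": a.odds_ratio,
                "ci_low": a.ci_low,
                "ci_high": a.ci_high,
                "citation_score": s.citation_score,
                "study_score": s.study_score,
                "race_score": s.race_score,
                "sample_score": s.sample_score,
                "pubmed_score": s.pubmed_score,
                "model_score": s.model_score,
                "evidence_degree": a.evidence_degree,
                "evidence_category": a.evidence_category.value,
                "impact_category": a.impact_category.value,
                "source": a.source,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_merge_map(path: Union[str, Path]) -> dict[str, str]:
    """Read a two-column (old_rsid, current_rsid) TSV merge map."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["old", "current"], comment="#", dtype=str
    )
    return dict(zip(df["old"], df["current"]))


def load_candidates(path: Union[str, Path]) -> list[AssociationCandidate]:
    """Read association candidates from a JSON list or a TSV table."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        return [AssociationCandidate.model_validate(rec) for rec in payload]
    df = pd.read_csv(path, sep="\t", comment="#")
    records = df.where(pd.notna(df), None).to_dict(orient="records")
    out = []
    for i, rec in enumerate(records, start=2):  # header is line 1
        try:
            out.append(AssociationCandidate.model_validate(rec))
        except Exception as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return out
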