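"""Model-based risk assessment: cumulative, branch-set and polygenic models.

Cumulative models are small published SNP panels.  Each panel SNP contributes
one unit of *impact* under its genetic model — dominant (one or two risk
alleles suffice) or recessive (only homozygous risk counts) — and some panels
accept a positive family health history (FHH) of the disease as one further
impact unit.  The total impact indexes a published reference table of odds
ratios; the table is monotone in impact and complete over the impact range by
construction.

Branch-set (probabilistic) models are disjunctions of conjunctive
requirement sets derived from trained decision trees: a subject matching
every requirement on at least one branch is classified at risk.  With
incomplete genotype or clinical data a branch can be neither matched nor
contradicted, so the verdict is three-valued (at_risk / risk_free /
indeterminate).

Polygenic scores aggregate the independent association hits directly: the
count method totals risk-allele copies; the log-odds method sums allele
copies times ln(OR); the multiplicative model multiplies per-genotype ORs
and, given an average population risk, yields a lifetime-risk estimate.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

from pydantic import BaseModel, Field, model_validator

from .association_engine import PersonalAssociationHit
from .genotype_io import (
    ClinicalProfile,
    PersonalGenome,
    TriState,
    Zygosity,
    genotype_zygosity,
)
from .knowledge_base import NUCLEOTIDES

__all__ = [
    "GeneticModel",
    "ModelSnp",
    "ReferenceEntry",
    "CumulativeModel",
    "CumulativeResult",
    "RiskCategory",
    "SnpRequirement",
    "ClinicalRequirement",
    "Branch",
    "BranchSetModel",
    "BranchVerdict",
    "BranchMatchResult",
    "PolygenicScores",
    "evaluate_cumulative",
    "classify_cumulative",
    "match_branches",
    "polygenic_scores",
    "load_models",
    "save_models",
    "builtin_models_path",
    "load_builtin_models",
]

HIGH_RISK_OR_THRESHOLD = 2.5


class GeneticModel(str, Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class ModelSnp(BaseModel):
    rsid: str
    risk_allele: str
    genetic_model: GeneticModel

    @model_validator(mode="after")
    def _check_allele(self) -> "ModelSnp":
        if self.risk_allele not in NUCLEOTIDES:
            raise ValueError(f"risk allele must be A/C/G/T, got {self.risk_allele!r}")
        return self


class ReferenceEntry(BaseModel):
    odds_ratio: float = Field(gt=0)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def _validate_table(
    table: dict[int, ReferenceEntry], max_impact: int, label: str
) -> None:
    expected = set(range(max_impact + 1))
    got = set(table)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(
            f"{label}: reference table must cover impacts 0..{max_impact}"
            + (f"; missing {missing}" if missing else "")
            + (f"; unexpected {extra}" if extra else "")
        )
    ors = [table[i].odds_ratio for i in range(max_impact + 1)]
    if any(b < a for a, b in zip(ors, ors[1:])):
        raise ValueError(f"{label}: odds ratios must be non-decreasing in impact")


class CumulativeModel(BaseModel):
    """A published SNP panel with its impact → odds-ratio reference table.

    ``reference_table`` covers impacts 0..n_snps; when ``supports_fhh`` the
    ``reference_table_fhh`` column covers 0..n_snps+1 (family history adds
    one impact unit).
    """

    name: str
    snps: list[ModelSnp]
    supports_fhh: bool = False
    reference_table: dict[int, ReferenceEntry]
    reference_table_fhh: Optional[dict[int, ReferenceEntry]] = None
    synthetic_reference: bool = False
    notes: str = ""

    @model_validator(mode="after")
    def _validate(self) -> "CumulativeModel":
        if not self.snps:
            raise ValueError(f"{self.name}: model has no SNPs")
        seen = set()
        for snp in self.snps:
            if snp.rsid in seen:
                raise ValueError(f"{self.name}: duplicate SNP {snp.rsid}")
            seen.add(snp.rsid)
        _validate_table(self.reference_table, len(self.snps), f"{self.name} (without FHH)")
        if self.supports_fhh:
            if self.reference_table_fhh is None:
                raise ValueError(f"{self.name}: supports_fhh but no FHH reference table")
            _validate_table(
                self.reference_table_fhh, len(self.snps) + 1, f"{self.name} (with FHH)"
            )
        return self


class RiskCategory(str, Enum):
    HIGH = "high"       # OR >= 2.5
    LOWER = "lower"     # OR < 2.5
    UNKNOWN = "unknown"


class CumulativeResult(BaseModel):
    model_name: str
    status: Literal["evaluated", "unknown"]
    total_impact: Optional[int] = None
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    used_fhh_column: bool = False
    fhh_unknown: bool = False
    missing_snps: list[str] = []
    nocall_snps: list[str] = []
    impact_bounds: Optional[tuple[int, int]] = None
    odds_ratio_bounds: Optional[tuple[float, float]] = None

    @property
    def category(self) -> RiskCategory:
        return classify_cumulative(self)


def _snp_impact(zygosity: Zygosity, genetic_model: GeneticModel) -> int:
    """One unit of impact per risk SNP; recessive needs homozygosity.

    Hemizygous calls (single allele on X/Y/MT) carry the risk allele on every
    copy present and are treated as homozygous-equivalent here.
    """
    if genetic_model is GeneticModel.DOMINANT:
        risky = zygosity in (
            Zygosity.HOM_RISK, Zygosity.HET_RISK, Zygosity.HEMIZYGOUS_RISK
        )
    else:
        risky = zygosity in (Zygosity.HOM_RISK, Zygosity.HEMIZYGOUS_RISK)
    return int(risky)


def evaluate_cumulative(
    genome: PersonalGenome,
    model: CumulativeModel,
    fhh: Union[TriState, str] = TriState.UNKNOWN,
    mode: Literal["strict", "bounds"] = "strict",
) -> CumulativeResult:
    """Evaluate a genome against one cumulative model.

    Per-SNP impact: dominant SNPs score 1 for het or hom risk; recessive
    SNPs only for hom risk.  A positive family health history adds 1 on
    FHH-aware models and switches the lookup to the with-FHH column; unknown
    FHH evaluates the without-FHH column and flags the result.

    In ``strict`` mode (the default) any unassayed or no-call panel SNP makes
    the whole result ``unknown`` — an incomplete panel cannot index the
    reference table honestly.  ``bounds`` mode instead brackets the impact by
    scoring missing SNPs 0 and 1, reporting impact and OR bounds.
    """
    fhh = TriState(fhh)
    missing: list[str] = []
    nocalls: list[str] = []
    impact = 0
    for snp in model.snps:
        record = genome.records.get(snp.rsid)
        if record is None:
            missing.append(snp.rsid)
            continue
        zygosity = genotype_zygosity(record, snp.risk_allele)
        if zygosity is Zygosity.NOCALL:
            nocalls.append(snp.rsid)
            continue
        impact += _snp_impact(zygosity, snp.genetic_model)

    use_fhh_column = model.supports_fhh and fhh is TriState.POSITIVE
    fhh_bonus = 1 if use_fhh_column else 0
    table = model.reference_table_fhh if use_fhh_column else model.reference_table
    n_unresolved = len(missing) + len(nocalls)

    if n_unresolved and mode == "strict":
        return CumulativeResult(
            model_name=model.name,
            status="unknown",
            missing_snps=missing,
            nocall_snps=nocalls,
            used_fhh_column=use_fhh_column,
            fhh_unknown=fhh is TriState.UNKNOWN,
        )

    if n_unresolved:  # bounds mode
        lo, hi = impact + fhh_bonus, impact + n_unresolved + fhh_bonus
        return CumulativeResult(
            model_name=model.name,
            status="unknown",
            missing_snps=missing,
            nocall_snps=nocalls,
            used_fhh_column=use_fhh_column,
            fhh_unknown=fhh is TriState.UNKNOWN,
            impact_bounds=(lo, hi),
            odds_ratio_bounds=(table[lo].odds_ratio, table[hi].odds_ratio),
        )

    total = impact + fhh_bonus
    if total not in table:
        raise ValueError(
            f"{model.name}: impact {total} outside reference table"
        )
    entry = table[total]
    return CumulativeResult(
        model_name=model.name,
        status="evaluated",
        total_impact=total,
        odds_ratio=entry.odds_ratio,
        ci_low=entry.ci_low,
        ci_high=entry.ci_high,
        used_fhh_column=use_fhh_column,
        fhh_unknown=fhh is TriState.UNKNOWN,
    )


def classify_cumulative(result: CumulativeResult) -> RiskCategory:
    """Three-way summary: high (OR >= 2.5), lower (OR < 2.5), unknown."""
    if result.status == "unknown" or result.odds_ratio is None:
        return RiskCategory.UNKNOWN
    if result.odds_ratio >= HIGH_RISK_OR_THRESHOLD:
        return RiskCategory.HIGH
    return RiskCategory.LOWER


# ---------------------------------------------------------------------------
# Branch-set (probabilistic) models


class SnpRequirement(BaseModel):
    """Genotype requirement on one branch.

    ``genotype`` requires an exact (order-insensitive) genotype call;
    ``allele`` requires carriage of at least one copy of the allele.  Exactly
    one of the two must be given.
    """

    rsid: str
    genotype: Optional[str] = None
    allele: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "SnpRequirement":
        if (self.genotype is None) == (self.allele is None):
            raise ValueError(f"{self.rsid}: specify exactly one of genotype/allele")
        if self.allele is not None and self.allele not in NUCLEOTIDES:
            raise ValueError(f"{self.rsid}: allele must be A/C/G/T")
        if self.genotype is not None:
            g = self.genotype.upper()
            if not (1 <= len(g) <= 2 and set(g) <= NUCLEOTIDES):
                raise ValueError(f"{self.rsid}: malformed required genotype {g!r}")
        return self


CLINICAL_FIELDS = ("bmi_class", "smoking", "alcohol")


class ClinicalRequirement(BaseModel):
    field: str
    value: str

    @model_validator(mode="after")
    def _check(self) -> "ClinicalRequirement":
        if self.field not in CLINICAL_FIELDS:
            raise ValueError(
                f"unknown clinical field {self.field!r}; expected one of {CLINICAL_FIELDS}"
            )
        return self


class Branch(BaseModel):
    branch_id: str
    snp_requirements: list[SnpRequirement] = []
    clinical_requirements: list[ClinicalRequirement] = []

    @model_validator(mode="after")
    def _check(self) -> "Branch":
        if not self.snp_requirements and not self.clinical_requirements:
            raise ValueError(f"branch {self.branch_id} has no requirements")
        return self


class BranchSetModel(BaseModel):
    """A decision-tree-derived model: risk iff any branch fully matches.

    ``accuracy``/``precision``/``recall`` are the published performance of
    the source model, carried as display metadata only.
    """

    name: str
    branches: list[Branch]
    accuracy: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    synthetic_reference: bool = False
    notes: str = ""

    @model_validator(mode="after")
    def _check(self) -> "BranchSetModel":
        ids = [b.branch_id for b in self.branches]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.name}: duplicate branch ids")
        if not self.branches:
            raise ValueError(f"{self.name}: no branches")
        return self


class BranchVerdict(str, Enum):
    AT_RISK = "at_risk"
    RISK_FREE = "risk_free"
    INDETERMINATE = "indeterminate"


class BranchMatchResult(BaseModel):
    model_name: str
    verdict: BranchVerdict
    matched_branches: list[str]
    indeterminate_branches: list[str]
    contradicted_branches: list[str]


_SAT, _VIOLATED, _UNKNOWN = 1, -1, 0


def _check_snp_requirement(req: SnpRequirement, genome: PersonalGenome) -> int:
    record = genome.records.get(req.rsid)
    if record is None or record.is_nocall:
        return _UNKNOWN
    if req.genotype is not None:
        want = "".join(sorted(req.genotype.upper()))
        have = "".join(sorted(record.genotype))
        return _SAT if have == want else _VIOLATED
    zyg = genotype_zygosity(record, req.allele)
    return _SAT if zyg in (
        Zygosity.HOM_RISK, Zygosity.HET_RISK, Zygosity.HEMIZYGOUS_RISK
    ) else _VIOLATED


def _check_clinical_requirement(
    req: ClinicalRequirement, clinical: Optional[ClinicalProfile]
) -> int:
    if clinical is None:
        return _UNKNOWN
    value = getattr(clinical, req.field)
    value = getattr(value, "value", value)  # unwrap TriState
    if value == "unknown":
        return _UNKNOWN
    return _SAT if value == req.value else _VIOLATED


def _branch_state(
    branch: Branch, genome: PersonalGenome, clinical: Optional[ClinicalProfile]
) -> int:
    states = [_check_snp_requirement(r, genome) for r in branch.snp_requirements]
    states += [
        _check_clinical_requirement(r, clinical) for r in branch.clinical_requirements
    ]
    if any(s == _VIOLATED for s in states):
        return _VIOLATED
    if all(s == _SAT for s in states):
        return _SAT
    return _UNKNOWN


def match_branches(
    genome: PersonalGenome,
    clinical: Optional[ClinicalProfile],
    model: BranchSetModel,
) -> BranchMatchResult:
    """Three-valued branch matching.

    A branch is *matched* when every requirement is satisfied by available
    data, *contradicted* when at least one requirement is definitively
    violated, and *indeterminate* otherwise (some requirement touches
    missing data while none is violated).  Verdict: ``at_risk`` if any
    branch matched; ``risk_free`` if every branch is contradicted;
    ``indeterminate`` otherwise.
    """
    matched, contradicted, indeterminate = [], [], []
    for branch in model.branches:
        state = _branch_state(branch, genome, clinical)
        if state == _SAT:
            matched.append(branch.branch_id)
        elif state == _VIOLATED:
            contradicted.append(branch.branch_id)
        else:
            indeterminate.append(branch.branch_id)
    if matched:
        verdict = BranchVerdict.AT_RISK
    elif not indeterminate:
        verdict = BranchVerdict.RISK_FREE
    else:
        verdict = BranchVerdict.INDETERMINATE
    return BranchMatchResult(
        model_name=model.name,
        verdict=verdict,
        matched_branches=matched,
        indeterminate_branches=indeterminate,
        contradicted_branches=contradicted,
    )


# ---------------------------------------------------------------------------
# Polygenic scores


class PolygenicScores(BaseModel):
    count_score: int
    log_odds_score: float
    multiplicative_or: float
    lifetime_risk: Optional[float] = None
    lifetime_risk_capped: bool = False


def polygenic_scores(
    hits: Sequence[PersonalAssociationHit],
    average_population_risk: Optional[float] = None,
    weighting: Literal["per_allele", "per_genotype"] = "per_allele",
) -> PolygenicScores:
    """Count, log-odds and multiplicative polygenic scores over the hits.

    ``per_allele`` weighting (default) counts risk-allele copies, so a
    homozygote contributes twice: count = Σ copies, log-odds = Σ copies·ln OR,
    multiplicative OR = Π OR^copies.  ``per_genotype`` weights every hit once
    regardless of zygosity.  When an average population risk in (0, 1) is
    supplied, lifetime risk = multiplicative OR × that risk, capped at 1.0
    and flagged when the cap bites.
    """
    if average_population_risk is not None and not (0 < average_population_risk < 1):
        raise ValueError("average_population_risk must lie in (0, 1)")
    count = 0
    log_odds = 0.0
    for h in hits:
        odds = h.association.odds_ratio
        if odds <= 0:
            raise ValueError(f"{h.association.rsid}: non-positive odds ratio")
        copies = h.allele_count if weighting == "per_allele" else 1
        count += copies
        log_odds += copies * math.log(odds)
    multiplicative = math.exp(log_odds)
    lifetime = None
    capped = False
    if average_population_risk is not None:
        lifetime = multiplicative * average_population_risk
        if lifetime > 1.0:
            lifetime, capped = 1.0, True
    return PolygenicScores(
        count_score=count,
        log_odds_score=log_odds,
        multiplicative_or=multiplicative,
        lifetime_risk=lifetime,
        lifetime_risk_capped=capped,
    )


# ---------------------------------------------------------------------------
# Model file I/O

AnyModel = Union[CumulativeModel, BranchSetModel]


def _parse_model(payload: dict) -> AnyModel:
    kind = payload.get("type")
    body = {k: v for k, v in payload.items() if k != "type"}
    if kind == "cumulative":
        return CumulativeModel.model_validate(body)
    if kind == "branch_set":
        return BranchSetModel.model_validate(body)
    raise ValueError(f"unknown model type {kind!r}")


def load_models(path: Union[str, Path]) -> list[AnyModel]:
    """Load cumulative and/or branch-set models from a JSON file.

    The file holds either one model object or a list of them; each object
    carries ``type`` ("cumulative" or "branch_set") beside the model fields.
    Validation enforces reference-table completeness and OR monotonicity for
    cumulative models and branch-id uniqueness for branch sets.
    """
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(payload, dict):
        payload = [payload]
    return [_parse_model(item) for item in payload]


def save_models(models: Sequence[AnyModel], path: Union[str, Path]) -> None:
    out = []
    for m in models:
        kind = "cumulative" if isinstance(m, CumulativeModel) else "branch_set"
        body = json.loads(m.model_dump_json(exclude_none=True))
        out.append({"type": kind, **body})
    Path(path).write_text(json.dumps(out, indent=1) + "\n", encoding="utf-8")


def builtin_models_path() -> Path:
    """Path of the shipped prostate-cancer model fixture file."""
    return Path(__file__).parent / "data" / "prostate_models.json"


def load_builtin_models() -> list[AnyModel]:
    return load_models(builtin_models_path())
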