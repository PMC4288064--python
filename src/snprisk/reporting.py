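"""Personal risk report assembly.

``assess`` runs the whole pipeline over one subject — parse the raw genotype
file, extract knowledge-base hits, compute the four independent scores and
the categorical grid, evaluate every cumulative and branch-set model, and
compute polygenic scores — and returns a single structured report.  The
report is deterministic: identical inputs give identical structured output
(the timestamp is optional precisely so outputs can be compared byte for
byte).
"""

from __future__ import annotations

import datetime
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Optional, Sequence, Union

from pydantic import BaseModel

from .association_engine import (
    CategoricalSummary,
    ExtractionResult,
    IndependentScorePanel,
    categorical_summary,
    extract_hits,
    score_panel,
)
from .genotype_io import (
    ClinicalProfile,
    PersonalGenome,
    TriState,
    load_clinical_profile,
    parse_genome,
)
from .knowledge_base import KnowledgeBase, load_kb
from .risk_models import (
    AnyModel,
    BranchMatchResult,
    BranchSetModel,
    CumulativeModel,
    CumulativeResult,
    PolygenicScores,
    classify_cumulative,
    evaluate_cumulative,
    load_models,
    match_branches,
    polygenic_scores,
)

__all__ = ["Provenance", "RiskReport", "assess", "assess_genome", "render_text"]


def _tool_version() -> str:
    try:
        return _pkg_version("snprisk")
    except PackageNotFoundError:
        return "unknown"


class Provenance(BaseModel):
    kb_version: str
    kb_disease_code: str
    model_names: list[str]
    tool_version: str
    timestamp: Optional[str] = None


class RiskReport(BaseModel):
    subject_id: str
    independent_scores: IndependentScorePanel
    categorical_summary: CategoricalSummary
    cumulative_results: list[CumulativeResult]
    cumulative_categories: dict[str, str]
    branch_verdicts: list[BranchMatchResult]
    polygenic: PolygenicScores
    n_hits: int
    nocall_rsids: list[str]
    missing_rsids: list[str]
    clinical_risk_tags: list[str] = []
    clinical_protective_tags: list[str] = []
    provenance: Provenance


def assess_genome(
    genome: PersonalGenome,
    kb: KnowledgeBase,
    models: Sequence[AnyModel] = (),
    clinical: Optional[ClinicalProfile] = None,
    fhh: Union[TriState, str, None] = None,
    average_population_risk: Optional[float] = None,
    mode: str = "strict",
    timestamp: bool = False,
) -> RiskReport:
    """Assemble a full risk report from already-loaded inputs.

    Family health history is taken from ``fhh`` when given, else from the
    clinical profile, else treated as unknown.  All scores share one hit
    extraction pass, so the categorical grid, the independent panel and the
    polygenic scores describe exactly the same set of CR-SNPs.
    """
    if fhh is None:
        fhh = clinical.family_health_history if clinical else TriState.UNKNOWN
    fhh = TriState(fhh)

    extraction: ExtractionResult = extract_hits(genome, kb)
    hits = extraction.hits

    cumulative_results: list[CumulativeResult] = []
    branch_verdicts: list[BranchMatchResult] = []
    for model in models:
        if isinstance(model, CumulativeModel):
            cumulative_results.append(
                evaluate_cumulative(genome, model, fhh=fhh, mode=mode)
            )
        elif isinstance(model, BranchSetModel):
            branch_verdicts.append(match_branches(genome, clinical, model))

    return RiskReport(
        subject_id=genome.subject_id,
        independent_scores=score_panel(extraction),
        categorical_summary=categorical_summary(hits),
        cumulative_results=cumulative_results,
        cumulative_categories={
            r.model_name: classify_cumulative(r).value for r in cumulative_results
        },
        branch_verdicts=branch_verdicts,
        polygenic=polygenic_scores(hits, average_population_risk),
        n_hits=len(hits),
        nocall_rsids=extraction.nocall_rsids,
        missing_rsids=extraction.missing_rsids,
        clinical_risk_tags=list(clinical.risk_factor_tags) if clinical else [],
        clinical_protective_tags=(
            list(clinical.protective_factor_tags) if clinical else []
        ),
        provenance=Provenance(
            kb_version=kb.version,
            kb_disease_code=kb.disease_code,
            model_names=[m.name for m in models],
            tool_version=_tool_version(),
            timestamp=(
                datetime.datetime.now(datetime.timezone.utc).isoformat()
                if timestamp
                else None
            ),
        ),
    )


def assess(
    genome_path: Union[str, Path],
    kb_path: Union[str, Path],
    model_paths: Sequence[Union[str, Path]] = (),
    clinical_path: Optional[Union[str, Path]] = None,
    **kwargs,
) -> RiskReport:
    """File-path front end to :func:`assess_genome`."""
    genome = parse_genome(genome_path, subject_id=Path(genome_path).stem)
    kb = load_kb(kb_path)
    models: list[AnyModel] = []
    for path in model_paths:
        models.extend(load_models(path))
    clinical = load_clinical_profile(clinical_path) if clinical_path else None
    return assess_genome(genome, kb, models, clinical=clinical, **kwargs)


def render_text(report: RiskReport) -> str:
    """Human-readable plain-text rendering of a risk report."""
    s = report.independent_scores
    lines = [
        f"Personal risk report — subject {report.subject_id or '(unnamed)'}",
        f"Knowledge base: {report.provenance.kb_disease_code} "
        f"v{report.provenance.kb_version}; tool {report.provenance.tool_version}",
        "",
        f"KB SNPs assayed: {s.n_kb_snps_assayed}   not on chip: {s.n_kb_snps_missing}"
        f"   no-calls: {len(report.nocall_rsids)}",
        f"Risk-carrying SNPs (hits): {report.n_hits}",
        "",
        "Independent scores",
        f"  SNP count        dominant {s.snp_count_dominant:>6}   additive {s.snp_count_additive:>6}",
        f"  evidence-impact  dominant {s.evidence_impact_dominant:>6.1f}   additive {s.evidence_impact_additive:>6.1f}",
        "",
        "Hits by impact (rows) x evidence (columns)",
        "            strong  moderate  weak",
    ]
    for impact in ("strong", "moderate", "weak"):
        row = report.categorical_summary.counts[impact]
        lines.append(
            f"  {impact:<9} {row['strong']:>5} {row['moderate']:>8} {row['weak']:>6}"
        )
    if report.cumulative_results:
        lines += ["", "Cumulative models"]
        for r in report.cumulative_results:
            cat = report.cumulative_categories[r.model_name]
            if r.status == "evaluated":
                lines.append(
                    f"  {r.model_name:<16} impact {r.total_impact}  OR {r.odds_ratio:.2f}  [{cat}]"
                    + ("  (FHH unknown; without-FHH column)" if r.fhh_unknown else "")
                )
            else:
                detail = []
                if r.missing_snps:
                    detail.append(f"{len(r.missing_snps)} SNP(s) not on chip")
                if r.nocall_snps:
                    detail.append(f"{len(r.nocall_snps)} no-call(s)")
                lines.append(
                    f"  {r.model_name:<16} unknown ({'; '.join(detail) or 'incomplete data'})"
                )
    if report.branch_verdicts:
        lines += ["", "Branch-set models"]
        for v in report.branch_verdicts:
            lines.append(
                f"  {v.model_name:<36} {v.verdict.value}"
                f"  (matched {len(v.matched_branches)}, "
                f"indeterminate {len(v.indeterminate_branches)}, "
                f"contradicted {len(v.contradicted_branches)})"
            )
    p = report.polygenic
    lines += [
        "",
        "Polygenic scores",
        f"  risk-allele count   {p.count_score}",
        f"  log-odds            {p.log_odds_score:.4f}",
        f"  multiplicative OR   {p.multiplicative_or:.4f}",
    ]
    if p.lifetime_risk is not None:
        capped = "  (capped at 1.0)" if p.lifetime_risk_capped else ""
        lines.append(f"  lifetime risk       {p.lifetime_risk:.4f}{capped}")
    if report.clinical_risk_tags:
        lines += ["", "Clinical risk factors: " + ", ".join(report.clinical_risk_tags)]
    if report.clinical_protective_tags:
        lines.append(
            "Clinical protective factors: "
            + ", ".join(report.clinical_protective_tags)
        )
    return "\n".join(lines) + "\n"
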