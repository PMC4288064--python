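"""Independent brute-force oracles, written directly from the method's rules.

These deliberately avoid the library's own code paths: the selection oracle
filters candidates phase by phase; the scoring oracle recounts hits from the
raw genotype strings; the branch oracle checks each requirement on its own.
"""

from __future__ import annotations

from snprisk.genotype_io import PersonalGenome
from snprisk.knowledge_base import AssociationCandidate
from snprisk.risk_models import Branch, BranchSetModel

_RACE_ORDER = ["caucasian", "mixed", "other"]  # best first
_STUDY_ORDER = ["meta_analysis", "research"]


def select_oracle(candidates: list[AssociationCandidate]) -> AssociationCandidate:
    """Phase-by-phase filtering: race, study type, citations, OR, tie-breaks."""
    pool = list(candidates)
    for race in _RACE_ORDER:
        kept = [c for c in pool if c.race_group.value == race]
        if kept:
            pool = kept
            break
    for study in _STUDY_ORDER:
        kept = [c for c in pool if c.study_type.value == study]
        if kept:
            pool = kept
            break
    best_cites = max((c.citation_count or 0) for c in pool)
    pool = [c for c in pool if (c.citation_count or 0) == best_cites]
    best_or = max(c.odds_ratio for c in pool)
    pool = [c for c in pool if c.odds_ratio == best_or]
    # deterministic tie-breaks: narrowest CI, then source tag
    best_width = min(c.ci_width for c in pool)
    pool = [c for c in pool if c.ci_width == best_width]
    return min(pool, key=lambda c: c.source)


def count_risk_alleles(genotype: str, risk: str) -> int:
    if genotype == "--":
        return 0
    return genotype.count(risk)


def independent_scores_oracle(
    genome: PersonalGenome, kb_rows: list[tuple[str, str, int, int]]
) -> dict[str, float]:
    """Recompute the four independent scores from raw genotype strings.

    ``kb_rows`` are (rsid, risk_allele, evidence_rank, impact_rank).
    A SNP is a hit when it carries >= 1 risk allele; homozygotes (or a
    hemizygous single risk allele... single-char calls count once) weight 2
    in additive scores; the per-SNP evidence-impact term is the rank product.
    """
    dom = add = 0
    ei_dom = ei_add = 0.0
    for rsid, risk, ev, im in kb_rows:
        rec = genome.records.get(rsid)
        if rec is None or rec.genotype == "--":
            continue
        n = count_risk_alleles(rec.genotype, risk)
        if n == 0:
            continue
        weight = 2 if (n == 2 and len(rec.genotype) == 2) else 1
        dom += 1
        add += weight
        ei_dom += ev * im
        ei_add += ev * im * weight
    return {
        "snp_count_dominant": dom,
        "snp_count_additive": add,
        "evidence_impact_dominant": ei_dom,
        "evidence_impact_additive": ei_add,
    }


def branch_verdict_oracle(
    genome: PersonalGenome, clinical, model: BranchSetModel
) -> str:
    """Three-valued verdict by checking every requirement independently."""

    def snp_state(req) -> str:
        rec = genome.records.get(req.rsid)
        if rec is None or rec.genotype == "--":
            return "unknown"
        if req.genotype is not None:
            ok = sorted(rec.genotype) == sorted(req.genotype.upper())
        else:
            ok = req.allele in rec.genotype
        return "sat" if ok else "violated"

    def clinical_state(req) -> str:
        if clinical is None:
            return "unknown"
        value = getattr(clinical, req.field)
        value = getattr(value, "value", value)
        if value == "unknown":
            return "unknown"
        return "sat" if value == req.value else "violated"

    def branch_state(branch: Branch) -> str:
        states = [snp_state(r) for r in branch.snp_requirements]
        states += [clinical_state(r) for r in branch.clinical_requirements]
        if "violated" in states:
            return "violated"
        if all(s == "sat" for s in states):
            return "sat"
        return "unknown"

    states = [branch_state(b) for b in model.branches]
    if "sat" in states:
        return "at_risk"
    if all(s == "violated" for s in states):
        return "risk_free"
    return "indeterminate"
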