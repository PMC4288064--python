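"""Shared fixtures: tiny synthetic knowledge bases and genome builders."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("repro", derandomize=True)
_hyp_settings.load_profile("repro")

from snprisk.genotype_io import GenotypeRecord, PersonalGenome
from snprisk.knowledge_base import (
    AssociationCandidate,
    KnowledgeBase,
    build_kb,
    grade_candidate,
)


def make_candidate(**overrides) -> AssociationCandidate:
    base = dict(
        rsid="rs1000",
        risk_allele="A",
        odds_ratio=1.4,
        race_group="caucasian",
        study_type="research",
        citation_count=10,
        author_count=5,
        sample_size_cases=500,
        sample_size_controls=500,
        pubmed_article_count=3,
        cumulative_model_count=1,
        source="unit-test",
    )
    base.update(overrides)
    return AssociationCandidate(**base)


def random_candidate(rng: random.Random, rsid="rs1000", allele="A") -> AssociationCandidate:
    return make_candidate(
        rsid=rsid,
        risk_allele=allele,
        odds_ratio=round(rng.uniform(1.0, 4.0), 2),
        race_group=rng.choice(["caucasian", "mixed", "other"]),
        study_type=rng.choice(["meta_analysis", "research"]),
        citation_count=rng.randrange(0, 200),
        author_count=rng.randrange(1, 60),
        sample_size_cases=rng.randrange(10, 5000),
        sample_size_controls=rng.randrange(10, 5000),
        pubmed_article_count=rng.randrange(0, 40),
        cumulative_model_count=rng.randrange(0, 6),
        source=f"src{rng.randrange(100)}",
    )


@pytest.fixture
def seven_snp_kb() -> KnowledgeBase:
    """Seven associations spanning the impact/evidence category grid."""
    specs = [
        ("rs1001", "A", 1.2),
        ("rs1002", "C", 1.8),
        ("rs1003", "G", 2.0),
        ("rs1004", "T", 2.3),
        ("rs1005", "A", 2.5),
        ("rs1006", "C", 3.1),
        ("rs1007", "G", 1.1),
    ]
    candidates = [
        make_candidate(
            rsid=r, risk_allele=a, odds_ratio=o,
            citation_count=5 + 30 * (i % 3),
            pubmed_article_count=3 * i,
            cumulative_model_count=i % 4,
        )
        for i, (r, a, o) in enumerate(specs)
    ]
    return build_kb(candidates, version="test")


def genome_from_genotypes(genotypes: dict[str, str], subject_id="test") -> PersonalGenome:
    """Build a genome directly from an rsid -> genotype-string mapping."""
    records = {
        rsid: GenotypeRecord(
            rsid=rsid, chromosome="1", position=1000 * (i + 1), genotype=gt
        )
        for i, (rsid, gt) in enumerate(genotypes.items())
    }
    return PersonalGenome(subject_id=subject_id, records=records)


def full_risk_genome(kb: KnowledgeBase, zygosity="hom") -> PersonalGenome:
    """A genome homozygous (or heterozygous) for every KB risk allele."""
    genotypes = {}
    for a in kb.associations:
        risk = a.risk_allele
        if zygosity == "hom":
            genotypes[a.rsid] = risk * 2
        else:
            other = sorted(set("ACGT") - {risk})[0]
            genotypes[a.rsid] = risk + other
    return genome_from_genotypes(genotypes)


__all__ = [
    "make_candidate",
    "random_candidate",
    "genome_from_genotypes",
    "full_risk_genome",
    "grade_candidate",
]
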