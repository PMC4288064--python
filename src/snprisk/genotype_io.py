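"""Direct-to-consumer raw genotype files: parsing, simulation, zygosity.

The 23andMe raw format is a tab-separated text file — comment lines starting
``#``, then one line per assayed marker with columns rsid, chromosome,
position and genotype.  Genotypes are one or two characters from A/C/G/T
(plus D/I for indels); ``--`` marks a no-call.  Matching downstream is by
rsID only, so genome-build differences in the position column are harmless.

Also provides a seeded synthetic-genome generator that plants chosen risk
zygosities at knowledge-base SNPs and pads with background markers, emulating
raw files of the kind shared through the Personal Genome Project.
"""

from __future__ import annotations

import json
import logging
import random
from enum import Enum
from pathlib import Path
from typing import IO, Mapping, Optional, Union

from pydantic import BaseModel, Field, field_validator

from .knowledge_base import NUCLEOTIDES, KnowledgeBase

__all__ = [
    "Zygosity",
    "TriState",
    "GenotypeRecord",
    "PersonalGenome",
    "ClinicalProfile",
    "parse_genome",
    "serialize_genome",
    "save_genome",
    "generate_synthetic_genome",
    "genotype_zygosity",
    "load_clinical_profile",
    "save_clinical_profile",
]

logger = logging.getLogger(__name__)

NOCALL = "--"
_GENOTYPE_CHARS = frozenset("ACGTDI")
_SEX_MT_CHROMS = frozenset({"X", "Y", "MT"})


class Zygosity(str, Enum):
    HOM_RISK = "hom_risk"
    HET_RISK = "het_risk"
    HEMIZYGOUS_RISK = "hemizygous_risk"
    NO_RISK = "no_risk"
    NOCALL = "nocall"


RISK_ZYGOSITIES = frozenset(
    {Zygosity.HOM_RISK, Zygosity.HET_RISK, Zygosity.HEMIZYGOUS_RISK}
)


class TriState(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class GenotypeRecord(BaseModel):
    rsid: str
    chromosome: str
    position: int = Field(ge=1)
    genotype: str

    @field_validator("genotype")
    @classmethod
    def _check_genotype(cls, v: str) -> str:
        v = v.strip().upper()
        if v == NOCALL:
            return v
        if not 1 <= len(v) <= 2 or any(ch not in _GENOTYPE_CHARS for ch in v):
            raise ValueError(f"malformed genotype call {v!r}")
        return v

    @property
    def is_nocall(self) -> bool:
        return self.genotype == NOCALL


class PersonalGenome(BaseModel):
    subject_id: str = ""
    records: dict[str, GenotypeRecord] = {}
    build_label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_nocalls(self) -> int:
        return sum(r.is_nocall for r in self.records.values())


class ClinicalProfile(BaseModel):
    """Self-reported clinical/behavioural covariates used by risk models.

    Tri-state fields default to ``unknown`` — never silently to negative —
    because branch-set models must distinguish a contradicted requirement
    from an unevaluable one.
    """

    subject_id: str = ""
    family_health_history: TriState = TriState.UNKNOWN
    bmi_class: str = "unknown"
    smoking: TriState = TriState.UNKNOWN
    alcohol: TriState = TriState.UNKNOWN
    risk_factor_tags: list[str] = []
    protective_factor_tags: list[str] = []

    model_config = {"extra": "allow"}  # unknown fields preserved round-trip


# ---------------------------------------------------------------------------
# Raw-format I/O


def parse_genome(
    source: Union[str, Path, IO[str]],
    subject_id: str = "",
    strict: bool = False,
) -> PersonalGenome:
    """Read a 23andMe-style raw genotype file.

    Lines beginning ``#`` are comments; data lines carry four tab-separated
    columns (rsid, chromosome, position, genotype).  Malformed lines are
    skipped with a warning (raised in ``strict`` mode); duplicate rsIDs keep
    the first occurrence.  CRLF endings and trailing whitespace tolerated.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        origin = getattr(source, "name", "<stream>")
    else:
        origin = str(source)
        lines = Path(source).read_text(encoding="utf-8").splitlines()

    records: dict[str, GenotypeRecord] = {}
    n_bad = n_dup = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            msg = f"{origin}: line {lineno}: expected 4 columns, got {len(fields)}"
            if strict:
                raise ValueError(msg)
            logger.warning(msg)
            n_bad += 1
            continue
        rsid, chrom, pos, genotype = (f.strip() for f in fields)
        try:
            rec = GenotypeRecord(
                rsid=rsid, chromosome=chrom, position=int(pos), genotype=genotype
            )
        except (ValueError, TypeError) as exc:
            msg = f"{origin}: line {lineno}: {exc}"
            if strict:
                raise ValueError(msg) from exc
            logger.warning(msg)
            n_bad += 1
            continue
        if rec.rsid in records:
            logger.warning("%s: line %d: duplicate rsID %s kept first", origin, lineno, rec.rsid)
            n_dup += 1
            continue
        records[rec.rsid] = rec

    if not records:
        raise ValueError(f"{origin}: no genotype records found")
    genome = PersonalGenome(subject_id=subject_id, records=records)
    logger.info(
        "%s: %d records, %d no-calls, %d malformed lines skipped, %d duplicates",
        origin, len(genome), genome.n_nocalls, n_bad, n_dup,
    )
    return genome


def serialize_genome(genome: PersonalGenome) -> str:
    """Render a genome back to the raw tab-separated text format."""
    out = [
        "# rsid\tchromosome\tposition\tgenotype",
    ]
    for rec in genome.records.values():
        out.append(f"{rec.rsid}\t{rec.chromosome}\t{rec.position}\t{rec.genotype}")
    return "\n".join(out) + "\n"


def save_genome(genome: PersonalGenome, path: Union[str, Path]) -> None:
    Path(path).write_text(serialize_genome(genome), encoding="utf-8")


# ---------------------------------------------------------------------------
# Synthetic genomes


def _non_risk_allele(risk_allele: str, rng: random.Random) -> str:
    return rng.choice(sorted(NUCLEOTIDES - {risk_allele}))


def generate_synthetic_genome(
    kb: KnowledgeBase,
    planted: Mapping[str, str],
    n_background: int = 0,
    seed: int = 0,
    subject_id: str = "synthetic",
) -> PersonalGenome:
    """Generate a deterministic synthetic genome with planted risk zygosities.

    ``planted`` maps KB rsIDs to one of ``hom``/``het``/``no_risk``/
    ``absent``/``nocall``: *hom* plants two copies of the KB risk allele,
    *het* one risk plus one drawn non-risk allele, *no_risk* two non-risk
    alleles, *absent* omits the marker (off-chip), *nocall* plants ``--``.
    KB SNPs not mentioned in ``planted`` are omitted.  ``n_background``
    markers with rsIDs disjoint from the KB are appended with random
    genotypes.  Identical seeds reproduce the genome byte-for-byte.
    """
    rng = random.Random(seed)
    by_rsid = kb.by_rsid()
    unknown = sorted(set(planted) - set(by_rsid))
    if unknown:
        raise ValueError(f"planted rsIDs not in knowledge base: {unknown}")

    records: dict[str, GenotypeRecord] = {}
    position = 1
    for rsid in sorted(planted):
        state = planted[rsid]
        risk = by_rsid[rsid].risk_allele
        if state == "absent":
            continue
        elif state == "hom":
            genotype = risk * 2
        elif state == "het":
            other = _non_risk_allele(risk, rng)
            genotype = risk + other
        elif state == "no_risk":
            other = _non_risk_allele(risk, rng)
            genotype = other * 2
        elif state == "nocall":
            genotype = NOCALL
        else:
            raise ValueError(f"unknown planted state {state!r} for {rsid}")
        records[rsid] = GenotypeRecord(
            rsid=rsid, chromosome="1", position=position, genotype=genotype
        )
        position += 1000

    kb_numbers = {int(r[2:]) for r in by_rsid}
    for _ in range(n_background):
        while True:
            number = rng.randrange(900_000_000, 999_999_999)
            rsid = f"rs{number}"
            if number not in kb_numbers and rsid not in records:
                break
        allele_pool = sorted(NUCLEOTIDES)
        genotype = rng.choice(allele_pool) + rng.choice(allele_pool)
        records[rsid] = GenotypeRecord(
            rsid=rsid,
            chromosome=str(rng.randrange(1, 23)),
            position=position,
            genotype=genotype,
        )
        position += 1000

    return PersonalGenome(subject_id=subject_id, records=records)


# ---------------------------------------------------------------------------
# Zygosity


def genotype_zygosity(record: GenotypeRecord, risk_allele: str) -> Zygosity:
    """Classify a genotype call against a forward-strand risk allele.

    Two-character calls count the risk-allele copies (0/1/2 → no_risk /
    het_risk / hom_risk); a single-character call on X/Y/MT is hemizygous and
    reports ``hemizygous_risk`` when it carries the risk allele.  Order of
    the two characters is irrelevant.  D/I (indel) calls are out of scope and
    report no_risk.
    """
    if risk_allele not in NUCLEOTIDES:
        raise ValueError(f"risk allele must be one of A/C/G/T, got {risk_allele!r}")
    if record.is_nocall:
        return Zygosity.NOCALL
    genotype = record.genotype
    if "D" in genotype or "I" in genotype:
        logger.warning("%s: indel call %s treated as no_risk", record.rsid, genotype)
        return Zygosity.NO_RISK
    if len(genotype) == 1:
        return (
            Zygosity.HEMIZYGOUS_RISK if genotype == risk_allele else Zygosity.NO_RISK
        )
    n_risk = genotype.count(risk_allele)
    if n_risk == 2:
        return Zygosity.HOM_RISK
    if n_risk == 1:
        return Zygosity.HET_RISK
    return Zygosity.NO_RISK


def zygosity_weight(zygosity: Zygosity) -> int:
    """Additive-model weight: homozygous risk counts 2, het/hemizygous 1."""
    if zygosity is Zygosity.HOM_RISK:
        return 2
    if zygosity in RISK_ZYGOSITIES:
        return 1
    return 0


# ---------------------------------------------------------------------------
# Clinical profiles


def load_clinical_profile(path: Union[str, Path]) -> ClinicalProfile:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return ClinicalProfile.model_validate(payload)


def save_clinical_profile(profile: ClinicalProfile, path: Union[str, Path]) -> None:
    Path(path).write_text(profile.model_dump_json(indent=2) + "\n", encoding="utf-8")
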