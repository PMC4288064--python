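"""Cumulative models, branch-set matching, polygenic scores."""

from __future__ import annotations

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from snprisk.association_engine import PersonalAssociationHit, extract_hits
from snprisk.genotype_io import (
    ClinicalProfile,
    GenotypeRecord,
    PersonalGenome,
    Zygosity,
)
from snprisk.knowledge_base import build_kb
from snprisk.risk_models import (
    Branch,
    BranchSetModel,
    BranchVerdict,
    ClinicalRequirement,
    CumulativeModel,
    GeneticModel,
    ModelSnp,
    ReferenceEntry,
    RiskCategory,
    SnpRequirement,
    classify_cumulative,
    evaluate_cumulative,
    load_builtin_models,
    load_models,
    match_branches,
    polygenic_scores,
    save_models,
)

from conftest import genome_from_genotypes, make_candidate
from oracles import branch_verdict_oracle

ZHENG_WITHOUT = [1.00, 1.50, 1.96, 2.21, 4.47, 4.47]
ZHENG_WITH = [1.00, 1.62, 2.07, 2.71, 4.76, 9.46, 9.46]


@pytest.fixture(scope="module")
def models():
    return {m.name: m for m in load_builtin_models()}


@pytest.fixture(scope="module")
def zheng(models):
    return models["5-SNP_Zheng"]


def zheng_genome(zheng, states: dict[str, str]) -> PersonalGenome:
    """Genome over the Zheng panel; states map rsid -> hom/het/none/nocall/absent."""
    genotypes = {}
    for snp in zheng.snps:
        state = states.get(snp.rsid, "none")
        risk = snp.risk_allele
        other = sorted(set("ACGT") - {risk})[0]
        if state == "absent":
            continue
        genotypes[snp.rsid] = {
            "hom": risk * 2, "het": risk + other, "none": other * 2, "nocall": "--",
        }[state]
    return genome_from_genotypes(genotypes)


class TestZhengModel:
    def test_panel_composition(self, zheng):
        by_model = {}
        for snp in zheng.snps:
            by_model.setdefault(snp.genetic_model, []).append(snp.rsid)
        assert sorted(by_model[GeneticModel.DOMINANT]) == [
            "rs1447295", "rs16901979", "rs6983267"
        ]
        assert sorted(by_model[GeneticModel.RECESSIVE]) == ["rs1859962", "rs4430796"]
        assert zheng.supports_fhh

    def test_reference_table_columns_verbatim(self, zheng):
        assert [zheng.reference_table[i].odds_ratio for i in range(6)] == ZHENG_WITHOUT
        assert [
            zheng.reference_table_fhh[i].odds_ratio for i in range(7)
        ] == ZHENG_WITH

    def test_all_risk_hom_with_fhh_scores_max(self, zheng):
        genome = zheng_genome(zheng, {s.rsid: "hom" for s in zheng.snps})
        result = evaluate_cumulative(genome, zheng, fhh="positive")
        assert result.total_impact == 6
        assert result.odds_ratio == 9.46
        assert classify_cumulative(result) is RiskCategory.HIGH

    def test_single_dominant_het_no_fhh(self, zheng):
        genome = zheng_genome(zheng, {"rs1447295": "het"})
        result = evaluate_cumulative(genome, zheng, fhh="negative")
        assert result.total_impact == 1
        assert result.odds_ratio == 1.50
        assert classify_cumulative(result) is RiskCategory.LOWER

    def test_het_at_recessive_snp_contributes_nothing(self, zheng):
        genome = zheng_genome(zheng, {"rs1859962": "het", "rs4430796": "het"})
        result = evaluate_cumulative(genome, zheng, fhh="negative")
        assert result.total_impact == 0
        assert result.odds_ratio == 1.00

    def test_hom_at_recessive_snp_counts(self, zheng):
        genome = zheng_genome(zheng, {"rs1859962": "hom"})
        result = evaluate_cumulative(genome, zheng, fhh="negative")
        assert result.total_impact == 1

    def test_fhh_unknown_uses_without_column_and_flags(self, zheng):
        genome = zheng_genome(zheng, {s.rsid: "hom" for s in zheng.snps})
        result = evaluate_cumulative(genome, zheng, fhh="unknown")
        assert result.total_impact == 5
        assert result.odds_ratio == 4.47
        assert result.fhh_unknown and not result.used_fhh_column


class TestMissingData:
    def test_strict_mode_abstains_on_missing_snp(self, zheng):
        genome = zheng_genome(zheng, {"rs1447295": "absent"})
        result = evaluate_cumulative(genome, zheng, fhh="negative")
        assert result.status == "unknown"
        assert result.missing_snps == ["rs1447295"]
        assert classify_cumulative(result) is RiskCategory.UNKNOWN

    def test_strict_mode_abstains_on_nocall(self, zheng):
        genome = zheng_genome(zheng, {"rs6983267": "nocall"})
        result = evaluate_cumulative(genome, zheng, fhh="negative")
        assert result.status == "unknown"
        assert result.nocall_snps == ["rs6983267"]

    def test_bounds_mode_brackets_impact(self, zheng):
        states = {s.rsid: "hom" for s in zheng.snps}
        states["rs1447295"] = "absent"
        genome = zheng_genome(zheng, states)
        result = evaluate_cumulative(genome, zheng, fhh="negative", mode="bounds")
        assert result.impact_bounds == (4, 5)
        assert result.odds_ratio_bounds == (4.47, 4.47)


class TestCumulativeProperties:
    def test_impact_monotone_in_added_risk_alleles(self, zheng):
        rng = random.Random(77)
        states_pool = ["none", "het", "hom"]
        order = {"none": 0, "het": 1, "hom": 2}
        for _ in range(50):
            states = {s.rsid: rng.choice(states_pool) for s in zheng.snps}
            base = evaluate_cumulative(
                zheng_genome(zheng, states), zheng, fhh="negative"
            )
            rsid = rng.choice([s.rsid for s in zheng.snps])
            if order[states[rsid]] < 2:
                states[rsid] = states_pool[order[states[rsid]] + 1]
            upgraded = evaluate_cumulative(
                zheng_genome(zheng, states), zheng, fhh="negative"
            )
            assert upgraded.total_impact >= base.total_impact
            assert 0 <= upgraded.total_impact <= len(zheng.snps)

    def test_hemizygous_counts_for_dominant_and_recessive(self):
        model = CumulativeModel(
            name="toy-x", supports_fhh=False,
            snps=[ModelSnp(rsid="rs5945572", risk_allele="A",
                           genetic_model="recessive")],
            reference_table={0: ReferenceEntry(odds_ratio=1.0),
                             1: ReferenceEntry(odds_ratio=1.4)},
        )
        genome = PersonalGenome(records={
            "rs5945572": GenotypeRecord(
                rsid="rs5945572", chromosome="X", position=1, genotype="A")
        })
        result = evaluate_cumulative(genome, model, fhh="negative")
        assert result.total_impact == 1


class TestModelIO:
    def test_builtin_set_loads_all_published_panels(self, models):
        for name, n in [("17-SNP_Helfand", 17), ("9-SNP_Helfand", 9),
                        ("5-SNP_Zheng", 5), ("5-SNP_Salinas", 5),
                        ("4-SNP_Nam", 4), ("3-SNP_Beuten", 3)]:
            assert len(models[name].snps) == n
        assert models["17-SNP_Helfand"].supports_fhh
        assert not models["9-SNP_Helfand"].supports_fhh
        # non-published reference tables are marked synthetic
        assert not models["5-SNP_Zheng"].synthetic_reference
        assert models["4-SNP_Nam"].synthetic_reference

    def test_incomplete_reference_table_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            CumulativeModel(
                name="bad",
                snps=[ModelSnp(rsid="rs1", risk_allele="A", genetic_model="dominant"),
                      ModelSnp(rsid="rs2", risk_allele="C", genetic_model="dominant"),
                      ModelSnp(rsid="rs3", risk_allele="G", genetic_model="dominant")],
                reference_table={0: ReferenceEntry(odds_ratio=1.0),
                                 1: ReferenceEntry(odds_ratio=1.2),
                                 2: ReferenceEntry(odds_ratio=1.4)},
            )

    def test_nonmonotone_reference_table_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            CumulativeModel(
                name="bad",
                snps=[ModelSnp(rsid="rs1", risk_allele="A", genetic_model="dominant")],
                reference_table={0: ReferenceEntry(odds_ratio=2.0),
                                 1: ReferenceEntry(odds_ratio=1.0)},
            )

    def test_duplicate_branch_ids_rejected(self):
        branch = Branch(branch_id="b1",
                        snp_requirements=[SnpRequirement(rsid="rs1", allele="A")])
        with pytest.raises(ValueError, match="duplicate"):
            BranchSetModel(name="bad", branches=[branch, branch])

    def test_roundtrip(self, tmp_path, models):
        path = tmp_path / "models.json"
        originals = list(models.values())
        save_models(originals, path)
        again = load_models(path)
        assert [m.name for m in again] == [m.name for m in originals]
        assert again == originals

    def test_unknown_clinical_field_rejected_at_load(self):
        with pytest.raises(ValueError, match="clinical field"):
            ClinicalRequirement(field="shoe_size", value="44")


class TestBranchMatching:
    @pytest.fixture
    def toy_model(self):
        return BranchSetModel(
            name="toy",
            branches=[
                Branch(branch_id="b1", snp_requirements=[
                    SnpRequirement(rsid="rs1", genotype="AA"),
                    SnpRequirement(rsid="rs2", allele="G"),
                ]),
                Branch(branch_id="b2",
                       snp_requirements=[SnpRequirement(rsid="rs3", genotype="CC")],
                       clinical_requirements=[
                           ClinicalRequirement(field="smoking", value="positive")]),
            ],
        )

    def test_fully_satisfied_branch_gives_at_risk(self, toy_model):
        genome = genome_from_genotypes({"rs1": "AA", "rs2": "GT", "rs3": "TT"})
        result = match_branches(genome, None, toy_model)
        assert result.verdict is BranchVerdict.AT_RISK
        assert result.matched_branches == ["b1"]

    def test_all_contradicted_gives_risk_free(self, toy_model):
        genome = genome_from_genotypes({"rs1": "AG", "rs2": "TT", "rs3": "TT"})
        clinical = ClinicalProfile(smoking="negative")
        result = match_branches(genome, clinical, toy_model)
        assert result.verdict is BranchVerdict.RISK_FREE
        assert set(result.contradicted_branches) == {"b1", "b2"}

    def test_missing_smoking_datum_gives_indeterminate(self, toy_model):
        # genotypes satisfy branch b2's SNP requirement; smoking unknown
        genome = genome_from_genotypes({"rs1": "AG", "rs2": "TT", "rs3": "CC"})
        result = match_branches(genome, ClinicalProfile(), toy_model)
        assert result.verdict is BranchVerdict.INDETERMINATE
        assert "b2" in result.indeterminate_branches

    def test_genotype_requirement_order_insensitive(self):
        model = BranchSetModel(name="m", branches=[
            Branch(branch_id="b", snp_requirements=[
                SnpRequirement(rsid="rs1", genotype="AG")])
        ])
        genome = genome_from_genotypes({"rs1": "GA"})
        assert match_branches(genome, None, model).verdict is BranchVerdict.AT_RISK

    def test_random_models_match_oracle_and_trichotomy(self):
        rng = random.Random(31337)
        fields = ["bmi_class", "smoking", "alcohol"]
        for trial in range(80):
            rsids = [f"rs{i}" for i in range(1, 9)]
            branches = []
            for b in range(rng.randrange(1, 11)):
                snp_reqs = []
                clin_reqs = []
                for _ in range(rng.randrange(1, 9)):
                    if rng.random() < 0.8:
                        rsid = rng.choice(rsids)
                        if rng.random() < 0.5:
                            geno = rng.choice("ACGT") + rng.choice("ACGT")
                            snp_reqs.append(SnpRequirement(rsid=rsid, genotype=geno))
                        else:
                            snp_reqs.append(
                                SnpRequirement(rsid=rsid, allele=rng.choice("ACGT")))
                    else:
                        field = rng.choice(fields)
                        value = (rng.choice(["positive", "negative"])
                                 if field != "bmi_class"
                                 else rng.choice(["normal", "obese"]))
                        clin_reqs.append(ClinicalRequirement(field=field, value=value))
                branches.append(Branch(
                    branch_id=f"b{b}", snp_requirements=snp_reqs,
                    clinical_requirements=clin_reqs))
            model = BranchSetModel(name=f"random{trial}", branches=branches)
            genotypes = {}
            for rsid in rsids:
                roll = rng.random()
                if roll < 0.2:
                    continue  # unassayed
                if roll < 0.3:
                    genotypes[rsid] = "--"
                else:
                    genotypes[rsid] = rng.choice("ACGT") + rng.choice("ACGT")
            genome = (genome_from_genotypes(genotypes) if genotypes
                      else PersonalGenome(records={}))
            clinical = None
            if rng.random() < 0.7:
                clinical = ClinicalProfile(
                    smoking=rng.choice(["positive", "negative", "unknown"]),
                    alcohol=rng.choice(["positive", "negative", "unknown"]),
                    bmi_class=rng.choice(["normal", "obese", "unknown"]),
                )
            result = match_branches(genome, clinical, model)
            assert result.verdict.value == branch_verdict_oracle(
                genome, clinical, model)
            # trichotomy: branch lists partition the model's branches
            all_ids = (set(result.matched_branches)
                       | set(result.indeterminate_branches)
                       | set(result.contradicted_branches))
            assert all_ids == {b.branch_id for b in model.branches}
            assert (len(result.matched_branches)
                    + len(result.indeterminate_branches)
                    + len(result.contradicted_branches)) == len(model.branches)

    def test_more_consistent_data_never_flips_at_risk(self, toy_model):
        # start: b1 matched with minimal data
        genome = genome_from_genotypes({"rs1": "AA", "rs2": "GT"})
        assert match_branches(genome, None, toy_model).verdict is BranchVerdict.AT_RISK
        # add more (consistent) data: still at risk
        fuller = genome_from_genotypes({"rs1": "AA", "rs2": "GT", "rs3": "CC"})
        clinical = ClinicalProfile(smoking="positive")
        assert match_branches(fuller, clinical, toy_model).verdict is BranchVerdict.AT_RISK


def make_hits(specs) -> list[PersonalAssociationHit]:
    """specs: list of (odds_ratio, zygosity)."""
    hits = []
    for i, (odds, zyg) in enumerate(specs):
        cand = make_candidate(rsid=f"rs{500 + i}", odds_ratio=odds)
        kb = build_kb([cand])
        hits.append(PersonalAssociationHit(
            association=kb.associations[0], zygosity=Zygosity(zyg)))
    return hits


class TestPolygenic:
    def test_empty_input(self):
        scores = polygenic_scores([])
        assert scores.count_score == 0
        assert scores.log_odds_score == 0.0
        assert scores.multiplicative_or == 1.0
        assert scores.lifetime_risk is None

    def test_single_het_or_e(self):
        scores = polygenic_scores(make_hits([(math.e, "het_risk")]))
        assert scores.log_odds_score == pytest.approx(1.0)
        assert scores.multiplicative_or == pytest.approx(math.e)

    def test_hand_computed_example(self):
        hits = make_hits([(1.5, "het_risk"), (1.2, "hom_risk")])
        scores = polygenic_scores(hits, average_population_risk=0.16)
        assert scores.count_score == 3
        assert scores.log_odds_score == pytest.approx(
            math.log(1.5) + 2 * math.log(1.2))
        assert scores.multiplicative_or == pytest.approx(1.5 * 1.44)
        assert scores.lifetime_risk == pytest.approx(1.5 * 1.44 * 0.16)

    def test_lifetime_risk_capped_and_flagged(self):
        hits = make_hits([(3.0, "hom_risk"), (3.0, "hom_risk")])
        scores = polygenic_scores(hits, average_population_risk=0.5)
        assert scores.lifetime_risk == 1.0
        assert scores.lifetime_risk_capped

    def test_per_genotype_weighting_option(self):
        hits = make_hits([(1.5, "hom_risk")])
        per_allele = polygenic_scores(hits)
        per_genotype = polygenic_scores(hits, weighting="per_genotype")
        assert per_allele.count_score == 2 and per_genotype.count_score == 1
        assert per_genotype.multiplicative_or == pytest.approx(1.5)

    def test_invalid_population_risk_rejected(self):
        with pytest.raises(ValueError):
            polygenic_scores([], average_population_risk=1.5)

    @given(st.lists(
        st.tuples(st.floats(min_value=0.2, max_value=5.0, allow_nan=False),
                  st.sampled_from(["het_risk", "hom_risk", "hemizygous_risk"])),
        max_size=8))
    @settings(max_examples=150, deadline=None)
    def test_exp_log_odds_equals_multiplicative(self, specs):
        scores = polygenic_scores(make_hits(specs))
        assert math.exp(scores.log_odds_score) == pytest.approx(
            scores.multiplicative_or, abs=1e-12, rel=1e-12)
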