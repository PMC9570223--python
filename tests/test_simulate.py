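"""Simulator: pedigree structure, gene dropping, phenotypes, studies."""

import math

import numpy as np
import pytest

import famseg as fs
from famseg.pedigree import Sex
from famseg.segregation import Classification


def _rng(seed):
    return np.random.default_rng(seed)


# --- pedigrees ----------------------------------------------------------


def test_two_generation_pedigree_shape():
    cfg = fs.SimConfig(generations=2, sibship_size_range=(2, 4))
    ped = fs.simulate_pedigree(cfg, "F1", _rng(1))
    founders = [p for p in ped if p.father_id is None and p.mother_id is None]
    children = [p for p in ped if p.father_id is not None]
    assert len(founders) == 2
    assert 2 <= len(children) <= 4
    by_id = {p.individual_id for p in ped}
    for c in children:
        assert c.father_id in by_id and c.mother_id in by_id


def test_same_seed_gives_identical_pedigree():
    cfg = fs.SimConfig(generations=3)
    assert fs.simulate_pedigree(cfg, "F1", _rng(9)) == \
        fs.simulate_pedigree(cfg, "F1", _rng(9))


def test_one_generation_is_founders_only():
    ped = fs.simulate_pedigree(fs.SimConfig(generations=1), "F1", _rng(0))
    assert len(ped) == 2 and all(p.father_id is None for p in ped)


def test_parents_precede_children_in_order():
    cfg = fs.SimConfig(generations=3, sibship_size_range=(3, 4))
    ped = fs.simulate_pedigree(cfg, "F1", _rng(3))
    seen = set()
    for p in ped:
        assert p.father_id is None or p.father_id in seen
        assert p.mother_id is None or p.mother_id in seen
        seen.add(p.individual_id)


# --- gene dropping ------------------------------------------------------


def _couple_with_children(n_children, child_sex=None):
    ped = [
        fs.Individual("I.1", "F1", sex=Sex.MALE),
        fs.Individual("I.2", "F1", sex=Sex.FEMALE),
    ]
    for i in range(n_children):
        sex = child_sex or (Sex.MALE if i % 2 else Sex.FEMALE)
        ped.append(fs.Individual(f"II.{i + 1}", "F1", father_id="I.1",
                                 mother_id="I.2", sex=sex))
    return ped


def test_het_father_transmits_to_half_of_offspring_within_3se():
    n = 10_000
    ped = _couple_with_children(1)
    rng = _rng(42)
    carriers = sum(
        fs.gene_drop(ped, {"I.1": (1, 0), "I.2": (0, 0)}, rng)["II.1"] >= 1
        for _ in range(n)
    )
    se = math.sqrt(0.25 / n)
    assert abs(carriers / n - 0.5) <= 3 * se


def test_hom_ref_parents_give_only_hom_ref_children():
    ped = _couple_with_children(4)
    counts = fs.gene_drop(ped, {"I.1": (0, 0), "I.2": (0, 0)}, _rng(0))
    assert all(c == 0 for c in counts.values())


def test_x_linked_sons_get_maternal_allele_only():
    ped = _couple_with_children(1, child_sex=Sex.MALE)
    rng = _rng(7)
    sons = [fs.gene_drop(ped, {"I.1": (0,), "I.2": (1, 0)}, rng, chrom="X")["II.1"]
            for _ in range(5000)]
    assert set(sons) <= {0, 1}
    se = math.sqrt(0.25 / 5000)
    assert abs(np.mean(sons) - 0.5) <= 3 * se
    # daughters of a carrier father on X are obligate carriers
    ped_d = _couple_with_children(1, child_sex=Sex.FEMALE)
    daughters = [fs.gene_drop(ped_d, {"I.1": (1,), "I.2": (0, 0)}, rng, chrom="X")["II.1"]
                 for _ in range(200)]
    assert set(daughters) == {1}


def test_missing_founder_assignment_errors():
    ped = _couple_with_children(1)
    with pytest.raises(fs.ValidationError, match="founder"):
        fs.gene_drop(ped, {"I.1": (0, 0)}, _rng(0))


def test_founder_allele_frequency_matches_maf_within_3se():
    ped = [fs.Individual(f"I.{i}", "F1", sex=Sex.FEMALE) for i in range(1, 3)]
    rng = _rng(11)
    maf = 20.0
    n_draws = 20_000  # 2 founders × 2 alleles × 5000 reps
    alt = sum(sum(sum(g) for g in
                  fs.draw_founder_genotypes(ped, maf, "1", rng).values())
              for _ in range(5000))
    p = maf / 100
    se = math.sqrt(p * (1 - p) / n_draws)
    assert abs(alt / n_draws - p) <= 3 * se


# --- phenotypes ---------------------------------------------------------


def _study_gm(ped, counts, vk="1:1:A>T"):
    gm = fs.GenotypeMatrix()
    for iid, c in counts.items():
        gm.set_call(vk, "F1", iid, c)
    return gm, vk


def test_full_penetrance_zero_phenocopy_affects_exactly_carriers():
    ped = _couple_with_children(4)
    counts = {"I.1": 1, "I.2": 0, "II.1": 1, "II.2": 0, "II.3": 2, "II.4": 0}
    gm, vk = _study_gm(ped, counts)
    cfg = fs.SimConfig(penetrance=1.0, phenocopy_rate=0.0)
    aff = fs.assign_phenotypes(ped, gm, vk, cfg, _rng(0))
    assert aff == {iid: c >= 1 for iid, c in counts.items()}
    cfg0 = fs.SimConfig(penetrance=0.0, phenocopy_rate=0.0)
    assert not any(fs.assign_phenotypes(ped, gm, vk, cfg0, _rng(0)).values())


def test_carrier_affection_rate_near_penetrance():
    ped = _couple_with_children(4)
    counts = {p.individual_id: 1 for p in ped}
    gm, vk = _study_gm(ped, counts)
    cfg = fs.SimConfig(penetrance=0.8, phenocopy_rate=0.01)
    rng = _rng(13)
    n = 6000  # 1000 families × 6 carriers
    affected = sum(sum(fs.assign_phenotypes(ped, gm, vk, cfg, rng).values())
                   for _ in range(1000))
    se = math.sqrt(0.8 * 0.2 / n)
    assert abs(affected / n - 0.8) <= 3 * se


# --- whole studies ------------------------------------------------------


def test_simulated_study_outputs_are_byte_identical_across_runs(tmp_path):
    cfg = fs.SimConfig(n_families=3, seed=7, background_variant_count=10)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = fs.write_study(fs.simulate_study(cfg), d1)
    p2 = fs.write_study(fs.simulate_study(cfg), d2)
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes(), name


def test_every_family_meets_inclusion_criteria():
    study = fs.simulate_study(fs.SimConfig(n_families=6, seed=3))
    for fam, members in study.cohort.families.items():
        cases = [m for m in members if m.is_case]
        unaff = [m for m in members if m.is_unaffected]
        assert len(cases) >= 2 and len(unaff) >= 1
        exome_cases = [m for m in cases
                       if m.sequencing_tier is fs.SequencingTier.EXOME]
        exome_unaff = [m for m in unaff
                       if m.sequencing_tier is fs.SequencingTier.EXOME]
        assert len(exome_cases) >= 2 and len(exome_unaff) >= 1


def test_mendelian_consistency_of_simulated_studies():
    for seed in range(10):
        study = fs.simulate_study(fs.SimConfig(n_families=2, seed=seed,
                                               background_variant_count=10))
        assert fs.check_mendelian(study) == []


def test_mendelian_checker_detects_impossible_child():
    study = fs.simulate_study(fs.SimConfig(n_families=1, seed=1,
                                           background_variant_count=1))
    fam = next(iter(study.cohort.families))
    child = next(m for m in study.cohort.members(fam) if m.father_id is not None)
    vk = study.truth[fam]
    # force a de novo-looking call: child hom-alt under hom-ref parents
    study.genotypes.set_call(vk, fam, child.father_id, 0)
    study.genotypes.set_call(vk, fam, child.mother_id, 0)
    study.genotypes.set_call(vk, fam, child.individual_id, 2)
    assert fs.check_mendelian(study) != []


def test_truth_variants_recovered_and_complete_under_full_penetrance():
    cfg = fs.SimConfig(n_families=10, penetrance=1.0, phenocopy_rate=0.0,
                       seed=21, background_variant_count=10)
    study = fs.simulate_study(cfg)
    selected = fs.run_cascade(study.cohort, study.variants, study.genotypes)
    by_key = {r.key: r for r in selected}
    coseg = {r.counts.variant_key: r
             for r in fs.cosegregation_table(selected, study.cohort,
                                             study.genotypes)}
    for fam, vk in study.truth.items():
        assert vk in by_key and fam in by_key[vk].contributing_families
        assert coseg[vk].classification is Classification.COMPLETE


def test_recovery_and_false_positives_regression_at_default_parameters():
    """Frozen regression numbers from this generator's own oracle run at the
    default penetrance/phenocopy setting (seed 101, 200 families)."""
    cfg = fs.SimConfig(n_families=200, seed=101)
    study = fs.simulate_study(cfg)
    selected = fs.run_cascade(study.cohort, study.variants, study.genotypes)
    truth_keys = set(study.truth.values())
    hits = sum(1 for fam, vk in study.truth.items()
               if any(r.key == vk and fam in r.contributing_families
                      for r in selected))
    false_positives = sum(1 for r in selected if r.key not in truth_keys)
    assert hits / 200 == 0.495
    assert false_positives == 0


def test_unattainable_inclusion_raises_with_diagnostics():
    cfg = fs.SimConfig(n_families=1, penetrance=0.0, phenocopy_rate=0.0, seed=0)
    with pytest.raises(fs.FamsegError, match="penetrance"):
        fs.simulate_study(cfg)


def test_sim_config_validation():
    with pytest.raises(fs.ValidationError):
        fs.SimConfig(penetrance=1.5)
    with pytest.raises(fs.ValidationError):
        fs.SimConfig(sibship_size_range=(0, 3))
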