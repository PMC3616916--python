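"""Synthetic-input generators: determinism, truth consistency, planted structure."""

import math
from dataclasses import replace

import numpy as np
import pytest

from orphanaudit.errors import ConfigurationError
from orphanaudit import synth
from orphanaudit.exclusivity import exclusive_families
from orphanaudit.expression import call_expression
from orphanaudit.homology import filter_hits
from orphanaudit.orf import find_orf
from orphanaudit.synth import SimConfig


class TestConfig:
    def test_invalid_fraction_names_the_field(self):
        with pytest.raises(ConfigurationError, match="frac_no_start"):
            replace(SimConfig(), frac_no_start=1.5).validate()

    def test_invalid_count_names_the_field(self):
        with pytest.raises(ConfigurationError, match="n_ests"):
            replace(SimConfig(), n_ests=0).validate()


class TestEstSet:
    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path, small_config):
        cfg = replace(small_config, n_ests=60)
        paths = []
        for i in range(2):
            est = synth.gen_est_set(cfg)
            p = tmp_path / f"run{i}.fasta"
            synth.write_fasta(est.records, p)
            est.truth.to_json(tmp_path / f"run{i}.json")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "run0.json").read_bytes() == (tmp_path / "run1.json").read_bytes()

    def test_zero_no_start_fraction_plants_a_start_everywhere(self):
        cfg = replace(SimConfig(), seed=1, n_ests=10, frac_no_start=0.0, redundancy=0.0)
        est = synth.gen_est_set(cfg)
        assert len(est.records) == 10
        for rec in est.records:
            o = est.truth.orfs[rec.id]
            assert o["has_start_codon"]
            assert rec.sequence[o["start"] : o["start"] + 3] == "ATG"

    def test_no_start_count_matches_truth_recount(self):
        """Planted start-less fraction: binomial tolerance vs config, exact vs truth."""
        cfg = replace(
            SimConfig(), seed=7, n_ests=200, frac_no_start=0.1, redundancy=0.0
        )
        est = synth.gen_est_set(cfg)
        n_no_start_truth = sum(
            1 for o in est.truth.orfs.values() if not o["has_start_codon"]
        )
        tol = 3 * math.sqrt(200 * 0.1 * 0.9)
        assert abs(n_no_start_truth - 20) <= tol
        # the measured calls agree with truth read by read
        n_no_start_measured = sum(
            1 for rec in est.records if not find_orf(rec).has_start_codon
        )
        assert n_no_start_measured == n_no_start_truth

    def test_planted_orf_is_the_maximal_orf(self, small_config):
        est = synth.gen_est_set(replace(small_config, n_ests=80))
        for rec in est.records:
            call = find_orf(rec)
            o = est.truth.orfs[rec.id]
            assert (call.start, call.end, call.frame) == (
                o["start"], o["end"], o["frame"],
            )

    def test_truth_ids_match_emitted_records(self, small_config):
        est = synth.gen_est_set(small_config)
        ids = {r.id for r in est.records}
        assert set(est.truth.orfs) == ids
        assert set(est.truth.homologs) <= ids
        for primary, dups in est.truth.duplicate_groups.items():
            assert primary in ids
            assert set(dups) <= ids

    def test_duplicates_are_exact_copies_by_default(self, small_config):
        est = synth.gen_est_set(small_config)
        seq_by_id = {r.id: r.sequence for r in est.records}
        assert est.truth.duplicate_groups  # redundancy 0.12 plants some
        for primary, dups in est.truth.duplicate_groups.items():
            for d in dups:
                assert seq_by_id[d] == seq_by_id[primary]


class TestHomologyTable:
    def test_complete_reference_detects_exactly_the_homologs(self):
        cfg = replace(
            SimConfig(),
            seed=3, n_ests=100, true_match_frac=0.5,
            reference_completeness=1.0, redundancy=0.0,
        )
        hit = synth.gen_homology_table(cfg)
        passing = filter_hits(hit.hits)
        assert set(passing["query_id"]) == set(hit.truth.homologs)
        assert len(hit.truth.homologs) == len(hit.truth.detected_homologs)

    def test_zero_completeness_gives_no_passing_hits(self):
        cfg = replace(SimConfig(), seed=3, n_ests=100, reference_completeness=0.0)
        hit = synth.gen_homology_table(cfg)
        assert len(filter_hits(hit.hits)) == 0
        assert hit.truth.detected_homologs == []

    def test_detected_fraction_matches_configured_completeness(self):
        c = 0.662
        cfg = replace(
            SimConfig(), seed=5, n_ests=10000, reference_completeness=c, redundancy=0.0
        )
        hit = synth.gen_homology_table(cfg)
        n_hom = len(hit.truth.homologs)
        frac = len(hit.truth.detected_homologs) / n_hom
        assert abs(frac - c) <= 3 * math.sqrt(c * (1 - c) / n_hom)
        # recount against the emitted table, not just the truth labels
        passing = filter_hits(hit.hits)
        assert set(passing["query_id"]) == set(hit.truth.detected_homologs)

    def test_decoy_rows_fail_exactly_one_filter(self, small_config):
        hit = synth.gen_homology_table(small_config)
        decoys = hit.hits[hit.hits["subject_id"].str.startswith("DECOY_")]
        assert len(decoys) > 0
        for _, row in decoys.iterrows():
            e_fail = row["e_value"] > 1e-5
            len_fail = row["aligned_length"] < 33
            assert e_fail != len_fail  # exactly one boundary violated


class TestCopyNumberScenario:
    def test_zero_multicopy_fraction_gives_all_singletons(self):
        cfg = replace(SimConfig(), seed=2, frac_multicopy=0.0)
        scen = synth.gen_copy_number_scenario(cfg)
        assert (scen.table["n_focal_sequences"] == 1).all()
        assert scen.truth.multicopy_families == {}

    def test_fixed_seed_gives_identical_table(self, tmp_path):
        cfg = replace(SimConfig(), seed=9)
        a = synth.gen_copy_number_scenario(cfg)
        b = synth.gen_copy_number_scenario(cfg)
        assert a.table.equals(b.table)

    def test_truth_records_the_planted_multicopy_families(self):
        scen = synth.gen_copy_number_scenario(replace(SimConfig(), seed=4))
        table = scen.table.set_index("family_id")["n_focal_sequences"]
        for fam, count in scen.truth.multicopy_families.items():
            assert table[fam] == count and count > 1
        n_multi = int((table > 1).sum())
        assert n_multi == len(scen.truth.multicopy_families)


class TestFamilyMatrix:
    FOCAL = ["sp01", "sp02", "sp03", "sp04", "sp05"]

    def test_planted_exclusive_families_are_listed_and_exclusive(self):
        cfg = replace(SimConfig(), seed=6, n_families=2000, n_species=14)
        fam = synth.gen_family_matrix(cfg, focal=self.FOCAL, n_exclusive=50)
        assert len(fam.truth.exclusive_families) == 50
        result = exclusive_families(fam.matrix, self.FOCAL)
        assert set(fam.truth.exclusive_families) <= set(result.families)

    def test_single_species_all_present_makes_every_family_exclusive(self):
        cfg = replace(SimConfig(), seed=6, n_families=100, n_species=1, presence_prob=1.0)
        fam = synth.gen_family_matrix(cfg)
        result = exclusive_families(fam.matrix, ["sp01"])
        assert result.n_exclusive == 100

    def test_no_family_row_is_empty(self):
        cfg = replace(SimConfig(), seed=8, n_families=500, presence_prob=0.05)
        fam = synth.gen_family_matrix(cfg)
        assert fam.matrix.any(axis=1).all()


class TestProbeMatrix:
    def test_fixed_seed_gives_identical_matrix(self, small_config):
        cfg = replace(small_config, n_ests=50)
        a = synth.gen_probe_matrix(cfg)
        b = synth.gen_probe_matrix(cfg)
        assert a.matrix.equals(b.matrix)

    def test_zero_effect_shift_means_nothing_is_truly_expressed(self, small_config):
        pm = synth.gen_probe_matrix(replace(small_config, n_ests=50, effect_shift=0.0))
        assert pm.truth.expressed_conditions == {}

    def test_huge_shift_with_everything_expressed_makes_all_functional(self, small_config):
        cfg = replace(
            small_config, n_ests=40, effect_shift=50.0, frac_expressed=1.0
        )
        pm = synth.gen_probe_matrix(cfg)
        calls = call_expression(pm.matrix)
        assert calls.per_target["functional"].all()

    def test_truth_targets_appear_in_matrix(self, small_config):
        pm = synth.gen_probe_matrix(replace(small_config, n_ests=60))
        targets = set(pm.matrix.loc[pm.matrix["target_id"] != "RANDOM", "target_id"])
        assert set(pm.truth.expressed_conditions) <= targets
        conditions = set(pm.matrix["condition_id"])
        for conds in pm.truth.expressed_conditions.values():
            assert set(conds) <= conditions
            assert len(conds) >= 2

    def test_random_probes_present_in_every_condition(self, small_config):
        pm = synth.gen_probe_matrix(replace(small_config, n_ests=30))
        nulls = pm.matrix[pm.matrix["target_id"] == "RANDOM"]
        assert set(nulls["condition_id"]) == set(pm.matrix["condition_id"])
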