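import numpy as np
import pytest

from mirhomology import (
    FixtureSpec,
    Kingdom,
    MiRNALibrary,
    ScreenConfig,
    filter_pairs,
    join_targets,
    make_screen_fixture,
    run_screen,
)
from mirhomology.screen import ComparisonResult
from mirhomology.significance import NullDistribution


def _null():
    return NullDistribution.from_scores([0.1, 0.2, 0.3, 0.4])


def _result(p_global, p_seed, plant="p", animal="a"):
    return ComparisonResult(
        plant_id=plant, animal_id=animal, s_global=0.5, s_seed=3.0,
        null_global=_null(), null_seed=_null(),
        p_global=p_global, p_seed=p_seed,
    )


class TestRunScreen:
    def test_cartesian_product_in_plant_major_order(self, tiny_plant, tiny_animal):
        cfg = ScreenConfig(n_scrambles=10, rng_seed=1)
        results = run_screen(tiny_plant, tiny_animal, cfg)
        assert len(results) == len(tiny_plant) * len(tiny_animal)
        expected = [(p.id, a.id) for p in tiny_plant for a in tiny_animal]
        assert [(r.plant_id, r.animal_id) for r in results] == expected

    def test_planted_copy_scores_one(self, tiny_plant, tiny_animal):
        # pla-1 and ani-1 carry the same sequence
        cfg = ScreenConfig(n_scrambles=10, rng_seed=1)
        results = run_screen(tiny_plant, tiny_animal, cfg)
        by_pair = {(r.plant_id, r.animal_id): r for r in results}
        assert by_pair[("pla-1", "ani-1")].s_global == 1.0

    def test_empty_library_rejected(self, tiny_plant):
        empty = MiRNALibrary(records=[], kingdom=Kingdom.ANIMAL)
        with pytest.raises(ValueError, match="non-empty"):
            run_screen(tiny_plant, empty)

    def test_reordering_libraries_leaves_pair_numbers_unchanged(self, tiny_plant, tiny_animal):
        cfg = ScreenConfig(n_scrambles=20, rng_seed=9)
        forward = run_screen(tiny_plant, tiny_animal, cfg)
        reordered = MiRNALibrary(records=list(tiny_animal)[::-1], kingdom=Kingdom.ANIMAL)
        backward = run_screen(tiny_plant, reordered, cfg)
        fwd = {(r.plant_id, r.animal_id): r for r in forward}
        bwd = {(r.plant_id, r.animal_id): r for r in backward}
        assert fwd == bwd


class TestFilterPairs:
    def test_conjunction_of_both_tests(self):
        results = [_result(0.01, 0.20), _result(0.20, 0.01), _result(0.01, 0.01)]
        selected = filter_pairs(results, ScreenConfig())
        assert [r.selected for r in results] == [False, False, True]
        assert selected == [results[2]]

    def test_raising_alpha_never_deselects(self):
        rng = np.random.default_rng(3)
        results = [_result(p, q) for p, q in rng.uniform(0, 1, size=(50, 2))]
        loose = ScreenConfig(alpha_global=0.2, alpha_seed=0.2)
        tight = ScreenConfig(alpha_global=0.05, alpha_seed=0.05)
        sel_tight = {id(r) for r in filter_pairs(results, tight)}
        sel_loose = {id(r) for r in filter_pairs(results, loose)}
        assert sel_tight <= sel_loose

    def test_bh_adjustment_is_less_permissive(self):
        ps = [0.001, 0.02, 0.04, 0.049, 0.5, 0.9]
        results = [_result(p, 0.001) for p in ps]
        raw = len(filter_pairs(results, ScreenConfig(p_adjust="none")))
        adj = len(filter_pairs(results, ScreenConfig(p_adjust="BH")))
        assert adj <= raw

    def test_empty_input(self):
        assert filter_pairs([], ScreenConfig()) == []


class TestJoinTargets:
    def test_no_selected_pairs_gives_empty_output(self):
        assert join_targets([], {"ani-1": ["TP53"]}) == []

    def test_plant_inherits_homolog_targets(self):
        sel = [_result(0.01, 0.01, plant="pla-1", animal="ani-1")]
        out = join_targets(sel, {"ani-1": ["TP53", "EGFR"]})
        assert out == [("pla-1", "TP53"), ("pla-1", "EGFR")]

    def test_shared_homolog_and_deduplication(self):
        sel = [
            _result(0.01, 0.01, plant="pla-1", animal="ani-1"),
            _result(0.01, 0.01, plant="pla-2", animal="ani-1"),
            _result(0.01, 0.01, plant="pla-1", animal="ani-2"),
        ]
        table = {"ani-1": ["G1", "G2"], "ani-2": ["G2", "G3"]}
        out = join_targets(sel, table)
        assert set(out) == {
            ("pla-1", "G1"), ("pla-1", "G2"), ("pla-1", "G3"),
            ("pla-2", "G1"), ("pla-2", "G2"),
        }
        # no duplicate (plant, gene) rows
        assert len(out) == len(set(out))

    def test_unknown_animal_id_warns_and_skips(self):
        sel = [_result(0.01, 0.01, plant="pla-1", animal="ani-unknown")]
        with pytest.warns(UserWarning, match="ani-unknown"):
            assert join_targets(sel, {"ani-1": ["G1"]}) == []


class TestPlantedHomologRecovery:
    def test_default_fixture_recovers_truth_and_rejects_decoys(self, default_fixture):
        plant, animal, truth = default_fixture
        results = run_screen(plant, animal, ScreenConfig(rng_seed=0))
        assert len(results) == 400
        selected = [r for r in results if r.selected]
        recovered = sum((r.plant_id, r.animal_id) in truth for r in selected)
        truth_plants = {p for p, _ in truth}
        decoy_plants = {r.id for r in plant} - truth_plants
        decoys_hit = {r.plant_id for r in selected if r.plant_id in decoy_plants}
        assert recovered >= 4
        assert len(decoys_hit) <= 2


class TestScreenConfig:
    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha_global"):
            ScreenConfig(alpha_global=0.0)

    def test_from_yaml_file(self, tmp_path):
        p = tmp_path / "config.yaml"
        p.write_text(
            "seed_start: 2\nseed_end: 8\nn_scrambles: 50\nrng_seed: 7\n"
            "alpha_global: 0.01\np_adjust: BH\nseed_mismatch: -0.4\n"
        )
        cfg = ScreenConfig.from_file(p)
        assert cfg.n_scrambles == 50
        assert cfg.rng_seed == 7
        assert cfg.alpha_global == 0.01
        assert cfg.p_adjust == "BH"
        assert cfg.alignment_params.mismatch_penalty == -0.4
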