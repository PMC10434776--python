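"""Design rendering, the attention objective, and the Pareto optimizer."""

import numpy as np
import pytest

from hudopt import codec
from hudopt.errors import ConfigError, DegenerateMapError, HudoptError
from hudopt.ga import GAConfig
from hudopt.moo import (
    MultiObjectiveOptimizer,
    ParetoFront,
    crowding_distance,
    dominates,
    fast_nondominated_sort,
)
from hudopt.render import (
    LayoutTemplate,
    aoi_coverage,
    attention_objective,
    default_template,
    render_design,
)


def _design(**overrides):
    choices = {g.name: 1 for g in codec.GROUPS}
    choices.update(overrides)
    return codec.InterfaceDesign(choices)


class TestRender:
    def test_deterministic_bytes(self):
        tpl = default_template(128, 64)
        d = _design(GM=2, GL=3)
        assert render_design(d, tpl).tobytes() == render_design(d, tpl).tobytes()

    def test_color_change_confined_to_aoi_fills(self):
        tpl = default_template(128, 64)
        a = render_design(_design(GM=1), tpl)
        b = render_design(_design(GM=4), tpl)
        changed = a != b
        assert changed.any()
        assert not changed[~tpl.aoi_mask()].any()

    def test_render_sweep_over_design_space_sample(self):
        tpl = default_template(320, 160)
        for i, design in enumerate(codec.iter_valid_designs()):
            if i % 173:
                continue
            img = render_design(design, tpl)
            assert img.shape == (160, 320)
            assert 0.0 <= img.min() and img.max() <= 1.0

    def test_template_validation(self):
        from hudopt.layout import Rect

        with pytest.raises(HudoptError):
            LayoutTemplate(64, 64, {"A": Rect(0, 0, 80, 10)})
        with pytest.raises(HudoptError):
            LayoutTemplate(64, 64, {"A": Rect(0, 0, 10, 10), "B": Rect(5, 5, 15, 15)})


class TestCoverage:
    def test_uniform_map_gives_area_ratio(self):
        tpl = default_template(96, 64)
        ratio = aoi_coverage(np.ones((64, 96)), tpl)
        assert ratio == pytest.approx(tpl.aoi_mask().mean())

    def test_mass_inside_boxes_gives_one(self):
        tpl = default_template(96, 64)
        m = np.where(tpl.aoi_mask(), 1.0, 0.0)
        assert aoi_coverage(m, tpl) == pytest.approx(1.0)

    def test_zero_mass_rejected(self):
        tpl = default_template(96, 64)
        with pytest.raises(DegenerateMapError):
            aoi_coverage(np.zeros((64, 96)), tpl)

    def test_objective_bounded_for_random_designs(self, rng):
        tpl = default_template(64, 64)

        class Uniform:
            def predict(self, X):
                return np.full((len(X), 64, 64), 0.5)

        for _ in range(20):
            choices = {g.name: int(rng.integers(1, g.arity + 1)) for g in codec.GROUPS}
            cov = attention_objective(Uniform(), codec.InterfaceDesign(choices), tpl)
            assert 0.0 <= cov <= 1.0


class TestDomination:
    def test_dominates_relation(self):
        assert dominates(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert dominates(np.array([1.0, 2.0]), np.array([1.0, 3.0]))
        assert not dominates(np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        assert not dominates(np.array([1.0, 1.0]), np.array([1.0, 1.0]))

    def test_two_point_toy_front(self):
        fronts = fast_nondominated_sort(np.array([[1.0, 1.0], [2.0, 2.0]]))
        assert fronts[0] == [0] and fronts[1] == [1]

    def test_sort_layers_match_bruteforce(self, rng):
        F = rng.random((30, 2))
        fronts = fast_nondominated_sort(F)
        assert sorted(i for fr in fronts for i in fr) == list(range(30))
        for i in fronts[0]:
            assert not any(dominates(F[j], F[i]) for j in range(30) if j != i)

    def test_crowding_extremes_infinite(self):
        F = np.array([[0.0, 3.0], [1.0, 2.0], [2.0, 1.0], [3.0, 0.0]])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[3])
        assert np.isfinite(d[1]) and np.isfinite(d[2])

    def test_front_container_rejects_dominated_member(self):
        with pytest.raises(ConfigError):
            ParetoFront(("a", "b"), np.array([[1.0, 1.0], [2.0, 2.0]]))


class _ToyObjectives:
    """o1 = x, o2 = 1 - x where x is the first GM bit: a pure trade-off."""

    def __call__(self, pop):
        x = pop[:, 0].astype(float)
        return np.stack([x, 1.0 - x], axis=1)


class TestMOO:
    def test_conflicting_toy_objectives_keep_both_extremes(self):
        cfg = GAConfig(population_size=16, max_generations=6, seed=0)
        fronts = MultiObjectiveOptimizer(_ToyObjectives(), cfg).run()
        final = fronts[-1].objectives
        assert {tuple(v) for v in final} == {(0.0, 1.0), (1.0, 0.0)}

    def test_final_front_nondominated_against_population(self, rng):
        def objectives(pop):
            # smooth conflicting objectives of the bit pattern
            x = pop[:, :13].sum(axis=1).astype(float)
            return np.stack([x, 13.0 - x + 0.1 * pop[:, 13:].sum(axis=1)], axis=1)

        cfg = GAConfig(population_size=24, max_generations=8, seed=2)
        fronts = MultiObjectiveOptimizer(objectives, cfg).run()
        F = fronts[-1].objectives
        for i in range(len(F)):
            assert not any(dominates(F[j], F[i]) for j in range(len(F)) if j != i)

    def test_seed_determinism(self):
        cfg = GAConfig(population_size=12, max_generations=5, seed=9)
        a = MultiObjectiveOptimizer(_ToyObjectives(), cfg).run()
        b = MultiObjectiveOptimizer(_ToyObjectives(), cfg).run()
        assert a[-1].codes == b[-1].codes

    def test_end_to_end_with_models(self, table3, small_scenes):
        from hudopt.ivpm import train_ivpm
        from hudopt.moo import run_moo_ga
        from hudopt.surrogate import train

        surrogate = train(table3, random_state=0)
        ivpm_model, _, _ = train_ivpm(small_scenes[:16], seed=0, epochs=2)
        tpl = default_template(64, 64)
        cfg = GAConfig(population_size=10, max_generations=3, seed=0)
        fronts = run_moo_ga(surrogate, ivpm_model, tpl, cfg, dataset=table3)
        assert len(fronts) == 3
        final = fronts[-1]
        assert len(final) >= 1
        for code, (load, neg_cov) in final.members:
            assert codec.is_valid_chromosome(code)
            assert -1.0 <= neg_cov <= 0.0
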