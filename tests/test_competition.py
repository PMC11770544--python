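"""Competition ratios, log-space graph least squares, anchoring, and cycle
consistency — cross-checked against a grid-search oracle and noise-free
round trips through the simulator."""

import numpy as np
import pytest

from larakit import (
    CompetitionObservation,
    CompetitionSimSpec,
    RelativeEfficiencySolver,
    aggregate_ratios,
    anchor_absolute,
    cycle_consistency_report,
    efficiency_ratio,
    simulate_competition,
    solve_relative_efficiencies,
)
from larakit.competition import chain_relative_efficiencies


def obs(x="X", y="Y", vx=1.0, vy=1.0, cx=30.0, cy=30.0, rep=0):
    return CompetitionObservation(
        enzyme="E", substrate_x=x, substrate_y=y, conc_x=cx, conc_y=cy,
        vx=vx, vy=vy, replicate=rep,
    )


class TestEfficiencyRatio:
    def test_equal_concentrations_cancel(self):
        assert efficiency_ratio(obs(vx=2.0, vy=1.0)) == pytest.approx(2.0)

    def test_concentration_correction(self):
        assert efficiency_ratio(obs(vx=1.0, vy=1.0, cx=60.0, cy=30.0)) == pytest.approx(0.5)

    def test_identical_replicates_have_zero_log_se(self):
        observations = [obs(vx=2.0, vy=1.0, rep=i) for i in range(3)]
        (estimate,) = aggregate_ratios(observations)
        assert estimate.ratio == pytest.approx(2.0)
        assert estimate.se_log == 0.0
        assert estimate.n == 3

    def test_zero_vy_rejected(self):
        with pytest.raises(ValueError, match="vy"):
            efficiency_ratio(obs(vx=1.0, vy=0.0))

    def test_zero_vx_flagged_as_no_activity(self):
        (estimate,) = aggregate_ratios([obs(vx=0.0, vy=1.0)])
        assert estimate.ratio == 0.0
        assert "no_activity_x" in estimate.flags


class TestSolveRelativeEfficiencies:
    def test_consistent_chain(self):
        (table,) = solve_relative_efficiencies(
            [(("A", "B"), 2.0), (("B", "C"), 5.0)]
        )
        assert table.as_dict() == pytest.approx({"A": 100.0, "B": 50.0, "C": 10.0})
        assert table.preferred == "A"
        assert table.as_dict()["A"] == 100.0  # exactly

    def test_consistent_triangle_zero_residuals(self):
        (table,) = solve_relative_efficiencies(
            [(("A", "B"), 2.0), (("B", "C"), 5.0), (("A", "C"), 10.0)]
        )
        assert table.as_dict() == pytest.approx({"A": 100.0, "B": 50.0, "C": 10.0})

    def test_inconsistent_triangle_matches_grid_search_oracle(self):
        ratios = [(("A", "B"), 2.0), (("B", "C"), 2.0), (("A", "C"), 3.0)]
        (table,) = solve_relative_efficiencies(ratios)

        # Independent oracle: dense grid over (log kB, log kC) with kA = 1,
        # refined once, minimizing the summed squared log residuals.
        targets = [np.log(2.0), np.log(2.0), np.log(3.0)]

        def sse(lb, lc):
            return (
                (0.0 - lb - targets[0]) ** 2
                + (lb - lc - targets[1]) ** 2
                + (0.0 - lc - targets[2]) ** 2
            )

        span = np.linspace(-2.0, 0.5, 501)
        lb_grid, lc_grid = np.meshgrid(span, span, indexing="ij")
        errors = sse(lb_grid, lc_grid)
        i, j = np.unravel_index(np.argmin(errors), errors.shape)
        fine_b = np.linspace(span[i] - 0.01, span[i] + 0.01, 401)
        fine_c = np.linspace(span[j] - 0.01, span[j] + 0.01, 401)
        fb, fc = np.meshgrid(fine_b, fine_c, indexing="ij")
        errors = sse(fb, fc)
        i, j = np.unravel_index(np.argmin(errors), errors.shape)
        expected = {
            "A": 100.0,
            "B": 100.0 * np.exp(fb[i, j]),
            "C": 100.0 * np.exp(fc[i, j]),
        }
        got = table.as_dict()
        for substrate in expected:
            assert got[substrate] == pytest.approx(expected[substrate], abs=1e-3 * 100)

    def test_edge_direction_invariance(self):
        forward = solve_relative_efficiencies([(("A", "B"), 2.0), (("B", "C"), 5.0)])
        backward = solve_relative_efficiencies(
            [(("B", "A"), 0.5), (("C", "B"), 0.2)]
        )
        assert forward[0].as_dict() == pytest.approx(backward[0].as_dict())

    def test_global_scale_invariance_and_exact_maximum(self):
        for scale in (1.0, 7.3e5):
            ratios = [(("A", "B"), 4.0), (("B", "C"), 2.5)]
            (table,) = solve_relative_efficiencies(ratios)
            values = table.as_dict()
            assert max(values.values()) == 100.0
            assert values == pytest.approx({"A": 100.0, "B": 25.0, "C": 10.0})

    def test_disconnected_components_produce_separate_tables(self):
        with pytest.warns(UserWarning, match="disconnected"):
            tables = solve_relative_efficiencies(
                [(("A", "B"), 2.0), (("C", "D"), 4.0)]
            )
        assert len(tables) == 2
        assert {t.preferred for t in tables} == {"A", "C"}

    def test_zero_ratio_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            solve_relative_efficiencies([(("A", "B"), 0.0)])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no ratios"):
            solve_relative_efficiencies([])

    def test_chain_mode_agrees_on_consistent_designs(self):
        ratios = [(("A", "B"), 2.0), (("B", "C"), 5.0), (("A", "C"), 10.0)]
        ls = solve_relative_efficiencies(ratios)[0].as_dict()
        chain = chain_relative_efficiencies(ratios)[0].as_dict()
        assert ls == pytest.approx(chain)


class TestAnchoring:
    def test_anchor_converts_relative_to_absolute(self):
        (table,) = solve_relative_efficiencies([(("A", "B"), 2.0)])
        absolute = anchor_absolute(table, "A", 1e4)
        assert absolute.as_dict() == pytest.approx({"A": 1e4, "B": 5e3})
        assert absolute.as_dict()["A"] == 1e4  # anchor cell exact

    def test_anchor_choice_invariance_on_consistent_table(self):
        (table,) = solve_relative_efficiencies([(("A", "B"), 2.0)])
        via_b = anchor_absolute(table, "B", 5e3)
        assert via_b.as_dict()["A"] == pytest.approx(1e4)

    def test_missing_anchor_substrate_rejected(self):
        (table,) = solve_relative_efficiencies([(("A", "B"), 2.0)])
        with pytest.raises(ValueError, match="anchor substrate"):
            anchor_absolute(table, "Z", 1e4)

    def test_anchor_ci_propagates_to_other_substrates(self):
        observations = []
        rng = np.random.default_rng(0)
        for rep in range(3):
            noise = float(np.exp(rng.normal(0, 0.05)))
            observations.append(obs(vx=2.0 * noise, vy=1.0, rep=rep))
        solver = RelativeEfficiencySolver().fit(observations)
        absolute = solver.anchor("X", 1e4, anchor_ci=(0.8e4, 1.25e4))
        lo, hi = absolute.ci_dict()["Y"]
        value = absolute.as_dict()["Y"]
        assert lo < value < hi
        assert absolute.ci_dict()["X"] == (0.8e4, 1.25e4)

    def test_noise_free_round_trip_recovers_hidden_table(self):
        substrates = ["S1", "S2", "S3", "S4", "S5", "S6"]
        hidden = dict(zip(substrates, (9.8e4, 1.02e4, 8.0e3, 9.0e1, 3.7e1, 2.4e1)))
        spec = CompetitionSimSpec(
            true_efficiencies=tuple(hidden.items()),
            pair_design=tuple(zip(substrates[:-1], substrates[1:])),
            noise_cv=0.0,
            replicates=1,
        )
        solver = RelativeEfficiencySolver().fit(simulate_competition(spec))
        absolute = solver.anchor("S1", hidden["S1"])
        for substrate, value in absolute.as_dict().items():
            assert abs(value - hidden[substrate]) / hidden[substrate] < 1e-10

    def test_round_trip_on_redundant_design(self):
        substrates = ["A", "B", "C", "D"]
        hidden = dict(zip(substrates, (1e4, 2.5e3, 4e2, 5e1)))
        pairs = (("A", "B"), ("B", "C"), ("C", "D"), ("A", "C"), ("B", "D"))
        spec = CompetitionSimSpec(
            true_efficiencies=tuple(hidden.items()),
            pair_design=pairs,
            noise_cv=0.0,
            replicates=1,
        )
        solver = RelativeEfficiencySolver().fit(simulate_competition(spec))
        absolute = solver.anchor("B", hidden["B"])
        for substrate, value in absolute.as_dict().items():
            assert abs(value - hidden[substrate]) / hidden[substrate] < 1e-10


class TestCycleConsistency:
    def test_consistent_triangle_unflagged(self):
        reports = cycle_consistency_report(
            [(("A", "B"), 2.0), (("B", "C"), 5.0), (("A", "C"), 10.0)]
        )
        assert len(reports) == 1
        assert reports[0].log_product == pytest.approx(0.0, abs=1e-12)
        assert not reports[0].flagged

    def test_inconsistent_cycle_flagged_with_product_four(self):
        reports = cycle_consistency_report(
            [(("A", "B"), 2.0), (("B", "C"), 2.0), (("C", "A"), 1.0)]
        )
        assert len(reports) == 1
        assert abs(reports[0].log_product) == pytest.approx(np.log(4.0))
        assert reports[0].flagged

    def test_tree_design_has_no_cycles(self):
        assert cycle_consistency_report([(("A", "B"), 2.0), (("B", "C"), 5.0)]) == []


class TestSolverEstimator:
    def test_fit_exposes_tables_and_cycles(self):
        observations = [obs(vx=2.0, vy=1.0, rep=i) for i in range(3)]
        solver = RelativeEfficiencySolver(enzyme="LarAH51").fit(observations)
        assert solver.table_.enzyme == "LarAH51"
        assert solver.table_.preferred == "X"
        assert solver.cycles_ == []

    def test_get_params_round_trip(self):
        solver = RelativeEfficiencySolver(enzyme="E", cycle_tolerance=0.1)
        clone_params = solver.get_params()
        assert clone_params == {"enzyme": "E", "cycle_tolerance": 0.1}
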