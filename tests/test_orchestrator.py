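"""End-to-end step/route validation, confidence updates, and fixtures."""

import json

import pytest
from hypothesis import given, strategies as st

from qcfill.energy_backends import SurrogateBackend
from qcfill.orchestrator import (
    RetroStep,
    Route,
    ValidationConfig,
    friedel_crafts_route,
    friedel_crafts_rule_table,
    load_route,
    make_fixtures,
    update_confidence,
    validate_route,
    validate_step,
    williamson_rule_table,
)


class TestValidateStep:
    def test_williamson_step_validated_and_confidence_raised(
        self, williamson_step, williamson_backend
    ):
        report = validate_step(williamson_step, backend=williamson_backend)
        assert report.status == "validated"
        assert report.n_trials_planned == 4  # mapping prunes 84 → 4
        assert report.verdict.target_barrier == pytest.approx(218.0)
        assert report.confidence_after == pytest.approx(0.71)
        assert report.confidence_after > report.confidence_before

    def test_without_mapping_the_full_exploration_runs(
        self, williamson_step, williamson_backend
    ):
        config = ValidationConfig(use_mapping=False)
        report = validate_step(williamson_step, config=config, backend=williamson_backend)
        assert report.status == "validated"
        assert report.n_trials_planned == 84
        assert report.summary.n_reactions == 38
        assert report.summary.n_endothermic == 34

    def test_decomposed_step_inconclusive_when_budget_cuts_the_second_search(self):
        route = friedel_crafts_route()
        backend = SurrogateBackend(rule_table=friedel_crafts_rule_table())
        config = ValidationConfig(trial_budget=100)
        report = validate_step(route.steps[0], config=config, backend=backend)
        assert report.status == "inconclusive"
        statuses = [r.status for r in report.sub_reports]
        assert statuses == ["validated", "inconclusive"]
        # the first elementary step (acylium formation) ran to completion …
        assert report.sub_reports[0].n_trials_run == report.sub_reports[0].n_trials_planned
        # … the second (aromatic attack) hit the budget wall mid-search
        assert report.sub_reports[1].n_trials_run < report.sub_reports[1].n_trials_planned
        assert report.confidence_after == report.confidence_before

    def test_empty_reactive_coordinate_is_inconclusive(self):
        step = RetroStep(
            product="CO",
            precursors=["CO", "O"],
            mapped_smiles="[CH3:1][OH:2].[OH2:3]>>[CH3:1][OH:2].[OH2:3]",
            confidence=0.5,
        )
        report = validate_step(step)
        assert report.status == "inconclusive"
        assert any("no reactive coordinate" in d for d in report.diagnostics)

    def test_unparseable_precursor_is_inconclusive_not_fatal(self):
        step = RetroStep(product="CCO", precursors=["CC(", "O"], confidence=0.3)
        report = validate_step(step)
        assert report.status == "inconclusive"
        assert report.confidence_after == 0.3

    def test_single_precursor_needs_no_bimolecular_partner(self):
        step = RetroStep(product="CCO", precursors=["CCO"], confidence=0.6)
        report = validate_step(step)
        assert report.status == "inconclusive"
        assert any("reacting pair" in d for d in report.diagnostics)


class TestUpdateConfidence:
    @pytest.mark.parametrize(
        "confidence, status, expected",
        [
            (0.42, "validated", 0.71),
            (1.0, "invalidated", 0.5),
            (0.0, "validated", 0.5),
            (0.9, "inconclusive", 0.9),
        ],
    )
    def test_default_combiner(self, confidence, status, expected):
        assert update_confidence(confidence, status) == pytest.approx(expected)

    @given(c=st.floats(min_value=0.0, max_value=1.0))
    def test_inconclusive_is_identity(self, c):
        assert update_confidence(c, "inconclusive") == c

    @given(
        c=st.floats(min_value=0.0, max_value=1.0),
        w=st.floats(min_value=0.0, max_value=1.0),
        status=st.sampled_from(["validated", "invalidated", "inconclusive"]),
    )
    def test_bounds_and_direction_preserved(self, c, w, status):
        updated = update_confidence(c, status, weight=w)
        assert 0.0 <= updated <= 1.0
        if status == "validated":
            assert updated >= c
        elif status == "invalidated":
            assert updated <= c

    def test_combiner_contract_enforced(self):
        with pytest.raises(ValueError, match="lower"):
            update_confidence(0.8, "validated", combiner=lambda c, s, w: 0.1)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            update_confidence(0.8, "validated", combiner=lambda c, s, w: 1.7)


class TestValidateRoute:
    def test_two_step_route_flags_the_low_confidence_acylation(self):
        route = friedel_crafts_route()
        backend = SurrogateBackend(rule_table=friedel_crafts_rule_table())
        result = validate_route(route, config=ValidationConfig(trial_budget=100), backend=backend)
        assert result.low_confidence_steps == [0]
        assert result.priority_order == [0, 1]  # acylation first: lowest confidence
        # the shared budget ran dry, so the later step is inconclusive with
        # its confidence untouched — never silently skipped
        assert result.reports[1].status == "inconclusive"
        assert result.updated_confidences[1] == route.steps[1].confidence

    def test_single_validated_step_route(self, williamson_step, williamson_backend):
        route = Route(steps=[williamson_step])
        result = validate_route(route, backend=williamson_backend)
        assert len(result.updated_confidences) == 1
        assert result.updated_confidences[0] == pytest.approx(0.71)

    def test_zero_budget_leaves_everything_inconclusive(
        self, williamson_step, williamson_backend
    ):
        route = Route(steps=[williamson_step])
        config = ValidationConfig(trial_budget=0)
        result = validate_route(route, config=config, backend=williamson_backend)
        assert [r.status for r in result.reports] == ["inconclusive"]
        assert result.updated_confidences == [williamson_step.confidence]

    def test_route_level_determinism(self, williamson_step):
        route = Route(steps=[williamson_step])
        docs = []
        for _ in range(2):
            backend = SurrogateBackend(rule_table=williamson_rule_table())
            result = validate_route(route, backend=backend)
            docs.append(json.dumps(result.to_dict(), sort_keys=True))
        assert docs[0] == docs[1]


class TestFixtures:
    def test_williamson_fixture_round_trips(self, tmp_path):
        paths = make_fixtures("williamson", seed=7, outdir=tmp_path)
        route = load_route(paths["route"])
        assert len(route.steps) == 1
        assert len(route.steps[0].precursors) == 2
        rules = json.loads(paths["rules"].read_text())
        barriers = {r["barrier"] for r in rules["rules"]}
        assert {218.0, 250.0, 253.0} <= barriers
        endothermic = [r for r in rules["rules"] if r["reaction_energy"] > 0]
        assert len(endothermic) == 34

    def test_friedel_crafts_fixture_shape(self, tmp_path):
        paths = make_fixtures("friedel_crafts", seed=7, outdir=tmp_path)
        route = load_route(paths["route"])
        assert len(route.steps) == 2
        acylation = route.steps[0]
        assert acylation.roles is not None and "catalyst" in acylation.roles
        assert len(acylation.decomposition) == 2

    def test_fixture_determinism(self, tmp_path):
        a = make_fixtures("williamson", seed=7, outdir=tmp_path / "a")
        b = make_fixtures("williamson", seed=7, outdir=tmp_path / "b")
        for k in a:
            assert a[k].read_bytes() == b[k].read_bytes()
        r1 = make_fixtures("random_route", seed=3, outdir=tmp_path / "c")
        r2 = make_fixtures("random_route", seed=3, outdir=tmp_path / "d")
        assert r1["route"].read_bytes() == r2["route"].read_bytes()

    def test_unknown_fixture_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixtures("grignard", seed=1, outdir=tmp_path)

    def test_confidence_out_of_range_rejected_by_schema(self):
        with pytest.raises(Exception):
            RetroStep(product="C", precursors=["C", "O"], confidence=1.2)
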