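import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vwmutil.scoring import (
    ReconstructionTrial,
    TrialEvent,
    aggregate_subjects,
    color_error,
    compute_utilization,
    exclude_outlier_trials,
    match_items,
    position_error,
    score_trial,
    scores_to_frame,
)
from vwmutil.simulate import AgentParams, simulate_reconstruction_trial
from vwmutil.stimuli import SquareItem, TargetModel, generate_target_model


def make_model(centers, hues=None):
    hues = hues or [0.0] * len(centers)
    return TargetModel(
        items=tuple(SquareItem(x, y, h) for (x, y), h in zip(centers, hues)),
        set_size=len(centers),
    )


def make_trial(model, n_views=1, empty_after=()):
    """Build a trial whose placements coincide with the model items, spread
    over ``n_views`` views; ``empty_after`` inserts extra empty views."""
    events = []
    t = 0.0
    per_view = math.ceil(model.set_size / n_views)
    idx = 0
    for v in range(n_views):
        events.append(TrialEvent("view", t))
        t += 1000.0
        if v in empty_after:
            events.append(TrialEvent("view", t))
            t += 1000.0
        for it in model.items[idx: idx + per_view]:
            events.append(TrialEvent("place", t, it.x_deg, it.y_deg, it.hue_deg))
            t += 500.0
            idx += 1
    return ReconstructionTrial(model=model, events=events)


class TestErrors:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (37.0, 37.0, 0.0),
            (0.0, 180.0, math.pi),
            (350.0, 10.0, math.radians(20.0)),  # 0.3491, wraps around 0
        ],
    )
    def test_color_error_circular(self, a, b, expected):
        assert color_error(a, b) == pytest.approx(expected, abs=1e-10)
        assert color_error(b, a) == pytest.approx(expected, abs=1e-10)

    def test_color_error_noncircular_option(self):
        assert color_error(350.0, 10.0, circular=False) == pytest.approx(
            math.radians(340.0)
        )

    def test_position_error_345(self):
        assert position_error(SquareItem(0, 0, 0), SquareItem(3, 4, 0)) == 5.0

    @settings(deadline=None, derandomize=True)
    @given(
        x1=st.floats(-6, 6), y1=st.floats(-6, 6),
        x2=st.floats(-6, 6), y2=st.floats(-6, 6),
    )
    def test_position_error_is_symmetric(self, x1, y1, x2, y2):
        a, b = SquareItem(x1, y1, 0), SquareItem(x2, y2, 0)
        assert position_error(a, b) == position_error(b, a)
        assert position_error(a, b) >= 0


class TestMatchItems:
    def test_single_placement_single_item(self):
        model = make_model([(1.0, 1.0)])
        res = match_items(model, [SquareItem(0.5, 0.5, 10.0)])
        assert not res.collision
        assert res.matches[0].target_index == 0

    def test_two_placements_same_target_collide(self):
        model = make_model([(0.0, 0.0), (5.0, 5.0)])
        res = match_items(
            model, [SquareItem(0.1, 0.0, 0), SquareItem(-0.1, 0.0, 0)]
        )
        assert res.collision

    def test_empty_placements_rejected(self):
        with pytest.raises(ValueError):
            match_items(make_model([(0, 0)]), [])

    def test_distance_tie_broken_by_lowest_index(self):
        model = make_model([(-1.0, 0.0), (1.0, 0.0)])
        res = match_items(model, [SquareItem(0.0, 0.0, 0)])
        assert res.matches[0].target_index == 0

    def test_agrees_with_min_total_distance_when_conflict_free(self, rng):
        # nearest-neighbor matching without conflicts is the global optimum;
        # check against exhaustive search over all one-to-one assignments
        checked = 0
        for _ in range(300):
            ss = int(rng.choice([2, 3, 4]))
            model = generate_target_model(ss, rng)
            k = int(rng.integers(1, ss + 1))
            subset = rng.choice(ss, size=k, replace=False)
            placements = [
                SquareItem(
                    model.items[i].x_deg + rng.normal(0, 0.2),
                    model.items[i].y_deg + rng.normal(0, 0.2),
                    model.items[i].hue_deg,
                )
                for i in subset
            ]
            res = match_items(model, placements)
            if res.collision:
                continue
            checked += 1
            pos = model.positions()
            best, best_cost = None, math.inf
            for perm in permutations(range(ss), k):
                cost = sum(
                    math.hypot(p.x_deg - pos[j][0], p.y_deg - pos[j][1])
                    for p, j in zip(placements, perm)
                )
                if cost < best_cost:
                    best, best_cost = perm, cost
            assert tuple(m.target_index for m in res.matches) == best
        assert checked > 200


class TestUtilization:
    def test_all_items_one_view(self):
        trial = make_trial(make_model([(0, 0), (3, 0), (0, 3), (3, 3)]))
        assert compute_utilization(trial) == 4.0

    def test_reviewing_before_placing_halves_ss1(self):
        model = make_model([(0, 0)])
        trial = make_trial(model, n_views=1, empty_after=(0,))
        assert compute_utilization(trial) == 0.5
        assert compute_utilization(trial, exclude_empty_views=True) == 1.0

    def test_nonempty_variant_at_least_plain(self, rng):
        a = AgentParams(
            capacity_k=4, utilization_u=1.3, sigma_pos_deg=0.4,
            kappa_color=6.0, p_empty_review=0.3,
        )
        for _ in range(100):
            ss = int(rng.choice([1, 2, 4]))
            trial = simulate_reconstruction_trial(
                a, generate_target_model(ss, rng), rng
            )
            plain = compute_utilization(trial)
            nonempty = compute_utilization(trial, exclude_empty_views=True)
            assert 0 < plain <= ss
            assert nonempty >= plain

    def test_trial_must_start_with_view(self):
        with pytest.raises(ValueError, match="view"):
            ReconstructionTrial(
                model=make_model([(0, 0)]),
                events=[TrialEvent("place", 0.0, 0, 0, 0)],
            )

    def test_placement_count_must_match_set_size(self):
        with pytest.raises(ValueError, match="placements"):
            ReconstructionTrial(
                model=make_model([(0, 0), (3, 3)]),
                events=[
                    TrialEvent("view", 0.0),
                    TrialEvent("place", 1.0, 0, 0, 0),
                ],
            )


def _score_rows(n, err=1.0, subject=0, ss=4, start_id=0, collision=False):
    rows = []
    for i in range(n):
        rows.append(
            dict(
                subject_id=subject, trial_id=start_id + i, set_size=ss,
                n_views=2, n_nonempty_views=2, utilization=2.0,
                utilization_nonempty=2.0,
                mean_position_error_deg=np.nan if collision else err,
                mean_color_error_rad=np.nan if collision else err / 10,
                view_time_ms=3000.0, collision=collision,
                excluded=collision,
                exclusion_reason="collision" if collision else "none",
            )
        )
    return rows


class TestOutlierExclusion:
    def test_single_extreme_trial_removed(self):
        df = pd.DataFrame(
            _score_rows(100, err=1.0)
            + [
                dict(
                    subject_id=0, trial_id=100, set_size=4, n_views=2,
                    n_nonempty_views=2, utilization=2.0, utilization_nonempty=2.0,
                    mean_position_error_deg=1000.0, mean_color_error_rad=0.1,
                    view_time_ms=3000.0, collision=False, excluded=False,
                    exclusion_reason="none",
                )
            ]
        )
        # jitter so the clean population has nonzero variance
        df.loc[:99, "mean_position_error_deg"] += np.linspace(0, 0.1, 100)
        out, report = exclude_outlier_trials(df)
        assert out["excluded"].sum() == 1
        assert out.loc[100, "exclusion_reason"] == "outlier"
        assert report.loc[0, "pct_outlier"] == pytest.approx(100 / 101, abs=0.01)

    def test_zero_variance_trims_nothing(self):
        df = pd.DataFrame(_score_rows(20, err=1.0))
        out, _ = exclude_outlier_trials(df)
        assert out["excluded"].sum() == 0

    def test_collisions_stay_out_of_the_trimming_population(self):
        df = pd.DataFrame(
            _score_rows(50, err=1.0) + _score_rows(5, collision=True, start_id=50)
        )
        df.loc[:49, "mean_position_error_deg"] += np.linspace(0, 0.1, 50)
        out, report = exclude_outlier_trials(df)
        assert (out.loc[out["collision"], "exclusion_reason"] == "collision").all()
        assert report.loc[0, "pct_collision"] == pytest.approx(100 * 5 / 55)
        assert report.loc[0, "pct_outlier"] == 0.0

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError, match="population"):
            exclude_outlier_trials(pd.DataFrame(_score_rows(5)), population="galaxy")


class TestAggregation:
    def test_noiseless_fixed_utilization_aggregates(self, rng):
        a = AgentParams(
            capacity_k=4, utilization_u=2, sigma_pos_deg=0.0,
            kappa_color=math.inf, p_empty_review=0.0,
        )
        scores = []
        for i in range(30):
            trial = simulate_reconstruction_trial(
                a, generate_target_model(4, rng), rng
            )
            trial.subject_id, trial.trial_id = 0, i
            scores.append(score_trial(trial))
        df, _ = exclude_outlier_trials(scores_to_frame(scores))
        summary = aggregate_subjects(df)
        row = summary.iloc[0]
        assert row["mean_utilization"] == 2.0  # SS / ceil(SS/u) = 4/2
        assert row["mean_position_error_deg"] == 0.0
        assert row["mean_color_error_rad"] == 0.0
        assert row["n_trials"] == 30

    def test_empty_cell_yields_missing_row(self):
        df = pd.DataFrame(_score_rows(3, collision=True))
        summary = aggregate_subjects(df)
        assert len(summary) == 1
        assert summary.iloc[0]["n_trials"] == 0
        assert np.isnan(summary.iloc[0]["mean_utilization"])
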