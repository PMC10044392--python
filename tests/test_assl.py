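"""Round manager: splits, pool accounting, stopping, reporting."""

from __future__ import annotations

import numpy as np
import pytest

from woundseg.assl import (
    ASSLConfig,
    ASSLRunner,
    PoolState,
    RoundState,
    bootstrap_round0,
    round_report,
    split_pool,
)
from woundseg.model import BackboneSpec, TrainingConfig, build_model
from woundseg.validation import ValidationResult


class TestSplitPool:
    def test_exact_ninety_ten(self):
        ids = [f"s{i:03d}" for i in range(100)]
        train, val = split_pool(ids, 0.1, seed=0)
        assert len(train) == 90 and len(val) == 10
        assert sorted(train + val) == sorted(ids)
        assert not set(train) & set(val)

    def test_rounding_rule_on_odd_pool(self):
        # 143 labeled at 10% -> round(14.3) = 14 validation, 129 training
        ids = [f"s{i:03d}" for i in range(143)]
        train, val = split_pool(ids, 0.1, seed=1)
        assert (len(train), len(val)) == (129, 14)

    def test_val_count_override(self):
        ids = [f"s{i:03d}" for i in range(143)]
        train, val = split_pool(ids, 0.1, seed=1, val_count=16)
        assert (len(train), len(val)) == (127, 16)

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(37)]
        assert split_pool(ids, 0.2, seed=7) == split_pool(ids, 0.2, seed=7)

    def test_too_small_pool(self):
        with pytest.raises(ValueError):
            split_pool(["only"], 0.1, seed=0)


class TestPoolState:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            PoolState(labeled=("a",), unlabeled=("a", "b"))

    def test_total(self):
        p = PoolState(labeled=("a", "b"), unlabeled=("c",))
        assert p.total == 3


class TestMiniRun:
    """Structural invariants of a seeded 3-round run on 50 images."""

    def test_pool_monotonicity(self, mini_run):
        _, history = mini_run
        for prev, cur in zip(history, history[1:]):
            assert set(prev.pool.labeled) <= set(cur.pool.labeled)

    def test_bookkeeping_conservation(self, mini_run):
        _, history = mini_run
        for st in history:
            assert st.pool.total == 50
            assert not set(st.pool.labeled) & set(st.pool.unlabeled)

    def test_round0_is_partial(self, mini_run):
        _, history = mini_run
        assert 0 < history[0].n_correct < 50

    def test_split_sizes_and_no_leakage(self, mini_run):
        runner, history = mini_run
        val = set(runner.val_ids_)
        # the validation split is drawn once from the round-0 pool and frozen
        assert val <= set(history[0].pool.labeled)
        for prev, st in zip(history, history[1:]):
            assert st.n_val == len(val)
            # each round trains on the pool as it stood at the round's start,
            # minus the frozen validation ids — so no validation id is ever
            # a training sample
            pool_at_start = set(prev.pool.labeled)
            assert st.n_train == len(pool_at_start - val)
            assert st.n_train + st.n_val == len(pool_at_start)

    def test_pseudo_labels_cover_labeled_pool(self, mini_run):
        runner, history = mini_run
        assert set(runner.pseudo_labels_) == set(history[-1].pool.labeled)

    def test_metrics_recorded(self, mini_run):
        _, history = mini_run
        assert np.isnan(history[0].f1)
        for st in history[1:]:
            assert 0.0 <= st.f1 <= 1.0
            assert 0.0 <= st.iou <= 1.0
            assert st.f1 >= st.iou


class TestOracleGating:
    def test_accept_everything_degenerates_to_self_training(self, mini_pretrained,
                                                            mini_dataset):
        """With no quality gate the whole dataset is pooled at round 0."""
        accept_all = lambda sid, pred, truth: ValidationResult(True, True, True)
        cfg = ASSLConfig(target_correct_fraction=0.999, max_rounds=1,
                         seed=1, training=TrainingConfig(epochs=1, learning_rate=1e-3))
        runner = ASSLRunner(mini_pretrained, cfg, decide=accept_all)
        history = runner.run(mini_dataset)
        assert history[0].n_correct == len(mini_dataset)
        assert len(history[0].pool.labeled) == len(mini_dataset)

    def test_reject_everything_warns_and_stops(self, mini_pretrained, mini_dataset):
        reject_all = lambda sid, pred, truth: ValidationResult(False, False, False)
        runner = ASSLRunner(mini_pretrained, ASSLConfig(seed=1), decide=reject_all)
        with pytest.warns(UserWarning, match="no masks"):
            history = runner.run(mini_dataset)
        assert len(history) == 1
        assert history[0].pool.labeled == ()

    def test_bootstrap_round0_only(self, mini_pretrained, mini_dataset):
        pool, state = bootstrap_round0(mini_pretrained, mini_dataset)
        assert state.round_index == 0
        assert state.n_train == state.n_val == 0
        assert len(pool.labeled) == state.n_correct


class TestStopping:
    def test_target_met_at_round0_runs_no_training(self, mini_pretrained, mini_dataset):
        accept_all = lambda sid, pred, truth: ValidationResult(True, True, True)
        cfg = ASSLConfig(target_correct_fraction=0.5, max_rounds=5, seed=1,
                         training=TrainingConfig(epochs=1))
        history = ASSLRunner(mini_pretrained, cfg, decide=accept_all).run(mini_dataset)
        assert len(history) == 1

    def test_plateau_stops_before_max_rounds(self, mini_pretrained, mini_dataset):
        """A gate that never accepts anything new forces a plateau stop."""
        frozen: dict[str, bool] = {}

        def first_round_only(sid, pred, truth):
            from woundseg.validation import oracle_validate
            if sid not in frozen:
                frozen[sid] = oracle_validate(pred, truth).accepted
            return ValidationResult(frozen[sid], frozen[sid], frozen[sid])

        cfg = ASSLConfig(target_correct_fraction=0.999, max_rounds=6,
                         plateau_patience=2, seed=1,
                         training=TrainingConfig(epochs=1, learning_rate=1e-3))
        history = ASSLRunner(mini_pretrained, cfg, decide=first_round_only).run(mini_dataset)
        # round 0 + exactly plateau_patience stalled training rounds
        assert len(history) == 3


class TestRecordedDecisions:
    def test_csv_round_trip_with_criteria(self, tmp_path):
        import pandas as pd
        from woundseg.assl import decisions_from_csv
        df = pd.DataFrame({
            "sample_id": ["a", "b"],
            "covers_wound": [True, False],
            "only_wound": [True, True],
            "boundary_ok": [True, True],
            "accepted": [True, False],
        })
        df.to_csv(tmp_path / "d.csv", index=False)
        decide = decisions_from_csv(tmp_path / "d.csv")
        assert decide("a", None, None).accepted
        assert not decide("b", None, None).accepted

    def test_accepted_only_schema(self, tmp_path):
        import pandas as pd
        from woundseg.assl import decisions_from_csv
        pd.DataFrame({"sample_id": ["x"], "accepted": [True]}).to_csv(
            tmp_path / "d.csv", index=False)
        decide = decisions_from_csv(tmp_path / "d.csv")
        assert decide("x", None, None).accepted

    def test_pending_ids_listed(self, tmp_path):
        import pandas as pd
        from woundseg.assl import decisions_from_csv
        pd.DataFrame({"sample_id": ["a"], "accepted": [True]}).to_csv(
            tmp_path / "d.csv", index=False)
        with pytest.raises(ValueError, match="b.*c|'b', 'c'"):
            decisions_from_csv(tmp_path / "d.csv", expected_ids=["a", "b", "c"])

    def test_unknown_sample_raises(self, tmp_path):
        import pandas as pd
        from woundseg.assl import decisions_from_csv
        pd.DataFrame({"sample_id": ["a"], "accepted": [True]}).to_csv(
            tmp_path / "d.csv", index=False)
        decide = decisions_from_csv(tmp_path / "d.csv")
        with pytest.raises(ValueError, match="zzz"):
            decide("zzz", None, None)


class TestRoundReport:
    def _mock_history(self):
        pools = [
            PoolState(tuple(f"s{i}" for i in range(60)),
                      tuple(f"s{i}" for i in range(60, 100))),
            PoolState(tuple(f"s{i}" for i in range(70)),
                      tuple(f"s{i}" for i in range(70, 100))),
        ]
        return [
            RoundState(0, 0, 0, 60, float("nan"), float("nan"), pools[0]),
            RoundState(1, 54, 6, 70, 0.98, 0.96, pools[1]),
        ]

    def test_columns_and_percentages(self):
        rep = round_report(self._mock_history())
        assert list(rep.columns) == [
            "round", "n_train", "train_pct", "n_val", "val_pct",
            "n_correct", "correct_pct", "f1", "iou",
        ]
        r1 = rep.iloc[1]
        assert r1["train_pct"] == pytest.approx(100 * 54 / 70)
        assert r1["correct_pct"] == pytest.approx(70.0)

    def test_report_of_real_run_round_trips(self, mini_run, tmp_path):
        from woundseg.io import load_history, save_history
        _, history = mini_run
        save_history(history, tmp_path / "history.json")
        loaded = load_history(tmp_path / "history.json")
        assert len(loaded) == len(history)
        for a, b in zip(history, loaded):
            assert a.pool == b.pool
            assert (a.round_index, a.n_train, a.n_val, a.n_correct) == (
                b.round_index, b.n_train, b.n_val, b.n_correct)
        assert round_report(loaded).equals(round_report(history))

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            round_report([])


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"val_fraction": 0.7},
        {"val_fraction": 0.0},
        {"target_correct_fraction": 0.0},
        {"max_rounds": 0},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ASSLConfig(**kwargs)
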