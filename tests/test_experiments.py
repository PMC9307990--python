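import numpy as np
import pandas as pd
import pytest

import tsgeeg as tg
from tsgeeg import (ProtocolConfig, SessionData, ablation_subsets,
                    channel_importance, cross_subject_summary, in_session,
                    non_constant_querying, summarize_table, transfer,
                    transfer_source_targets)


def tiny_cohort(n_subjects=2, n_sessions=1, seed=3, duration=40.0,
                specs=None, n_channels=4, jitter=0.1):
    specs = specs or tg.combined_effect_specs(n_channels=n_channels)
    cfg = tg.SyntheticCohortConfig(
        class_specs=specs, n_subjects=n_subjects,
        n_sessions_per_subject=n_sessions, n_channels=n_channels,
        duration_per_class=duration, subject_jitter=jitter, seed=seed,
    )
    return tg.build_sessions(tg.generate_cohort(cfg))


def fast_config(**kw):
    kw.setdefault("classifier", tg.LeafPosteriorForest(n_estimators=15))
    kw.setdefault("n_replicates", 3)
    kw.setdefault("seed", 1)
    return ProtocolConfig(**kw)


def stub_sessions(n_subjects, n_sessions):
    out = []
    k = 0
    for i in range(n_subjects):
        for j in range(n_sessions):
            out.append(SessionData(
                windows=np.zeros((2, 2, 4)), labels=np.array([0, 1]),
                sampling_rate=128.0, channel_labels=["a", "b"],
                subject_id=f"S{i:02d}", session_id=str(j), seed_key=k))
            k += 1
    return out


class TestInSession:
    def test_record_count(self):
        sessions = tiny_cohort(n_subjects=3)
        res = in_session(sessions, fast_config(n_replicates=4))
        assert len(res.records) == 3 * 4
        assert res.records["score"].between(0, 1).all()

    def test_replayable_from_seeds(self):
        sessions = tiny_cohort()
        cfg = fast_config()
        r1 = in_session(sessions, cfg)
        r2 = in_session(sessions, cfg)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_multiple_proportions_recorded_as_settings(self):
        sessions = tiny_cohort(n_subjects=1)
        res = in_session(sessions, fast_config(
            train_proportions=(0.5, 0.8), n_replicates=2))
        assert sorted(res.records["setting"].unique()) == [0.5, 0.8]

    def test_cohort_se_is_sd_of_subject_means(self):
        sessions = tiny_cohort(n_subjects=3)
        res = in_session(sessions, fast_config())
        m = res.subject_means(0.8)
        assert res.cohort_se(0.8) == pytest.approx(
            m.std(ddof=1) / np.sqrt(len(m)))


class TestQuerying:
    def test_ratio_one_reproduces_in_session_at_080(self):
        sessions = tiny_cohort()
        cfg_q = fast_config(labeled_ratios=(1.0,))
        cfg_i = fast_config(train_proportions=(0.8,))
        rq = non_constant_querying(sessions, cfg_q)
        ri = in_session(sessions, cfg_i)
        np.testing.assert_allclose(rq.records["score"].to_numpy(),
                                   ri.records["score"].to_numpy())

    def test_labeled_share_arithmetic(self):
        """Ratio 0.125 of an 80% training split labels 10% of the session."""
        from sklearn.model_selection import train_test_split
        n = 120
        labels = np.tile([0, 1], n // 2)
        tr, _ = train_test_split(np.arange(n), train_size=0.8,
                                 stratify=labels, random_state=0)
        lab, _ = train_test_split(np.arange(len(tr)), train_size=0.125,
                                  stratify=labels[tr], random_state=0)
        assert len(tr) == 96 and len(lab) == 12
        assert len(lab) / n == pytest.approx(0.125 * 0.8) == pytest.approx(0.1)

    def test_scores_recorded_per_ratio(self):
        sessions = tiny_cohort(n_subjects=1, duration=60.0)
        res = non_constant_querying(sessions, fast_config(
            labeled_ratios=(0.25, 1.0), n_replicates=2))
        assert sorted(res.records["setting"].unique()) == [0.25, 1.0]


class TestTransfer:
    def test_self_transfer_zero_shot_equals_in_session(self):
        sessions = tiny_cohort(n_subjects=1)
        cfg = fast_config(finetune_fractions=(0.0,))
        rt = transfer(sessions[0], sessions[0], cfg)
        ri = in_session(sessions, fast_config(train_proportions=(0.8,)))
        np.testing.assert_allclose(rt.records["score"].to_numpy(),
                                   ri.records["score"].to_numpy())

    def test_zero_shot_uses_source_model_unchanged(self):
        s1, s2 = tiny_cohort(n_subjects=2)
        cfg = fast_config(finetune_fractions=(0.0, 1.0))
        res = transfer(s1, s2, cfg)
        assert sorted(res.records["setting"].unique()) == [0.0, 1.0]
        assert res.records["score"].between(0, 1).all()

    def test_channel_mismatch_rejected(self):
        s1 = tiny_cohort(n_subjects=1, n_channels=4)[0]
        s2 = tiny_cohort(n_subjects=1, n_channels=6,
                         specs=tg.combined_effect_specs(n_channels=6))[0]
        with pytest.raises(ValueError, match="channel counts"):
            transfer(s1, s2, fast_config())


class TestCrossSubjectHarness:
    def test_mental_math_shape_gives_35_sources(self):
        plan = transfer_source_targets(stub_sessions(36, 1))
        assert len(plan) == 36
        assert all(len(sources) == 35 for _, sources in plan)

    def test_two_session_shape_gives_98_sources(self):
        plan = transfer_source_targets(stub_sessions(50, 2))
        assert len(plan) == 100
        assert all(len(sources) == 98 for _, sources in plan)

    def test_sources_never_share_target_subject(self):
        for target, sources in transfer_source_targets(stub_sessions(5, 2)):
            assert all(s.subject_id != target.subject_id for s in sources)

    def test_summary_min_mean_max_ordering(self, rng):
        rows = []
        for tgt in range(4):
            for src in range(3):
                rows.append({"target_subject": f"S{tgt}", "target_session": "0",
                             "source_subject": f"X{src}", "source_session": "0",
                             "setting": 0.0, "score": rng.random()})
        per_target, cohort = cross_subject_summary(pd.DataFrame(rows))
        assert (per_target["min"] <= per_target["mean"]).all()
        assert (per_target["mean"] <= per_target["max"]).all()
        assert (per_target["n_sources"] == 3).all()
        assert cohort.loc[0, "mean"] == pytest.approx(per_target["mean"].mean())

    def test_end_to_end_cross_subject(self):
        sessions = tiny_cohort(n_subjects=3)
        cfg = fast_config(n_replicates=2, finetune_fractions=(0.0,))
        pair_scores = tg.cross_subject_transfer(sessions, cfg)
        per_target, _ = cross_subject_summary(pair_scores)
        assert (per_target["n_sources"] == 2).all()


class TestAblation:
    def test_subset_counts_for_ten_channel_pool(self):
        pool = [3, 4, 5, 6, 7, 8, 13, 14, 18, 19]
        assert len(ablation_subsets(pool, 2)) == 1013  # 2^10 - 1 - 10
        assert len(ablation_subsets(pool, 1)) == 1023  # 2^10 - 1

    def test_tsg_rejects_singleton_request(self):
        sessions = tiny_cohort(n_subjects=1)
        with pytest.raises(ValueError, match="size >= 2"):
            tg.sensor_ablation(sessions, [0, 1, 2], fast_config(),
                               min_subset_size=1)

    def test_importance_hand_example(self):
        scores = {(1, 2): 0.9, (1, 3): 0.7, (2, 3): 0.5}
        res = channel_importance(scores)
        assert res.channel_importance[1] == pytest.approx(0.8)
        assert res.channel_importance[2] == pytest.approx(0.7)
        assert res.channel_importance[3] == pytest.approx(0.6)
        assert res.channel_ranks == [1, 2, 3]
        assert res.pair_ranks[0] == (1, 2)

    def test_equal_scores_tie_broken_by_index(self):
        scores = {(0, 1): 0.7, (0, 2): 0.7, (1, 2): 0.7}
        res = channel_importance(scores)
        assert res.channel_ranks == [0, 1, 2]

    def test_removing_foreign_subset_leaves_importance_unchanged(self):
        scores = {(1, 2): 0.9, (1, 3): 0.7, (2, 3): 0.5}
        imp_with = channel_importance(scores).channel_importance[1]
        del scores[(2, 3)]  # channel 1 is not in this subset
        imp_without = channel_importance(scores).channel_importance[1]
        assert imp_with == imp_without

    def test_planted_channels_recovered(self):
        sessions = tiny_cohort(
            n_subjects=1, duration=60.0, n_channels=4,
            specs=tg.planted_channel_specs(n_channels=4, channels=(0, 1)))
        res = tg.sensor_ablation(sessions, [0, 1, 2, 3],
                                 fast_config(n_replicates=3))
        assert set(res.channel_ranks[:2]) == {0, 1}

    def test_size_summary_quantiles(self):
        scores = {s: v for s, v in zip(ablation_subsets([0, 1, 2], 2),
                                       [0.5, 0.6, 0.7, 0.9])}
        res = channel_importance(scores)
        row = res.size_summary.set_index("size").loc[2]
        assert row["n_subsets"] == 3
        assert row["q05"] <= row["mean"] <= row["q95"]


class TestSummarizeTable:
    def test_cells_match_recomputation(self):
        sessions = tiny_cohort(n_subjects=2)
        res = in_session(sessions, fast_config())
        table = summarize_table({"TSG+BF in-session": res})
        cell = table.loc["TSG+BF in-session", 0.8]
        expected = (f"{100 * res.cohort_mean(0.8):.1f} "
                    f"({100 * res.cohort_se(0.8):.1f})")
        assert cell == expected

    def test_missing_cells_are_na(self):
        sessions = tiny_cohort(n_subjects=1)
        r1 = in_session(sessions, fast_config(train_proportions=(0.8,)))
        r2 = in_session(sessions, fast_config(train_proportions=(0.5,)))
        table = summarize_table({"a": r1, "b": r2})
        assert table.loc["a", 0.5] == "n/a" and table.loc["b", 0.8] == "n/a"


class TestBlockSplit:
    def test_test_set_is_contiguous_per_class(self):
        from tsgeeg.experiments import _block_split
        labels = np.array([0] * 30 + [1] * 30)
        tr, te = _block_split(np.arange(60), labels, 0.8, seed=4)
        assert len(te) == 12 and len(tr) == 48
        for c in (0, 1):
            block = np.sort(te[labels[te] == c])
            assert len(block) == 6
            assert (np.diff(block) == 1).all()

    def test_protocol_runs_in_block_mode(self):
        sessions = tiny_cohort(n_subjects=1)
        res = in_session(sessions, fast_config(block_split=True))
        assert len(res.records) == 3
        assert res.records["score"].between(0, 1).all()


class TestConfigValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            ProtocolConfig(train_proportions=(1.2,))

    def test_bad_feature_set_rejected(self):
        with pytest.raises(ValueError):
            ProtocolConfig(feature_set="wavelets")
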