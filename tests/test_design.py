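"""Rotation equalization, list composition, and run-length constraints."""

from __future__ import annotations

import numpy as np
import pytest

from smst.design import (
    CONDITIONS,
    DesignConfig,
    _max_run_length,
    _order_with_max_run,
    generate_trial_schedule,
    make_rotation_plan,
    save_schedules,
    load_schedules,
    schedules_to_frame,
    validate_schedule,
)
from smst.embedding import Phrase
from smst.errors import DesignError
from smst.stimuli import StimulusSet, Triplet


def _toy_stimulus_set(n_triplets, n_foils):
    triplets = [
        Triplet(
            noun=f"noun{i:03d}", target_adj=f"ta{i:03d}", close_adj=f"ca{i:03d}",
            distant_adj=f"da{i:03d}", sim_close=0.85, sim_distant=0.5,
        )
        for i in range(n_triplets)
    ]
    foils = [Phrase(f"fa{i:03d}", f"fn{i:03d}") for i in range(n_foils)]
    return StimulusSet(triplets=triplets, foils=foils)


class TestRotationPlan:
    def test_default_design_exposures_exact(self, design40):
        config, plan, _ = design40
        counts = plan.exposure_counts()
        assert set(np.unique(counts["target"])) == {20}
        assert set(np.unique(counts["close_lure"])) == {10}
        assert set(np.unique(counts["distant_lure"])) == {10}
        assert set(np.unique(counts["foil"])) == {8}

    def test_single_participant_cannot_equalize(self):
        # one participant partitions the triplet pool across conditions, so
        # per-condition exposure can never be equal across items
        ss = _toy_stimulus_set(4, 2)
        cfg = DesignConfig(
            n_participants=1, enc_targets=4, enc_fillers=0,
            rec_targets=2, rec_close=1, rec_distant=1, rec_foils=2,
            pool_triplets=4, pool_foils=2, seed=1,
        )
        with pytest.raises(DesignError):
            make_rotation_plan(cfg, ss)

    def test_minimal_full_cycle_identity_rotation(self):
        # the smallest full rotation cycle gives every item its exact quota
        ss = _toy_stimulus_set(4, 2)
        cfg = DesignConfig(
            n_participants=4, enc_targets=4, enc_fillers=0,
            rec_targets=2, rec_close=1, rec_distant=1, rec_foils=2,
            pool_triplets=4, pool_foils=2, seed=1,
        )
        plan = make_rotation_plan(cfg, ss)
        counts = plan.exposure_counts()
        assert set(np.unique(counts["target"])) == {2}
        assert set(np.unique(counts["close_lure"])) == {1}
        assert set(np.unique(counts["distant_lure"])) == {1}
        assert set(np.unique(counts["foil"])) == {4}

    def test_indivisible_participant_count_rejected(self):
        ss = _toy_stimulus_set(100, 125)
        cfg = DesignConfig(n_participants=39)
        with pytest.raises(DesignError, match="not\\s+divisible|multiple"):
            make_rotation_plan(cfg, ss)

    def test_pool_size_mismatch_rejected(self, design40):
        config, _, _ = design40
        with pytest.raises(DesignError, match="triplets"):
            make_rotation_plan(config, _toy_stimulus_set(50, 125))

    def test_per_participant_condition_partition_disjoint(self, design40):
        _, plan, _ = design40
        for assign in plan.triplet_conditions:
            # every triplet appears exactly once, in exactly one condition
            assert sorted(assign) == list(range(100))


class TestTrialSchedule:
    def test_paper_shaped_list_lengths(self, design40):
        config, _, schedules = design40
        assert all(len(s.encoding) == 200 for s in schedules)
        assert all(len(s.recognition) == 125 for s in schedules)

    def test_all_schedules_validate_clean(self, design40):
        config, _, schedules = design40
        for s in schedules:
            assert validate_schedule(s, config) == []

    def test_conservation_of_exposures_across_participants(self, design40):
        config, plan, schedules = design40
        seen: dict[tuple[str, str], int] = {}
        for s in schedules:
            for phrase, cond, _ in s.recognition:
                seen[(str(phrase), cond)] = seen.get((str(phrase), cond), 0) + 1
        by_cond = {c: [] for c in CONDITIONS}
        for (_, cond), n in seen.items():
            by_cond[cond].append(n)
        assert set(by_cond["target"]) == {20} and len(by_cond["target"]) == 100
        assert set(by_cond["close_lure"]) == {10} and len(by_cond["close_lure"]) == 100
        assert set(by_cond["distant_lure"]) == {10}
        assert set(by_cond["foil"]) == {8} and len(by_cond["foil"]) == 125

    def test_same_seed_reproducible_distinct_participants_differ(
        self, design40, stimulus_set
    ):
        config, plan, schedules = design40
        again = generate_trial_schedule(plan, 3, config, stimulus_set=stimulus_set)
        assert again.recognition == schedules[3].recognition
        assert again.encoding == schedules[3].encoding
        assert schedules[3].recognition != schedules[4].recognition

    def test_injected_run_violation_flagged(self, design40):
        config, _, schedules = design40
        s = schedules[0]
        foil_trials = [t for t in s.recognition if t[1] == "foil"][:4]
        other = [t for t in s.recognition if t not in foil_trials]
        tampered = type(s)(
            participant_id=s.participant_id,
            encoding=s.encoding,
            recognition=foil_trials + other,
        )
        report = validate_schedule(tampered, config)
        assert any("run length" in r for r in report)

    def test_unencoded_lure_noun_flagged(self, design40):
        config, _, schedules = design40
        s = schedules[0]
        bad = (Phrase("novellady", "neverseen"), "close_lure", 0.8)
        tampered = type(s)(
            participant_id=s.participant_id,
            encoding=s.encoding,
            recognition=[bad] + s.recognition[1:],
        )
        report = validate_schedule(tampered, config)
        assert any("never appeared at encoding" in r for r in report)

    def test_csv_roundtrip(self, design40, tmp_path):
        _, _, schedules = design40
        save_schedules(schedules[:3], tmp_path / "lists.csv")
        back = load_schedules(tmp_path / "lists.csv")
        assert back == schedules[:3]


class TestRunLengthOrdering:
    def test_strict_alternation_forced(self):
        rng = np.random.default_rng(0)
        labels = ["a"] * 10 + ["b"] * 10
        perm = _order_with_max_run(labels, rng, max_run=1)
        seq = [labels[i] for i in perm]
        assert seq == ["a", "b"] * 10 or seq == ["b", "a"] * 10

    @pytest.mark.parametrize("seed", range(5))
    def test_never_exceeds_max_run(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["t"] * 100 + ["f"] * 100
        perm = _order_with_max_run(labels, rng, max_run=3)
        assert sorted(perm) == list(range(200))
        assert _max_run_length([labels[i] for i in perm]) <= 3

    def test_random_valid_configs_validate_clean(self):
        # random small designs satisfying the divisibility invariants
        rng = np.random.default_rng(123)
        checked = 0
        attempts = 0
        while checked < 150 and attempts < 3000:
            attempts += 1
            block = int(rng.integers(1, 4))
            kt, kc, kd = (int(rng.integers(1, 4)) for _ in range(3))
            n_blocks = kt + kc + kd
            pool_t = block * n_blocks
            foil_cycle = int(rng.integers(1, 4))
            rec_foils = int(rng.integers(1, 5))
            pool_f = foil_cycle * rec_foils
            cycle = int(np.lcm(n_blocks, foil_cycle))
            n_part = cycle * int(rng.integers(1, 3))
            if n_part > 24:
                continue
            enc_fillers = min(int(rng.integers(0, 4)), pool_f - rec_foils)
            max_run = int(rng.integers(2, 5))

            def runs_feasible(counts, r=max_run):
                counts = [c for c in counts if c > 0]
                if len(counts) <= 1:
                    return True
                total = sum(counts)
                return all(c <= r * (total - c + 1) for c in counts)

            if not runs_feasible([pool_t, enc_fillers]):
                continue
            if not runs_feasible([block * kt, block * kc, block * kd, rec_foils]):
                continue
            cfg = DesignConfig(
                n_participants=n_part,
                enc_targets=pool_t, enc_fillers=enc_fillers,
                rec_targets=block * kt, rec_close=block * kc, rec_distant=block * kd,
                rec_foils=rec_foils, pool_triplets=pool_t, pool_foils=pool_f,
                max_run=max_run, seed=int(rng.integers(0, 1000)),
            )
            ss = _toy_stimulus_set(pool_t, pool_f)
            plan = make_rotation_plan(cfg, ss)
            for p in range(cfg.n_participants):
                s = generate_trial_schedule(plan, p, cfg, stimulus_set=ss)
                assert validate_schedule(s, cfg) == [], (cfg, p)
            checked += 1
        assert checked == 150


class TestScheduleExport:
    def test_frame_layout(self, design40):
        _, _, schedules = design40
        df = schedules_to_frame(schedules[:1])
        assert list(df.columns) == [
            "participant_id", "phase", "trial_index", "adjective", "noun",
            "role_or_condition", "similarity",
        ]
        assert (df.phase == "encoding").sum() == 200
        assert (df.phase == "recognition").sum() == 125
        rec = df[df.phase == "recognition"]
        assert rec[rec.role_or_condition == "target"].similarity.eq(1.0).all()
        assert rec[rec.role_or_condition == "foil"].similarity.isna().all()
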