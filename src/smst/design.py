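"""Counterbalanced per-participant encoding and recognition lists.

Every participant partitions the triplet pool across the three
triplet-derived recognition conditions (exact-repeat target, close lure,
distant lure) and sees a rotating block of the foil pool.  Rotating the
block-to-condition assignment across participants equalizes exposure
exactly: under the default design (40 participants, 100 triplets, 125
foils) every triplet serves as a target 20 times, as a close-lure source
10 times and a distant-lure source 10 times, and every foil appears 8
times.

Trial orderings are pseudorandomized under a run-length constraint: no
more than ``max_run`` consecutive trials may share a condition (applied
to both the encoding target/filler sequence and the recognition
condition sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from smst.embedding import Phrase
from smst.errors import DesignError, SchedulingError, ValidationError
from smst.stimuli import StimulusSet

EncodingRole = Literal["target", "filler"]
Condition = Literal["target", "close_lure", "distant_lure", "foil"]

CONDITIONS: tuple[Condition, ...] = ("target", "close_lure", "distant_lure", "foil")


@dataclass(frozen=True)
class DesignConfig:
    """Counts and constraints defining the experiment lists."""

    n_participants: int = 40
    enc_targets: int = 100
    enc_fillers: int = 100
    rec_targets: int = 50
    rec_close: int = 25
    rec_distant: int = 25
    rec_foils: int = 25
    pool_triplets: int = 100
    pool_foils: int = 125
    max_run: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_participants",
            "enc_targets",
            "rec_targets",
            "rec_close",
            "rec_distant",
            "rec_foils",
            "pool_triplets",
            "pool_foils",
            "max_run",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.enc_fillers < 0:
            raise ValidationError("enc_fillers must be non-negative")

    def check_divisibility(self) -> None:
        """Raise DesignError unless exact exposure equalization is possible."""
        checks = [
            ("rec_targets", self.rec_targets, self.pool_triplets),
            ("rec_close", self.rec_close, self.pool_triplets),
            ("rec_distant", self.rec_distant, self.pool_triplets),
            ("rec_foils", self.rec_foils, self.pool_foils),
        ]
        for name, per_list, pool in checks:
            if (self.n_participants * per_list) % pool != 0:
                raise DesignError(
                    f"n_participants * {name} = {self.n_participants * per_list} is not "
                    f"divisible by the pool size {pool}: exact equalization impossible"
                )
        if self.rec_targets + self.rec_close + self.rec_distant != self.pool_triplets:
            raise DesignError(
                "rec_targets + rec_close + rec_distant must equal pool_triplets "
                f"({self.rec_targets}+{self.rec_close}+{self.rec_distant} != "
                f"{self.pool_triplets}): every triplet must take exactly one "
                "recognition condition per participant"
            )
        block = math.gcd(self.rec_targets, self.rec_close, self.rec_distant)
        n_blocks = self.pool_triplets // block
        if self.n_participants % n_blocks != 0:
            raise DesignError(
                f"n_participants must be a multiple of {n_blocks} "
                f"(triplet rotation cycle) for exact equalization"
            )
        if self.pool_foils % self.rec_foils != 0:
            raise DesignError(
                f"pool_foils {self.pool_foils} not divisible by rec_foils "
                f"{self.rec_foils}: foil rotation impossible"
            )
        if self.n_participants % (self.pool_foils // self.rec_foils) != 0:
            raise DesignError(
                f"n_participants must be a multiple of {self.pool_foils // self.rec_foils} "
                "(foil rotation cycle) for exact equalization"
            )

    @property
    def expected_exposures(self) -> dict[str, float]:
        """Scheduled presentations per pool item in its own condition."""
        return {
            "target": self.n_participants * self.rec_targets / self.pool_triplets,
            "close_lure": self.n_participants * self.rec_close / self.pool_triplets,
            "distant_lure": self.n_participants * self.rec_distant / self.pool_triplets,
            "foil": self.n_participants * self.rec_foils / self.pool_foils,
        }


@dataclass
class RotationPlan:
    """Per-participant assignment of pool items to recognition conditions.

    ``triplet_conditions[p]`` maps triplet index -> condition for
    participant ``p``; ``foil_indices[p]`` lists the foil-pool indices
    that participant sees at recognition.
    """

    config: DesignConfig
    triplet_conditions: list[dict[int, Condition]]
    foil_indices: list[list[int]]

    def exposure_counts(self) -> dict[str, np.ndarray]:
        """Item-by-item presentation counts in each item's own condition."""
        cfg = self.config
        counts = {
            "target": np.zeros(cfg.pool_triplets, dtype=int),
            "close_lure": np.zeros(cfg.pool_triplets, dtype=int),
            "distant_lure": np.zeros(cfg.pool_triplets, dtype=int),
            "foil": np.zeros(cfg.pool_foils, dtype=int),
        }
        for assign in self.triplet_conditions:
            for idx, cond in assign.items():
                counts[cond][idx] += 1
        for foils in self.foil_indices:
            for idx in foils:
                counts["foil"][idx] += 1
        return counts


@dataclass
class TrialSchedule:
    """One participant's ordered encoding and recognition lists."""

    participant_id: int
    encoding: list[tuple[Phrase, EncodingRole]]
    recognition: list[tuple[Phrase, Condition, float | None]]


def make_rotation_plan(config: DesignConfig, stimulus_set: StimulusSet) -> RotationPlan:
    """Rotate pool items across participants for exact exposure equalization.

    Triplets are cut into equal blocks; a fixed block-role pattern
    (so many target blocks, close blocks, distant blocks) is rotated by
    one block per participant, so over each full rotation cycle every
    block serves every role its quota of times. Foils rotate as
    contiguous blocks of ``rec_foils``. The block *composition* is a
    seeded permutation, so lists differ across seeds while exposure
    counts stay exact.
    """
    config.check_divisibility()
    if len(stimulus_set.triplets) != config.pool_triplets:
        raise DesignError(
            f"stimulus set has {len(stimulus_set.triplets)} triplets, "
            f"config expects {config.pool_triplets}"
        )
    if len(stimulus_set.foils) != config.pool_foils:
        raise DesignError(
            f"stimulus set has {len(stimulus_set.foils)} foils, "
            f"config expects {config.pool_foils}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E37]))
    block = math.gcd(config.rec_targets, config.rec_close, config.rec_distant)
    n_blocks = config.pool_triplets // block
    # role pattern over blocks, e.g. defaults: (T, T, C, D)
    roles: list[Condition] = (
        ["target"] * (config.rec_targets // block)
        + ["close_lure"] * (config.rec_close // block)
        + ["distant_lure"] * (config.rec_distant // block)
    )
    triplet_perm = rng.permutation(config.pool_triplets)
    blocks = [
        list(triplet_perm[b * block : (b + 1) * block]) for b in range(n_blocks)
    ]

    foil_cycle = config.pool_foils // config.rec_foils
    foil_perm = rng.permutation(config.pool_foils)
    foil_blocks = [
        list(foil_perm[b * config.rec_foils : (b + 1) * config.rec_foils])
        for b in range(foil_cycle)
    ]

    triplet_conditions: list[dict[int, Condition]] = []
    foil_indices: list[list[int]] = []
    for p in range(config.n_participants):
        assign: dict[int, Condition] = {}
        for b in range(n_blocks):
            role = roles[(b + p) % n_blocks]
            for idx in blocks[b]:
                assign[int(idx)] = role
        triplet_conditions.append(assign)
        foil_indices.append([int(i) for i in foil_blocks[p % foil_cycle]])
    return RotationPlan(
        config=config,
        triplet_conditions=triplet_conditions,
        foil_indices=foil_indices,
    )


def _order_with_max_run(
    labels: Sequence[str],
    rng: np.random.Generator,
    max_run: int,
) -> list[int]:
    """Return a permutation of indices whose label sequence obeys max_run.

    Greedy sequential sampling with a feasibility guard: a label may be
    placed only if the run constraint allows it *and* every label c would
    still satisfy remaining_c <= max_run * (others_c + 1) afterwards (the
    rearrangement condition for runs of length <= max_run). Any choice
    that maintains the guard keeps the schedule completable, so the draw
    never dead-ends; labels are drawn with probability proportional to
    their remaining counts, and items within a label are pre-shuffled.
    """
    n = len(labels)
    pools: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        pools.setdefault(lab, []).append(i)
    if len(pools) <= 1:
        # a single-label list has no condition mixing to constrain
        return [int(i) for i in rng.permutation(n)]
    for lab in pools:
        pools[lab] = [pools[lab][j] for j in rng.permutation(len(pools[lab]))]
    counts = {lab: len(v) for lab, v in pools.items()}

    def feasible(after: dict[str, int]) -> bool:
        total = sum(after.values())
        return all(c <= max_run * (total - c + 1) for c in after.values())

    if not feasible(counts):
        raise SchedulingError(
            f"run-length constraint max_run={max_run} unsatisfiable "
            f"for label counts {counts}"
        )

    out: list[int] = []
    last: str | None = None
    run = 0
    for _ in range(n):
        allowed = []
        for lab, c in counts.items():
            if c == 0 or (lab == last and run >= max_run):
                continue
            counts[lab] -= 1
            if feasible(counts):
                allowed.append(lab)
            counts[lab] += 1
        if not allowed:
            raise SchedulingError(
                f"run-length constraint max_run={max_run} unsatisfiable "
                f"for label counts {counts} (run of {last!r})"
            )
        weights = np.array([counts[lab] for lab in allowed], dtype=float)
        lab = allowed[rng.choice(len(allowed), p=weights / weights.sum())]
        out.append(pools[lab].pop())
        counts[lab] -= 1
        run = run + 1 if lab == last else 1
        last = lab
    return out


def _max_run_length(seq: Sequence[str]) -> int:
    best = run = 0
    prev = None
    for s in seq:
        run = run + 1 if s == prev else 1
        prev = s
        best = max(best, run)
    return best


def _participant_rng(seed: int, participant_id: int) -> np.random.Generator:
    # stable per-participant substream, independent of generation order
    return np.random.default_rng(np.random.SeedSequence([seed, 1 + participant_id]))


def generate_trial_schedule(
    plan: RotationPlan,
    participant_id: int,
    config: DesignConfig | None = None,
    seed: int | None = None,
    stimulus_set: StimulusSet | None = None,
) -> TrialSchedule:
    """Build one participant's pseudorandomized encoding + recognition lists.

    Encoding presents every triplet's target phrase (the nouns later
    probed at recognition) plus fillers; recognition presents exact
    repeats for target-condition triplets and the banded lure phrase for
    lure-condition triplets, plus the participant's foil block. Fillers
    are target phrases of triplets unassigned to this participant's
    recognition conditions, topped up with foil-pool phrases *not* in
    this participant's recognition foils, so no filler reappears at
    recognition and no recognition-foil noun is pre-exposed.
    """
    config = config or plan.config
    if stimulus_set is None:
        raise ValidationError("stimulus_set is required to materialize phrases")
    if not (0 <= participant_id < len(plan.triplet_conditions)):
        raise ValidationError(f"participant {participant_id} not in plan")
    seed = config.seed if seed is None else seed
    rng = _participant_rng(seed, participant_id)

    triplets = stimulus_set.triplets
    foils = stimulus_set.foils
    assign = plan.triplet_conditions[participant_id]
    my_foils = plan.foil_indices[participant_id]

    # encoding: targets of all assigned triplets, then fillers
    assigned = sorted(assign)
    if len(assigned) < config.enc_targets:
        raise DesignError(
            f"plan assigns {len(assigned)} triplets but enc_targets={config.enc_targets}"
        )
    target_phrases = [triplets[i].target for i in assigned[: config.enc_targets]]

    unassigned = [i for i in range(len(triplets)) if i not in assign]
    unseen_foils = [i for i in range(len(foils)) if i not in set(my_foils)]
    filler_pool: list[Phrase] = [triplets[i].target for i in unassigned] + [
        foils[i] for i in unseen_foils
    ]
    if len(filler_pool) < config.enc_fillers:
        raise DesignError(
            f"filler pool has {len(filler_pool)} phrases, need {config.enc_fillers}"
        )
    filler_order = rng.permutation(len(filler_pool))[: config.enc_fillers]
    fillers = [filler_pool[i] for i in filler_order]

    enc_items: list[tuple[Phrase, EncodingRole]] = [
        (p, "target") for p in target_phrases
    ] + [(p, "filler") for p in fillers]
    enc_perm = _order_with_max_run([r for _, r in enc_items], rng, config.max_run)
    encoding = [enc_items[i] for i in enc_perm]

    # recognition: condition-specific phrases and similarities
    rec_items: list[tuple[Phrase, Condition, float | None]] = []
    by_cond: dict[Condition, list[int]] = {c: [] for c in CONDITIONS}
    for idx, cond in assign.items():
        by_cond[cond].append(idx)
    for idx in sorted(by_cond["target"])[: config.rec_targets]:
        rec_items.append((triplets[idx].target, "target", 1.0))
    for idx in sorted(by_cond["close_lure"])[: config.rec_close]:
        rec_items.append((triplets[idx].close_lure, "close_lure", triplets[idx].sim_close))
    for idx in sorted(by_cond["distant_lure"])[: config.rec_distant]:
        rec_items.append(
            (triplets[idx].distant_lure, "distant_lure", triplets[idx].sim_distant)
        )
    for idx in my_foils[: config.rec_foils]:
        rec_items.append((foils[idx], "foil", None))

    rec_perm = _order_with_max_run([c for _, c, _ in rec_items], rng, config.max_run)
    recognition = [rec_items[i] for i in rec_perm]

    return TrialSchedule(
        participant_id=participant_id, encoding=encoding, recognition=recognition
    )


def generate_all_schedules(
    plan: RotationPlan, stimulus_set: StimulusSet, config: DesignConfig | None = None
) -> list[TrialSchedule]:
    config = config or plan.config
    return [
        generate_trial_schedule(plan, p, config, stimulus_set=stimulus_set)
        for p in range(config.n_participants)
    ]


def validate_schedule(schedule: TrialSchedule, config: DesignConfig) -> list[str]:
    """Check every schedule invariant; returns a list of violation messages."""
    report: list[str] = []
    enc_n = config.enc_targets + config.enc_fillers
    if len(schedule.encoding) != enc_n:
        report.append(
            f"encoding length {len(schedule.encoding)} != {enc_n}"
        )
    rec_n = config.rec_targets + config.rec_close + config.rec_distant + config.rec_foils
    if len(schedule.recognition) != rec_n:
        report.append(f"recognition length {len(schedule.recognition)} != {rec_n}")

    counts = {c: 0 for c in CONDITIONS}
    for _, cond, _ in schedule.recognition:
        counts[cond] += 1
    expected = {
        "target": config.rec_targets,
        "close_lure": config.rec_close,
        "distant_lure": config.rec_distant,
        "foil": config.rec_foils,
    }
    for cond, want in expected.items():
        if counts[cond] != want:
            report.append(f"{cond} count {counts[cond]} != {want}")

    enc_labels = [r for _, r in schedule.encoding]
    enc_runs = _max_run_length(enc_labels)
    if len(set(enc_labels)) > 1 and enc_runs > config.max_run:
        report.append(f"encoding run length {enc_runs} > max_run {config.max_run}")
    rec_runs = _max_run_length([c for _, c, _ in schedule.recognition])
    if rec_runs > config.max_run:
        report.append(f"recognition run length {rec_runs} > max_run {config.max_run}")

    encoded_target_nouns = {p.noun for p, role in schedule.encoding if role == "target"}
    encoded_nouns = {p.noun for p, _ in schedule.encoding}
    for phrase, cond, _ in schedule.recognition:
        if cond in ("close_lure", "distant_lure") and phrase.noun not in encoded_target_nouns:
            report.append(
                f"lure noun {phrase.noun!r} never appeared at encoding as a target"
            )
        if cond == "foil" and phrase.noun in encoded_nouns:
            report.append(f"foil noun {phrase.noun!r} appeared at encoding")
    return report


def schedules_to_frame(schedules: Sequence[TrialSchedule]) -> pd.DataFrame:
    """Flatten schedules to the CSV export layout."""
    rows = []
    for s in schedules:
        for i, (phrase, role) in enumerate(s.encoding):
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "phase": "encoding",
                    "trial_index": i,
                    "adjective": phrase.adjective,
                    "noun": phrase.noun,
                    "role_or_condition": role,
                    "similarity": np.nan,
                }
            )
        for i, (phrase, cond, sim) in enumerate(s.recognition):
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "phase": "recognition",
                    "trial_index": i,
                    "adjective": phrase.adjective,
                    "noun": phrase.noun,
                    "role_or_condition": cond,
                    "similarity": np.nan if sim is None else sim,
                }
            )
    return pd.DataFrame(rows)


def schedules_from_frame(df: pd.DataFrame) -> list[TrialSchedule]:
    schedules = []
    for pid, g in df.groupby("participant_id", sort=True):
        enc = g[g.phase == "encoding"].sort_values("trial_index")
        rec = g[g.phase == "recognition"].sort_values("trial_index")
        encoding = [
            (Phrase(r.adjective, r.noun), r.role_or_condition) for r in enc.itertuples()
        ]
        recognition = [
            (
                Phrase(r.adjective, r.noun),
                r.role_or_condition,
                None if pd.isna(r.similarity) else float(r.similarity),
            )
            for r in rec.itertuples()
        ]
        schedules.append(
            TrialSchedule(participant_id=int(pid), encoding=encoding, recognition=recognition)
        )
    return schedules


def save_schedules(schedules: Sequence[TrialSchedule], path: str | Path) -> None:
    schedules_to_frame(schedules).to_csv(path, index=False)


def load_schedules(path: str | Path) -> list[TrialSchedule]:
    return schedules_from_frame(pd.read_csv(path, float_precision="round_trip"))
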