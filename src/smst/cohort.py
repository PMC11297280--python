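"""Generative probit signal-detection model of recognition responses.

Each recognition decision arises from a latent-evidence race: the linear
predictor (intercept, similarity slope, age offsets, a per-participant
intercept) plus standard normal noise crosses zero for an 'old'
response, so the marginal 'old' probability is the probit of the linear
predictor.  Targets carry similarity 1.0 (exact repeats), lures their
banded compound-phrase cosine, and foils have no similarity term.  A
small lapse rate mixes in uniform guessing; confidence is read off the
absolute latent evidence against two thresholds.

The default slope and age coefficients are anchored on reported effect
sizes for this design in the verbal-aging literature (log of the
exponentiated estimates: similarity ln 158.0, old-age offset ln 3.67,
similarity x age ln 0.25).  The foil intercept is then chosen so that,
at the similarity levels the default stimulus build realizes (close
lures near 0.92, distant near 0.53), per-condition 'old' proportions
show the canonical ordering targets >> close lures > distant lures >
foils, with old adults above young on lures and slightly below on
targets.  A single-index probit cannot simultaneously match all four
observed response levels of a real cohort (exact repetition boosts
targets beyond what similarity alone predicts); the preset favors the
ordering over absolute levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from smst.design import TrialSchedule
from smst.errors import ValidationError

AgeGroup = Literal["young", "old"]
Response = Literal["old", "new"]
Confidence = Literal["guessing", "unsure", "sure"]


@dataclass(frozen=True)
class ResponseModelParams:
    """Coefficients of the generative probit response model."""

    b0_foil: float = -4.4
    b_sim: float = math.log(158.0)
    b_age: float = math.log(3.67)
    b_sim_age: float = math.log(0.25)
    sd_participant: float = 0.35
    lapse: float = 0.02
    conf_thresholds: tuple[float, float] = (0.8, 2.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse <= 0.5):
            raise ValidationError(f"lapse must lie in [0, 0.5], got {self.lapse}")
        if self.sd_participant < 0:
            raise ValidationError("sd_participant must be non-negative")
        lo, hi = self.conf_thresholds
        if not lo < hi:
            raise ValidationError("conf_thresholds must be strictly increasing")


@dataclass(frozen=True)
class TrialResponse:
    """One recognition decision with its condition and similarity."""

    participant_id: int
    age_group: AgeGroup
    condition: str
    similarity: float | None
    response: Response
    confidence: Confidence
    trial_index: int

    def __post_init__(self) -> None:
        if self.condition == "foil":
            if self.similarity is not None:
                raise ValidationError("foil trials carry no similarity")
        else:
            if self.similarity is None:
                raise ValidationError(f"{self.condition} trial requires a similarity")
            if self.condition == "target" and self.similarity != 1.0:
                raise ValidationError("targets carry similarity 1.0")


def _linear_predictor(
    condition: str,
    similarity: float | None,
    age_group: str,
    participant_effect: float,
    params: ResponseModelParams,
) -> float:
    old = 1.0 if age_group == "old" else 0.0
    eta = params.b0_foil + params.b_age * old + participant_effect
    if condition != "foil":
        if similarity is None:
            raise ValidationError(f"{condition} trial requires a similarity")
        if not (0.0 <= similarity <= 1.0):
            raise ValidationError(f"similarity {similarity} outside [0, 1]")
        eta += (params.b_sim + params.b_sim_age * old) * similarity
    return eta


def response_probability(
    condition: str,
    similarity: float | None,
    age_group: AgeGroup,
    participant_effect: float,
    params: ResponseModelParams,
) -> float:
    """P('old') for one trial: lapse/2 + (1 - lapse) * Phi(linear predictor)."""
    eta = _linear_predictor(condition, similarity, age_group, participant_effect, params)
    return float(params.lapse / 2.0 + (1.0 - params.lapse) * norm.cdf(eta))


def _participant_stream(seed: int, participant_id: int) -> np.random.Generator:
    # stable per-participant substream keyed by id, not by iteration order
    return np.random.default_rng(np.random.SeedSequence([seed, 7_777, participant_id]))


def simulate_cohort(
    schedules: Sequence[TrialSchedule],
    age_assignment: dict[int, AgeGroup],
    params: ResponseModelParams | None = None,
    seed: int = 0,
) -> list[TrialResponse]:
    """Draw one TrialResponse per recognition trial of every schedule.

    Participant intercepts are drawn once per participant from
    N(0, sd_participant^2); the response on each trial is 'old' when the
    latent evidence (linear predictor + standard normal noise) is
    positive, except on lapse trials, where a fair coin decides.
    Confidence bins |evidence| against ``conf_thresholds``. Fully
    reproducible from ``seed`` via per-participant substreams.
    """
    params = params or ResponseModelParams()
    responses: list[TrialResponse] = []
    for schedule in schedules:
        pid = schedule.participant_id
        if pid not in age_assignment:
            raise ValidationError(f"participant {pid} has no age-group assignment")
        age = age_assignment[pid]
        rng = _participant_stream(seed, pid)
        participant_effect = float(rng.normal(0.0, params.sd_participant))

        n = len(schedule.recognition)
        etas = np.array(
            [
                _linear_predictor(cond, sim, age, participant_effect, params)
                for _, cond, sim in schedule.recognition
            ]
        )
        noise = rng.standard_normal(n)
        evidence = etas + noise
        old = evidence > 0
        lapse_mask = rng.random(n) < params.lapse
        coin = rng.random(n) < 0.5
        old = np.where(lapse_mask, coin, old)

        lo, hi = params.conf_thresholds
        abs_ev = np.abs(evidence)
        conf = np.where(abs_ev < lo, "guessing", np.where(abs_ev < hi, "unsure", "sure"))

        for i, (_, cond, sim) in enumerate(schedule.recognition):
            responses.append(
                TrialResponse(
                    participant_id=pid,
                    age_group=age,
                    condition=cond,
                    similarity=sim,
                    response="old" if old[i] else "new",
                    confidence=str(conf[i]),
                    trial_index=i,
                )
            )
    return responses


def responses_to_frame(responses: Sequence[TrialResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "age_group": r.age_group,
                "trial_index": r.trial_index,
                "condition": r.condition,
                "similarity": np.nan if r.similarity is None else r.similarity,
                "response": r.response,
                "confidence": r.confidence,
            }
            for r in responses
        ]
    )


def responses_from_frame(df: pd.DataFrame) -> list[TrialResponse]:
    return [
        TrialResponse(
            participant_id=int(r.participant_id),
            age_group=str(r.age_group),
            condition=str(r.condition),
            similarity=None if pd.isna(r.similarity) else float(r.similarity),
            response=str(r.response),
            confidence=str(r.confidence),
            trial_index=int(r.trial_index),
        )
        for r in df.itertuples()
    ]


def save_responses(responses: Sequence[TrialResponse], path: str | Path) -> None:
    responses_to_frame(responses).to_csv(path, index=False)


def load_responses(path: str | Path) -> list[TrialResponse]:
    return responses_from_frame(pd.read_csv(path, float_precision="round_trip"))


def default_age_assignment(n_participants: int) -> dict[int, AgeGroup]:
    """First half young, second half old (balanced groups)."""
    half = n_participants // 2
    return {
        p: ("young" if p < half else "old") for p in range(n_participants)
    }
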