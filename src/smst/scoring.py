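"""Signal-detection summaries: 'old' proportions, d' contrasts, LDI.

d' for a contrast is z(p('old'|target)) - z(p('old'|comparison)), with
an explicit edge correction for proportions of 0 or 1 (clip to
1/(2N) .. 1 - 1/(2N)) or the always-on log-linear correction
((count + 0.5) / (N + 1)); which one ran is recorded per score.

The LDI follows the three-response variant of the task exactly as the
companion picture task prints it: p('similar'|foil) - p('similar'|lure).
Note this is the *negation* of the more common lure-minus-foil
convention; the sign is kept as printed so scores are directly
comparable with that task's output.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from smst.cohort import TrialResponse, responses_to_frame
from smst.errors import ValidationError

CONDITIONS = ("target", "close_lure", "distant_lure", "foil")


def _as_frame(responses: Sequence[TrialResponse] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(responses, pd.DataFrame):
        return responses
    return responses_to_frame(responses)


def response_proportions(
    responses: Sequence[TrialResponse] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-participant 'old' proportions and trial counts by condition.

    Rows with a missing response (no press within the response window)
    are excluded from both numerator and denominator. Raises if any
    participant lacks trials in any condition present in the design.
    """
    df = _as_frame(responses)
    df = df[df.response.notna()]
    out_rows = []
    for pid, g in df.groupby("participant_id", sort=True):
        row: dict = {"participant_id": pid}
        if "age_group" in g.columns:
            row["age_group"] = g.age_group.iloc[0]
        for cond in CONDITIONS:
            sub = g[g.condition == cond]
            if len(sub) == 0:
                raise ValidationError(
                    f"participant {pid} has zero trials in condition {cond!r}"
                )
            short = {"target": "target", "close_lure": "close",
                     "distant_lure": "distant", "foil": "foil"}[cond]
            row[f"p_old_{short}"] = float((sub.response == "old").mean())
            row[f"n_{short}"] = int(len(sub))
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def _correct(p: float, n: int, correction: str) -> tuple[float, bool]:
    if correction == "clip":
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        pc = min(max(p, lo), hi)
        return pc, pc != p
    if correction == "loglinear":
        return (p * n + 0.5) / (n + 1.0), True
    raise ValueError(f"unknown correction {correction!r}")


def dprime(
    p_hit: float,
    p_fa: float,
    n_hit_trials: int,
    n_fa_trials: int,
    correction: str = "clip",
) -> float:
    """z(hit rate) - z(false-alarm rate) with an explicit edge correction.

    ``correction="clip"`` bounds each proportion to [1/(2N), 1 - 1/(2N)]
    and only bites at 0 or 1; ``correction="loglinear"`` applies
    (count + 0.5)/(N + 1) to every proportion.
    """
    for name, p in (("p_hit", p_hit), ("p_fa", p_fa)):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name}={p} outside [0, 1]")
    if n_hit_trials <= 0 or n_fa_trials <= 0:
        raise ValidationError("trial counts must be positive")
    ph, _ = _correct(p_hit, n_hit_trials, correction)
    pf, _ = _correct(p_fa, n_fa_trials, correction)
    return float(norm.ppf(ph) - norm.ppf(pf))


def dprime_scores(
    responses: Sequence[TrialResponse] | pd.DataFrame, correction: str = "clip"
) -> pd.DataFrame:
    """Per-participant d' for target-vs-close, -distant, -foil contrasts."""
    props = response_proportions(responses)
    rows = []
    for r in props.itertuples():
        row = {"participant_id": r.participant_id}
        if hasattr(r, "age_group"):
            row["age_group"] = r.age_group
        for contrast in ("close", "distant", "foil"):
            p_fa = getattr(r, f"p_old_{contrast}")
            n_fa = getattr(r, f"n_{contrast}")
            row[f"dprime_target_vs_{contrast}"] = dprime(
                r.p_old_target, p_fa, r.n_target, n_fa, correction
            )
            row[f"corrected_{contrast}"] = bool(
                _correct(r.p_old_target, r.n_target, correction)[1]
                or _correct(p_fa, n_fa, correction)[1]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def dprime_lures_collapsed(
    responses: Sequence[TrialResponse] | pd.DataFrame, correction: str = "clip"
) -> pd.DataFrame:
    """Per-participant target-vs-lure d' with close and distant lures pooled.

    This is the single lure-discriminability score used to correlate the
    phrase task with the picture task (which has no similarity grading).
    """
    df = _as_frame(responses)
    df = df[df.response.notna()]
    rows = []
    for pid, g in df.groupby("participant_id", sort=True):
        hits = g[g.condition == "target"]
        lures = g[g.condition.isin(["close_lure", "distant_lure"])]
        if len(hits) == 0 or len(lures) == 0:
            raise ValidationError(f"participant {pid} lacks target or lure trials")
        row = {
            "participant_id": pid,
            "dprime_target_vs_lure": dprime(
                float((hits.response == "old").mean()),
                float((lures.response == "old").mean()),
                len(hits),
                len(lures),
                correction,
            ),
        }
        if "age_group" in g.columns:
            row["age_group"] = g.age_group.iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def similarity_response_curve(
    responses: Sequence[TrialResponse] | pd.DataFrame, n_bins: int = 5
) -> pd.DataFrame:
    """Binned 'old'-response rate as a function of cosine similarity.

    Pools target and lure trials (foils carry no similarity), bins the
    similarity axis into ``n_bins`` equal-width bins per age group, and
    returns one row per (age_group, bin) with the bin midpoint, the
    'old' rate and the trial count — the minimal table behind a
    similarity-response curve plot.
    """
    df = _as_frame(responses)
    df = df[(df.condition != "foil") & df.response.notna()].copy()
    if df.empty:
        raise ValidationError("no target/lure trials to bin")
    edges = np.linspace(float(df.similarity.min()) - 1e-9, 1.0, n_bins + 1)
    df["bin"] = np.digitize(df.similarity, edges[1:-1])
    rows = []
    for (age, b), g in df.groupby(["age_group", "bin"], sort=True):
        rows.append(
            {
                "age_group": age,
                "similarity_mid": float((edges[b] + edges[b + 1]) / 2),
                "p_old": float((g.response == "old").mean()),
                "n_trials": int(len(g)),
            }
        )
    return pd.DataFrame(rows)


def ldi(responses: pd.DataFrame) -> float:
    """Lure discrimination index of the three-response task format.

    p('similar'|foil) - p('similar'|lure), exactly as the picture task
    prints it (the negation of the common lure-minus-foil convention).
    Input needs columns ``condition`` (containing 'foil' and lure
    conditions) and ``response`` with a three-way old/similar/new coding.
    """
    df = responses[responses.response.notna()]
    if not (df.response == "similar").any():
        warnings.warn(
            "no 'similar' responses found; input may not be three-response data",
            stacklevel=2,
        )
    is_lure = df.condition.str.contains("lure")
    foils = df[df.condition == "foil"]
    lures = df[is_lure]
    if len(foils) == 0 or len(lures) == 0:
        raise ValidationError("LDI needs both foil and lure trials")
    p_sim_foil = float((foils.response == "similar").mean())
    p_sim_lure = float((lures.response == "similar").mean())
    return p_sim_foil - p_sim_lure


def ldi_scores(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant LDI for three-response (old/similar/new) data."""
    rows = []
    for pid, g in responses.groupby("participant_id", sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append({"participant_id": pid, "ldi": ldi(g)})
    return pd.DataFrame(rows)
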