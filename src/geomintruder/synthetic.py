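"""Synthetic behavioral data with the statistical structure the analysis
pipeline assumes.

Two groups perform the 88-trial tactile intruder task: a blind group
(default 9 subjects) and a blindfolded sighted group (default 13).  Per
trial, the probability of an error grows linearly with the shape's
empirical complexity rank (1..11), with a group-specific slope and a
Gaussian subject-level intercept shift; the linear-probability form (not
logistic) is deliberately matched to the linear slope estimators used in
the analysis stage, with clipping at the [0, 1] boundary.  Confidence
(Likert 1..10) decreases linearly with complexity rank and is coupled to
the subject's realized session error rate, mirroring the subject-level
confidence-on-error regression.

The packaged defaults in ``data/group_params.json`` carry the fitted
group-level slopes and coupling as generative truths, so parameter
recovery can be checked against them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from importlib.resources import files

import numpy as np
import pandas as pd

from .geometry import FAMILY_ORDER, CardSpec

__all__ = [
    "GroupParams",
    "default_group_params",
    "default_model_weights",
    "simulate_subject",
    "simulate_experiment",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "subject",
    "group",
    "trial",
    "card_id",
    "family",
    "complexity_rank",
    "chosen_position",
    "correct",
    "confidence",
]

_RANK_OF = {name: i + 1 for i, name in enumerate(FAMILY_ORDER)}


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one experimental group.

    ``error_intercept`` + ``error_slope_per_rank`` * rank (+ subject shift)
    is the per-trial error probability; ``conf_*`` build the confidence
    score, with ``conf_error_coupling`` in Likert units per unit error
    rate acting through the subject's realized session error rate.
    """

    label: str
    n_subjects: int
    error_intercept: float
    error_slope_per_rank: float
    subject_sd: float
    conf_intercept: float
    conf_slope_per_rank: float
    conf_error_coupling: float
    conf_noise_sd: float

    def to_dict(self) -> dict:
        return asdict(self)


def default_group_params() -> tuple[GroupParams, GroupParams]:
    """The packaged (blind, blindfolded) generative parameters."""
    raw = json.loads(
        files("geomintruder.data").joinpath("group_params.json").read_text()
    )
    return GroupParams(**raw["blind"]), GroupParams(**raw["blindfolded"])


def default_model_weights() -> dict[str, float]:
    raw = json.loads(
        files("geomintruder.data").joinpath("group_params.json").read_text()
    )
    return raw["model_weights"]


def _ranks_of(sequence: list[CardSpec]) -> np.ndarray:
    return np.array([_RANK_OF[c.family] for c in sequence])


def simulate_subject(
    params: GroupParams,
    sequence: list[CardSpec],
    subject_seed: int | np.random.SeedSequence,
    subject_id: str = "s01",
) -> pd.DataFrame:
    """Simulate one subject's pass through a sequenced deck.

    Error probability per trial: clip(intercept + slope * rank + u, 0, 1)
    with u ~ Normal(0, subject_sd) drawn once per subject.  On an error
    the chosen position is uniform over the five wrong positions.
    Confidence: round(clip(conf_intercept + conf_slope * rank +
    coupling * realized_error_rate + eps, 1, 10)).
    """
    rng = np.random.default_rng(subject_seed)
    ranks = _ranks_of(sequence)
    u = rng.normal(0.0, params.subject_sd) if params.subject_sd > 0 else 0.0
    p_raw = params.error_intercept + params.error_slope_per_rank * ranks + u
    p = np.clip(p_raw, 0.0, 1.0)
    if np.all((p_raw <= 0) | (p_raw >= 1)):
        warnings.warn(
            f"subject {subject_id}: error probability clipped at every rank "
            f"(raw range {p_raw.min():.3f}..{p_raw.max():.3f})"
        )
    errs = rng.random(len(sequence)) < p
    chosen = np.empty(len(sequence), dtype=int)
    for i, (card, e) in enumerate(zip(sequence, errs)):
        if e:
            wrong = [k for k in range(1, 7) if k != card.intruder_position]
            chosen[i] = wrong[rng.integers(5)]
        else:
            chosen[i] = card.intruder_position
    err_rate = errs.mean()
    conf_raw = (
        params.conf_intercept
        + params.conf_slope_per_rank * ranks
        + params.conf_error_coupling * err_rate
        + rng.normal(0.0, params.conf_noise_sd, size=len(sequence))
    )
    conf = np.rint(np.clip(conf_raw, 1.0, 10.0)).astype(int)
    return pd.DataFrame(
        {
            "subject": subject_id,
            "group": params.label,
            "trial": np.arange(1, len(sequence) + 1),
            "card_id": [c.card_id for c in sequence],
            "family": [c.family for c in sequence],
            "complexity_rank": ranks,
            "chosen_position": chosen,
            "correct": ~errs,
            "confidence": conf,
        }
    )


def simulate_experiment(
    blind: GroupParams,
    blindfolded: GroupParams,
    sequence: list[CardSpec],
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate the full two-group experiment over one sequenced deck.

    Returns a trial-record table (one row per subject x trial) with the
    generative parameters attached as provenance in ``.attrs``.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(blind.n_subjects + blindfolded.n_subjects)
    tables = []
    k = 0
    for params, prefix in ((blind, "b"), (blindfolded, "f")):
        for i in range(params.n_subjects):
            tables.append(
                simulate_subject(
                    params, sequence, children[k], subject_id=f"{prefix}{i + 1:02d}"
                )
            )
            k += 1
    out = pd.concat(tables, ignore_index=True)
    out.attrs["generative_params"] = {
        "blind": blind.to_dict(),
        "blindfolded": blindfolded.to_dict(),
    }
    return out
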