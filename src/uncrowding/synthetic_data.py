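"""Seeded generator of synthetic Likert rating datasets.

Emulates the rating-study design: each participant rates each of the six
flanker configurations (A-F) twice per side (left/right), i.e. 24
judgments per participant.  Ratings come from a thresholded-Gaussian
latent model (cumulative-link structure):

    latent = condition_mean + participant_effect + trial_noise
    rating = 1 + #(cutpoints < latent)

The default condition means are illustrative, shaped like the observed
qualitative pattern (gapped conditions rated high, long flankers low,
inward inducers elevating the long condition); they are NOT estimates of
the human data, which are unpublished.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .rating_analysis import CONDITION_CODES, RATING_COLUMNS, validate_ratings

__all__ = [
    "DEFAULT_LATENT_MEANS",
    "RatingModelParams",
    "generate_ratings",
    "generate_null_pair",
    "params_to_yaml",
    "params_from_yaml",
]

#: Illustrative per-condition latent means (strictly distinct so rank-order
#: recovery is well defined).  Gapped conditions (B, D, F) high, long
#: flankers (A) low, inward inducers (C) in between, mirroring the
#: qualitative summary-figure pattern.
DEFAULT_LATENT_MEANS = {
    "A": 1.8,
    "B": 3.5,
    "C": 2.9,
    "D": 4.0,
    "E": 2.3,
    "F": 4.5,
}

SIDES = ("left", "right")
REPETITIONS = (1, 2)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class RatingModelParams:
    condition_latent_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_MEANS)
    )
    participant_sd: float = 0.4
    trial_sd: float = 0.7
    cutpoints: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5)
    n_participants: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        cp = np.asarray(self.cutpoints, dtype=float)
        if len(cp) != 4 or not np.all(np.diff(cp) > 0):
            raise ParameterError("cutpoints must be 4 strictly increasing values")
        if self.participant_sd < 0 or self.trial_sd < 0:
            raise ParameterError("standard deviations must be non-negative")
        missing = set(CONDITION_CODES) - set(self.condition_latent_means)
        if missing:
            raise ParameterError(f"missing latent means for conditions: {sorted(missing)}")
        if self.n_participants < 1:
            raise ParameterError("need at least one participant")


def _discretize(latent: np.ndarray, cutpoints) -> np.ndarray:
    # side="right": a latent value exactly on a cutpoint maps upward, so an
    # integer-plus-half mean with default cutpoints yields its own rating
    return 1 + np.searchsorted(np.asarray(cutpoints, dtype=float), latent, side="right")


def generate_ratings(params: RatingModelParams = RatingModelParams()) -> pd.DataFrame:
    """Complete design: every participant x 6 conditions x 2 sides x 2 reps.

    Trial order is randomized independently per participant; the whole
    dataset is a deterministic function of ``params`` (including the seed).
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    design = [
        (cond, side, rep)
        for cond in CONDITION_CODES
        for side in SIDES
        for rep in REPETITIONS
    ]
    for pid in range(1, params.n_participants + 1):
        p_eff = rng.normal(0.0, params.participant_sd)
        order = rng.permutation(len(design))
        for k in order:
            cond, side, rep = design[k]
            latent = (
                params.condition_latent_means[cond]
                + p_eff
                + rng.normal(0.0, params.trial_sd)
            )
            rating = int(_discretize(np.asarray([latent]), params.cutpoints)[0])
            rows.append((pid, cond, side, rep, rating))
    data = pd.DataFrame(rows, columns=RATING_COLUMNS)
    validate_ratings(data)
    return data


def generate_null_pair(
    params: RatingModelParams,
    conditions: tuple[str, str] = ("A", "D"),
    delta: float = 0.0,
) -> pd.DataFrame:
    """Two-condition dataset in which both conditions share one latent mean.

    The shared mean is the first condition's; ``delta`` shifts the second
    condition away from the null (for power checks).  Useful as a type-I
    error harness for the signed-rank test.
    """
    c1, c2 = conditions
    if c1 == c2:
        raise ParameterError("conditions must differ")
    mu = params.condition_latent_means[c1]
    means = dict(params.condition_latent_means)
    means[c1] = mu
    means[c2] = mu + delta
    full = generate_ratings(replace(params, condition_latent_means=means))
    return full[full.condition.isin([c1, c2])].reset_index(drop=True)


def params_to_yaml(params: RatingModelParams) -> str:
    doc = {
        "condition_latent_means": dict(params.condition_latent_means),
        "participant_sd": params.participant_sd,
        "trial_sd": params.trial_sd,
        "cutpoints": list(params.cutpoints),
        "n_participants": params.n_participants,
        "seed": params.seed,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def params_from_yaml(text: str) -> RatingModelParams:
    doc = yaml.safe_load(text)
    if "cutpoints" in doc:
        doc["cutpoints"] = tuple(doc["cutpoints"])
    return RatingModelParams(**doc)
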