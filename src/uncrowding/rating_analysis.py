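"""Summaries and nonparametric tests for Likert rating datasets.

A rating dataset is a long-format table with columns
``participant, condition, side, repetition, rating`` where conditions are
coded A-F (A = long flankers, B = gapped, C = long + inward inducers,
D = gapped + inward, E = long + outward, F = gapped + outward) and ratings
are integers 1-5.

The signed-rank test is implemented from scratch: midranks for tied
absolute differences, the smaller signed-rank sum as the statistic, and an
exact p-value from the full distribution over all 2^n sign assignments
(computed by dynamic programming, equivalent to complete enumeration).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONDITION_CODES",
    "RATING_COLUMNS",
    "WilcoxonResult",
    "ConditionSummary",
    "ConsistencyResult",
    "validate_ratings",
    "condition_summary",
    "wilcoxon_signed_rank",
    "within_consistency",
    "paired_condition_test",
    "read_ratings",
    "write_ratings",
]

CONDITION_CODES = ("A", "B", "C", "D", "E", "F")
RATING_COLUMNS = ["participant", "condition", "side", "repetition", "rating"]

#: Condition code -> battery condition name.
CODE_TO_CONDITION = {
    "A": "LONG",
    "B": "GAPPED",
    "C": "LONG_INWARD",
    "D": "GAPPED_INWARD",
    "E": "LONG_OUTWARD",
    "F": "GAPPED_OUTWARD",
}


def validate_ratings(data: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"rating table missing columns: {missing}")
    r = data["rating"]
    if not ((r >= 1) & (r <= 5) & (r == r.astype(int))).all():
        raise ValueError("ratings must be integers in 1..5")
    bad = set(data["condition"]) - set(CONDITION_CODES)
    if bad:
        raise ValueError(f"unknown condition codes: {sorted(bad)}")


@dataclass(frozen=True)
class ConditionSummary:
    grand_means: pd.Series  # condition -> mean over all ratings (NaN if absent)
    participant_means: pd.DataFrame  # participant x condition
    complete: bool  # every participant x condition cell has 4 ratings


def condition_summary(data: pd.DataFrame) -> ConditionSummary:
    """Per-condition grand means and per-participant condition means."""
    validate_ratings(data)
    grand = data.groupby("condition")["rating"].mean()
    grand = grand.reindex(CONDITION_CODES)
    per = data.pivot_table(index="participant", columns="condition", values="rating", aggfunc="mean")
    per = per.reindex(columns=CONDITION_CODES)
    counts = data.groupby(["participant", "condition"]).size()
    complete = bool(len(counts) and (counts == 4).all()
                    and counts.index.get_level_values("condition").nunique() == len(CONDITION_CODES))
    return ConditionSummary(grand_means=grand, participant_means=per, complete=complete)


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test result.

    ``statistic`` is the smaller of the positive and negative signed-rank
    sums (the conventional W); midranks are used for tied absolute
    differences.
    """

    statistic: float
    p_value: float
    n_effective: int
    w_plus: float
    w_minus: float
    sidedness: str
    method: str
    zero_policy: str

    def __str__(self) -> str:  # convention printed with every report
        return (
            f"Wilcoxon signed-rank: W = {self.statistic:g} "
            f"(smaller signed-rank sum; W+ = {self.w_plus:g}, W- = {self.w_minus:g}), "
            f"n = {self.n_effective}, p = {self.p_value:.4g} "
            f"({self.sidedness}, {self.method}, zeros: {self.zero_policy})"
        )


def _exact_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ over all 2^n sign assignments.

    Ranks are midranks, so they live on a half-integer grid; doubling makes
    them integers and the distribution is built by iterated polynomial
    multiplication — arithmetic identical to full enumeration.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r] if r else counts
        counts = counts + shifted if r else counts * 2
    support = np.arange(total + 1) / 2.0
    return support, counts / counts.sum()


def wilcoxon_signed_rank(
    x,
    y=None,
    zero_policy: str = "discard",
    sidedness: str = "two_sided",
    method: str = "auto",
    exact_limit: int = 25,
) -> WilcoxonResult:
    """Paired signed-rank test on ``x - y`` (or on ``x`` directly if y is None).

    ``sidedness``: "two_sided" (default), "greater" (W+ large), or "less".
    ``method``: "auto" picks exact enumeration for n <= ``exact_limit``,
    normal approximation (with tie correction and continuity correction)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    if y is None:
        d = x
    else:
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        d = x - y
    if sidedness not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if zero_policy not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    nonzero = d != 0
    if zero_policy == "discard":
        d_used = d[nonzero]
        ranks = stats.rankdata(np.abs(d_used)) if len(d_used) else np.zeros(0)
    else:  # pratt: rank zeros too, then drop them from the sums
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    n_eff = len(d_used)
    if n_eff == 0:
        warnings.warn("all paired differences are zero; degenerate result", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, 0.0, 0.0, sidedness, "degenerate", zero_policy)

    w_plus = float(ranks[d_used > 0].sum())
    w_minus = float(ranks[d_used < 0].sum())
    statistic = min(w_plus, w_minus)

    if method == "auto":
        method = "exact_enumeration" if n_eff <= exact_limit else "normal_approx"

    if method == "exact_enumeration":
        support, pmf = _exact_distribution(ranks)
        cdf = np.cumsum(pmf)
        sf = np.cumsum(pmf[::-1])[::-1]

        def p_le(w):  # P(W+ <= w)
            return float(cdf[np.searchsorted(support, w + 1e-9, side="right") - 1])

        def p_ge(w):  # P(W+ >= w)
            return float(sf[np.searchsorted(support, w - 1e-9, side="left")])

        if sidedness == "greater":
            p = p_ge(w_plus)
        elif sidedness == "less":
            p = p_le(w_plus)
        else:
            p = min(1.0, p_le(min(w_plus, w_minus)) + p_ge(max(w_plus, w_minus)))
    elif method == "normal_approx":
        mu = ranks.sum() / 2.0
        sigma = np.sqrt((ranks**2).sum() / 4.0)  # tie-corrected (midranks enter directly)
        if sidedness == "greater":
            p = float(stats.norm.sf((w_plus - mu - 0.5) / sigma))
        elif sidedness == "less":
            p = float(stats.norm.cdf((w_plus - mu + 0.5) / sigma))
        else:
            z = (abs(w_plus - mu) - 0.5) / sigma
            p = float(2.0 * stats.norm.sf(max(z, 0.0)))
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")

    return WilcoxonResult(statistic, p, n_eff, w_plus, w_minus, sidedness, method, zero_policy)


@dataclass(frozen=True)
class ConsistencyResult:
    """Mean within-cell absolute pairwise rating difference."""

    value: float
    n_cells: int
    n_singleton_excluded: int
    per_participant: pd.Series


def within_consistency(data: pd.DataFrame) -> ConsistencyResult:
    """Average trial-to-trial rating difference within participant x condition.

    Per cell: the mean absolute difference over all unordered rating pairs.
    Cell values are averaged within each participant, then across
    participants.  Cells with fewer than 2 ratings are excluded and counted.
    """
    validate_ratings(data)
    cell_vals: dict[tuple, float] = {}
    n_single = 0
    for (pid, cond), grp in data.groupby(["participant", "condition"]):
        r = grp["rating"].to_numpy(dtype=float)
        if len(r) < 2:
            n_single += 1
            continue
        diffs = [abs(a - b) for a, b in itertools.combinations(r, 2)]
        cell_vals[(pid, cond)] = float(np.mean(diffs))
    if not cell_vals:
        raise ValueError("no participant x condition cell has two or more ratings")
    ser = pd.Series(cell_vals)
    per_participant = ser.groupby(level=0).mean()
    return ConsistencyResult(
        value=float(per_participant.mean()),
        n_cells=len(ser),
        n_singleton_excluded=n_single,
        per_participant=per_participant,
    )


def paired_condition_test(
    data: pd.DataFrame,
    cond_a: str = "A",
    cond_b: str = "D",
    unit: str = "participant_mean",
    **kwargs,
) -> WilcoxonResult:
    """Signed-rank test between two conditions.

    ``unit="participant_mean"`` pairs per-participant condition means (one
    pair per participant, as plotted in the summary figure);
    ``unit="trial"`` pairs trials in repetition/side order.
    """
    summary = condition_summary(data)
    if unit == "participant_mean":
        a = summary.participant_means[cond_a].to_numpy()
        b = summary.participant_means[cond_b].to_numpy()
    elif unit == "trial":
        key = ["participant", "side", "repetition"]
        a = data[data.condition == cond_a].sort_values(key)["rating"].to_numpy()
        b = data[data.condition == cond_b].sort_values(key)["rating"].to_numpy()
    else:
        raise ValueError(f"unknown pairing unit {unit!r}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("incomplete data for the requested conditions")
    return wilcoxon_signed_rank(a, b, **kwargs)


def read_ratings(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    validate_ratings(data)
    return data


def write_ratings(data: pd.DataFrame, path) -> None:
    validate_ratings(data)
    data.to_csv(path, index=False)
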