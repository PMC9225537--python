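"""Discrimination-trial schema, rate aggregation and response simulation.

The experimental design mirrored here: per chromaticity point, a reference
(minimum-ipRGC) stimulus is followed either by the maximum-ipRGC metamer or
by a dummy identical to the reference; participants report whether the
colour appearance differed.  Rates are raw percentages of "different"
responses; dummy (catch) trials estimate the guessing rate and are reported
alongside, not subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from .errors import FormatError, MelametError

__all__ = [
    "TrialRecord",
    "DiscriminationSummary",
    "discrimination_rates",
    "trend_statistic",
    "simulate_responses",
    "read_trials_csv",
    "write_trials_csv",
]

TRIAL_COLUMNS = ["participant", "group", "point", "kind", "delta_i_pct", "response"]
_KINDS = {"metamer", "dummy"}
_RESPONSES = {"different", "same"}


@dataclass(frozen=True)
class TrialRecord:
    participant: str
    group: int
    point_index: int
    stimulus_kind: str  # "metamer" | "dummy"
    delta_i: float      # percent; 0 for dummy trials
    response: str       # "different" | "same"

    def __post_init__(self):
        if self.stimulus_kind not in _KINDS:
            raise ValueError(f"unknown stimulus kind {self.stimulus_kind!r}")
        if self.response not in _RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.stimulus_kind == "dummy" and self.delta_i != 0:
            raise ValueError("dummy trials must have delta_i = 0")
        if not 1 <= self.group <= 6:
            raise ValueError(f"group must be 1-6, got {self.group}")
        if not 1 <= self.point_index <= 4:
            raise ValueError(f"point index must be 1-4, got {self.point_index}")


@dataclass(frozen=True)
class DiscriminationSummary:
    """Aggregated 'different'-response percentages.

    ``per_pair``: DataFrame (group, point, delta_i, n_trials, rate_pct);
    ``per_delta``: mean rate per nominal delta-I label (1-4 %);
    ``per_group``: mean rate per hue group; ``dummy_rate_pct``: false-alarm
    percentage over all dummy trials (NaN when no dummies present).
    """

    per_pair: pd.DataFrame
    per_delta: pd.Series
    per_group: pd.Series
    dummy_rate_pct: float


def _trials_frame(trials) -> pd.DataFrame:
    rows = [
        (t.participant, t.group, t.point_index, t.stimulus_kind, t.delta_i, t.response)
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def discrimination_rates(trials, pool_dummies: bool = False) -> DiscriminationSummary:
    """Aggregate trials into per-pair, per-delta and per-group rates.

    ``pool_dummies=True`` includes dummy trials in the per-pair denominators
    (some analyses pool catch trials); the default keeps them separate.
    """
    trials = list(trials)
    if not trials:
        raise MelametError("no trials to aggregate")
    df = _trials_frame(trials)
    metamer = df if pool_dummies else df[df["kind"] == "metamer"]
    if (df["kind"] == "metamer").sum() == 0:
        raise MelametError("need at least one metamer trial")
    hit = (metamer["response"] == "different").astype(float)
    grouped = metamer.assign(hit=hit).groupby(["group", "point"], sort=True)
    per_pair = grouped.agg(
        delta_i=("delta_i_pct", "max"),
        n_trials=("hit", "size"),
        rate_pct=("hit", lambda h: 100.0 * h.mean()),
    ).reset_index()
    nominal = per_pair["delta_i"].round().astype(int)
    per_delta = per_pair.groupby(nominal)["rate_pct"].mean()
    per_delta.index.name = "delta_i_nominal_pct"
    per_group = per_pair.groupby("group")["rate_pct"].mean()
    dummies = df[df["kind"] == "dummy"]
    dummy_rate = (
        100.0 * (dummies["response"] == "different").mean()
        if len(dummies)
        else float("nan")
    )
    return DiscriminationSummary(per_pair, per_delta, per_group, float(dummy_rate))


def trend_statistic(summary: DiscriminationSummary):
    """Least-squares slope and Spearman correlation of rate vs nominal delta-I.

    Returns ``(slope_pct_per_pct, rho)``; ``rho`` is NaN (flagged undefined)
    when the rates are constant across levels.
    """
    s = summary.per_delta
    if len(s) < 2:
        raise MelametError("need at least two distinct delta-I levels")
    x = s.index.to_numpy(dtype=float)
    y = s.to_numpy(dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    if np.allclose(y, y[0]):
        return slope, float("nan")
    rho = spearmanr(x, y).statistic
    return slope, float(rho)


def detection_probability(delta_i, slope: float) -> np.ndarray:
    """Folded-logistic psychometric link: 0 at delta_i = 0, saturating at 1."""
    return 2.0 * expit(slope * np.asarray(delta_i, dtype=float)) - 1.0


def simulate_responses(pairs, n_participants: int = 5, n_trials: int = 2,
                       guess_rate: float = 0.1, slope: float = 1.0,
                       seed: int = 0) -> list:
    """Generate synthetic trials for the given (group, point, delta_i) pairs.

    Metamer trials respond "different" with probability
    guess_rate + (1 - guess_rate) * d(slope * delta_i) where d is the
    folded logistic (so a zero slope collapses to pure guessing); dummy
    trials use guess_rate alone.  Each participant contributes ``n_trials``
    metamer and ``n_trials`` dummy trials per pair.  Deterministic for a
    fixed seed.
    """
    if not 0.0 <= guess_rate <= 1.0:
        raise ValueError("guess_rate must be a probability")
    rng = np.random.default_rng(seed)
    records = []
    for group, point, delta_i in pairs:
        p_hit = guess_rate + (1.0 - guess_rate) * float(
            detection_probability(delta_i, slope)
        )
        for s in range(n_participants):
            pid = f"P{s + 1}"
            for _ in range(n_trials):
                records.append(TrialRecord(
                    pid, int(group), int(point), "metamer", float(delta_i),
                    "different" if rng.random() < p_hit else "same",
                ))
            for _ in range(n_trials):
                records.append(TrialRecord(
                    pid, int(group), int(point), "dummy", 0.0,
                    "different" if rng.random() < guess_rate else "same",
                ))
    return records


def read_trials_csv(path) -> list:
    df = pd.read_csv(path)
    if list(df.columns) != TRIAL_COLUMNS:
        raise FormatError(f"{path}: expected columns {TRIAL_COLUMNS}")
    records = []
    for idx, row in df.iterrows():
        if row["response"] not in _RESPONSES:
            raise FormatError(
                f"{path}: unknown response {row['response']!r} at data row {idx}"
            )
        records.append(TrialRecord(
            str(row["participant"]), int(row["group"]), int(row["point"]),
            str(row["kind"]), float(row["delta_i_pct"]), str(row["response"]),
        ))
    return records


def write_trials_csv(trials, path) -> None:
    _trials_frame(trials).to_csv(path, index=False)
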