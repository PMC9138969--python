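"""Scoring of motor-sequence-learning keypress logs.

Performance on the bimanual finger-tapping task (cyclic target sequence
4-7-3-8-2-6, 20 blocks of 60 presses per session) is summarized per block as
speed — the mean time to complete a correct key transition, in seconds — and
accuracy — the percentage of correct transitions.  Online gains contrast the
first versus last four blocks of the 16-block training phase; offline gains
contrast the four post-training test blocks with the first four retest
blocks.  Gains are literal first-minus-last differences, so a positive speed
gain and a *negative* accuracy gain both mean improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

TARGET_SEQUENCE: tuple[int, ...] = (4, 7, 3, 8, 2, 6)

#: Missing-value sentinel used throughout (propagates through pandas/numpy).
SENTINEL = float("nan")


@dataclass
class KeypressLog:
    """Raw task events: (session, block, press_idx, key, t_ms)."""

    events: pd.DataFrame
    sequence: tuple[int, ...] = TARGET_SEQUENCE

    def __post_init__(self) -> None:
        required = {"session", "block", "press_idx", "key", "t_ms"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"keypress log is missing columns {sorted(missing)}")
        for (_, _), grp in self.events.groupby(["session", "block"]):
            t = grp.sort_values("press_idx")["t_ms"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError("timestamps must be strictly increasing per block")

    def sessions(self) -> list[str]:
        return list(dict.fromkeys(self.events["session"]))


@dataclass
class PerformanceSummary:
    """Per-block speed/accuracy plus per-subject online/offline gains."""

    blocks: pd.DataFrame  # columns: session, block, speed_s, accuracy_pct
    gains: dict[str, float] = field(default_factory=dict)


def sequence_repetitions(presses_per_block: int = 60,
                         sequence: tuple[int, ...] = TARGET_SEQUENCE) -> int:
    """Complete sequence repetitions possible in one block."""
    return presses_per_block // len(sequence)


def _score_presses(keys: np.ndarray, sequence: tuple[int, ...]) -> np.ndarray:
    """Correctness per press against a cyclic expected-position pointer.

    The pointer advances after every press (a wrong press is treated as a
    substitution for the expected element, so scoring resyncs to the next
    expected element after an error).
    """
    n = len(sequence)
    expected = np.array([sequence[i % n] for i in range(len(keys))])
    return keys == expected


def score_blocks(log: KeypressLog) -> PerformanceSummary:
    """Per-block speed (s) and accuracy (%) from consecutive-press transitions.

    A transition is correct when both of its presses are correct.  Blocks
    with zero correct transitions get sentinel speed and zero accuracy.
    """
    rows = []
    for (session, block), grp in log.events.groupby(["session", "block"], sort=True):
        grp = grp.sort_values("press_idx")
        keys = grp["key"].to_numpy()
        t = grp["t_ms"].to_numpy()
        good = _score_presses(keys, log.sequence)
        trans_ok = good[:-1] & good[1:]
        dt = np.diff(t) / 1000.0
        n_trans = len(trans_ok)
        accuracy = 100.0 * trans_ok.sum() / n_trans if n_trans else SENTINEL
        speed = float(dt[trans_ok].mean()) if trans_ok.any() else SENTINEL
        rows.append((session, block, speed, accuracy))
    blocks = pd.DataFrame(rows, columns=["session", "block", "speed_s", "accuracy_pct"])
    return PerformanceSummary(blocks=blocks)


def _window_mean(blocks: pd.DataFrame, session: str, lo: int, hi: int,
                 col: str) -> float:
    sel = blocks[(blocks["session"] == session)
                 & blocks["block"].between(lo, hi)][col]
    return float(sel.mean()) if len(sel) else SENTINEL


def compute_gains(
    summary: PerformanceSummary,
    training_session: str = "training",
    retest_session: str = "retest",
) -> dict[str, float]:
    """Online and offline gains for speed and accuracy.

    online  = mean(training blocks 1-4)  - mean(training blocks 13-16)
    offline = mean(training blocks 17-20, the fatigue-free test) -
              mean(retest blocks 1-4)
    Offline gains are sentinel when the retest session is absent.
    """
    blocks = summary.blocks
    has_retest = (blocks["session"] == retest_session).any()
    gains: dict[str, float] = {}
    for col, tag in (("speed_s", "speed"), ("accuracy_pct", "accuracy")):
        early = _window_mean(blocks, training_session, 1, 4, col)
        late = _window_mean(blocks, training_session, 13, 16, col)
        gains[f"online_{tag}"] = early - late
        if has_retest:
            test = _window_mean(blocks, training_session, 17, 20, col)
            retest = _window_mean(blocks, retest_session, 1, 4, col)
            gains[f"offline_{tag}"] = test - retest
        else:
            gains[f"offline_{tag}"] = SENTINEL
    summary.gains.update(gains)
    return gains


def gains_t_test(per_subject_gains: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed one-sample t of per-subject gains against zero."""
    g = np.asarray(per_subject_gains, float)
    g = g[np.isfinite(g)]
    if g.size < 2:
        raise ValueError("need at least 2 subjects with finite gains")
    if g.std(ddof=1) == 0:
        # degenerate: identical gains; t is 0 (all zero) or unbounded
        t = 0.0 if g[0] == 0 else float(np.inf) * np.sign(g[0])
        return t, g.size - 1, 1.0 if t == 0 else 0.0
    t, p = stats.ttest_1samp(g, 0.0)
    return float(t), g.size - 1, float(p)


def block_effect_anova(values: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA (sphericity assumed) over blocks.

    ``values`` is subjects x blocks; rows with missing entries are dropped
    (listwise deletion).  Returns F, (df1, df2), p with df = (b-1, (b-1)(n-1)).
    """
    values = np.asarray(values, float)
    values = values[np.all(np.isfinite(values), axis=1)]
    n, b = values.shape
    if n < 2 or b < 2:
        raise ValueError("need at least 2 subjects and 2 blocks")
    if np.allclose(values, values[:, [0]]):
        # no block variation at all: the F ratio degenerates to 0/0
        return 0.0, (b - 1, (b - 1) * (n - 1)), 1.0
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), b),
        "block": np.tile(np.arange(b), n),
        "value": values.ravel(),
    })
    res = AnovaRM(long, "value", "subject", within=["block"]).fit()
    row = res.anova_table.iloc[0]
    return (
        float(row["F Value"]),
        (int(row["Num DF"]), int(row["Den DF"])),
        float(row["Pr > F"]),
    )
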