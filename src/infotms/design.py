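"""Affective Go/No-Go (AGNG) session designs.

The task crosses action goal (Go: press, No-Go: withhold) with the emotional
valence of face cues.  A session comprises 6 runs; each run contains the four
miniblocks "Go Happy / No-Go Fear", "Go Fear / No-Go Happy",
"Go Happy / No-Go Neutral" and "Go Fear / No-Go Neutral" in a counterbalanced
order, each with 20 trials (15 Go, 5 No-Go).  Every trial is a 500 ms fixation
cross, a 500 ms face, and an exponential inter-trial interval truncated to
2.75-7.0 s.  A run is acquired as 222 volumes at TR = 2 s.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrialEvent",
    "SessionDesign",
    "DesignGenerationError",
    "sample_iti",
    "generate_session_design",
    "events_dataframe",
    "write_events_tsv",
    "MINIBLOCK_NAMES",
]

GO = "Go"
NOGO = "No-Go"
POSITIVE = "Positive"
NEGATIVE = "Negative"
NEUTRAL = "Neutral"

#: (Go valence, No-Go valence) for the four miniblock types.
MINIBLOCK_NAMES = (
    "Go Happy / No-Go Fear",
    "Go Fear / No-Go Happy",
    "Go Happy / No-Go Neutral",
    "Go Fear / No-Go Neutral",
)
_MINIBLOCK_VALENCES = (
    (POSITIVE, NEGATIVE),
    (NEGATIVE, POSITIVE),
    (POSITIVE, NEUTRAL),
    (NEGATIVE, NEUTRAL),
)

# Two fixed Latin-square-style miniblock orderings across the six runs,
# indexed by run_order_id (counterbalanced across subjects).
_RUN_ORDERS = {
    1: ((0, 1, 2, 3), (1, 2, 3, 0), (2, 3, 0, 1), (3, 0, 1, 2), (0, 2, 1, 3), (1, 3, 0, 2)),
    2: ((3, 2, 1, 0), (2, 1, 0, 3), (1, 0, 3, 2), (0, 3, 2, 1), (3, 1, 2, 0), (2, 0, 3, 1)),
}

N_RUNS = 6
TRIALS_PER_MINIBLOCK = 20
GO_PER_MINIBLOCK = 15
TR = 2.0
VOLUMES_PER_RUN = 222
STIM_DURATION = 0.5
FIXATION_DURATION = 0.5
ITI_MIN = 2.75
ITI_MAX = 7.0
#: Exponential rate above the ITI floor (mean 1.25 s above 2.75 s), chosen so
#: the expected run length (~390 s) fits the 444 s acquisition window.
ITI_RATE = 0.8
#: Lead-in before the first trial, covering the volumes discarded at analysis.
LEAD_IN = 8.0


class DesignGenerationError(RuntimeError):
    """Raised when a sampled schedule cannot fit the run acquisition window."""


@dataclass
class TrialEvent:
    """One AGNG trial; behavioral fields are filled by the behavior simulator."""

    run_index: int
    miniblock_index: int
    onset: float
    duration: float
    action_goal: str
    valence: str
    is_target: bool
    response: str | None = None
    rt: float | None = None
    correct: bool | None = None


@dataclass
class SessionDesign:
    trials: list[TrialEvent]
    run_order_id: int
    tr: float = TR
    volumes_per_run: int = VOLUMES_PER_RUN
    n_runs: int = N_RUNS

    def run_trials(self, run_index: int) -> list[TrialEvent]:
        return [t for t in self.trials if t.run_index == run_index]

    def with_trials(self, trials: list[TrialEvent]) -> "SessionDesign":
        return replace(self, trials=trials)


def sample_iti(
    rng: np.random.Generator,
    n: int,
    rate: float = ITI_RATE,
    lo: float = ITI_MIN,
    hi: float = ITI_MAX,
) -> np.ndarray:
    """Inter-trial intervals: ``lo`` plus an exponential, rejected above ``hi``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = lo + rng.exponential(scale=1.0 / rate, size=2 * (n - filled))
        draws = draws[draws <= hi]
        take = min(draws.size, n - filled)
        out[filled : filled + take] = draws[:take]
        filled += take
    return out


def _make_run(
    run_index: int, block_order: tuple[int, ...], rng: np.random.Generator, max_attempts: int = 100
) -> list[TrialEvent]:
    run_span = VOLUMES_PER_RUN * TR
    for _ in range(max_attempts):
        trials: list[TrialEvent] = []
        cursor = LEAD_IN
        for slot, block_type in enumerate(block_order):
            go_val, nogo_val = _MINIBLOCK_VALENCES[block_type]
            goals = [GO] * GO_PER_MINIBLOCK + [NOGO] * (TRIALS_PER_MINIBLOCK - GO_PER_MINIBLOCK)
            rng.shuffle(goals)
            itis = sample_iti(rng, TRIALS_PER_MINIBLOCK)
            for goal, iti in zip(goals, itis):
                onset = cursor + FIXATION_DURATION
                trials.append(
                    TrialEvent(
                        run_index=run_index,
                        miniblock_index=slot + 1,
                        onset=onset,
                        duration=STIM_DURATION,
                        action_goal=goal,
                        valence=go_val if goal == GO else nogo_val,
                        is_target=goal == GO,
                    )
                )
                cursor = onset + STIM_DURATION + iti
        if cursor <= run_span:
            return trials
    raise DesignGenerationError(
        f"run {run_index}: schedule exceeded {run_span:.0f} s in {max_attempts} attempts"
    )


def generate_session_design(run_order_id: int, rng_seed: int) -> SessionDesign:
    """Generate the full 6-run, 480-trial AGNG session schedule.

    Deterministic given ``(run_order_id, rng_seed)``.
    """
    if run_order_id not in _RUN_ORDERS:
        raise ValueError(f"run_order_id must be 1 or 2, got {run_order_id}")
    rng = np.random.default_rng(rng_seed)
    trials: list[TrialEvent] = []
    for run_index, block_order in enumerate(_RUN_ORDERS[run_order_id], start=1):
        trials.extend(_make_run(run_index, block_order, rng))
    return SessionDesign(trials=trials, run_order_id=run_order_id)


def events_dataframe(trials: list[TrialEvent]) -> pd.DataFrame:
    """BIDS-style events table (one row per trial)."""
    return pd.DataFrame(
        {
            "onset": [t.onset for t in trials],
            "duration": [t.duration for t in trials],
            "run": [t.run_index for t in trials],
            "miniblock": [t.miniblock_index for t in trials],
            "action_goal": [t.action_goal for t in trials],
            "valence": [t.valence for t in trials],
            "response": [t.response if t.response is not None else "n/a" for t in trials],
            "rt": [t.rt if t.rt is not None else np.nan for t in trials],
            "correct": [t.correct if t.correct is not None else np.nan for t in trials],
        }
    )


def write_events_tsv(trials: list[TrialEvent], path) -> None:
    df = events_dataframe(trials)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep="n/a", float_format="%.6g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
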