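"""Behavioral simulator for the AGNG task.

Trial correctness is Bernoulli with a cell probability determined by action
goal and cue valence.  Negative cues facilitate goal-congruent withholding:
No-Go accuracy for negative faces is ``p_nogo_correct_base + (1 - alpha) *
nogo_negative_boost``.  The attenuation factor ``alpha`` (0 = no stimulation,
1 = full cTBS-like disruption) abolishes that boost and additionally lowers
all No-Go cells by ``alpha * tms_nogo_decrement``, reproducing the impaired
inhibitory performance after disruption of prefrontal goal representations.
Response times for button presses are lognormal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import GO, NEGATIVE, NOGO, SessionDesign, TrialEvent

__all__ = ["BehaviorParams", "cell_probability", "simulate_behavior"]


@dataclass(frozen=True)
class BehaviorParams:
    p_go_correct: float = 0.96
    p_nogo_correct_base: float = 0.78
    nogo_negative_boost: float = 0.08
    rt_lognormal_mu: float = -0.8  # log-seconds; median RT ~0.45 s
    rt_lognormal_sigma: float = 0.25
    tms_attenuation: float = 0.0
    tms_nogo_decrement: float = 0.025

    def __post_init__(self) -> None:
        if not 0 <= self.tms_attenuation <= 1:
            raise ValueError("tms_attenuation must lie in [0, 1]")


def cell_probability(action_goal: str, valence: str, params: BehaviorParams) -> float:
    """Probability of a correct response in the (action goal, valence) cell."""
    if action_goal == GO:
        p = params.p_go_correct
    elif action_goal == NOGO:
        p = params.p_nogo_correct_base - params.tms_attenuation * params.tms_nogo_decrement
        if valence == NEGATIVE:
            p += (1.0 - params.tms_attenuation) * params.nogo_negative_boost
    else:
        raise ValueError(f"unknown action goal {action_goal!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"cell probability {p:.3f} outside [0, 1] for {action_goal}/{valence}")
    return p


def simulate_behavior(
    design: SessionDesign, params: BehaviorParams, rng: np.random.Generator
) -> SessionDesign:
    """Fill response, RT and correctness for every trial (new design returned)."""
    out: list[TrialEvent] = []
    for trial in design.trials:
        p = cell_probability(trial.action_goal, trial.valence, params)
        correct = bool(rng.random() < p)
        pressed = (trial.action_goal == GO) == correct
        rt = (
            float(rng.lognormal(params.rt_lognormal_mu, params.rt_lognormal_sigma))
            if pressed
            else None
        )
        out.append(
            replace(trial, response="press" if pressed else "withhold", rt=rt, correct=correct)
        )
    return design.with_trials(out)
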