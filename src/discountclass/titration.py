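"""Adjusting-amount titration: simulate the staircase that produces indifference points.

The task offers, at each delay, a choice between an immediate smaller-sooner
reward (SSR, adjustable) and the fixed larger-later reward (LLR, amount A).
The SSR starts at A/2; after each choice it moves up (LLR chosen) or down
(SSR chosen) by an adjustment that starts at A/4 and halves each trial.
After five choices the final SSR value is recorded as the indifference
point, which therefore lies on the grid {A*j/64 : j odd}.

Agents stand in for participants: a value function V(d) gives the agent's
present subjective value of the LLR at delay d, and a choice rule
(deterministic or logistic) maps the offer s against V(d) to a choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .core import Cohort, DiscountingSeries, TaskSpec

__all__ = [
    "AgentSpec",
    "TitrationTrace",
    "run_titration",
    "enumerate_titration_outcomes",
    "simulate_cohort_responses",
    "load_agents",
]

SSR = "SSR"
LLR = "LLR"
N_CHOICES = 5


@dataclass(frozen=True)
class AgentSpec:
    """A simulated decision-maker.

    value_fn
        One of ``hyperbolic`` (params: k), ``exponential`` (params: k),
        ``fixed_profile`` (params: values, aligned to task delays), or
        ``riser`` (params: c0, c1 — subjective value A*(c0 + c1*x) rising
        with normalized delay x).
    choice_noise
        ``deterministic`` (choose SSR iff s > V(d); ties go to the LLR) or
        ``logistic`` (choose SSR with probability 1/(1+exp(-beta*(s-V)))).
    """

    value_fn: str
    params: Mapping[str, object] = field(default_factory=dict)
    choice_noise: str = "deterministic"
    beta: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.value_fn not in ("hyperbolic", "exponential", "fixed_profile", "riser"):
            raise ValueError(f"unknown value_fn {self.value_fn!r}")
        if self.choice_noise not in ("deterministic", "logistic"):
            raise ValueError(f"unknown choice_noise {self.choice_noise!r}")
        if self.choice_noise == "logistic" and not (self.beta and self.beta > 0):
            raise ValueError("logistic noise requires beta > 0")
        if self.value_fn in ("hyperbolic", "exponential"):
            k = float(self.params.get("k", -1.0))
            if k < 0:
                raise ValueError(f"{self.value_fn} requires k >= 0")
        object.__setattr__(self, "params", dict(self.params))

    def subjective_value(self, task: TaskSpec, delay: float) -> float:
        """Present value V(d) of the delayed amount A, clipped to [0, A]."""
        A = task.magnitude
        if self.value_fn == "hyperbolic":
            v = A / (1.0 + float(self.params["k"]) * delay)
        elif self.value_fn == "exponential":
            v = A * np.exp(-float(self.params["k"]) * delay)
        elif self.value_fn == "fixed_profile":
            vals = np.asarray(self.params["values"], dtype=float)
            if vals.shape != (task.n_delays,):
                raise ValueError("fixed_profile values must align with task delays")
            j = task.delays.index(float(delay))
            v = vals[j]
        else:  # riser
            c0 = float(self.params["c0"])
            c1 = float(self.params["c1"])
            x = (delay - task.delays[0]) / (task.delays[-1] - task.delays[0])
            v = A * (c0 + c1 * x)
        return float(np.clip(v, 0.0, A))


@dataclass
class TitrationTrace:
    """Record of one five-choice staircase at a single delay."""

    delay: float
    ssr_sequence: list[float]   # s_1..s_6, s_1 = A/2
    choices: list[str]          # five entries in {"SSR", "LLR"}
    indifference_point: float   # = s_6


def _adjustments(A: float, final_adjustment: bool) -> list[float]:
    n = N_CHOICES if final_adjustment else N_CHOICES - 1
    return [A * 2.0 ** -(t + 2) for t in range(n)]  # A/4, A/8, ...


def _staircase(A: float, choices: Sequence[str], final_adjustment: bool) -> list[float]:
    """SSR offer sequence implied by a full choice sequence."""
    s = [A / 2.0]
    deltas = _adjustments(A, final_adjustment)
    for t, choice in enumerate(choices):
        if t < len(deltas):
            step = deltas[t]
            s.append(s[-1] + step if choice == LLR else s[-1] - step)
    return s


def run_titration(
    agent: AgentSpec,
    task: TaskSpec,
    delay: float,
    *,
    final_adjustment: bool = True,
    rng: np.random.Generator | None = None,
) -> TitrationTrace:
    """Run the five-choice staircase for one agent at one delay.

    For a deterministic agent the final value is within A/32 of V(delay)
    (A/16 when ``final_adjustment`` is false).
    """
    if float(delay) not in task.delays:
        raise ValueError(f"delay {delay} is not one of the task delays {task.delays}")
    if rng is None:
        rng = _agent_rng(agent, task, delay)
    A = task.magnitude
    V = agent.subjective_value(task, delay)
    s = A / 2.0
    seq = [s]
    choices: list[str] = []
    deltas = _adjustments(A, final_adjustment)
    for t in range(N_CHOICES):
        if agent.choice_noise == "deterministic":
            choice = SSR if s > V else LLR
        else:
            p_ssr = 1.0 / (1.0 + np.exp(-agent.beta * (s - V)))
            choice = SSR if rng.uniform() < p_ssr else LLR
        choices.append(choice)
        if t < len(deltas):
            s = s + deltas[t] if choice == LLR else s - deltas[t]
            seq.append(s)
    return TitrationTrace(
        delay=float(delay), ssr_sequence=seq, choices=choices,
        indifference_point=seq[-1],
    )


def _agent_rng(agent: AgentSpec, task: TaskSpec, delay: float) -> np.random.Generator:
    # one stream per (agent seed, delay index): reproducible across cohort sizes
    j = task.delays.index(float(delay))
    return np.random.default_rng([int(agent.seed) % 2**31, j])


def enumerate_titration_outcomes(
    task: TaskSpec, *, final_adjustment: bool = True
) -> dict[tuple[str, ...], float]:
    """Brute-force map from every 5-choice sequence to its final SSR value.

    With the final adjustment applied there are 32 distinct outcomes on
    the grid {A*j/64 : j odd}; replacing any SSR choice by LLR strictly
    increases the outcome.
    """
    A = task.magnitude
    out: dict[tuple[str, ...], float] = {}
    for bits in range(2 ** N_CHOICES):
        choices = tuple(
            LLR if (bits >> (N_CHOICES - 1 - t)) & 1 else SSR
            for t in range(N_CHOICES)
        )
        out[choices] = _staircase(A, choices, final_adjustment)[-1]
    return out


def simulate_cohort_responses(
    agents: Sequence[AgentSpec],
    task: TaskSpec,
    *,
    final_adjustment: bool = True,
    participant_ids: Sequence[str] | None = None,
) -> Cohort:
    """One titrated series per agent, delays run in ascending order."""
    if not agents:
        raise ValueError("agent list must be non-empty")
    if participant_ids is None:
        participant_ids = [f"agent_{i:05d}" for i in range(len(agents))]
    series = []
    for pid, agent in zip(participant_ids, agents):
        vals = [
            run_titration(agent, task, d, final_adjustment=final_adjustment)
            .indifference_point
            for d in task.delays
        ]
        series.append(DiscountingSeries(pid, task, np.asarray(vals)))
    return Cohort(task=task, series=series)


def load_agents(path: str | Path) -> list[AgentSpec]:
    """Load a list of agents from a YAML/JSON config.

    Each entry: ``{value_fn, params, choice_noise, beta, seed}``; top level
    may be the list itself or a mapping with key ``agents``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["agents"] if isinstance(doc, Mapping) else doc
    agents = []
    for e in entries:
        agents.append(AgentSpec(
            value_fn=e["value_fn"],
            params=e.get("params", {}),
            choice_noise=e.get("choice_noise", "deterministic"),
            beta=e.get("beta"),
            seed=int(e.get("seed", 0)),
        ))
    return agents
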