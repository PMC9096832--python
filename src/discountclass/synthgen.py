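"""Synthetic cohorts with planted latent-class structure.

Cohorts emulate the structure of a large adjusting-amount study: ~1200
participants, six delays (1, 6, 12, 36, 60, 120 months), indifference
points on the titration grid, a majority of monotonically decreasing
(hyperbolic-like) series plus small classes with flat or rising trends.
Ground-truth class labels are retained so recovery and screening behaviour
can be tested against a known answer.

Three class kinds are supported:

* ``hyperbolic`` — mean value A/(1 + k_i d); per-subject discount rate
  drawn log-normally (mean/sd of ln k per month).
* ``riser``      — mean value A*(c0 + c1*x), increasing in the normalized
  delay x; emulates the minority subgroup responding in the direction
  opposite to discounting.
* ``flat``       — mean value A*c0, constant across delays.

Per-subject intercepts (``subject_sd``) and per-observation noise
(``noise_sd``), both as fractions of A, are added on the indifference-point
scale; values are clamped to [0, A] and optionally snapped to the grid
{A*j/64 : j odd} the titration staircase can actually produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import Cohort, DiscountingSeries, TaskSpec, hcp_task
from .titration import AgentSpec, run_titration

__all__ = [
    "ClassRecipe",
    "CohortRecipe",
    "generate_cohort",
    "hcp_like_recipe",
    "snap_to_titration_grid",
    "load_recipe",
    "save_recipe",
]


@dataclass(frozen=True)
class ClassRecipe:
    """One planted class: trajectory shape, mixing weight, noise levels."""

    kind: str                       # hyperbolic | riser | flat
    weight: float
    params: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0           # residual SD as fraction of A
    subject_sd: float = 0.0         # between-subject intercept SD as fraction of A

    def __post_init__(self):
        if self.kind not in ("hyperbolic", "riser", "flat"):
            raise ValueError(f"unknown class kind {self.kind!r}")
        if not (0 < self.weight <= 1):
            raise ValueError("weight must be in (0, 1]")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        object.__setattr__(self, "params", dict(self.params))


@dataclass(frozen=True)
class CohortRecipe:
    """Generative description of a synthetic cohort."""

    n_subjects: int
    task: TaskSpec
    classes: tuple[ClassRecipe, ...]
    snap_to_grid: bool = True
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "classes", tuple(self.classes))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.classes:
            raise ValueError("at least one class is required")
        total = sum(c.weight for c in self.classes)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class weights must sum to 1, got {total}")


def snap_to_titration_grid(values: np.ndarray, magnitude: float) -> np.ndarray:
    """Snap values to the nearest reachable staircase outcome A*j/64, j odd."""
    j = np.round((np.asarray(values, float) / magnitude * 64.0 - 1.0) / 2.0)
    j = 2.0 * np.clip(j, 0, 31) + 1.0
    return magnitude * j / 64.0


def _mean_trajectory(recipe: ClassRecipe, task: TaskSpec,
                     k: float | None = None) -> np.ndarray:
    A = task.magnitude
    d = np.asarray(task.delays, float)
    if recipe.kind == "hyperbolic":
        return A / (1.0 + k * d)
    x = task.normalized_delays()
    if recipe.kind == "riser":
        return A * (recipe.params["c0"] + recipe.params["c1"] * x)
    return A * recipe.params["c0"] * np.ones_like(x)


def generate_cohort(recipe: CohortRecipe, *, mode: str = "values") -> Cohort:
    """Generate a cohort with ground-truth classes, reproducibly from the seed.

    ``mode="values"`` (default) adds Gaussian subject and residual noise on
    the indifference-point scale, clamps to [0, A], and (optionally) snaps
    to the titration grid.  ``mode="behavioral"`` instead drives a
    deterministic titration agent with each subject's latent value profile
    through the five-choice staircase, so every recorded point is a true
    staircase outcome (residual noise perturbs the latent profile before
    titration; grid snapping is inherent).
    """
    if mode not in ("values", "behavioral"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(recipe.seed)
    task = recipe.task
    A = task.magnitude
    m = task.n_delays
    weights = np.array([c.weight for c in recipe.classes])
    labels = rng.choice(len(recipe.classes), size=recipe.n_subjects, p=weights)

    series = []
    true_class: dict[str, int] = {}
    width = max(5, len(str(recipe.n_subjects)))
    for i in range(recipe.n_subjects):
        cls = recipe.classes[labels[i]]
        k = float(np.exp(rng.normal(cls.params["log_k_mean"],
                                    cls.params.get("log_k_sd", 0.0)))) \
            if cls.kind == "hyperbolic" else None
        mean = _mean_trajectory(cls, task, k)
        b = rng.normal(0.0, cls.subject_sd * A) if cls.subject_sd > 0 else 0.0
        e = rng.normal(0.0, cls.noise_sd * A, size=m) if cls.noise_sd > 0 \
            else np.zeros(m)
        latent = np.clip(mean + b + e, 0.0, A)
        if mode == "behavioral":
            agent = AgentSpec(value_fn="fixed_profile",
                              params={"values": latent})
            v = np.array([
                run_titration(agent, task, d).indifference_point
                for d in task.delays
            ])
        else:
            v = snap_to_titration_grid(latent, A) if recipe.snap_to_grid else latent
        pid = f"sim_{i:0{width}d}"
        series.append(DiscountingSeries(pid, task, v))
        true_class[pid] = int(labels[i]) + 1
    return Cohort(task=task, series=series, true_class=true_class)


def hcp_like_recipe(magnitude: float = 200, *, n_subjects: int = 1198,
                    seed: int = 0) -> CohortRecipe:
    """Default cohort emulating a large adjusting-amount study.

    1198 subjects over the six standard delays, with five hyperbolic
    classes whose log-discount-rate means spread trajectories from near-
    immediate devaluation (AUC ~ 0.05) to shallow discounting (AUC ~ 0.9),
    one small rising class (~0.6% of subjects) and one small flat class.
    One mid-rate hyperbolic class is given a high residual SD to emulate
    the erratic minority that drives local-criterion violations in real
    cohorts; the resulting pass rates fall in the range large
    adjusting-amount studies report (roughly 80-90% per criterion).
    """
    if magnitude not in (200, 40000):
        raise ValueError("magnitude must be 200 or 40000")
    hyper_weights = [0.44, 0.25, 0.14, 0.08, 0.05]
    log_k_means = [0.0, -2.3, -3.7, -5.0, -7.0]   # ln k per month
    noise_sds = [0.05, 0.20, 0.05, 0.05, 0.05]    # one erratic class
    classes = [
        ClassRecipe(
            kind="hyperbolic", weight=w,
            params={"log_k_mean": mu, "log_k_sd": 0.5},
            noise_sd=ns, subject_sd=0.02,
        )
        for w, mu, ns in zip(hyper_weights, log_k_means, noise_sds)
    ]
    classes.append(ClassRecipe(
        kind="riser", weight=0.006, params={"c0": 0.25, "c1": 0.5},
        noise_sd=0.03, subject_sd=0.02,
    ))
    classes.append(ClassRecipe(
        kind="flat", weight=0.034, params={"c0": 0.5},
        noise_sd=0.05, subject_sd=0.02,
    ))
    return CohortRecipe(
        n_subjects=n_subjects, task=hcp_task(magnitude),
        classes=tuple(classes), snap_to_grid=True, seed=seed,
    )


# ---------------------------------------------------------------------------
# Recipe (de)serialization
# ---------------------------------------------------------------------------

def load_recipe(path: str | Path) -> CohortRecipe:
    """Read a CohortRecipe from YAML/JSON."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    task = TaskSpec(
        magnitude=float(doc["task"]["magnitude"]),
        delays=tuple(doc["task"]["delays"]),
        label=doc["task"].get("label", ""),
    )
    classes = tuple(
        ClassRecipe(
            kind=c["kind"], weight=float(c["weight"]),
            params={k: v for k, v in c.get("params", {}).items()},
            noise_sd=float(c.get("noise_sd", 0.0)),
            subject_sd=float(c.get("subject_sd", 0.0)),
        )
        for c in doc["classes"]
    )
    return CohortRecipe(
        n_subjects=int(doc["n_subjects"]), task=task, classes=classes,
        snap_to_grid=bool(doc.get("snap_to_grid", True)),
        seed=int(doc.get("seed", 0)),
    )


def save_recipe(recipe: CohortRecipe, path: str | Path) -> None:
    doc = {
        "n_subjects": recipe.n_subjects,
        "task": {
            "magnitude": recipe.task.magnitude,
            "delays": list(recipe.task.delays),
            "label": recipe.task.label,
        },
        "classes": [
            {
                "kind": c.kind, "weight": c.weight,
                "params": dict(c.params),
                "noise_sd": c.noise_sd, "subject_sd": c.subject_sd,
            }
            for c in recipe.classes
        ],
        "snap_to_grid": recipe.snap_to_grid,
        "seed": recipe.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
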