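"""Synthetic cohorts with planted MRI-motor effects for recovery tests.

A cohort table has one row per subject: MRI columns (``mri_*``, spared
tissue percent, uniform on [0, 100]) and motor columns (``motor_*``)
generated per family through the canonical link:

* linear   : y = intercept + sum(effect * mri) + Normal(0, noise_sd)
* poisson  : y ~ Poisson(exp(intercept + sum(effect * mri)))
* logistic : y ~ Bernoulli(expit(intercept + sum(effect * mri)))

The default continuous noise (sd = 1.0 on the percent-scale design)
makes a planted slope of -0.02 sit at the edge of detectability in a
13-subject cohort, the regime the association pipeline is meant for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["Effect", "CohortSpec", "make_cohort", "DEFAULT_MRI_VARS"]

FAMILIES = ("linear", "poisson", "logistic")

DEFAULT_MRI_VARS = (
    "mri_spared_total",
    "mri_spared_anterior",
    "mri_spared_posterior",
    "mri_spared_left",
    "mri_spared_right",
)

_DEFAULT_INTERCEPT = {"linear": 2.0, "poisson": math.log(2.0), "logistic": 0.0}


@dataclass(frozen=True)
class Effect:
    """One planted association: motor_var responds to mri_var with this slope."""

    mri_var: str
    motor_var: str
    effect: float
    family: str = "linear"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; use one of {FAMILIES}")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``extra_motor`` adds motor columns with no planted effect (pure
    noise of the given family); ``noise_sd`` applies to linear columns.
    """

    n_subjects: int = 13
    effect_map: list[Effect] = field(default_factory=list)
    extra_motor: list[tuple[str, str]] = field(default_factory=list)  # (name, family)
    mri_vars: tuple[str, ...] = DEFAULT_MRI_VARS
    noise_sd: float | dict[str, float] = 1.0
    intercepts: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        for eff in self.effect_map:
            if eff.mri_var not in self.mri_vars:
                raise ValueError(f"effect references unknown MRI variable {eff.mri_var!r}")
        for _, family in self.extra_motor:
            if family not in FAMILIES:
                raise ValueError(f"unknown family {family!r}")

    def motor_columns(self) -> dict[str, str]:
        """Ordered mapping motor column -> family."""
        cols: dict[str, str] = {}
        for eff in self.effect_map:
            prev = cols.setdefault(eff.motor_var, eff.family)
            if prev != eff.family:
                raise ValueError(f"motor variable {eff.motor_var!r} declared with two families")
        for name, family in self.extra_motor:
            cols.setdefault(name, family)
        return cols

    def noise_for(self, motor_var: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(motor_var, 0.0))
        return float(self.noise_sd)


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate the cohort table and its column-family mapping.

    MRI variables are uniform on [0, 100] (percent scale). Per-column
    noise uses sub-streams derived from the spec seed and the column
    index so columns are independent and individually reproducible.
    Returns ``(table, families)`` where families maps each motor column
    to its declared family tag (``continuous``/``count``/``binary``).
    """
    rng_mri = np.random.default_rng([spec.seed, 0])
    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(spec.mri_vars):
        data[name] = rng_mri.uniform(0.0, 100.0, size=spec.n_subjects)

    effects_by_motor: dict[str, list[Effect]] = {}
    for eff in spec.effect_map:
        effects_by_motor.setdefault(eff.motor_var, []).append(eff)

    family_tag = {"linear": "continuous", "poisson": "count", "logistic": "binary"}
    families: dict[str, str] = {}
    for ci, (motor_var, family) in enumerate(spec.motor_columns().items(), start=1):
        rng = np.random.default_rng([spec.seed, ci])
        intercept = spec.intercepts.get(motor_var, _DEFAULT_INTERCEPT[family])
        eta = np.full(spec.n_subjects, float(intercept))
        for eff in effects_by_motor.get(motor_var, []):
            eta = eta + eff.effect * data[eff.mri_var]
        if not np.all(np.isfinite(eta)):
            raise ValueError(f"non-finite linear predictor for {motor_var!r}")
        if family == "linear":
            sd = spec.noise_for(motor_var)
            y = eta + (rng.normal(0.0, sd, size=spec.n_subjects) if sd > 0 else 0.0)
        elif family == "poisson":
            y = rng.poisson(np.exp(eta)).astype(float)
        else:  # logistic
            p = expit(eta)
            y = (rng.random(spec.n_subjects) < p).astype(float)
        data[motor_var] = np.asarray(y, dtype=float)
        families[motor_var] = family_tag[family]

    table = pd.DataFrame(data)
    table.insert(0, "subject_id", [f"S{i:03d}" for i in range(spec.n_subjects)])
    return table, families
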