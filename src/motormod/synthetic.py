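"""Synthetic gait-cycle muscle activations with planted modular structure.

This generator emulates the muscle activations produced by muscle-driven
walking simulations across the 27-condition grid, with known ground truth
so that every downstream stage (NMF extraction, module-number selection,
structure comparison, fixed-module reconstruction, activation metrics) can
be verified by parameter recovery.

The model is low-rank by construction: a condition-invariant nonnegative
weight matrix ``W_true`` (muscles x modules, columns unit-max) recruits
condition-dependent activation patterns ``C_true`` (modules x 101 grid
points), and the observed activation matrix is

    E = W_true @ C_true(condition) + noise,   clipped at zero.

Activation patterns are smooth Gaussian bumps in circular gait phase
(grid point 0 = ipsilateral heel strike; stance occupies roughly the first
60% of the cycle at the reference speed).  Condition dependence enters only
through recruitment modulation:

* faster walking raises the plantarflexor and dorsiflexor peaks and pulls
  the plantarflexor burst slightly earlier;
* step-length asymmetry raises the hip-flexor module's peak and, on the
  shorter-step side, attenuates late-stance activity of the stance-extensor
  and plantarflexor modules;
* wider steps add swing-phase activity to the stance-extensor module
  (its abductor/adductor musculature works harder to place a wide step).

With all modulation gains at zero the patterns are identical across
conditions, so condition effects in downstream analyses are attributable
to the gains alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import (
    ASYMMETRIES,
    LEGS,
    N_GRID_POINTS,
    SPEEDS,
    STEP_WIDTHS,
    ConditionSpec,
)
from .muscles import BASELINE_WEIGHT, MuscleSetDefinition

# Reference values the modulations are expressed relative to.
_REF_SPEED = 1.1
_REF_WIDTH = 0.1

# Gait-phase layout (cycle fractions; heel strike = 0, toe-off ~ 0.6).
_BUMP_CENTERS: dict[str, float] = {
    "stance_extensor": 0.17,  # through much of stance
    "plantarflexor": 0.47,    # late stance push-off
    "hip_flexor": 0.62,       # late stance into swing
    "dorsiflexor": 0.97,      # late swing into early stance (wraps)
}
_BUMP_WIDTHS: dict[str, float] = {
    "stance_extensor": 0.13,
    "plantarflexor": 0.07,
    "hip_flexor": 0.10,
    "dorsiflexor": 0.09,
}
# Reference-condition peak recruitment per module, in activation units on
# unit-max modules; magnitudes typical of module recruitment in walking.
_BASE_AMPLITUDES: dict[str, float] = {
    "stance_extensor": 0.37,
    "plantarflexor": 0.44,
    "hip_flexor": 0.26,
    "dorsiflexor": 0.38,
}
# Late-stance window used for the asymmetry attenuation.
_LATE_STANCE_CENTER = 0.50
_LATE_STANCE_WIDTH = 0.08
# Swing window used for the step-width response of the extensor module.
_SWING_CENTER = 0.75
_SWING_WIDTH = 0.10


@dataclass(frozen=True)
class ModulationGains:
    """Gains controlling how recruitment varies across the condition grid.

    All gains are dimensionless multipliers on relative deviations from the
    reference condition; zeroing every gain makes the activation patterns
    condition-invariant.

    speed_peak
        Fractional peak increase of the plantarflexor and dorsiflexor
        modules per unit relative speed change (v - 1.1)/1.1.
    speed_shift
        Cycle-fraction shift (earlier) of the plantarflexor burst per unit
        relative speed change.
    asym_hip_flexor
        Fractional peak increase of the hip-flexor module per unit
        asymmetry (at 30% asymmetry the peak rises by 0.30 * gain... /0.30,
        i.e. gain * asym / 0.30 at the grid maximum).
    asym_late_stance
        Maximum fractional late-stance attenuation of the stance-extensor
        and plantarflexor modules on the shorter-step side, scaled by
        asym / 0.30.
    width_swing
        Fractional swing-bump amplitude added to the stance-extensor module
        per unit relative width change (w - 0.1)/0.1.
    """

    speed_peak: float = 0.8
    speed_shift: float = 0.05
    asym_hip_flexor: float = 0.6
    asym_late_stance: float = 0.35
    width_swing: float = 0.18

    @classmethod
    def zero(cls) -> "ModulationGains":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Planted factorization underlying a synthetic study.

    ``W_true`` has unit-max nonnegative columns in the canonical module
    order of ``muscle_set``; ``C_true_by_condition`` maps condition labels
    to modules x T nonnegative patterns.
    """

    muscle_set: MuscleSetDefinition
    W_true: np.ndarray
    C_true_by_condition: dict[str, np.ndarray]
    noise_sd: float
    seed: int
    gains: ModulationGains = field(default_factory=ModulationGains)
    T: int = N_GRID_POINTS

    @property
    def n_modules(self) -> int:
        return self.W_true.shape[1]

    def C_true(self, cond: ConditionSpec) -> np.ndarray:
        return self.C_true_by_condition[cond.label()]


def make_module_templates(
    muscle_set: MuscleSetDefinition, n_modules: int
) -> np.ndarray:
    """Build the planted module weight matrix W_true (muscles x modules).

    Dominant muscles per column follow the canonical walking-module
    composition stored on ``muscle_set``; all remaining muscles receive a
    small uniform baseline weight.  Columns are scaled to unit maximum.

    ``n_modules`` must equal the number of roles the muscle set supports
    (4 for the full set, 3 for the 8-muscle subset, which lacks a
    hip-flexor module).
    """
    roles = muscle_set.module_roles
    if n_modules not in (3, 4):
        raise ValueError(f"n_modules must be 3 or 4, got {n_modules}")
    if n_modules > len(roles):
        raise ValueError(
            f"muscle set {muscle_set.name!r} supports at most {len(roles)} "
            f"modules ({', '.join(roles)}); got n_modules={n_modules}"
        )
    roles = roles[:n_modules]
    W = np.full((muscle_set.n_muscles, len(roles)), BASELINE_WEIGHT)
    for j, role in enumerate(roles):
        for muscle, weight in muscle_set.module_template_map[role].items():
            W[muscle_set.index_of(muscle), j] = weight
    W /= W.max(axis=0, keepdims=True)
    return W


def _circular_bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian bump in circular phase (cycle-fraction units, period 1)."""
    d = np.abs(phase - center)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


def _shorter_step_side(asymmetry: float) -> str | None:
    """Leg taking the shorter step; None for symmetric gait.

    Positive asymmetry means larger right steps, so the left step is the
    shorter one.
    """
    if asymmetry == 0:
        return None
    return "left" if asymmetry > 0 else "right"


def make_activation_patterns(
    cond: ConditionSpec,
    n_modules: int,
    T: int = N_GRID_POINTS,
    gains: ModulationGains | None = None,
    roles: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Condition-modulated module activation patterns C (modules x T).

    Each row is a smooth unimodal bump (wrap-around permitted) in gait
    phase; recruitment amplitude and, for the plantarflexor, timing are
    modulated by the condition per the gains (see module docstring).
    """
    if T < 3:
        raise ValueError(f"T must be at least 3, got {T}")
    if gains is None:
        gains = ModulationGains()
    if roles is None:
        from .muscles import MODULE_ROLES_FULL, MODULE_ROLES_SUBSET

        roles = MODULE_ROLES_FULL if n_modules == 4 else MODULE_ROLES_SUBSET
    if len(roles) != n_modules:
        raise ValueError(
            f"{n_modules} modules requested but {len(roles)} roles given"
        )

    # Duplicate-endpoint grid: phase 0..1 inclusive over T points.
    phase = np.linspace(0.0, 1.0, T)
    dv = (cond.speed - _REF_SPEED) / _REF_SPEED
    da = cond.asymmetry / max(ASYMMETRIES)
    dw = (cond.step_width - _REF_WIDTH) / _REF_WIDTH
    short_side = _shorter_step_side(cond.asymmetry)

    C = np.empty((n_modules, T))
    for i, role in enumerate(roles):
        center = _BUMP_CENTERS[role]
        width = _BUMP_WIDTHS[role]
        amp = _BASE_AMPLITUDES[role]

        if role in ("plantarflexor", "dorsiflexor"):
            amp *= 1.0 + gains.speed_peak * dv
        if role == "plantarflexor":
            center = (center - gains.speed_shift * dv) % 1.0
        if role == "hip_flexor":
            amp *= 1.0 + gains.asym_hip_flexor * da

        row = amp * _circular_bump(phase, center, width)

        if role == "stance_extensor" and dw > 0:
            row = row + (
                gains.width_swing
                * dw
                * _BASE_AMPLITUDES[role]
                * _circular_bump(phase, _SWING_CENTER, _SWING_WIDTH)
            )
        if (
            role in ("stance_extensor", "plantarflexor")
            and short_side is not None
            and cond.leg == short_side
        ):
            attenuation = 1.0 - gains.asym_late_stance * da * _circular_bump(
                phase, _LATE_STANCE_CENTER, _LATE_STANCE_WIDTH
            )
            row = row * attenuation
        C[i] = row
    return C


def make_ground_truth(
    muscle_set: MuscleSetDefinition,
    n_modules: int | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    gains: ModulationGains | None = None,
    T: int = N_GRID_POINTS,
) -> GroundTruth:
    """Assemble the planted W and per-condition C for a whole study.

    ``n_modules`` defaults to the number of roles the muscle set supports
    (4 full / 3 subset).  ``noise_sd`` is the standard deviation of the
    additive Gaussian observation noise, in activation units on unit-max
    modules.
    """
    if gains is None:
        gains = ModulationGains()
    if n_modules is None:
        n_modules = len(muscle_set.module_roles)
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    W = make_module_templates(muscle_set, n_modules)
    roles = muscle_set.module_roles[:n_modules]
    C_by_cond: dict[str, np.ndarray] = {}
    for leg in LEGS:
        for speed in SPEEDS:
            for asym in ASYMMETRIES:
                for width in STEP_WIDTHS:
                    cond = ConditionSpec(speed, asym, width, leg, muscle_set.name)
                    C_by_cond[cond.label()] = make_activation_patterns(
                        cond, n_modules, T=T, gains=gains, roles=roles
                    )
    return GroundTruth(
        muscle_set=muscle_set,
        W_true=W,
        C_true_by_condition=C_by_cond,
        noise_sd=noise_sd,
        seed=seed,
        gains=gains,
        T=T,
    )


def _condition_rng(truth: GroundTruth, cond: ConditionSpec) -> np.random.Generator:
    # Stable per-condition stream: same seed + condition -> identical noise.
    leg_idx = LEGS.index(cond.leg)
    return np.random.default_rng(
        np.random.SeedSequence([truth.seed, cond.grid_index, leg_idx])
    )


def synthesize_activations(truth: GroundTruth, cond: ConditionSpec) -> np.ndarray:
    """Observed activation matrix E = W_true @ C_true(cond) + noise, >= 0.

    Noise is i.i.d. Gaussian per entry (sd ``truth.noise_sd``), and the sum
    is truncated at zero to preserve nonnegativity.  Deterministic given
    ``truth.seed`` and the condition.
    """
    if truth.noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {truth.noise_sd}")
    C = truth.C_true(cond)
    E = truth.W_true @ C
    if truth.noise_sd > 0:
        rng = _condition_rng(truth, cond)
        E = E + rng.normal(0.0, truth.noise_sd, size=E.shape)
    return np.clip(E, 0.0, None)


def with_gains(truth: GroundTruth, gains: ModulationGains) -> GroundTruth:
    """Rebuild a ground truth with different modulation gains."""
    return make_ground_truth(
        truth.muscle_set,
        n_modules=truth.n_modules,
        noise_sd=truth.noise_sd,
        seed=truth.seed,
        gains=gains,
        T=truth.T,
    )


__all__ = [
    "GroundTruth",
    "ModulationGains",
    "make_module_templates",
    "make_activation_patterns",
    "make_ground_truth",
    "synthesize_activations",
    "with_gains",
]
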