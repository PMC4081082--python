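"""Kinetic model of cooperative target repression by a miRNA pair.

Species (all nM): free target mRNA ``m``, free miRNAs ``R1``/``R2``, the two
mRNA-miRNA duplexes ``C1``/``C2``, the triplex ``T`` and the protein ``P``.
Processes: constitutive mRNA synthesis, miRNA synthesis scaled by the
expression factors ``TF1``/``TF2``, reversible duplex and triplex assembly,
first-order degradation of every species (complexed mRNA degrades faster
than free mRNA, the triplex fastest) and translation from free mRNA.
miRNAs act catalytically: when a complex degrades, the mRNA is destroyed and
the miRNAs are recycled (config switch).

Steady states are found by a Newton/least-squares solve of the algebraic
system with an ODE-integration fallback; the two routes cross-validate each
other.  Steady-state protein is reported normalized by the miRNA-free model,
so the readout lies in [0, 1]: 1 = no repression, 0 = silenced.

The repression gains compare normalized steady states over the expression
grid: ``RG1 = SS(1,1) - SS(10,1)`` and ``RG2 = SS(1,1) - SS(1,10)`` (strong
up-regulation of one miRNA), ``RG3 = SS(1,1) - SS(5,5)`` (modest joint
up-regulation).  A pair is synergistic when RG3 exceeds both single-miRNA
gains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .io_model import NumericalError
from .rna_structure import R_KCAL, TriplexEnergetics

RHO0_NM = 1e9  # 1 M standard state expressed in nM
TF_MIN, TF_MAX = 1e-1, 1e2
_EXP_CLAMP = 60.0  # clamp on dG/RT to keep dissociation rates finite


@dataclass(frozen=True)
class KineticConfig:
    """Documented default rate constants (package configuration values)."""

    k_on: float = 1e-3  # association, nM^-1 s^-1
    k_m: float = 1e-3  # mRNA synthesis, nM/s
    # With recycling, free miRNA sits at TF * k_i / delta_R; these defaults
    # put it at ~TF nM, the dynamic range of duplex dissociation constants.
    k_1: float = 1e-5  # baseline miRNA1 synthesis, nM/s
    k_2: float = 1e-5  # baseline miRNA2 synthesis, nM/s
    delta_m: float = 1e-4  # free mRNA degradation, s^-1
    delta_R: float = 1e-5  # free miRNA degradation, s^-1
    delta_C: float = 2e-4  # duplex degradation, s^-1
    delta_T: float = 4e-4  # triplex degradation, s^-1
    k_p: float = 1e-3  # translation, s^-1
    delta_P: float = 1e-4  # protein degradation, s^-1
    recycle_mirna: bool = True


@dataclass(frozen=True)
class KineticModel:
    """Fully parameterized reaction system for one triplex."""

    k_m: float
    k_1: float
    k_2: float
    a1: float
    a2: float
    d1: float
    d2: float
    a12: float  # R1 association onto C2
    a21: float  # R2 association onto C1
    d12: float  # T -> C2 + R1
    d21: float  # T -> C1 + R2
    delta_m: float
    delta_R: float
    delta_C: float
    delta_T: float
    delta_P: float
    k_p: float
    TF1: float = 1.0
    TF2: float = 1.0
    recycle_mirna: bool = True

    def __post_init__(self):
        for name in (
            "k_m", "k_1", "k_2", "a1", "a2", "d1", "d2", "a12", "a21",
            "d12", "d21", "delta_m", "delta_R", "delta_C", "delta_T",
            "delta_P", "k_p",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")

    def with_tf(self, TF1: float, TF2: float) -> "KineticModel":
        return replace(self, TF1=TF1, TF2=TF2)

    def rhs(self, y: np.ndarray) -> np.ndarray:
        """Time derivatives of (m, R1, R2, C1, C2, T, P)."""
        m, R1, R2, C1, C2, T, P = y
        f1 = self.a1 * m * R1 - self.d1 * C1  # net duplex-1 assembly
        f2 = self.a2 * m * R2 - self.d2 * C2
        g1 = self.a12 * C2 * R1 - self.d12 * T  # R1 joining C2
        g2 = self.a21 * C1 * R2 - self.d21 * T
        rec = 1.0 if self.recycle_mirna else 0.0
        dm = self.k_m - self.delta_m * m - f1 - f2
        dR1 = (
            self.TF1 * self.k_1
            - self.delta_R * R1
            - f1
            - g1
            + rec * (self.delta_C * C1 + self.delta_T * T)
        )
        dR2 = (
            self.TF2 * self.k_2
            - self.delta_R * R2
            - f2
            - g2
            + rec * (self.delta_C * C2 + self.delta_T * T)
        )
        dC1 = f1 - self.delta_C * C1 - g2
        dC2 = f2 - self.delta_C * C2 - g1
        dT = g1 + g2 - self.delta_T * T
        dP = self.k_p * m - self.delta_P * P
        return np.array([dm, dR1, dR2, dC1, dC2, dT, dP])

    def reaction_list(self) -> str:
        """Human-readable reaction table (for manual SBML transcription)."""
        rows = [
            ("0 -> m", f"k_m = {self.k_m}"),
            ("0 -> R1", f"TF1*k_1 = {self.TF1 * self.k_1}"),
            ("0 -> R2", f"TF2*k_2 = {self.TF2 * self.k_2}"),
            ("m + R1 -> C1", f"a1 = {self.a1}"),
            ("C1 -> m + R1", f"d1 = {self.d1}"),
            ("m + R2 -> C2", f"a2 = {self.a2}"),
            ("C2 -> m + R2", f"d2 = {self.d2}"),
            ("C2 + R1 -> T", f"a12 = {self.a12}"),
            ("T -> C2 + R1", f"d12 = {self.d12}"),
            ("C1 + R2 -> T", f"a21 = {self.a21}"),
            ("T -> C1 + R2", f"d21 = {self.d21}"),
            ("m -> 0", f"delta_m = {self.delta_m}"),
            ("R1 -> 0", f"delta_R = {self.delta_R}"),
            ("R2 -> 0", f"delta_R = {self.delta_R}"),
            (
                "C1 -> R1" if self.recycle_mirna else "C1 -> 0",
                f"delta_C = {self.delta_C}",
            ),
            (
                "C2 -> R2" if self.recycle_mirna else "C2 -> 0",
                f"delta_C = {self.delta_C}",
            ),
            (
                "T -> R1 + R2" if self.recycle_mirna else "T -> 0",
                f"delta_T = {self.delta_T}",
            ),
            ("m -> m + P", f"k_p = {self.k_p}"),
            ("P -> 0", f"delta_P = {self.delta_P}"),
        ]
        width = max(len(r) for r, _ in rows)
        return "\n".join(f"{r:<{width}}  {k}" for r, k in rows)


@dataclass(frozen=True)
class RepressionResult:
    """Steady-state surface over the miRNA expression grid plus gains."""

    tf1_values: np.ndarray
    tf2_values: np.ndarray
    ss_grid: np.ndarray  # shape (len(tf1), len(tf2))
    rg1: float
    rg2: float
    rg3: float
    synergy_class: str  # "synergistic" | "additive"


def _stepwise_kd(dG_total: float, dG_remaining: float, temperature: float) -> float:
    """Dissociation constant (nM) of the last strand joining: from the free
    energy difference between the full complex and the one left behind."""
    RT = R_KCAL * temperature
    expo = (dG_total - dG_remaining) / RT
    if expo > _EXP_CLAMP:
        warnings.warn(
            "free-energy difference implies an implausibly fast dissociation; "
            "clamping",
            stacklevel=3,
        )
        expo = _EXP_CLAMP
    return RHO0_NM * math.exp(expo)


def build_model(
    energetics: TriplexEnergetics,
    eq_state=None,
    config: KineticConfig | None = None,
    temperature: float = 310.15,
) -> KineticModel:
    """Parameterize the kinetic model from complex free energies.

    Associations are diffusion-limited at ``config.k_on``; dissociations
    follow detailed balance: ``d_i = k_on * Kd_i`` with
    ``Kd_i = rho0 * exp(dG_duplex_i / RT)`` for the duplexes and the
    stepwise ``Kd = rho0 * exp((dG_triplex - dG_duplex_j) / RT)`` for the
    miRNA leaving the triplex while miRNA ``j`` stays bound.

    ``eq_state`` (the solved equilibrium of the same energies) is accepted
    for provenance; the rate constants are fully determined by the free
    energies and ``config``.
    """
    cfg = config or KineticConfig()
    kd1 = _stepwise_kd(energetics.dG_duplex1, 0.0, temperature)
    kd2 = _stepwise_kd(energetics.dG_duplex2, 0.0, temperature)
    # d12: R1 leaves the triplex, duplex 2 remains; d21: R2 leaves, duplex 1.
    kd_12 = _stepwise_kd(energetics.dG_triplex, energetics.dG_duplex2, temperature)
    kd_21 = _stepwise_kd(energetics.dG_triplex, energetics.dG_duplex1, temperature)
    return KineticModel(
        k_m=cfg.k_m,
        k_1=cfg.k_1,
        k_2=cfg.k_2,
        a1=cfg.k_on,
        a2=cfg.k_on,
        d1=cfg.k_on * kd1,
        d2=cfg.k_on * kd2,
        a12=cfg.k_on,
        a21=cfg.k_on,
        d12=cfg.k_on * kd_12,
        d21=cfg.k_on * kd_21,
        delta_m=cfg.delta_m,
        delta_R=cfg.delta_R,
        delta_C=cfg.delta_C,
        delta_T=cfg.delta_T,
        delta_P=cfg.delta_P,
        k_p=cfg.k_p,
        recycle_mirna=cfg.recycle_mirna,
    )


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

def _baseline_protein(model: KineticModel) -> float:
    m0 = model.k_m / model.delta_m
    return model.k_p * m0 / model.delta_P


def _solve_algebraic(model: KineticModel, y0: np.ndarray) -> np.ndarray | None:
    fun = lambda y: model.rhs(y)
    sol = root(fun, y0, method="hybr", tol=1e-13)
    y = sol.x
    if not sol.success or np.any(y < -1e-9):
        return None
    scale = np.maximum(np.abs(y), 1e-12)
    if np.max(np.abs(model.rhs(y)) / (model.k_m + model.delta_m * scale)) > 1e-7:
        return None
    return np.maximum(y, 0.0)


def _solve_ode(model: KineticModel, y0: np.ndarray | None = None) -> np.ndarray:
    rates = [
        model.delta_m, model.delta_R, model.delta_C, model.delta_T,
        model.delta_P,
    ]
    t_end = 50.0 / min(r for r in rates if r > 0)
    if y0 is None:
        y0 = np.zeros(7)
        y0[0] = model.k_m / model.delta_m
    sol = solve_ivp(
        lambda t, y: model.rhs(y),
        (0.0, t_end),
        y0,
        method="BDF",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    return np.maximum(sol.y[:, -1], 0.0)


def steady_state(
    model: KineticModel,
    TF1: float | None = None,
    TF2: float | None = None,
    method: str = "newton",
    _warm_start: np.ndarray | None = None,
) -> float:
    """Normalized steady-state target expression at the given expression
    factors: protein at steady state divided by the miRNA-free baseline.

    ``method``: ``newton`` (algebraic root-solve with ODE fallback) or
    ``ode`` (time integration to convergence, then a Newton polish).
    """
    if TF1 is not None or TF2 is not None:
        model = model.with_tf(
            TF1 if TF1 is not None else model.TF1,
            TF2 if TF2 is not None else model.TF2,
        )
    y = None
    if method == "newton":
        guesses = []
        if _warm_start is not None:
            guesses.append(_warm_start)
        m0 = model.k_m / model.delta_m
        r1 = model.TF1 * model.k_1 / model.delta_R
        r2 = model.TF2 * model.k_2 / model.delta_R
        guesses.append(np.array([m0, r1, r2, 0.0, 0.0, 0.0, model.k_p * m0 / model.delta_P]))
        guesses.append(np.full(7, 1.0))
        for g in guesses:
            y = _solve_algebraic(model, g)
            if y is not None:
                break
        if y is None:
            y = _solve_ode(model)
            y_polish = _solve_algebraic(model, y)
            if y_polish is not None:
                y = y_polish
    elif method == "ode":
        y = _solve_ode(model)
        y_polish = _solve_algebraic(model, y)
        if y_polish is not None and np.allclose(
            y_polish, y, rtol=1e-4, atol=1e-8
        ):
            y = y_polish
    else:
        raise ValueError(f"unknown steady-state method {method!r}")
    residual = np.max(np.abs(model.rhs(y)))
    if not np.isfinite(residual) or residual > 1e-6 * max(model.k_m, 1e-12):
        raise NumericalError(
            f"no steady-state convergence; final residual {residual}"
        )
    return float(y[6] / _baseline_protein(model))


def steady_state_vector(
    model: KineticModel, TF1: float, TF2: float
) -> np.ndarray:
    """Full steady-state species vector (m, R1, R2, C1, C2, T, P)."""
    model = model.with_tf(TF1, TF2)
    y = _solve_algebraic(model, _solve_ode(model))
    if y is None:
        y = _solve_ode(model)
    return y


def repression_gain(
    model: KineticModel,
    sign_convention: str = "positive",
) -> tuple[float, float, float]:
    """(RG1, RG2, RG3) at the canonical grid points.

    ``positive`` (default): RG = SS(1,1) - SS(point), so larger gain means
    stronger repression.  ``literal``: the opposite sign.
    """
    if sign_convention not in ("positive", "literal"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    ss11 = steady_state(model, 1.0, 1.0)
    rg1 = ss11 - steady_state(model, 10.0, 1.0)
    rg2 = ss11 - steady_state(model, 1.0, 10.0)
    rg3 = ss11 - steady_state(model, 5.0, 5.0)
    if sign_convention == "literal":
        rg1, rg2, rg3 = -rg1, -rg2, -rg3
    return rg1, rg2, rg3


def repression_surface(
    model: KineticModel,
    tf_points: int = 25,
    tf_bounds: tuple[float, float] = (TF_MIN, TF_MAX),
    sign_convention: str = "positive",
) -> RepressionResult:
    """Steady-state surface over a log-spaced expression-factor grid plus
    repression gains and the synergy verdict."""
    lo, hi = tf_bounds
    if lo < TF_MIN - 1e-12 or hi > TF_MAX + 1e-12 or lo >= hi:
        raise ValueError(
            f"grid bounds must lie within [{TF_MIN}, {TF_MAX}] with lo < hi"
        )
    tf1 = np.logspace(math.log10(lo), math.log10(hi), tf_points)
    tf2 = np.logspace(math.log10(lo), math.log10(hi), tf_points)
    grid = np.empty((tf_points, tf_points))
    for i, x in enumerate(tf1):
        for j, y in enumerate(tf2):
            grid[i, j] = steady_state(model, float(x), float(y))
    rg1, rg2, rg3 = repression_gain(model, sign_convention=sign_convention)
    if sign_convention == "positive":
        synergistic = rg3 > max(rg1, rg2)
    else:
        synergistic = rg3 < min(rg1, rg2)
    return RepressionResult(
        tf1_values=tf1,
        tf2_values=tf2,
        ss_grid=grid,
        rg1=rg1,
        rg2=rg2,
        rg3=rg3,
        synergy_class="synergistic" if synergistic else "additive",
    )
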