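"""Equilibrium concentrations of monomers, duplexes and the triplex.

In dilute solution the equilibrium concentration of complex ``c`` built from
strands with stoichiometry ``n_sc`` is

    [c] = rho0 * exp(-dG_c / RT) * prod_s lambda_s ** n_sc

with ``rho0 = 1 M`` the standard state, monomer ``dG = 0`` (unstructured
single strands are the zero point of the energy scale) and per-strand
activities ``lambda_s`` fixed by strand conservation.  The activities are
found by damped Newton iteration on ``log lambda``; a bounded per-coordinate
bisection is the fallback.  Concentrations are exposed in nM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_model import InputError, NumericalError

R_KCAL = 1.9872e-3  # kcal/(mol K)

#: Default heterocomplex set over strands M (mRNA), A and B (the miRNAs).
DEFAULT_COMPLEXES: dict[str, dict[str, int]] = {
    "M": {"M": 1},
    "A": {"A": 1},
    "B": {"B": 1},
    "MA": {"M": 1, "A": 1},
    "MB": {"M": 1, "B": 1},
    "AB": {"A": 1, "B": 1},
    "MAB": {"M": 1, "A": 1, "B": 1},
}

DEFAULT_TOTAL_NM = 100.0
DEFAULT_TEC_THRESHOLD_NM = 50.0


@dataclass(frozen=True)
class EquilibriumState:
    """Solved equilibrium of a strand system; concentrations in nM."""

    strand_totals: dict
    dG: dict
    concentrations: dict
    temperature: float
    complexes: dict = field(default_factory=lambda: dict(DEFAULT_COMPLEXES))

    def fraction_in(self, complex_name: str, strand: str) -> float:
        """Fraction of a strand's total bound in the given complex."""
        n = self.complexes[complex_name].get(strand, 0)
        return n * self.concentrations[complex_name] / self.strand_totals[strand]


def dg_for_kd(kd_nM: float, temperature: float = 310.15) -> float:
    """Free energy (kcal/mol) whose association constant matches the given
    dissociation constant: ``rho0 * exp(-dG/RT) = 1 / Kd``."""
    return R_KCAL * temperature * math.log(kd_nM * 1e-9)


def equilibrium_concentrations(
    dG: Mapping[str, float],
    strand_totals: Mapping[str, float] | None = None,
    temperature: float = 310.15,
    complexes: Mapping[str, Mapping[str, int]] | None = None,
    rtol: float = 1e-10,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve the mass-action equilibrium for the declared complex set.

    ``dG`` maps complex name -> free energy (kcal/mol); monomers default to 0
    and multimers missing from ``dG`` are an error.  ``strand_totals`` maps
    strand -> total concentration in nM (default 100 nM each).  A complex
    with ``dG = +inf`` has zero concentration (binding disabled).
    """
    complexes = {k: dict(v) for k, v in (complexes or DEFAULT_COMPLEXES).items()}
    strands = sorted({s for comp in complexes.values() for s in comp})
    for name, comp in complexes.items():
        if sum(comp.values()) > 1 and name not in dG:
            raise InputError(f"no free energy given for complex {name!r}")
    totals_nM = dict.fromkeys(strands, DEFAULT_TOTAL_NM)
    if strand_totals:
        unknown = set(strand_totals) - set(strands)
        if unknown:
            raise InputError(f"totals given for undeclared strand(s): {unknown}")
        totals_nM.update(strand_totals)
    RT = R_KCAL * temperature
    totals = {s: t * 1e-9 for s, t in totals_nM.items()}  # molar

    names, comps, logK = [], [], []
    for name, comp in complexes.items():
        g = dG.get(name, 0.0)
        if math.isinf(g):
            continue  # disabled complex: concentration identically zero
        names.append(name)
        comps.append([comp.get(s, 0) for s in strands])
        logK.append(-g / RT)
    A = np.array(comps, dtype=float)  # (n_complex, n_strand)
    logK = np.array(logK)
    t = np.array([totals[s] for s in strands])
    sizes = A.sum(axis=1)

    # nondimensionalize: totals of order 1 keep the line search well scaled
    tref = float(np.exp(np.mean(np.log(t))))
    logK = logK + (sizes - 1.0) * math.log(tref)
    t = t / tref

    x = np.log(t)  # log activities, start at free-strand totals
    # pre-shift so no complex starts absurdly oversaturated
    for _ in range(200):
        excess = np.max(logK + A @ x) - (math.log(np.min(t)) + 40.0)
        if excess <= 0:
            break
        x -= excess / np.min(sizes[sizes > 0])

    def conc(xv: np.ndarray) -> np.ndarray:
        return np.exp(logK + A @ xv)

    def residual(xv: np.ndarray) -> np.ndarray:
        return A.T @ conc(xv) / t - 1.0

    # Strand conservation is the stationarity condition of the convex
    # potential Phi(x) = sum_c [c](x) - sum_s t_s x_s; damped Newton with
    # Levenberg regularization on its (PSD, possibly singular) Hessian.
    def phi(xv: np.ndarray) -> float:
        return float(np.sum(conc(xv)) - t @ xv)

    converged = False
    lam = 0.0
    for _ in range(max_iter):
        c = conc(x)
        per_strand = A.T @ c
        if np.max(np.abs(per_strand / t - 1.0)) < rtol:
            converged = True
            break
        grad = per_strand - t
        H = (A.T * c) @ A
        scale = np.trace(H) / len(t)
        step = None
        for boost in range(40):
            try:
                step = np.linalg.solve(
                    H + (lam + 1e-14 * (10.0 ** boost)) * scale * np.eye(len(t)),
                    grad,
                )
                break
            except np.linalg.LinAlgError:
                continue
        if step is None:
            break
        if np.max(np.abs(per_strand / t - 1.0)) < 1e-3:
            # near the solution the Phi decrease falls below machine
            # precision; line-search on the residual norm instead
            r0 = np.linalg.norm(per_strand / t - 1.0)
            alpha = 1.0
            accepted = False
            for _ in range(60):
                xn = x - alpha * step
                if np.linalg.norm(residual(xn)) < r0:
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                lam = max(lam / 10.0, 0.0)
                x = xn
            else:
                lam = max(lam * 10.0, 1e-10)
            continue
        f0 = phi(x)
        alpha = 1.0
        for _ in range(80):
            xn = x - alpha * step
            if phi(xn) < f0:
                break
            alpha *= 0.5
        else:
            lam = max(lam * 10.0, 1e-10)
            continue
        lam = max(lam / 10.0, 0.0)
        x = xn
    if not converged:
        x = _bisect_fallback(A, logK, t, x, rtol)
        if np.max(np.abs(residual(x))) >= rtol:
            raise NumericalError(
                "equilibrium solve did not converge; residuals "
                f"{residual(x).tolist()}"
            )

    c = conc(x) * tref
    concentrations = dict.fromkeys(complexes, 0.0)
    for name, ci in zip(names, c):
        concentrations[name] = float(ci) * 1e9  # nM
    state = EquilibriumState(
        strand_totals=dict(totals_nM),
        dG={k: float(dG.get(k, 0.0)) for k in complexes},
        concentrations=concentrations,
        temperature=temperature,
        complexes=complexes,
    )
    _assert_mass_conservation(state)
    return state


def _bisect_fallback(A, logK, t, x, rtol, sweeps: int = 400) -> np.ndarray:
    """Per-coordinate bounded bisection on log activities.

    Each strand's conservation residual is strictly increasing in its own
    log activity, so a one-dimensional root always exists and is unique.
    """
    x = x.copy()
    for _ in range(sweeps):
        worst = 0.0
        for s in range(len(t)):
            lo, hi = x[s] - 80.0, math.log(t[s]) + 1.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                x[s] = mid
                r = (A.T @ np.exp(logK + A @ x))[s] / t[s] - 1.0
                if r > 0:
                    hi = mid
                else:
                    lo = mid
                if hi - lo < 1e-15:
                    break
            worst = max(worst, abs(r))
        if worst < rtol:
            break
    return x


def _assert_mass_conservation(state: EquilibriumState, rtol: float = 1e-6) -> None:
    for strand, total in state.strand_totals.items():
        bound = sum(
            comp.get(strand, 0) * state.concentrations[name]
            for name, comp in state.complexes.items()
        )
        if abs(bound - total) > rtol * total:
            raise NumericalError(
                f"mass conservation violated for strand {strand}: "
                f"{bound} vs {total} nM"
            )


def triplex_filter(
    state: EquilibriumState,
    threshold_nM: float = DEFAULT_TEC_THRESHOLD_NM,
    triplex: str = "MAB",
) -> bool:
    """True when the triplex equilibrium concentration strictly exceeds the
    threshold (default 50 nM at 100 nM strand totals)."""
    if triplex not in state.complexes:
        raise InputError(f"complex {triplex!r} not in the declared set")
    return state.concentrations[triplex] > threshold_nM


def equilibrium_from_energetics(
    dG_triplex: float,
    dG_duplex1: float,
    dG_duplex2: float,
    dG_mirna_dimer: float = 0.0,
    strand_totals: Mapping[str, float] | None = None,
    temperature: float = 310.15,
) -> EquilibriumState:
    """Equilibrium of the standard {M, A, B, MA, MB, AB, MAB} system from
    complex free energies (mRNA = M, upstream miRNA = A, downstream = B)."""
    return equilibrium_concentrations(
        {
            "MA": dG_duplex1,
            "MB": dG_duplex2,
            "AB": dG_mirna_dimer,
            "MAB": dG_triplex,
        },
        strand_totals=strand_totals,
        temperature=temperature,
    )
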