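"""Mass-action equilibrium speciation at fixed pH.

Solves the free-metal / free-ligand concentrations of a system consisting of
a polyprotic ligand (described by its stepwise pKa ladder) and a set of
M_m L_l complexes with cumulative formation constants log beta, at a fixed,
buffered proton activity.  All constants are conditional constants at the
working ionic strength and temperature; no activity-coefficient model is
applied.

The two mass balances solved simultaneously, with [H+] = 10**(-pH) fixed,
are::

    L_tot = [L] * alpha_L(H) + sum_j l_j * beta_j * [M]**m_j * [L]**l_j
    M_tot = [M]              + sum_j m_j * beta_j * [M]**m_j * [L]**l_j

where ``alpha_L(H) = 1 + sum_i beta_H_i [H+]**i`` is the ligand's proton
side-reaction coefficient (binding polynomial).

The primary solver is a damped Newton iteration in log10 free-concentration
coordinates (concentrations span many decades; log coordinates preserve
positivity).  A nested-bisection scan is kept as a fallback for the rare
starting points from which Newton fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ProtolysisScheme",
    "ComplexSpecies",
    "EquilibriumConditions",
    "SpeciationResult",
    "SpeciationError",
    "protonation_betas",
    "binding_polynomial",
    "conditional_logK",
    "solve_speciation",
    "titration_speciation",
]

#: convergence tolerance on scaled mass-balance residuals
RESIDUAL_TOL = 1e-12
MAX_NEWTON_ITER = 200


class SpeciationError(RuntimeError):
    """Raised when the equilibrium solver cannot close the mass balances.

    Carries the best-achieved residuals for diagnostics.
    """

    def __init__(self, message: str, residuals: tuple[float, float] | None = None):
        if residuals is not None:
            message = f"{message} (residuals: metal={residuals[0]:.3e}, ligand={residuals[1]:.3e})"
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class ProtolysisScheme:
    """Stepwise acid-dissociation ladder of the ligand, most acidic first."""

    stepwise_pKa: tuple[float, ...]

    def __init__(self, stepwise_pKa: Sequence[float] = ()):
        values = tuple(float(v) for v in stepwise_pKa)
        if any(not math.isfinite(v) for v in values):
            raise ValueError("all pKa values must be finite")
        object.__setattr__(self, "stepwise_pKa", values)

    @property
    def n_protons(self) -> int:
        return len(self.stepwise_pKa)


@dataclass(frozen=True)
class ComplexSpecies:
    """An M_m L_l complex with cumulative formation constant log10(beta).

    ``log_beta`` refers to free metal and the fully deprotonated ligand.
    """

    m: int
    l: int
    log_beta: float
    label: str = ""

    def __post_init__(self):
        if self.m < 1 or self.l < 1:
            raise ValueError("stoichiometric coefficients must be >= 1")
        if not math.isfinite(self.log_beta):
            raise ValueError("log_beta must be finite")


@dataclass(frozen=True)
class EquilibriumConditions:
    """Totals and fixed master variables of one equilibrium problem."""

    metal_total: float
    ligand_total: float
    pH: float
    temperature: float = 25.0  # metadata, degC
    ionic_strength: float = 0.1  # metadata, M

    def __post_init__(self):
        if self.metal_total < 0 or self.ligand_total < 0:
            raise ValueError("totals must be non-negative")
        if not (0.0 < self.pH < 14.0):
            raise ValueError("pH must lie in (0, 14)")


@dataclass
class SpeciationResult:
    free_metal: float
    free_ligand: float
    species_concentrations: dict[str, float]
    mass_balance_residuals: tuple[float, float]
    conditions: EquilibriumConditions | None = None
    species: tuple[ComplexSpecies, ...] = field(default_factory=tuple)

    @property
    def complexed_metal(self) -> float:
        return sum(
            sp.m * self.species_concentrations[_species_key(sp)] for sp in self.species
        )

    @property
    def complexed_fraction(self) -> float:
        """Fraction of total metal bound in complexes (0 if no metal)."""
        if self.conditions is None or self.conditions.metal_total == 0:
            return 0.0
        return self.complexed_metal / self.conditions.metal_total


def _species_key(sp: ComplexSpecies) -> str:
    return sp.label or f"M{sp.m}L{sp.l}"


def protonation_betas(scheme: ProtolysisScheme) -> list[float]:
    """Cumulative protonation constants log10(beta_H,i) from the pKa ladder.

    In protonation order (most basic step first), log beta_H,i is the sum of
    the i most basic stepwise pKa values: an aprotic ligand yields ``[]``.
    """
    ladder = sorted(scheme.stepwise_pKa, reverse=True)  # most basic first
    out: list[float] = []
    acc = 0.0
    for pka in ladder:
        acc += pka
        out.append(acc)
    return out


def binding_polynomial(scheme: ProtolysisScheme, pH: float) -> float:
    """Proton side-reaction coefficient alpha_L(H) = 1 + sum beta_H,i [H]^i."""
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    log_h = -pH
    alpha = 1.0
    for i, log_beta_h in enumerate(protonation_betas(scheme), start=1):
        alpha += 10.0 ** (log_beta_h + i * log_h)
    return alpha


def conditional_logK(scheme: ProtolysisScheme, log_K: float, pH: float) -> float:
    """pH-conditional stability constant: log K' = log K - log10 alpha_L(H)."""
    return log_K - math.log10(binding_polynomial(scheme, pH))


def _balances(
    log_m: float,
    log_l: float,
    alpha: float,
    species: Sequence[ComplexSpecies],
) -> tuple[float, float]:
    """Total metal and total ligand implied by free concentrations."""
    m = 10.0**log_m
    l = 10.0**log_l
    m_tot = m
    l_tot = l * alpha
    for sp in species:
        c = 10.0 ** (sp.log_beta + sp.m * log_m + sp.l * log_l)
        m_tot += sp.m * c
        l_tot += sp.l * c
    return m_tot, l_tot


def _newton_solve(
    m_total: float,
    l_total: float,
    alpha: float,
    species: Sequence[ComplexSpecies],
) -> tuple[float, float] | None:
    """Damped Newton in log10 coordinates; returns (log_m, log_l) or None."""
    ln10 = math.log(10.0)
    log_m = math.log10(m_total)  # free <= total: start at totals
    log_l = math.log10(l_total / alpha)

    for _ in range(MAX_NEWTON_ITER):
        m = 10.0**log_m
        l = 10.0**log_l
        fm = m - m_total
        fl = l * alpha - l_total
        # Jacobian entries d(balance)/d(log10 free), analytic
        jmm = ln10 * m
        jml = 0.0
        jlm = 0.0
        jll = ln10 * l * alpha
        for sp in species:
            c = 10.0 ** (sp.log_beta + sp.m * log_m + sp.l * log_l)
            fm += sp.m * c
            fl += sp.l * c
            jmm += ln10 * sp.m * sp.m * c
            jml += ln10 * sp.m * sp.l * c
            jlm += ln10 * sp.l * sp.m * c
            jll += ln10 * sp.l * sp.l * c

        rm = fm / m_total
        rl = fl / l_total
        if abs(rm) < RESIDUAL_TOL and abs(rl) < RESIDUAL_TOL:
            return log_m, log_l

        det = jmm * jll - jml * jlm
        if det == 0 or not math.isfinite(det):
            return None
        dm = -(jll * fm - jml * fl) / det
        dl = -(-jlm * fm + jmm * fl) / det
        # damp: free concentrations move at most one decade per iteration
        step = max(abs(dm), abs(dl))
        if step > 1.0:
            dm /= step
            dl /= step
        log_m += dm
        log_l += dl
        if not (math.isfinite(log_m) and math.isfinite(log_l)):
            return None
    return None


def _bisection_solve(
    m_total: float,
    l_total: float,
    alpha: float,
    species: Sequence[ComplexSpecies],
    tol: float = 1e-14,
) -> tuple[float, float]:
    """Nested bisection fallback on (log[M], log[L]).

    For a fixed free metal, the ligand balance is strictly increasing in
    log[L]; the resulting metal balance is strictly increasing in log[M],
    so both levels bracket a unique root.
    """

    def inner_log_l(log_m: float) -> float:
        lo = math.log10(l_total / alpha) - 30.0
        hi = math.log10(l_total / alpha)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            _, lt = _balances(log_m, mid, alpha, species)
            if lt > l_total:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    lo = math.log10(m_total) - 30.0
    hi = math.log10(m_total)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mt, _ = _balances(mid, inner_log_l(mid), alpha, species)
        if mt > m_total:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    log_m = 0.5 * (lo + hi)
    return log_m, inner_log_l(log_m)


def solve_speciation(
    conditions: EquilibriumConditions,
    scheme: ProtolysisScheme,
    species_set: Sequence[ComplexSpecies] = (),
) -> SpeciationResult:
    """Solve the equilibrium speciation of one (M_tot, L_tot, pH) point.

    Degenerate totals short-circuit: with no ligand every complex
    concentration is zero, and symmetrically for no metal.

    Raises
    ------
    SpeciationError
        If neither Newton nor the bisection fallback closes the mass
        balances to the 1e-12 scaled-residual tolerance.
    """
    species = tuple(species_set)
    alpha = binding_polynomial(scheme, conditions.pH)
    m_total = conditions.metal_total
    l_total = conditions.ligand_total

    if m_total == 0.0 or l_total == 0.0 or not species:
        free_m = m_total
        free_l = l_total / alpha
        conc = {_species_key(sp): 0.0 for sp in species}
        return SpeciationResult(
            free_metal=free_m,
            free_ligand=free_l,
            species_concentrations=conc,
            mass_balance_residuals=(0.0, 0.0),
            conditions=conditions,
            species=species,
        )

    sol = _newton_solve(m_total, l_total, alpha, species)
    if sol is None:
        sol = _bisection_solve(m_total, l_total, alpha, species)
    log_m, log_l = sol

    mt, lt = _balances(log_m, log_l, alpha, species)
    residuals = ((mt - m_total) / m_total, (lt - l_total) / l_total)
    if max(abs(residuals[0]), abs(residuals[1])) > 1e-10:
        raise SpeciationError("speciation solver did not converge", residuals)

    conc = {
        _species_key(sp): 10.0 ** (sp.log_beta + sp.m * log_m + sp.l * log_l)
        for sp in species
    }
    return SpeciationResult(
        free_metal=10.0**log_m,
        free_ligand=10.0**log_l,
        species_concentrations=conc,
        mass_balance_residuals=residuals,
        conditions=conditions,
        species=species,
    )


def titration_speciation(
    schedule: Sequence[EquilibriumConditions],
    scheme: ProtolysisScheme,
    species_set: Sequence[ComplexSpecies] = (),
) -> list[SpeciationResult]:
    """Solve speciation for every step of a titration schedule."""
    out = []
    for i, cond in enumerate(schedule):
        try:
            out.append(solve_speciation(cond, scheme, species_set))
        except SpeciationError as exc:
            raise SpeciationError(f"titration step {i} failed: {exc}") from exc
    return out


def speciation_table(results: Sequence[SpeciationResult]):
    """Long-form table of a titration speciation series (one row per step)."""
    import pandas as pd

    rows = []
    for i, r in enumerate(results):
        row = {
            "step": i,
            "metal_total": r.conditions.metal_total if r.conditions else np.nan,
            "ligand_total": r.conditions.ligand_total if r.conditions else np.nan,
            "pH": r.conditions.pH if r.conditions else np.nan,
            "free_metal": r.free_metal,
            "free_ligand": r.free_ligand,
        }
        row.update(r.species_concentrations)
        rows.append(row)
    return pd.DataFrame(rows)
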