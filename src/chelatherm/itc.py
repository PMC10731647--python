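"""Speciation-based forward modeling and global fitting of ITC titrations.

Per-injection heats are predicted from the change in complex concentrations
between consecutive equilibrium states of the cell, using the overflow
(perfusion-cell) displaced-volume equations: with ``dV_i`` the cumulative
injected volume after injection ``i`` and ``V0`` the working cell volume,

    metal_total_i  = n * M0 * (1 - dV_i/(2 V0)) / (1 + dV_i/(2 V0))
    ligand_total_i = L_syr * (dV_i/V0) / (1 + dV_i/(2 V0))

The reported heat of injection ``i`` includes the heat carried out with the
displaced liquid (midpoint rule) and a constant dilution offset::

    q_i = (Q_i - Q_{i-1}) + (v_i/V0) * (Q_i + Q_{i-1})/2 + q_dil
    Q_i = 1e6 * V0 * sum_j dH_j * [complex_j]_i        (microjoule)

Sign convention is endothermic-positive.  Global fits share log beta and
dH across datasets of the same system while the active fraction ``n`` and
the dilution offset ``q_dil`` stay per-dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .montecarlo import MCInterval, monte_carlo_intervals
from .speciation import (
    ComplexSpecies,
    EquilibriumConditions,
    ProtolysisScheme,
    solve_speciation,
)

__all__ = [
    "InjectionSchedule",
    "Thermogram",
    "ITCFitResult",
    "cell_totals_after_injection",
    "predict_injection_heats",
    "subtract_background",
    "fit_itc",
    "monte_carlo_errors",
    "MICROCAL_TO_MICROJOULE",
]

MICROCAL_TO_MICROJOULE = 4.184

#: default 19-aliquot program: one 0.5 uL pre-titration step then 18 x 2 uL
DEFAULT_INJECTION_VOLUMES_UL = (0.5,) + (2.0,) * 18

SYRINGE_CAPACITY = 40e-6  # liters


@dataclass(frozen=True)
class InjectionSchedule:
    """Cell/syringe geometry plus the per-injection volume program."""

    cell_volume: float = 200e-6  # liters
    syringe_conc: float = 500e-6  # molar ligand
    cell_metal_conc: float = 50e-6  # molar
    injection_volumes: tuple[float, ...] = tuple(
        v * 1e-6 for v in DEFAULT_INJECTION_VOLUMES_UL
    )
    spacing: float = 150.0  # seconds, metadata

    def __post_init__(self):
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if self.cell_volume <= 0 or any(v <= 0 for v in vols):
            raise ValueError("all volumes must be positive")
        if sum(vols) > SYRINGE_CAPACITY + 1e-12:
            raise ValueError(
                f"cumulative injected volume {sum(vols) * 1e6:.1f} uL exceeds syringe capacity"
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @property
    def cumulative_volumes(self) -> np.ndarray:
        """Cumulative injected volume including the pre-injection zero."""
        return np.concatenate([[0.0], np.cumsum(self.injection_volumes)])


@dataclass
class Thermogram:
    """Integrated per-injection heats of one titration run."""

    heats: np.ndarray  # microjoule, endothermic positive
    pH: float
    label: str = ""
    is_blank: bool = False

    def __post_init__(self):
        self.heats = np.asarray(self.heats, dtype=float)
        if not np.all(np.isfinite(self.heats)):
            raise ValueError("heats must be finite")

    @classmethod
    def from_microcal(cls, heats_ucal, pH, label="", is_blank=False) -> "Thermogram":
        heats = np.asarray(heats_ucal, dtype=float) * MICROCAL_TO_MICROJOULE
        return cls(heats=heats, pH=pH, label=label, is_blank=is_blank)


@dataclass
class ITCFitResult:
    species: tuple[ComplexSpecies, ...]
    log_betas: dict[str, float]
    delta_H: dict[str, float]  # J/mol
    n_factors: tuple[float, ...]  # per dataset
    q_dils: tuple[float, ...]  # per dataset, microjoule
    rms: float
    mc_intervals: dict[str, MCInterval] = field(default_factory=dict)
    seed: int | None = None
    warnings: tuple[str, ...] = ()

    @property
    def n_factor(self) -> float:
        return self.n_factors[0]

    @property
    def q_dil(self) -> float:
        return self.q_dils[0]


def _species_key(sp: ComplexSpecies) -> str:
    return sp.label or f"M{sp.m}L{sp.l}"


def cell_totals_after_injection(
    schedule: InjectionSchedule, i: int, n_factor: float = 1.0
) -> tuple[float, float]:
    """Effective cell totals after injection ``i`` (``i = 0``: pre-injection)."""
    if not 0 <= i <= schedule.n_injections:
        raise IndexError(f"injection index {i} out of range 0..{schedule.n_injections}")
    dv = schedule.cumulative_volumes[i]
    v0 = schedule.cell_volume
    ratio = dv / (2.0 * v0)
    metal = n_factor * schedule.cell_metal_conc * (1.0 - ratio) / (1.0 + ratio)
    ligand = schedule.syringe_conc * (dv / v0) / (1.0 + ratio)
    return metal, ligand


def _complex_profiles(
    schedule: InjectionSchedule,
    scheme: ProtolysisScheme,
    species: Sequence[ComplexSpecies],
    pH: float,
    n_factor: float,
) -> np.ndarray:
    """Per-complex concentrations at every injection state, shape (n+1, n_species)."""
    out = np.empty((schedule.n_injections + 1, len(species)))
    for i in range(schedule.n_injections + 1):
        m_tot, l_tot = cell_totals_after_injection(schedule, i, n_factor)
        result = solve_speciation(
            EquilibriumConditions(metal_total=m_tot, ligand_total=l_tot, pH=pH),
            scheme,
            species,
        )
        out[i] = [result.species_concentrations[_species_key(sp)] for sp in species]
    return out


def predict_injection_heats(
    schedule: InjectionSchedule,
    scheme: ProtolysisScheme,
    species: Sequence[ComplexSpecies],
    delta_H: Sequence[float],
    pH: float,
    n_factor: float = 1.0,
    q_dil: float = 0.0,
    include_displaced_heat: bool = True,
) -> np.ndarray:
    """Forward-model the per-injection heat series (microjoule).

    ``delta_H`` is per complex species in J/mol, endothermic positive.
    """
    species = tuple(species)
    dH = np.asarray(delta_H, dtype=float)
    if dH.shape != (len(species),):
        raise ValueError("delta_H must have one entry per complex species")
    profiles = _complex_profiles(schedule, scheme, species, pH, n_factor)
    q_cum = 1e6 * schedule.cell_volume * (profiles @ dH)  # microjoule
    diff = q_cum[1:] - q_cum[:-1]
    if include_displaced_heat:
        v = np.asarray(schedule.injection_volumes)
        diff = diff + (v / schedule.cell_volume) * 0.5 * (q_cum[1:] + q_cum[:-1])
    return diff + q_dil


def subtract_background(sample: Thermogram, blank: Thermogram) -> Thermogram:
    """Elementwise blank (metal-free) subtraction."""
    if len(sample.heats) != len(blank.heats):
        raise ValueError(
            f"length mismatch: sample has {len(sample.heats)} injections, blank {len(blank.heats)}"
        )
    return Thermogram(
        heats=sample.heats - blank.heats,
        pH=sample.pH,
        label=sample.label,
        is_blank=False,
    )


# ---------------------------------------------------------------------------
# global fitting


def _pack(log_betas, delta_H, n_factors, q_dils):
    return np.concatenate([log_betas, delta_H, n_factors, q_dils])


def _unpack(theta, n_species, n_datasets):
    lb = theta[:n_species]
    dh = theta[n_species : 2 * n_species]
    nf = theta[2 * n_species : 2 * n_species + n_datasets]
    qd = theta[2 * n_species + n_datasets :]
    return lb, dh, nf, qd


def _predict_all(theta, schedules, scheme, species, pHs, exclude_first):
    n_species = len(species)
    n_datasets = len(schedules)
    lb, dh, nf, qd = _unpack(theta, n_species, n_datasets)
    current = [replace(sp, log_beta=b) for sp, b in zip(species, lb)]
    chunks = []
    for d in range(n_datasets):
        q = predict_injection_heats(
            schedules[d], scheme, current, dh, pHs[d], n_factor=nf[d], q_dil=qd[d]
        )
        if exclude_first:
            q = q[1:]
        chunks.append(q)
    return chunks


def _linear_subfit_sse(log_betas, schedules, scheme, species, pHs, observed):
    """SSE after solving dH and q_dil linearly at n = 1 for given log betas.

    Used by the deterministic grid scan that seeds the multistart.
    """
    current = [replace(sp, log_beta=b) for sp, b in zip(species, log_betas)]
    sse = 0.0
    dh_best = None
    for sched, pH, obs in zip(schedules, pHs, observed):
        profiles = _complex_profiles(sched, scheme, current, pH, 1.0)
        q_cum_unit = 1e6 * sched.cell_volume * profiles  # per unit dH, per species
        v = np.asarray(sched.injection_volumes)[:, None]
        design = (q_cum_unit[1:] - q_cum_unit[:-1]) + (v / sched.cell_volume) * 0.5 * (
            q_cum_unit[1:] + q_cum_unit[:-1]
        )
        design = np.hstack([design, np.ones((len(obs), 1))])
        coef, *_ = np.linalg.lstsq(design, obs, rcond=None)
        resid = obs - design @ coef
        sse += float(resid @ resid)
        dh_best = coef[:-1]
    return sse, dh_best


def fit_itc(
    thermograms: Sequence[Thermogram],
    schedules: Sequence[InjectionSchedule] | InjectionSchedule,
    scheme: ProtolysisScheme,
    species_set: Sequence[ComplexSpecies],
    exclude_first_injection: bool = False,
    n_starts: int = 5,
    log_beta_bounds: tuple[float, float] = (0.0, 30.0),
) -> ITCFitResult:
    """Globally fit log beta / dH / active fraction / dilution offset.

    The pKa scheme is fixed (taken from the NMR stage), never refit.  The
    ``log_beta`` values on ``species_set`` seed the optimization: a coarse
    grid scan over a common log-beta shift (with linear dH / q_dil sub-fits)
    picks the best seed, then bounded least squares is launched from
    ``n_starts`` deterministic offsets around it.
    """
    if len(thermograms) == 0:
        raise ValueError("need at least one thermogram")
    species = tuple(species_set)
    if not species:
        raise ValueError("need at least one complex species")
    if isinstance(schedules, InjectionSchedule):
        schedules = [schedules] * len(thermograms)
    if len(schedules) != len(thermograms):
        raise ValueError("one schedule per thermogram required")
    pHs = [t.pH for t in thermograms]
    observed = [
        t.heats[1:] if exclude_first_injection else t.heats for t in thermograms
    ]
    obs_vec = np.concatenate(observed)

    n_species = len(species)
    n_datasets = len(thermograms)
    lb0 = np.array([sp.log_beta for sp in species])

    # deterministic grid scan over a common shift of the seed log betas
    best_shift, best_sse, best_dh = 0.0, np.inf, None
    for shift in np.linspace(-4.0, 4.0, 17):
        lb = np.clip(lb0 + shift, *log_beta_bounds)
        try:
            sse, dh = _linear_subfit_sse(
                lb, schedules, scheme, species, pHs, observed
            )
        except Exception:
            continue
        if sse < best_sse:
            best_shift, best_sse, best_dh = shift, sse, dh
    lb_seed = np.clip(lb0 + best_shift, *log_beta_bounds)
    dh_seed = best_dh if best_dh is not None else np.full(n_species, 1e4)

    def residuals(theta):
        chunks = _predict_all(theta, schedules, scheme, species, pHs,
                              exclude_first_injection)
        return np.concatenate(chunks) - obs_vec

    lo = _pack(
        np.full(n_species, log_beta_bounds[0]),
        np.full(n_species, -1e7),
        np.full(n_datasets, 0.05),
        np.full(n_datasets, -np.inf),
    )
    hi = _pack(
        np.full(n_species, log_beta_bounds[1]),
        np.full(n_species, 1e7),
        np.full(n_datasets, 3.0),
        np.full(n_datasets, np.inf),
    )

    offsets = np.linspace(-3.0, 3.0, n_starts) if n_starts > 1 else np.array([0.0])
    best = None
    for off in offsets:
        theta0 = _pack(
            lb_seed + off,
            dh_seed,
            np.ones(n_datasets),
            np.zeros(n_datasets),
        )
        # keep every start strictly feasible (grid-scan dH can be extreme)
        lo_in, hi_in = lo.copy(), hi.copy()
        m = np.isfinite(lo)
        lo_in[m] = lo[m] + 1e-9 * (np.abs(lo[m]) + 1)
        m = np.isfinite(hi)
        hi_in[m] = hi[m] - 1e-9 * (np.abs(hi[m]) + 1)
        theta0 = np.clip(theta0, lo_in, hi_in)
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("ITC global fit failed to converge from every start")

    lb, dh, nf, qd = _unpack(best.x, n_species, n_datasets)
    rms = float(np.sqrt(np.mean(best.fun**2)))

    flags: list[str] = []
    sv = np.linalg.svd(best.jac, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        flags.append("underdetermined: fit Jacobian is numerically rank-deficient")
    for sp, b in zip(species, lb):
        if abs(b - log_beta_bounds[0]) < 1e-6 or abs(b - log_beta_bounds[1]) < 1e-6:
            flags.append(f"log_beta for {_species_key(sp)} pinned at bound")

    return ITCFitResult(
        species=tuple(replace(sp, log_beta=b) for sp, b in zip(species, lb)),
        log_betas={_species_key(sp): float(b) for sp, b in zip(species, lb)},
        delta_H={_species_key(sp): float(h) for sp, h in zip(species, dh)},
        n_factors=tuple(float(x) for x in nf),
        q_dils=tuple(float(x) for x in qd),
        rms=rms,
        warnings=tuple(flags),
    )


def monte_carlo_errors(
    fit: ITCFitResult,
    thermograms: Sequence[Thermogram],
    schedules: Sequence[InjectionSchedule] | InjectionSchedule,
    scheme: ProtolysisScheme,
    n_reps: int = 200,
    seed: int = 0,
    exclude_first_injection: bool = False,
) -> dict[str, MCInterval]:
    """Parametric Monte Carlo intervals for a converged ITC fit.

    Gaussian noise at the fitted rms is added to the model-predicted heats;
    every replicate is refit by warm-started least squares from the point
    estimate.
    """
    species = fit.species
    if isinstance(schedules, InjectionSchedule):
        schedules = [schedules] * len(thermograms)
    pHs = [t.pH for t in thermograms]
    n_species = len(species)
    n_datasets = len(thermograms)

    theta_hat = _pack(
        np.array([fit.log_betas[_species_key(sp)] for sp in species]),
        np.array([fit.delta_H[_species_key(sp)] for sp in species]),
        np.array(fit.n_factors),
        np.array(fit.q_dils),
    )
    chunks = _predict_all(theta_hat, schedules, scheme, species, pHs,
                          exclude_first_injection)
    predicted = np.concatenate(chunks)

    lo = _pack(np.zeros(n_species), np.full(n_species, -1e7),
               np.full(n_datasets, 0.05), np.full(n_datasets, -np.inf))
    hi = _pack(np.full(n_species, 30.0), np.full(n_species, 1e7),
               np.full(n_datasets, 3.0), np.full(n_datasets, np.inf))

    def refit(replicate, _rng):
        def residuals(theta):
            sim = _predict_all(theta, schedules, scheme, species, pHs,
                               exclude_first_injection)
            return np.concatenate(sim) - replicate

        sol = least_squares(residuals, theta_hat, bounds=(lo, hi), method="trf",
                            xtol=1e-10, ftol=1e-10)
        lb, dh, nf, qd = _unpack(sol.x, n_species, n_datasets)
        out = {}
        for sp, b, h in zip(species, lb, dh):
            out[f"log_beta:{_species_key(sp)}"] = b
            out[f"delta_H:{_species_key(sp)}"] = h
        for d in range(n_datasets):
            out[f"n_factor:{d}"] = nf[d]
            out[f"q_dil:{d}"] = qd[d]
        return out

    sigma = max(fit.rms, 1e-12)
    intervals = monte_carlo_intervals(predicted, sigma, refit, n_reps, seed)
    fit.mc_intervals = intervals
    fit.seed = seed
    return intervals
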