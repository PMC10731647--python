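"""Seeded synthetic datasets with the statistical structure each stage assumes.

Every generator draws all randomness from a single ``numpy`` Generator
seeded per call and embeds its full ground truth (and the seed) in the
returned dataset object, so recovery tests are self-contained.  Noise-free
outputs reuse the forward-model code paths of the consuming modules, so
bit-level identity with the fitters' predictions holds by construction.

The Eu(III) emission band defaults (five Gaussian bands near 579 / 592 /
616 / 650 / 700 nm) are package defaults chosen for realism; the study this
mirrors prints no spectral tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nmr as _nmr
from .itc import InjectionSchedule, Thermogram, predict_injection_heats
from .speciation import ComplexSpecies, EquilibriumConditions, ProtolysisScheme
from .trlfs import (
    DelaySchedule,
    LuminescentSpecies,
    TRLFSCube,
    _reconstruct,
    _speciation_profiles,
    build_delay_schedule,
)

__all__ = [
    "SyntheticNMRDataset",
    "SyntheticITCDataset",
    "SyntheticTRLFSDataset",
    "gen_nmr_titration",
    "gen_itc_dataset",
    "gen_trlfs_cube",
    "default_eu_species",
    "default_titration_conditions",
    "DEFAULT_WAVELENGTHS",
]

DEFAULT_WAVELENGTHS = np.arange(570.0, 721.0, 1.0)

#: (center nm, width nm, relative amplitude) of the 5D0->7FJ bands, J=0..4.
#: Aquo ion: dominant magnetic-dipole 592 nm band; complexed ion: dominant
#: hypersensitive 616 nm band plus a symmetry-allowed 579 nm line.
AQUO_BANDS = (
    (579.0, 1.5, 0.01),
    (592.0, 4.0, 1.00),
    (616.0, 4.0, 0.35),
    (650.0, 4.0, 0.03),
    (700.0, 5.0, 0.20),
)
COMPLEX_BANDS = (
    (579.0, 1.5, 0.08),
    (592.0, 4.5, 0.80),
    (616.0, 5.0, 1.60),
    (650.0, 4.0, 0.06),
    (700.0, 6.0, 0.90),
)


@dataclass
class SyntheticNMRDataset:
    series: list[_nmr.NMRTitrationSeries]
    truth: dict
    seed: int


@dataclass
class SyntheticITCDataset:
    sample: Thermogram
    blank: Thermogram
    schedule: InjectionSchedule
    scheme: ProtolysisScheme
    truth: dict
    seed: int


@dataclass
class SyntheticTRLFSDataset:
    cube: TRLFSCube
    scheme: ProtolysisScheme
    truth: dict
    seed: int
    luminescent_species: list[LuminescentSpecies] = field(default_factory=list)
    complex_species: tuple[ComplexSpecies, ...] = ()


def _gaussian_mixture(wavelengths: np.ndarray, bands) -> np.ndarray:
    spec = np.zeros_like(wavelengths, dtype=float)
    for center, width, amp in bands:
        spec += amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    area = np.trapezoid(spec, wavelengths)
    return spec / area


def default_eu_species(
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    tau_aquo_ms: float = 0.109,
    tau_complex_ms: float = 0.385,
) -> list[LuminescentSpecies]:
    """Two-species Eu(III) defaults: aquo ion and 1:1 complex."""
    return [
        LuminescentSpecies(
            spectrum=_gaussian_mixture(wavelengths, AQUO_BANDS),
            lifetime_ms=tau_aquo_ms,
            brightness=1.0,
            label="aquo",
        ),
        LuminescentSpecies(
            spectrum=_gaussian_mixture(wavelengths, COMPLEX_BANDS),
            lifetime_ms=tau_complex_ms,
            brightness=3.0,
            label="complex",
        ),
    ]


def default_titration_conditions(
    metal_total: float = 10e-6,
    ligand_max: float = 112e-6,
    n_steps: int = 15,
    pH: float = 3.5,
) -> list[EquilibriumConditions]:
    """Ligand-into-metal titration design (0 -> ligand_max into fixed metal)."""
    return [
        EquilibriumConditions(metal_total=metal_total, ligand_total=float(L), pH=pH)
        for L in np.linspace(0.0, ligand_max, n_steps)
    ]


# ---------------------------------------------------------------------------
# NMR


DEFAULT_PROBES = (
    # signal_id, baseline ppm, per-transition amplitudes ppm, transitions (indices
    # into the pKa ladder, most acidic first)
    ("aromatic_H", 8.20, (-0.30, -0.40), (0, 1)),
    ("macrocycle_CH2", 3.90, (-0.45, -0.55), (2, 3)),
)


def gen_nmr_titration(
    pka_ladder: Sequence[float],
    pD_grid: np.ndarray | None = None,
    probes=DEFAULT_PROBES,
    noise_sigma: float = 0.0,
    seed: int = 0,
    slopes: float = 1.0,
) -> SyntheticNMRDataset:
    """Per-probe sigmoidal shift titrations from an aqueous pKa ladder.

    pD-scale inflections sit at pKa + 0.4 (the deuterium correction run in
    reverse).  An empty ladder yields flat baselines.
    """
    ladder = sorted(float(p) for p in pka_ladder)
    if pD_grid is None:
        pD_grid = np.arange(0.8, 9.61, 0.2)
    pD_grid = np.asarray(pD_grid, float)
    rng = np.random.default_rng(seed)

    series = []
    truth_probes = {}
    for signal_id, baseline, amplitudes, transition_idx in probes:
        idx = [i for i in transition_idx if i < len(ladder)]
        infl = np.array([ladder[i] + _nmr.DEUTERIUM_CORRECTION for i in idx])
        amps = np.array(amplitudes[: len(idx)])
        slope_arr = np.full(len(idx), slopes)
        clean = _nmr._model(pD_grid, baseline, amps, infl, slope_arr)
        noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
        series.append(
            _nmr.NMRTitrationSeries(signal_id=signal_id, pD=pD_grid, shift_ppm=noisy)
        )
        truth_probes[signal_id] = {
            "inflections_pD": infl.tolist(),
            "amplitudes": amps.tolist(),
            "baseline": baseline,
            "transitions": idx,
        }
    truth = {
        "pka_ladder": ladder,
        "probes": truth_probes,
        "noise_sigma": noise_sigma,
        "slopes": slopes,
    }
    return SyntheticNMRDataset(series=series, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# ITC


def gen_itc_dataset(
    scheme: ProtolysisScheme,
    species_set: Sequence[ComplexSpecies],
    delta_H: Sequence[float],
    pH: float,
    n_factor: float = 1.0,
    q_dil: float = 0.0,
    schedule: InjectionSchedule | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> SyntheticITCDataset:
    """Sample + blank thermogram pair from the speciation forward model.

    The sample carries the complexation heats plus the dilution offset; the
    blank carries the dilution offset alone.
    """
    if schedule is None:
        schedule = InjectionSchedule()
    rng = np.random.default_rng(seed)
    clean = predict_injection_heats(
        schedule, scheme, species_set, delta_H, pH, n_factor=n_factor, q_dil=q_dil
    )
    sample = Thermogram(
        heats=clean + rng.normal(0.0, noise_sigma, size=clean.shape),
        pH=pH,
        label=label,
    )
    blank_clean = np.full(schedule.n_injections, q_dil)
    blank = Thermogram(
        heats=blank_clean + rng.normal(0.0, noise_sigma, size=blank_clean.shape),
        pH=pH,
        label=f"{label}_blank",
        is_blank=True,
    )
    truth = {
        "log_betas": {sp.label or f"M{sp.m}L{sp.l}": sp.log_beta for sp in species_set},
        "delta_H": {
            sp.label or f"M{sp.m}L{sp.l}": float(h)
            for sp, h in zip(species_set, delta_H)
        },
        "n_factor": n_factor,
        "q_dil": q_dil,
        "pH": pH,
        "noise_sigma": noise_sigma,
    }
    return SyntheticITCDataset(
        sample=sample, blank=blank, schedule=schedule, scheme=scheme,
        truth=truth, seed=seed,
    )


# ---------------------------------------------------------------------------
# TRLFS


def gen_trlfs_cube(
    scheme: ProtolysisScheme,
    species_set: Sequence[ComplexSpecies],
    luminescent_species: Sequence[LuminescentSpecies] | None = None,
    conditions: Sequence[EquilibriumConditions] | None = None,
    delay_schedule: DelaySchedule | None = None,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    snr: float | None = None,
    noise_sigma: float = 0.0,
    noise_model: str = "poisson",
    scale: float = 1e9,
    seed: int = 0,
) -> SyntheticTRLFSDataset:
    """Titration TRLFS cube from speciation profiles and species triplets.

    The luminescent species are ordered (free metal, complexes...) to match
    ``species_set``.  ``snr`` is the peak signal-to-noise ratio and, when
    given, overrides ``noise_sigma``.  ``noise_model="poisson"`` draws shot
    noise with the count scale chosen so the brightest voxel has the
    requested SNR (counts are non-negative by construction, matching gated
    photon counting); ``"gaussian"`` adds additive noise, clipped at zero.
    """
    if delay_schedule is None:
        delay_schedule = build_delay_schedule(a=7.0)
    if conditions is None:
        conditions = default_titration_conditions()
    if luminescent_species is None:
        luminescent_species = default_eu_species(wavelengths)
    if len(luminescent_species) != 1 + len(species_set):
        raise ValueError("need one luminescent species per profile column")

    log_betas = np.array([sp.log_beta for sp in species_set])
    profiles = _speciation_profiles(log_betas, conditions, scheme, species_set)

    C = profiles * scale * np.array([ls.brightness for ls in luminescent_species])
    S = np.stack([ls.spectrum for ls in luminescent_species])
    t = delay_schedule.delays_ms
    T = np.exp(-t[None, :] / np.array([ls.lifetime_ms for ls in luminescent_species])[:, None])
    clean = _reconstruct(C, S, T)

    rng = np.random.default_rng(seed)
    peak = float(clean.max())
    if noise_model == "poisson" and (snr or noise_sigma):
        target_snr = snr if snr else peak / noise_sigma
        count_scale = target_snr**2 / peak  # peak counts = snr^2
        noisy = rng.poisson(clean * count_scale).astype(float) / count_scale
        sigma = peak / target_snr  # noise scale at the brightest voxel
    else:
        sigma = peak / snr if snr else noise_sigma
        noisy = (
            clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean
        )
    cube = TRLFSCube(
        conditions=tuple(conditions),
        wavelengths=np.asarray(wavelengths, float),
        delays_ms=t,
        intensities=np.clip(noisy, 0.0, None),
    )
    truth = {
        "log_betas": {sp.label or f"M{sp.m}L{sp.l}": sp.log_beta for sp in species_set},
        "lifetimes_ms": [ls.lifetime_ms for ls in luminescent_species],
        "noise_sigma": sigma,
        "noise_model": noise_model if (snr or noise_sigma) else "none",
        "scale": scale,
        "delays_us": delay_schedule.delays_us.tolist(),
        "clean_factors": (C, S, T),
    }
    return SyntheticTRLFSDataset(
        cube=cube, scheme=scheme, truth=truth, seed=seed,
        luminescent_species=list(luminescent_species),
        complex_species=tuple(species_set),
    )
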