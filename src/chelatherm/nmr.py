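"""pKa determination from pD-dependent NMR chemical-shift titrations.

Fast-exchange chemical shifts along a pD titration trace out sigmoidal
transitions whose inflection points are the (pD-scale) acid-dissociation
exponents.  Each probe signal is fitted with a (bi)dose-response model

    delta(pD) = delta0 + sum_k A_k / (1 + 10**(s_k * (pD_k - pD)))

and inflections are converted to aqueous pKa values by subtracting the
constant deuterium-isotope correction of 0.4 (the same constant that maps a
glass-electrode reading onto the pD scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .speciation import ProtolysisScheme

__all__ = [
    "NMRTitrationSeries",
    "DoseResponseFit",
    "DegenerateFitError",
    "pd_from_meter",
    "fit_dose_response",
    "deuterium_correct_pka",
    "assemble_scheme",
]

#: deuterium isotope correction, both electrode->pD and pD->pKa directions
DEUTERIUM_CORRECTION = 0.4

#: electrode-dominated floor on reported pKa uncertainty
PKA_UNCERTAINTY_FLOOR = 0.15


class DegenerateFitError(ValueError):
    """Series carries no resolvable titration transition."""


@dataclass
class NMRTitrationSeries:
    """One probe signal's (pD, shift) titration track."""

    signal_id: str
    pD: np.ndarray
    shift_ppm: np.ndarray
    nucleus: str = "1H"

    def __post_init__(self):
        self.pD = np.asarray(self.pD, dtype=float)
        self.shift_ppm = np.asarray(self.shift_ppm, dtype=float)
        if self.pD.shape != self.shift_ppm.shape or self.pD.ndim != 1:
            raise ValueError("pD and shift arrays must be equal-length 1-D")
        if not np.all(np.isfinite(self.shift_ppm)):
            raise ValueError("shifts must be finite")
        order = np.argsort(self.pD)
        self.pD = self.pD[order]
        self.shift_ppm = self.shift_ppm[order]
        if np.any(np.diff(self.pD) <= 0):
            raise ValueError("pD values must be distinct")


@dataclass
class DoseResponseFit:
    """Converged (bi)dose-response fit of one titration series."""

    signal_id: str
    n_transitions: int
    inflections: np.ndarray  # pD scale, sorted ascending
    amplitudes: np.ndarray  # ppm
    baseline: float  # ppm
    slopes: np.ndarray
    rms: float
    uncertainties: np.ndarray  # per-inflection 1-sigma
    transition_labels: tuple[str, ...] = ()

    def predict(self, pD: np.ndarray) -> np.ndarray:
        return _model(
            np.asarray(pD, float),
            self.baseline,
            self.amplitudes,
            self.inflections,
            self.slopes,
        )


def pd_from_meter(reading: float) -> float:
    """pD from a glass-electrode meter reading: reading + 0.4."""
    if not math.isfinite(reading):
        raise ValueError("meter reading must be finite")
    return reading + DEUTERIUM_CORRECTION


def deuterium_correct_pka(pD_inflection: float) -> float:
    """Aqueous-scale pKa from a pD-scale inflection: pD - 0.4."""
    if not math.isfinite(pD_inflection):
        raise ValueError("inflection must be finite")
    return pD_inflection - DEUTERIUM_CORRECTION


def _model(pD, baseline, amplitudes, inflections, slopes):
    out = np.full_like(pD, baseline, dtype=float)
    for a, p, s in zip(amplitudes, inflections, slopes):
        out += a / (1.0 + 10.0 ** (s * (p - pD)))
    return out


def _noise_estimate(shift: np.ndarray) -> float:
    """Robust noise scale from second differences of the ordered series."""
    if len(shift) < 3:
        return 0.0
    d2 = np.diff(shift, n=2)
    return 1.4826 * float(np.median(np.abs(d2))) / math.sqrt(6.0)


def _initial_inflections(series: NMRTitrationSeries, n: int) -> np.ndarray:
    """Deterministic inflection guesses from the smoothed shift derivative."""
    pd_grid = series.pD
    shift = series.shift_ppm
    # 3-point moving average keeps the guess robust to point noise
    if len(shift) >= 3:
        smooth = np.convolve(shift, np.ones(3) / 3.0, mode="same")
        smooth[0], smooth[-1] = shift[0], shift[-1]
    else:
        smooth = shift
    mid = 0.5 * (pd_grid[:-1] + pd_grid[1:])
    deriv = np.abs(np.diff(smooth) / np.diff(pd_grid))
    # greedy peak picking with a half-unit exclusion window
    guesses: list[float] = []
    d = deriv.copy()
    for _ in range(n):
        k = int(np.argmax(d))
        guesses.append(float(mid[k]))
        d[np.abs(mid - mid[k]) < 0.5] = -np.inf
    return np.sort(np.array(guesses))


def fit_dose_response(
    series: NMRTitrationSeries,
    n_transitions: int,
    free_slopes: bool = False,
    transition_labels: Sequence[str] = (),
) -> DoseResponseFit:
    """Least-squares (bi)dose-response fit of one titration series.

    Slopes default to 1 (one-proton fast-exchange limit); set
    ``free_slopes`` to co-fit them.  Raises :class:`DegenerateFitError` when
    the series' shift range is indistinguishable from noise.
    """
    if n_transitions not in (1, 2):
        raise ValueError("n_transitions must be 1 or 2")
    npts = len(series.pD)
    if npts < 6 * n_transitions:
        raise ValueError(
            f"need >= {6 * n_transitions} points for {n_transitions} transition(s), got {npts}"
        )

    shift = series.shift_ppm
    span = float(shift.max() - shift.min())
    noise = _noise_estimate(shift)
    if span == 0.0 or (noise > 0 and span < 3.0 * noise):
        raise DegenerateFitError(
            f"signal {series.signal_id!r}: shift range {span:.4g} ppm below 3x noise {noise:.4g} ppm"
        )

    p_guess = _initial_inflections(series, n_transitions)
    total_amp = shift[-1] - shift[0]
    a_guess = np.full(n_transitions, total_amp / n_transitions)

    def pack(baseline, amps, infl, slopes):
        theta = [baseline, *amps, *infl]
        if free_slopes:
            theta += list(slopes)
        return np.array(theta)

    def unpack(theta):
        baseline = theta[0]
        amps = theta[1 : 1 + n_transitions]
        infl = theta[1 + n_transitions : 1 + 2 * n_transitions]
        slopes = (
            theta[1 + 2 * n_transitions :] if free_slopes else np.ones(n_transitions)
        )
        return baseline, amps, infl, slopes

    def residuals(theta):
        return _model(series.pD, *unpack(theta)) - shift

    theta0 = pack(shift[0], a_guess, p_guess, np.ones(n_transitions))
    lo = np.full_like(theta0, -np.inf)
    hi = np.full_like(theta0, np.inf)
    # inflections constrained to the observed window +- 1
    lo[1 + n_transitions : 1 + 2 * n_transitions] = series.pD.min() - 1.0
    hi[1 + n_transitions : 1 + 2 * n_transitions] = series.pD.max() + 1.0
    if free_slopes:
        lo[1 + 2 * n_transitions :] = 0.1
        hi[1 + 2 * n_transitions :] = 10.0

    sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-14)
    if not sol.success:
        raise RuntimeError(
            f"dose-response fit failed for {series.signal_id!r}: {sol.message}"
        )

    baseline, amps, infl, slopes = unpack(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))

    # covariance-based sigma on the inflections, floored at the electrode error
    dof = max(npts - len(sol.x), 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * (np.sum(sol.fun**2) / dof)
        sigma = np.sqrt(np.diag(cov)[1 + n_transitions : 1 + 2 * n_transitions])
    except np.linalg.LinAlgError:
        sigma = np.full(n_transitions, np.inf)
    sigma = np.maximum(sigma, PKA_UNCERTAINTY_FLOOR)

    order = np.argsort(infl)
    return DoseResponseFit(
        signal_id=series.signal_id,
        n_transitions=n_transitions,
        inflections=np.asarray(infl)[order],
        amplitudes=np.asarray(amps)[order],
        baseline=float(baseline),
        slopes=np.asarray(slopes)[order],
        rms=rms,
        uncertainties=sigma[order],
        transition_labels=tuple(transition_labels),
    )


def assemble_scheme(
    fits: Sequence[DoseResponseFit],
    merge_tol: float = 0.3,
    correct: bool = True,
) -> ProtolysisScheme:
    """Merge per-probe fits into a single deuterium-corrected pKa ladder.

    Inflections from different probes are treated as reports of the same
    transition when they either share a transition label or lie within
    ``merge_tol`` pD units; same-label reports further apart raise, since
    they contradict the claimed assignment.  Merged values are
    uncertainty-weighted means.
    """
    entries: list[tuple[float, float, str | None]] = []  # (pD, sigma, label)
    for fit in fits:
        labels = fit.transition_labels or (None,) * fit.n_transitions
        if len(labels) != fit.n_transitions:
            raise ValueError(
                f"fit {fit.signal_id!r}: {len(labels)} labels for {fit.n_transitions} transitions"
            )
        for p, s, lab in zip(fit.inflections, fit.uncertainties, labels):
            entries.append((float(p), float(s), lab))

    # same-label conflict check
    by_label: dict[str, list[float]] = {}
    for p, _, lab in entries:
        if lab is not None:
            by_label.setdefault(lab, []).append(p)
    for lab, vals in by_label.items():
        if max(vals) - min(vals) > merge_tol:
            raise ValueError(
                f"transition {lab!r}: probes disagree by {max(vals) - min(vals):.2f} (> {merge_tol})"
            )

    # proximity clustering on the sorted values
    entries.sort(key=lambda e: e[0])
    clusters: list[list[tuple[float, float, str | None]]] = []
    for e in entries:
        if clusters and e[0] - clusters[-1][-1][0] <= merge_tol:
            clusters.append(clusters.pop() + [e])
        else:
            clusters.append([e])

    ladder = []
    for cluster in clusters:
        w = np.array([1.0 / max(s, 1e-12) ** 2 for _, s, _ in cluster])
        p = np.array([p for p, _, _ in cluster])
        merged = float(np.sum(w * p) / np.sum(w))
        ladder.append(deuterium_correct_pka(merged) if correct else merged)
    return ProtolysisScheme(sorted(ladder))
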