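"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's solver code paths: speciation is
solved by literal nested bisection on (log[M], log[L]); ITC cell totals by
a stepwise mixing simulation; ITC heats by finite-difference bookkeeping at
10x finer injection granularity.
"""

from __future__ import annotations

import math

import numpy as np


def alpha_direct(pkas, pH):
    """Term-by-term binding polynomial from the stepwise pKa values."""
    ladder = sorted(pkas, reverse=True)  # protonation order
    alpha = 1.0
    for i in range(1, len(ladder) + 1):
        log_beta_h = sum(ladder[:i])
        alpha += 10.0 ** (log_beta_h - i * pH)
    return alpha


def bisect_speciation(m_tot, l_tot, pH, pkas, species, n_iter=160):
    """Nested-bisection equilibrium solve.

    ``species`` is a sequence of (m, l, log_beta).  Returns
    (free_metal, free_ligand).  Bisection scans sign changes of the metal
    balance over log[M], with an inner bisection on log[L] for each trial.
    """
    alpha = alpha_direct(pkas, pH)
    if m_tot == 0 or l_tot == 0 or not species:
        return m_tot, l_tot / alpha

    def ligand_balance(log_m, log_l):
        total = 10.0**log_l * alpha
        for m, l, lb in species:
            total += l * 10.0 ** (lb + m * log_m + l * log_l)
        return total - l_tot

    def metal_balance(log_m, log_l):
        total = 10.0**log_m
        for m, l, lb in species:
            total += m * 10.0 ** (lb + m * log_m + l * log_l)
        return total - m_tot

    def inner(log_m):
        hi = math.log10(l_tot / alpha)
        lo = hi - 40.0
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            if ligand_balance(log_m, mid) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    hi = math.log10(m_tot)
    lo = hi - 40.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if metal_balance(mid, inner(mid)) > 0:
            hi = mid
        else:
            lo = mid
    log_m = 0.5 * (lo + hi)
    return 10.0**log_m, 10.0 ** inner(log_m)


def stepwise_mixing_totals(v0, syringe_conc, cell_metal_conc, volumes,
                           substeps=100):
    """Cell totals after each injection by explicit mix-then-overflow steps.

    Each sub-injection adds ``dv`` of titrant to the constant-volume cell,
    mixes, and expels ``dv`` of the mixed solution.
    """
    moles_m = cell_metal_conc * v0
    moles_l = 0.0
    out = [(moles_m / v0, moles_l / v0)]
    for v in volumes:
        dv = v / substeps
        for _ in range(substeps):
            moles_l += syringe_conc * dv
            keep = v0 / (v0 + dv)
            moles_m *= keep
            moles_l *= keep
        out.append((moles_m / v0, moles_l / v0))
    return np.array(out)


def finite_difference_heats(schedule, pkas, species, delta_H, pH,
                            n_factor=1.0, q_dil=0.0, substeps=10):
    """Per-injection heats from 10x finer stepwise dilution bookkeeping.

    Uses the stepwise mixing model for the totals and the nested-bisection
    speciation oracle for the complex concentrations; the displaced-liquid
    heat is accumulated sub-step by sub-step with midpoint concentrations.
    """
    v0 = schedule.cell_volume
    moles_m = n_factor * schedule.cell_metal_conc * v0
    moles_l = 0.0

    def complexes(mm, ml):
        fm, fl = bisect_speciation(mm / v0, ml / v0, pH, pkas, species)
        return np.array(
            [10.0 ** (lb) * fm**m * fl**l for m, l, lb in species]
        )

    conc_prev = complexes(moles_m, moles_l)
    heats = []
    for v in schedule.injection_volumes:
        dv = v / substeps
        q = 0.0
        for _ in range(substeps):
            moles_l += schedule.syringe_conc * dv
            keep = v0 / (v0 + dv)
            moles_m *= keep
            moles_l *= keep
            conc = complexes(moles_m, moles_l)
            dH = np.asarray(delta_H)
            q += 1e6 * (
                v0 * float(dH @ (conc - conc_prev))
                + dv * float(dH @ (0.5 * (conc + conc_prev)))
            )
            conc_prev = conc
        heats.append(q + q_dil)
    return np.array(heats)
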