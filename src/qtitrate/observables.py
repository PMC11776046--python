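"""pH-dependent observables from standard-state spectra.

The q-canonical separation makes pH enter analytically: a mesostate with n
released protons has pH-dependent free energy

    G_n(pH) = G_n^0 - n * RT * ln(10) * pH

so its population is a softmax over mesostates at any pH, with no explicit
titration of microstates. The sign convention is fixed by the decoupled
(single-site) limit, which must reduce to Henderson-Hasselbalch:
released fraction = 10^(pH - pKa) / (1 + 10^(pH - pKa)).

Conventions: the global curve ``f_tot`` is the fraction of ionizable protons
*released* (0 at low pH -> 1 at high pH); per-site curves report the fraction
proton-*bound* (1 at low pH -> 0 at high pH), the quantity site-specific NMR
titrations measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .context_db import ContextDB
from .ionization_model import (
    IonizableSite,
    LN10,
    ProteinSequence,
    R_KCAL_MOL_K,
    find_ionizable_sites,
)
from .partition_engine import (
    BOUND,
    MesostateSpectrum,
    OpCounter,
    RELEASED,
    SiteSpectrum,
    site_dp,
)

_CONSISTENCY_GUARD = 1e-6  # kcal/mol-scale guard on bound+released closure


def ph_grid(start: float = 0.0, stop: float = 14.0, step: float = 0.05) -> np.ndarray:
    """Strictly increasing pH grid (used for reporting only — all crossings
    are refined on the analytic curves, so the step affects bracketing only)."""
    if step <= 0 or stop <= start:
        raise ValueError("pH grid must be strictly increasing")
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    return grid[grid <= stop + 1e-12]


def mesostate_populations(
    spec: MesostateSpectrum,
    ph_values,
    T: float = 298.0,
) -> np.ndarray:
    """Mesostate population matrix, shape (n_pH, N+1); rows sum to 1.

    p_n(pH) is proportional to exp(-(g_n - n RT ln10 pH)/RT), computed with a
    per-row shift so no exponential overflows.
    """
    ph = np.atleast_1d(np.asarray(ph_values, dtype=float))
    rt = R_KCAL_MOL_K * T
    n = np.arange(spec.n_sites + 1)
    logw = -(spec.g[None, :] / rt) + LN10 * np.outer(ph, n)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def global_titration(
    spec: MesostateSpectrum,
    ph_values,
    T: float = 298.0,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Global released fraction f_tot and mean net charge versus pH.

    f_tot(pH) = sum_n (n/N) p_n(pH); the net charge follows from the exact
    bijection q = q_max - n. Both curves are monotone in pH (f_tot
    nondecreasing, net charge nonincreasing). For a sequence without
    ionizable sites f_tot is None (empty-result marker) and the charge is 0.
    """
    ph = np.atleast_1d(np.asarray(ph_values, dtype=float))
    if spec.n_sites == 0:
        return None, np.zeros(len(ph))
    p = mesostate_populations(spec, ph, T)
    n = np.arange(spec.n_sites + 1)
    f_tot = p @ (n / spec.n_sites)
    net = p @ (spec.q_max - n).astype(float)
    return f_tot, net


def site_fractions(
    site_spec: SiteSpectrum,
    spec: MesostateSpectrum,
    T: float = 298.0,
) -> np.ndarray:
    """Mesostate-conditional state fractions f[n, r, s], pH independent.

    f = exp(-(g_site[r,s,n] - g[n])/RT); bound and released sum to 1 for
    every populated (r, n). A violation beyond the numerical guard means the
    two spectra do not describe the same ensemble (contract violation).
    """
    if site_spec.n_sites != spec.n_sites:
        raise ValueError("site and mesostate spectra describe different systems")
    rt = R_KCAL_MOL_K * T
    diff = site_spec.g - spec.g[None, None, :]
    f = np.where(np.isfinite(diff), np.exp(-np.where(np.isfinite(diff), diff, 0.0) / rt), 0.0)
    closure = f[:, BOUND, :] + f[:, RELEASED, :]
    if site_spec.n_sites and np.nanmax(np.abs(closure - 1.0)) > _CONSISTENCY_GUARD:
        raise ValueError(
            "inconsistent spectra: bound + released fractions do not close to 1"
        )
    return f


def site_titration(
    site_spec: SiteSpectrum,
    spec: MesostateSpectrum,
    ph_values,
    T: float = 298.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site proton-bound fraction versus pH.

    Returns (f_site, f_nrs): f_site has shape (n_pH, N) with
    f_site[., r] = sum_n f[n, r, bound] p_n(pH); f_nrs has shape (N, 2, N+1)
    holding the pH-independent mesostate-conditional fractions.
    """
    f = site_fractions(site_spec, spec, T)
    p = mesostate_populations(spec, ph_values, T)
    f_site = p @ f[:, BOUND, :].T
    return f_site, f


def site_bound_fraction(
    site_spec: SiteSpectrum,
    spec: MesostateSpectrum,
    r: int,
    ph: float,
    T: float = 298.0,
) -> float:
    """Analytic bound fraction of site r at one pH (used to refine crossings)."""
    f = site_fractions(site_spec, spec, T)
    p = mesostate_populations(spec, np.array([ph]), T)[0]
    return float(p @ f[r, BOUND, :])


def extract_pka(
    ph_values,
    curve,
    analytic: Callable[[float], float] | None = None,
    tol: float = 1e-6,
) -> tuple[float | None, str]:
    """pH at which a bound-fraction curve crosses 0.5, with a quality flag.

    The grid locates brackets; each crossing is refined on the analytic curve
    (root finding to ``tol`` pH units) when one is supplied, else by linear
    interpolation. Flags: "sigmoid" (exactly one crossing), "multi" (several;
    the first is reported — coupled sites can titrate non-sigmoidally, and a
    single number cannot summarize such a curve), "none" (no crossing in the
    grid range; the value is None).
    """
    ph = np.asarray(ph_values, dtype=float)
    c = np.asarray(curve, dtype=float) - 0.5
    brackets: list[tuple[int, int]] = []
    for i in range(len(ph) - 1):
        if c[i] == 0.0:
            brackets.append((i, i))
        elif c[i] * c[i + 1] < 0.0:
            brackets.append((i, i + 1))
    if c[-1] == 0.0:
        brackets.append((len(ph) - 1, len(ph) - 1))
    if not brackets:
        return None, "none"
    i, j = brackets[0]
    if i == j:
        root = ph[i]
    elif analytic is not None:
        root = brentq(lambda x: analytic(x) - 0.5, ph[i], ph[j], xtol=tol * 1e-2)
    else:
        root = ph[i] + (ph[j] - ph[i]) * (-c[i]) / (c[j] - c[i])
    flag = "sigmoid" if len(brackets) == 1 else "multi"
    return float(root), flag


def extract_site_pkas(
    site_spec: SiteSpectrum,
    spec: MesostateSpectrum,
    ph_values,
    T: float = 298.0,
) -> tuple[np.ndarray, list[str]]:
    """pKa and flag for every site, refined on the analytic curves."""
    f_site, _ = site_titration(site_spec, spec, ph_values, T)
    f = site_fractions(site_spec, spec, T)
    pkas = np.full(site_spec.n_sites, np.nan)
    flags = []
    for r in range(site_spec.n_sites):
        fr = f[r, BOUND, :]

        def analytic(x: float, fr=fr) -> float:
            p = mesostate_populations(spec, np.array([x]), T)[0]
            return float(p @ fr)

        pka, flag = extract_pka(ph_values, f_site[:, r], analytic)
        if pka is not None:
            pkas[r] = pka
        flags.append(flag)
    return pkas, flags


def cooperativity_metric(
    spec: MesostateSpectrum,
    ph_values,
    T: float = 298.0,
    h: float | None = None,
) -> float | None:
    """Slope of the net-charge curve at its midpoint (charge units per pH).

    The midpoint is the pH where the mean net charge crosses
    (q_max + q_min)/2; the slope is a central difference of the analytic
    curve there. A steeper (more negative) slope means more cooperative
    proton binding; like-charge segregation flattens it. Returns None when
    the curve does not cross the midpoint inside the grid.
    """
    ph = np.asarray(ph_values, dtype=float)
    if spec.n_sites == 0:
        return None
    q_mid = spec.q_max - spec.n_sites / 2.0

    def q_of(x: float) -> float:
        p = mesostate_populations(spec, np.array([x]), T)[0]
        n = np.arange(spec.n_sites + 1)
        return float(p @ (spec.q_max - n).astype(float))

    _, net = global_titration(spec, ph, T)
    d = net - q_mid
    idx = np.nonzero(d[:-1] * d[1:] <= 0.0)[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    if d[i] == 0.0:
        mid = float(ph[i])
    else:
        mid = brentq(lambda x: q_of(x) - q_mid, ph[i], ph[i + 1], xtol=1e-9)
    if h is None:
        h = float(ph[1] - ph[0]) if len(ph) > 1 else 0.05
    return (q_of(mid + h) - q_of(mid - h)) / (2.0 * h)


def type_titration_slope(
    ph_values,
    f_site: np.ndarray,
    sites: Sequence[IonizableSite],
    residue_type: str,
) -> float | None:
    """Midpoint steepness of one residue type's mean titration branch.

    Averages the bound-fraction curves of all sites of ``residue_type`` and
    returns the central-difference slope where that mean curve crosses 0.5
    (per-pH-unit, negative). This probes the cooperativity of a single
    titration branch: anti-cooperative deprotonation — e.g. a block of like
    charges resisting further charging — broadens the branch and flattens
    this slope, whereas independently titrating sites of a common shifted pKa
    keep the Henderson-Hasselbalch steepness. Returns None if the type is
    absent or its mean curve does not cross 0.5 inside the grid.
    """
    ph = np.asarray(ph_values, dtype=float)
    mask = np.array([s.residue_type == residue_type for s in sites], dtype=bool)
    if not mask.any():
        return None
    mean = f_site[:, mask].mean(axis=1)
    d = mean - 0.5
    idx = np.nonzero(d[:-1] * d[1:] <= 0.0)[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    lo, hi = max(i - 1, 0), min(i + 2, len(ph) - 1)
    return float((mean[hi] - mean[lo]) / (ph[hi] - ph[lo]))


@dataclass
class TitrationResult:
    """Bundle of every pH-dependent observable for one sequence."""

    seq_id: str
    ph: np.ndarray
    sites: list
    q_max: int
    p_meso: np.ndarray          # (n_pH, N+1)
    f_tot: np.ndarray | None    # fraction of ionizable protons released
    net_charge: np.ndarray
    f_site: np.ndarray          # (n_pH, N) fraction proton-bound
    f_nrs: np.ndarray           # (N, 2, N+1) mesostate-conditional fractions
    pka: np.ndarray             # per-site pKa (NaN when flagged "none")
    pka_flags: list
    spectrum: MesostateSpectrum
    site_spectrum: SiteSpectrum
    midpoint_slope: float | None = None
    counter: OpCounter | None = None


def compute_titration(
    seq: ProteinSequence,
    db: ContextDB,
    T: float = 298.0,
    ph_values=None,
    enabled_types: Sequence[str] | None = None,
    context_depth: int | None = None,
    allow_approx: bool = False,
    max_context_depth: int = 12,
) -> TitrationResult:
    """Full pipeline: sites -> exact spectra -> pH observables -> pKa values."""
    ph = ph_grid() if ph_values is None else np.asarray(ph_values, dtype=float)
    if np.any(np.diff(ph) <= 0):
        raise ValueError("pH grid must be strictly increasing")
    counter = OpCounter()
    sites = find_ionizable_sites(seq, enabled_types)
    site_spec, spec = site_dp(
        seq, sites, db, T=T,
        context_depth=context_depth,
        allow_approx=allow_approx,
        max_context_depth=max_context_depth,
        counter=counter,
    )
    p_meso = mesostate_populations(spec, ph, T)
    f_tot, net = global_titration(spec, ph, T)
    if spec.n_sites:
        f_site, f_nrs = site_titration(site_spec, spec, ph, T)
        pka, flags = extract_site_pkas(site_spec, spec, ph, T)
    else:
        f_site = np.zeros((len(ph), 0))
        f_nrs = np.zeros((0, 2, 1))
        pka, flags = np.zeros(0), []
    slope = cooperativity_metric(spec, ph, T)
    return TitrationResult(
        seq_id=seq.id,
        ph=ph,
        sites=list(sites),
        q_max=spec.q_max,
        p_meso=p_meso,
        f_tot=f_tot,
        net_charge=net,
        f_site=f_site,
        f_nrs=f_nrs,
        pka=pka,
        pka_flags=flags,
        spectrum=spec,
        site_spectrum=site_spec,
        midpoint_slope=slope,
        counter=counter,
    )
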