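"""Exact charge-state partition functions by dynamic programming.

Standard-state microstate free energies are defined along the N-to-C
thermodynamic path: a microstate's energy is the sum, over its released sites
taken in increasing site index, of the context-dependent deprotonation free
energy of each site given the states of the sites already processed (right
neighbors still protonated). Everything here is pH independent; pH enters
analytically downstream (see :mod:`qtitrate.observables`).

Three routes to the same quantities, in increasing sophistication:

* :func:`enumerate_microstates` — the brute-force oracle over all 2**N
  patterns (reference implementation, exponential cost);
* :func:`dynamic_build` — same output via prefix sharing, each shared context
  evaluated once;
* :func:`global_dp` / :func:`site_dp` — polynomial-cost recurrences that
  propagate pooled (log-sum-exp combined) free energies per mesostate and per
  context of the last L processed sites, never materializing microstates.
  They are exact: a site's free energy depends only on the states of the
  ionizable sites within its left window, which in N-to-C order are always
  among the most recently processed sites, so a context depth L covering the
  densest left window reproduces the oracle to floating-point accuracy.

Internally the DPs work with Boltzmann weights scaled by a per-mesostate
free-energy offset, renormalized each step, which keeps every exponential in
range regardless of sequence length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .context_db import ContextDB, context_delta_g, left_window_sites
from .ionization_model import (
    IonizableSite,
    Microstate,
    ProteinSequence,
    R_KCAL_MOL_K,
    q_max_of,
)

#: state index of the proton-bound (retained) ledger in a SiteSpectrum
BOUND = 0
#: state index of the proton-released ledger
RELEASED = 1

#: free energies beyond this agreement are considered distinct ensembles
ORACLE_TOL = 1e-9


@dataclass
class OpCounter:
    """Instrumented operation counts: energy additions and pairwise merges."""

    adds: int = 0
    combines: int = 0


@dataclass(frozen=True)
class MesostateSpectrum:
    """Overall standard free energy per mesostate n = 0..N (kcal/mol).

    ``g[0]`` is exactly 0 (the fully protonated reference is a single
    microstate). Net charge of mesostate n is ``q_max - n``.
    """

    g: np.ndarray
    n_sites: int
    q_max: int


@dataclass(frozen=True)
class SiteSpectrum:
    """Site-restricted free energies, shape (site, state, mesostate).

    ``g[r, s, n]`` pools the microstates of mesostate n in which site r is in
    state s (BOUND / RELEASED). Impossible combinations — e.g. released at
    n = 0 — carry +inf (an empty ensemble has zero weight). For every r and n,
    combining the bound and released entries recovers the mesostate free
    energy.
    """

    g: np.ndarray
    n_sites: int


def combine_free_energies(
    g_list: Sequence[float],
    T: float = 298.0,
    counter: OpCounter | None = None,
) -> float:
    """Free energy of the pooled ensemble: -RT ln sum_i exp(-g_i / RT).

    Overflow-safe (shifted by the minimum before exponentiation); +inf
    entries are empty ensembles and contribute zero weight. The result never
    exceeds min(g_list).
    """
    arr = np.asarray(g_list, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot combine an empty list of free energies")
    rt = R_KCAL_MOL_K * T
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        return math.inf
    m = finite.min()
    if counter is not None:
        counter.combines += finite.size - 1
    return float(m - rt * math.log(np.exp(-(finite - m) / rt).sum()))


# ---------------------------------------------------------------------------
# brute-force oracle and dynamic building
# ---------------------------------------------------------------------------

def microstate_free_energy(
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    db: ContextDB,
    pattern: Sequence[int],
) -> float:
    """Standard free energy of one release pattern along the N-to-C path."""
    g = 0.0
    for i, bit in enumerate(pattern):
        if bit:
            g += context_delta_g(db, seq, sites, i, pattern)
    return g


def enumerate_microstates(
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    db: ContextDB,
    cap: int = 20,
    counter: OpCounter | None = None,
) -> list[Microstate]:
    """All 2**N microstates with path free energies (the brute-force oracle)."""
    n_sites = len(sites)
    if n_sites > cap:
        raise ValueError(
            f"{n_sites} ionizable sites means 2**{n_sites} microstates; "
            f"enumeration is capped at {cap} — use global_dp/site_dp instead"
        )
    q_max = q_max_of(sites)
    out = []
    for pattern in itertools.product((0, 1), repeat=n_sites):
        n_rel = sum(pattern)
        g = microstate_free_energy(seq, sites, db, pattern)
        if counter is not None:
            counter.adds += n_rel
        out.append(Microstate(pattern, n_rel, q_max - n_rel, g))
    return out


def dynamic_build(
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    db: ContextDB,
    cap: int = 20,
    counter: OpCounter | None = None,
) -> list[Microstate]:
    """Same microstate set as the oracle, via prefix sharing.

    Microstates that agree on the states of the first i sites share the free
    energy accumulated up to site i; a depth-first expansion therefore
    evaluates each context exactly once (2**N - 1 additions instead of the
    oracle's N * 2**(N-1)).
    """
    n_sites = len(sites)
    if n_sites > cap:
        raise ValueError(
            f"{n_sites} ionizable sites exceeds the enumeration cap {cap} — "
            "use global_dp/site_dp instead"
        )
    q_max = q_max_of(sites)
    out: list[Microstate] = []
    pattern = [0] * n_sites

    def expand(i: int, g: float) -> None:
        if i == n_sites:
            n_rel = sum(pattern)
            out.append(Microstate(tuple(pattern), n_rel, q_max - n_rel, g))
            return
        pattern[i] = 0
        expand(i + 1, g)
        dg = context_delta_g(db, seq, sites, i, pattern)
        if counter is not None:
            counter.adds += 1
        pattern[i] = 1
        expand(i + 1, g + dg)
        pattern[i] = 0

    expand(0, 0.0)
    return out


def oracle_mesostate_spectrum(
    microstates: Sequence[Microstate],
    n_sites: int,
    q_max: int,
    T: float = 298.0,
) -> MesostateSpectrum:
    """Mesostate free energies by direct log-sum-exp over enumerated states."""
    g = np.full(n_sites + 1, math.inf)
    for n in range(n_sites + 1):
        members = [m.g_standard for m in microstates if m.n_released == n]
        if members:
            g[n] = combine_free_energies(members, T)
    return MesostateSpectrum(g=g, n_sites=n_sites, q_max=q_max)


def oracle_site_spectrum(
    microstates: Sequence[Microstate],
    n_sites: int,
    T: float = 298.0,
) -> SiteSpectrum:
    """Site-restricted free energies by direct log-sum-exp (reference)."""
    g = np.full((n_sites, 2, n_sites + 1), math.inf)
    for r in range(n_sites):
        for s, want in ((BOUND, 0), (RELEASED, 1)):
            for n in range(n_sites + 1):
                members = [
                    m.g_standard
                    for m in microstates
                    if m.n_released == n and m.pattern[r] == want
                ]
                if members:
                    g[r, s, n] = combine_free_energies(members, T)
    return SiteSpectrum(g=g, n_sites=n_sites)


# ---------------------------------------------------------------------------
# dynamic programs
# ---------------------------------------------------------------------------

def exact_context_depth(
    sites: Sequence[IonizableSite],
    window: int,
) -> int:
    """Smallest context depth that makes the DP exact for this sequence.

    Site i's free energy reads the states of the sites in its left window;
    the oldest of those is min(nb), so the context must reach back
    i - min(nb) processed sites. The depth is the maximum of that span over
    all sites (at least 1).
    """
    depth = 1
    for i in range(len(sites)):
        nb = left_window_sites(sites, i, window)
        if nb:
            depth = max(depth, i - min(nb))
    return depth


def _delta_e_table(
    db: ContextDB,
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    t: int,
    L: int,
) -> np.ndarray:
    """Deprotonation free energy of site t for each of the 2**L contexts.

    Context bit b holds the release state of site t - 1 - b (bit 0 = most
    recent). Neighbors older than the context depth (approximate mode only)
    are taken as protonated.
    """
    C = 1 << L
    nb = left_window_sites(sites, t, db.window)
    tracked = [j for j in nb if t - 1 - j < L]
    k = len(tracked)
    states = [0] * t
    vals = np.empty(1 << k)
    for m in range(1 << k):
        for idx, j in enumerate(tracked):
            states[j] = (m >> idx) & 1
        vals[m] = context_delta_g(db, seq, sites, t, states)
    if k == 0:
        return np.full(C, vals[0])
    dE = np.empty(C)
    for c in range(C):
        m = 0
        for idx, j in enumerate(tracked):
            m |= ((c >> (t - 1 - j)) & 1) << idx
        dE[c] = vals[m]
    return dE


def _resolve_depth(
    sites: Sequence[IonizableSite],
    window: int,
    context_depth: int | None,
    allow_approx: bool,
    max_context_depth: int,
) -> int:
    exact = exact_context_depth(sites, window)
    if context_depth is None:
        L = exact
    else:
        L = int(context_depth)
        if L < 1:
            raise ValueError("context depth must be >= 1")
        if L < exact and not allow_approx:
            raise ValueError(
                f"context depth {L} is below the exact requirement {exact} for "
                "this sequence/window; pass allow_approx=True to accept an "
                "approximate (right-filled protonated) context"
            )
    if L > max_context_depth:
        raise ValueError(
            f"context depth {L} exceeds the cap {max_context_depth} "
            f"(2**{L} context states per cell)"
        )
    return L


def _run_dp(
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    db: ContextDB,
    T: float,
    L: int,
    counter: OpCounter | None,
    want_site: bool,
):
    n_sites = len(sites)
    rt = R_KCAL_MOL_K * T
    C = 1 << L
    half = C >> 1
    W = np.zeros((n_sites + 1, C))
    W[0, 0] = 1.0
    O = np.zeros(n_sites + 1)  # per-mesostate free-energy offsets
    if want_site:
        S = np.zeros((n_sites, 2, n_sites + 1, C))
        S_next = np.zeros_like(S)

    for t in range(n_sites):
        rows = t + 1  # mesostates populated so far: n = 0..t
        nr = rows + 1
        dE = _delta_e_table(db, seq, sites, t, L)
        Ef = np.exp(-dE / rt)
        # mesostate t+1 is populated for the first time this step: seed its
        # offset from its only source row so the transfer factor stays O(1)
        O[rows] = O[rows - 1]
        fac = np.exp(-(O[:rows] - O[1:nr]) / rt)

        Wv = W[:rows].reshape(rows, 2, half)
        ret = Wv[:, 0, :] + Wv[:, 1, :]
        relv = (W[:rows] * Ef).reshape(rows, 2, half)
        rel = (relv[:, 0, :] + relv[:, 1, :]) * fac[:, None]

        if want_site:
            if t > 0:
                old = S[:t, :, :rows, :]
                o4 = old.reshape(t, 2, rows, 2, half)
                s_ret = o4[..., 0, :] + o4[..., 1, :]
                r4 = (old * Ef).reshape(t, 2, rows, 2, half)
                s_rel = (r4[..., 0, :] + r4[..., 1, :]) * fac[None, None, :, None]
                blk = S_next[:t, :, :nr, :]
                blk[...] = 0.0
                blk[:, :, :rows, 0::2] = s_ret
                blk[:, :, 1:nr, 1::2] = s_rel
            # the newly considered site inherits the accumulated ensemble:
            # its bound ledger is the retained branch of the global table,
            # its released ledger the released branch
            fresh = S_next[t, :, :nr, :]
            fresh[...] = 0.0
            fresh[BOUND, :rows, 0::2] = ret
            fresh[RELEASED, 1:nr, 1::2] = rel

        W_next = np.zeros_like(W)
        W_next[:rows, 0::2] = ret
        W_next[1:nr, 1::2] = rel

        # renormalize each mesostate row by its max weight; the same factors
        # apply to the site ledgers (they partition the same ensembles)
        m = W_next[:nr].max(axis=1)
        m = np.where(m > 0.0, m, 1.0)
        W_next[:nr] /= m[:, None]
        if want_site:
            S_next[: t + 1, :, :nr, :] /= m[None, None, :, None]
        O[:nr] -= rt * np.log(m)
        W = W_next
        if want_site:
            S, S_next = S_next, S

        if counter is not None:
            counter.adds += rows * C * ((t + 1) if want_site else 1)
            counter.combines += rows * C * ((t + 1) if want_site else 1)

    with np.errstate(divide="ignore"):
        sw = W.sum(axis=1)
        g = np.where(sw > 0.0, O - rt * np.log(np.where(sw > 0.0, sw, 1.0)), math.inf)
    g[0] = 0.0 if sw[0] > 0 else g[0]  # binary-exact reference
    if not want_site:
        return g
    with np.errstate(divide="ignore"):
        ssw = S.sum(axis=3)
        g_site = np.where(
            ssw > 0.0,
            O[None, None, :] - rt * np.log(np.where(ssw > 0.0, ssw, 1.0)),
            math.inf,
        )
    return g, g_site


def global_dp(
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    db: ContextDB,
    T: float = 298.0,
    context_depth: int | None = None,
    allow_approx: bool = False,
    max_context_depth: int = 12,
    counter: OpCounter | None = None,
) -> MesostateSpectrum:
    """Mesostate free energies by the ensemble-weight recurrences.

    One step per ionizable site (N-to-C): the released branch adds the
    context-dependent deprotonation free energy and advances the mesostate,
    the retained branch adds nothing; branches landing on the same
    (mesostate, context) cell are pooled by log-sum-exp. With the default
    exact context depth the result matches the brute-force oracle to well
    under 1e-9 kcal/mol for any database.
    """
    if len(sites) == 0:
        return MesostateSpectrum(g=np.zeros(1), n_sites=0, q_max=0)
    L = _resolve_depth(sites, db.window, context_depth, allow_approx, max_context_depth)
    g = _run_dp(seq, sites, db, T, L, counter, want_site=False)
    return MesostateSpectrum(g=g, n_sites=len(sites), q_max=q_max_of(sites))


def site_dp(
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    db: ContextDB,
    T: float = 298.0,
    context_depth: int | None = None,
    allow_approx: bool = False,
    max_context_depth: int = 12,
    counter: OpCounter | None = None,
) -> tuple[SiteSpectrum, MesostateSpectrum]:
    """Site-restricted and global free energies in one pass.

    Alongside the global recurrences, a per-(site, state, mesostate, context)
    ledger is propagated: already-tracked sites update through the same
    retained/released branching, and each newly considered site initializes
    its bound/released ledgers from the accumulated global table. Marginalizing
    contexts yields g[r, s, n]; combining the two states of any site recovers
    the global mesostate free energy exactly.
    """
    if len(sites) == 0:
        return (
            SiteSpectrum(g=np.zeros((0, 2, 1)), n_sites=0),
            MesostateSpectrum(g=np.zeros(1), n_sites=0, q_max=0),
        )
    L = _resolve_depth(sites, db.window, context_depth, allow_approx, max_context_depth)
    g, g_site = _run_dp(seq, sites, db, T, L, counter, want_site=True)
    return (
        SiteSpectrum(g=g_site, n_sites=len(sites)),
        MesostateSpectrum(g=g, n_sites=len(sites), q_max=q_max_of(sites)),
    )
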