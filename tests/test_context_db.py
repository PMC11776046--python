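"""Database representation, evaluation, additivity, synthesis, I/O, rescaling."""

import json
import math

import numpy as np
import pytest

from qtitrate import (
    ContextDB,
    NeighborContribution,
    ProteinSequence,
    RescalingFactors,
    apply_rescaling,
    compute_titration,
    context_delta_g,
    find_ionizable_sites,
    load_db,
    save_db,
    synthesize_db,
)
from qtitrate.context_db import DEPROTONATED, PROTONATED, left_window_sites
from qtitrate.ionization_model import LN10, R_KCAL_MOL_K

from conftest import random_instance

RT_LN10 = R_KCAL_MOL_K * 298.0 * LN10


def manual_db(contribs=(), intrinsic=None, window=2, **kw):
    return ContextDB(
        mode="implicit",
        window=window,
        intrinsic=intrinsic or {"E": RT_LN10 * 4.34, "K": RT_LN10 * 10.34},
        contributions=contribs,
        **kw,
    )


def test_isolated_site_returns_intrinsic_exactly():
    db = manual_db()
    seq = ProteinSequence.from_string("t", "GGEGG")
    sites = find_ionizable_sites(seq)
    assert context_delta_g(db, seq, sites, 0, []) == db.intrinsic["E"]


def test_left_neighbor_state_additivity():
    """Flipping one left neighbor changes the value by exactly the term difference."""
    db = synthesize_db(window=3, coupling_a=1.3, seed=5)
    seq = ProteinSequence.from_string("t", "EE")
    sites = find_ionizable_sites(seq)
    g_prot = context_delta_g(db, seq, sites, 1, [0])
    g_deprot = context_delta_g(db, seq, sites, 1, [1])
    expected = db.contribution("E", "E", -1, DEPROTONATED) - db.contribution(
        "E", "E", -1, PROTONATED
    )
    assert g_deprot - g_prot == pytest.approx(expected, abs=1e-15)


def test_symmetric_neighbors_counted_per_side():
    contribs = [
        NeighborContribution("E", "K", -1, PROTONATED, -0.7),
        NeighborContribution("E", "K", +1, PROTONATED, -0.7),
    ]
    db = manual_db(contribs)
    seq = ProteinSequence.from_string("t", "KEK")
    sites = find_ionizable_sites(seq)
    e_index = next(s.site_index for s in sites if s.residue_type == "E")
    g = context_delta_g(db, seq, sites, e_index, [0])
    assert g == pytest.approx(db.intrinsic["E"] + 2 * (-0.7), abs=1e-15)


def test_multi_neighbor_additivity(rng):
    """Value with k flipped neighbors = base + sum of single-flip differences."""
    for _ in range(10):
        seq, sites, db = random_instance(rng, 3, 8)
        i = len(sites) - 1
        nb = left_window_sites(sites, i, db.window)
        base = [0] * i
        g0 = context_delta_g(db, seq, sites, i, base)
        singles = {}
        for j in nb:
            states = list(base)
            states[j] = 1
            singles[j] = context_delta_g(db, seq, sites, i, states) - g0
        all_on = list(base)
        for j in nb:
            all_on[j] = 1
        g_all = context_delta_g(db, seq, sites, i, all_on)
        assert g_all == pytest.approx(g0 + sum(singles.values()), abs=1e-12)


class _GuardedStates:
    """Raises if any site at or beyond the center is consulted."""

    def __init__(self, states, limit):
        self._states = states
        self._limit = limit

    def __getitem__(self, idx):
        if idx >= self._limit:
            raise AssertionError(f"read state of site {idx} >= center {self._limit}")
        return self._states[idx]


def test_path_convention_never_reads_right_states(rng):
    """context_delta_g must not consult states of larger site indices."""
    for _ in range(10):
        seq, sites, db = random_instance(rng, 3, 8)
        for i in range(len(sites)):
            guarded = _GuardedStates([0] * len(sites), i)
            context_delta_g(db, seq, sites, i, guarded)


def test_save_load_round_trip_is_exact(tmp_path, rng):
    db = synthesize_db(window=4, coupling_a=0.8, decay_p=1.3, seed=11)
    path = tmp_path / "db.json"
    save_db(db, path)
    db2 = load_db(path)
    assert db2.window == db.window and db2.mode == db.mode
    assert db2.intrinsic == db.intrinsic
    for _ in range(100):
        seq, sites, _ = random_instance(rng, 2, 8)
        i = int(rng.integers(0, len(sites)))
        states = [int(rng.integers(0, 2)) for _ in range(i)]
        assert context_delta_g(db, seq, sites, i, states) == context_delta_g(
            db2, seq, sites, i, states
        )


def test_load_rejects_missing_intrinsic(tmp_path):
    db = manual_db([NeighborContribution("E", "G", 1, PROTONATED, 0.1)])
    path = tmp_path / "db.json"
    save_db(db, path)
    doc = json.loads(path.read_text())
    del doc["intrinsic"]["E"]
    path.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="intrinsic"):
        load_db(path)


def test_load_rejects_duplicate_contribution(tmp_path):
    db = manual_db([NeighborContribution("E", "G", 1, PROTONATED, 0.1)])
    path = tmp_path / "db.json"
    save_db(db, path)
    doc = json.loads(path.read_text())
    doc["contributions"].append(doc["contributions"][0])
    path.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="duplicate"):
        load_db(path)


def test_explicit_duplicate_key_rejected(tmp_path):
    doc = {
        "mode": "explicit",
        "window": 1,
        "intrinsic": {},
        "contributions": [],
        "explicit_table": [
            {"center": "E", "left": "e", "right": "", "dg": "1.0"},
            {"center": "E", "left": "e", "right": "", "dg": "2.0"},
        ],
    }
    path = tmp_path / "db.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="duplicate"):
        load_db(path)


def test_deprotonated_right_neighbor_rejected():
    with pytest.raises(ValueError, match="path convention"):
        NeighborContribution("E", "E", +1, DEPROTONATED, 0.3)


def test_missing_contribution_policy():
    seq = ProteinSequence.from_string("t", "GEKG")
    sites = find_ionizable_sites(seq)
    lax = manual_db()
    # no contributions at all: every lookup falls back to 0 -> intrinsic only
    assert context_delta_g(lax, seq, sites, 0, []) == lax.intrinsic["E"]
    strict = manual_db(strict=True)
    with pytest.raises(KeyError, match="missing contribution"):
        context_delta_g(strict, seq, sites, 0, [])


def test_explicit_mode_matches_implicit_reference():
    """An explicit table built from implicit evaluations reproduces them."""
    from qtitrate.context_db import render_context

    imp = synthesize_db(window=2, coupling_a=1.0, seed=2)
    seq = ProteinSequence.from_string("t", "EKE")
    sites = find_ionizable_sites(seq)
    table = {}
    for i in range(len(sites)):
        for bits in range(1 << i):
            states = [(bits >> k) & 1 for k in range(i)]
            key = render_context(imp, seq, sites, i, states)
            table[key] = context_delta_g(imp, seq, sites, i, states)
    exp = ContextDB(mode="explicit", window=2, explicit_table=table)
    for i in range(len(sites)):
        for bits in range(1 << i):
            states = [(bits >> k) & 1 for k in range(i)]
            assert context_delta_g(exp, seq, sites, i, states) == context_delta_g(
                imp, seq, sites, i, states
            )


def test_explicit_mode_miss_is_hard_error():
    exp = ContextDB(mode="explicit", window=1, explicit_table={("E", "k", "g"): 1.0})
    seq = ProteinSequence.from_string("t", "KEG")
    sites = find_ionizable_sites(seq)
    e_index = next(s.site_index for s in sites if s.residue_type == "E")
    with pytest.raises(KeyError, match="no entry for context"):
        context_delta_g(exp, seq, sites, e_index, [0])  # left K protonated -> "K"


def test_synthesize_deterministic(tmp_path):
    a = tmp_path / "a.json"
    b = tmp_path / "b.json"
    save_db(synthesize_db(window=3, coupling_a=1.0, seed=42), a)
    save_db(synthesize_db(window=3, coupling_a=1.0, seed=42), b)
    assert a.read_bytes() == b.read_bytes()
    save_db(synthesize_db(window=3, coupling_a=1.0, seed=43), b)
    assert a.read_bytes() != b.read_bytes()


def test_synthesize_charge_signs():
    """Opposite charges favor deprotonation; like charges disfavor it."""
    db = synthesize_db(window=2, coupling_a=1.0, seed=0)
    # Glu center next to a protonated (charged) lysine: pKa drops
    assert db.contribution("E", "K", -1, PROTONATED) < 0
    # Glu center next to a deprotonated (charged) glutamate: pKa rises
    assert db.contribution("E", "E", -1, DEPROTONATED) > 0
    # Lys center next to a deprotonated glutamate: favorable environment
    # raises the lysine pKa (deprotonation disfavored)
    assert db.contribution("K", "E", -1, DEPROTONATED) > 0
    # neutral-in-state neighbors carry no Coulomb term
    assert db.contribution("E", "E", -1, PROTONATED) == 0.0


def test_synthesize_distance_decay():
    db = synthesize_db(window=4, coupling_a=1.0, decay_p=1.0, seed=0)
    mags = [abs(db.contribution("E", "K", -d, PROTONATED)) for d in range(1, 5)]
    assert mags == sorted(mags, reverse=True)
    assert mags[1] == pytest.approx(mags[0] / 2)


def test_decoupled_limit_has_zero_neighbor_terms():
    db = synthesize_db(window=3, coupling_a=0.0, seed=9)
    for c in db.contributions_list():
        assert c.delta_g == 0.0


def test_rescaling_identity_is_bitwise(rng):
    db = synthesize_db(window=3, coupling_a=1.0, seed=1)
    db2 = apply_rescaling(db, RescalingFactors())
    seq, sites, _ = random_instance(rng, 3, 8)
    for i in range(len(sites)):
        states = [int(rng.integers(0, 2)) for _ in range(i)]
        assert context_delta_g(db, seq, sites, i, states) == context_delta_g(
            db2, seq, sites, i, states
        )


def test_rescaling_offset_shifts_pka_by_one_unit(decoupled_db):
    factors = RescalingFactors(intrinsic_offset={"E": RT_LN10 * 1.0})
    shifted = apply_rescaling(decoupled_db, factors)
    seq = ProteinSequence.from_string("t", "GEGKG")
    res0 = compute_titration(seq, decoupled_db)
    res1 = compute_titration(seq, shifted)
    assert res1.pka[0] - res0.pka[0] == pytest.approx(1.0, abs=1e-6)  # the Glu
    assert res1.pka[1] - res0.pka[1] == pytest.approx(0.0, abs=1e-6)  # the Lys


def test_rescaling_scale_zero_removes_coupling():
    """Zeroing the electrostatic factor leaves only state-independent terms."""
    db = synthesize_db(window=3, coupling_a=1.0, seed=4)
    types = sorted(db.intrinsic)
    off = apply_rescaling(db, RescalingFactors(electrostatic_scale={t: 0.0 for t in types}))
    for c in off.contributions_list():
        from qtitrate.ionization_model import formal_charge

        if formal_charge(c.neighbor, int(c.state == DEPROTONATED)) != 0:
            assert c.delta_g == 0.0
    # with every charged-neighbor term gone, sites titrate independently:
    # flipping a left neighbor's state no longer changes anything
    seq = ProteinSequence.from_string("t", "EE")
    sites = find_ionizable_sites(seq)
    assert context_delta_g(off, seq, sites, 1, [0]) == context_delta_g(
        off, seq, sites, 1, [1]
    )


def test_rescaling_explicit_mode_rejected():
    exp = ContextDB(mode="explicit", window=1, explicit_table={("E", "", ""): 1.0})
    with pytest.raises(ValueError, match="implicit"):
        apply_rescaling(exp, RescalingFactors())
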