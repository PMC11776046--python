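"""The sequence-context deprotonation free-energy database.

The free energy of releasing a proton from an ionizable residue depends on
which residues surround it within a window of w sequence neighbors per side,
and — for neighbors that are themselves titratable — on their protonation
state. Two representations are supported:

* **implicit** mode: an intrinsic term per ionizable type plus *additive*
  neighbor contributions keyed by (center type, neighbor type, signed
  sequence distance, neighbor protonation state);
* **explicit** mode: a direct lookup keyed by the fully rendered left/right
  context strings.

Free energies of whole microstates are defined along a fixed thermodynamic
path in which protons are released in N-to-C order. Under that convention a
site's deprotonation free energy is evaluated while every neighbor to its
right is still protonated, so the database never needs (and never stores) a
contribution from a deprotonated right-side neighbor.

A synthetic generator (:func:`synthesize_db`) produces physically structured
stand-in parameters — screened-Coulomb-like, distance-decaying, charge-sign
dependent — so the whole stack runs without any externally fitted database.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .ionization_model import (
    ACID_TYPES,
    BASE_TYPES,
    IONIZABLE_TYPES,
    LN10,
    R_KCAL_MOL_K,
    STANDARD_AA,
    IonizableSite,
    ProteinSequence,
    formal_charge,
)

log = logging.getLogger(__name__)

PROTONATED = "protonated"
DEPROTONATED = "deprotonated"
#: neighbor markers for the chain termini in contribution records
TERMINUS_MARKERS = ("NTERM", "CTERM")


@dataclass(frozen=True)
class NeighborContribution:
    """Additive free-energy term of one neighbor on one center.

    ``distance`` is a signed sequence separation (negative = N-terminal side),
    measured in residues along the chain, non-ionizable residues included.
    ``state`` may be "deprotonated" only for left-side ionizable neighbors:
    by the N-to-C path convention a right-side neighbor is always protonated
    when the center's free energy is evaluated.
    """

    center: str
    neighbor: str
    distance: int
    state: str
    delta_g: float

    def __post_init__(self) -> None:
        if self.center not in IONIZABLE_TYPES:
            raise ValueError(f"center {self.center!r} is not a titratable type")
        if self.neighbor not in STANDARD_AA and self.neighbor not in TERMINUS_MARKERS:
            raise ValueError(f"neighbor {self.neighbor!r} is not a residue or terminus")
        if self.distance == 0:
            raise ValueError("neighbor distance must be nonzero")
        if self.state not in (PROTONATED, DEPROTONATED):
            raise ValueError(f"bad state {self.state!r}")
        if self.state == DEPROTONATED:
            if self.distance > 0:
                raise ValueError(
                    "deprotonated right-side neighbors are excluded by the "
                    "N-to-C path convention"
                )
            if self.neighbor not in IONIZABLE_TYPES:
                raise ValueError(
                    f"non-titratable neighbor {self.neighbor!r} cannot be deprotonated"
                )


def _key(center: str, neighbor: str, distance: int, state: str):
    return (center, neighbor, distance, state)


@dataclass
class RescalingFactors:
    """Per-center-type recalibration of a database.

    ``intrinsic_offset`` (kcal/mol) is added to the intrinsic deprotonation
    free energy of the type; ``electrostatic_scale`` multiplies every additive
    neighbor contribution of that center whose neighbor carries a nonzero
    formal charge in its stated protonation state. Types not listed get
    identity factors (offset 0, scale 1).
    """

    intrinsic_offset: dict = field(default_factory=dict)
    electrostatic_scale: dict = field(default_factory=dict)

    def offset(self, center: str) -> float:
        return float(self.intrinsic_offset.get(center, 0.0))

    def scale(self, center: str) -> float:
        return float(self.electrostatic_scale.get(center, 1.0))


class ContextDB:
    """Container for intrinsic and context-dependent deprotonation terms.

    Parameters
    ----------
    mode:
        "implicit" (additive neighbor terms) or "explicit" (keyed lookup of
        rendered context strings).
    window:
        number of sequence neighbors per side that modulate a center.
    intrinsic:
        map center type -> intrinsic deprotonation free energy (kcal/mol) of
        the isolated site, conventionally RT ln(10) * model pKa.
    contributions:
        iterable of :class:`NeighborContribution` (implicit mode).
    explicit_table:
        map (center, left string, right string) -> delta G (explicit mode).
    strict:
        implicit mode only — if True a missing contribution is an error; if
        False it resolves to 0.0 with a once-per-key warning.
    """

    def __init__(
        self,
        mode: str = "implicit",
        window: int = 5,
        intrinsic: Mapping[str, float] | None = None,
        contributions: Sequence[NeighborContribution] = (),
        explicit_table: Mapping[tuple, float] | None = None,
        metadata: Mapping[str, object] | None = None,
        strict: bool = False,
    ) -> None:
        if mode not in ("implicit", "explicit"):
            raise ValueError(f"bad mode {mode!r}")
        if window < 0:
            raise ValueError("window must be >= 0")
        self.mode = mode
        self.window = int(window)
        self.intrinsic = dict(intrinsic or {})
        self.strict = bool(strict)
        self.metadata = dict(metadata or {})
        self._table: dict = {}
        for c in contributions:
            k = _key(c.center, c.neighbor, c.distance, c.state)
            if k in self._table:
                raise ValueError(f"duplicate contribution for {k}")
            if abs(c.distance) > self.window:
                raise ValueError(
                    f"contribution at distance {c.distance} exceeds window {self.window}"
                )
            self._table[k] = float(c.delta_g)
        self.explicit_table = dict(explicit_table or {})
        for k in self.explicit_table:
            if len(k) != 3:
                raise ValueError(f"explicit key must be (center,left,right): {k!r}")
        self._warned: set = set()
        # every center named in contributions must have an intrinsic term
        for (center, *_rest) in self._table:
            if center not in self.intrinsic:
                raise ValueError(f"contributions name center {center!r} with no intrinsic term")

    # -- elementary lookups --------------------------------------------------
    def intrinsic_dg(self, center: str) -> float:
        try:
            return self.intrinsic[center]
        except KeyError:
            raise KeyError(f"no intrinsic deprotonation free energy for {center!r}") from None

    def contribution(self, center: str, neighbor: str, distance: int, state: str) -> float:
        """Additive term, 0.0 (warn once) or error for a missing key."""
        k = _key(center, neighbor, distance, state)
        try:
            return self._table[k]
        except KeyError:
            if self.strict:
                raise KeyError(f"missing contribution for {k}") from None
            if k not in self._warned:
                self._warned.add(k)
                log.warning("missing contribution for %s; using 0.0", (k,))
            return 0.0

    def contributions_list(self) -> list[NeighborContribution]:
        return [
            NeighborContribution(c, n, d, s, dg)
            for (c, n, d, s), dg in sorted(self._table.items())
        ]


# ---------------------------------------------------------------------------
# context evaluation
# ---------------------------------------------------------------------------

def _residue_site_by_position(sites: Sequence[IonizableSite]) -> dict:
    return {
        s.position: s
        for s in sites
        if s.residue_type not in TERMINUS_MARKERS
    }


def left_window_sites(
    sites: Sequence[IonizableSite],
    site_index: int,
    window: int,
) -> list[int]:
    """Site indices (< site_index) within ``window`` residues left of the center.

    These are the only earlier sites whose protonation state the center's
    free energy depends on. Because sites are ordered N-to-C, the result is a
    contiguous run of the most recent site indices — the fact the dynamic
    program's truncated context relies on. A terminus sharing the center's own
    position (sequence distance 0) is excluded: the schema carries no distance-0
    term.
    """
    center = sites[site_index]
    return [
        s.site_index
        for s in sites[:site_index]
        if 1 <= center.position - s.position <= window
    ]


def render_context(
    db: ContextDB,
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    site_index: int,
    left_states: Sequence[int],
) -> tuple[str, str, str]:
    """Render (center, left, right) strings for explicit-mode lookup.

    Left ionizable neighbors are case-coded by their state (charged = upper
    case); right neighbors are rendered in their protonated form per the
    N-to-C path convention; non-ionizable residues are upper case.
    """
    center = sites[site_index]
    pos = center.position
    w = db.window
    by_pos = _residue_site_by_position(sites)

    def render(j: int) -> str:
        res = seq.residues[j]
        site = by_pos.get(j)
        if site is None:
            return res.upper()
        if j < pos:
            released = int(left_states[site.site_index])
        else:
            released = 0  # right side: protonated by path convention
        charged = (released == 1) if site.charge_class == "acid" else (released == 0)
        return res.upper() if charged else res.lower()

    left = "".join(render(j) for j in range(max(0, pos - w), pos))
    right = "".join(render(j) for j in range(pos + 1, min(len(seq), pos + w + 1)))
    return center.residue_type, left, right


def context_delta_g(
    db: ContextDB,
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    site_index: int,
    left_states: Sequence[int],
) -> float:
    """Deprotonation free energy of one site in its current context (kcal/mol).

    ``left_states`` must be indexable by site_index for every site preceding
    the center; states of sites at or beyond ``site_index`` are never read
    (N-to-C path convention — right-side neighbors count as protonated).
    """
    center = sites[site_index]
    if db.mode == "explicit":
        key = render_context(db, seq, sites, site_index, left_states)
        try:
            return db.explicit_table[key]
        except KeyError:
            raise KeyError(
                f"explicit database has no entry for context {key!r}"
            ) from None

    pos = center.position
    w = db.window
    by_pos = _residue_site_by_position(sites)
    dg = db.intrinsic_dg(center.residue_type)
    lo = max(0, pos - w)
    hi = min(len(seq) - 1, pos + w)
    for j in range(lo, hi + 1):
        if j == pos:
            continue
        neighbor = seq.residues[j]
        site = by_pos.get(j)
        if site is not None and j < pos and int(left_states[site.site_index]) == 1:
            state = DEPROTONATED
        else:
            state = PROTONATED
        dg += db.contribution(center.residue_type, neighbor, j - pos, state)
    # terminus pseudo-neighbors (only present when termini are titrated)
    for s in sites:
        if s.residue_type not in TERMINUS_MARKERS or s.site_index == site_index:
            continue
        d = s.position - pos
        if d == 0 or abs(d) > w:
            continue
        if d < 0 and int(left_states[s.site_index]) == 1:
            state = DEPROTONATED
        else:
            state = PROTONATED
        dg += db.contribution(center.residue_type, s.residue_type, d, state)
    return dg


# ---------------------------------------------------------------------------
# synthesis, rescaling, serialization
# ---------------------------------------------------------------------------

def default_pka_table() -> dict:
    """Model-compound pKa values shipped as package config data."""
    import importlib.resources

    import yaml

    ref = importlib.resources.files("qtitrate").joinpath("data/model_pkas.yaml")
    with ref.open("r") as fh:
        table = yaml.safe_load(fh)
    return {str(k): float(v) for k, v in table.items()}


def synthesize_db(
    window: int = 5,
    coupling_a: float = 1.0,
    decay_p: float = 1.0,
    pka_table: Mapping[str, float] | None = None,
    seed: int = 0,
    temperature: float = 298.0,
    noise_fraction: float = 0.05,
    strict: bool = False,
) -> ContextDB:
    """Generate a physically structured stand-in database (implicit mode).

    Intrinsic terms are RT ln(10) * model pKa. Neighbor terms follow a
    screened-Coulomb form: releasing a proton changes the center's charge by
    exactly -1, so the interaction change with a neighbor of formal charge z
    at distance d is delta_g = -A * z / |d|**p. A protonated lysine neighbor
    (z = +1) therefore *favors* deprotonation of a glutamic acid (its pKa
    drops near an opposite charge) while a deprotonated glutamate neighbor
    (z = -1) disfavors it. Non-ionizable neighbors receive small seeded
    zero-mean perturbations (|dg| <= noise_fraction * A) so that distinct
    contexts remain distinguishable. Deterministic for a given seed.
    """
    if window < 0 or coupling_a < 0:
        raise ValueError("window and coupling strength must be nonnegative")
    pka = dict(pka_table) if pka_table is not None else default_pka_table()
    rt_ln10 = R_KCAL_MOL_K * temperature * LN10
    intrinsic = {t: rt_ln10 * pka[t] for t in sorted(pka)}
    centers = [t for t in sorted(pka) if t in IONIZABLE_TYPES]
    neighbors = sorted(STANDARD_AA) + [t for t in TERMINUS_MARKERS if t in pka]
    rng = np.random.default_rng(seed)
    contribs: list[NeighborContribution] = []
    distances = [d for d in range(-window, window + 1) if d != 0]
    for center in centers:
        for nb in neighbors:
            ionizable = nb in IONIZABLE_TYPES
            for d in distances:
                states = [PROTONATED]
                if ionizable and d < 0:
                    states.append(DEPROTONATED)
                for state in states:
                    z = formal_charge(nb, int(state == DEPROTONATED))
                    dg = -coupling_a * z / abs(d) ** decay_p
                    if not ionizable:
                        dg += rng.uniform(-1.0, 1.0) * noise_fraction * coupling_a
                    contribs.append(NeighborContribution(center, nb, d, state, dg))
    meta = {
        "provenance": "synthetic screened-Coulomb stand-in",
        "version": "1",
        "coupling_a": coupling_a,
        "decay_p": decay_p,
        "seed": int(seed),
        "temperature": float(temperature),
    }
    return ContextDB(
        mode="implicit",
        window=window,
        intrinsic=intrinsic,
        contributions=contribs,
        metadata=meta,
        strict=strict,
    )


def apply_rescaling(db: ContextDB, factors: RescalingFactors) -> ContextDB:
    """Return a new database with per-type recalibration applied.

    Intrinsic terms are shifted by the type's offset; contributions whose
    neighbor is charged in its stated state are multiplied by the type's
    electrostatic scale; uncharged-neighbor contributions are untouched.
    Identity factors reproduce every evaluation bit-for-bit. Only implicit
    databases can be rescaled (an explicit table does not separate the
    electrostatic part).
    """
    if db.mode != "implicit":
        raise ValueError("rescaling is defined for implicit-mode databases only")
    intrinsic = {t: g + factors.offset(t) for t, g in db.intrinsic.items()}
    contribs = []
    for c in db.contributions_list():
        z = formal_charge(c.neighbor, int(c.state == DEPROTONATED))
        dg = c.delta_g * factors.scale(c.center) if z != 0 else c.delta_g
        contribs.append(replace(c, delta_g=dg))
    meta = dict(db.metadata)
    meta["rescaled"] = True
    return ContextDB(
        mode="implicit",
        window=db.window,
        intrinsic=intrinsic,
        contributions=contribs,
        metadata=meta,
        strict=db.strict,
    )


def save_db(db: ContextDB, path) -> None:
    """Serialize to JSON; floats are written as full-precision repr strings."""
    doc = {
        "mode": db.mode,
        "window": db.window,
        "intrinsic": {t: repr(g) for t, g in sorted(db.intrinsic.items())},
        "contributions": [
            {
                "center": c.center,
                "neighbor": c.neighbor,
                "distance": c.distance,
                "state": c.state,
                "dg": repr(c.delta_g),
            }
            for c in db.contributions_list()
        ],
        "metadata": db.metadata,
    }
    if db.mode == "explicit":
        doc["explicit_table"] = [
            {"center": k[0], "left": k[1], "right": k[2], "dg": repr(v)}
            for k, v in sorted(db.explicit_table.items())
        ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_db(path, strict: bool = False) -> ContextDB:
    """Load a JSON database; schema violations raise with record context."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        mode = doc["mode"]
        window = int(doc["window"])
        intrinsic = {t: float(v) for t, v in doc["intrinsic"].items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"database {path}: malformed header: {exc}") from exc
    contribs = []
    for i, rec in enumerate(doc.get("contributions", [])):
        try:
            contribs.append(
                NeighborContribution(
                    rec["center"],
                    rec["neighbor"],
                    int(rec["distance"]),
                    rec["state"],
                    float(rec["dg"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"database {path}: contribution record {i}: {exc}") from exc
    explicit = {}
    for i, rec in enumerate(doc.get("explicit_table", []) or []):
        try:
            key = (rec["center"], rec["left"], rec["right"])
            if key in explicit:
                raise ValueError(f"duplicate explicit context key {key!r}")
            explicit[key] = float(rec["dg"])
        except (KeyError, TypeError) as exc:
            raise ValueError(f"database {path}: explicit record {i}: {exc}") from exc
    try:
        return ContextDB(
            mode=mode,
            window=window,
            intrinsic=intrinsic,
            contributions=contribs,
            explicit_table=explicit,
            metadata=doc.get("metadata", {}),
            strict=strict,
        )
    except ValueError as exc:
        raise ValueError(f"database {path}: {exc}") from exc


def export_tsv(db: ContextDB, path) -> None:
    """Flat one-contribution-per-row TSV for human inspection."""
    with open(path, "w") as fh:
        fh.write(f"# mode={db.mode}\twindow={db.window}\n")
        fh.write("record\tcenter\tneighbor\tdistance\tstate\tdg_kcal_mol\n")
        for t, g in sorted(db.intrinsic.items()):
            fh.write(f"intrinsic\t{t}\t.\t0\t.\t{g:.10g}\n")
        for c in db.contributions_list():
            fh.write(
                f"contribution\t{c.center}\t{c.neighbor}\t{c.distance}\t"
                f"{c.state}\t{c.delta_g:.10g}\n"
            )
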