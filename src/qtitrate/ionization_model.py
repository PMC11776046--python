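"""Sequence parsing, ionizable-site identification and the charge-microstate data model.

A protein with N ionizable residues populates 2**N charge *microstates* (each
site either retains or has released its proton). Microstates sharing the same
number of released protons n form a *mesostate*; there are N + 1 mesostates,
and the net charge q is an exact bijection of n: q = q_max - n, where q_max is
the net charge of the fully protonated chain (one +1 per basic site). Every
deprotonation event — acid or base — lowers the net charge by exactly 1.

All free energies in this package are standard-state values in kcal/mol,
measured relative to the fully protonated microstate (G_ref = 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: the 20 standard one-letter amino-acid codes
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: residue letters that can titrate (arginine is excluded: its guanidinium
#: group does not deprotonate in any biologically relevant pH range)
IONIZABLE_RESIDUES = frozenset("DECYHK")

#: acid class: neutral when protonated, -1 when deprotonated
ACID_TYPES = frozenset({"D", "E", "C", "Y", "CTERM"})
#: base class: +1 when protonated, neutral when deprotonated
BASE_TYPES = frozenset({"H", "K", "NTERM"})
#: every titratable site type, including the chain termini
IONIZABLE_TYPES = ACID_TYPES | BASE_TYPES

#: codes tolerated (position kept, treated as non-titratable) in lenient mode
AMBIGUOUS_AA = frozenset("XBZUJO")

#: gas constant in kcal/(mol K)
R_KCAL_MOL_K = 1.987204259e-3
LN10 = math.log(10.0)


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant, temperature and derived thermal factors.

    ``rt_ln10`` is the free-energy cost of one pH unit; at 298 K it is
    approximately 1.364 kcal/mol.
    """

    T: float = 298.0
    R: float = R_KCAL_MOL_K

    @property
    def rt(self) -> float:
        return self.R * self.T

    @property
    def rt_ln10(self) -> float:
        return self.R * self.T * LN10


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over one-letter codes, indexed from 0.

    ``include_termini`` controls whether the free alpha-amino and
    alpha-carboxyl groups are treated as titratable sites (off by default).
    """

    id: str
    residues: str
    include_termini: bool = False

    def __post_init__(self) -> None:
        bad = [c for c in self.residues if c not in STANDARD_AA | AMBIGUOUS_AA]
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: unexpected residue code(s) {sorted(set(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_string(
        cls,
        seq_id: str,
        residues: str,
        *,
        strict: bool = True,
        include_termini: bool = False,
    ) -> "ProteinSequence":
        """Validate a raw string.

        In strict mode any code outside the 20 standard amino acids is an
        error naming the offending position. In lenient mode ambiguous codes
        (X/B/Z/U/J/O) keep their position but are never titrated and carry no
        database contribution; a warning is logged.
        """
        residues = residues.strip().upper()
        for i, c in enumerate(residues):
            if c in STANDARD_AA:
                continue
            if strict:
                raise ValueError(
                    f"sequence {seq_id!r}: non-standard residue {c!r} at position {i}"
                )
            if c in AMBIGUOUS_AA:
                log.warning(
                    "sequence %r: non-standard residue %r at position %d kept as "
                    "non-titratable placeholder (lenient mode)",
                    seq_id, c, i,
                )
            else:
                raise ValueError(
                    f"sequence {seq_id!r}: unknown residue {c!r} at position {i}"
                )
        return cls(id=seq_id, residues=residues, include_termini=include_termini)


@dataclass(frozen=True)
class IonizableSite:
    """One titratable position.

    ``site_index`` is the 0-based rank of the site among all ionizable sites
    in N-to-C order; the terminal amine (if titrated) is always site 0 and the
    terminal carboxyl the last site. ``charge_class`` is "acid" or "base"; the
    internal protonation bit is always "proton released", and releasing a
    proton changes the net charge by exactly -1 for either class.
    """

    position: int
    residue_type: str
    charge_class: str
    site_index: int

    def __post_init__(self) -> None:
        if self.residue_type not in IONIZABLE_TYPES:
            raise ValueError(f"{self.residue_type!r} is not a titratable type")
        expected = "acid" if self.residue_type in ACID_TYPES else "base"
        if self.charge_class != expected:
            raise ValueError(
                f"{self.residue_type} must have charge_class {expected!r}"
            )


@dataclass(frozen=True)
class Microstate:
    """One assignment of release bits to every ionizable site.

    ``g_standard`` is the standard-state free energy relative to the fully
    protonated reference (the all-zeros pattern has g_standard = 0 exactly).
    """

    pattern: tuple
    n_released: int
    net_charge: int
    g_standard: float


def charge_class_of(residue_type: str) -> str:
    return "acid" if residue_type in ACID_TYPES else "base"


def formal_charge(residue_type: str, released: int) -> int:
    """Formal charge of an ionizable type in a given protonation state.

    ``released`` is the internal bit (1 = proton released). Acids are 0/-1
    (protonated/deprotonated), bases +1/0. Non-ionizable types are always 0.
    """
    if residue_type in ACID_TYPES:
        return -1 if released else 0
    if residue_type in BASE_TYPES:
        return 0 if released else 1
    return 0


def find_ionizable_sites(
    seq: ProteinSequence,
    enabled_types: Iterable[str] | None = None,
) -> list[IonizableSite]:
    """Identify titratable sites in N-to-C order.

    ``enabled_types`` restricts which residue letters titrate (e.g. drop "C"
    for disulfide-bonded cysteines); termini are controlled by the sequence's
    ``include_termini`` flag. Arginine is never a site.
    """
    enabled = set(enabled_types) if enabled_types is not None else set(IONIZABLE_RESIDUES)
    sites: list[IonizableSite] = []
    idx = 0
    if seq.include_termini and len(seq) > 0:
        sites.append(IonizableSite(0, "NTERM", "base", idx))
        idx += 1
    for pos, res in enumerate(seq.residues):
        if res in IONIZABLE_RESIDUES and res in enabled:
            sites.append(IonizableSite(pos, res, charge_class_of(res), idx))
            idx += 1
    if seq.include_termini and len(seq) > 0:
        sites.append(IonizableSite(len(seq) - 1, "CTERM", "acid", idx))
    return sites


def q_max_of(sites: Sequence[IonizableSite]) -> int:
    """Net charge of the fully protonated state: +1 per basic site."""
    return sum(1 for s in sites if s.charge_class == "base")


def net_charge_of(pattern: Sequence[int], sites: Sequence[IonizableSite]) -> int:
    """Net charge of a release pattern: q = q_max - (protons released)."""
    if len(pattern) != len(sites):
        raise ValueError(
            f"pattern length {len(pattern)} != number of sites {len(sites)}"
        )
    return q_max_of(sites) - int(sum(pattern))


# --- display alphabet ------------------------------------------------------
#
# Display follows the charge convention: the ionized (charged) state of a
# titratable residue is written upper-case, the neutral state lower-case.
# For acids, charged means deprotonated (released bit 1 -> upper case); for
# bases, charged means protonated (released bit 0 -> upper case). Termini are
# rendered as a leading and trailing marker character since they share their
# sequence position with a residue: N-terminus "+" (charged) / "n" (neutral),
# C-terminus "-" (charged) / "c" (neutral). The string form is presentation
# only; all arithmetic uses the release-bit vector.

_NTERM_CHAR = {0: "+", 1: "n"}  # released bit -> char
_CTERM_CHAR = {0: "c", 1: "-"}


def _site_char(site: IonizableSite, released: int) -> str:
    if site.residue_type == "NTERM":
        return _NTERM_CHAR[released]
    if site.residue_type == "CTERM":
        return _CTERM_CHAR[released]
    charged = (released == 1) if site.charge_class == "acid" else (released == 0)
    return site.residue_type.upper() if charged else site.residue_type.lower()


def microstate_to_string(
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    pattern: Sequence[int],
) -> str:
    """Render a release pattern as a case-coded sequence string."""
    if len(pattern) != len(sites):
        raise ValueError(
            f"pattern length {len(pattern)} != number of sites {len(sites)}"
        )
    chars = list(seq.residues.upper())
    prefix = suffix = ""
    for site, bit in zip(sites, pattern):
        if site.residue_type == "NTERM":
            prefix = _site_char(site, bit)
        elif site.residue_type == "CTERM":
            suffix = _site_char(site, bit)
        else:
            chars[site.position] = _site_char(site, bit)
    return prefix + "".join(chars) + suffix


def string_to_pattern(
    seq: ProteinSequence,
    sites: Sequence[IonizableSite],
    text: str,
) -> tuple:
    """Invert :func:`microstate_to_string` (exact round trip)."""
    has_n = any(s.residue_type == "NTERM" for s in sites)
    has_c = any(s.residue_type == "CTERM" for s in sites)
    body = text
    nterm_char = cterm_char = None
    if has_n:
        nterm_char, body = body[0], body[1:]
    if has_c:
        body, cterm_char = body[:-1], body[-1]
    if len(body) != len(seq):
        raise ValueError("rendered string length does not match sequence")
    bits = []
    for site in sites:
        if site.residue_type == "NTERM":
            bits.append(0 if nterm_char == "+" else 1)
        elif site.residue_type == "CTERM":
            bits.append(1 if cterm_char == "-" else 0)
        else:
            c = body[site.position]
            charged = c.isupper()
            bits.append(int(charged) if site.charge_class == "acid" else int(not charged))
    return tuple(bits)


def read_fasta(
    path,
    *,
    strict: bool = True,
    include_termini: bool = False,
) -> list[ProteinSequence]:
    """Read a multi-record FASTA file (description line kept as the id)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinSequence.from_string(
                rec.description or rec.id,
                str(rec.seq),
                strict=strict,
                include_termini=include_termini,
            )
        )
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for seq_id, residues in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(residues), 60):
                fh.write(residues[i : i + 60] + "\n")
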