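"""Oligo thermodynamics: duplex melting temperature and mismatch-strength classes.

Melting temperatures are nearest-neighbor estimates of the oligo against its
perfect complement (the convention under which a single Tm per primer is
meaningful, even for ARMS primers that carry deliberate template mismatches).
The default conditions — 0.25 µM oligo, 50 mM Na+, no Mg2+ — are the common
web-calculator defaults for primer QC, with the unified nearest-neighbor
parameter set and the Owczarzy quadratic sodium correction.

Mismatch strength follows the destabilization hierarchy used in ARMS primer
design: strong (G/A, C/T), weak (C/A, G/T), medium (the four identical-base
pairs). Watson-Crick pairs are matches and carry no class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "Oligo",
    "MismatchClass",
    "melting_temperature",
    "classify_mismatch",
    "revcomp",
    "DEFAULT_OLIGO_CONC",
    "DEFAULT_MONOVALENT_SALT",
    "DEFAULT_DIVALENT_SALT",
]

VALID_BASES = frozenset("ACGT")

#: default molar concentrations (config keys tm.oligo_conc, tm.monovalent_salt,
#: tm.divalent_salt)
DEFAULT_OLIGO_CONC = 0.25e-6
DEFAULT_MONOVALENT_SALT = 0.05
DEFAULT_DIVALENT_SALT = 0.0

MIN_LENGTH = 8
MAX_LENGTH = 60

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(sequence: str) -> str:
    """Reverse complement of an unambiguous DNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]


class MismatchClass(str, enum.Enum):
    """Destabilization strength of a primer:template heteroduplex base pair."""

    STRONG = "strong"
    WEAK = "weak"
    MEDIUM = "medium"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# classical ARMS pairing: the deliberate second mismatch must complement the
# 3' allele mismatch in strength
PAIRING_RULE = {
    MismatchClass.STRONG: MismatchClass.WEAK,
    MismatchClass.WEAK: MismatchClass.STRONG,
    MismatchClass.MEDIUM: MismatchClass.MEDIUM,
}


@dataclass(frozen=True)
class Oligo:
    """A single-stranded DNA oligo (5'->3') with its hybridization conditions.

    Parameters
    ----------
    sequence:
        Unambiguous DNA, 8-60 nt.
    name:
        Free-form label (e.g. the primer role).
    concentration:
        Molar single-strand concentration (default 0.25 µM).
    monovalent_salt:
        Molar Na+-equivalent concentration (default 50 mM).
    divalent_salt:
        Molar Mg2+ concentration (default 0).
    """

    sequence: str
    name: str = ""
    concentration: float = DEFAULT_OLIGO_CONC
    monovalent_salt: float = DEFAULT_MONOVALENT_SALT
    divalent_salt: float = DEFAULT_DIVALENT_SALT

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = next((c for c in seq if c not in VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"oligo {self.name or seq!r}: invalid character {bad!r} "
                f"at position {seq.index(bad) + 1}; only A/C/G/T allowed"
            )
        if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
            raise ValueError(
                f"oligo {self.name or seq!r}: length {len(seq)} outside "
                f"[{MIN_LENGTH}, {MAX_LENGTH}]"
            )
        if self.concentration <= 0:
            raise ValueError("oligo concentration must be strictly positive")
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent salt concentration must be strictly positive")
        if self.divalent_salt < 0:
            raise ValueError("divalent salt concentration must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return (self.sequence.count("G") + self.sequence.count("C")) / len(self)


def melting_temperature(oligo: Oligo) -> float:
    """Nearest-neighbor duplex Tm (°C) of ``oligo`` against its perfect complement.

    Unified nearest-neighbor ΔH/ΔS parameters with the Owczarzy (2004)
    quadratic ln[Na+] correction applied in 1/Tm space; excess single strand
    (primer >> template), so the effective strand concentration is the full
    oligo concentration. Deterministic, and monotone non-decreasing in
    monovalent salt over [0.01 M, 1 M].
    """
    return float(
        _mt.Tm_NN(
            oligo.sequence,
            nn_table=_mt.DNA_NN3,
            dnac1=oligo.concentration * 1e9,  # nM
            dnac2=0.0,
            Na=oligo.monovalent_salt * 1e3,  # mM
            Mg=oligo.divalent_salt * 1e3,
            saltcorr=7,
        )
    )


def classify_mismatch(primer_base: str, template_base: str) -> MismatchClass | str:
    """Classify the pair formed by a primer base annealed opposite a template base.

    Returns ``"match"`` for the two Watson-Crick pairs, otherwise the
    :class:`MismatchClass`: {G,A} and {C,T} are strong, {C,A} and {G,T} weak,
    identical-base pairs medium. Symmetric in its arguments.
    """
    a, b = primer_base.upper(), template_base.upper()
    for x in (a, b):
        if x not in VALID_BASES:
            raise ValueError(f"invalid base {x!r}; expected one of A/C/G/T")
    pair = frozenset((a, b))
    if pair in (frozenset("AT"), frozenset("GC")):
        return "match"
    if pair in (frozenset("GA"), frozenset("CT")):
        return MismatchClass.STRONG
    if pair in (frozenset("CA"), frozenset("GT")):
        return MismatchClass.WEAK
    return MismatchClass.MEDIUM  # identical bases
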