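"""Construction and validation of four-primer tetra-ARMS (T-ARMS) assays.

A T-ARMS assay genotypes a biallelic SNP in a single PCR: two outer primers
(OF, OR) amplify a control product spanning the SNP, and two allele-specific
inner primers (IF on the plus strand, IR on the minus strand) whose 3'
termini sit exactly on the SNP produce two allele-specific products of
different sizes. Each inner primer additionally carries one deliberate
mismatch near its 3' end to sharpen allele discrimination.

Two inner-primer strategies are provided:

``ye2001``
    the classical rule set: the deliberate mismatch sits at offset -2 from
    the 3' end, and its strength must complement the strength of the 3'
    allele mismatch (strong<->weak, medium<->medium).

``tm_matched``
    a melting-temperature-matched search over offsets -2..-4 and all three
    substitutions, ranked by closeness to the counter outer primer's Tm.
    This is the strategy under which the classical strength-pairing rule may
    be deliberately broken in exchange for a tight Tm budget (every
    amplicon-forming primer pair within 2 °C by default).

All coordinates are 1-based inclusive plus-strand positions; a primer's
``anchor`` is the plus-strand coordinate of its 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

from .thermo import (
    PAIRING_RULE,
    MismatchClass,
    Oligo,
    VALID_BASES,
    classify_mismatch,
    melting_temperature,
    revcomp,
)

__all__ = [
    "SnpLocus",
    "DeliberateMismatch",
    "ArmsPrimer",
    "OuterPair",
    "TarmsAssay",
    "ConstraintReport",
    "DesignError",
    "NoCandidatesError",
    "RuleInfeasibleError",
    "design_outer_primers",
    "design_inner_primer",
    "assemble_assay",
    "validate_constraints",
    "rank_assays",
    "primer_from_sequence",
    "has_self_complementary_run",
    "DEFAULT_TM_THRESHOLD",
    "DEFAULT_MIN_BAND_SEP",
]

Role = Literal["OF", "OR", "IF", "IR"]
Strand = Literal["plus", "minus"]
Allele = Literal["wild", "mutant", "both"]

DEFAULT_TM_THRESHOLD = 2.0  # °C, compared with <=
DEFAULT_MIN_BAND_SEP = 30  # bp, agarose-resolvable
DEFAULT_OUTER_PRODUCT_RANGE = (300, 500)
DEFAULT_LENGTH_RANGE = (20, 30)
DEFAULT_GC_RANGE = (0.30, 0.70)
SELF_COMP_RUN = 8  # reject primers with a self-reverse-complement run this long

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


class DesignError(ValueError):
    """A primer-design request that cannot be satisfied."""


class NoCandidatesError(DesignError):
    """Candidate enumeration pruned everything; the message names the constraint."""


class RuleInfeasibleError(DesignError):
    """The classical strength-pairing rule admits no substitution."""


@dataclass(frozen=True)
class SnpLocus:
    """A target sequence (plus strand) carrying one biallelic SNP.

    ``sequence[snp_position]`` (1-based) must equal ``wild_allele`` and at
    least 150 nt of context must flank the SNP on both sides so that outer
    primers can be placed.
    """

    sequence: str
    snp_position: int
    wild_allele: str
    mutant_allele: str
    id: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "wild_allele", self.wild_allele.upper())
        object.__setattr__(self, "mutant_allele", self.mutant_allele.upper())
        bad = next((c for c in seq if c not in VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"locus {self.id!r}: invalid character {bad!r} at position "
                f"{seq.index(bad) + 1}"
            )
        for allele in (self.wild_allele, self.mutant_allele):
            if allele not in VALID_BASES:
                raise ValueError(f"allele {allele!r} is not one of A/C/G/T")
        if self.wild_allele == self.mutant_allele:
            raise ValueError("wild and mutant alleles must differ")
        if not 1 <= self.snp_position <= len(seq):
            raise ValueError(f"snp_position {self.snp_position} outside sequence")
        if seq[self.snp_position - 1] != self.wild_allele:
            raise ValueError(
                f"sequence has {seq[self.snp_position - 1]!r} at position "
                f"{self.snp_position}, expected wild allele {self.wild_allele!r}"
            )
        if self.snp_position - 1 < 150 or len(seq) - self.snp_position < 150:
            raise ValueError(
                "need >=150 nt of context on each side of the SNP "
                f"(have {self.snp_position - 1} and {len(seq) - self.snp_position})"
            )

    def base(self, position: int) -> str:
        """Plus-strand base at a 1-based position."""
        return self.sequence[position - 1]

    def allele_sequence(self, allele: Literal["wild", "mutant"]) -> str:
        """Plus-strand sequence of the given allele template."""
        if allele == "wild":
            return self.sequence
        if allele == "mutant":
            i = self.snp_position - 1
            return self.sequence[:i] + self.mutant_allele + self.sequence[i + 1 :]
        raise ValueError(f"allele must be 'wild' or 'mutant', got {allele!r}")

    def allele_base(self, allele: Literal["wild", "mutant"]) -> str:
        return self.wild_allele if allele == "wild" else self.mutant_allele


class DeliberateMismatch(NamedTuple):
    """A deliberately introduced primer:template mismatch near the 3' end.

    ``offset`` counts from the 3' terminus (the terminus itself is -1);
    ``template_base`` is the base of the annealed template strand opposite
    the primer base, so ``classify_mismatch(primer_base, template_base)``
    reproduces ``mismatch_class``.
    """

    offset: int
    primer_base: str
    template_base: str
    mismatch_class: MismatchClass


@dataclass(frozen=True)
class ArmsPrimer:
    """A role-annotated T-ARMS primer placed on a locus.

    ``anchor`` is the 1-based plus-strand coordinate of the 3' end. Outer
    primers (OF/OR) target both alleles and carry no deliberate mismatches;
    inner primers (IF/IR) are anchored on the SNP, their 3' base reads the
    target allele, and they carry exactly one deliberate mismatch at an
    offset in {-2, -3, -4}.
    """

    oligo: Oligo
    role: Role
    strand: Strand
    target_allele: Allele
    anchor: int
    deliberate_mismatches: tuple[DeliberateMismatch, ...] = ()

    def __post_init__(self) -> None:
        expected_strand = "plus" if self.role in ("OF", "IF") else "minus"
        if self.strand != expected_strand:
            raise ValueError(
                f"{self.role} must be on the {expected_strand} strand, "
                f"got {self.strand}"
            )
        if self.role in ("OF", "OR"):
            if self.target_allele != "both":
                raise ValueError(f"outer primer {self.role} must target both alleles")
            if self.deliberate_mismatches:
                raise ValueError(f"outer primer {self.role} cannot carry mismatches")
        else:
            if self.target_allele not in ("wild", "mutant"):
                raise ValueError(
                    f"inner primer {self.role} must target wild or mutant"
                )
        for mm in self.deliberate_mismatches:
            if mm.offset not in (-2, -3, -4):
                raise ValueError(
                    f"deliberate mismatch offset {mm.offset} outside {{-2,-3,-4}}"
                )

    @property
    def sequence(self) -> str:
        return self.oligo.sequence

    def __len__(self) -> int:
        return len(self.oligo.sequence)

    @property
    def five_prime(self) -> int:
        """1-based plus-strand coordinate of the 5' end."""
        if self.strand == "plus":
            return self.anchor - len(self) + 1
        return self.anchor + len(self) - 1

    @property
    def footprint(self) -> tuple[int, int]:
        """Inclusive plus-strand interval covered by the primer."""
        return (min(self.anchor, self.five_prime), max(self.anchor, self.five_prime))


class OuterPair(NamedTuple):
    of: ArmsPrimer
    or_: ArmsPrimer
    product_size: int
    tm_diff: float


@dataclass(frozen=True)
class ConstraintReport:
    """Pure report of an assay's constraint status (never mutates the assay)."""

    pairwise_tm_diffs: dict[str, float]
    max_tm_diff: float
    tm_criterion_met: bool
    tm_threshold: float
    band_separation: int
    mismatch_rule_report: dict[str, dict]
    violations: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "pairwise_tm_diffs": dict(self.pairwise_tm_diffs),
            "max_tm_diff": self.max_tm_diff,
            "tm_criterion_met": self.tm_criterion_met,
            "tm_threshold": self.tm_threshold,
            "band_separation": self.band_separation,
            "mismatch_rule_report": self.mismatch_rule_report,
            "violations": list(self.violations),
        }


@dataclass(frozen=True)
class TarmsAssay:
    """A complete four-primer assay with expected products and constraint report."""

    locus: SnpLocus
    of: ArmsPrimer
    or_: ArmsPrimer
    if_: ArmsPrimer
    ir: ArmsPrimer
    expected_products: dict[str, list[tuple[str, int]]]
    tm_table: dict[str, float]
    constraint_report: ConstraintReport
    protocol_metadata: dict[str, str] = field(default_factory=dict)

    @property
    def primers(self) -> tuple[ArmsPrimer, ArmsPrimer, ArmsPrimer, ArmsPrimer]:
        return (self.of, self.or_, self.if_, self.ir)

    @property
    def control_size(self) -> int:
        return dict(self.expected_products["wild"])["OF/OR"]

    def inner_size(self, allele: Literal["wild", "mutant"]) -> int:
        pairs = dict(self.expected_products[allele])
        (size,) = [v for k, v in pairs.items() if k != "OF/OR"]
        return size

    @property
    def product_sizes(self) -> dict[str, int]:
        """All three product sizes keyed by primer pair."""
        out: dict[str, int] = {}
        for products in self.expected_products.values():
            out.update(dict(products))
        return out


def has_self_complementary_run(sequence: str, run: int = SELF_COMP_RUN) -> bool:
    """True if the sequence contains a perfect self-reverse-complement run.

    A simple deterministic dimer/hairpin screen: any substring of length
    ``run`` whose reverse complement also occurs in the sequence.
    """
    rc = revcomp(sequence)
    return any(sequence[i : i + run] in rc for i in range(len(sequence) - run + 1))


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def design_outer_primers(
    locus: SnpLocus,
    outer_product_range: tuple[int, int] = DEFAULT_OUTER_PRODUCT_RANGE,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    gc_range: tuple[float, float] = DEFAULT_GC_RANGE,
    max_candidates: int | None = None,
) -> list[OuterPair]:
    """Enumerate outer primer pairs flanking the SNP.

    Every pair satisfies: OF is an exact plus-strand substring entirely 5' of
    the SNP, OR an exact minus-strand substring entirely 3' of it, GC content
    within ``gc_range``, no long self-complementary run, and a product size
    (OF 5' to OR 5', inclusive) within ``outer_product_range``. Pairs are
    sorted by |Tm(OF) - Tm(OR)| ascending, ties broken by (OF 5' position,
    OR 5' position).
    """
    lo_p, hi_p = outer_product_range
    lo_l, hi_l = length_range
    if lo_p > hi_p or lo_l > hi_l:
        raise ValueError("empty product or length range")
    if hi_p > len(locus.sequence):
        hi_p = len(locus.sequence)
    if lo_p > len(locus.sequence):
        raise NoCandidatesError(
            f"no candidates: minimum product size {lo_p} exceeds locus length "
            f"{len(locus.sequence)}"
        )

    seq = locus.sequence
    snp = locus.snp_position

    def enumerate_side(side: str) -> list[ArmsPrimer]:
        out = []
        n_geom = n_gc = n_selfcomp = 0
        for length in range(lo_l, hi_l + 1):
            if side == "forward":
                # footprint must end before the SNP
                starts = range(1, snp - length + 1)  # 1-based 5' start
            else:
                starts = range(snp + 1, len(seq) - length + 2)  # 1-based left end
            for start in starts:
                sub = seq[start - 1 : start - 1 + length]
                n_geom += 1
                if not gc_range[0] <= _gc(sub) <= gc_range[1]:
                    n_gc += 1
                    continue
                primer_seq = sub if side == "forward" else revcomp(sub)
                if has_self_complementary_run(primer_seq):
                    n_selfcomp += 1
                    continue
                if side == "forward":
                    primer = ArmsPrimer(
                        Oligo(primer_seq, name="OF"), "OF", "plus", "both",
                        anchor=start + length - 1,
                    )
                else:
                    primer = ArmsPrimer(
                        Oligo(primer_seq, name="OR"), "OR", "minus", "both",
                        anchor=start,
                    )
                out.append(primer)
        if not out:
            reasons = []
            if n_geom == 0:
                reasons.append("no positions flank the SNP at the requested lengths")
            if n_gc:
                reasons.append(f"GC range {gc_range} rejected {n_gc}")
            if n_selfcomp:
                reasons.append(f"self-complementarity screen rejected {n_selfcomp}")
            raise NoCandidatesError(
                f"no {side} outer primer candidates: " + "; ".join(reasons)
            )
        return out

    forwards = enumerate_side("forward")
    reverses = enumerate_side("reverse")

    tm_cache: dict[str, float] = {}

    def tm(p: ArmsPrimer) -> float:
        s = p.sequence
        if s not in tm_cache:
            tm_cache[s] = melting_temperature(p.oligo)
        return tm_cache[s]

    pairs: list[OuterPair] = []
    for of in forwards:
        for orp in reverses:
            size = orp.five_prime - of.five_prime + 1
            if lo_p <= size <= hi_p:
                pairs.append(OuterPair(of, orp, size, abs(tm(of) - tm(orp))))
    if not pairs:
        raise NoCandidatesError(
            f"no candidates: product range {outer_product_range} admits no "
            f"OF/OR pair around the SNP"
        )
    pairs.sort(key=lambda p: (p.tm_diff, p.of.five_prime, p.or_.five_prime))
    return pairs[:max_candidates] if max_candidates else pairs


def _allele_mismatch_class(
    locus: SnpLocus, target: Literal["wild", "mutant"], strand: Strand
) -> MismatchClass:
    """Strength of the inner primer's 3' mismatch against the NON-target allele.

    Classification is done on the annealed strand: a plus-strand primer's 3'
    base pairs against the minus strand of the non-target template, a
    minus-strand primer's against the plus strand. (The class is invariant to
    which strand is chosen, since complementing both members of a pair maps
    strong<->strong, weak<->weak, medium<->medium.)
    """
    other = "mutant" if target == "wild" else "wild"
    target_base = locus.allele_base(target)
    other_base = locus.allele_base(other)
    if strand == "plus":
        cls = classify_mismatch(target_base, _COMP[other_base])
    else:
        cls = classify_mismatch(_COMP[target_base], other_base)
    assert cls != "match"
    return cls


def design_inner_primer(
    locus: SnpLocus,
    allele: Literal["wild", "mutant"],
    strand: Strand,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    strategy: Literal["ye2001", "tm_matched"] = "tm_matched",
    tm_target: float | None = None,
    tm_tolerance: float = DEFAULT_TM_THRESHOLD,
) -> list[ArmsPrimer]:
    """Enumerate allele-specific inner primers anchored on the SNP.

    Every candidate's 3' terminus sits on the SNP and reads the target
    allele; exactly one deliberate mismatch is introduced. Under ``ye2001``
    the mismatch is at offset -2 and obeys the classical strength pairing
    against the 3' allele mismatch; under ``tm_matched`` offsets -2..-4 and
    all three substitutions are searched and candidates are ranked by
    |Tm - tm_target| (the counter outer primer's Tm), keeping those within
    ``tm_tolerance`` whenever any qualify.
    """
    if strand not in ("plus", "minus"):
        raise ValueError(f"strand must be plus or minus, got {strand!r}")
    if strategy == "tm_matched" and tm_target is None:
        raise ValueError("tm_matched strategy requires tm_target")
    lo_l, hi_l = length_range
    role: Role = "IF" if strand == "plus" else "IR"
    snp = locus.snp_position
    allele_cls = _allele_mismatch_class(locus, allele, strand)
    offsets = (-2,) if strategy == "ye2001" else (-2, -3, -4)
    required = PAIRING_RULE[allele_cls] if strategy == "ye2001" else None

    candidates: list[tuple[tuple, ArmsPrimer]] = []
    for length in range(lo_l, hi_l + 1):
        if strand == "plus":
            if snp - length < 0:
                continue
            base_seq = list(locus.sequence[snp - length : snp])
            base_seq[-1] = locus.allele_base(allele)
        else:
            if snp + length - 1 > len(locus.sequence):
                continue
            base_seq = list(revcomp(locus.sequence[snp - 1 : snp + length - 1]))
            base_seq[-1] = _COMP[locus.allele_base(allele)]
        for offset in offsets:
            idx = length + offset  # 0-based index of the mismatch position
            if strand == "plus":
                plus_coord = snp + offset + 1
                template_sense = locus.base(plus_coord)  # primer copies plus strand
                annealed = _COMP[template_sense]
            else:
                plus_coord = snp - offset - 1
                annealed = locus.base(plus_coord)
                template_sense = _COMP[annealed]
            for sub in sorted(VALID_BASES - {template_sense}):
                cls = classify_mismatch(sub, annealed)
                assert isinstance(cls, MismatchClass)
                if required is not None and cls != required:
                    continue
                primer_seq = base_seq.copy()
                primer_seq[idx] = sub
                seq = "".join(primer_seq)
                if has_self_complementary_run(seq):
                    continue
                primer = ArmsPrimer(
                    Oligo(seq, name=role),
                    role,
                    strand,
                    allele,
                    anchor=snp,
                    deliberate_mismatches=(
                        DeliberateMismatch(offset, sub, annealed, cls),
                    ),
                )
                tm = melting_temperature(primer.oligo)
                score = abs(tm - tm_target) if tm_target is not None else 0.0
                candidates.append(((score, length, -offset, sub), primer))

    if not candidates:
        if strategy == "ye2001":
            raise RuleInfeasibleError(
                f"classical strength pairing ({allele_cls} 3' mismatch requires a "
                f"{required} second mismatch at -2) admits no candidate on this "
                "locus; consider strategy='tm_matched'"
            )
        raise NoCandidatesError("no inner primer candidates at the requested lengths")

    candidates.sort(key=lambda c: c[0])
    if strategy == "tm_matched":
        within = [c for c in candidates if c[0][0] <= tm_tolerance]
        if within:
            candidates = within
    return [p for _, p in candidates]


def primer_from_sequence(
    locus: SnpLocus,
    sequence: str,
    role: Role,
    target_allele: Allele | None = None,
) -> ArmsPrimer:
    """Place a known primer sequence (5'->3') on the locus and annotate it.

    Outer primers must match their template strand exactly on the proper side
    of the SNP. Inner primers are anchored with their 3' terminus on the SNP;
    the target allele is read off the 3' base (unless given) and every other
    primer:template difference is recorded as a deliberate mismatch, which
    must lie at offsets -2..-4.
    """
    seq = sequence.upper()
    snp = locus.snp_position
    strand: Strand = "plus" if role in ("OF", "IF") else "minus"
    if role in ("OF", "OR"):
        template = locus.sequence if strand == "plus" else revcomp(locus.sequence)
        hits = []
        start = template.find(seq)
        while start != -1:
            hits.append(start)
            start = template.find(seq, start + 1)
        if strand == "minus":  # convert to plus-strand 5' left-end coordinates
            hits = [len(locus.sequence) - (h + len(seq)) for h in hits]
        if role == "OF":
            hits = [h for h in hits if h + len(seq) < snp]  # fully 5' of SNP
        else:
            hits = [h for h in hits if h + 1 > snp]  # fully 3' of SNP
        if not hits:
            raise DesignError(
                f"{role} sequence does not match the template on the "
                f"{'5-prime' if role == 'OF' else '3-prime'} side of the SNP"
            )
        if len(hits) > 1:
            raise DesignError(f"{role} sequence matches the template at {len(hits)} sites")
        h = hits[0]
        anchor = h + len(seq) if role == "OF" else h + 1
        return ArmsPrimer(Oligo(seq, name=role), role, strand, "both", anchor=anchor)

    # inner primer: 3' on the SNP
    three_prime_base = seq[-1] if strand == "plus" else _COMP[seq[-1]]
    if target_allele is None:
        if three_prime_base == locus.wild_allele:
            target_allele = "wild"
        elif three_prime_base == locus.mutant_allele:
            target_allele = "mutant"
        else:
            raise DesignError(
                f"{role} 3' base {seq[-1]!r} reads neither allele at the SNP"
            )
    mismatches = []
    for offset in range(-len(seq), -1):  # exclude the allele-reading terminus
        idx = len(seq) + offset
        if strand == "plus":
            plus_coord = snp + offset + 1
            template_sense = locus.base(plus_coord)
            annealed = _COMP[template_sense]
        else:
            plus_coord = snp - offset - 1
            annealed = locus.base(plus_coord)
            template_sense = _COMP[annealed]
        if plus_coord < 1 or plus_coord > len(locus.sequence):
            raise DesignError(f"{role} extends beyond the locus")
        if seq[idx] != template_sense:
            cls = classify_mismatch(seq[idx], annealed)
            if offset not in (-2, -3, -4):
                raise DesignError(
                    f"{role} mismatches the template at offset {offset} "
                    "(only deliberate mismatches at -2..-4 are allowed); "
                    "is the primer anchored on the SNP?"
                )
            mismatches.append(DeliberateMismatch(offset, seq[idx], annealed, cls))
    return ArmsPrimer(
        Oligo(seq, name=role), role, strand, target_allele,
        anchor=snp, deliberate_mismatches=tuple(mismatches),
    )


AMPLICON_PAIRS = ("OF/OR", "IF/OR", "OF/IR")


def validate_constraints(
    assay: "TarmsAssay",
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
    min_band_sep: int = DEFAULT_MIN_BAND_SEP,
    tm_table: dict[str, float] | None = None,
) -> ConstraintReport:
    """Build the constraint report for an assembled assay (pure; no mutation).

    The Tm criterion compares exactly the three amplicon-forming pairs
    (OF/OR, IF/OR, OF/IR): the assay passes iff the largest pairwise
    difference is <= ``tm_threshold``. ``tm_table`` defaults to the assay's
    own table, so printed Tm values can be swapped in for an audit.
    """
    tms = tm_table if tm_table is not None else assay.tm_table
    diffs = {
        "OF/OR": abs(tms["OF"] - tms["OR"]),
        "IF/OR": abs(tms["IF"] - tms["OR"]),
        "OF/IR": abs(tms["OF"] - tms["IR"]),
    }
    max_diff = max(diffs.values())
    sizes = assay.product_sizes
    size_values = [sizes[p] for p in AMPLICON_PAIRS]
    seps = [
        abs(a - b)
        for i, a in enumerate(size_values)
        for b in size_values[i + 1 :]
    ]
    band_sep = min(seps)

    rule_report: dict[str, dict] = {}
    for primer in (assay.if_, assay.ir):
        allele_cls = _allele_mismatch_class(
            assay.locus, primer.target_allele, primer.strand
        )
        mm = primer.deliberate_mismatches[0] if primer.deliberate_mismatches else None
        rule_report[primer.role] = {
            "target_allele": primer.target_allele,
            "allele_mismatch_class": str(allele_cls),
            "deliberate_mismatch_offset": mm.offset if mm else None,
            "deliberate_mismatch_class": str(mm.mismatch_class) if mm else None,
            "classical_rule_holds": bool(
                mm
                and mm.offset == -2
                and mm.mismatch_class == PAIRING_RULE[allele_cls]
            ),
        }

    violations: list[str] = []
    if max_diff > tm_threshold:
        violations.append(
            f"tm_criterion: max pairwise ΔTm {max_diff:.1f} °C > {tm_threshold:.1f} °C"
        )
    if band_sep < min_band_sep:
        violations.append(
            f"band_separation: minimum size difference {band_sep} bp < {min_band_sep} bp"
        )
    control = sizes["OF/OR"]
    for pair in ("IF/OR", "OF/IR"):
        if sizes[pair] >= control:
            violations.append(f"product_geometry: {pair} not smaller than control")
    for primer in assay.primers:
        if has_self_complementary_run(primer.sequence):
            violations.append(f"self_complementarity: {primer.role}")

    return ConstraintReport(
        pairwise_tm_diffs=diffs,
        max_tm_diff=max_diff,
        tm_criterion_met=max_diff <= tm_threshold,
        tm_threshold=tm_threshold,
        band_separation=band_sep,
        mismatch_rule_report=rule_report,
        violations=tuple(violations),
    )


def assemble_assay(
    locus: SnpLocus,
    of: ArmsPrimer,
    or_: ArmsPrimer,
    if_: ArmsPrimer,
    ir: ArmsPrimer,
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
    min_band_sep: int = DEFAULT_MIN_BAND_SEP,
    tm_table: dict[str, float] | None = None,
    protocol_metadata: dict[str, str] | None = None,
) -> TarmsAssay:
    """Assemble four primers into a T-ARMS assay with expected products.

    Sizes follow plus-strand 1-based inclusive coordinate arithmetic:
    size(OF/OR) = OR5' - OF5' + 1, size(OF/IR) = IR5' - OF5' + 1,
    size(IF/OR) = OR5' - IF5' + 1, which satisfy
    size(OF/IR) + size(IF/OR) = size(OF/OR) + (IR5' - IF5' + 1).
    """
    for primer, role in ((of, "OF"), (or_, "OR"), (if_, "IF"), (ir, "IR")):
        if primer.role != role:
            raise DesignError(f"expected role {role}, got {primer.role}")
    for inner in (if_, ir):
        if inner.anchor != locus.snp_position:
            raise DesignError(
                f"{inner.role} 3' end anchored at {inner.anchor}, "
                f"not on the SNP at {locus.snp_position}"
            )
    if {if_.target_allele, ir.target_allele} != {"wild", "mutant"}:
        raise DesignError("inner primers must target the two different alleles")

    control = or_.five_prime - of.five_prime + 1
    of_ir = ir.five_prime - of.five_prime + 1
    if_or = or_.five_prime - if_.five_prime + 1
    pair_for = {if_.target_allele: ("IF/OR", if_or), ir.target_allele: ("OF/IR", of_ir)}
    expected_products = {
        "wild": [("OF/OR", control), pair_for["wild"]],
        "mutant": [("OF/OR", control), pair_for["mutant"]],
    }
    if of_ir == if_or:
        raise DesignError("allele-specific products have equal size; not resolvable")

    if tm_table is None:
        tm_table = {
            p.role: round(melting_temperature(p.oligo), 1) for p in (of, or_, if_, ir)
        }

    # temporary assay for the pure validator
    assay = TarmsAssay(
        locus=locus,
        of=of, or_=or_, if_=if_, ir=ir,
        expected_products=expected_products,
        tm_table=tm_table,
        constraint_report=ConstraintReport({}, 0.0, True, tm_threshold, 0, {}, ()),
        protocol_metadata=dict(protocol_metadata or {}),
    )
    report = validate_constraints(assay, tm_threshold, min_band_sep)
    return TarmsAssay(
        locus=locus,
        of=of, or_=or_, if_=if_, ir=ir,
        expected_products=expected_products,
        tm_table=tm_table,
        constraint_report=report,
        protocol_metadata=dict(protocol_metadata or {}),
    )


def rank_assays(candidates: Sequence[TarmsAssay]) -> list[TarmsAssay]:
    """Order assays best-first: fewest violations, tightest Tm budget, widest
    band separation, then leftmost OF 5' position. Stable and deterministic."""
    loci = {id(c.locus) for c in candidates} and {
        (c.locus.sequence, c.locus.snp_position) for c in candidates
    }
    if len(loci) > 1:
        raise ValueError("all candidate assays must target the same locus")
    return sorted(
        candidates,
        key=lambda a: (
            len(a.constraint_report.violations),
            a.constraint_report.max_tm_diff,
            -a.constraint_report.band_separation,
            a.of.five_prime,
        ),
    )
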