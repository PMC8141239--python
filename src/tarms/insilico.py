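"""In-silico PCR and restriction digestion.

Binding-site search models the ARMS premise as an all-or-none idealization:
a primer is extensible only if its 3'-terminal window (one base by default)
matches the template exactly, while a limited number of internal mismatches
(deliberate ARMS mismatches plus a margin) are tolerated. Amplification then
pairs every convergent forward/reverse extensible site; heterozygotes are
simulated as the union of products over the two allele templates, with no
allele-competition modeling.

Restriction digestion is linear-molecule only: recognition sites are located
on both strands (one scan suffices for palindromes), overlapping sites are
taken left-to-right greedily per strand, and fragment sizes always sum to the
input length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

from .design import ArmsPrimer, SnpLocus, TarmsAssay
from .thermo import Oligo, VALID_BASES, revcomp

__all__ = [
    "Template",
    "BindingSite",
    "Amplicon",
    "BandPattern",
    "find_binding_sites",
    "simulate_pcr",
    "predict_band_pattern",
    "digest",
    "allele_templates",
]

PrimerLike = Union[ArmsPrimer, Oligo, str]


@dataclass(frozen=True)
class Template:
    """A plus-strand DNA template for amplification."""

    id: str
    sequence: str
    allele_note: Literal["wild", "mutant", "unknown"] = "unknown"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"template {self.id!r}: empty sequence")
        bad = next((c for c in seq if c not in VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"template {self.id!r}: ambiguity code {bad!r} at position "
                f"{seq.index(bad) + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """An extensible, ungapped primer placement on a template.

    ``three_prime_pos`` is the 1-based template coordinate of the primer's 3'
    end; ``terminal_match`` is true for every reported site (non-extensible
    placements are never reported).
    """

    primer_sequence: str
    strand: Literal["plus", "minus"]
    three_prime_pos: int
    internal_mismatches: int
    terminal_match: bool = True

    @property
    def five_prime_pos(self) -> int:
        n = len(self.primer_sequence)
        if self.strand == "plus":
            return self.three_prime_pos - n + 1
        return self.three_prime_pos + n - 1


@dataclass(frozen=True)
class Amplicon:
    forward_site: BindingSite
    reverse_site: BindingSite
    size: int
    sequence: str

    def __post_init__(self) -> None:
        assert self.size == len(self.sequence)


@dataclass(frozen=True)
class BandPattern:
    """The set of product sizes expected in one gel lane."""

    sizes: frozenset[int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("band sizes must be positive")

    def __or__(self, other: "BandPattern") -> "BandPattern":
        return BandPattern(self.sizes | other.sizes)

    def __contains__(self, size: int) -> bool:
        return size in self.sizes


def _primer_sequence(primer: PrimerLike) -> str:
    if isinstance(primer, ArmsPrimer):
        return primer.sequence
    if isinstance(primer, Oligo):
        return primer.sequence
    return str(primer).upper()


def find_binding_sites(
    primer: PrimerLike,
    template: Template,
    max_internal_mismatches: int = 3,
    terminal_exact_len: int = 1,
) -> list[BindingSite]:
    """Locate extensible primer placements on both strands of a template.

    A placement is reported iff the primer aligns ungapped with at most
    ``max_internal_mismatches`` mismatches outside the 3'-terminal window and
    matches exactly over the last ``terminal_exact_len`` bases. A primer
    longer than the template has no placements (empty list, not an error).
    """
    seq = _primer_sequence(primer)
    bad = next((c for c in seq if c not in VALID_BASES), None)
    if bad is not None:
        raise ValueError(f"primer contains invalid character {bad!r}")
    if terminal_exact_len < 1 or terminal_exact_len > len(seq):
        raise ValueError("terminal_exact_len must be in [1, primer length]")
    t = template.sequence
    n = len(seq)
    if n > len(t):
        return []

    sites: list[BindingSite] = []
    rc = revcomp(seq)  # the minus-strand primer as it reads on the plus strand
    for start in range(len(t) - n + 1):
        window = t[start : start + n]
        # plus-strand placement: primer copies the plus strand, 3' at the right
        mism = [i for i in range(n) if seq[i] != window[i]]
        if all(i < n - terminal_exact_len for i in mism):
            internal = len(mism)
            if internal <= max_internal_mismatches:
                sites.append(
                    BindingSite(seq, "plus", start + n, internal, True)
                )
        # minus-strand placement: primer anneals to the plus strand, 3' at the left
        mism = [i for i in range(n) if rc[i] != window[i]]
        if all(i >= terminal_exact_len for i in mism):
            internal = len(mism)
            if internal <= max_internal_mismatches:
                sites.append(
                    BindingSite(seq, "minus", start + 1, internal, True)
                )
    return sites


def simulate_pcr(
    primers: Sequence[PrimerLike],
    template: Template,
    max_product: int = 2000,
    max_internal_mismatches: int = 3,
    terminal_exact_len: int = 1,
) -> list[Amplicon]:
    """Predict all products of a multi-primer PCR on one template.

    Every convergent pair of a plus-strand and a minus-strand extensible site
    whose product size (forward 5' to reverse 5', inclusive) is at most
    ``max_product`` yields one amplicon. The amplicon sequence carries the
    primer sequences at its ends (primers, not template, define the ends).
    """
    fwd: list[BindingSite] = []
    rev: list[BindingSite] = []
    for primer in primers:
        for site in find_binding_sites(
            primer, template, max_internal_mismatches, terminal_exact_len
        ):
            (fwd if site.strand == "plus" else rev).append(site)

    out: list[Amplicon] = []
    for f in fwd:
        for r in rev:
            if r.three_prime_pos < f.three_prime_pos:
                continue  # divergent or nested 3' ends cannot converge
            size = r.five_prime_pos - f.five_prime_pos + 1
            if size > max_product:
                continue
            # primers, not template, define the product ends: substitute their
            # sequences at their footprints (reverse wins a rare 3' overlap)
            left = f.five_prime_pos
            product = list(template.sequence[left - 1 : r.five_prime_pos])
            product[: len(f.primer_sequence)] = f.primer_sequence
            product[r.three_prime_pos - left :] = revcomp(r.primer_sequence)
            out.append(Amplicon(f, r, size, "".join(product)))
    out.sort(key=lambda a: (a.forward_site.five_prime_pos, a.size))
    return out


def allele_templates(locus: SnpLocus) -> dict[str, Template]:
    """Wild and mutant plus-strand templates implied by a SNP locus."""
    return {
        allele: Template(
            f"{locus.id or 'locus'}:{allele}", locus.allele_sequence(allele), allele
        )
        for allele in ("wild", "mutant")
    }


def predict_band_pattern(
    assay: TarmsAssay,
    genotype: Literal["wild", "carrier", "mutant"],
    max_product: int = 2000,
) -> BandPattern:
    """Predict the gel band pattern of a genotype by running the full
    four-primer reaction on the allele template(s) the genotype implies.

    A heterozygote (carrier) is the union of products over the two allele
    templates. Computed by simulation, never by table lookup.
    """
    templates = allele_templates(assay.locus)
    if genotype == "wild":
        chosen = [templates["wild"]]
    elif genotype == "mutant":
        chosen = [templates["mutant"]]
    elif genotype == "carrier":
        chosen = [templates["wild"], templates["mutant"]]
    else:
        raise ValueError(f"genotype must be wild/carrier/mutant, got {genotype!r}")
    sizes: set[int] = set()
    for template in chosen:
        for amp in simulate_pcr(assay.primers, template, max_product=max_product):
            sizes.add(amp.size)
    return BandPattern(frozenset(sizes))


def digest(
    sequence: str,
    recognition_site: str,
    cut_offset: int,
) -> list[int]:
    """Digest a linear molecule; returns fragment sizes, left to right.

    The top-strand cut of a site starting at 0-based position ``s`` falls
    after ``s + cut_offset`` bases. Both strands are scanned (bottom-strand
    cut positions are mapped to top-strand coordinates as
    ``s + len(site) - cut_offset``); palindromic sites therefore need only
    the one scan they naturally produce. Overlapping occurrences on a strand
    are consumed left-to-right greedily. Fragment sizes always sum to the
    input length; zero-length fragments are never emitted.
    """
    seq = sequence.upper()
    site = recognition_site.upper()
    if not 4 <= len(site) <= 8:
        raise ValueError("recognition site must be 4-8 nt")
    for s in (seq, site):
        bad = next((c for c in s if c not in VALID_BASES), None)
        if bad is not None:
            raise ValueError(f"ambiguous character {bad!r} not supported")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must be within the recognition site")

    def greedy_starts(pattern: str) -> list[int]:
        starts, i = [], seq.find(pattern)
        while i != -1:
            starts.append(i)
            i = seq.find(pattern, i + len(pattern))
        return starts

    cuts: set[int] = set()
    for s in greedy_starts(site):
        cuts.add(s + cut_offset)
    rc = revcomp(site)
    if rc != site:
        for s in greedy_starts(rc):
            cuts.add(s + len(site) - cut_offset)

    bounds = [0] + sorted(c for c in cuts if 0 < c < len(seq)) + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
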