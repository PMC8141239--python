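"""Canonical CVM (rs438228855) assay data and a synthetic test locus.

Complex vertebral malformation (CVM) is a recessive lethal defect of
Holstein-derived cattle caused by a G>T missense SNP (V180F) in SLC35A3.
This module carries the published T-ARMS primer sets for that SNP — the
software-designed set following the classical inner-primer rules, and the
manually Tm-matched set — together with their published melting temperatures
and a SYNTHETIC reconstruction of the target region for offline work.

The synthetic locus is NOT the deposited genomic sequence: every base
covered by a primer footprint is fixed by the published primer sequences
(each deliberate-mismatch position is recovered from the design in which
that position is an exact template match), the SNP alleles are placed at
their mapped position, and all remaining bases are seeded random filler.
All primer-binding geometry, product sizes and ARMS behaviour on this locus
therefore reproduce the real assay exactly; the filler does not.

Coordinate map (plus strand, OF 5' end at amplicon position 1):
SNP at 176, OR 5' end at 389 -> control product 389 bp, wild-specific OF/IR
product 199 bp, mutant-specific IF/OR product 241 bp (software set, 28-nt
IF) or 240 bp (Tm-matched set, 27-nt IF; gels cannot distinguish the two and
the published figure rounds both to 241).
"""

from __future__ import annotations

import numpy as np

from .design import ArmsPrimer, SnpLocus, TarmsAssay, assemble_assay, primer_from_sequence

__all__ = [
    "SNP_ID",
    "OF_SEQ",
    "OR_SEQ",
    "IF_SOFTWARE_SEQ",
    "IR_SOFTWARE_SEQ",
    "IF_MODIFIED_SEQ",
    "IR_MODIFIED_SEQ",
    "PUBLISHED_TM",
    "DEFAULT_SEED",
    "cvm_locus",
    "cvm_assay",
]

SNP_ID = "rs438228855"
WILD_ALLELE = "G"
MUTANT_ALLELE = "T"

# outer primers, shared by both designs
OF_SEQ = "TGGAAATGGTTGCATTTTTACCTTAAG"
OR_SEQ = "TTGCAACAACAAGCAGTTTTTATAAGG"
# classical (software-designed) inner primers
IF_SOFTWARE_SEQ = "GGCTCACAATTTGTAGGTCTCATGGTAT"
IR_SOFTWARE_SEQ = "ACTGGAAAAACATGCTGTGAGGAC"
# manually Tm-matched inner primers
IF_MODIFIED_SEQ = "GCTCACAATTTGTAGGTCTCATGTCAT"
IR_MODIFIED_SEQ = "ACTGGAAAAACATGCTGTGACAAC"

#: published melting temperatures (°C) per primer
PUBLISHED_TM = {
    "software": {"OF": 54.7, "OR": 55.2, "IF": 58.5, "IR": 57.7},
    "modified": {"OF": 54.7, "OR": 55.2, "IF": 57.2, "IR": 56.4},
}

#: one documented seed used across the test suite (the assay's publication date)
DEFAULT_SEED = 20210522

# amplicon-relative coordinates (1-based): OF 5' at 1
_SNP_POS = 176
_AMPLICON_LEN = 389
_FLANK = 150


def _amplicon_wild() -> str:
    """Wild-allele plus strand of the 389 bp amplicon, synthetic filler at 'N'."""
    seq = ["N"] * _AMPLICON_LEN

    def place_plus(primer: str, five_prime: int, skip: set[int] = set()) -> None:
        for i, b in enumerate(primer):
            if i not in skip:
                seq[five_prime - 1 + i] = b

    # exact-match outer primers
    place_plus(OF_SEQ, 1)
    comp = str.maketrans("ACGT", "TGCA")
    or_plus = OR_SEQ.translate(comp)[::-1]
    place_plus(or_plus, _AMPLICON_LEN - len(OR_SEQ) + 1)

    # inner-forward footprint [149, 176]: the software 28-mer matches the
    # template except at offset -3 (its deliberate mismatch) and the SNP;
    # the Tm-matched 27-mer recovers offset -3 (it matches there) while the
    # software set recovers offset -4.
    if_five = _SNP_POS - len(IF_SOFTWARE_SEQ) + 1  # 149
    place_plus(IF_SOFTWARE_SEQ, if_five, skip={len(IF_SOFTWARE_SEQ) - 3, len(IF_SOFTWARE_SEQ) - 1})
    seq[_SNP_POS - 1 - 2] = IF_MODIFIED_SEQ[-3]  # offset -3 from the 27-mer
    seq[_SNP_POS - 1] = WILD_ALLELE

    # inner-reverse footprint [176, 199]: minus-strand primers; plus-strand
    # bases are complements, again cross-recovering each design's mismatch
    # position from the other design.
    ir_plus_sw = IR_SOFTWARE_SEQ.translate(comp)[::-1]  # plus-strand reading
    place_plus(ir_plus_sw, _SNP_POS, skip={0, 2})  # skip SNP and its offset -3
    ir_plus_mod = IR_MODIFIED_SEQ.translate(comp)[::-1]
    seq[_SNP_POS - 1 + 2] = ir_plus_mod[2]  # offset -3 of the modified 24-mer

    assert seq[_SNP_POS - 1] == WILD_ALLELE
    return "".join(seq)


def cvm_locus(seed: int = DEFAULT_SEED, flank: int = _FLANK) -> SnpLocus:
    """Synthetic reconstruction of the CVM target region (see module docs).

    Seeded random filler replaces every base not pinned by a primer
    footprint, plus ``flank`` nt on each side so outer-primer design has
    room. Deterministic for a given (seed, flank).
    """
    rng = np.random.default_rng(seed)
    core = _amplicon_wild()
    bases = "ACGT"

    def filler(n: int) -> str:
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    body = "".join(b if b != "N" else filler(1) for b in core)
    sequence = filler(flank) + body + filler(flank)
    return SnpLocus(
        sequence=sequence,
        snp_position=flank + _SNP_POS,
        wild_allele=WILD_ALLELE,
        mutant_allele=MUTANT_ALLELE,
        id=SNP_ID,
    )


def cvm_assay(
    design: str = "modified",
    locus: SnpLocus | None = None,
    use_published_tm: bool = False,
    tm_threshold: float = 2.0,
) -> TarmsAssay:
    """Assemble the published CVM assay on the (synthetic) locus.

    ``design`` selects the primer set: ``"modified"`` (the Tm-matched assay)
    or ``"software"`` (the classical design). With ``use_published_tm`` the
    constraint report is computed from the published Tm values instead of
    the package's own estimates.
    """
    if design not in ("modified", "software"):
        raise ValueError("design must be 'modified' or 'software'")
    locus = locus or cvm_locus()
    if_seq = IF_MODIFIED_SEQ if design == "modified" else IF_SOFTWARE_SEQ
    ir_seq = IR_MODIFIED_SEQ if design == "modified" else IR_SOFTWARE_SEQ
    of = primer_from_sequence(locus, OF_SEQ, "OF")
    or_ = primer_from_sequence(locus, OR_SEQ, "OR")
    if_ = primer_from_sequence(locus, if_seq, "IF")
    ir = primer_from_sequence(locus, ir_seq, "IR")
    tm_table = dict(PUBLISHED_TM[design]) if use_published_tm else None
    return assemble_assay(
        locus, of, or_, if_, ir,
        tm_threshold=tm_threshold,
        tm_table=tm_table,
        protocol_metadata={
            "annealing_temperature_C": "62",
            "outer_primer_pmol": "5",
            "inner_primer_pmol": "10",
            "MgCl2_mM": "2",
        },
    )
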