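"""Assay construction, constraint validation and candidate ranking."""

import numpy as np
import pytest

from tarms import cvm
from tarms.design import (
    ArmsPrimer,
    DesignError,
    NoCandidatesError,
    SnpLocus,
    assemble_assay,
    design_inner_primer,
    design_outer_primers,
    has_self_complementary_run,
    primer_from_sequence,
    rank_assays,
    validate_constraints,
)
from tarms.thermo import (
    PAIRING_RULE,
    Oligo,
    classify_mismatch,
    melting_temperature,
    revcomp,
)


# ---------------------------------------------------------------------------
# outer primers
# ---------------------------------------------------------------------------

def test_published_outer_pair_product_is_389(cvm_locus):
    of = primer_from_sequence(cvm_locus, cvm.OF_SEQ, "OF")
    or_ = primer_from_sequence(cvm_locus, cvm.OR_SEQ, "OR")
    assert or_.five_prime - of.five_prime + 1 == 389


def test_outer_design_infeasible_geometry():
    locus = SnpLocus("A" * 150 + "G" + "C" * 150, 151, "G", "T")
    with pytest.raises(NoCandidatesError, match="no candidates"):
        design_outer_primers(locus, outer_product_range=(5000, 6000))


def test_outer_design_matches_bruteforce_enumeration(small_locus):
    """Candidate pairs equal an exhaustive double-loop oracle over start positions."""
    locus, _, _ = small_locus
    length_range, product_range, gc_range = (25, 28), (350, 450), (0.2, 0.8)
    got = design_outer_primers(locus, product_range, length_range, gc_range)

    def gc(s):
        return (s.count("G") + s.count("C")) / len(s)

    seq, snp = locus.sequence, locus.snp_position
    fwd, rev = [], []
    for L in range(length_range[0], length_range[1] + 1):
        for start in range(1, len(seq) - L + 2):
            sub = seq[start - 1 : start - 1 + L]
            if start + L - 1 < snp and gc_range[0] <= gc(sub) <= gc_range[1] \
                    and not has_self_complementary_run(sub):
                fwd.append((start, sub))
            rc = revcomp(sub)
            if start > snp and gc_range[0] <= gc(rc) <= gc_range[1] \
                    and not has_self_complementary_run(rc):
                rev.append((start, rc))
    expected = []
    for fs, fseq in fwd:
        for rs, rseq in rev:
            size = (rs + len(rseq) - 1) - fs + 1
            if product_range[0] <= size <= product_range[1]:
                d = abs(
                    melting_temperature(Oligo(fseq)) - melting_temperature(Oligo(rseq))
                )
                expected.append((d, fs, rs + len(rseq) - 1, size))
    expected.sort()

    assert len(got) == len(expected)
    for pair, (d, fs, r5, size) in zip(got, expected):
        assert (pair.of.five_prime, pair.or_.five_prime, pair.product_size) == (
            fs, r5, size,
        )
        assert pair.tm_diff == pytest.approx(d)


# ---------------------------------------------------------------------------
# inner primers
# ---------------------------------------------------------------------------

def test_inner_mutant_candidate_has_strong_allele_mismatch(cvm_locus):
    """Mutant-specific plus-strand candidates end in T; the 3' mismatch against
    the wild template's annealed strand ({T,C}) is strong."""
    cands = design_inner_primer(
        cvm_locus, "mutant", "plus", strategy="tm_matched", tm_target=55.2
    )
    assert cands, "expected at least one candidate"
    for p in cands:
        assert p.sequence[-1] == "T"
        assert p.anchor == cvm_locus.snp_position
        assert classify_mismatch("T", "C") == "strong"
        assert len(p.deliberate_mismatches) == 1


def test_inner_ye2001_satisfies_strength_pairing(small_locus):
    """Classical-rule candidates re-classify to the required pairing at -2."""
    locus, _, _ = small_locus
    for allele in ("wild", "mutant"):
        for strand in ("plus", "minus"):
            for p in design_inner_primer(locus, allele, strand, strategy="ye2001"):
                (mm,) = p.deliberate_mismatches
                assert mm.offset == -2
                # independent re-classification of both mismatches
                allele_base = p.sequence[-1]
                other = locus.mutant_allele if allele == "wild" else locus.wild_allele
                annealed_at_snp = (
                    revcomp(other) if strand == "plus" else other
                )
                allele_cls = classify_mismatch(allele_base, annealed_at_snp)
                assert classify_mismatch(mm.primer_base, mm.template_base) == (
                    PAIRING_RULE[allele_cls]
                )


def test_inner_candidates_mismatch_is_real(small_locus):
    """Each candidate genuinely differs from its target-allele template at the
    deliberate-mismatch position (the destabilizing substitution exists)."""
    locus, _, _ = small_locus
    for p in design_inner_primer(locus, "wild", "minus", strategy="tm_matched",
                                 tm_target=60.0):
        (mm,) = p.deliberate_mismatches
        template = locus.allele_sequence(p.target_allele)
        plus_coord = locus.snp_position - mm.offset - 1  # minus strand
        template_sense = revcomp(template[plus_coord - 1])
        assert mm.primer_base != template_sense
        assert classify_mismatch(mm.primer_base, mm.template_base) == mm.mismatch_class


def test_inner_tm_matched_equals_exhaustive_oracle(small_locus):
    """The ranked-first candidate matches an exhaustive search over
    (length x offset x substitution) scored by |Tm - target|."""
    locus, _, _ = small_locus
    target = 58.0
    length_range = (20, 24)
    got = design_inner_primer(
        locus, "mutant", "plus", length_range, "tm_matched", tm_target=target
    )

    best_score, best_seq = None, None
    snp = locus.snp_position
    for L in range(length_range[0], length_range[1] + 1):
        base = list(locus.sequence[snp - L : snp])
        base[-1] = locus.mutant_allele
        for offset in (-2, -3, -4):
            tmpl = locus.sequence[snp + offset]  # 0-based snp+offset+1-1
            for sub in "ACGT":
                if sub == tmpl:
                    continue
                cand = base.copy()
                cand[L + offset] = sub
                seq = "".join(cand)
                if has_self_complementary_run(seq):
                    continue
                score = abs(melting_temperature(Oligo(seq)) - target)
                if best_score is None or score < best_score:
                    best_score, best_seq = score, seq
    assert got[0].sequence == best_seq


def test_inner_requires_tm_target_for_tm_matched(small_locus):
    locus, _, _ = small_locus
    with pytest.raises(ValueError, match="tm_target"):
        design_inner_primer(locus, "wild", "minus", strategy="tm_matched")


# ---------------------------------------------------------------------------
# assembly and constraints
# ---------------------------------------------------------------------------

def test_assemble_published_modified_set_sizes(modified_assay):
    """The Tm-matched CVM set assembles to 389/199/240 (the published figure
    rounds the 240 bp mutant product up to 241)."""
    assert modified_assay.product_sizes == {"OF/OR": 389, "OF/IR": 199, "IF/OR": 240}


def test_assemble_software_set_sizes(software_assay):
    assert software_assay.product_sizes == {"OF/OR": 389, "OF/IR": 199, "IF/OR": 241}


def test_assemble_size_identity(modified_assay, software_assay):
    """size(OF/IR) + size(IF/OR) = size(OF/OR) + (IR5' - IF5' + 1)."""
    for assay in (modified_assay, software_assay):
        overlap = assay.ir.five_prime - assay.if_.five_prime + 1
        sizes = assay.product_sizes
        assert sizes["OF/IR"] + sizes["IF/OR"] == sizes["OF/OR"] + overlap


def test_assemble_rejects_swapped_roles(cvm_locus, modified_assay):
    with pytest.raises(DesignError, match="role"):
        assemble_assay(
            cvm_locus,
            modified_assay.or_, modified_assay.of,
            modified_assay.if_, modified_assay.ir,
        )


def test_assemble_rejects_unanchored_inner(cvm_locus, modified_assay):
    off_snp = ArmsPrimer(
        modified_assay.if_.oligo, "IF", "plus", "mutant",
        anchor=cvm_locus.snp_position - 10,
    )
    with pytest.raises(DesignError, match=str(cvm_locus.snp_position - 10)):
        assemble_assay(
            cvm_locus, modified_assay.of, modified_assay.or_, off_snp,
            modified_assay.ir,
        )


def test_assemble_synthetic_coordinates_oracle(small_locus):
    """Product sizes equal direct coordinate arithmetic on a designed assay."""
    locus, _, _ = small_locus
    outer = design_outer_primers(locus, (350, 450), (25, 28), (0.2, 0.8))[0]
    if_ = design_inner_primer(locus, "mutant", "plus", strategy="tm_matched",
                              tm_target=melting_temperature(outer.or_.oligo))[0]
    ir = design_inner_primer(locus, "wild", "minus", strategy="tm_matched",
                             tm_target=melting_temperature(outer.of.oligo))[0]
    assay = assemble_assay(locus, outer.of, outer.or_, if_, ir)
    snp = locus.snp_position
    assert assay.product_sizes["OF/OR"] == outer.or_.five_prime - outer.of.five_prime + 1
    assert assay.product_sizes["IF/OR"] == outer.or_.five_prime - (snp - len(if_) + 1) + 1
    assert assay.product_sizes["OF/IR"] == (snp + len(ir) - 1) - outer.of.five_prime + 1
    # both inner products span the SNP; control spans both inner primer sites
    assert outer.of.five_prime <= snp <= snp + len(ir) - 1
    assert snp - len(if_) + 1 <= snp <= outer.or_.five_prime


@pytest.mark.parametrize(
    "tms, expected_max, met",
    [
        ({"OF": 54.7, "OR": 55.2, "IF": 57.2, "IR": 56.4}, 2.0, True),
        ({"OF": 54.7, "OR": 55.2, "IF": 58.5, "IR": 57.7}, 3.3, False),
        ({"OF": 60.0, "OR": 60.0, "IF": 60.0, "IR": 60.0}, 0.0, True),
    ],
)
def test_validate_constraints_published_tm_table(modified_assay, tms, expected_max, met):
    """The published ΔTm column is reproduced from the printed Tm values:
    OF/OR 0.5 everywhere; modified IF/OR 2.0 and OF/IR 1.7 pass the <=2 °C
    criterion; the software set's 3.3/3.0 fail it."""
    report = validate_constraints(modified_assay, tm_table=tms)
    assert report.max_tm_diff == pytest.approx(expected_max)
    assert report.tm_criterion_met is met
    assert set(report.pairwise_tm_diffs) == {"OF/OR", "IF/OR", "OF/IR"}


def test_validate_constraints_is_pure(modified_assay):
    before = modified_assay.constraint_report
    validate_constraints(modified_assay, tm_table={"OF": 1, "OR": 9, "IF": 1, "IR": 1})
    assert modified_assay.constraint_report is before


def test_band_separation_of_published_assay(modified_assay):
    assert modified_assay.constraint_report.band_separation == 41


def test_published_tm_table_validates_clean(cvm_locus):
    """Audited with its published Tm values, the Tm-matched set is violation-free."""
    assay = cvm.cvm_assay("modified", locus=cvm_locus, use_published_tm=True)
    assert assay.constraint_report.violations == ()


def test_mismatch_rule_report_flags_flexed_rules(modified_assay, software_assay):
    """The software set obeys the classical pairing (at -3 it is reported as
    non-classical since the rule fixes -2); the Tm-matched set breaks it."""
    for assay in (modified_assay, software_assay):
        rep = assay.constraint_report.mismatch_rule_report
        assert set(rep) == {"IF", "IR"}
        for role in ("IF", "IR"):
            assert rep[role]["allele_mismatch_class"] == "strong"
            assert not rep[role]["classical_rule_holds"]
    mod = modified_assay.constraint_report.mismatch_rule_report
    assert mod["IF"]["deliberate_mismatch_offset"] == -4
    assert mod["IR"]["deliberate_mismatch_offset"] == -4
    assert mod["IF"]["deliberate_mismatch_class"] == "strong"
    assert mod["IR"]["deliberate_mismatch_class"] == "medium"


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_rank_prefers_tighter_tm(cvm_locus):
    good = cvm.cvm_assay("modified", locus=cvm_locus, use_published_tm=True)
    bad = cvm.cvm_assay("software", locus=cvm_locus, use_published_tm=True)
    ranked = rank_assays([bad, good])
    assert ranked[0] is good
    assert ranked[0].constraint_report.violations == ()


def test_rank_is_stable_for_identical_assays(modified_assay):
    a, b = modified_assay, cvm.cvm_assay("modified")
    assert rank_assays([a, b]) == [a, b]
    assert rank_assays([b, a]) == [b, a]


def test_rank_matches_independent_sort_oracle(small_locus):
    """Ranking equals an oracle sort by (violations, maxΔTm, -sep, OF 5')."""
    locus, _, _ = small_locus
    rng = np.random.default_rng(7)
    outer = design_outer_primers(locus, (350, 450), (25, 28), (0.2, 0.8))
    if_cands = design_inner_primer(locus, "mutant", "plus", (20, 26),
                                   "tm_matched", tm_target=58.0)
    ir_cands = design_inner_primer(locus, "wild", "minus", (20, 26),
                                   "tm_matched", tm_target=58.0)
    assays = []
    for _ in range(10):
        pair = outer[rng.integers(len(outer))]
        try:
            assays.append(
                assemble_assay(
                    locus, pair.of, pair.or_,
                    if_cands[rng.integers(len(if_cands))],
                    ir_cands[rng.integers(len(ir_cands))],
                )
            )
        except DesignError:
            continue
    assert len(assays) >= 5
    ranked = rank_assays(assays)
    oracle = sorted(
        assays,
        key=lambda a: (
            len(a.constraint_report.violations),
            a.constraint_report.max_tm_diff,
            -a.constraint_report.band_separation,
            a.of.five_prime,
        ),
    )
    assert ranked == oracle


# ---------------------------------------------------------------------------
# locus and primer placement validation
# ---------------------------------------------------------------------------

def test_locus_invariants():
    with pytest.raises(ValueError, match="wild allele"):
        SnpLocus("A" * 400, 200, "G", "T")
    with pytest.raises(ValueError, match="150"):
        SnpLocus("A" * 99 + "G" + "A" * 300, 100, "G", "T")
    with pytest.raises(ValueError, match="differ"):
        SnpLocus("A" * 200 + "G" + "A" * 200, 201, "G", "G")


def test_primer_from_sequence_detects_modified_mismatches(cvm_locus):
    ir = primer_from_sequence(cvm_locus, cvm.IR_MODIFIED_SEQ, "IR")
    assert ir.target_allele == "wild"
    (mm,) = ir.deliberate_mismatches
    assert (mm.offset, mm.primer_base) == (-4, "C")


def test_primer_from_sequence_rejects_nonmatching_outer(cvm_locus):
    with pytest.raises(DesignError, match="does not match"):
        primer_from_sequence(cvm_locus, "ACGTACGTACGTACGTACGT", "OF")
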