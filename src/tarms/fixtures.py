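"""Deterministic synthetic-data generators.

Every generator is a pure function of its parameters and seed, so the whole
toolkit is testable offline: synthetic SNP loci with their allele templates,
genotyped cohorts with noisy gel observations (emulating agarose readouts of
a two-hundred-head screening cohort), and two-test diagnostic datasets for
the latent class model.

Gel size noise is Gaussian truncated at +-3 SD — a simplicity choice, not
gel physics. Heterozygous lanes show the union of both alleles' bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cvm import DEFAULT_SEED
from .design import SnpLocus, TarmsAssay
from .diagnostics import CrossTab
from .genotyping import GelObservation
from .insilico import Template, predict_band_pattern

__all__ = [
    "SyntheticCohort",
    "synth_locus",
    "synth_gel_cohort",
    "synth_two_test_data",
    "DEFAULT_SEED",
]

GENOTYPES = ("wild", "carrier", "mutant")


@dataclass(frozen=True)
class SyntheticCohort:
    """A simulated genotyped cohort with its gel observations and parameters."""

    genotypes: dict[str, str]
    observations: list[GelObservation]
    carrier_freq: float
    mutant_freq: float
    size_noise_sd: float
    dropout_p: float
    extra_band_p: float
    seed: int


def synth_locus(
    length: int = 600,
    snp_offset: int = 300,
    wild: str = "G",
    mutant: str = "T",
    gc_content: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> tuple[SnpLocus, Template, Template]:
    """Random SNP locus at the requested GC, plus its two allele templates.

    ``snp_offset`` is the 1-based SNP position and must leave >=150 nt on
    each side. The two returned templates differ at exactly that position.
    """
    if snp_offset - 1 < 150 or length - snp_offset < 150:
        raise ValueError(
            f"snp_offset {snp_offset} leaves <150 nt of flank in length {length}"
        )
    rng = np.random.default_rng(seed)
    p_gc = gc_content / 2.0
    p = [(1 - gc_content) / 2, p_gc, p_gc, (1 - gc_content) / 2]
    seq = "".join(rng.choice(list("AGCT"), size=length, p=[p[0], p[1], p[2], p[3]]))
    i = snp_offset - 1
    seq = seq[:i] + wild.upper() + seq[i + 1 :]
    locus = SnpLocus(seq, snp_offset, wild, mutant, id=f"synth-{seed}")
    return (
        locus,
        Template(f"{locus.id}:wild", locus.allele_sequence("wild"), "wild"),
        Template(f"{locus.id}:mutant", locus.allele_sequence("mutant"), "mutant"),
    )


def _truncated_normal(rng: np.random.Generator, sd: float) -> float:
    """N(0, sd) truncated at +-3 SD (resampling)."""
    if sd == 0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= 3 * sd:
            return x


def synth_gel_cohort(
    assay: TarmsAssay,
    n: int = 200,
    carrier_freq: float = 0.01,
    mutant_freq: float = 0.0,
    size_noise_sd: float = 0.0,
    dropout_p: float = 0.0,
    extra_band_p: float = 0.0,
    seed: int = DEFAULT_SEED,
    genotypes: Mapping[str, str] | None = None,
) -> SyntheticCohort:
    """Simulate gel observations for a genotyped cohort.

    Genotypes are drawn i.i.d. with the given carrier/mutant frequencies
    (or fixed via ``genotypes``); each genotype's expected bands come from
    :func:`predict_band_pattern` (simulation, not lookup), are perturbed by
    truncated Gaussian size noise, independently dropped with ``dropout_p``,
    and spurious bands are added with ``extra_band_p`` at uniform sizes
    between 50 bp and 1.5x the control product.
    """
    if carrier_freq + mutant_freq > 1.0:
        raise ValueError("carrier_freq + mutant_freq must be <= 1")
    rng = np.random.default_rng(seed)
    expected = {g: sorted(predict_band_pattern(assay, g).sizes) for g in GENOTYPES}

    if genotypes is None:
        draws = rng.choice(
            GENOTYPES,
            size=n,
            p=[1.0 - carrier_freq - mutant_freq, carrier_freq, mutant_freq],
        )
        genotype_map = {f"S{i + 1:04d}": str(g) for i, g in enumerate(draws)}
    else:
        genotype_map = {k: str(v) for k, v in genotypes.items()}

    observations = []
    hi = 1.5 * assay.control_size
    for sample_id, genotype in genotype_map.items():
        bands = []
        for size in expected[genotype]:
            if rng.random() < dropout_p:
                continue
            bands.append(size + _truncated_normal(rng, size_noise_sd))
        if rng.random() < extra_band_p:
            bands.append(float(rng.uniform(50.0, hi)))
        observations.append(GelObservation(sample_id, tuple(bands)))
    return SyntheticCohort(
        genotypes=genotype_map,
        observations=observations,
        carrier_freq=carrier_freq,
        mutant_freq=mutant_freq,
        size_noise_sd=size_noise_sd,
        dropout_p=dropout_p,
        extra_band_p=extra_band_p,
        seed=seed,
    )


def synth_two_test_data(
    n: int,
    prevalence: float,
    se1: float,
    sp1: float,
    se2: float,
    sp2: float,
    seed: int = DEFAULT_SEED,
) -> CrossTab:
    """Simulate a 2x2 cross-tabulation of two conditionally independent tests.

    Latent statuses are Bernoulli(prevalence); given status, each test fires
    independently with its Se (positives) or 1-Sp (negatives).
    """
    for name, v in (
        ("prevalence", prevalence), ("se1", se1), ("sp1", sp1),
        ("se2", se2), ("sp2", sp2),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    status = rng.random(n) < prevalence
    t1 = np.where(status, rng.random(n) < se1, rng.random(n) >= sp1)
    t2 = np.where(status, rng.random(n) < se2, rng.random(n) >= sp2)
    return CrossTab(
        n11=int(np.sum(t1 & t2)),
        n10=int(np.sum(t1 & ~t2)),
        n01=int(np.sum(~t1 & t2)),
        n00=int(np.sum(~t1 & ~t2)),
    )
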