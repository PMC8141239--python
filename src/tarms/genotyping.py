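"""Genotype calling from observed gel band sizes.

Agarose sizing against a 100 bp ladder is coarse, so each expected band is
matched to the nearest observed band within a tolerance of
``max(10 bp, 5% of the expected size)`` by default. Presence/absence of the
control and the two allele-specific bands then determines the call:

==========  =======  ==========  ============
control     wild     mutant      call
==========  =======  ==========  ============
absent      any      any         no_call (control failure)
present     no       no          no_call (allele dropout)
present     yes      no          wild
present     no       yes         mutant
present     yes      yes         carrier
==========  =======  ==========  ============

Unmatched extra bands are reported but do not veto a call unless strict mode
is on (nonspecific amplification happens on real gels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .design import TarmsAssay

__all__ = [
    "GelObservation",
    "GenotypeCall",
    "CohortSummary",
    "call_genotype",
    "cohort_summary",
    "default_tolerance",
]

Call = Literal["wild", "carrier", "mutant", "no_call"]


@dataclass(frozen=True)
class GelObservation:
    """Observed band sizes (bp estimates) for one gel lane."""

    sample_id: str
    observed_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed_sizes", tuple(self.observed_sizes))
        if any(s <= 0 for s in self.observed_sizes):
            raise ValueError(f"sample {self.sample_id!r}: band sizes must be positive")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: Call
    matched_bands: dict[int, float | None]
    unmatched_observed: tuple[float, ...] = ()
    reason: str = ""


def default_tolerance(expected: float) -> float:
    """Sizing tolerance for one expected band: max(10 bp, 5%)."""
    return max(10.0, 0.05 * expected)


def _match_bands(
    expected: Sequence[int],
    observed: Sequence[float],
    tolerance: float | None,
) -> tuple[dict[int, float | None], list[float]]:
    """Greedy nearest-first matching; each observed band consumed at most once."""
    pairs = []
    for e in expected:
        tol = tolerance if tolerance is not None else default_tolerance(e)
        for j, o in enumerate(observed):
            d = abs(o - e)
            if d <= tol:
                pairs.append((d, e, j))
    pairs.sort()
    matched: dict[int, float | None] = {e: None for e in expected}
    used: set[int] = set()
    for d, e, j in pairs:
        if matched[e] is None and j not in used:
            matched[e] = observed[j]
            used.add(j)
    leftover = [o for j, o in enumerate(observed) if j not in used]
    return matched, leftover


def call_genotype(
    obs: GelObservation,
    assay: TarmsAssay,
    tolerance: float | None = None,
    strict: bool = False,
) -> GenotypeCall:
    """Call one sample's genotype against an assay's expected band pattern.

    ``tolerance`` overrides the per-band default of max(10 bp, 5%). In strict
    mode any unmatched observed band forces no_call.
    """
    control = assay.control_size
    wild_size = assay.inner_size("wild")
    mutant_size = assay.inner_size("mutant")

    if not obs.observed_sizes:
        return GenotypeCall(
            obs.sample_id, "no_call",
            {control: None, wild_size: None, mutant_size: None},
            (), "empty lane",
        )

    matched, leftover = _match_bands(
        [control, wild_size, mutant_size], obs.observed_sizes, tolerance
    )
    extras = tuple(sorted(set(leftover)))

    if matched[control] is None:
        return GenotypeCall(
            obs.sample_id, "no_call", matched, extras, "control failure"
        )
    has_wild = matched[wild_size] is not None
    has_mut = matched[mutant_size] is not None
    if not has_wild and not has_mut:
        return GenotypeCall(
            obs.sample_id, "no_call", matched, extras, "allele dropout"
        )
    if strict and extras:
        return GenotypeCall(
            obs.sample_id, "no_call", matched, extras,
            f"unexpected bands in strict mode: {list(extras)}",
        )
    call: Call = "carrier" if (has_wild and has_mut) else ("wild" if has_wild else "mutant")
    return GenotypeCall(obs.sample_id, call, matched, extras)


@dataclass(frozen=True)
class CohortSummary:
    counts: dict[str, int]
    carriers: int
    called: int
    carrier_prevalence_pct: float | None

    def __str__(self) -> str:
        prev = (
            "undefined (no called samples)"
            if self.carrier_prevalence_pct is None
            else f"{self.carrier_prevalence_pct:.1f}% ({self.carriers}/{self.called})"
        )
        lines = [f"{k}: {v}" for k, v in sorted(self.counts.items())]
        return "\n".join(lines + [f"carrier prevalence: {prev}"])


def cohort_summary(calls: Sequence[GenotypeCall]) -> CohortSummary:
    """Counts per call class plus carrier prevalence.

    Prevalence = 100 x (carrier + mutant calls) / called samples, reported
    with its numerator and denominator; undefined when nothing was called.
    """
    counts = {"wild": 0, "carrier": 0, "mutant": 0, "no_call": 0}
    for c in calls:
        counts[c.call] += 1
    called = counts["wild"] + counts["carrier"] + counts["mutant"]
    carriers = counts["carrier"] + counts["mutant"]
    prevalence = None if called == 0 else 100.0 * carriers / called
    return CohortSummary(counts, carriers, called, prevalence)
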