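"""File formats: FASTA templates, primer/call TSV tables, cross-tab CSV,
assay JSON bundles. All writers emit stable column orders and ``\\n`` line
endings so outputs are diffable across runs."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .design import ArmsPrimer, TarmsAssay
from .diagnostics import CrossTab, HuiWalterResults, MetricEstimate
from .genotyping import GelObservation, GenotypeCall
from .insilico import Template
from .thermo import VALID_BASES

logger = logging.getLogger("tarms")

__all__ = [
    "read_fasta",
    "read_crosstab_csv",
    "write_crosstab_csv",
    "read_bands_tsv",
    "write_calls_tsv",
    "assay_to_json",
    "write_assay_json",
    "write_primer_tsv",
    "write_posterior_tsv",
]


def read_fasta(path: str | Path) -> list[Template]:
    """Read templates from FASTA: uppercased, U->T normalized with a warning,
    header order kept. Empty files, duplicate ids and non-ACGT characters are
    errors naming the record and offending position."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    templates = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            logger.warning("%s: record %s contains U; normalizing U->T", path, rec.id)
            seq = seq.replace("U", "T")
        bad = next((c for c in seq if c not in VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"{path}: record {rec.id!r} has unsupported character {bad!r} "
                f"at position {seq.index(bad) + 1}"
            )
        templates.append(Template(rec.id, seq))
    return templates


def read_crosstab_csv(path: str | Path) -> CrossTab:
    """Read a 2x2 cross-tabulation from CSV with header n11,n10,n01,n00."""
    df = pd.read_csv(path)
    missing = [c for c in ("n11", "n10", "n01", "n00") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    row = df.iloc[0]
    return CrossTab(int(row.n11), int(row.n10), int(row.n01), int(row.n00))


def write_crosstab_csv(ct: CrossTab, path: str | Path) -> None:
    Path(path).write_text(f"n11,n10,n01,n00\n{ct.n11},{ct.n10},{ct.n01},{ct.n00}\n")


def read_bands_tsv(path: str | Path) -> list[GelObservation]:
    """Read gel observations: sample_id <tab> comma-separated sizes (bp).

    An empty size field is an empty lane.
    """
    out = []
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if i == 1 and line.lower().startswith("sample_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
        sizes_field = parts[1].strip()
        sizes = (
            tuple(float(x) for x in sizes_field.split(",")) if sizes_field else ()
        )
        out.append(GelObservation(parts[0].strip(), sizes))
    return out


def write_calls_tsv(calls: Sequence[GenotypeCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        matched = ";".join(
            f"{e}->{'-' if o is None else f'{o:g}'}" for e, o in sorted(c.matched_bands.items())
        )
        rows.append(
            {
                "sample_id": c.sample_id,
                "call": c.call,
                "matched_bands": matched,
                "extra_bands": ",".join(f"{b:g}" for b in c.unmatched_observed),
                "reason": c.reason,
            }
        )
    pd.DataFrame(
        rows, columns=["sample_id", "call", "matched_bands", "extra_bands", "reason"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _primer_row(p: ArmsPrimer, tm: float | None) -> dict:
    return {
        "role": p.role,
        "sequence": p.sequence,
        "length": len(p),
        "tm": tm,
        "strand": p.strand,
        "target_allele": p.target_allele,
        "anchor": p.anchor,
        "deliberate_mismatches": ";".join(
            f"{m.offset}:{m.primer_base}/{m.template_base}:{m.mismatch_class}"
            for m in p.deliberate_mismatches
        ),
    }


def write_primer_tsv(assay: TarmsAssay, path: str | Path) -> None:
    """One row per primer: role, sequence 5'->3', length, Tm, anchor, mismatches."""
    rows = [_primer_row(p, assay.tm_table.get(p.role)) for p in assay.primers]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def assay_to_json(assay: TarmsAssay) -> dict:
    """Machine-readable assay bundle (field names match the type definitions)."""
    return {
        "locus": {
            "id": assay.locus.id,
            "snp_position": assay.locus.snp_position,
            "wild_allele": assay.locus.wild_allele,
            "mutant_allele": assay.locus.mutant_allele,
            "sequence": assay.locus.sequence,
        },
        "primers": [_primer_row(p, assay.tm_table.get(p.role)) for p in assay.primers],
        "expected_products": {
            allele: [[pair, size] for pair, size in products]
            for allele, products in assay.expected_products.items()
        },
        "tm_table": assay.tm_table,
        "constraint_report": assay.constraint_report.to_dict(),
        "protocol_metadata": assay.protocol_metadata,
    }


def write_assay_json(assay: TarmsAssay, path: str | Path) -> None:
    Path(path).write_text(json.dumps(assay_to_json(assay), indent=2) + "\n")


def read_assay_json(path: str | Path) -> TarmsAssay:
    """Rebuild an assay from its JSON bundle (re-deriving primers on the locus)."""
    from .design import SnpLocus, assemble_assay, primer_from_sequence

    data = json.loads(Path(path).read_text())
    loc = data["locus"]
    locus = SnpLocus(
        loc["sequence"], loc["snp_position"], loc["wild_allele"],
        loc["mutant_allele"], loc.get("id", ""),
    )
    by_role = {p["role"]: p for p in data["primers"]}
    primers = {
        role: primer_from_sequence(locus, by_role[role]["sequence"], role)
        for role in ("OF", "OR", "IF", "IR")
    }
    return assemble_assay(
        locus, primers["OF"], primers["OR"], primers["IF"], primers["IR"],
        tm_threshold=data["constraint_report"]["tm_threshold"],
        tm_table={k: float(v) for k, v in data["tm_table"].items()},
        protocol_metadata=data.get("protocol_metadata", {}),
    )


def metrics_frame(metrics: dict[str, MetricEstimate]) -> pd.DataFrame:
    rows = []
    for name, m in metrics.items():
        rows.append(
            {
                "metric": name,
                "numerator": m.numerator,
                "denominator": m.denominator,
                "estimate_pct": None if m.pct is None else round(m.pct, 1),
                "ci95_low_pct": None if m.ci_low is None else round(100 * m.ci_low, 1),
                "ci95_high_pct": None if m.ci_high is None else round(100 * m.ci_high, 1),
                "defined": m.defined,
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def write_posterior_tsv(results: HuiWalterResults, path: str | Path) -> None:
    df = results.summary().reset_index()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")
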