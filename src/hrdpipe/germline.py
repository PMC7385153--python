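"""Germline truncating-variant filter cascade over a DDR gene panel.

Candidate germline variants (upstream: a paired tumor/normal caller run in
germline mode plus a functional annotator; expected provenance VarScan2
``somatic --min-coverage 30 --min-var-freq 0.08`` with ANNOVAR annotation)
are pushed through a conjunctive rule cascade:

1. quality       — depth >= 10, supporting reads >= 5, VAF >= 0.08, and
                   not labelled somatic by the caller;
2. context       — not adjacent to a homopolymer run, reference/variant
                   mean mapping-quality difference < 30, variant not
                   confined to read ends;
3. population    — population allele frequency < 1% (missing = rare);
4. function      — exonic or splicing (drops intergenic/intronic/UTR/
                   upstream/downstream/ncRNA);
5. truncation    — ClinVar hotspot, nonsense, frameshift indel, or splice
                   site;
6. panel         — gene in the 11-gene DDR panel.

Rules are conjunctive, so the survivor set is independent of rule order;
every variant gets a full trace of per-rule outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: The 11-gene DNA-damage-response germline panel.
DDR11_PANEL = frozenset(
    {
        "ATM", "BAP1", "BRCA1", "BRCA2", "BRIP1", "CDK12",
        "CHEK2", "NBN", "PALB2", "POLQ", "RAD51C",
    }
)

FAIL_REGIONS = {"intergenic", "intronic", "UTR3", "UTR5", "upstream", "downstream"}
PASS_REGIONS = {"exonic", "splicing"}
TRUNCATING_CLASSES = {"nonsense", "frameshift_indel"}
KNOWN_EXONIC_CLASSES = TRUNCATING_CLASSES | {
    "nonframeshift", "missense", "synonymous", "unknown",
}

RULE_ORDER = (
    "quality", "homopolymer", "mapq_difference", "read_end",
    "population", "function", "truncation", "panel",
)


@dataclass(frozen=True)
class GermlineVariantRecord:
    """One candidate variant with every field the cascade inspects.

    Context evidence may arrive precomputed (``homopolymer_flag``,
    ``read_end_flag``) or raw (``flank_sequence`` centred on the site,
    ``median_read_position_fraction`` in [0, 1]); flags win when both are
    present.  Missing optional evidence passes the corresponding rule with
    a logged warning.
    """

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    total_depth: int
    variant_count: int
    vaf: float
    caller_label: str = "germline"  # germline | somatic | LOH | unknown
    homopolymer_flag: bool | None = None
    flank_sequence: str | None = None
    mapq_ref_mean: float | None = None
    mapq_alt_mean: float | None = None
    read_end_flag: bool | None = None
    median_read_position_fraction: float | None = None
    population_af: float | None = None
    func_region: str = "exonic"
    exonic_class: str = "unknown"
    clinvar_hotspot: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise DataError(f"{self.key}: VAF {self.vaf} outside [0, 1]")
        if self.variant_count > self.total_depth:
            raise DataError(f"{self.key}: variant count exceeds depth")

    @property
    def key(self) -> str:
        return f"{self.sample}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class FilterTrace:
    """Ordered per-rule outcomes for one variant."""

    variant: str
    checks: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def final_status(self) -> bool:
        return all(ok for _, ok in self.checks)

    @property
    def first_failing_rule(self) -> str | None:
        return next((rule for rule, ok in self.checks if not ok), None)


# ---------------------------------------------------------------------------
# Individual rules; each returns (passed, reason_or_None)
# ---------------------------------------------------------------------------


def quality_filter(
    record: GermlineVariantRecord,
    min_depth: int = 10,
    min_variant_count: int = 5,
    min_vaf: float = 0.08,
) -> tuple[bool, str | None]:
    """Low-quality rule: depth, supporting-read count, VAF, caller label.

    A VAF exactly at the floor passes (the exclusion is strict ``<``).
    """
    if record.total_depth < min_depth:
        return False, f"depth {record.total_depth} < {min_depth}"
    if record.variant_count < min_variant_count:
        return False, f"variant count {record.variant_count} < {min_variant_count}"
    if record.vaf < min_vaf:
        return False, f"VAF {record.vaf} < {min_vaf}"
    if record.caller_label == "somatic":
        return False, "labelled somatic by the caller"
    return True, None


def _has_homopolymer_near(
    flank: str, center: int, run_length: int, window: int
) -> bool:
    """True if a single-base run of >= ``run_length`` lies within
    ``window`` bp of position ``center`` in ``flank``."""
    i = 0
    n = len(flank)
    while i < n:
        j = i
        while j < n and flank[j] == flank[i]:
            j += 1
        if j - i >= run_length:
            # distance from the run interval [i, j-1] to the site
            dist = max(i - center, center - (j - 1), 0)
            if dist <= window:
                return True
        i = j
    return False


def homopolymer_rule(
    record: GermlineVariantRecord,
    run_length: int = 5,
    window: int = 3,
) -> tuple[bool, str | None]:
    """Fail variants adjacent to a homopolymer run.

    Triggered by a run of one base of length >= ``run_length`` within
    ``window`` bp of the site.  Uses the precomputed flag when present,
    else scans ``flank_sequence`` (variant at the centre index).
    """
    if record.homopolymer_flag is not None:
        return (not record.homopolymer_flag), (
            "homopolymer flag set" if record.homopolymer_flag else None
        )
    if record.flank_sequence:
        center = len(record.flank_sequence) // 2
        hit = _has_homopolymer_near(
            record.flank_sequence.upper(), center, run_length, window
        )
        return (not hit), ("homopolymer run near site" if hit else None)
    logger.warning("%s: no homopolymer evidence; rule passes", record.key)
    return True, None


def mapq_difference_rule(
    record: GermlineVariantRecord, max_diff: float = 30.0
) -> tuple[bool, str | None]:
    """Fail when |mean MAPQ(ref reads) - mean MAPQ(alt reads)| >= 30."""
    if record.mapq_ref_mean is None or record.mapq_alt_mean is None:
        logger.warning("%s: no mapping-quality evidence; rule passes", record.key)
        return True, None
    diff = abs(record.mapq_ref_mean - record.mapq_alt_mean)
    if diff >= max_diff:
        return False, f"mapping-quality difference {diff:g} >= {max_diff:g}"
    return True, None


def read_end_rule(
    record: GermlineVariantRecord, terminal_fraction: float = 0.10
) -> tuple[bool, str | None]:
    """Fail variants positioned in read ends.

    With positional evidence, fails when the median variant position falls
    in the terminal ``terminal_fraction`` of the read at either end; else
    uses the provided flag.
    """
    if record.median_read_position_fraction is not None:
        f = record.median_read_position_fraction
        if f <= terminal_fraction or f >= 1.0 - terminal_fraction:
            return False, f"median read position {f:g} in terminal {terminal_fraction:.0%}"
        return True, None
    if record.read_end_flag is not None:
        return (not record.read_end_flag), (
            "read-end flag set" if record.read_end_flag else None
        )
    logger.warning("%s: no read-position evidence; rule passes", record.key)
    return True, None


def context_filters(
    record: GermlineVariantRecord,
    run_length: int = 5,
    window: int = 3,
    max_mapq_diff: float = 30.0,
    terminal_fraction: float = 0.10,
) -> tuple[bool, str | None]:
    """Combined sequence-context rules (homopolymer, MAPQ, read end)."""
    for rule, kwargs in (
        (homopolymer_rule, {"run_length": run_length, "window": window}),
        (mapq_difference_rule, {"max_diff": max_mapq_diff}),
        (read_end_rule, {"terminal_fraction": terminal_fraction}),
    ):
        ok, reason = rule(record, **kwargs)
        if not ok:
            return False, reason
    return True, None


def population_filter(
    record: GermlineVariantRecord, max_af: float = 0.01
) -> tuple[bool, str | None]:
    """Remove common variants: population AF >= 1% fails (inclusive).

    A missing AF passes: the filter removes known-common variants only.
    """
    if record.population_af is None:
        return True, None
    if record.population_af >= max_af:
        return False, f"population AF {record.population_af:g} >= {max_af:g}"
    return True, None


def function_filter(record: GermlineVariantRecord) -> tuple[bool, str | None]:
    """Keep protein-affecting regions (exonic, splicing); drop the rest."""
    region = record.func_region
    if region in PASS_REGIONS:
        return True, None
    if region in FAIL_REGIONS or region.startswith("ncRNA"):
        return False, f"region {region}"
    raise DataError(f"{record.key}: unknown functional region {region!r}")


def truncation_selector(record: GermlineVariantRecord) -> tuple[bool, str | None]:
    """Keep only variants likely to disable the protein.

    Passes ClinVar hotspots, nonsense substitutions, frameshift indels,
    and splice-site variants; everything else fails.
    """
    if record.clinvar_hotspot:
        return True, None
    if record.exonic_class in TRUNCATING_CLASSES:
        return True, None
    if record.func_region == "splicing":
        return True, None
    return False, f"non-truncating ({record.exonic_class})"


def ddr_panel_extract(
    records: Iterable[GermlineVariantRecord],
    panel: frozenset[str] = DDR11_PANEL,
) -> list[GermlineVariantRecord]:
    """Subset records to genes in the DDR panel (symbols upper-cased)."""
    return [r for r in records if r.gene.upper() in panel]


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def run_cascade(
    records: Sequence[GermlineVariantRecord],
    panel: frozenset[str] = DDR11_PANEL,
    min_depth: int = 10,
    min_variant_count: int = 5,
    min_vaf: float = 0.08,
    homopolymer_run: int = 5,
    homopolymer_window: int = 3,
    max_mapq_diff: float = 30.0,
    terminal_fraction: float = 0.10,
    max_population_af: float = 0.01,
) -> tuple[list[GermlineVariantRecord], list[FilterTrace]]:
    """Apply the full conjunctive cascade; return survivors and traces.

    Every rule is evaluated for every variant (the trace is complete even
    after a failure), so the survivor set provably does not depend on rule
    order.
    """
    survivors: list[GermlineVariantRecord] = []
    traces: list[FilterTrace] = []
    for rec in records:
        trace = FilterTrace(variant=rec.key)
        checks = {
            "quality": quality_filter(
                rec, min_depth=min_depth, min_variant_count=min_variant_count,
                min_vaf=min_vaf,
            ),
            "homopolymer": homopolymer_rule(
                rec, run_length=homopolymer_run, window=homopolymer_window
            ),
            "mapq_difference": mapq_difference_rule(rec, max_diff=max_mapq_diff),
            "read_end": read_end_rule(rec, terminal_fraction=terminal_fraction),
            "population": population_filter(rec, max_af=max_population_af),
            "function": function_filter(rec),
            "truncation": truncation_selector(rec),
            "panel": (rec.gene.upper() in panel, None),
        }
        for rule in RULE_ORDER:
            trace.checks.append((rule, checks[rule][0]))
        traces.append(trace)
        if trace.final_status:
            survivors.append(rec)
    return survivors, traces


# ---------------------------------------------------------------------------
# Flattened-TSV and VCF interfaces
# ---------------------------------------------------------------------------

_OPTIONAL_FLOAT = (
    "mapq_ref_mean", "mapq_alt_mean", "median_read_position_fraction",
    "population_af",
)
_OPTIONAL_BOOL = ("homopolymer_flag", "read_end_flag")


def _coerce_optional(row: dict) -> dict:
    for col in _OPTIONAL_FLOAT:
        v = row.get(col)
        row[col] = None if v is None or pd.isna(v) else float(v)
    for col in _OPTIONAL_BOOL:
        v = row.get(col)
        row[col] = None if v is None or pd.isna(v) else bool(v)
    v = row.get("flank_sequence")
    row["flank_sequence"] = None if v is None or pd.isna(v) else str(v)
    return row


def read_candidates_tsv(path) -> list[GermlineVariantRecord]:
    """Read candidate variants from a single flattened TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    records = []
    for raw in df.to_dict(orient="records"):
        row = {k: v for k, v in raw.items() if k in GermlineVariantRecord.__dataclass_fields__}
        row = _coerce_optional(row)
        row["clinvar_hotspot"] = bool(raw.get("clinvar_hotspot", False))
        records.append(GermlineVariantRecord(**row))
    return records


def write_candidates_tsv(records: Sequence[GermlineVariantRecord], path) -> None:
    # repr round-trips floats exactly
    pd.DataFrame([vars(r) for r in records]).to_csv(
        path, sep="\t", index=False, float_format=lambda x: repr(float(x))
    )


def write_traces_tsv(traces: Sequence[FilterTrace], path) -> None:
    rows = []
    for t in traces:
        row = {"variant": t.variant}
        row.update({rule: ("pass" if ok else "fail") for rule, ok in t.checks})
        row["final_status"] = "pass" if t.final_status else "fail"
        row["first_failing_rule"] = t.first_failing_rule or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_candidates_vcf(vcf_path, sidecar_path) -> list[GermlineVariantRecord]:
    """Read candidates from a VCF plus an annotation sidecar TSV.

    The VCF supplies coordinates, alleles, per-sample depth/alt counts
    (FORMAT DP/AD) and the caller's germline/somatic label (INFO SS when
    present); the sidecar, keyed by (sample, chrom, pos, ref, alt),
    supplies annotation fields (gene, region, class, population AF,
    context evidence).
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    side = pd.read_csv(sidecar_path, sep="\t", dtype={"chrom": str})
    side_key = {
        (r["sample"], str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"]): r
        for r in side.to_dict(orient="records")
    }
    label_map = {"0": "unknown", "1": "germline", "2": "somatic", "3": "LOH"}
    records = []
    vcf = VCF(str(vcf_path))
    sample_names = vcf.samples
    for var in vcf:
        for alt in var.ALT:
            for si, sample in enumerate(sample_names):
                depth = int(var.format("DP")[si][0]) if var.format("DP") is not None else 0
                ad = var.format("AD")
                alt_count = int(ad[si][1]) if ad is not None and ad.shape[1] > 1 else 0
                if depth <= 0 and alt_count <= 0:
                    continue
                key = (sample, str(var.CHROM), int(var.POS), var.REF, alt)
                ann = side_key.get(key)
                if ann is None:
                    raise DataError(f"no sidecar annotation for {key}")
                ss = var.INFO.get("SS")
                row = {
                    k: v
                    for k, v in ann.items()
                    if k in GermlineVariantRecord.__dataclass_fields__
                }
                row.update(
                    sample=sample,
                    chrom=str(var.CHROM),
                    pos=int(var.POS),
                    ref=var.REF,
                    alt=alt,
                    total_depth=depth,
                    variant_count=alt_count,
                    vaf=alt_count / depth if depth else 0.0,
                    caller_label=label_map.get(str(ss), str(ss)) if ss is not None
                    else ann.get("caller_label", "unknown"),
                )
                row = _coerce_optional(row)
                row["clinvar_hotspot"] = bool(ann.get("clinvar_hotspot", False))
                records.append(GermlineVariantRecord(**row))
    return records
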