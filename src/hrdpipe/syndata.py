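"""Synthetic TCGA-like cohort generator with a full ground-truth ledger.

Every downstream stage (catalog, signatures, scars, germline, silencing,
stats, classify) is exercised on cohorts produced here, so each generated
table is paired with the exact quantity the stage should recover:

* somatic SNVs are placed on a synthetic reference so that their
  96-context tallies equal a recorded truth catalog; consensus-filter
  decoys (single-caller calls) are emitted but not counted;
* allele-specific copy-number segments are laid out so that the LOH/TAI/
  LST counters return exactly the per-sample counts in the ledger,
  with optional non-qualifying decoy segments;
* expression is log-normal around per-gene baselines with configured
  per-group log2 shifts; promoter methylation and expression are jointly
  set for planted silencing events;
* germline candidate variants include, for each cascade rule, one variant
  whose sole disqualifier is that rule, plus one clean truncating
  DDR-panel variant per BRCA-mutant sample.

Mutation positions are confined to a mutation-accessible window at the
start of each chromosome; the emitted FASTA covers that window.  Scar
segments use the full stated chromosome lengths (no sequence needed).
Identical (config, seed) always reproduces a byte-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import (
    BASES, CONTEXT_96, SomaticMutation, TrinucleotideCatalog, write_maf,
)
from .errors import ConfigurationError
from .genome import MB, GenomeMeta, default_synthetic_genome
from .germline import GermlineVariantRecord
from .reference import synthetic_reference_signatures
from .signatures import SignatureMatrix

GROUPS = ("BRCA1mut", "BRCA2mut", "HRDwt", "nonHRD")

CALLERS = ("mutect", "muse", "somaticsniper", "varscan")

_PAM50 = ("LumA", "LumB", "Her2", "Basal", "Normal")
_PAM50_PROBS = {
    "BRCA1mut": (0.05, 0.05, 0.03, 0.85, 0.02),
    "BRCA2mut": (0.55, 0.28, 0.05, 0.07, 0.05),
    "HRDwt": (0.15, 0.15, 0.15, 0.45, 0.10),
    "nonHRD": (0.50, 0.20, 0.08, 0.10, 0.12),
}

_EXPR_BACKGROUND_PREFIX = "GENE"


def _default_mixtures() -> dict[str, tuple[float, ...]]:
    # weights over ("COSMIC 1", "COSMIC 2", "COSMIC 3", "COSMIC 6"):
    # CpG-, APOBEC-, BRCA- and MSI-like processes
    return {
        "BRCA1mut": (0.20, 0.10, 0.62, 0.08),
        "BRCA2mut": (0.25, 0.12, 0.55, 0.08),
        "HRDwt": (0.28, 0.14, 0.50, 0.08),
        "nonHRD": (0.47, 0.28, 0.10, 0.15),
    }


def _default_scar_params() -> dict[str, tuple[int, int, int]]:
    # expected (LOH, TAI, LST) counts per group; scaled to the synthetic
    # three-chromosome genome rather than a full human genome
    return {
        "BRCA1mut": (9, 4, 7),
        "BRCA2mut": (7, 3, 6),
        "HRDwt": (8, 4, 6),
        "nonHRD": (2, 1, 2),
    }


def _default_expr_shifts() -> dict[str, dict[str, float]]:
    # log2 shifts per group; HRD-like tumors overexpress BARD1/BRIP1 and
    # the repair-pathway RPS genes, BRCA1-mutant tumors run basal-like
    # keratins and a stronger interferon programme, BRCA2-mutant tumors
    # run a luminal hormone programme
    ifng_up = {g: 1.2 for g in ("IDO1", "CXCL10", "CXCL9", "HLA-DRA", "STAT1", "IFNG")}
    hrd_core = {"BARD1": 1.5, "BRIP1": 1.2,
                "RIF1": 0.5, "PARPBP": 0.5, "RAD51": 0.5, "XRCC5": 0.5}
    return {
        "BRCA1mut": {**hrd_core, **ifng_up, "KRT5": 2.2, "KRT14": 2.0},
        "BRCA2mut": {**hrd_core, "ESR1": 2.2, "PGR": 2.0},
        "HRDwt": {**hrd_core, **{g: 0.6 for g in ifng_up}},
        "nonHRD": {},
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``signature_mixtures`` maps each group to true signature weights over
    ``signature_ids`` (ids into the bundled synthetic reference).  When
    ``mixture_dirichlet_conc`` is set, per-sample weights are drawn from a
    Dirichlet centred on the group mixture (weights x concentration), so
    exposures vary between samples of a group; ``None`` uses the group
    mixture exactly.
    """

    n_samples: int = 200
    seed: int = 0
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "BRCA1mut": 0.02, "BRCA2mut": 0.03, "HRDwt": 0.05, "nonHRD": 0.90,
        }
    )
    group_labels: dict[str, str] | None = None
    signature_ids: tuple[str, ...] = ("COSMIC 1", "COSMIC 2", "COSMIC 3", "COSMIC 6")
    signature_mixtures: dict[str, tuple[float, ...]] = field(default_factory=_default_mixtures)
    mixture_dirichlet_conc: float | None = 1.5
    mutations_per_sample: int | tuple[int, int] = (500, 2000)
    single_caller_fraction: float = 0.05
    non_silent_fraction: float = 0.7
    n_hypermutants: int = 0
    hypermutant_mutations: int = 8000
    plant_singleton: bool = False
    singleton_signature: str = "COSMIC 10"
    singleton_mutations: int = 4500
    singleton_weight: float = 0.9
    singleton_background_weight: float = 0.005
    scar_rate_params: dict[str, tuple[int, int, int]] = field(default_factory=_default_scar_params)
    scar_mode: str = "stochastic"  # "deterministic" places exactly the stated counts
    scar_decoys: bool = True
    expr_fold_changes: dict[str, dict[str, float]] = field(default_factory=_default_expr_shifts)
    expr_sigma_log2: float = 1.0
    n_expr_background: int = 120
    silencing_fraction: float = 0.03
    silencing_genes: tuple[str, ...] = ("BRCA1", "RAD51C")
    silencing_decoys: bool = True
    genome: GenomeMeta = field(default_factory=default_synthetic_genome)
    sequence_window: int = 300_000

    def validate(self) -> None:
        if self.group_labels is None and self.n_samples < 2:
            raise ConfigurationError("n_samples: must be >= 2")
        for group, w in self.signature_mixtures.items():
            w = np.asarray(w, dtype=float)
            if len(w) != len(self.signature_ids):
                raise ConfigurationError(
                    f"signature_mixtures[{group}]: needs one weight per signature id"
                )
            if (w < 0).any():
                raise ConfigurationError(f"signature_mixtures[{group}]: negative weight")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"signature_mixtures[{group}]: weights must sum to 1 (got {w.sum()!r})"
                )
        if isinstance(self.mutations_per_sample, tuple):
            lo, hi = self.mutations_per_sample
            if lo < 1 or hi < lo:
                raise ConfigurationError("mutations_per_sample: invalid range")
        elif self.mutations_per_sample < 1:
            raise ConfigurationError("mutations_per_sample: must be positive")
        if self.scar_mode not in ("deterministic", "stochastic"):
            raise ConfigurationError("scar_mode: must be deterministic or stochastic")
        for group in self.scar_rate_params:
            if group not in GROUPS:
                raise ConfigurationError(f"scar_rate_params: unknown group {group!r}")
        for c in self.genome.chromosomes:
            # both arms must hold at least a telomeric segment plus margin
            if min(c.centro_start - 1, c.length - c.centro_end) < 2 * _TAI_LEN:
                raise ConfigurationError(
                    f"genome: chromosome {c.name} arms too short for telomeric scars"
                )
        if not 0 <= self.silencing_fraction <= 1:
            raise ConfigurationError("silencing_fraction: must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground-truth ledger."""

    config: SimConfig
    genome: GenomeMeta
    reference: dict[str, str]
    maf: list[SomaticMutation]
    catalog: TrinucleotideCatalog  # truth context tallies (consensus calls only)
    segments: pd.DataFrame
    germline_candidates: list[GermlineVariantRecord]
    fpkm: pd.DataFrame
    methylation: pd.DataFrame
    annotations: pd.DataFrame
    truth: dict

    @property
    def samples(self) -> list[str]:
        return list(self.annotations["sample"])


# ---------------------------------------------------------------------------
# mutation channel
# ---------------------------------------------------------------------------


def _make_reference(genome: GenomeMeta, window: int, rng: np.random.Generator) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        c.name: "".join(bases[rng.integers(0, 4, size=min(window, c.length))])
        for c in genome.chromosomes
    }


def _position_index(reference: dict[str, str]) -> dict[str, list[tuple[str, np.ndarray]]]:
    """Map each pyrimidine-centred triplet to its (chrom, positions).

    Positions are 1-based and exclude the first and last base of each
    window so every site has both flanks.
    """
    index: dict[str, list[tuple[str, np.ndarray]]] = {}
    code = {b: i for i, b in enumerate(BASES)}
    for chrom, seq in reference.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        num = np.zeros(arr.size, dtype=np.int32)
        for b, i in code.items():
            num[arr == ord(b)] = i
        tri = num[:-2] * 16 + num[1:-1] * 4 + num[2:]
        for center in ("C", "T"):
            for five in BASES:
                for three in BASES:
                    key = five + center + three
                    t = code[five] * 16 + code[center] * 4 + code[three]
                    pos = np.flatnonzero(tri == t) + 2  # 1-based center
                    index.setdefault(key, []).append((chrom, pos))
    return index


_ALTS = {  # category -> (ref, alt)
    sub: (sub[0], sub[2]) for sub in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
}


def _draw_mutations(
    sample: str,
    context_counts: np.ndarray,
    index: dict[str, list[tuple[str, np.ndarray]]],
    rng: np.random.Generator,
    callers_min: int,
) -> list[SomaticMutation]:
    """Place mutations on the pyrimidine strand at sites matching each
    drawn context; sites are unique within a sample."""
    out = []
    for j, count in enumerate(context_counts):
        if count == 0:
            continue
        label = CONTEXT_96[j]
        five, sub, three = label[0], label[2:5], label[6]
        ref, alt = _ALTS[sub]
        pools = index[five + ref + three]
        sizes = np.array([len(p) for _, p in pools])
        total = sizes.sum()
        if total < count:
            raise ConfigurationError(
                "sequence_window: too small for the requested mutation load"
            )
        flat = rng.choice(total, size=count, replace=False)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for f in np.sort(flat):
            ci = int(np.searchsorted(offsets, f, side="right")) - 1
            chrom, positions = pools[ci]
            pos = int(positions[f - offsets[ci]])
            n_callers = int(rng.integers(callers_min, len(CALLERS) + 1))
            caller_set = frozenset(rng.choice(CALLERS, size=n_callers, replace=False))
            out.append(
                SomaticMutation(
                    sample=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    variant_classification="pending", callers=caller_set,
                )
            )
    return out


# ---------------------------------------------------------------------------
# segment channel
# ---------------------------------------------------------------------------

_TAI_LEN = 12 * MB
_LOH_LEN = 16 * MB
_LST_SEG = int(10.5 * MB)
_SPACING = 4 * MB  # always > the LST max_gap, so placements never interact


class _ArmCursor:
    """Sequential allocator over the interstitial part of one arm."""

    def __init__(self, start: int, end: int):
        self.pos = start
        self.end = end

    def take(self, length: int) -> int | None:
        if self.pos + length - 1 > self.end:
            return None
        s = self.pos
        self.pos += length + _SPACING
        return s


def _sample_segments(
    sample: str,
    genome: GenomeMeta,
    counts: tuple[int, int, int],
    decoys: bool,
    strict: bool,
) -> tuple[list[dict], tuple[int, int, int]]:
    """Lay out qualifying segments for exactly ``counts`` = (LOH, TAI, LST).

    In strict (deterministic) mode a layout that does not fit raises; in
    stochastic mode counts are truncated to capacity.  Returns rows and
    the realized counts.
    """
    loh_n, tai_n, lst_n = counts
    margin = _TAI_LEN + 5 * MB
    rows: list[dict] = []

    # telomeric slots for TAI, fixed order: (chrom, p) then (chrom, q)
    tai_slots = []
    for c in genome.chromosomes:
        tai_slots.append((c.name, 1, _TAI_LEN))
        tai_slots.append((c.name, c.length - _TAI_LEN + 1, c.length))
    if tai_n > len(tai_slots):
        if strict:
            raise ConfigurationError(
                f"scar_rate_params: TAI count {tai_n} exceeds the "
                f"{len(tai_slots)} telomeric slots of the genome"
            )
        tai_n = len(tai_slots)
    for chrom, s, e in tai_slots[:tai_n]:
        rows.append(dict(sample=sample, chrom=chrom, start=s, end=e, major_cn=2, minor_cn=1))

    arms = []
    for c in genome.chromosomes:
        arms.append((c.name, _ArmCursor(margin + 1, c.centro_start - _SPACING)))
        arms.append((c.name, _ArmCursor(c.centro_end + _SPACING, c.length - margin)))

    # LST chains: alternating-state runs of >=10 Mb segments, n transitions
    # per chain of n+1 segments; chains may span several arms
    lst_done = 0
    for chrom, cursor in arms:
        while lst_done < lst_n:
            remaining = cursor.end - cursor.pos + 1
            max_segs = (remaining + 0) // _LST_SEG if remaining > 0 else 0
            if max_segs < 2:
                break
            chain = min(lst_n - lst_done + 1, int(max_segs))
            start = cursor.take(chain * _LST_SEG)
            assert start is not None
            for i in range(chain):
                state = (2, 2) if i % 2 == 0 else (1, 1)
                rows.append(
                    dict(
                        sample=sample, chrom=chrom,
                        start=start + i * _LST_SEG,
                        end=start + (i + 1) * _LST_SEG - 1,
                        major_cn=state[0], minor_cn=state[1],
                    )
                )
            lst_done += chain - 1
        if lst_done >= lst_n:
            break

    loh_done = 0
    for chrom, cursor in arms:
        while loh_done < loh_n:
            start = cursor.take(_LOH_LEN)
            if start is None:
                break
            rows.append(
                dict(sample=sample, chrom=chrom, start=start, end=start + _LOH_LEN - 1,
                     major_cn=1, minor_cn=0)
            )
            loh_done += 1
        if loh_done >= loh_n:
            break

    if strict and (loh_done < loh_n or lst_done < lst_n):
        raise ConfigurationError(
            f"scar_rate_params: requested (LOH={loh_n}, LST={lst_n}) does not "
            f"fit the synthetic genome (placed LOH={loh_done}, LST={lst_done})"
        )

    if decoys:
        decoy_specs = (
            (8 * MB, 1, 0),              # LOH too short
            (12 * MB, 2, 1),             # imbalanced but interstitial: no TAI
            (2 * MB, 3, 1),              # below the LST smoothing floor
        )
        for length, major, minor in decoy_specs:
            for chrom, cursor in arms:
                start = cursor.take(length)
                if start is not None:
                    rows.append(
                        dict(sample=sample, chrom=chrom, start=start,
                             end=start + length - 1, major_cn=major, minor_cn=minor)
                    )
                    break
        # sub-threshold state transition: two 9 Mb segments, states differ
        for chrom, cursor in arms:
            start = cursor.take(18 * MB)
            if start is not None:
                rows.append(dict(sample=sample, chrom=chrom, start=start,
                                 end=start + 9 * MB - 1, major_cn=2, minor_cn=2))
                rows.append(dict(sample=sample, chrom=chrom, start=start + 9 * MB,
                                 end=start + 18 * MB - 1, major_cn=1, minor_cn=1))
                break

    return rows, (loh_done, tai_n, lst_done)


# ---------------------------------------------------------------------------
# germline channel
# ---------------------------------------------------------------------------

_GENE_LOCI = {  # synthetic coordinates inside the mutation window
    "BRCA1": ("1", 41_000), "BRCA2": ("2", 32_000), "ATM": ("1", 108_000),
    "BAP1": ("3", 52_000), "BRIP1": ("1", 59_000), "CDK12": ("2", 37_000),
    "CHEK2": ("2", 29_000), "NBN": ("3", 90_000), "PALB2": ("1", 23_000),
    "POLQ": ("3", 121_000), "RAD51C": ("1", 56_000), "TP53": ("1", 7_500),
}

_CLEAN = dict(
    total_depth=60, variant_count=28, vaf=28 / 60, caller_label="germline",
    flank_sequence="ACGTACGTACG", mapq_ref_mean=60.0, mapq_alt_mean=58.0,
    median_read_position_fraction=0.45, population_af=0.0001,
    func_region="exonic", exonic_class="nonsense", clinvar_hotspot=False,
)


def _clean_variant(sample: str, gene: str, **overrides) -> GermlineVariantRecord:
    chrom, pos = _GENE_LOCI[gene]
    fields = {**_CLEAN, **overrides}
    return GermlineVariantRecord(
        sample=sample, chrom=chrom, pos=pos, ref="C", alt="T", gene=gene, **fields
    )


def _rule_violators(sample: str) -> list[GermlineVariantRecord]:
    """One variant per cascade rule whose sole disqualifier is that rule."""
    mk = _clean_variant
    return [
        mk(sample, "ATM", total_depth=8, variant_count=5, vaf=5 / 8),
        mk(sample, "BAP1", variant_count=4, vaf=4 / 60),
        mk(sample, "BRIP1", total_depth=100, variant_count=6, vaf=0.06),
        mk(sample, "CDK12", caller_label="somatic"),
        mk(sample, "CHEK2", flank_sequence="CGTAAAAACGT"),
        mk(sample, "NBN", mapq_ref_mean=60.0, mapq_alt_mean=25.0),
        mk(sample, "PALB2", median_read_position_fraction=0.05),
        mk(sample, "POLQ", population_af=0.015),
        mk(sample, "RAD51C", func_region="intronic", exonic_class="unknown",
           clinvar_hotspot=True),
        mk(sample, "BRCA1", exonic_class="missense"),
    ]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _assign_groups(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    if config.group_labels is not None:
        return dict(config.group_labels)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    counts = {g: int(round(config.group_proportions.get(g, 0.0) * n)) for g in GROUPS}
    # give any rounding remainder to the largest group
    delta = n - sum(counts.values())
    counts[max(counts, key=counts.get)] += delta
    labels = [g for g in GROUPS for _ in range(counts[g])]
    rng.shuffle(labels)
    return dict(zip(samples, labels))


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a cohort under ``config``; reproducible from its seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genome = config.genome
    reference = _make_reference(genome, config.sequence_window, rng)
    index = _position_index(reference)

    groups = _assign_groups(config, rng)
    samples = list(groups)

    ref_sigs = synthetic_reference_signatures()
    sig_ids = list(config.signature_ids)
    if config.plant_singleton:
        sig_ids = sig_ids + [config.singleton_signature]
    profiles = np.vstack([ref_sigs.profiles[ref_sigs.names.index(s)] for s in sig_ids])

    hyper_samples = set(samples[: config.n_hypermutants])

    singleton_sample = None
    if config.plant_singleton:
        singleton_sample = "S_SGL"
        samples = samples + [singleton_sample]
        groups[singleton_sample] = "nonHRD"

    # --- mutations + truth catalog
    maf: list[SomaticMutation] = []
    truth_expo: dict[str, list[float]] = {}
    truth_counts: dict[str, np.ndarray] = {}
    n_mut: dict[str, int] = {}
    n_non_silent: dict[str, int] = {}
    for sample in samples:
        group = groups[sample]
        base_w = np.asarray(config.signature_mixtures[group], dtype=float)
        if config.mixture_dirichlet_conc is not None:
            alpha = np.maximum(base_w * config.mixture_dirichlet_conc, 1e-3)
            w = rng.dirichlet(alpha)
        else:
            w = base_w.copy()
        if config.plant_singleton:
            if sample == singleton_sample:
                w = np.append(
                    np.asarray(config.signature_mixtures[group], dtype=float)
                    * (1.0 - config.singleton_weight),
                    config.singleton_weight,
                )
            else:
                w = np.append(
                    w * (1.0 - config.singleton_background_weight),
                    config.singleton_background_weight,
                )
        if sample == singleton_sample:
            n = config.singleton_mutations
        elif sample in hyper_samples:
            n = config.hypermutant_mutations
        elif isinstance(config.mutations_per_sample, tuple):
            lo, hi = config.mutations_per_sample
            n = int(rng.integers(lo, hi + 1))
        else:
            n = int(config.mutations_per_sample)
        probs = w @ profiles
        counts = rng.multinomial(n, probs / probs.sum())
        muts = _draw_mutations(sample, counts, index, rng, callers_min=2)
        # single-caller decoys: drawn from the same process, never counted
        n_decoy = int(round(config.single_caller_fraction * n))
        if n_decoy:
            dcounts = rng.multinomial(n_decoy, probs / probs.sum())
            decoys = _draw_mutations(sample, dcounts, index, rng, callers_min=2)
            decoys = [
                SomaticMutation(
                    sample=m.sample, chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                    variant_classification=m.variant_classification,
                    callers=frozenset({str(rng.choice(CALLERS))}),
                )
                for m in decoys
            ]
        else:
            decoys = []
        non_silent = rng.random(len(muts)) < config.non_silent_fraction
        muts = [
            SomaticMutation(
                sample=m.sample, chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                variant_classification=(
                    "Missense_Mutation" if ns else "Silent"
                ),
                callers=m.callers,
            )
            for m, ns in zip(muts, non_silent)
        ]
        dec = [
            SomaticMutation(
                sample=m.sample, chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                variant_classification="Missense_Mutation", callers=m.callers,
            )
            for m in decoys
        ]
        maf.extend(muts)
        maf.extend(dec)
        truth_expo[sample] = [float(x) for x in w]
        truth_counts[sample] = counts
        n_mut[sample] = int(counts.sum())
        n_non_silent[sample] = int(non_silent.sum())

    catalog = TrinucleotideCatalog(
        pd.DataFrame(
            np.vstack([truth_counts[s] for s in samples]),
            index=pd.Index(samples, name="sample"),
            columns=list(CONTEXT_96),
        )
    )

    # --- copy-number segments + scar truth
    seg_rows: list[dict] = []
    truth_scars: dict[str, tuple[int, int, int]] = {}
    strict = config.scar_mode == "deterministic"
    for sample in samples:
        want = config.scar_rate_params[groups[sample]]
        if not strict:
            want = tuple(int(rng.poisson(v)) for v in want)
        rows, realized = _sample_segments(sample, genome, want, config.scar_decoys, strict)
        seg_rows.extend(rows)
        truth_scars[sample] = realized
    segments = (
        pd.DataFrame(seg_rows, columns=["sample", "chrom", "start", "end", "major_cn", "minor_cn"])
        .sort_values(["sample", "chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )

    # --- germline candidates
    germline: list[GermlineVariantRecord] = []
    truth_survivors: list[str] = []
    for sample in samples:
        if groups[sample] == "BRCA1mut":
            v = _clean_variant(sample, "BRCA1")
            germline.append(v)
            truth_survivors.append(v.key)
        elif groups[sample] == "BRCA2mut":
            v = _clean_variant(sample, "BRCA2", exonic_class="frameshift_indel")
            germline.append(v)
            truth_survivors.append(v.key)
    violator_host = samples[0]
    germline.extend(_rule_violators(violator_host))
    germline.append(_clean_variant(violator_host, "TP53"))  # off-panel decoy

    # --- expression
    genes = sorted(
        set(_GENE_LOCI)
        | {"RIF1", "PARPBP", "RAD51", "XRCC5"}
        | {"IDO1", "CXCL10", "CXCL9", "HLA-DRA", "STAT1", "IFNG"}
        | {"BARD1", "KRT5", "KRT14", "ESR1", "PGR"}
        | set(config.silencing_genes)
        | {
            g
            for shifts in config.expr_fold_changes.values()
            for g in shifts
        }
    ) + [f"{_EXPR_BACKGROUND_PREFIX}{i + 1:04d}" for i in range(config.n_expr_background)]
    base_log2 = pd.Series(rng.uniform(1.0, 6.0, size=len(genes)), index=genes)
    log2_expr = np.empty((len(genes), len(samples)))
    for j, sample in enumerate(samples):
        shifts = config.expr_fold_changes.get(groups[sample], {})
        shift_vec = np.array([shifts.get(g, 0.0) for g in genes])
        noise = rng.normal(0.0, config.expr_sigma_log2, size=len(genes))
        log2_expr[:, j] = base_log2.to_numpy() + shift_vec + noise
    fpkm = pd.DataFrame(
        np.power(2.0, log2_expr), index=pd.Index(genes, name="gene"), columns=samples
    )

    # --- methylation + silencing events
    meth_rows: list[dict] = []
    truth_silenced: list[tuple[str, str]] = []
    n_events = int(round(config.silencing_fraction * len(samples)))
    preferred = [s for s in samples if groups[s] == "HRDwt"] + [
        s for s in samples if groups[s] == "nonHRD"
    ]
    event_samples = preferred[:n_events]
    for k, sample in enumerate(event_samples):
        gene = config.silencing_genes[k % len(config.silencing_genes)]
        beta = float(rng.uniform(0.78, 0.95))
        fpkm.loc[gene, sample] = float(rng.uniform(0.05, 0.8))
        meth_rows.append(dict(sample=sample, gene=gene, beta=beta))
        truth_silenced.append((sample, gene))
    silenced_set = set(truth_silenced)
    decoy_budget = 2 if config.silencing_decoys else 0
    for sample in samples:
        for gene in config.silencing_genes:
            if (sample, gene) in silenced_set:
                continue
            if decoy_budget > 0 and sample not in event_samples:
                # hypermethylated but still expressed: not silenced
                beta = float(rng.uniform(0.76, 0.9))
                fpkm.loc[gene, sample] = float(rng.uniform(1.5, 8.0))
                decoy_budget -= 1
            else:
                beta = float(rng.uniform(0.05, 0.45))
            meth_rows.append(dict(sample=sample, gene=gene, beta=beta))
    methylation = pd.DataFrame(meth_rows, columns=["sample", "gene", "beta"])
    methylation = methylation.sort_values(["sample", "gene"], kind="mergesort").reset_index(drop=True)

    # --- annotations
    ann_rows = []
    for sample in samples:
        group = groups[sample]
        probs = _PAM50_PROBS[group]
        ann_rows.append(
            dict(
                sample=sample,
                group=group,
                pam50_subtype=str(rng.choice(_PAM50, p=probs)),
                brca1_germline=group == "BRCA1mut",
                brca2_germline=group == "BRCA2mut",
            )
        )
    annotations = pd.DataFrame(ann_rows)

    dominant = {
        s: sig_ids[int(np.argmax(truth_expo[s]))] for s in samples
    }
    shifts_1 = config.expr_fold_changes.get("BRCA1mut", {})
    shifts_2 = config.expr_fold_changes.get("BRCA2mut", {})
    deg_truth = sorted(
        g
        for g in set(shifts_1) | set(shifts_2)
        if shifts_1.get(g, 0.0) != shifts_2.get(g, 0.0)
    )

    truth = {
        "samples": samples,
        "groups": groups,
        "signature_ids": sig_ids,
        "exposures": truth_expo,
        "catalog_counts": {s: truth_counts[s].tolist() for s in samples},
        "n_mutations": n_mut,
        "n_non_silent": n_non_silent,
        "first_signature": dominant,
        "scar_counts": {s: list(truth_scars[s]) for s in samples},
        "silenced": [list(t) for t in truth_silenced],
        "germline_survivors": truth_survivors,
        "deg_genes_brca1_vs_brca2": deg_truth,
        "hypermutants": sorted(hyper_samples),
        "singleton_sample": singleton_sample,
    }

    return SyntheticCohort(
        config=config,
        genome=genome,
        reference=reference,
        maf=maf,
        catalog=catalog,
        segments=segments,
        germline_candidates=germline,
        fpkm=fpkm,
        methylation=methylation,
        annotations=annotations,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_fasta(reference: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write every cohort table to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": outdir / "somatic.maf.tsv",
        "reference": outdir / "reference.fa",
        "genome_meta": outdir / "genome_meta.tsv",
        "catalog": outdir / "truth_catalog.tsv",
        "segments": outdir / "segments.tsv",
        "germline": outdir / "germline_candidates.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "methylation": outdir / "methylation.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
    }
    write_maf(cohort.maf, paths["maf"])
    write_fasta(cohort.reference, paths["reference"])
    cohort.genome.to_tsv(paths["genome_meta"])
    cohort.catalog.to_tsv(paths["catalog"])
    cohort.segments.to_csv(paths["segments"], sep="\t", index=False)
    from .germline import write_candidates_tsv

    write_candidates_tsv(cohort.germline_candidates, paths["germline"])
    cohort.fpkm.to_csv(paths["fpkm"], sep="\t", float_format="%.6g", index_label="gene")
    cohort.methylation.to_csv(paths["methylation"], sep="\t", float_format="%.6g", index=False)
    cohort.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
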