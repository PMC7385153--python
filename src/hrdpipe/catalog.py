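"""Somatic SNV catalogs on the 96-trinucleotide scheme.

Single-base substitutions are reduced to the six pyrimidine-reference
substitutions (C>A, C>G, C>T, T>A, T>C, T>G) in their 16 flanking-base
contexts, giving the standard 96 categories in COSMIC order.  Coordinates
are 1-based inclusive (MAF convention) at every external interface.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ReferenceMismatchError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The fixed 96 context categories, grouped by substitution then ordered by
#: 5' and 3' flanking base (COSMIC ordering).  Labels look like "A[C>A]A".
CONTEXT_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CONTEXT_INDEX: dict[str, int] = {c: i for i, c in enumerate(CONTEXT_96)}


@dataclass(frozen=True)
class SomaticMutation:
    """One somatic variant call with its supporting caller set."""

    sample: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_classification: str = "Missense_Mutation"
    callers: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in BASES
            and self.alt in BASES
            and self.ref != self.alt
        )


@dataclass
class TrinucleotideCatalog:
    """Sample x 96 mutation-context count matrix.

    ``counts`` is a DataFrame indexed by sample with the 96 context labels
    as columns, in fixed order.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CONTEXT_96:
            raise DataError("catalog columns must be the 96 contexts in COSMIC order")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("catalog counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset(self, samples: Sequence[str]) -> "TrinucleotideCatalog":
        return TrinucleotideCatalog(self.counts.loc[list(samples)])

    def to_tsv(self, path) -> None:
        # contexts as rows, samples as columns
        self.counts.T.to_csv(path, sep="\t", index_label="context")

    @classmethod
    def from_tsv(cls, path) -> "TrinucleotideCatalog":
        df = pd.read_csv(path, sep="\t", index_col="context")
        return cls(df.T.loc[:, list(CONTEXT_96)])


def consensus_filter(
    mutations: Iterable[SomaticMutation], min_callers: int = 2
) -> list[SomaticMutation]:
    """Keep mutations supported by at least ``min_callers`` variant callers.

    Order-preserving; ``min_callers=1`` returns the input unchanged.
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    out = [m for m in mutations if len(m.callers) >= min_callers]
    return out


def normalize_chrom(name: str, style: str = "bare") -> str:
    """Normalize chromosome naming between "chr1" and "1" dialects."""
    if style == "bare":
        return name[3:] if name.lower().startswith("chr") else name
    if style == "chr":
        return name if name.lower().startswith("chr") else f"chr{name}"
    raise ValueError(f"unknown chromosome style: {style!r}")


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence, 1-based inclusive.

    Accepts a plain mapping of chromosome -> sequence string or a
    ``pyfaidx.Fasta`` object (anything whose ``[chrom]`` slices like a
    sequence).
    """
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise DataError(f"chromosome {chrom!r} not in reference") from exc
    return str(seq[start - 1 : end]).upper()


def trinucleotide_context(
    chrom: str, pos: int, ref: str, alt: str, reference
) -> str | None:
    """Return the pyrimidine-normalized 96-category for one SNV.

    Purine-reference substitutions are reverse-complemented (base and both
    flanks).  Positions at a chromosome edge (no 5' or 3' neighbour) are
    skipped with a warning and return ``None``.  A mismatch between ``ref``
    and the reference sequence raises :class:`ReferenceMismatchError`.
    """
    chrom_len = len(reference[chrom])
    if pos < 2 or pos > chrom_len - 1:
        logger.warning(
            "skipping edge position %s:%d (no flanking base)", chrom, pos
        )
        return None
    tri = _fetch(reference, chrom, pos - 1, pos + 1)
    if tri[1] != ref:
        raise ReferenceMismatchError(
            f"reference base at {chrom}:{pos} is {tri[1]!r}, record says {ref!r}"
        )
    if ref in ("A", "G"):  # purine: flip to the pyrimidine strand
        tri = "".join(COMPLEMENT[b] for b in reversed(tri))
        alt = COMPLEMENT[alt]
        ref = COMPLEMENT[ref]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def build_catalog(
    mutations: Iterable[SomaticMutation],
    reference,
    samples: Sequence[str] | None = None,
) -> TrinucleotideCatalog:
    """Count pyrimidine-normalized contexts per sample.

    Non-SNV records (indels, MNVs) are dropped with a logged count; samples
    listed in ``samples`` but carrying zero SNVs are retained as zero rows.
    """
    tallies: dict[str, Counter] = {}
    n_non_snv = 0
    n_edge = 0
    order: list[str] = list(samples) if samples is not None else []
    seen = set(order)
    for m in mutations:
        if m.sample not in seen:
            seen.add(m.sample)
            order.append(m.sample)
        if not m.is_snv:
            n_non_snv += 1
            continue
        ctx = trinucleotide_context(m.chrom, m.pos, m.ref, m.alt, reference)
        if ctx is None:
            n_edge += 1
            continue
        tallies.setdefault(m.sample, Counter())[ctx] += 1
    if n_non_snv:
        logger.info("dropped %d non-SNV records from catalog", n_non_snv)
    if n_edge:
        logger.info("skipped %d edge-position records", n_edge)
    mat = np.zeros((len(order), 96), dtype=int)
    for i, s in enumerate(order):
        for ctx, n in tallies.get(s, {}).items():
            mat[i, CONTEXT_INDEX[ctx]] = n
    counts = pd.DataFrame(mat, index=pd.Index(order, name="sample"), columns=list(CONTEXT_96))
    return TrinucleotideCatalog(counts)


def exclude_hypermutants(
    catalog: TrinucleotideCatalog, max_snv: int = 5800
) -> tuple[TrinucleotideCatalog, list[str]]:
    """Remove samples whose total SNV count is >= ``max_snv``.

    Returns the reduced catalog and the list of excluded sample ids.
    """
    sums = catalog.row_sums()
    excluded = list(sums.index[sums >= max_snv])
    kept = catalog.counts.loc[sums < max_snv]
    if excluded:
        logger.info("excluded %d hypermutant sample(s): %s", len(excluded), excluded)
    return TrinucleotideCatalog(kept), excluded


# ---------------------------------------------------------------------------
# MAF-like TSV interface
# ---------------------------------------------------------------------------

MAF_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "variant_classification", "callers"]

NON_SILENT_CLASSES = {
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Nonstop_Mutation",
    "Translation_Start_Site",
}


def read_maf(path, chrom_style: str | None = None) -> list[SomaticMutation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"MAF table is missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom_style is not None:
            chrom = normalize_chrom(chrom, chrom_style)
        out.append(
            SomaticMutation(
                sample=str(row.sample),
                chrom=chrom,
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                variant_classification=str(row.variant_classification),
                callers=frozenset(str(row.callers).split(";")) if row.callers else frozenset(),
            )
        )
    return out


def write_maf(mutations: Sequence[SomaticMutation], path) -> None:
    rows = [
        {
            "sample": m.sample,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "variant_classification": m.variant_classification,
            "callers": ";".join(sorted(m.callers)),
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)
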