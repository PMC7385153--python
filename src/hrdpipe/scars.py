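"""Genomic-scar HRD components (LOH, TAI, LST) and expression-based RPS.

The three scar components are counted from allele-specific copy-number
segments, following the standard published definitions the pan-cancer HRD
scores are built on:

* LOH — segments with lost minor allele (minor_cn = 0) longer than 15 Mb
  that do not span a whole chromosome;
* TAI — allelic-imbalance segments (major_cn != minor_cn) longer than
  11 Mb that reach a chromosome end and do not cross the centromere;
* LST — breakpoints between adjacent segments of at least 10 Mb in
  different copy-number states, separated by at most 3 Mb, counted per
  chromosome arm after smoothing away segments shorter than 3 Mb.

Their sum is the HRD score.  No ploidy normalization is applied to LST;
raw breakpoint counts are reported (see docs/methods.md).  Externally
supplied (imported) scores are passed through with a source flag and are
never silently mixed with computed ones.

The recombination proficiency score (RPS) is the negative (optionally
weighted) sum of RIF1, PARPBP, RAD51 and XRCC5 expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .genome import MB, GenomeMeta

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]

RPS_GENES = ("RIF1", "PARPBP", "RAD51", "XRCC5")
RPS_BETA_WEIGHTS = {
    "RIF1": 0.2171423,
    "PARPBP": 0.1946173,
    "RAD51": 0.2783017,
    "XRCC5": 0.3099387,
}


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Check the allele-specific segment-table contract.

    Requires start <= end, minor_cn <= major_cn, non-negative copy
    numbers, and non-overlapping sorted segments within (sample, chrom).
    Returns the table sorted by (sample, chrom, start).
    """
    missing = [c for c in SEGMENT_COLUMNS if c not in segments.columns]
    if missing:
        raise DataError(f"segment table is missing columns: {missing}")
    df = segments.copy()
    df["chrom"] = df["chrom"].astype(str)
    if (df["start"] > df["end"]).any():
        raise DataError("segment with start > end")
    if (df["minor_cn"] > df["major_cn"]).any():
        raise DataError("segment with minor_cn > major_cn")
    if (df[["major_cn", "minor_cn"]] < 0).to_numpy().any():
        raise DataError("negative copy number")
    df = df.sort_values(["sample", "chrom", "start"], kind="mergesort").reset_index(drop=True)
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] <= ends[:-1]).any():
            raise DataError(f"overlapping segments for sample {sample} chrom {chrom}")
    return df


def _seg_len(start: int, end: int) -> int:
    return end - start + 1


def count_loh(
    sample_segments: pd.DataFrame,
    genome: GenomeMeta,
    min_len: float = 15 * MB,
) -> int:
    """LOH segments: minor allele lost, > ``min_len``, not whole-chromosome."""
    n = 0
    for row in sample_segments.itertuples(index=False):
        if row.minor_cn != 0:
            continue
        length = _seg_len(row.start, row.end)
        if length <= min_len:
            continue
        chrom = genome[str(row.chrom)]
        if row.start == 1 and row.end == chrom.length:
            continue  # whole-chromosome LOH is excluded
        n += 1
    return n


def _crosses_centromere(start: int, end: int, chrom) -> bool:
    # spans the entire centromere interval, i.e. has mass on both arms
    return start < chrom.centro_start and end > chrom.centro_end


def count_tai(
    sample_segments: pd.DataFrame,
    genome: GenomeMeta,
    min_len: float = 11 * MB,
) -> int:
    """Telomeric allelic-imbalance segments.

    Counts segments with major_cn != minor_cn, longer than ``min_len``,
    reaching a chromosome end, and not crossing the centromere.
    """
    for c in set(sample_segments["chrom"].astype(str)):
        if c not in genome:
            raise ConfigurationError(f"no centromere data for chromosome {c!r}")
    n = 0
    for row in sample_segments.itertuples(index=False):
        if row.major_cn == row.minor_cn:
            continue
        if _seg_len(row.start, row.end) <= min_len:
            continue
        chrom = genome[str(row.chrom)]
        if not (row.start == 1 or row.end == chrom.length):
            continue  # interstitial
        if _crosses_centromere(row.start, row.end, chrom):
            continue
        n += 1
    return n


def _arm_segments(
    sample_segments: pd.DataFrame, genome: GenomeMeta
) -> Iterable[list[tuple[int, int, int, int]]]:
    """Yield per-arm lists of (start, end, major, minor), split at the
    centromere midpoint, sorted by start."""
    for chrom_name, grp in sample_segments.groupby(sample_segments["chrom"].astype(str)):
        chrom = genome[chrom_name]
        mid = chrom.centromere_mid
        p_arm: list[tuple[int, int, int, int]] = []
        q_arm: list[tuple[int, int, int, int]] = []
        for row in grp.sort_values("start").itertuples(index=False):
            s, e = int(row.start), int(row.end)
            state = (int(row.major_cn), int(row.minor_cn))
            if e <= mid:
                p_arm.append((s, e, *state))
            elif s > mid:
                q_arm.append((s, e, *state))
            else:  # spans the midpoint: split
                p_arm.append((s, mid, *state))
                q_arm.append((mid + 1, e, *state))
        yield p_arm
        yield q_arm


def _smooth(
    segs: list[tuple[int, int, int, int]],
    smooth_below: float,
    max_gap: float,
) -> list[tuple[int, int, int, int]]:
    """Drop segments shorter than ``smooth_below``, then merge consecutive
    same-state segments whose gap is at most ``max_gap``."""
    kept = [s for s in segs if _seg_len(s[0], s[1]) >= smooth_below]
    merged: list[tuple[int, int, int, int]] = []
    for seg in kept:
        if (
            merged
            and merged[-1][2:] == seg[2:]
            and seg[0] - merged[-1][1] - 1 <= max_gap
        ):
            prev = merged.pop()
            merged.append((prev[0], seg[1], *seg[2:]))
        else:
            merged.append(seg)
    return merged


def count_lst(
    sample_segments: pd.DataFrame,
    genome: GenomeMeta,
    min_seg: float = 10 * MB,
    max_gap: float = 3 * MB,
    smooth_below: float = 3 * MB,
) -> int:
    """Large-scale state transitions.

    After per-arm smoothing, counts breakpoints between adjacent segments
    that are each at least ``min_seg`` long, in different copy-number
    states, with an inter-segment gap of at most ``max_gap``.
    """
    n = 0
    for arm in _arm_segments(sample_segments, genome):
        segs = _smooth(arm, smooth_below, max_gap)
        for left, right in zip(segs, segs[1:]):
            if left[2:] == right[2:]:
                continue
            if _seg_len(left[0], left[1]) < min_seg:
                continue
            if _seg_len(right[0], right[1]) < min_seg:
                continue
            if right[0] - left[1] - 1 > max_gap:
                continue
            n += 1
    return n


@dataclass(frozen=True)
class HrdScoreRecord:
    """Per-sample scar components and their sum."""

    sample: str
    loh_count: int
    tai_count: int
    lst_count: int
    source: str = "computed"  # or "imported"

    def __post_init__(self) -> None:
        if min(self.loh_count, self.tai_count, self.lst_count) < 0:
            raise DataError("scar components must be non-negative")

    @property
    def hrd_sum(self) -> int:
        return self.loh_count + self.tai_count + self.lst_count


def hrd_sum(
    sample: str,
    segments: pd.DataFrame | None = None,
    genome: GenomeMeta | None = None,
    imported_score: int | None = None,
    loh_min_len: float = 15 * MB,
    tai_min_len: float = 11 * MB,
    lst_min_seg: float = 10 * MB,
    lst_max_gap: float = 3 * MB,
    lst_smooth_below: float = 3 * MB,
) -> HrdScoreRecord:
    """HRD score for one sample, computed from segments or imported.

    If both a segment table and an imported score are supplied, they must
    agree, otherwise a conflict is raised.  An empty segment table yields
    (0, 0, 0).
    """
    if segments is None and imported_score is None:
        raise ConfigurationError(
            f"sample {sample}: neither segments nor an imported score supplied"
        )
    if segments is not None:
        if genome is None:
            raise ConfigurationError("genome meta required to compute scar scores")
        own = segments[segments["sample"] == sample]
        rec = HrdScoreRecord(
            sample=sample,
            loh_count=count_loh(own, genome, min_len=loh_min_len),
            tai_count=count_tai(own, genome, min_len=tai_min_len),
            lst_count=count_lst(
                own, genome, min_seg=lst_min_seg, max_gap=lst_max_gap,
                smooth_below=lst_smooth_below,
            ),
            source="computed",
        )
        if imported_score is not None and imported_score != rec.hrd_sum:
            raise DataError(
                f"sample {sample}: computed HRD sum {rec.hrd_sum} conflicts "
                f"with imported score {imported_score}"
            )
        return rec
    return HrdScoreRecord(
        sample=sample, loh_count=0, tai_count=0, lst_count=int(imported_score),
        source="imported",
    )


def hrd_score_table(
    segments: pd.DataFrame, genome: GenomeMeta, **kwargs
) -> pd.DataFrame:
    """Compute per-sample scar components for every sample in a table."""
    segments = validate_segments(segments)
    rows = []
    for sample in segments["sample"].drop_duplicates():
        rec = hrd_sum(str(sample), segments=segments, genome=genome, **kwargs)
        rows.append(
            {
                "sample": rec.sample,
                "loh_count": rec.loh_count,
                "tai_count": rec.tai_count,
                "lst_count": rec.lst_count,
                "hrd_sum": rec.hrd_sum,
                "source": rec.source,
            }
        )
    return pd.DataFrame(rows)


def import_hrd_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Wrap an externally published per-sample HRD score table.

    Expects columns (sample, hrd_score); component counts are not
    available on the import path and are reported as missing.
    """
    if not {"sample", "hrd_score"} <= set(scores.columns):
        raise DataError("imported score table needs columns: sample, hrd_score")
    out = pd.DataFrame(
        {
            "sample": scores["sample"].astype(str),
            "loh_count": pd.NA,
            "tai_count": pd.NA,
            "lst_count": pd.NA,
            "hrd_sum": scores["hrd_score"].astype(int),
            "source": "imported",
        }
    )
    return out


# ---------------------------------------------------------------------------
# Recombination proficiency score
# ---------------------------------------------------------------------------


def _rps_values(inputs: Mapping[str, float]) -> np.ndarray:
    try:
        vals = np.array([float(inputs[g]) for g in RPS_GENES])
    except KeyError as exc:
        raise DataError(f"missing expression for RPS gene {exc.args[0]!r}") from exc
    return vals


def rps(inputs: Mapping[str, float]) -> float:
    """Unweighted RPS: -1 x (RIF1 + PARPBP + RAD51 + XRCC5)."""
    return float(-_rps_values(inputs).sum())


def rps_beta(inputs: Mapping[str, float]) -> float:
    """Weighted RPS with the published regression coefficients."""
    vals = _rps_values(inputs)
    w = np.array([RPS_BETA_WEIGHTS[g] for g in RPS_GENES])
    return float(-(w * vals).sum())


def rps_table(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Per-sample RPS and RPS-beta from a genes x samples FPKM matrix."""
    for g in RPS_GENES:
        if g not in fpkm.index:
            raise DataError(f"missing expression for RPS gene {g!r}")
    sub = fpkm.loc[list(RPS_GENES)]
    w = np.array([RPS_BETA_WEIGHTS[g] for g in RPS_GENES])
    return pd.DataFrame(
        {
            "rps": -sub.sum(axis=0),
            "rps_beta": -(sub.mul(w, axis=0)).sum(axis=0),
        }
    )
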