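"""Promoter hypermethylation and epigenetic-silencing calls.

A gene is called hypermethylated in a sample when its summarized promoter
methylation beta is at least 0.75 (inclusive), and epigenetically silenced
when it is additionally expressed below 1 FPKM (strict).  Silencing
therefore implies hypermethylation by construction.

Promoter-probe summarization defaults to the mean, which keeps the
summary on the [0, 1] beta scale that the 0.75 threshold is defined on; a
sum mode is provided for fidelity to summed-level conventions but its
scale exceeds 1 for multi-probe promoters (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DataError


def summarize_promoter(
    probes: Sequence[tuple[float, bool]], mode: str = "mean"
) -> float | None:
    """Summarize promoter-probe betas; returns None when no promoter probe.

    ``probes`` is a list of (beta, in_promoter) pairs; ``mode`` is "mean"
    (default) or "sum".
    """
    betas = [b for b, in_prom in probes if in_prom]
    if not betas:
        return None
    if mode == "mean":
        return float(sum(betas) / len(betas))
    if mode == "sum":
        return float(sum(betas))
    raise DataError(f"unknown promoter summarization mode {mode!r}")


@dataclass(frozen=True)
class SilencingCall:
    sample: str
    gene: str
    beta: float
    expressed_fpkm: float
    hypermethylated: bool
    silenced: bool

    def __post_init__(self) -> None:
        if self.silenced and not self.hypermethylated:
            raise DataError("silenced call without hypermethylation")


def call_silencing(
    sample: str,
    gene: str,
    beta_summary: float,
    fpkm: float,
    beta_cut: float = 0.75,
    fpkm_cut: float = 1.0,
) -> SilencingCall:
    """One silencing call: beta >= cut (inclusive) and FPKM < cut (strict)."""
    if beta_summary is None or fpkm is None or math.isnan(beta_summary) or math.isnan(fpkm):
        raise DataError(f"{sample}/{gene}: missing methylation or expression input")
    hyper = beta_summary >= beta_cut
    return SilencingCall(
        sample=sample,
        gene=gene,
        beta=float(beta_summary),
        expressed_fpkm=float(fpkm),
        hypermethylated=hyper,
        silenced=hyper and fpkm < fpkm_cut,
    )


def call_silencing_table(
    methylation: pd.DataFrame,
    fpkm: pd.DataFrame,
    genes: Sequence[str] | None = None,
    beta_cut: float = 0.75,
    fpkm_cut: float = 1.0,
) -> pd.DataFrame:
    """Silencing calls for a cohort.

    ``methylation`` has columns (sample, gene, beta); ``fpkm`` is a
    genes x samples matrix.  Pairs with a missing channel are excluded
    from the output (and hence from tallies).
    """
    need = {"sample", "gene", "beta"}
    if not need <= set(methylation.columns):
        raise DataError(f"methylation table needs columns {sorted(need)}")
    rows = []
    for r in methylation.itertuples(index=False):
        gene, sample = str(r.gene), str(r.sample)
        if genes is not None and gene not in genes:
            continue
        if gene not in fpkm.index or sample not in fpkm.columns:
            continue
        expr = float(fpkm.loc[gene, sample])
        if pd.isna(r.beta) or pd.isna(expr):
            continue
        call = call_silencing(
            sample, gene, float(r.beta), expr, beta_cut=beta_cut, fpkm_cut=fpkm_cut
        )
        rows.append(
            {
                "sample": call.sample,
                "gene": call.gene,
                "beta": call.beta,
                "fpkm": call.expressed_fpkm,
                "hypermethylated": call.hypermethylated,
                "silenced": call.silenced,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "gene", "beta", "fpkm", "hypermethylated", "silenced"]
    )
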