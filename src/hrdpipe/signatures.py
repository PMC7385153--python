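"""Mutational-signature extraction, refitting, and naming.

De-novo extraction runs many randomly initialized KL-divergence NMF fits
with relevance pruning (components holding a negligible share of total
activity are dropped during fitting), votes on the surviving component
count across restarts, and averages the profiles of the winning restarts
into a consensus.  Refitting projects each sample's 96-context frequency
vector onto a fixed reference by non-negative least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

from .catalog import CONTEXT_96, TrinucleotideCatalog
from .errors import DataError, UnstableExtractionError

logger = logging.getLogger(__name__)

_EPS = 1e-12


def cosine_similarity(u, v) -> float:
    """Cosine of the angle between two non-negative profile vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DataError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class SignatureMatrix:
    """k x 96 matrix of signature probability profiles."""

    names: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[1] != 96:
            raise DataError("profiles must be a k x 96 matrix")
        if len(self.names) != self.profiles.shape[0]:
            raise DataError("one name per profile required")
        if (self.profiles < 0).any():
            raise DataError("profiles must be non-negative")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise DataError("each profile row must sum to 1 (within 1e-6)")

    @property
    def k(self) -> int:
        return self.profiles.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=self.names, columns=list(CONTEXT_96))

    def to_tsv(self, path) -> None:
        self.to_frame().T.to_csv(path, sep="\t", index_label="context")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="context").T
        return cls(names=list(df.index), profiles=df.loc[:, list(CONTEXT_96)].to_numpy())


@dataclass
class ExposureTable:
    """Per-sample signature activities.

    ``activities`` holds non-negative attributions on the mutation-count
    scale; ``normalized`` rescales each row to sum to 1 (a zero row stays
    zero).  ``first_signature`` is the per-sample argmax label, with exact
    ties resolved to the lexicographically first signature name.
    """

    activities: pd.DataFrame
    normalized: pd.DataFrame
    reconstruction_cosine: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.activities.to_numpy() < -1e-9).any():
            raise DataError("activities must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.activities.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.activities.columns)

    @property
    def first_signature(self) -> pd.Series:
        return assign_first_signature(self)


def assign_first_signature(exposures: ExposureTable) -> pd.Series:
    """Per-sample dominant signature label.

    Argmax of normalized activity; an exact tie goes to the
    lexicographically first signature name (logged); an all-zero row is
    labelled "unassigned".
    """
    norm = exposures.normalized
    cols = np.array(norm.columns, dtype=object)
    labels = []
    for sample, row in zip(norm.index, norm.to_numpy()):
        if row.sum() <= 0:
            labels.append("unassigned")
            continue
        best = row.max()
        winners = sorted(cols[row == best])
        if len(winners) > 1:
            logger.warning(
                "sample %s: tie between %s; taking %s", sample, winners, winners[0]
            )
        labels.append(winners[0])
    return pd.Series(labels, index=norm.index, name="first_signature")


# ---------------------------------------------------------------------------
# De-novo extraction
# ---------------------------------------------------------------------------


def _ard_nmf_kl(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    shrinkage: float = 10.0,
    max_iter: int = 2000,
    tol: float = 1e-7,
    prune_share: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """KL-divergence NMF with automatic relevance determination.

    Multiplicative updates for the Poisson/KL objective, augmented with a
    per-component exponential (L1) relevance prior whose scale is
    re-estimated each sweep: irrelevant components are driven to zero
    during fitting, so the returned rank is data-driven rather than fixed
    at ``k``.  ``shrinkage`` is the relevance prior's shape parameter
    (larger = stronger pruning pressure).  After convergence, components
    holding less than ``prune_share`` of total activity are dropped.
    Returns (W, H) with H rows normalized to sum 1 and W carrying the
    activity scale.
    """
    n, m = X.shape
    a = shrinkage
    mean = X.mean()
    W = rng.random((n, k)) * np.sqrt(mean) + _EPS
    H = rng.random((k, m)) * np.sqrt(mean) + _EPS
    b = np.sqrt((a - 1.0) * (a - 2.0) * mean / k)
    lam = (W.sum(axis=0) + H.sum(axis=1) + b) / (n + m + a + 1.0)
    prev_obj = np.inf
    for it in range(max_iter):
        WH = W @ H + _EPS
        W *= ((X / WH) @ H.T) / (H.sum(axis=1)[None, :] + 1.0 / lam[None, :] + _EPS)
        WH = W @ H + _EPS
        H *= (W.T @ (X / WH)) / (W.sum(axis=0)[:, None] + 1.0 / lam[:, None] + _EPS)
        lam = (W.sum(axis=0) + H.sum(axis=1) + b) / (n + m + a + 1.0)
        if (it + 1) % 50 == 0:
            WH = W @ H + _EPS
            obj = float((X * np.log((X + _EPS) / WH) - X + WH).sum())
            if abs(prev_obj - obj) < tol * max(abs(prev_obj), 1.0):
                break
            prev_obj = obj
    activity = W.sum(axis=0) * H.sum(axis=1)
    share = activity / max(activity.sum(), _EPS)
    keep = share >= prune_share
    if not keep.any():
        keep = share == share.max()
    W, H = W[:, keep], H[keep]
    h_sums = H.sum(axis=1)
    return W * h_sums[None, :], H / h_sums[:, None]


@dataclass
class ExtractionReport:
    """Outcome of consensus-over-restarts extraction."""

    n_restarts: int
    signature_count_votes: dict[int, int]
    chosen_k: int
    consensus: SignatureMatrix
    exposures: ExposureTable
    singleton_flags: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def vote_fraction(self) -> float:
        return self.signature_count_votes[self.chosen_k] / self.n_restarts


def extract_signatures(
    catalog: TrinucleotideCatalog,
    n_restarts: int = 50,
    k_max: int = 10,
    seed: int | None = None,
    quorum: float = 0.6,
    prune_share: float = 0.01,
    shrinkage: float = 10.0,
    max_iter: int = 2000,
    singleton_threshold: float = 0.5,
) -> ExtractionReport:
    """Consensus de-novo extraction over randomly initialized restarts.

    Each restart starts at ``k_max`` components and prunes irrelevant ones;
    the surviving count votes for the cohort's signature number.  The modal
    count must win at least ``quorum`` of the restarts, otherwise an
    :class:`UnstableExtractionError` carrying the vote table is raised.
    Consensus profiles are the cosine-matched centroids of the winning
    restarts, renormalized; exposures are an NNLS refit of the catalog onto
    the consensus (no floor).
    """
    X = catalog.matrix
    if X.size == 0 or X.sum() == 0:
        raise DataError("cannot extract signatures from an empty catalog")
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    results: list[tuple[np.ndarray, np.ndarray]] = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        W, H = _ard_nmf_kl(
            X, k_max, rng, shrinkage=shrinkage, max_iter=max_iter,
            prune_share=prune_share,
        )
        results.append((W, H))
    votes: dict[int, int] = {}
    for _, H in results:
        votes[H.shape[0]] = votes.get(H.shape[0], 0) + 1
    chosen_k = max(sorted(votes), key=lambda k: votes[k])
    if votes[chosen_k] < quorum * n_restarts:
        raise UnstableExtractionError(
            f"no component count reached the quorum "
            f"({quorum:.0%} of {n_restarts} restarts); votes: {votes}",
            votes,
        )
    winners = [H for _, H in results if H.shape[0] == chosen_k]
    anchor = winners[0]
    acc = np.zeros_like(anchor)
    for H in winners:
        # match this restart's components to the anchor by cosine
        sim = (H / np.linalg.norm(H, axis=1, keepdims=True)) @ (
            anchor / np.linalg.norm(anchor, axis=1, keepdims=True)
        ).T
        row, col = linear_sum_assignment(-sim)
        aligned = np.empty_like(H)
        aligned[col] = H[row]
        acc += aligned
    profiles = acc / acc.sum(axis=1, keepdims=True)
    names = [f"W{i + 1}" for i in range(chosen_k)]
    consensus = SignatureMatrix(names=names, profiles=profiles)
    exposures = refit_exposures(catalog, consensus, floor=0.0)
    flags = flag_singleton_signature(exposures, threshold_fraction=singleton_threshold)
    return ExtractionReport(
        n_restarts=n_restarts,
        signature_count_votes=votes,
        chosen_k=chosen_k,
        consensus=consensus,
        exposures=exposures,
        singleton_flags=flags,
    )


def flag_singleton_signature(
    exposures: ExposureTable, threshold_fraction: float = 0.5
) -> list[tuple[str, str, float]]:
    """Flag signatures whose activity is dominated by a single sample.

    A signature is flagged when its largest single-sample contribution is
    at least ``threshold_fraction`` of its total activity (inclusive).
    Returns (signature, dominant sample, fraction) triples.  The pipeline
    contract is that a flagged signature's dominant sample is excluded and
    extraction re-run.
    """
    flags = []
    act = exposures.activities
    for sig in act.columns:
        total = act[sig].sum()
        if total <= 0:
            continue
        top_sample = act[sig].idxmax()
        frac = float(act.loc[top_sample, sig] / total)
        if frac >= threshold_fraction:
            flags.append((sig, top_sample, frac))
    return flags


# ---------------------------------------------------------------------------
# Refitting against a fixed reference
# ---------------------------------------------------------------------------


def refit_exposures(
    catalog: TrinucleotideCatalog,
    reference_signatures: SignatureMatrix,
    floor: float = 0.06,
) -> ExposureTable:
    """Per-sample NNLS fit of context frequencies onto reference profiles.

    Normalized contributions below ``floor`` are zeroed and the remainder
    renormalized.  Activities are reported on the mutation-count scale
    (normalized weight x sample SNV count).  A zero-mutation sample yields
    a zero row and is flagged in the log.
    """
    A = reference_signatures.profiles.T  # 96 x k
    names = reference_signatures.names
    n_samples = len(catalog.samples)
    raw = np.zeros((n_samples, len(names)))
    recon_cos = np.full(n_samples, np.nan)
    X = catalog.matrix
    totals = X.sum(axis=1)
    for i in range(n_samples):
        if totals[i] == 0:
            logger.warning("sample %s has zero mutations; zero exposure row", catalog.samples[i])
            continue
        b = X[i] / totals[i]
        x, _ = nnls(A, b)
        s = x.sum()
        w = x / s if s > 0 else x
        if floor > 0:
            w[w < floor] = 0.0
            if w.sum() > 0:
                w = w / w.sum()
        raw[i] = w
        fit = A @ x
        if fit.sum() > 0:
            recon_cos[i] = cosine_similarity(fit, b)
    normalized = pd.DataFrame(raw, index=catalog.samples, columns=names)
    activities = normalized.mul(totals, axis=0)
    return ExposureTable(
        activities=activities,
        normalized=normalized,
        reconstruction_cosine=pd.Series(recon_cos, index=catalog.samples, name="reconstruction_cosine"),
    )


# ---------------------------------------------------------------------------
# Matching extracted signatures to a reference
# ---------------------------------------------------------------------------


@dataclass
class SignatureMatch:
    """Best reference match(es) for one extracted signature."""

    extracted_name: str
    best_ids: list[str]
    cosine_similarities: dict[str, float]
    assigned_label: str


def match_to_cosmic(
    extracted: SignatureMatrix,
    reference: SignatureMatrix,
    merged_pairs: tuple[tuple[str, str], ...] | None = None,
    report_floor: float = 0.8,
    aliases: dict[str, str] | None = None,
) -> list[SignatureMatch]:
    """Name extracted signatures by cosine similarity to a reference set.

    If the two best matches form a configured merged pair (by default the
    two APOBEC members) and both exceed ``report_floor``, a combined label
    carrying both similarities is emitted.  No alias promotion happens
    below the floor; the best match and its cosine are still reported.
    """
    if merged_pairs is None or aliases is None:
        from .reference import MERGED_PAIRS, SIGNATURE_ALIASES

        merged_pairs = MERGED_PAIRS if merged_pairs is None else merged_pairs
        aliases = SIGNATURE_ALIASES if aliases is None else aliases
    out = []
    for name, prof in zip(extracted.names, extracted.profiles):
        cos = {
            rn: cosine_similarity(prof, rp)
            for rn, rp in zip(reference.names, reference.profiles)
        }
        ranked = sorted(cos, key=cos.get, reverse=True)
        best = ranked[0]
        top_two = frozenset(ranked[:2])
        merged = next(
            (p for p in merged_pairs if frozenset(p) == top_two), None
        )
        if merged is not None and all(cos[m] >= report_floor for m in merged):
            alias = aliases.get(merged[0], "merged")
            nums = " + ".join(m.replace("COSMIC ", "") for m in merged)
            label = f"{alias} signature (COSMIC {nums})"
            best_ids = list(merged)
        elif cos[best] >= report_floor and best in aliases:
            label = f"{aliases[best]} signature ({best})"
            best_ids = [best]
        else:
            label = best
            best_ids = [best]
        out.append(
            SignatureMatch(
                extracted_name=name,
                best_ids=best_ids,
                cosine_similarities=cos,
                assigned_label=label,
            )
        )
    return out
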