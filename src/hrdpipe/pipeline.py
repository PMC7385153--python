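"""End-to-end orchestration: simulate/load -> catalog -> signatures ->
scars -> germline -> silencing -> stats -> classify -> cohort report.

Every stage writes its table under the output directory and the report
only re-tabulates stage outputs (no report-only computation).  The whole
run is deterministic from (config, seed): rerunning with the same inputs
produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as catalog_mod
from . import classify as classify_mod
from . import germline as germline_mod
from . import scars as scars_mod
from . import silencing as silencing_mod
from . import stats as stats_mod
from .errors import ConfigurationError, DataError, HrdPipeError
from .genome import GenomeMeta
from .reference import synthetic_reference_signatures
from .signatures import (
    ExposureTable, assign_first_signature, extract_signatures, match_to_cosmic,
)
from .syndata import SimConfig, SyntheticCohort, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run.

    Either ``sim`` (a :class:`SimConfig` for a synthetic cohort) or
    ``input_dir`` (a directory holding the cohort tables as written by
    :func:`hrdpipe.syndata.write_cohort`) must be set.  Threshold defaults
    mirror the study conditions: hypermutant floor 5800 SNVs, consensus
    >= 2 callers, hypermethylation beta >= 0.75, silencing FPKM < 1,
    common-variant AF >= 1%, MAPQ difference >= 30, depth >= 10,
    supporting reads >= 5, VAF >= 0.08, HRD top decile (imported-score
    cutoff 57), DEG |log2 FC| > 1.5 at FDR < 0.05, activity floor 0.5.
    """

    sim: SimConfig | None = None
    input_dir: str | None = None
    seed: int = 0
    outdir: str = "hrdpipe_out"
    # catalog
    min_callers: int = 2
    max_snv: int = 5800
    # signatures
    n_restarts: int = 50
    k_max: int = 10
    quorum: float = 0.6
    singleton_threshold: float = 0.5
    max_singleton_rounds: int = 3
    match_floor: float = 0.8
    # scars / classification
    imported_hrd_path: str | None = None
    hrd_rule: str = "top_quantile"  # or "fixed_cutoff"
    hrd_q: float = 0.10
    hrd_cutoff: float = 57.0
    # germline
    max_population_af: float = 0.01
    # silencing
    beta_cut: float = 0.75
    fpkm_cut: float = 1.0
    # stats
    fc_cut: float = 1.5
    q_cut: float = 0.05
    activity_floor: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_raw is not None:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ConfigurationError(f"unknown sim config keys: {sorted(bad)}")
            if "signature_mixtures" in sim_raw:
                sim_raw["signature_mixtures"] = {
                    g: tuple(v) for g, v in sim_raw["signature_mixtures"].items()
                }
            cfg.sim = SimConfig(**sim_raw)
        return cfg


@dataclass
class PipelineResult:
    cohort_frame: pd.DataFrame
    report: dict
    outdir: Path
    cohort: SyntheticCohort | None = None


def _load_cohort_inputs(input_dir: Path) -> dict:
    from pyfaidx import Fasta

    ref = {
        name: str(rec[:]) for name, rec in Fasta(str(input_dir / "reference.fa")).items()
    }
    return {
        "maf": catalog_mod.read_maf(input_dir / "somatic.maf.tsv"),
        "reference": ref,
        "genome": GenomeMeta.from_tsv(input_dir / "genome_meta.tsv"),
        "segments": (
            pd.read_csv(input_dir / "segments.tsv", sep="\t", dtype={"chrom": str})
            if (input_dir / "segments.tsv").exists()
            else None
        ),
        "germline": germline_mod.read_candidates_tsv(
            input_dir / "germline_candidates.tsv"
        ),
        "fpkm": pd.read_csv(input_dir / "fpkm.tsv", sep="\t", index_col="gene"),
        "methylation": pd.read_csv(input_dir / "methylation.tsv", sep="\t"),
        "annotations": pd.read_csv(input_dir / "annotations.tsv", sep="\t"),
    }


def overlap_sets(
    sig3: pd.Series, hrd_top: pd.Series, brca1: pd.Series, brca2: pd.Series
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Membership table and intersection counts of the four result sets.

    The inputs are per-sample booleans on a shared index: dominant
    BRCA-like signature, top-HRD class, and the two germline statuses.
    Counts cover each set, each pairwise intersection, and every joint
    membership pattern.
    """
    sets = {"sig3": sig3, "hrd_top": hrd_top, "brca1": brca1, "brca2": brca2}
    idx = None
    for name, s in sets.items():
        s = pd.Series(s)
        idx = s.index if idx is None else idx
        if not s.index.equals(idx):
            raise DataError(f"misaligned sample ids in overlap set {name!r}")
    member = pd.DataFrame({k: pd.Series(v).astype(bool) for k, v in sets.items()})
    counts: dict[str, int] = {k: int(member[k].sum()) for k in sets}
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            counts[f"{a}&{b}"] = int((member[a] & member[b]).sum())
    counts["all_four"] = int(member.all(axis=1).sum())
    pattern = member.apply(
        lambda row: "+".join(k for k in names if row[k]) or "none", axis=1
    )
    for pat, n in pattern.value_counts().items():
        counts[f"pattern:{pat}"] = int(n)
    return member, counts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in dependency order; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        cohort = None
        if config.sim is not None:
            cohort = simulate_cohort(config.sim)
            write_cohort(cohort, outdir / "inputs")
            data = {
                "maf": cohort.maf,
                "reference": cohort.reference,
                "genome": cohort.genome,
                "segments": cohort.segments,
                "germline": cohort.germline_candidates,
                "fpkm": cohort.fpkm,
                "methylation": cohort.methylation,
                "annotations": cohort.annotations,
            }
        elif config.input_dir is not None:
            data = _load_cohort_inputs(Path(config.input_dir))
        else:
            raise ConfigurationError("RunConfig needs either sim or input_dir")

        annotations = data["annotations"].set_index("sample", drop=False)
        all_samples = list(annotations.index)

        stage = "catalog"
        kept = catalog_mod.consensus_filter(data["maf"], config.min_callers)
        cat = catalog_mod.build_catalog(kept, data["reference"], samples=all_samples)
        cat, hyperm = catalog_mod.exclude_hypermutants(cat, config.max_snv)

        stage = "signatures"
        excluded_singletons: list[str] = []
        work = cat
        for _ in range(config.max_singleton_rounds):
            report = extract_signatures(
                work,
                n_restarts=config.n_restarts,
                k_max=config.k_max,
                seed=config.seed,
                quorum=config.quorum,
                singleton_threshold=config.singleton_threshold,
            )
            if not report.singleton_flags:
                break
            drop = sorted({s for _, s, _ in report.singleton_flags})
            excluded_singletons.extend(drop)
            logger.info("singleton signature(s): excluding %s and re-extracting", drop)
            work = work.subset([s for s in work.samples if s not in drop])
        ref_sigs = synthetic_reference_signatures()
        matches = match_to_cosmic(report.consensus, ref_sigs, report_floor=config.match_floor)
        exposures: ExposureTable = report.exposures
        first_sig = assign_first_signature(exposures)
        brca_like = [
            m.extracted_name for m in matches if "COSMIC 3" in m.best_ids
        ]
        sig3_dominant = first_sig.isin(brca_like)

        stage = "scars"
        if data.get("segments") is not None:
            scores = scars_mod.hrd_score_table(data["segments"], data["genome"])
        elif config.imported_hrd_path is not None:
            scores = scars_mod.import_hrd_scores(
                pd.read_csv(config.imported_hrd_path, sep="\t")
            )
        else:
            raise ConfigurationError(
                "no segment table and no imported HRD scores configured"
            )
        scores = scores.set_index("sample")
        hrd_score = scores["hrd_sum"].reindex(all_samples)
        if config.hrd_rule == "top_quantile":
            cls = classify_mod.classify_by_quantile(hrd_score.dropna(), q=config.hrd_q)
        else:
            cls = classify_mod.classify_by_cutoff(hrd_score.dropna(), cutoff=config.hrd_cutoff)
        hrd_class = cls.table.set_index("sample")["is_hrd_top"].reindex(all_samples, fill_value=False)

        stage = "germline"
        survivors, traces = germline_mod.run_cascade(
            data["germline"], max_population_af=config.max_population_af
        )
        surv_by_sample: dict[str, set[str]] = {}
        for v in survivors:
            surv_by_sample.setdefault(v.sample, set()).add(v.gene.upper())
        brca1_g = pd.Series(
            [("BRCA1" in surv_by_sample.get(s, set())) for s in all_samples],
            index=all_samples,
        )
        brca2_g = pd.Series(
            [("BRCA2" in surv_by_sample.get(s, set())) for s in all_samples],
            index=all_samples,
        )

        stage = "silencing"
        sil = silencing_mod.call_silencing_table(
            data["methylation"], data["fpkm"],
            beta_cut=config.beta_cut, fpkm_cut=config.fpkm_cut,
        )
        silenced_by_sample = (
            sil[sil["silenced"]].groupby("sample")["gene"].apply(lambda g: ",".join(sorted(g)))
            if len(sil)
            else pd.Series(dtype=object)
        )

        stage = "stats"
        rps_tab = scars_mod.rps_table(data["fpkm"])
        ifng = stats_mod.ifng_signature(data["fpkm"])
        burden = pd.Series(0, index=all_samples, dtype=int)
        for m in kept:
            if m.variant_classification in catalog_mod.NON_SILENT_CLASSES and m.sample in burden.index:
                burden[m.sample] += 1

        subtype_sig = (
            pd.crosstab(annotations["pam50_subtype"], first_sig.reindex(all_samples))
            if "pam50_subtype" in annotations
            else pd.DataFrame()
        )
        burden_by_subtype_p: dict[str, float] = {}
        if annotations["pam50_subtype"].nunique() >= 3:
            burden_by_subtype_p = stats_mod.one_vs_rest(
                annotations["pam50_subtype"].to_numpy(), burden.to_numpy()
            )
        fit = None
        if brca_like:
            act = exposures.normalized[brca_like[0]].reindex(all_samples).fillna(0.0)
            try:
                fit = stats_mod.burden_activity_fit(
                    burden.to_numpy(dtype=float), act.to_numpy(),
                    activity_floor=config.activity_floor,
                )
            except (DataError, HrdPipeError) as exc:
                logger.warning("burden-activity fit unavailable: %s", exc)

        b1 = [s for s in all_samples if brca1_g[s]]
        b2 = [s for s in all_samples if brca2_g[s]]
        contrasts: dict[str, float] = {}
        degs = None
        if len(b1) >= 2 and len(b2) >= 2:
            for name, series in (
                ("hrd_score", hrd_score),
                ("burden", burden.astype(float)),
                ("ifng", ifng.reindex(all_samples)),
            ):
                x = series.loc[b1].dropna().to_numpy()
                y = series.loc[b2].dropna().to_numpy()
                if len(x) and len(y):
                    _, p = stats_mod.ranksum_test(x, y)
                    contrasts[f"brca1_vs_brca2_{name}_p"] = float(p)
            degs = stats_mod.select_degs(
                data["fpkm"], b1, b2, fc_cut=config.fc_cut, q_cut=config.q_cut
            )
        brca_any = brca1_g | brca2_g
        roc_summaries: dict[str, dict] = {}
        predictors = {
            "hrd_score": hrd_score,
            "rps": rps_tab["rps"].reindex(all_samples),
        }
        if brca_like:
            predictors["sig3_activity"] = exposures.normalized[brca_like[0]].reindex(all_samples)
        for label_name, labels in (("brca1", brca1_g), ("brca1_2", brca_any)):
            if labels.sum() == 0 or labels.sum() == len(labels):
                continue
            rocs = classify_mod.compare_predictors(predictors, labels)
            roc_summaries[label_name] = {
                name: {
                    "auc": r.auc,
                    "best_cutoff": r.best_cutoff,
                    "best_sens": r.best_sens,
                    "best_spec": r.best_spec,
                }
                for name, r in rocs.items()
            }

        stage = "report"
        member, overlap_counts = overlap_sets(
            sig3_dominant.reindex(all_samples, fill_value=False),
            hrd_class,
            brca1_g,
            brca2_g,
        )
        germline_gene_tally = (
            pd.Series([v.gene.upper() for v in survivors]).value_counts().to_dict()
            if survivors
            else {}
        )
        frame = pd.DataFrame(
            {
                "sample": all_samples,
                "pam50_subtype": annotations["pam50_subtype"],
                "brca1_germline": brca1_g,
                "brca2_germline": brca2_g,
                "hrd_score": hrd_score,
                "hrd_class": hrd_class,
                "first_signature": first_sig.reindex(all_samples, fill_value="unassigned"),
                "non_silent_mutation_count": burden,
                "rps": rps_tab["rps"].reindex(all_samples),
                "rps_beta": rps_tab["rps_beta"].reindex(all_samples),
                "ifng_score": ifng.reindex(all_samples),
                "silenced_genes": silenced_by_sample.reindex(all_samples).fillna(""),
            }
        )
        for sig in exposures.normalized.columns:
            frame[f"activity_{sig}"] = exposures.normalized[sig].reindex(all_samples)

        report_dict = {
            "n_samples": len(all_samples),
            "excluded_hypermutants": hyperm,
            "excluded_singletons": excluded_singletons,
            "chosen_k": report.chosen_k,
            "signature_count_votes": {str(k): v for k, v in sorted(report.signature_count_votes.items())},
            "signature_matches": [
                {
                    "extracted": m.extracted_name,
                    "label": m.assigned_label,
                    "best_ids": m.best_ids,
                    "cosines": {k: round(v, 4) for k, v in sorted(
                        m.cosine_similarities.items(), key=lambda kv: -kv[1]
                    )[:3]},
                }
                for m in matches
            ],
            "hrd_rule": cls.rule,
            "hrd_threshold": cls.threshold,
            "n_hrd": int(hrd_class.sum()),
            "subtype_by_first_signature": {
                str(k): {str(c): int(x) for c, x in row.items()}
                for k, row in subtype_sig.iterrows()
            },
            "burden_by_subtype_p": burden_by_subtype_p,
            "burden_activity_fit": dataclasses.asdict(fit) if fit else None,
            "overlap_counts": overlap_counts,
            "germline_survivor_genes": germline_gene_tally,
            "n_silenced_events": int(sil["silenced"].sum()) if len(sil) else 0,
            "contrasts": contrasts,
            "n_degs_selected": int(degs["selected"].sum()) if degs is not None else None,
            "roc": roc_summaries,
        }

        # --- write artifacts
        frame.to_csv(outdir / "cohort_frame.tsv", sep="\t", index=False, float_format="%.6g")
        exposures.normalized.to_csv(
            outdir / "exposures.tsv", sep="\t", float_format="%.6g", index_label="sample"
        )
        report.consensus.to_tsv(outdir / "signatures.tsv")
        scores.to_csv(outdir / "hrd_scores.tsv", sep="\t", float_format="%.6g")
        sil.to_csv(outdir / "silencing_calls.tsv", sep="\t", index=False, float_format="%.6g")
        germline_mod.write_candidates_tsv(survivors, outdir / "germline_survivors.tsv")
        germline_mod.write_traces_tsv(traces, outdir / "germline_traces.tsv")
        member.to_csv(outdir / "overlap_membership.tsv", sep="\t", index_label="sample")
        if degs is not None:
            degs.to_csv(outdir / "degs.tsv", sep="\t", float_format="%.6g")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report_dict, fh, indent=1, sort_keys=True)
            fh.write("\n")
        manifest = {
            p.name: _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except HrdPipeError as exc:
        raise HrdPipeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return PipelineResult(cohort_frame=frame, report=report_dict, outdir=outdir, cohort=cohort)
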