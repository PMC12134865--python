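"""End-to-end orchestration: simulate -> differential stats -> signature
-> connectivity -> shortlist, with every intermediate written to disk
and a manifest recording the exact configuration, seeds, and per-stage
feature counts (the selection funnel)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import sigrev
from sigrev import io as sio
from sigrev.connectivity import per_partition_frame, query, rank_drugs
from sigrev.diffexpr import (
    SelectionRule,
    proteomic_stats,
    select_degs,
    stats_frame,
    transcriptomic_stats,
)
from sigrev.shortlist import apply_shortlist
from sigrev.signature import consolidate, partition
from sigrev.synth import (
    CohortSpec,
    ReferenceSpec,
    gen_annotations,
    gen_literature_features,
    gen_proteomic_cohort,
    gen_reference,
    gen_transcriptomic_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "diff_expr", "signature", "connectivity", "shortlist")


class PipelineError(RuntimeError):
    """Stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully serializable run configuration.

    The single ``seed`` drives every stage; per-stage seeds are derived
    from it with fixed small offsets so stages stay independently
    reproducible.
    """

    seed: int = 0
    # cohort generation
    n_group1: int = 20
    n_group2: int = 20
    n_features_transcriptomic: int = 1000
    n_features_proteomic: int = 600
    frac_shifted: float = 0.1
    effect_size: float = 1.5
    missing_rate: float = 0.2
    platform_corr: float = 0.8
    n_literature: int = 40
    frac_contradictory: float = 0.1
    # selection thresholds
    alpha: float = 0.05
    adjust_method: str = "BH"
    auc_min: float = 0.6
    detect_min: float = 0.10
    # connectivity
    n_drugs: int = 50
    n_genes: int = 2000
    n_reversers: int = 3
    n_mimics: int = 2
    reversal_strength: float = 3.0
    K: int = 10
    B: int = 1000
    score_variant: str = "ks"
    stratify_partition: bool = False
    threads: int = 1

    def validate(self) -> None:
        if self.score_variant != "ks":
            raise ValueError(
                f"unknown score_variant {self.score_variant!r}; available: 'ks'"
            )
        if self.K < 1 or self.B < 100:
            raise ValueError("require K >= 1 and B >= 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages, write intermediates, and return the manifest."""
    config.validate()
    out = sio.ensure_dir(outdir)
    manifest: dict = {
        "package": "sigrev",
        "version": sigrev.__version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, counts: dict, files: dict) -> None:
        manifest["stages"].append({"stage": stage, "counts": counts})
        manifest["outputs"].update(files)
        log.info("stage %s done: %s", stage, counts)

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        tspec = CohortSpec(
            n_group1=config.n_group1, n_group2=config.n_group2,
            n_features=config.n_features_transcriptomic,
            frac_shifted=config.frac_shifted, effect_size=config.effect_size,
            seed=config.seed,
        )
        pspec = CohortSpec(
            n_group1=config.n_group1, n_group2=config.n_group2,
            n_features=config.n_features_proteomic,
            frac_shifted=config.frac_shifted, effect_size=config.effect_size,
            missing_rate=config.missing_rate, platform_corr=config.platform_corr,
            seed=config.seed + 1,
        )
        tmat, t_truth = gen_transcriptomic_cohort(tspec)
        pmat_a, pmat_b, p_truth = gen_proteomic_cohort(pspec)
        lit = gen_literature_features(
            min(config.n_literature, len(t_truth)),
            config.frac_contradictory, t_truth, seed=config.seed + 2,
        )
        sio.write_omics(tmat, out / "transcriptomics.tsv", out / "groups.tsv")
        sio.write_omics(pmat_a, out / "proteomics_a.tsv", out / "groups_proteomics.tsv")
        sio.write_matrix(pmat_b.values, out / "proteomics_b.tsv")
        sio.write_table(t_truth, out / "truth_transcriptomic.tsv")
        sio.write_table(p_truth, out / "truth_proteomic.tsv")
        sio.write_table(lit, out / "literature.tsv")
        record(stage, {
            "transcriptomic_features": tspec.n_features,
            "proteomic_features": pspec.n_features,
            "planted_transcriptomic": len(t_truth),
            "planted_proteomic": len(p_truth),
            "literature_entries": len(lit),
        }, {
            "transcriptomics": str(out / "transcriptomics.tsv"),
            "literature": str(out / "literature.tsv"),
        })
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc

    # ---- differential statistics ---------------------------------------
    stage = "diff_expr"
    try:
        rule = SelectionRule(
            alpha=config.alpha, adjust_method=config.adjust_method,
            auc_min=config.auc_min, detect_min=config.detect_min,
        )
        tstats = transcriptomic_stats(tmat, adjust_method=config.adjust_method)
        degs = select_degs(tstats, rule)
        pstats, daps, p_excl = proteomic_stats(pmat_a, pmat_b, rule)
        tframe = stats_frame(tstats)
        pframe = stats_frame(pstats)
        sio.write_table(tframe, out / "transcriptomic_stats.tsv")
        sio.write_table(pframe, out / "proteomic_stats.tsv")
        sio.write_table(p_excl, out / "proteomic_exclusions.tsv")
        direction = {s.feature_id: s.direction for s in tstats}
        deg_signed = [(f, direction[f]) for f in degs]
        pdirection = {s.feature_id: s.direction for s in pstats}
        dap_signed = [(f, pdirection[f]) for f in daps]
        record(stage, {
            "features_tested_transcriptomic": len(tstats),
            "degs_selected": len(degs),
            "features_tested_proteomic": len(pstats),
            "daps_selected": len(daps),
        }, {"transcriptomic_stats": str(out / "transcriptomic_stats.tsv")})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- signature ------------------------------------------------------
    stage = "signature"
    try:
        lit_signed = list(zip(lit["feature_id"], lit["direction"]))
        sig = consolidate(deg_signed, dap_signed, lit_signed)
        if len(sig) == 0:
            raise ValueError("consolidated signature is empty")
        sio.signature_to_gmt(sig, out / "signature.gmt")
        sio.write_table(sig.to_frame(), out / "signature.tsv")
        sio.write_table(sig.exclusions_frame(), out / "signature_exclusions.tsv")
        K = min(config.K, len(sig))
        part = partition(sig, K, seed=config.seed + 3, stratify=config.stratify_partition)
        record(stage, {
            "signature_entries": len(sig),
            "signature_up": len(sig.up_ids),
            "signature_down": len(sig.down_ids),
            "excluded_conflicts": len(sig.excluded),
            "partitions": K,
        }, {"signature": str(out / "signature.gmt")})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- connectivity ---------------------------------------------------
    stage = "connectivity"
    try:
        rspec = ReferenceSpec(
            n_drugs=config.n_drugs, n_genes=config.n_genes,
            n_reversers=config.n_reversers, n_mimics=config.n_mimics,
            reversal_strength=config.reversal_strength, seed=config.seed + 4,
        )
        # the synthetic reference universe must contain the signature genes
        ref, labels = gen_reference(rspec, sig)
        sio.write_reference(ref, out / "reference.tsv")
        sio.write_table(labels, out / "reference_labels.tsv")
        results = query(part, ref, B=config.B, seed=config.seed + 5)
        ranked = rank_drugs(results, alpha=config.alpha)
        sio.write_table(ranked, out / "connectivity_ranked.tsv")
        sio.write_table(per_partition_frame(results), out / "connectivity_per_partition.tsv")
        record(stage, {
            "drugs_scored": len(ranked),
            "significant_reversers": int(ranked["significant"].sum()),
        }, {"connectivity_ranked": str(out / "connectivity_ranked.tsv")})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- shortlist ------------------------------------------------------
    stage = "shortlist"
    try:
        ann = gen_annotations(ref.drug_ids, labels, seed=config.seed + 6)
        sio.write_table(ann, out / "annotations.tsv")
        candidates, rejections = apply_shortlist(ranked, ann)
        sio.write_table(candidates, out / "shortlist.tsv")
        sio.write_table(rejections, out / "shortlist_rejections.tsv")
        record(stage, {
            "candidates": len(candidates),
            "rejected": len(rejections),
        }, {"shortlist": str(out / "shortlist.tsv")})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def load_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
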