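"""End-to-end pipeline orchestration with seeded reproducibility.

Stages run in dependency order — simulate, de, enrich, signalnet, targets,
build, validate — each writing its outputs under its own subdirectory of the
output directory.  A manifest (``manifest.json``) records a SHA-256 content
hash for every output file, so two runs with the same seed and inputs can be
compared bitwise.  One global seed fans out to per-stage seeds by stable
hashing of the stage name, making each stage's randomness independent of
execution order.  A stage failure aborts downstream stages with an error
naming the stage; outputs of completed stages are left intact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cernanet import (
    cerna_network,
    clinical_validation,
    diffexpr,
    enrichment,
    io_formats,
    signalnet,
    synthetic_data,
    target_prediction,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "enrich", "signalnet", "targets", "build", "validate")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "cerna_out"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    class_rules: dict | None = None
    enrich_max_p: float = 0.05
    enrich_max_fdr: float = 0.05
    min_classes: tuple[str, str] = ("7mer-m8", "8mer")
    corr_max_p: float = 0.05
    endpoint: str = "OS"
    stages: dict = field(default_factory=dict)  # stage -> bool toggle

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "min_classes" in raw:
            raw["min_classes"] = tuple(raw["min_classes"])
        cfg = cls(**raw)
        for stage in cfg.stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage toggle {stage!r}")
        return cfg

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    state: dict = {}

    def record(stage: str, path: Path) -> None:
        manifest.setdefault(stage, {})[str(path.relative_to(out))] = _sha256(path)

    plan = [s for s in STAGES if config.enabled(s)]
    logger.info("pipeline stages: %s (seed=%d)", plan, config.seed)
    for stage in plan:
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            _STAGE_FUNCS[stage](config, state, stage_dir, record)
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise StageError(stage, exc) from exc
        logger.info("stage %s: applied thresholds %s", stage, state.get(f"{stage}_thresholds", {}))

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, state: dict, stage_dir: Path, record) -> None:
    sim_kwargs = dict(config.sim)
    if "samples_per_cohort" in sim_kwargs:
        sim_kwargs["samples_per_cohort"] = tuple(sim_kwargs["samples_per_cohort"])
    sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
    sim = synthetic_data.SimulationConfig(**sim_kwargs)
    bundle = synthetic_data.generate(sim)
    state["bundle"] = bundle
    state["simulate_thresholds"] = {"seed": sim.seed}

    io_formats.write_sample_sheet(bundle.mrna.samples, stage_dir / "samples.tsv")
    for name, mat in (("mrna", bundle.mrna), ("lncrna", bundle.lncrna), ("mirna", bundle.mirna)):
        io_formats.write_expression(mat, stage_dir / f"{name}.tsv")
    io_formats.write_fasta(bundle.mirna_seqs, stage_dir / "mirna.fa")
    io_formats.write_fasta(bundle.transcript_seqs, stage_dir / "transcripts.fa")
    io_formats.write_gmt(bundle.go_sets, stage_dir / "go.gmt")
    io_formats.write_gmt(bundle.kegg_sets, stage_dir / "kegg.gmt")
    io_formats.write_relations(bundle.relations, stage_dir / "relations.tsv")
    io_formats.write_clinical(bundle.clinical, stage_dir / "clinical.tsv")
    with open(stage_dir / "truth.json", "w") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=2, sort_keys=True)
    for f in sorted(stage_dir.iterdir()):
        record("simulate", f)


def _stage_de(config: PipelineConfig, state: dict, stage_dir: Path, record) -> None:
    bundle = state["bundle"]
    per_class_intersections = {}
    de_frames = []
    for name, mat in (("mRNA", bundle.mrna), ("lncRNA", bundle.lncrna), ("miRNA", bundle.mirna)):
        per_cohort = {}
        for cohort in mat.cohorts:
            records = diffexpr.run_de(mat, cohort=cohort)
            selected = diffexpr.select_de(records, config.class_rules)
            per_cohort[cohort] = selected
            de_frames.append(records)
        intersected, venn = diffexpr.intersect_de(per_cohort)
        per_class_intersections[name] = intersected
        logger.info("%s: %d intersecting DE features; venn=%s", name, len(intersected), venn)
    all_de = pd.concat(de_frames, ignore_index=True)
    all_de.to_csv(stage_dir / "de_records.tsv", sep="\t", index=False, float_format="%.10g")
    combined = pd.concat(per_class_intersections.values(), ignore_index=True)
    combined.to_csv(stage_dir / "intersected.tsv", sep="\t", index=False)
    state["de"] = per_class_intersections
    state["de_thresholds"] = {"class_rules": config.class_rules or diffexpr.DEFAULT_CLASS_RULES}
    record("de", stage_dir / "de_records.tsv")
    record("de", stage_dir / "intersected.tsv")


def _stage_enrich(config: PipelineConfig, state: dict, stage_dir: Path, record) -> None:
    bundle = state["bundle"]
    degs = state["de"]["mRNA"]
    flagged = set(degs["feature_id"])
    universe = set(bundle.mrna.feature_ids)
    go_res = enrichment.enrich(flagged, universe, bundle.go_sets)
    kegg_res = enrichment.enrich(flagged, universe, bundle.kegg_sets)
    directions = dict(zip(degs["feature_id"], degs["direction"]))
    pool = enrichment.significant_term_gene_union(
        go_res,
        kegg_res,
        flagged,
        bundle.go_sets,
        bundle.kegg_sets,
        max_p=config.enrich_max_p,
        max_fdr=config.enrich_max_fdr,
        directions=directions,
    )
    go_res.to_csv(stage_dir / "go_enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    kegg_res.to_csv(stage_dir / "kegg_enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    pool.to_csv(stage_dir / "functional_degs.tsv", sep="\t", index=False)
    state["functional_degs"] = pool
    state["enrich_thresholds"] = {"max_p": config.enrich_max_p, "max_fdr": config.enrich_max_fdr}
    for f in ("go_enrichment.tsv", "kegg_enrichment.tsv", "functional_degs.tsv"):
        record("enrich", stage_dir / f)


def _functional_deg_pool(state: dict) -> pd.DataFrame:
    # when enrichment is toggled off, the ceRNA stage consumes all intersected DEGs
    if "functional_degs" in state:
        return state["functional_degs"]
    degs = state["de"]["mRNA"]
    return degs[["feature_id", "direction"]].copy()


def _stage_signalnet(config: PipelineConfig, state: dict, stage_dir: Path, record) -> None:
    bundle = state["bundle"]
    members = set(_functional_deg_pool(state)["feature_id"])
    net = signalnet.build_signalnet(bundle.relations, members) if members else None
    if net is None:
        raise ValueError("no members for the signal network")
    metrics = signalnet.node_metrics(net)
    metrics.to_csv(stage_dir / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
    io_formats.write_network(net.undirected, stage_dir / "signalnet.graphml")
    state["signalnet"] = net
    state["signalnet_thresholds"] = {"members": len(members)}
    record("signalnet", stage_dir / "metrics.tsv")
    record("signalnet", stage_dir / "signalnet.graphml")


def _stage_targets(config: PipelineConfig, state: dict, stage_dir: Path, record) -> None:
    bundle = state["bundle"]
    dems = set(state["de"]["miRNA"]["feature_id"])
    dels = set(state["de"]["lncRNA"]["feature_id"])
    degs = set(_functional_deg_pool(state)["feature_id"])
    if not dems:
        raise ValueError("no intersecting differentially expressed miRNAs to predict targets for")
    mirnas = io_formats.SequenceSet(
        records={m: bundle.mirna_seqs[m] for m in sorted(dems)}, moltype="miRNA"
    )
    lnc_seqs = io_formats.SequenceSet(
        records={t: bundle.transcript_seqs[t] for t in sorted(dels)}, moltype="transcript"
    )
    m_seqs = io_formats.SequenceSet(
        records={t: bundle.transcript_seqs[t] for t in sorted(degs)}, moltype="transcript"
    )
    lo, hi = config.min_classes
    pairs_lnc = target_prediction.intersect_predictions(
        target_prediction.predict_pairs(mirnas, lnc_seqs, min_class=lo),
        target_prediction.predict_pairs(mirnas, lnc_seqs, min_class=hi),
    )
    pairs_m = target_prediction.intersect_predictions(
        target_prediction.predict_pairs(mirnas, m_seqs, min_class=lo),
        target_prediction.predict_pairs(mirnas, m_seqs, min_class=hi),
    )
    target_prediction.pairs_to_frame(pairs_lnc).to_csv(stage_dir / "pairs_mi_lnc.tsv", sep="\t", index=False)
    target_prediction.pairs_to_frame(pairs_m).to_csv(stage_dir / "pairs_mi_mrna.tsv", sep="\t", index=False)
    state["pairs_mi_lnc"] = pairs_lnc
    state["pairs_mi_m"] = pairs_m
    state["targets_thresholds"] = {"min_classes": list(config.min_classes)}
    record("targets", stage_dir / "pairs_mi_lnc.tsv")
    record("targets", stage_dir / "pairs_mi_mrna.tsv")


def _stage_build(config: PipelineConfig, state: dict, stage_dir: Path, record) -> None:
    bundle = state["bundle"]
    pool = _functional_deg_pool(state)
    de_records = pd.concat(
        [
            pool.assign(feature_class="mRNA")[["feature_id", "feature_class", "direction"]],
            state["de"]["lncRNA"][["feature_id", "feature_class", "direction"]],
            state["de"]["miRNA"][["feature_id", "feature_class", "direction"]],
        ],
        ignore_index=True,
    )
    net = cerna_network.build_cerna(
        de_records,
        state["pairs_mi_m"],
        state["pairs_mi_lnc"],
        {"mRNA": bundle.mrna, "lncRNA": bundle.lncrna, "miRNA": bundle.mirna},
        max_p=config.corr_max_p,
    )
    net.edges.to_csv(stage_dir / "edges.tsv", sep="\t", index=False, float_format="%.10g")
    net.triplets.to_csv(stage_dir / "triplets.tsv", sep="\t", index=False, float_format="%.10g")
    io_formats.write_network(net.graph, stage_dir / "cerna.graphml")
    summary = cerna_network.summarize_network(net)
    with open(stage_dir / "summary.json", "w") as fh:
        json.dump({k: v for k, v in summary.items() if k != "degree"}, fh, indent=2, sort_keys=True)
    metrics = synthetic_data.truth_report(bundle.truth, net)
    with open(stage_dir / "recovery.json", "w") as fh:
        json.dump(
            {
                "precision": metrics.precision,
                "recall": metrics.recall,
                "f1": metrics.f1,
                "n_true": metrics.n_true,
                "n_inferred": metrics.n_inferred,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    state["cerna"] = net
    state["build_thresholds"] = {"corr_max_p": config.corr_max_p}
    for f in ("edges.tsv", "triplets.tsv", "cerna.graphml", "summary.json", "recovery.json"):
        record("build", stage_dir / f)


def _stage_validate(config: PipelineConfig, state: dict, stage_dir: Path, record) -> None:
    bundle = state["bundle"]
    net = state["cerna"]
    clin = bundle.clinical.endpoint_frame(config.endpoint)
    features = sorted(
        set(net.nodes.query("feature_class == 'lncRNA'")["feature_id"]) | set(bundle.truth.hazard_betas)
    )
    if not features:
        raise ValueError("no lncRNA features to validate")
    expr = pd.concat([bundle.lncrna.subset_condition("tumor").values,
                      bundle.mrna.subset_condition("tumor").values,
                      bundle.mirna.subset_condition("tumor").values])
    features = [f for f in features if f in expr.index]
    report = clinical_validation.validate_features(expr, clin, features, endpoint=config.endpoint)
    report.to_csv(stage_dir / "validation.tsv", sep="\t", index=False, float_format="%.10g")
    state["validation"] = report
    state["validate_thresholds"] = {"endpoint": config.endpoint}
    record("validate", stage_dir / "validation.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "enrich": _stage_enrich,
    "signalnet": _stage_signalnet,
    "targets": _stage_targets,
    "build": _stage_build,
    "validate": _stage_validate,
}
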