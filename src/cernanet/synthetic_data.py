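"""Multi-cohort synthetic data with planted, recoverable ground truth.

The generator emulates the structure of multi-cohort tumor/normal microarray
studies: several cohorts measured on shared mRNA/lncRNA/miRNA feature
panels, a minority of truly differentially expressed features with tumor
mean shifts on the log2 scale, ceRNA triplets realized through a latent
per-tumor-sample miRNA activity (so miRNA-lncRNA and miRNA-mRNA correlate
negatively and lncRNA-mRNA positively), target sequences carrying embedded
8mer seed sites for the planted pairs (decoys are scrubbed of canonical
sites), gene sets enriched for the planted DE genes, a relation table with
a planted hub, and exponential survival whose hazard is tied to configured
features.  All randomness flows from ``config.seed``; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from cernanet.io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    Relation,
    RelationTable,
    SampleInfo,
    SequenceSet,
)
from cernanet.target_prediction import reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror a multi-cohort tumor/normal microarray design of roughly
    99 tumors vs 24 normals split over three cohorts, ~10% truly DE features
    with an 8-fold (3 log2 units) mean shift — intersecting screen survivors
    in such studies show fold changes far above the FC > 2 gate — unit log2
    noise, ten planted triplets with sponge strength 2, and 30%
    administrative censoring.
    """

    n_cohorts: int = 3
    samples_per_cohort: tuple[int, int] = (33, 8)  # (n_tumor, n_normal)
    n_mRNA: int = 800
    n_lncRNA: int = 200
    n_miRNA: int = 100
    de_fraction: float = 0.1
    effect_log2fc: float = 3.0
    noise_sd: float = 1.0
    n_triplets: int = 10
    sponge_strength: float = 2.0
    censor_fraction: float = 0.3
    hazard_betas: dict[str, float] | None = None
    mirna_length: int = 22
    transcript_length: int = 300
    site_class: str = "8mer"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cohorts,
            *self.samples_per_cohort,
            self.n_mRNA,
            self.n_lncRNA,
            self.n_miRNA,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all design counts must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        if not (0.0 <= self.censor_fraction < 1.0):
            raise ValueError("censor_fraction must lie in [0, 1)")
        if self.effect_log2fc < 0 or self.noise_sd <= 0 or self.sponge_strength < 0:
            raise ValueError("effect_log2fc >= 0, noise_sd > 0, sponge_strength >= 0 required")
        if self.n_triplets > min(self.n_mRNA, self.n_lncRNA, self.n_miRNA):
            raise ValueError("n_triplets exceeds available features in some class")
        if self.site_class not in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
            raise ValueError(f"unknown site_class {self.site_class!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    de_features: dict[str, str]  # feature_id -> planted direction {up, down}
    triplets: list[tuple[str, str, str]]  # (lncRNA, miRNA, mRNA)
    target_pairs: dict[tuple[str, str], str]  # (miRNA, target) -> embedded site class
    hazard_betas: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "de_features": self.de_features,
            "triplets": [list(t) for t in self.triplets],
            "target_pairs": {f"{m}|{t}": c for (m, t), c in self.target_pairs.items()},
            "hazard_betas": self.hazard_betas,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            de_features=dict(d["de_features"]),
            triplets=[tuple(t) for t in d["triplets"]],
            target_pairs={tuple(k.split("|")): v for k, v in d["target_pairs"].items()},
            hazard_betas=dict(d["hazard_betas"]),
        )


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces."""

    config: SimulationConfig
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    mirna_seqs: SequenceSet
    transcript_seqs: SequenceSet
    go_sets: GeneSetCollection
    kegg_sets: GeneSetCollection
    relations: RelationTable
    clinical: ClinicalTable
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _sample_sheet(config: SimulationConfig) -> list[SampleInfo]:
    samples = []
    n_t, n_n = config.samples_per_cohort
    for c in range(1, config.n_cohorts + 1):
        cohort = f"C{c}"
        for i in range(1, n_t + 1):
            samples.append(SampleInfo(f"{cohort}T{i:03d}", "tumor", cohort))
        for i in range(1, n_n + 1):
            samples.append(SampleInfo(f"{cohort}N{i:03d}", "normal", cohort))
    return samples


def _expression(
    rng: np.random.Generator,
    ids: list[str],
    fclass: str,
    samples: list[SampleInfo],
    de_dir: Mapping[str, str],
    effect: float,
    noise_sd: float,
) -> ExpressionMatrix:
    n_f, n_s = len(ids), len(samples)
    baseline = rng.uniform(6.0, 12.0, size=n_f)
    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_f, n_s))
    tumor = np.array([s.condition == "tumor" for s in samples])
    for i, fid in enumerate(ids):
        d = de_dir.get(fid)
        if d is not None:
            x[i, tumor] += effect if d == "up" else -effect
    df = pd.DataFrame(x, index=ids, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(values=df, feature_class=pd.Series(fclass, index=ids), samples=samples)


def _scrub_sites(rng: np.random.Generator, seq: np.ndarray, cores: set[str], max_rounds: int = 300) -> np.ndarray:
    """Mutate a sequence (char array) until it contains no 6mer seed core."""
    for _ in range(max_rounds):
        s = "".join(seq)
        hit = next((j for j in range(len(s) - 5) if s[j : j + 6] in cores), None)
        if hit is None:
            return seq
        pos = hit + 2
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    raise RuntimeError("could not scrub seed cores from decoy sequence")


def _site_sequence(mirna: str, site_class: str) -> str:
    seed28 = reverse_complement(mirna[1:8])
    seed27 = reverse_complement(mirna[1:7])
    return {
        "8mer": seed28 + "A",
        "7mer-m8": seed28,
        "7mer-A1": seed27 + "A",
        "6mer": seed27,
    }[site_class]


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def generate(config: SimulationConfig) -> SyntheticBundle:
    """Generate one complete synthetic study from ``config``."""
    rng = np.random.default_rng(config.seed)
    mrna_ids = [f"G{i:04d}" for i in range(1, config.n_mRNA + 1)]
    lnc_ids = [f"L{i:04d}" for i in range(1, config.n_lncRNA + 1)]
    mir_ids = [f"mir{i:04d}" for i in range(1, config.n_miRNA + 1)]
    samples = _sample_sheet(config)

    # -- plant triplets first (members are DE by construction), then fill the
    #    per-class DE quota with free features
    trip_lnc = list(rng.choice(lnc_ids, size=config.n_triplets, replace=False)) if config.n_triplets else []
    trip_mir = list(rng.choice(mir_ids, size=config.n_triplets, replace=False)) if config.n_triplets else []
    trip_m = list(rng.choice(mrna_ids, size=config.n_triplets, replace=False)) if config.n_triplets else []
    triplets = list(zip(trip_lnc, trip_mir, trip_m))

    de_dir: dict[str, str] = {}
    for lnc, mir, m in triplets:
        d_mir = "up" if rng.random() < 0.5 else "down"
        d_part = "down" if d_mir == "up" else "up"
        de_dir[mir] = d_mir
        de_dir[lnc] = d_part
        de_dir[m] = d_part
    for ids in (mrna_ids, lnc_ids, mir_ids):
        quota = int(round(config.de_fraction * len(ids)))
        pool = [f for f in ids if f not in de_dir]
        extra = max(0, quota - (len(ids) - len(pool)))
        for fid in rng.choice(pool, size=min(extra, len(pool)), replace=False):
            de_dir[fid] = "up" if rng.random() < 0.5 else "down"

    # -- expression: baseline + DE shift + triplet latent activity + noise
    mrna = _expression(rng, mrna_ids, "mRNA", samples, de_dir, config.effect_log2fc, config.noise_sd)
    lncrna = _expression(rng, lnc_ids, "lncRNA", samples, de_dir, config.effect_log2fc, config.noise_sd)
    mirna = _expression(rng, mir_ids, "miRNA", samples, de_dir, config.effect_log2fc, config.noise_sd)
    tumor_mask = np.array([s.condition == "tumor" for s in samples])
    n_tumor = int(tumor_mask.sum())
    for lnc, mir, m in triplets:
        activity = rng.normal(0.0, 1.0, size=n_tumor)  # latent miRNA activity per tumor sample
        mirna.values.loc[mir, tumor_mask] += activity
        lncrna.values.loc[lnc, tumor_mask] -= config.sponge_strength * activity
        mrna.values.loc[m, tumor_mask] -= config.sponge_strength * activity

    # -- sequences: random miRNAs; decoy transcripts scrubbed of every seed
    #    core; planted pairs get one embedded site
    mir_seqs = {}
    for mid in mir_ids:
        mir_seqs[mid] = "".join(_BASES[rng.integers(4, size=config.mirna_length)])
    cores = {reverse_complement(seq[1:7]) for seq in mir_seqs.values()}
    tx_arr: dict[str, np.ndarray] = {}
    for tid in lnc_ids + mrna_ids:
        arr = _BASES[rng.integers(4, size=config.transcript_length)].copy()
        tx_arr[tid] = _scrub_sites(rng, arr, cores)
    target_pairs: dict[tuple[str, str], str] = {}
    for lnc, mir, m in triplets:
        site = _site_sequence(mir_seqs[mir], config.site_class)
        for tid in (lnc, m):
            pos = int(rng.integers(10, config.transcript_length - len(site) - 10))
            tx_arr[tid][pos : pos + len(site)] = list(site)
            target_pairs[(mir, tid)] = config.site_class
    mirna_seqs = SequenceSet(records=mir_seqs, moltype="miRNA")
    transcript_seqs = SequenceSet(records={t: "".join(a) for t, a in tx_arr.items()}, moltype="transcript")

    # -- gene sets: background sets plus sets enriched for DE mRNAs
    de_mrna = [f for f in mrna_ids if f in de_dir]
    go_sets = _gene_sets(rng, "GO", 30, 8, mrna_ids, de_mrna)
    kegg_sets = _gene_sets(rng, "PATH", 15, 5, mrna_ids, de_mrna)

    # -- relation table among mRNAs with one planted hub
    relations, _hub = _relations(rng, mrna_ids, de_mrna)

    # -- clinical: exponential survival tied to hazard features
    betas = dict(config.hazard_betas) if config.hazard_betas else {}
    if not betas and triplets:
        betas = {triplets[0][0]: 0.7}  # default: first planted lncRNA is harmful
    clinical = _clinical(rng, config, {**_stack_tumor(mrna, lncrna, mirna, tumor_mask)}, betas)

    truth = SyntheticTruth(
        de_features=dict(sorted(de_dir.items())),
        triplets=triplets,
        target_pairs=target_pairs,
        hazard_betas=betas,
    )
    logger.info(
        "simulated %d cohorts, %d features, %d planted DE, %d triplets",
        config.n_cohorts,
        len(mrna_ids) + len(lnc_ids) + len(mir_ids),
        len(de_dir),
        len(triplets),
    )
    return SyntheticBundle(
        config=config,
        mrna=mrna,
        lncrna=lncrna,
        mirna=mirna,
        mirna_seqs=mirna_seqs,
        transcript_seqs=transcript_seqs,
        go_sets=go_sets,
        kegg_sets=kegg_sets,
        relations=relations,
        clinical=clinical,
        truth=truth,
    )


def _gene_sets(
    rng: np.random.Generator,
    prefix: str,
    n_sets: int,
    n_enriched: int,
    universe: list[str],
    de_pool: list[str],
    set_size: int = 25,
    de_share: float = 0.8,
) -> GeneSetCollection:
    sets = {}
    for i in range(1, n_sets + 1):
        set_id = f"{prefix}{i:04d}"
        if i <= n_enriched and de_pool:
            k_de = min(int(round(de_share * set_size)), len(de_pool))
            members = list(rng.choice(de_pool, size=k_de, replace=False))
            rest = [g for g in universe if g not in set(members)]
            members += list(rng.choice(rest, size=set_size - k_de, replace=False))
        else:
            members = list(rng.choice(universe, size=set_size, replace=False))
        sets[set_id] = (f"synthetic set {set_id}", tuple(members))
    return GeneSetCollection(sets=sets)


def _relations(
    rng: np.random.Generator, mrna_ids: list[str], de_mrna: list[str]
) -> tuple[RelationTable, str | None]:
    labels = ["activation", "inhibition", "phosphorylation", "expression"]
    edges = []
    for src in mrna_ids:
        for tgt in rng.choice(mrna_ids, size=2, replace=False):
            if tgt != src:
                edges.append(Relation(src, tgt, labels[rng.integers(len(labels))], 1.0, True))
    hub = None
    if len(de_mrna) >= 10:
        hub = de_mrna[0]
        spokes = [g for g in de_mrna[1:] if g != hub][:30]
        for tgt in spokes:
            edges.append(Relation(hub, tgt, "activation", 1.0, True))
    return RelationTable(edges=edges), hub


def _stack_tumor(mrna, lncrna, mirna, tumor_mask) -> dict[str, np.ndarray]:
    out = {}
    for mat in (mrna, lncrna, mirna):
        arr = mat.values.to_numpy()[:, tumor_mask]
        for i, fid in enumerate(mat.feature_ids):
            out[fid] = arr[i]
    return out


def _clinical(
    rng: np.random.Generator,
    config: SimulationConfig,
    tumor_expr: dict[str, np.ndarray],
    betas: dict[str, float],
    baseline_hazard: float = np.log(2) / 30.0,  # median ~30 months at zero linear predictor
) -> ClinicalTable:
    samples = _sample_sheet(config)
    patients = [s.sample_id for s in samples if s.condition == "tumor"]
    n = len(patients)
    lp = np.zeros(n)
    for fid, beta in betas.items():
        if fid not in tumor_expr:
            raise ValueError(f"hazard feature {fid!r} not among simulated features")
        x = tumor_expr[fid]
        z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        lp += beta * z
    lam = baseline_hazard * np.exp(lp)
    t_true = rng.exponential(1.0 / lam)
    # administrative censoring at a cutoff calibrated to the target fraction
    if config.censor_fraction > 0:
        cutoff = float(np.quantile(t_true, 1.0 - config.censor_fraction))
    else:
        cutoff = float(t_true.max())
    event = (t_true <= cutoff).astype(int)
    time = np.minimum(t_true, cutoff)
    time = np.maximum(time, 1e-6)
    age = rng.integers(35, 80, size=n)
    df = pd.DataFrame(
        {
            "patient_id": patients,
            "time": time,
            "event": event,
            "endpoint": "OS",
            "age": age,
        }
    )
    return ClinicalTable(data=df)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float
    n_true: int
    n_inferred: int
    n_recovered: int
    precision_defined: bool = True


def truth_report(truth: SyntheticTruth, inferred) -> RecoveryMetrics:
    """Triplet-level recovery of planted truth by an inferred ceRNA network.

    A planted triplet counts as recovered iff the identical
    (lncRNA, miRNA, mRNA) triple appears among the inferred triplets (which
    entails all three members and both miRNA-centered edges being present).
    Empty inference yields recall 0 and precision reported as 0 with
    ``precision_defined=False``.
    """
    true_set = set(truth.triplets)
    inferred_set = {
        (row["lncRNA_id"], row["miRNA_id"], row["mRNA_id"]) for _, row in inferred.triplets.iterrows()
    }
    for trip in inferred_set:
        for fid in trip:
            if not any(fid.startswith(p) for p in ("G", "L", "mir")):
                raise ValueError(f"inferred feature {fid!r} outside the synthetic namespace")
    recovered = true_set & inferred_set
    n_true, n_inf, n_rec = len(true_set), len(inferred_set), len(recovered)
    recall = n_rec / n_true if n_true else 0.0
    if n_inf == 0:
        precision, defined = 0.0, False
    else:
        precision, defined = n_rec / n_inf, True
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        n_true=n_true,
        n_inferred=n_inf,
        n_recovered=n_rec,
        precision_defined=defined,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["samples_per_cohort"] = list(config.samples_per_cohort)
    return d
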