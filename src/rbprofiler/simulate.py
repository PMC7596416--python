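"""Synthetic probe-level microarray cohorts with a ground-truth record.

The generator emulates the structure of a three-group airway-epithelium
brushing cohort (non-smokers, smokers, COPD; 12/12/6 by default) profiled
on a multi-probe array:

* a log2-normal intensity model — per-gene baseline, per-probe offset,
  per-observation noise;
* a planted disease effect of fixed log2 magnitude on a subset of census
  (regulator) genes, predominantly downregulated, applied to every COPD
  sample *and* to a planted subset of "admixed" smoker controls that carry
  the disease signature subclinically;
* planted co-expression modules: disjoint groups of regulated genes
  sharing a per-sample latent factor, recoverable from the correlation
  structure;
* a configurable discordant-probe rate that flips the planted direction on
  one probe of a multi-probe gene, to exercise the downstream
  probe-consistency filter;
* detection p-values from a deterministic monotone squashing of the
  signal-to-background ratio plus small additive noise (the array's
  detection-call machinery itself is not simulated).

Everything is reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    GeneCensus,
    GroupDesign,
    ValidationError,
)
from .differential import ComparisonResult

DEFAULT_GROUP_SIZES = {"NS": 12, "S": 12, "COPD": 6}
DEFAULT_CONTRASTS = [("S", "NS"), ("COPD", "NS"), ("COPD", "S")]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the emulated study.

    ``effect_log2`` is the magnitude of the planted disease effect
    (log2 scale; 2.0 means a 4-fold change).  ``probes_per_gene_law`` is an
    inclusive (min, max) range for the uniform number of probes per gene.
    """

    n_background_genes: int = 600
    n_census_genes: int = 250
    n_regulated_census_genes: int = 120
    fraction_down: float = 0.75
    probes_per_gene_law: tuple[int, int] = (1, 4)
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    effect_log2: float = 3.0
    within_group_sd_log2: float = 0.5
    n_admixed_controls: int = 4
    n_modules: int = 5
    module_size: int = 10
    module_latent_sd: float = 1.0
    detection_background: float = 8.0
    seed: int = 0
    # secondary knobs (documented defaults, rarely moved)
    discordant_probe_rate: float = 0.15
    biological_factor_sd: float = 1.0
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    probe_offset_sd: float = 0.25
    detection_noise_sd: float = 0.01
    disease_group: str = "COPD"
    admixed_group: str = "S"
    # biology_seed fixes the gene-level draws (regulated set, directions,
    # modules, baselines, probe layout) independently of the cohort draws,
    # so two configs sharing biology_seed but differing in seed emulate a
    # test cohort and an independent validation cohort of the same disease
    biology_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_regulated_census_genes > self.n_census_genes:
            raise ValidationError(
                "n_regulated_census_genes exceeds n_census_genes"
            )
        if not 0.0 <= self.fraction_down <= 1.0:
            raise ValidationError("fraction_down must lie in [0, 1]")
        if self.disease_group not in self.group_sizes:
            raise ValidationError(f"no group {self.disease_group!r} in group_sizes")
        if self.admixed_group not in self.group_sizes:
            raise ValidationError(f"no group {self.admixed_group!r} in group_sizes")
        if self.n_admixed_controls > self.group_sizes[self.admixed_group]:
            raise ValidationError("n_admixed_controls exceeds the control group size")
        lo, hi = self.probes_per_gene_law
        if lo < 1 or hi < lo:
            raise ValidationError("probes_per_gene_law must satisfy 1 <= min <= max")
        if self.n_modules * self.module_size > self.n_regulated_census_genes:
            raise ValidationError(
                "planted modules need n_modules*module_size <= regulated genes"
            )
        for bad_field in (
            "effect_log2",
            "within_group_sd_log2",
            "module_latent_sd",
            "detection_background",
        ):
            if getattr(self, bad_field) < 0:
                raise ValidationError(f"{bad_field} must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: per-gene effects, per-sample flags, modules."""

    genes: pd.DataFrame  # index gene; columns census, regulated, direction, effect_log2, module
    samples: pd.DataFrame  # index sample; columns group, admixed
    modules: list[list[str]]
    discordant_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            if seen & set(mod):
                raise ValidationError("module memberships must be disjoint")
            seen |= set(mod)

    def regulated_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["regulated"]])

    def admixed_samples(self) -> list[str]:
        return sorted(self.samples.index[self.samples["admixed"]])

    def census(self) -> GeneCensus:
        return GeneCensus(
            symbols=frozenset(self.genes.index[self.genes["census"]])
        )

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.reset_index()
            .rename(columns={"index": "gene"})
            .to_dict(orient="records"),
            "samples": self.samples.reset_index()
            .rename(columns={"index": "sample"})
            .to_dict(orient="records"),
            "modules": self.modules,
            "discordant_probes": self.discordant_probes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = pd.DataFrame(payload["genes"]).set_index("gene")
        samples = pd.DataFrame(payload["samples"]).set_index("sample")
        return cls(
            genes=genes,
            samples=samples,
            modules=[list(m) for m in payload["modules"]],
            discordant_probes=list(payload["discordant_probes"]),
        )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroupDesign, GroundTruth]:
    """Draw one synthetic cohort.

    The intensity model on the log2 scale is

        x[p, s] = baseline(gene) + offset(probe) + beta(probe) * disease(s)
                  + factor(gene, s) + eps[p, s]

    with ``beta = +-effect_log2`` on regulated genes (sign flipped on a
    planted discordant probe) and ``disease(s) = 1`` for disease-group
    samples and for the planted admixed controls.  ``factor(gene, s)`` is
    the gene's biological per-sample variation: an independent draw per
    gene, except that all members of a planted module share their module's
    latent factor — which is exactly what makes modules stand out from the
    disease-driven background correlation.  Intensities are ``2**x``;
    detection p-values are a monotone squashing of intensity over
    ``detection_background``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)  # cohort stream: subjects + noise
    bio = np.random.default_rng(
        cfg.seed if cfg.biology_seed is None else cfg.biology_seed
    )  # biology stream: gene- and probe-level structure

    # --- samples ------------------------------------------------------
    sample_ids: list[str] = []
    groups: list[str] = []
    for label, size in cfg.group_sizes.items():
        if size < 1:
            raise ValidationError(f"group {label!r} has no samples")
        for i in range(size):
            sample_ids.append(f"{label}_{i + 1:02d}")
            groups.append(label)
    groups_s = pd.Series(groups, index=sample_ids, dtype=object)
    control_pool = list(groups_s.index[groups_s == cfg.admixed_group])
    admixed = sorted(
        rng.choice(control_pool, size=cfg.n_admixed_controls, replace=False)
    )
    disease_flag = np.array(
        [
            (g == cfg.disease_group) or (s in admixed)
            for s, g in zip(sample_ids, groups)
        ],
        dtype=float,
    )

    # --- genes --------------------------------------------------------
    census_genes = [f"MRBP{i + 1:04d}" for i in range(cfg.n_census_genes)]
    background_genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_background_genes)]
    genes = census_genes + background_genes
    regulated = sorted(
        bio.choice(census_genes, size=cfg.n_regulated_census_genes, replace=False)
    )
    # i.i.d. directions first (down with prob fraction_down), modules after
    direction = {
        g: (-1 if bio.random() < cfg.fraction_down else 1) for g in regulated
    }
    # modules are direction-homogeneous groups of regulated genes: members
    # are drawn from the larger direction pool first so a shared latent
    # factor produces positive pairwise correlation
    down_pool = [g for g in regulated if direction[g] == -1]
    up_pool = [g for g in regulated if direction[g] == 1]
    pools = sorted([down_pool, up_pool], key=len, reverse=True)
    modules: list[list[str]] = []
    for _ in range(cfg.n_modules):
        pool = pools[0] if len(pools[0]) >= cfg.module_size else pools[1]
        if len(pool) < cfg.module_size:
            raise ValidationError(
                "not enough same-direction regulated genes to plant modules"
            )
        members = sorted(bio.choice(pool, size=cfg.module_size, replace=False))
        for g in members:
            pool.remove(g)
        modules.append(members)
    module_of = {g: m for m, mod in enumerate(modules) for g in mod}

    # --- probes -------------------------------------------------------
    lo, hi = cfg.probes_per_gene_law
    n_probes_per_gene = bio.integers(lo, hi + 1, size=len(genes))
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    for g, k in zip(genes, n_probes_per_gene):
        for j in range(int(k)):
            probe_ids.append(f"{g}_{j + 1:02d}_at")
            probe_gene.append(g)
    P, S = len(probe_ids), len(sample_ids)

    baseline = bio.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(genes))
    baseline_of = dict(zip(genes, baseline))
    offsets = bio.normal(0.0, cfg.probe_offset_sd, size=P)

    beta = np.zeros(P)
    for i, g in enumerate(probe_gene):
        if g in direction:
            beta[i] = direction[g] * cfg.effect_log2
    # discordant probes: flip one probe of a multi-probe regulated gene
    discordant: list[str] = []
    gene_probe_idx: dict[str, list[int]] = {}
    for i, g in enumerate(probe_gene):
        gene_probe_idx.setdefault(g, []).append(i)
    for g in regulated:
        idxs = gene_probe_idx[g]
        if len(idxs) >= 2 and bio.random() < cfg.discordant_probe_rate:
            flip = int(bio.choice(idxs))
            beta[flip] = -beta[flip]
            discordant.append(probe_ids[flip])

    # per-sample gene factors: every gene varies biologically across
    # samples; module members *share* their module's latent factor, which
    # is what makes planted modules recoverable from correlation
    latent = rng.normal(0.0, cfg.module_latent_sd, size=(cfg.n_modules, S))
    gene_factor = rng.normal(0.0, cfg.biological_factor_sd, size=(len(genes), S))
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, m in module_of.items():
        gene_factor[gene_index[g]] = latent[m]

    noise = rng.normal(0.0, cfg.within_group_sd_log2, size=(P, S))
    log2x = (
        np.array([baseline_of[g] for g in probe_gene])[:, None]
        + offsets[:, None]
        + beta[:, None] * disease_flag[None, :]
        + gene_factor[[gene_index[g] for g in probe_gene], :]
        + noise
    )
    intensities = np.power(2.0, log2x)

    ratio = intensities / cfg.detection_background
    det_p = 1.0 / (1.0 + ratio**3)
    det_p = det_p + rng.normal(0.0, cfg.detection_noise_sd, size=det_p.shape)
    det_p = np.clip(det_p, 0.0, 1.0)

    matrix = ExpressionMatrix(
        intensities=pd.DataFrame(intensities, index=probe_ids, columns=sample_ids),
        detection_p=pd.DataFrame(det_p, index=probe_ids, columns=sample_ids),
        annotation=pd.Series(probe_gene, index=probe_ids, dtype=object),
    )
    design = GroupDesign(groups=groups_s, contrasts=list(DEFAULT_CONTRASTS)
                         if set(DEFAULT_GROUP_SIZES) <= set(cfg.group_sizes)
                         else [])

    gene_table = pd.DataFrame(
        {
            "census": [g in set(census_genes) for g in genes],
            "regulated": [g in direction for g in genes],
            "direction": [direction.get(g, 0) for g in genes],
            "effect_log2": [
                cfg.effect_log2 if g in direction else 0.0 for g in genes
            ],
            "module": [module_of.get(g, -1) for g in genes],
        },
        index=genes,
    )
    sample_table = pd.DataFrame(
        {
            "group": groups,
            "admixed": [s in admixed for s in sample_ids],
        },
        index=sample_ids,
    )
    truth = GroundTruth(
        genes=gene_table,
        samples=sample_table,
        modules=modules,
        discordant_probes=discordant,
    )
    return matrix, design, truth


def truth_confusion(
    result: ComparisonResult,
    truth: GroundTruth,
    universe: set[str] | None = None,
) -> dict:
    """Gene-level confusion summary of SDEG calls against the ground truth.

    "Positive" means called SDEG (after the discordance filter).  The
    universe defaults to the census genes of the truth record, matching a
    census-restricted comparison.  Observed FDR is defined as 0 when no
    positives were called.  Directional accuracy is computed on true
    positives only.
    """
    if universe is None:
        universe = set(truth.genes.index[truth.genes["census"]])
    called = result.sdeg_genes()
    if not called <= set(truth.genes.index):
        raise ValidationError("called genes outside the truth universe")
    called &= universe
    regulated = truth.regulated_genes() & universe
    tp_genes = called & regulated
    fp = len(called - regulated)
    tp = len(tp_genes)
    fn = len(regulated - called)
    tn = len(universe) - tp - fp - fn
    sensitivity = tp / len(regulated) if regulated else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    observed_fdr = fp / (tp + fp) if (tp + fp) else 0.0
    if tp:
        dirs = result.gene_calls.set_index("gene_symbol")["direction"]
        true_dir = truth.genes["direction"]
        hits = sum(
            1
            for g in tp_genes
            if (dirs[g] == "down") == (true_dir[g] < 0)
        )
        directional_accuracy = hits / tp
    else:
        directional_accuracy = 0.0
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "observed_fdr": observed_fdr,
        "directional_accuracy": directional_accuracy,
    }


def module_recovery_score(
    recovered_probe_clusters: list[list[str]],
    truth: GroundTruth,
    annotation: pd.Series,
    clustered_universe: set[str] | None = None,
) -> float:
    """Mean best-match Jaccard between planted modules and recovered clusters.

    Recovered probe clusters are mapped to gene sets through the probe
    annotation; each planted module is scored against its best-matching
    recovered gene set, and the scores are averaged (0 if nothing was
    recovered).  When ``clustered_universe`` is given (the genes that were
    actually present in the clustered signature), planted modules are
    restricted to it first — clustering is scored on what it could see,
    not on genes the upstream selection dropped.
    """
    gene_clusters = [
        {annotation[p] for p in cluster if p in annotation.index}
        for cluster in recovered_probe_clusters
    ]
    gene_clusters = [c for c in gene_clusters if c]
    scores = []
    for mod in truth.modules:
        mod_set = set(mod)
        if clustered_universe is not None:
            mod_set = mod_set & set(clustered_universe)
        if not mod_set:
            continue
        best = 0.0
        for c in gene_clusters:
            j = len(mod_set & c) / len(mod_set | c)
            best = max(best, j)
        scores.append(best)
    return float(np.mean(scores)) if scores else 0.0
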