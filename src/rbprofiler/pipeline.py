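"""End-to-end pipeline orchestration, bookkeeping report and run manifest.

A run is driven by a config mapping (usually a YAML file) that either
names the input files (expression/detection/annotation/groups/census, and
optionally a GMT pathway file) or asks for a synthetic cohort via a
``simulate`` section.  Outputs per contrast are probe- and gene-level
TSVs; the run additionally emits the Venn partition over the contrasts'
SDEG sets, sample clustering with admixture flags, co-expression
clusters, optional pathway enrichment, a human-readable counts report and
a JSON manifest that makes the run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .model import GeneCensus, GroupDesign, ValidationError
from . import io as rio
from .differential import (
    ComparisonResult,
    detection_filter,
    median_normalize,
    percent,
    run_comparison,
)
from .venn import venn_partition
from .cluster import (
    admixture_detect,
    extract_coexpression_clusters,
    hier_cluster,
    signature_matrix,
)
from .enrichment import enrich_pathways
from .simulate import SimulationConfig, generate_dataset

_FLOAT_FMT = "%.17g"


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_contrast(text: str) -> tuple[str, str]:
    if ":" not in text:
        raise ValidationError(f"contrast must be CASE:CONTROL, got {text!r}")
    case, control = text.split(":", 1)
    return case.strip(), control.strip()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def report_lines(results: list[ComparisonResult]) -> list[str]:
    """Fig-2-style bookkeeping: counts with recomputable percentages."""
    lines: list[str] = []
    for res in results:
        c = res.counts
        lines.append(f"== {res.label} ==")
        lines.append(f"probes tested: {c['probes_tested']}")
        lines.append(
            f"DEG probes: {c['probes_deg']}; SDEG probes: {c['probes_sdeg']} "
            f"(up {c['probes_sdeg_up']}, down {c['probes_sdeg_down']})"
        )
        lines.append(f"DEG genes: {c['genes_deg']}")
        lines.append(
            f"SDEG genes: {c['genes_sdeg']}/{c['genes_deg']} "
            f"({percent(c['genes_sdeg'], c['genes_deg'])}%)"
        )
        lines.append(
            f"down: {c['genes_sdeg_down']}/{c['genes_sdeg']} "
            f"({percent(c['genes_sdeg_down'], c['genes_sdeg'])}%)"
        )
        lines.append(
            f"up: {c['genes_sdeg_up']}/{c['genes_sdeg']} "
            f"({percent(c['genes_sdeg_up'], c['genes_sdeg'])}%)"
        )
        n_with_excl = c["genes_sdeg"] + c["genes_excluded_discordant"]
        lines.append(
            f"discordant excluded: {c['genes_excluded_discordant']}/{n_with_excl} "
            f"({percent(c['genes_excluded_discordant'], n_with_excl)}%)"
        )
    return lines


def run_pipeline(config: Mapping[str, Any], outdir) -> dict:
    """Execute diff -> venn -> cluster -> enrich and write all outputs.

    Returns the manifest dict.  On a stage failure the partial outputs
    written so far are removed and a stage-labeled :class:`PipelineError`
    is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    stage = "config"
    try:
        manifest: dict[str, Any] = {
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config": json.loads(json.dumps(config, default=str)),
            "inputs": {},
            "counts": {},
        }

        # ---------- inputs ------------------------------------------
        stage = "inputs"
        thresholds = config.get("thresholds", {})
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            if "probes_per_gene_law" in sim_kwargs:
                sim_kwargs["probes_per_gene_law"] = tuple(
                    sim_kwargs["probes_per_gene_law"]
                )
            sim_cfg = SimulationConfig(**sim_kwargs)
            matrix, design, truth = generate_dataset(sim_cfg)
            census = truth.census()
            manifest["seed"] = sim_cfg.seed
            manifest["inputs"]["simulate"] = asdict(sim_cfg) | {
                "group_sizes": dict(sim_cfg.group_sizes),
                "probes_per_gene_law": list(sim_cfg.probes_per_gene_law),
            }
            truth.to_json(out("truth.json"))
        else:
            inputs = config.get("inputs")
            if not inputs:
                raise ValidationError("config needs an 'inputs' or 'simulate' section")
            for key in ("expression", "detection", "annotation", "groups", "census"):
                if key not in inputs:
                    raise ValidationError(f"config inputs missing {key!r}")
                manifest["inputs"][key] = {
                    "path": str(inputs[key]),
                    "sha256": _sha256(Path(inputs[key])),
                }
            matrix = rio.read_expression_table(
                inputs["expression"],
                inputs["annotation"],
                detection_path=inputs["detection"],
            )
            design = rio.read_group_design(inputs["groups"])
            census = rio.read_gene_census(inputs["census"])
            if "gmt" in inputs:
                manifest["inputs"]["gmt"] = {
                    "path": str(inputs["gmt"]),
                    "sha256": _sha256(Path(inputs["gmt"])),
                }
        contrasts = [
            _parse_contrast(c) for c in config.get("contrasts", [])
        ] or list(design.contrasts)
        if not contrasts:
            raise ValidationError("no contrasts configured")
        design = GroupDesign(groups=design.groups, contrasts=contrasts)

        # ---------- differential ------------------------------------
        stage = "diff"
        kept = detection_filter(
            matrix, design, alpha=thresholds.get("detection_alpha", 0.05)
        )
        filtered = median_normalize(matrix.subset_probes(kept))
        manifest["counts"]["probes_input"] = len(matrix.probeset_ids)
        manifest["counts"]["probes_detected"] = len(kept)
        manifest["counts"]["probes_unannotated"] = filtered.n_unannotated
        results: list[ComparisonResult] = []
        for contrast in contrasts:
            res = run_comparison(
                filtered,
                design,
                contrast,
                census=census,
                fdr_max=thresholds.get("fdr_max", 0.05),
                fc_min=thresholds.get("fc_min", 1.5),
                consistency_min=thresholds.get("consistency_min", 2.0 / 3.0),
                prefiltered_normalized=True,
            )
            results.append(res)
            tag = f"{contrast[0]}_vs_{contrast[1]}"
            res.probe_stats.to_csv(
                out(f"probes_{tag}.tsv"), sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )
            res.gene_calls.to_csv(
                out(f"genes_{tag}.tsv"), sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )
            manifest["counts"][res.label] = res.counts

        # ---------- venn --------------------------------------------
        stage = "venn"
        if len(results) >= 2:
            named = {r.label: r.sdeg_genes() for r in results[:3]}
            part = venn_partition(named)
            rows = []
            for region, genes in sorted(
                part.regions.items(), key=lambda kv: sorted(kv[0])
            ):
                rows.append(
                    {
                        "region": "&".join(sorted(region)),
                        "n_genes": len(genes),
                        "genes": ",".join(sorted(genes)),
                    }
                )
            pd.DataFrame(rows).to_csv(out("venn.tsv"), sep="\t", index=False)
            manifest["counts"]["venn"] = {
                "&".join(sorted(k)): v for k, v in part.counts.items()
            }

        # ---------- clustering --------------------------------------
        stage = "cluster"
        cluster_cfg = config.get("cluster", {})
        sig_label = cluster_cfg.get("signature_contrast")
        sig_res = results[-1]
        if sig_label:
            wanted = _parse_contrast(sig_label)
            matches = [r for r in results if r.contrast == wanted]
            if not matches:
                raise ValidationError(f"signature contrast {sig_label!r} not run")
            sig_res = matches[0]
        sdeg_probes = sig_res.sdeg_probes()
        manifest["counts"]["signature_probes"] = len(sdeg_probes)
        if len(sdeg_probes) >= 2:
            sig = signature_matrix(filtered, sdeg_probes)
            sample_dend = hier_cluster(sig.T, metric="euclidean")
            out("samples.nwk").write_text(sample_dend.to_newick() + "\n")
            disease = cluster_cfg.get("disease_label", sig_res.contrast[0])
            flagged, height = admixture_detect(sample_dend, design, disease)
            pd.DataFrame({"sample_id": flagged}).to_csv(
                out("admixed_samples.tsv"), sep="\t", index=False
            )
            manifest["counts"]["admixed_flagged"] = flagged
            clusters = extract_coexpression_clusters(
                sig,
                r_min=cluster_cfg.get("r_min", 0.70),
                size_min=cluster_cfg.get("size_min", 2),
            )
            rows = []
            for i, (probes, min_r) in enumerate(
                zip(clusters.clusters, clusters.min_pairwise_r), start=1
            ):
                for p in probes:
                    rows.append(
                        {
                            "cluster": i,
                            "probeset_id": p,
                            "gene_symbol": filtered.annotation.get(p, ""),
                            "min_pairwise_r": min_r,
                        }
                    )
            pd.DataFrame(
                rows, columns=["cluster", "probeset_id", "gene_symbol", "min_pairwise_r"]
            ).to_csv(out("coexpression_clusters.tsv"), sep="\t", index=False,
                     float_format=_FLOAT_FMT)
            manifest["counts"]["coexpression_clusters"] = [
                len(c) for c in clusters.clusters
            ]

        # ---------- enrichment --------------------------------------
        stage = "enrich"
        enrich_cfg = config.get("enrichment", {})
        gmt_path = config.get("inputs", {}).get("gmt")
        if gmt_path:
            db = rio.read_gmt(gmt_path)
            universe = {
                g for g in filtered.annotation if g in census
            }
            for res in results:
                tag = f"{res.contrast[0]}_vs_{res.contrast[1]}"
                table = enrich_pathways(
                    res,
                    db,
                    universe,
                    p_max=enrich_cfg.get("p_max", 0.05),
                    tier=enrich_cfg.get("tier", "DEG"),
                    denominator=enrich_cfg.get("denominator", "sqrt"),
                )
                table.to_csv(out(f"enrichment_{tag}.tsv"), sep="\t", index=False,
                             float_format=_FLOAT_FMT)
                manifest["counts"][f"enriched_{res.label}"] = len(table)

        # ---------- report + manifest -------------------------------
        stage = "report"
        out("report.txt").write_text("\n".join(report_lines(results)) + "\n")
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
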