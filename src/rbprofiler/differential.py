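"""Probe filtering, normalization, differential statistics and gene calls.

The stages compose into the per-contrast pipeline:

1. detection filter — keep probesets detected (detection p < 0.05) in at
   least one sample of *every* group;
2. per-array median normalization;
3. per-probe two-sample test (Welch t on log2 intensities) with
   Benjamini–Hochberg FDR across all tested probes, and signed fold change
   from linear-scale group means;
4. tier classification: DEG (FDR <= 0.05) and SDEG (DEG plus |FC| >= 1.5);
5. probe->gene aggregation with a directional-consistency filter (genes
   whose significant probes disagree in direction on more than a third of
   probes are flagged as discordant and excluded from final counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, GeneCensus, GroupDesign, ValidationError

DEFAULT_DETECTION_ALPHA = 0.05
DEFAULT_FDR_MAX = 0.05
DEFAULT_FC_MIN = 1.5
DEFAULT_CONSISTENCY_MIN = 2.0 / 3.0

# slack so that an exact 2-of-3 gene passes a 2/3 threshold despite floats
_CONSISTENCY_EPS = 1e-12

PROBE_COLUMNS = [
    "probeset_id",
    "gene_symbol",
    "case_mean",
    "control_mean",
    "fc_signed",
    "log2_fc",
    "p_value",
    "fdr",
    "tier",
    "direction",
]


def percent(numerator: int, denominator: int) -> int:
    """Whole-number percentage, rounded half-up (194/267 -> 73)."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def signed_fold_change(case_mean: float, control_mean: float) -> float:
    """Signed-ratio convention: ratio r reported as r if r >= 1, else -1/r.

    A gene halved in cases is -2.0, not 0.5; |FC| is always >= 1.
    """
    if control_mean <= 0 or case_mean <= 0:
        raise ValidationError("fold change requires positive group means")
    r = case_mean / control_mean
    return r if r >= 1.0 else -1.0 / r


def detection_filter(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    alpha: float = DEFAULT_DETECTION_ALPHA,
) -> list[str]:
    """Probesets detected (p < alpha) in >= 1 sample within every group.

    Order of the input matrix is preserved.
    """
    if len(design.labels) == 0:
        raise ValidationError("empty design")
    keep = np.ones(len(matrix.probeset_ids), dtype=bool)
    for label in design.labels:
        samples = design.samples_in(label)
        if not samples:
            raise ValidationError(f"group {label!r} has no samples")
        detected = (matrix.detection_p[samples].to_numpy() < alpha).any(axis=1)
        keep &= detected
    return [pid for pid, k in zip(matrix.probeset_ids, keep) if k]


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its median; idempotent.

    After normalization every column's median equals 1 up to float
    tolerance, putting arrays on a common scale before fold changes.
    """
    medians = matrix.intensities.median(axis=0)
    if (medians <= 0).any() or medians.isna().any():
        bad = list(medians.index[(medians <= 0) | medians.isna()])
        raise ValidationError(f"non-positive median intensity in samples: {bad}")
    return ExpressionMatrix(
        intensities=matrix.intensities / medians,
        detection_p=matrix.detection_p.copy(),
        annotation=matrix.annotation.copy(),
    )


def _welch_test(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(case, control, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def probe_differential(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    contrast: tuple[str, str],
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-probe p, BH-FDR and signed FC for one (case, control) contrast.

    The location test runs on log2 intensities (Welch t by default; any
    callable mapping two (probes x samples) arrays to p-values can be
    injected, e.g. a moderated-t variant).  Fold changes come from the
    linear-scale group means of the normalized intensities.  BH correction
    spans *all* probes passed in, i.e. the full detection-filtered set.
    """
    case_label, control_label = contrast
    case_samples = design.samples_in(case_label)
    control_samples = design.samples_in(control_label)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValidationError(
            "each contrast group needs >= 2 samples for a variance estimate"
        )
    case = matrix.intensities[case_samples].to_numpy(dtype=float)
    control = matrix.intensities[control_samples].to_numpy(dtype=float)
    if (case <= 0).any() or (control <= 0).any():
        raise ValidationError("probe_differential requires positive intensities")
    test = test or _welch_test
    pvals = test(np.log2(case), np.log2(control))
    pvals = np.nan_to_num(np.asarray(pvals, dtype=float), nan=1.0)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    case_mean = case.mean(axis=1)
    control_mean = control.mean(axis=1)
    fc = np.array(
        [signed_fold_change(a, b) for a, b in zip(case_mean, control_mean)]
    )
    ann = matrix.annotation
    genes = [ann.get(pid, None) for pid in matrix.probeset_ids]
    return pd.DataFrame(
        {
            "probeset_id": matrix.probeset_ids,
            "gene_symbol": genes,
            "case_mean": case_mean,
            "control_mean": control_mean,
            "fc_signed": fc,
            "log2_fc": np.log2(case_mean / control_mean),
            "p_value": pvals,
            "fdr": fdr,
        }
    )


def classify_probes(
    stats_df: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    fc_min: float = DEFAULT_FC_MIN,
) -> pd.DataFrame:
    """Assign tiers: DEG iff FDR <= fdr_max; SDEG additionally |FC| >= fc_min."""
    df = stats_df.copy()
    deg = df["fdr"] <= fdr_max
    sdeg = deg & (df["fc_signed"].abs() >= fc_min)
    df["tier"] = np.where(sdeg, "SDEG", np.where(deg, "DEG", "none"))
    df["direction"] = np.where(
        df["tier"] == "none", "none", np.where(df["fc_signed"] > 0, "up", "down")
    )
    return df


def aggregate_genes(
    stats_df: pd.DataFrame,
    consistency_min: float = DEFAULT_CONSISTENCY_MIN,
) -> pd.DataFrame:
    """Collapse classified probe statistics to per-gene calls.

    Only significant probes (tier DEG or SDEG) vote.  Per gene:
    consistency = (majority-direction probes) / (significant probes);
    genes below ``consistency_min`` are flagged ``excluded_for_discordance``.
    The gene direction is the majority direction, the gene FC the median of
    majority-direction probe FCs, and the gene tier is SDEG if any
    majority-direction probe is SDEG, else DEG.  Probes without a gene
    annotation are dropped here (their count is visible on the input frame).
    """
    sig = stats_df[stats_df["tier"].isin(["DEG", "SDEG"])]
    sig = sig[sig["gene_symbol"].notna()]
    rows = []
    for gene, grp in sig.groupby("gene_symbol", sort=True):
        n_up = int((grp["direction"] == "up").sum())
        n_down = int((grp["direction"] == "down").sum())
        n_sig = n_up + n_down
        majority = "up" if n_up >= n_down else "down"
        consistency = max(n_up, n_down) / n_sig
        excluded = consistency < consistency_min - _CONSISTENCY_EPS
        maj = grp[grp["direction"] == majority]
        gene_fc = float(maj["fc_signed"].median())
        tier = "SDEG" if (maj["tier"] == "SDEG").any() else "DEG"
        rows.append(
            {
                "gene_symbol": gene,
                "n_probes_significant": n_sig,
                "n_up": n_up,
                "n_down": n_down,
                "consistency": consistency,
                "direction": majority,
                "gene_fc": gene_fc,
                "tier": tier,
                "excluded_for_discordance": bool(excluded),
            }
        )
    columns = [
        "gene_symbol",
        "n_probes_significant",
        "n_up",
        "n_down",
        "consistency",
        "direction",
        "gene_fc",
        "tier",
        "excluded_for_discordance",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df.astype(
        {
            "n_probes_significant": int,
            "n_up": int,
            "n_down": int,
            "consistency": float,
            "gene_fc": float,
            "excluded_for_discordance": bool,
        }
    )


@dataclass
class ComparisonResult:
    """All differential statistics for one case/control contrast."""

    contrast: tuple[str, str]
    probe_stats: pd.DataFrame
    gene_calls: pd.DataFrame
    counts: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.contrast[0]}/{self.contrast[1]}"

    def sdeg_genes(self) -> set[str]:
        """Genes called SDEG after the discordance filter."""
        gc = self.gene_calls
        keep = (gc["tier"] == "SDEG") & ~gc["excluded_for_discordance"]
        return set(gc.loc[keep, "gene_symbol"])

    def deg_genes(self) -> set[str]:
        gc = self.gene_calls
        return set(gc.loc[~gc["excluded_for_discordance"], "gene_symbol"])

    def sdeg_probes(self) -> list[str]:
        ps = self.probe_stats
        return list(ps.loc[ps["tier"] == "SDEG", "probeset_id"])


def _count_summary(probe_stats: pd.DataFrame, gene_calls: pd.DataFrame) -> dict:
    ps, gc = probe_stats, gene_calls
    kept = gc[~gc["excluded_for_discordance"]]
    sdeg = kept[kept["tier"] == "SDEG"]
    counts = {
        "probes_tested": int(len(ps)),
        "probes_deg": int((ps["tier"] != "none").sum()),
        "probes_sdeg": int((ps["tier"] == "SDEG").sum()),
        "probes_sdeg_up": int(((ps["tier"] == "SDEG") & (ps["direction"] == "up")).sum()),
        "probes_sdeg_down": int(((ps["tier"] == "SDEG") & (ps["direction"] == "down")).sum()),
        "genes_deg": int(len(kept)),
        "genes_sdeg": int(len(sdeg)),
        "genes_sdeg_up": int((sdeg["direction"] == "up").sum()),
        "genes_sdeg_down": int((sdeg["direction"] == "down").sum()),
        "genes_excluded_discordant": int(gc["excluded_for_discordance"].sum()),
    }
    counts["pct_sdeg_of_deg"] = percent(counts["genes_sdeg"], counts["genes_deg"])
    counts["pct_sdeg_down"] = percent(counts["genes_sdeg_down"], counts["genes_sdeg"])
    counts["pct_sdeg_up"] = percent(counts["genes_sdeg_up"], counts["genes_sdeg"])
    n_sdeg_incl = counts["genes_sdeg"] + counts["genes_excluded_discordant"]
    counts["pct_excluded_discordant"] = percent(
        counts["genes_excluded_discordant"], n_sdeg_incl
    )
    return counts


def run_comparison(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    contrast: tuple[str, str],
    census: GeneCensus | set[str] | None = None,
    detection_alpha: float = DEFAULT_DETECTION_ALPHA,
    fdr_max: float = DEFAULT_FDR_MAX,
    fc_min: float = DEFAULT_FC_MIN,
    consistency_min: float = DEFAULT_CONSISTENCY_MIN,
    test: Callable | None = None,
    prefiltered_normalized: bool = False,
) -> ComparisonResult:
    """Full per-contrast pipeline; census restriction happens *after* FDR.

    The FDR correction is computed over every detection-filtered probe of
    the contrast, and only then are gene calls restricted to census members
    — the census is searched in the finished differential table, it does
    not shrink the multiple-testing family.
    """
    if not prefiltered_normalized:
        kept = detection_filter(matrix, design, alpha=detection_alpha)
        matrix = matrix.subset_probes(kept)
        matrix = median_normalize(matrix)
    stats_df = probe_differential(matrix, design, contrast, test=test)
    stats_df = classify_probes(stats_df, fdr_max=fdr_max, fc_min=fc_min)
    gene_calls = aggregate_genes(stats_df, consistency_min=consistency_min)
    if census is not None:
        symbols = census.symbols if isinstance(census, GeneCensus) else set(census)
        gene_calls = gene_calls[
            gene_calls["gene_symbol"].isin(symbols)
        ].reset_index(drop=True)
        probe_view = stats_df[
            stats_df["gene_symbol"].isin(symbols)
        ].reset_index(drop=True)
    else:
        probe_view = stats_df
    counts = _count_summary(probe_view, gene_calls)
    return ComparisonResult(
        contrast=contrast,
        probe_stats=probe_view,
        gene_calls=gene_calls,
        counts=counts,
    )


def cross_dataset_fc_concordance(
    a: ComparisonResult,
    b: ComparisonResult,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Pair gene-level FCs of two datasets and report sign agreement.

    Used to check that a disease signature found in a test cohort
    replicates its direction in an independent validation cohort.  Genes
    missing from either result are listed with NaN and do not count toward
    the agreement fraction.
    """
    fa = a.gene_calls.set_index("gene_symbol")["gene_fc"]
    fb = b.gene_calls.set_index("gene_symbol")["gene_fc"]
    if genes is None:
        genes = sorted(set(fa.index) | set(fb.index))
    table = pd.DataFrame(
        {
            "gene_symbol": list(genes),
            "fc_a": [fa.get(g, np.nan) for g in genes],
            "fc_b": [fb.get(g, np.nan) for g in genes],
        }
    )
    both = table.dropna(subset=["fc_a", "fc_b"])
    if len(both) == 0:
        return table, float("nan")
    agreement = float((np.sign(both["fc_a"]) == np.sign(both["fc_b"])).mean())
    return table, agreement
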