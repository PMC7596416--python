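"""Pathway over-representation and directional activation scoring.

Over-representation uses the right-tailed Fisher / hypergeometric test:
given a universe of U genes of which K belong to a pathway, and a selected
(differentially expressed) set of n genes overlapping the pathway in k,
p = P(X >= k) for X ~ Hypergeometric(U, K, n).

The activation z-score summarizes the *direction* of the overlapping
genes: z = (#up - #down) / sqrt(#up + #down).  A pathway whose regulated
members are predominantly down gets z < 0 (predicted Inhibition), mostly
up gives z > 0 (Activation), and an even split gives exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .model import PathwayDB, ValidationError
from .differential import ComparisonResult

ENRICH_COLUMNS = [
    "pathway",
    "p_value",
    "z_score",
    "prediction",
    "n_overlap",
    "n_up",
    "n_down",
    "molecules",
]


def fisher_overrep(
    selected: Iterable[str],
    pathway: Iterable[str],
    universe: Iterable[str],
) -> float:
    """Right-tailed over-representation p-value, P(X >= observed overlap).

    Genes outside the universe are dropped (with a warning for selected
    genes, since that usually signals an annotation mismatch).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    selected = set(selected)
    outside = selected - universe
    if outside:
        warnings.warn(
            f"{len(outside)} selected gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    selected &= universe
    pathway = set(pathway) & universe
    k = len(selected & pathway)
    # P(X >= k) via the survival function at k-1
    return float(hypergeom.sf(k - 1, len(universe), len(pathway), len(selected)))


def activation_zscore(
    directions: Sequence[str], denominator: str = "sqrt"
) -> float:
    """Directional z-score over the overlap genes' up/down calls.

    ``denominator="sqrt"`` gives (#up - #down)/sqrt(N), the scaling under
    which an all-down pair scores -1.41 and an all-down quartet -2.  The
    plain-N variant (``denominator="ntot"``) is retained as an option.
    """
    dirs = list(directions)
    if not dirs:
        raise ValidationError("empty direction list")
    bad = set(dirs) - {"up", "down"}
    if bad:
        raise ValidationError(f"directions must be 'up'/'down', got {sorted(bad)}")
    n_up = dirs.count("up")
    n_down = dirs.count("down")
    n = n_up + n_down
    if denominator == "sqrt":
        return (n_up - n_down) / sqrt(n)
    if denominator == "ntot":
        return (n_up - n_down) / n
    raise ValidationError(f"unknown denominator: {denominator}")


def prediction_label(z: float) -> str:
    """Activation if z > 0, Inhibition if z < 0, "0" for an even split."""
    if z > 0:
        return "Activation"
    if z < 0:
        return "Inhibition"
    return "0"


@dataclass
class PathwayEnrichment:
    pathway: str
    overlap_genes: dict[str, str]  # gene -> direction
    fisher_p: float
    z_score: float
    prediction: str

    @property
    def n_total(self) -> int:
        return len(self.overlap_genes)

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.overlap_genes.values() if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.overlap_genes.values() if d == "down")


def enrich_pathways(
    result: ComparisonResult,
    db: PathwayDB,
    universe: Iterable[str],
    p_max: float = 0.05,
    tier: str = "DEG",
    denominator: str = "sqrt",
) -> pd.DataFrame:
    """Over-representation of each pathway in the contrast's gene calls.

    ``tier="DEG"`` tests all significant genes (the default — more genes
    means more statistical power for enrichment); ``tier="SDEG"``
    restricts to fold-change-filtered calls.  Pathways with p <= p_max are
    returned sorted by ascending p, each with its activation z-score and
    prediction computed from the overlap genes' directions.
    """
    if tier not in {"DEG", "SDEG"}:
        raise ValidationError(f"tier must be DEG or SDEG, got {tier!r}")
    gc = result.gene_calls
    keep = ~gc["excluded_for_discordance"]
    if tier == "SDEG":
        keep &= gc["tier"] == "SDEG"
    calls = gc[keep]
    directions = dict(zip(calls["gene_symbol"], calls["direction"]))
    selected = set(directions)
    universe = set(universe)
    outside = selected - universe
    if outside:
        warnings.warn(
            f"{len(outside)} selected gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        selected &= universe
        directions = {g: d for g, d in directions.items() if g in selected}
    rows = []
    for name, genes in db.items():
        overlap = sorted(selected & genes)
        if not overlap:
            continue
        p = fisher_overrep(selected, genes, universe)
        if p > p_max:
            continue
        dirs = [directions[g] for g in overlap]
        z = activation_zscore(dirs, denominator=denominator)
        rows.append(
            {
                "pathway": name,
                "p_value": p,
                "z_score": round(z, 2),
                "prediction": prediction_label(z),
                "n_overlap": len(overlap),
                "n_up": dirs.count("up"),
                "n_down": dirs.count("down"),
                "molecules": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    return df.sort_values(["p_value", "pathway"]).reset_index(drop=True)
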