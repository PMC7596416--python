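"""Core in-memory containers for probe-level microarray analysis.

The pipeline operates on already-summarized probe intensities (one value per
probeset per sample) together with the per-probe/per-sample detection
p-values produced by the array summarization step (MAS5 convention: small p
means the probe signal stands clearly above background).  Detection p-values
are an *input* — this package never recomputes them from raw probe pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table or container violates its contract."""


def normalize_symbol(symbol: str) -> str:
    """Case-normalize a gene symbol (uppercase, stripped)."""
    return symbol.strip().upper()


@dataclass
class ExpressionMatrix:
    """Probeset x sample intensity table with parallel detection p-values.

    Parameters
    ----------
    intensities
        Non-negative fluorescence intensities, indexed by probeset id with
        one column per sample.
    detection_p
        Detection p-values in [0, 1], same index/columns as ``intensities``.
    annotation
        Maps probeset id -> gene symbol.  Many probesets may map to the same
        gene (arrays carry multiple probes spanning different transcript
        portions); probesets without annotation are allowed and are dropped
        only at the gene-aggregation stage.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    annotation: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if not self.intensities.index.is_unique:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise ValidationError(f"duplicate probeset ids: {sorted(set(dups))}")
        if self.intensities.shape != self.detection_p.shape:
            raise ValidationError(
                "intensity/detection shape mismatch: "
                f"{self.intensities.shape} vs {self.detection_p.shape}"
            )
        if list(self.intensities.index) != list(self.detection_p.index) or list(
            self.intensities.columns
        ) != list(self.detection_p.columns):
            raise ValidationError("intensity and detection tables are not aligned")
        vals = self.intensities.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite intensity values")
        if (vals < 0).any():
            raise ValidationError("negative intensity values")
        pvals = self.detection_p.to_numpy()
        if not np.isfinite(pvals).all() or (pvals < 0).any() or (pvals > 1).any():
            raise ValidationError("detection p-values must lie in [0, 1]")
        # annotation covers a subset of probesets; extra entries are an error
        unknown = set(self.annotation.index) - set(self.intensities.index)
        if unknown:
            raise ValidationError(
                f"annotation refers to unknown probesets: {sorted(unknown)[:5]}"
            )
        self.annotation = self.annotation.map(normalize_symbol)

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_unannotated(self) -> int:
        return len(self.intensities.index.difference(self.annotation.index))

    def subset_probes(self, probeset_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(probeset_ids) - set(self.intensities.index)
        if missing:
            raise ValidationError(f"unknown probesets: {sorted(missing)[:5]}")
        ann = self.annotation[self.annotation.index.isin(probeset_ids)]
        return ExpressionMatrix(
            intensities=self.intensities.loc[list(probeset_ids)],
            detection_p=self.detection_p.loc[list(probeset_ids)],
            annotation=ann,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.intensities.columns)
        if missing:
            raise ValidationError(f"unknown samples: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            intensities=self.intensities[list(sample_ids)],
            detection_p=self.detection_p[list(sample_ids)],
            annotation=self.annotation.copy(),
        )


@dataclass
class GroupDesign:
    """Sample-to-group assignment plus the ordered list of contrasts.

    ``contrasts`` entries are ``(case_label, control_label)`` pairs, e.g.
    ``("COPD", "NS")`` compares COPD patients against non-smokers.
    """

    groups: pd.Series  # sample_id -> group label
    contrasts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups.index.is_unique:
            raise ValidationError("a sample is assigned more than one group")
        if len(self.groups) == 0:
            raise ValidationError("empty group design")
        labels = set(self.groups)
        for case, control in self.contrasts:
            if case not in labels or control not in labels:
                raise ValidationError(
                    f"contrast ({case}, {control}) references unknown group"
                )

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.groups:
            seen.setdefault(lab, None)
        return list(seen)

    def samples_in(self, label: str) -> list[str]:
        if label not in set(self.groups):
            raise ValidationError(f"unknown group label: {label}")
        return list(self.groups.index[self.groups == label])


@dataclass
class GeneCensus:
    """A curated regulator gene list (e.g. the 692-gene mRNA-binding-protein
    census), matched case-insensitively against array annotations."""

    symbols: frozenset[str]
    metadata: dict[str, dict] = field(default_factory=dict)
    n_lines_read: int = 0

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError("empty gene census")
        bad = [s for s in self.symbols if not s or s != normalize_symbol(s)]
        if bad:
            raise ValidationError(f"non-normalized census symbols: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols


@dataclass
class PathwayDB:
    """Named gene sets (GMT-style) used for over-representation analysis."""

    pathways: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {name!r} has no genes")

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]

    def items(self):
        return self.pathways.items()
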