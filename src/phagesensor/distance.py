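"""Colour distance between ΔRGB response patterns.

The dissimilarity between two response patterns a, b over n bins is

    D(a, b) = sum_i [ (ΔR_i^a - ΔR_i^b)^2
                    + (ΔG_i^a - ΔG_i^b)^2
                    + (ΔB_i^a - ΔB_i^b)^2 ]

("squared" dialect, the default), or its square root ("euclidean" dialect,
a true metric).  No channel or bin normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ResponsePattern, PatternError

DIALECTS = ("squared", "euclidean")


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric pairwise distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    dialect: str = "squared"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} labels")
        if not np.allclose(vals, vals.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(vals) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="analyte_id")

    @classmethod
    def load_csv(cls, path, dialect: str = "squared") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=tuple(df.index.astype(str)),
                   values=df.to_numpy(dtype=float), dialect=dialect)

    def save_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style text for interoperability."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{self.values[i, j]:.10g}" for j in range(i))
                fh.write(f"{lab[:10]:<10s} {row}".rstrip() + "\n")


def color_distance(
    a: ResponsePattern, b: ResponsePattern, dialect: str = "squared"
) -> float:
    """Colour distance between two response patterns.

    Bins must be equally long and identically ordered; the caller is
    responsible for that alignment (patterns from one feature table share it
    by construction).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if a.n_bins != b.n_bins:
        raise PatternError(
            f"incompatible patterns: {a.n_bins} vs {b.n_bins} bins"
        )
    diff = a.bins - b.bins
    total = float(np.sum(diff * diff))
    return float(np.sqrt(total)) if dialect == "euclidean" else total


def distance_matrix(
    patterns: list[ResponsePattern], dialect: str = "squared"
) -> DistanceMatrix:
    """All pairwise colour distances between patterns."""
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns")
    labels = [p.analyte_id for p in patterns]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate analyte labels in {labels}")
    n = len(patterns)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = color_distance(patterns[i], patterns[j], dialect)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=tuple(labels), values=vals, dialect=dialect)
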