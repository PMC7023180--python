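"""Per-cell mean RGB extraction and ΔRGB response patterns.

The sensor signal of one unit cell is the mean 8-bit RGB over a centred
~1000-pixel square ROI; the response to an analyte is the signed change
ΔR, ΔG, ΔB between the pre- and post-exposure images of the same chip.
One exposure yields a response pattern: an ordered vector of per-cell
(ΔR, ΔG, ΔB) bins in row-major cell order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import ChipLayout, LayoutError

CHANNELS = ("R", "G", "B")


class PatternError(ValueError):
    """Raised when response patterns cannot be paired or assembled."""


@dataclass(frozen=True)
class ResponsePattern:
    """ΔRGB response of one analyte exposure.

    ``bins`` is an (n, 3) float array of signed channel changes, one row per
    sensor cell (bin), values in [-255, 255] at full floating precision.
    ``temperature_c`` is None for concatenated multi-temperature patterns.
    """

    analyte_id: str
    temperature_c: float | None
    bins: np.ndarray
    bin_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.bins, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise PatternError(f"bins must be (n, 3), got shape {arr.shape}")
        if np.any(np.abs(arr) > 255.0):
            raise PatternError("channel deltas must lie in [-255, 255]")
        object.__setattr__(self, "bins", arr)
        if self.bin_names and len(self.bin_names) != arr.shape[0]:
            raise PatternError("bin_names length must match bin count")

    @property
    def n_bins(self) -> int:
        return self.bins.shape[0]

    def flat(self) -> np.ndarray:
        """Bins flattened to a 3n vector (bin-major: R,G,B per bin)."""
        return self.bins.reshape(-1)


def extract_cell_means(image: np.ndarray, layout: ChipLayout) -> np.ndarray:
    """Mean RGB over each cell's centred ROI square, in layout cell order.

    Returns an (n_cells, 3) float array of channel means at full precision.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise LayoutError(f"expected an RGB raster, got shape {img.shape}")
    if img.shape[0] != layout.image_height or img.shape[1] != layout.image_width:
        raise LayoutError(
            f"image is {img.shape[1]}x{img.shape[0]} but layout expects "
            f"{layout.image_width}x{layout.image_height}"
        )
    means = np.empty((len(layout.cells), 3), dtype=float)
    for i, cell in enumerate(layout.cells):
        x0, y0, x1, y1 = layout.roi_bounds(cell)
        if x0 < 0 or y0 < 0 or x1 > layout.image_width or y1 > layout.image_height:
            raise LayoutError(f"ROI of cell ({cell.row},{cell.col}) out of bounds")
        roi = img[y0:y1, x0:x1, :3].astype(float)
        means[i] = roi.mean(axis=(0, 1))
    return means


def compute_delta_pattern(
    pre_means: np.ndarray,
    post_means: np.ndarray,
    analyte_id: str,
    temperature_c: float,
    bin_names: tuple[str, ...] = (),
    absolute: bool = False,
) -> ResponsePattern:
    """Signed per-cell change post - pre (per channel).

    ``absolute=True`` takes magnitudes instead; the signed form is the
    default because it preserves the direction of the spectral shift.
    """
    pre = np.asarray(pre_means, dtype=float)
    post = np.asarray(post_means, dtype=float)
    if pre.shape != post.shape:
        raise PatternError(
            f"pre/post cell counts differ: {pre.shape} vs {post.shape}"
        )
    delta = post - pre
    if absolute:
        delta = np.abs(delta)
    return ResponsePattern(
        analyte_id=analyte_id, temperature_c=temperature_c,
        bins=delta, bin_names=tuple(bin_names),
    )


def assemble_feature_table(
    patterns: list[ResponsePattern], mode: str = "concatenated"
) -> list[ResponsePattern] | dict[float, list[ResponsePattern]]:
    """Combine per-(analyte, temperature) patterns into analysis inputs.

    concatenated (default)
        One pattern per analyte whose bins are all temperatures' bins
        stacked temperature-major (sorted ascending); n_bins multiplies by
        the number of temperatures.
    per-temperature
        Dict temperature -> list of per-analyte patterns.

    Every analyte must cover the same temperature set.
    """
    if mode not in ("concatenated", "per-temperature"):
        raise ValueError(f"unknown mode {mode!r}")
    by_analyte: dict[str, dict[float, ResponsePattern]] = {}
    analyte_order: list[str] = []
    for p in patterns:
        if p.temperature_c is None:
            raise PatternError("input patterns must carry a temperature")
        slot = by_analyte.setdefault(p.analyte_id, {})
        if p.temperature_c in slot:
            raise PatternError(
                f"duplicate pattern for ({p.analyte_id}, {p.temperature_c})"
            )
        slot[float(p.temperature_c)] = p
        if p.analyte_id not in analyte_order:
            analyte_order.append(p.analyte_id)
    temp_sets = {frozenset(v) for v in by_analyte.values()}
    if len(temp_sets) != 1:
        raise PatternError("analytes do not share an identical temperature set")
    temps = sorted(temp_sets.pop())
    n_bins = {p.n_bins for p in patterns}
    if len(n_bins) != 1:
        raise PatternError("patterns have inconsistent bin counts")

    if mode == "per-temperature":
        return {
            t: [by_analyte[a][t] for a in analyte_order] for t in temps
        }
    out = []
    for a in analyte_order:
        stacked = np.vstack([by_analyte[a][t].bins for t in temps])
        names = tuple(
            f"t{int(t)}_{name}"
            for t in temps
            for name in (by_analyte[a][t].bin_names
                         or tuple(f"bin{i}" for i in range(by_analyte[a][t].n_bins)))
        )
        out.append(ResponsePattern(
            analyte_id=a, temperature_c=None, bins=stacked, bin_names=names,
        ))
    return out


# --- CSV interchange ----------------------------------------------------

def patterns_to_frame(patterns: list[ResponsePattern]) -> pd.DataFrame:
    """Flat table: analyte_id, temperature_c, then <bin>_<channel> columns."""
    if not patterns:
        raise PatternError("no patterns to tabulate")
    names = patterns[0].bin_names or tuple(
        f"bin{i}" for i in range(patterns[0].n_bins))
    cols = [f"{b}_{ch}" for b in names for ch in CHANNELS]
    rows = []
    for p in patterns:
        row: dict = {"analyte_id": p.analyte_id,
                     "temperature_c": p.temperature_c}
        row.update(dict(zip(cols, p.flat())))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_patterns(df: pd.DataFrame) -> list[ResponsePattern]:
    """Inverse of :func:`patterns_to_frame`."""
    bin_cols = [c for c in df.columns if c not in ("analyte_id", "temperature_c")]
    if len(bin_cols) % 3 != 0:
        raise PatternError("bin columns must come in R/G/B triples")
    names = tuple(c.rsplit("_", 1)[0] for c in bin_cols[::3])
    out = []
    for _, row in df.iterrows():
        temp = row.get("temperature_c")
        temp = None if pd.isna(temp) else float(temp)
        bins = np.asarray(row[bin_cols], dtype=float).reshape(-1, 3)
        out.append(ResponsePattern(
            analyte_id=str(row["analyte_id"]), temperature_c=temp,
            bins=bins, bin_names=names,
        ))
    return out
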