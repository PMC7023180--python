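"""Sensor-chip geometry: the 3x3 grid of unit cells on a chip image.

Rows of the grid carry the three engineered phage types (wild, RGD, EEEE),
columns carry the three film colours (red, green, blue, set at deposition by
the pulling speed).  Pixel coordinates are 0-based, x right / y down, and
cell rectangles are half-open ``[x0, x0+w) x [y0, y0+h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

PHAGE_TYPES = ("wild", "RGD", "EEEE")
FILM_COLORS = ("red", "green", "blue")

# Pulling speed (um/min) that sets each film colour at deposition.
PULLING_SPEED_UM_MIN = {"red": 30, "green": 40, "blue": 50}


class LayoutError(ValueError):
    """Raised for geometrically invalid chip layouts."""


@dataclass(frozen=True)
class CellSpec:
    row: int
    col: int
    x0: int
    y0: int
    width: int
    height: int


@dataclass(frozen=True)
class ChipLayout:
    """Geometry and identity of the sensor-cell grid on a chip image.

    ``roi_side`` is the side of the centred square region averaged per cell;
    the default 32 px gives 1024 pixels, matching the ~1000-pixel averaging
    window used when reading the sensor signal.
    """

    image_width: int
    image_height: int
    cells: tuple[CellSpec, ...]
    phage_types: tuple[str, ...] = PHAGE_TYPES
    film_colors: tuple[str, ...] = FILM_COLORS
    roi_side: int = 32

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for c in self.cells:
            if c.width <= 0 or c.height <= 0:
                raise LayoutError(f"cell ({c.row},{c.col}) has non-positive size")
            if c.x0 < 0 or c.y0 < 0 or c.x0 + c.width > self.image_width \
                    or c.y0 + c.height > self.image_height:
                raise LayoutError(f"cell ({c.row},{c.col}) outside image bounds")
            if self.roi_side > c.width or self.roi_side > c.height:
                raise LayoutError(
                    f"roi_side {self.roi_side} does not fit in cell ({c.row},{c.col})"
                )
        # pairwise disjoint rectangles
        for i, a in enumerate(self.cells):
            for b in self.cells[i + 1:]:
                if (a.x0 < b.x0 + b.width and b.x0 < a.x0 + a.width
                        and a.y0 < b.y0 + b.height and b.y0 < a.y0 + a.height):
                    raise LayoutError(
                        f"cells ({a.row},{a.col}) and ({b.row},{b.col}) overlap"
                    )

    def roi_bounds(self, cell: CellSpec) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) of the centred ROI square, half-open."""
        rx = cell.x0 + (cell.width - self.roi_side) // 2
        ry = cell.y0 + (cell.height - self.roi_side) // 2
        return rx, ry, rx + self.roi_side, ry + self.roi_side

    def cell_identity(self, cell: CellSpec) -> tuple[str, str]:
        """(phage_type, film_color) of a cell: rows are phages, columns films."""
        return self.phage_types[cell.row], self.film_colors[cell.col]

    def bin_names(self) -> list[str]:
        return [f"cell{c.row}{c.col}" for c in self.cells]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cells"] = [asdict(c) for c in self.cells]
        d["phage_types"] = list(self.phage_types)
        d["film_colors"] = list(self.film_colors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChipLayout":
        cells = tuple(CellSpec(**c) for c in d["cells"])
        return cls(
            image_width=int(d["image_width"]),
            image_height=int(d["image_height"]),
            cells=cells,
            phage_types=tuple(d.get("phage_types", PHAGE_TYPES)),
            film_colors=tuple(d.get("film_colors", FILM_COLORS)),
            roi_side=int(d.get("roi_side", 32)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ChipLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_layout(
    cell_size: int = 64, margin: int = 8, gap: int = 8, roi_side: int = 32
) -> ChipLayout:
    """The default 3x3 chip: 64 px cells, 8 px margins, 32x32 px ROI."""
    cells = []
    for r in range(3):
        for c in range(3):
            cells.append(CellSpec(
                row=r, col=c,
                x0=margin + c * (cell_size + gap),
                y0=margin + r * (cell_size + gap),
                width=cell_size, height=cell_size,
            ))
    side = margin * 2 + cell_size * 3 + gap * 2
    return ChipLayout(
        image_width=side, image_height=side,
        cells=tuple(cells), roi_side=roi_side,
    )
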