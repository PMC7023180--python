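"""Synthetic sensor-chip generator with known ground truth.

Emulates the study design of a phage-based colorimetric sensor array:
9 unit cells per chip (3 engineered phage types x 3 film colours), exposed
to 8 analytes (4 estrogen drugs, 4 antibiotics) at 4 temperatures.  Analyte
uptake swells the photonic film; the swelling shifts the Bragg peak and
hence the cell colour.  Swelling follows a saturating-binding form

    s = s_max * e / (e + affinity) * temp_gain,

with ``e`` the configured exposure, ``affinity`` the per-(phage, analyte)
half-saturation and ``temp_gain`` a per-analyte multiplicative factor per
temperature level (hotter vapour reacts more strongly).  All randomness
flows from the single scenario seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .colorimetry import bragg_peak, spectrum_to_rgb8
from .layout import ChipLayout, default_layout, PHAGE_TYPES, FILM_COLORS

DEFAULT_TEMPERATURES_C = (30.0, 60.0, 90.0, 120.0)

# Unswollen film periods (nm) chosen so that zero-swelling Bragg peaks land
# near 650 / 550 / 450 nm with n_eff = 1.45: d0 = lambda / (2 * n_eff).
DEFAULT_N_EFF = 1.45
DEFAULT_D0_NM = {
    "red": 650.0 / (2 * DEFAULT_N_EFF),
    "green": 550.0 / (2 * DEFAULT_N_EFF),
    "blue": 450.0 / (2 * DEFAULT_N_EFF),
}

# Half-saturation (exposure units) of each phage coat toward each analyte
# class; lower affinity value = stronger response.  Estrogens bind the
# wild/RGD coats, the acidic EEEE coat prefers the antibiotics.
CLASS_AFFINITY_PROFILE = {
    "estrogen": {"wild": 0.6, "RGD": 0.25, "EEEE": 2.5},
    "antibiotic": {"wild": 1.8, "RGD": 2.2, "EEEE": 0.35},
}

DEFAULT_ANALYTES = ("E1", "E2", "E3", "EE2", "AMX", "AMP", "TET", "PEN")
DEFAULT_CLASSES = ("estrogen",) * 4 + ("antibiotic",) * 4


class ScenarioLookupError(KeyError):
    """Unknown analyte or temperature for a scenario."""


@dataclass(frozen=True)
class SwellingModel:
    """Optical and binding parameters of the simulated films.

    ``affinity`` maps phage type -> analyte -> half-saturation exposure (>0);
    ``temp_gain`` maps analyte -> gain per temperature level (aligned with
    the scenario's ``temperatures_c``).
    """

    d0_nm: dict = field(default_factory=lambda: dict(DEFAULT_D0_NM))
    n_eff: float = DEFAULT_N_EFF
    s_max: float = 0.12
    exposure: float = 1.0
    affinity: dict = field(default_factory=dict)
    temp_gain: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.d0_nm.values()):
            raise ValueError("all film periods d0_nm must be positive")
        if self.n_eff < 1.0:
            raise ValueError("n_eff must be >= 1")
        if self.s_max < 0:
            raise ValueError("s_max must be >= 0")
        for per_analyte in self.affinity.values():
            if any(a <= 0 for a in per_analyte.values()):
                raise ValueError("affinities must be positive")
        for gains in self.temp_gain.values():
            if any(g < 0 for g in gains):
                raise ValueError("temp_gain factors must be >= 0")

    def swelling_fraction(self, phage: str, analyte: str, temp_index: int) -> float:
        """Fractional swelling of one film; always in [0, s_max]."""
        a = self.affinity[phage][analyte]
        gain = self.temp_gain[analyte][temp_index]
        s = self.s_max * self.exposure / (self.exposure + a) * gain
        return float(min(max(s, 0.0), self.s_max))


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth generative parameters for a simulated sensing campaign."""

    analyte_ids: tuple
    class_labels: tuple
    temperatures_c: tuple
    swelling: SwellingModel
    phage_types: tuple = PHAGE_TYPES
    film_colors: tuple = FILM_COLORS
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.analyte_ids):
            raise ValueError("class_labels must align with analyte_ids")
        if len(set(self.analyte_ids)) != len(self.analyte_ids):
            raise ValueError("analyte_ids must be unique")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.phage_types) * len(self.film_colors)

    def class_of(self, analyte: str) -> str:
        try:
            return self.class_labels[self.analyte_ids.index(analyte)]
        except ValueError:
            raise ScenarioLookupError(f"unknown analyte {analyte!r}") from None

    # --- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "analyte_ids": list(self.analyte_ids),
            "class_labels": list(self.class_labels),
            "temperatures_c": [float(t) for t in self.temperatures_c],
            "phage_types": list(self.phage_types),
            "film_colors": list(self.film_colors),
            "noise_sd": float(self.noise_sd),
            "seed": int(self.seed),
            "swelling": {
                "d0_nm": {k: float(v) for k, v in self.swelling.d0_nm.items()},
                "n_eff": float(self.swelling.n_eff),
                "s_max": float(self.swelling.s_max),
                "exposure": float(self.swelling.exposure),
                "affinity": {p: {a: float(v) for a, v in d.items()}
                             for p, d in self.swelling.affinity.items()},
                "temp_gain": {a: [float(g) for g in gs]
                              for a, gs in self.swelling.temp_gain.items()},
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        sw = d["swelling"]
        return cls(
            analyte_ids=tuple(d["analyte_ids"]),
            class_labels=tuple(d["class_labels"]),
            temperatures_c=tuple(float(t) for t in d["temperatures_c"]),
            phage_types=tuple(d.get("phage_types", PHAGE_TYPES)),
            film_colors=tuple(d.get("film_colors", FILM_COLORS)),
            noise_sd=float(d.get("noise_sd", 0.0)),
            seed=int(d.get("seed", 0)),
            swelling=SwellingModel(
                d0_nm=dict(sw["d0_nm"]),
                n_eff=float(sw["n_eff"]),
                s_max=float(sw["s_max"]),
                exposure=float(sw.get("exposure", 1.0)),
                affinity={p: dict(a) for p, a in sw["affinity"].items()},
                temp_gain={a: list(g) for a, g in sw["temp_gain"].items()},
            ),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_scenario(
    seed: int = 0,
    noise_sd: float = 2.0,
    class_contrast: float = 1.0,
    s_max: float = 0.12,
) -> SyntheticScenario:
    """The default two-class study design: 8 analytes x 4 temperatures.

    ``class_contrast`` scales the log-affinity separation between the two
    class binding profiles (1 = nominal, 0 = classes indistinguishable);
    it is the separability dial used in sensitivity checks.
    """
    analytes = DEFAULT_ANALYTES
    classes = DEFAULT_CLASSES
    affinity: dict = {p: {} for p in PHAGE_TYPES}
    for phage in PHAGE_TYPES:
        logs = {c: np.log(CLASS_AFFINITY_PROFILE[c][phage])
                for c in ("estrogen", "antibiotic")}
        mean_log = (logs["estrogen"] + logs["antibiotic"]) / 2.0
        for idx, (analyte, cls_label) in enumerate(zip(analytes, classes)):
            j = idx % 4  # index within class
            class_log = mean_log + class_contrast * (logs[cls_label] - mean_log)
            # small deterministic within-class spread so replicate drugs
            # respond similarly but not identically
            member_factor = 0.88 + 0.08 * j
            affinity[phage][analyte] = float(np.exp(class_log) * member_factor)
    temp_gain = {}
    for idx, analyte in enumerate(analytes):
        j = idx % 4
        tweak = 1.0 + 0.04 * ((j % 2) - 0.5)
        temp_gain[analyte] = [
            (0.55 + 0.15 * t) * tweak for t in range(len(DEFAULT_TEMPERATURES_C))
        ]
    return SyntheticScenario(
        analyte_ids=analytes,
        class_labels=classes,
        temperatures_c=DEFAULT_TEMPERATURES_C,
        swelling=SwellingModel(s_max=s_max, affinity=affinity, temp_gain=temp_gain),
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_response(
    scenario: SyntheticScenario, analyte: str, temperature_c: float
) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """Pre/post-exposure RGB of each of the 9 cells, row-major.

    Cell order is phage (row) major over film colour (column).  The pre
    colour is the zero-swelling Bragg colour of the film; the post colour
    uses the scenario's swelling model.  Deterministic given the scenario.
    """
    if analyte not in scenario.analyte_ids:
        raise ScenarioLookupError(f"unknown analyte {analyte!r}")
    temps = [float(t) for t in scenario.temperatures_c]
    if float(temperature_c) not in temps:
        raise ScenarioLookupError(f"unknown temperature {temperature_c!r}")
    t_idx = temps.index(float(temperature_c))
    sw = scenario.swelling
    out = []
    for phage in scenario.phage_types:
        for film in scenario.film_colors:
            d0 = sw.d0_nm[film]
            pre, _ = spectrum_to_rgb8(bragg_peak(d0, sw.n_eff, 0.0))
            s = sw.swelling_fraction(phage, analyte, t_idx)
            post, _ = spectrum_to_rgb8(bragg_peak(d0, sw.n_eff, s))
            out.append((pre, post))
    return out


def scenario_delta_patterns(scenario: SyntheticScenario):
    """Noise-free ground-truth ΔRGB patterns, one per (analyte, temperature).

    Bypasses imaging entirely: bins are post - pre of the simulated cell
    colours.  Useful as the exact reference for round-trip checks and for
    fast expectation studies.
    """
    from .features import ResponsePattern  # local import avoids a cycle

    names = tuple(
        f"cell{r}{c}"
        for r in range(len(scenario.phage_types))
        for c in range(len(scenario.film_colors))
    )
    out = []
    for analyte in scenario.analyte_ids:
        for temp in scenario.temperatures_c:
            pairs = simulate_response(scenario, analyte, temp)
            bins = np.array(
                [[post[ch] - pre[ch] for ch in range(3)] for pre, post in pairs],
                dtype=float,
            )
            out.append(ResponsePattern(
                analyte_id=analyte, temperature_c=float(temp),
                bins=bins, bin_names=names,
            ))
    return out


def render_chip_image(
    layout: ChipLayout,
    cell_rgbs: list[tuple[int, int, int]],
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Paint a chip raster: mid-grey background, one flat patch per cell,
    i.i.d. Gaussian pixel noise rounded and clipped to [0, 255].

    Same seed -> bit-identical raster.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(cell_rgbs) != len(layout.cells):
        raise ValueError(
            f"expected {len(layout.cells)} cell colours, got {len(cell_rgbs)}"
        )
    img = np.full((layout.image_height, layout.image_width, 3), 128.0)
    for cell, rgb in zip(layout.cells, cell_rgbs):
        img[cell.y0:cell.y0 + cell.height, cell.x0:cell.x0 + cell.width, :] = rgb
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _pair_seed(root_seed: int, analyte_index: int, temp_index: int,
               phase: int, replicate: int = 0) -> int:
    ss = np.random.SeedSequence(
        [int(root_seed), analyte_index, temp_index, phase, replicate])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_measured_patterns(
    scenario: SyntheticScenario,
    layout: ChipLayout | None = None,
    replicate: int = 0,
):
    """Render chips in memory and extract noisy ΔRGB patterns (no disk I/O).

    Equivalent to generate_dataset followed by extraction, for
    ``replicate=0``; larger replicate indices draw fresh noise, giving
    independent repeat measurements of the same ground truth.
    """
    from .features import extract_cell_means, compute_delta_pattern

    if layout is None:
        layout = default_layout()
    names = tuple(layout.bin_names())
    out = []
    for ai, analyte in enumerate(scenario.analyte_ids):
        for ti, temp in enumerate(scenario.temperatures_c):
            pairs = simulate_response(scenario, analyte, temp)
            pre_img = render_chip_image(
                layout, [p[0] for p in pairs], scenario.noise_sd,
                _pair_seed(scenario.seed, ai, ti, 0, replicate))
            post_img = render_chip_image(
                layout, [p[1] for p in pairs], scenario.noise_sd,
                _pair_seed(scenario.seed, ai, ti, 1, replicate))
            out.append(compute_delta_pattern(
                extract_cell_means(pre_img, layout),
                extract_cell_means(post_img, layout),
                analyte_id=analyte, temperature_c=float(temp),
                bin_names=names,
            ))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_dataset(
    scenario: SyntheticScenario,
    output_dir,
    layout: ChipLayout | None = None,
) -> pd.DataFrame:
    """Write one pre/post PNG pair per (analyte, temperature) plus manifest.

    Outputs under ``output_dir``:

    * ``images/<analyte>_<temp>C_{pre,post}.png`` — 8-bit RGB chips
    * ``manifest.csv`` — analyte_id, class_label, temperature_c, pre_image,
      post_image, seed (the pre-image noise seed; post seed = seed + 1 slot)
    * ``ground_truth.csv`` — per-cell pre/post RGB and swelling fraction
    * ``scenario.yaml`` / ``layout.yaml`` — config snapshot
    * ``checksums.csv`` — sha256 of every written image

    Re-running with the same scenario reproduces identical files.
    Returns the manifest as a DataFrame.
    """
    if layout is None:
        layout = default_layout()
    out = Path(output_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for ai, analyte in enumerate(scenario.analyte_ids):
        for ti, temp in enumerate(scenario.temperatures_c):
            pairs = simulate_response(scenario, analyte, temp)
            pre_seed = _pair_seed(scenario.seed, ai, ti, 0)
            post_seed = _pair_seed(scenario.seed, ai, ti, 1)
            pre_img = render_chip_image(
                layout, [p[0] for p in pairs], scenario.noise_sd, pre_seed)
            post_img = render_chip_image(
                layout, [p[1] for p in pairs], scenario.noise_sd, post_seed)
            tag = f"{analyte}_{int(temp)}C"
            pre_path = out / "images" / f"{tag}_pre.png"
            post_path = out / "images" / f"{tag}_post.png"
            Image.fromarray(pre_img).save(pre_path)
            Image.fromarray(post_img).save(post_path)
            manifest_rows.append({
                "analyte_id": analyte,
                "class_label": scenario.class_of(analyte),
                "temperature_c": float(temp),
                "pre_image": str(pre_path.relative_to(out)),
                "post_image": str(post_path.relative_to(out)),
                "seed": pre_seed,
            })
            for cell, (pre, post) in zip(layout.cells, pairs):
                phage, film = layout.cell_identity(cell)
                truth_rows.append({
                    "analyte_id": analyte,
                    "temperature_c": float(temp),
                    "row": cell.row, "col": cell.col,
                    "phage_type": phage, "film_color": film,
                    "pre_r": pre[0], "pre_g": pre[1], "pre_b": pre[2],
                    "post_r": post[0], "post_g": post[1], "post_b": post[2],
                    "swelling": scenario.swelling.swelling_fraction(
                        phage, analyte, ti),
                })
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    scenario.save(out / "scenario.yaml")
    layout.save(out / "layout.yaml")
    checksums = pd.DataFrame([
        {"file": row[col], "sha256": _sha256(out / row[col])}
        for _, row in manifest.iterrows() for col in ("pre_image", "post_image")
    ])
    checksums.to_csv(out / "checksums.csv", index=False)
    return manifest
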