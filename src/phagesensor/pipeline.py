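"""End-to-end analysis pipeline over a sensor-chip dataset.

Reads a dataset directory (as written by :func:`phagesensor.simulate.generate_dataset`
or assembled from real images plus a layout/manifest), extracts ΔRGB
response patterns, builds the colour-distance matrix, performs hierarchical
clustering, and writes machine-readable outputs with full run provenance.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .layout import ChipLayout
from .features import (
    ResponsePattern, extract_cell_means, compute_delta_pattern,
    assemble_feature_table, patterns_to_frame,
)
from .distance import distance_matrix, DistanceMatrix
from .clustering import (
    hierarchical_cluster, cut_tree, dendrogram_to_newick, Dendrogram,
)
from .simulate import render_chip_image


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_dataset_patterns(dataset_dir) -> tuple[list[ResponsePattern], dict[str, str], ChipLayout]:
    """Extract per-(analyte, temperature) ΔRGB patterns from a dataset dir.

    Expects ``manifest.csv`` (analyte_id, class_label, temperature_c,
    pre_image, post_image) and ``layout.yaml`` alongside the images.
    Returns (patterns, class label per analyte, layout).
    """
    root = Path(dataset_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    layout = ChipLayout.load(root / "layout.yaml")
    names = tuple(layout.bin_names())
    patterns = []
    classes: dict[str, str] = {}
    for _, row in manifest.iterrows():
        pre = np.asarray(Image.open(root / row["pre_image"]).convert("RGB"))
        post = np.asarray(Image.open(root / row["post_image"]).convert("RGB"))
        pre_means = extract_cell_means(pre, layout)
        post_means = extract_cell_means(post, layout)
        patterns.append(compute_delta_pattern(
            pre_means, post_means,
            analyte_id=str(row["analyte_id"]),
            temperature_c=float(row["temperature_c"]),
            bin_names=names,
        ))
        if "class_label" in row:
            classes[str(row["analyte_id"])] = str(row["class_label"])
    return patterns, classes, layout


def write_difference_maps(
    patterns: list[ResponsePattern], layout: ChipLayout, out_dir
) -> list[Path]:
    """Render each pattern's |ΔRGB| as a colour-patch chip image (display only;
    the analysis path keeps signed values)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for p in patterns:
        cells = [tuple(int(round(v)) for v in np.abs(row)) for row in p.bins]
        img = render_chip_image(layout, cells, noise_sd=0.0, seed=0)
        tag = f"{p.analyte_id}_{int(p.temperature_c)}C" \
            if p.temperature_c is not None else p.analyte_id
        path = out / f"diffmap_{tag}.png"
        Image.fromarray(img).save(path)
        written.append(path)
    return written


def plot_dendrogram(tree: Dendrogram, path, title: str = "") -> None:
    """Dendrogram figure via matplotlib (merge table in scipy layout)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    Z = np.array([[m[0], m[1], m[2], m[3]] for m in tree.merges], dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4))
    scipy_dendrogram(Z, labels=list(tree.leaf_labels), ax=ax,
                     color_threshold=0.0, above_threshold_color="k")
    ax.set_ylabel("merge height (colour distance)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def analyze_dataset(
    dataset_dir,
    out_dir,
    mode: str = "concatenated",
    dialect: str = "squared",
    linkage: str = "ward_d",
    k: int = 2,
    make_plots: bool = True,
) -> dict:
    """Full analysis of a chip dataset; writes outputs and the run manifest.

    Outputs under ``out_dir``: features.csv, distances.csv / distances.phy,
    dendrogram.nwk, merges.csv, cut_labels.csv, difference maps and a
    dendrogram plot, plus run_manifest.json listing every file's checksum
    and the options used.  Returns a summary dict (tree, labels, ARI when
    ground-truth classes are known).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patterns, classes, layout = load_dataset_patterns(dataset_dir)
    patterns_to_frame(patterns).to_csv(out / "features.csv", index=False)

    assembled = assemble_feature_table(patterns, mode=mode)
    results: dict = {"mode": mode, "dialect": dialect, "linkage": linkage, "k": k}
    tables = {"all": assembled} if mode == "concatenated" \
        else {f"{int(t)}C": pats for t, pats in assembled.items()}

    summaries = {}
    for tag, pats in tables.items():
        suffix = "" if tag == "all" else f"_{tag}"
        dmat = distance_matrix(pats, dialect=dialect)
        dmat.save_csv(out / f"distances{suffix}.csv")
        dmat.save_phylip(out / f"distances{suffix}.phy")
        tree = hierarchical_cluster(dmat, linkage=linkage)
        (out / f"dendrogram{suffix}.nwk").write_text(
            dendrogram_to_newick(tree) + "\n")
        tree.save_csv(out / f"merges{suffix}.csv")
        labels = cut_tree(tree, k)
        lab_df = pd.DataFrame({
            "analyte_id": list(tree.leaf_labels),
            "cluster": labels,
        })
        if classes:
            lab_df["class_label"] = [classes[a] for a in tree.leaf_labels]
        lab_df.to_csv(out / f"cut_labels{suffix}.csv", index=False)
        entry = {"tree": tree, "distance": dmat, "cut_labels": labels}
        if classes:
            from sklearn.metrics import adjusted_rand_score
            truth = [classes[a] for a in tree.leaf_labels]
            entry["ari"] = float(adjusted_rand_score(truth, labels))
        if make_plots:
            plot_dendrogram(tree, out / f"dendrogram{suffix}.png",
                            title=f"{linkage} / {dialect} / {tag}")
        summaries[tag] = entry
    if make_plots:
        write_difference_maps(patterns, layout, out / "difference_maps")
    results["tables"] = summaries

    file_list = sorted(p for p in out.rglob("*") if p.is_file()
                       and p.name != "run_manifest.json")
    manifest = {
        "tool": "phagesensor",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "dataset_dir": str(dataset_dir),
        "options": {"mode": mode, "dialect": dialect,
                    "linkage": linkage, "k": k},
        "files": {str(p.relative_to(out)): _sha256(p) for p in file_list},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
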