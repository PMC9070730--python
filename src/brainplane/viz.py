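"""Static figures: morph profile, linear-prediction error, and side-by-side
choice previews for the console chooser."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_morph_profile(profile, path: str | Path) -> Path:
    """Step plot of the normalised morph ratio across AP, anterior left."""
    fig, ax = plt.subplots(figsize=(6, 3))
    for iv in profile.intervals:
        ax.plot(
            [iv.ap_start_mm, iv.ap_end_mm],
            [iv.morph_ratio, iv.morph_ratio],
            color="k",
        )
        ax.plot(iv.ap_start_mm, iv.morph_ratio, "ro", ms=4)
    ax.axhline(1.0, color="0.6", ls="--", lw=0.8)
    ax.invert_xaxis()
    ax.set_xlabel("AP (mm from bregma)")
    ax.set_ylabel("normalised morph ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_linear_error(error_table, path: str | Path) -> Path:
    """Deviation of the anchored mapping from a two-endpoint linear fit."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(error_table["ap_actual"], error_table["error_um"], "k-", lw=1)
    anchors = error_table[error_table["is_anchor"]]
    ax.plot(anchors["ap_actual"], anchors["error_um"], "ro", ms=4)
    ax.axhline(0.0, color="0.6", ls="--", lw=0.8)
    ax.invert_xaxis()
    ax.set_xlabel("AP (mm from bregma)")
    ax.set_ylabel("actual - linear prediction (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def save_choice_preview(
    stack, left: int, middle: int, right: int, reference_ap: float,
    path: str | Path, plate=None,
) -> Path:
    """Side-by-side candidate planes (and the reference plate mask, if
    given) written for the console chooser to inspect."""
    panels = [("left", left), ("middle", middle), ("right", right)]
    n = len(panels) + (plate is not None)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3))
    axes = np.atleast_1d(axes)
    for ax, (name, z) in zip(axes, panels):
        ax.imshow(stack.read_plane(z), cmap="gray")
        ax.set_title(f"{name}: plane {z}")
        ax.axis("off")
    if plate is not None:
        axes[-1].imshow(plate.label_mask, cmap="tab10")
        axes[-1].set_title(f"plate AP {plate.ap_mm:+.2f}")
        axes[-1].axis("off")
    fig.suptitle(f"reference AP {reference_ap:+.3f} mm")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
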