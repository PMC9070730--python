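"""Per-plane blob segmentation and 3D duplicate consolidation (2.5D).

High z-resolution stacks image each labelled soma on several adjacent
planes, so independent 2D segmentation of every plane counts the same cell
multiple times.  The pipeline therefore segments plane by plane
(difference-of-Gaussians band-pass, threshold, connected components, area
filter) and then consolidates the per-plane detections: detections whose
in-plane centroid distance and axial separation both fall within
user-chosen thresholds are linked, each connected group becomes one cell at
the member with the highest peak intensity, and the remaining members are
erased.

Grouping is transitive (graph connected components), so a cell smeared
across many planes merges into a single call even when its extreme planes
are farther apart than the axial threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from skimage import filters, measure

from .errors import SegmentationError
from .io_core import CleanupParams, SegmentationFilter, StackManifest

DETECTION_COLUMNS = ["x_um", "y_um", "z_index", "peak_intensity", "area_um2"]
CELL_COLUMNS = ["x_um", "y_um", "z_index", "peak_intensity", "n_merged"]


@dataclass(frozen=True)
class Detection:
    """One 2D segmented object: intensity-weighted centroid in physical
    in-plane coordinates, plane index, peak raw intensity, and area."""

    x_um: float
    y_um: float
    z_index: int
    peak_intensity: float
    area_um2: float


@dataclass(frozen=True)
class Cell:
    """One consolidated 3D cell; atlas fields are filled by the mapping
    stage."""

    x_um: float
    y_um: float
    z_index: int
    peak_intensity: float
    n_merged: int
    ap_mm: float | None = None
    atlas_x: float | None = None
    atlas_y: float | None = None
    region_id: int | None = None


def empty_detections() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "z_index": pd.Series(dtype=int),
            "peak_intensity": pd.Series(dtype=float),
            "area_um2": pd.Series(dtype=float),
        }
    )


def segment_plane(
    image: np.ndarray,
    filt: SegmentationFilter,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Segment one plane; returns a detections frame (without ``z_index``).

    Pipeline: DoG band-pass at the filter's two scales -> threshold on the
    filtered response (absolute, or a quantile of the plane if
    ``threshold_quantile`` is set) -> connected components -> area filter ->
    per-object intensity-weighted centroid and peak raw intensity.
    """
    if pixel_size_um <= 0:
        raise SegmentationError("pixel_size_um must be positive")
    sig_lo = filt.dog_sigma_small_um / pixel_size_um
    sig_hi = filt.dog_sigma_large_um / pixel_size_um
    if sig_lo < 1.0:
        raise SegmentationError(
            f"dog_sigma_small_um {filt.dog_sigma_small_um} um is below one "
            f"pixel ({pixel_size_um} um) — increase the scale or the "
            "sampling"
        )
    img = np.asarray(image, dtype=float)
    response = filters.difference_of_gaussians(img, sig_lo, sig_hi)
    if filt.threshold_quantile is not None:
        thr = float(np.quantile(response, filt.threshold_quantile))
    else:
        thr = float(filt.intensity_threshold)
    fg = response > thr
    if not fg.any():
        return empty_detections().drop(columns=["z_index"])
    labels = measure.label(fg, connectivity=2)
    px_area = pixel_size_um**2
    rows = []
    for region in measure.regionprops(labels, intensity_image=img):
        area_um2 = region.area * px_area
        if not filt.min_area_um2 <= area_um2 <= filt.max_area_um2:
            continue
        # centroid weighted by the raw intensity within the object
        cy, cx = region.centroid_weighted
        rows.append(
            {
                "x_um": cx * pixel_size_um,
                "y_um": cy * pixel_size_um,
                "peak_intensity": float(region.intensity_max),
                "area_um2": area_um2,
            }
        )
    if not rows:
        return empty_detections().drop(columns=["z_index"])
    return pd.DataFrame(rows)[["x_um", "y_um", "peak_intensity", "area_um2"]]


def segment_loop(
    stack: StackManifest,
    filt: SegmentationFilter,
    *,
    checkpoint_dir: str | Path | None = None,
    log=None,
) -> pd.DataFrame:
    """Segment every plane of the stack and concatenate the detections.

    If ``checkpoint_dir`` is given, per-plane results are appended to
    ``detections.partial.csv`` as they complete; a rerun after a failure
    resumes from the first unfinished plane and yields the same final frame
    as an uninterrupted run.  An unreadable plane raises
    :class:`SegmentationError` naming the file.
    """
    partial_path = progress = None
    done_planes: set[int] = set()
    frames: list[pd.DataFrame] = []
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
        partial_path = checkpoint_dir / "detections.partial.csv"
        if partial_path.exists():
            prior = pd.read_csv(partial_path)
            if len(prior):
                done_planes = set(prior["z_index"].astype(int))
                frames.append(prior)
    for z in range(stack.n_planes):
        if z in done_planes:
            continue
        try:
            image = stack.read_plane(z)
        except Exception as exc:
            raise SegmentationError(
                f"cannot read plane {z} "
                f"({stack.image_paths[z]}): {exc}"
            ) from exc
        dets = segment_plane(image, filt, stack.pixel_size_um)
        dets.insert(2, "z_index", z)
        if log is not None:
            log(f"segment: plane {z}: {len(dets)} detections")
        frames.append(dets)
        if partial_path is not None:
            dets.to_csv(
                partial_path,
                mode="a",
                header=not partial_path.exists(),
                index=False,
            )
    if not frames:
        return empty_detections()
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["z_index", "y_um", "x_um"], kind="stable"
    ).reset_index(drop=True)
    return out[DETECTION_COLUMNS]


# ---------------------------------------------------------------------------
# duplicate cleanup
# ---------------------------------------------------------------------------


def duplicate_groups(
    dets: pd.DataFrame, p: CleanupParams, z_step_um: float
) -> np.ndarray:
    """Component label per detection: two detections are linked iff their
    in-plane centroid distance is <= ``xy_thresh_um`` *and* their axial
    separation ``|dz_index| * z_step_um`` is <= ``z_thresh_um``; labels are
    the transitive closure (connected components).

    Neighbor candidates come from a KD-tree on the in-plane coordinates
    (not an all-pairs scan); the result is exactly the all-pairs answer.
    """
    n = len(dets)
    if n == 0:
        return np.empty(0, dtype=int)
    xy = dets[["x_um", "y_um"]].to_numpy(float)
    z = dets["z_index"].to_numpy(float) * z_step_um
    tree = cKDTree(xy)
    pairs = tree.query_pairs(p.xy_thresh_um, output_type="ndarray")
    if len(pairs):
        keep = np.abs(z[pairs[:, 0]] - z[pairs[:, 1]]) <= p.z_thresh_um
        pairs = pairs[keep]
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = sparse.csgraph.connected_components(adj, directed=False)
    return labels


def clean_duplicates(
    dets: pd.DataFrame, p: CleanupParams, z_step_um: float
) -> pd.DataFrame:
    """Consolidate per-plane detections into cells.

    Each duplicate group is represented by its member with the maximum
    ``peak_intensity`` (ties broken toward the lower ``z_index``, then
    original order); the representative's coordinates are kept and
    ``n_merged`` records the group size.
    """
    if len(dets) == 0:
        return pd.DataFrame(
            {c: pd.Series(dtype=float) for c in CELL_COLUMNS}
        ).astype({"z_index": int, "n_merged": int})
    labels = duplicate_groups(dets, p, z_step_um)
    peak = dets["peak_intensity"].to_numpy()
    zidx = dets["z_index"].to_numpy()
    order = np.lexsort((np.arange(len(dets)), zidx, -peak))
    # first occurrence of each label in that order is the representative
    seen: dict[int, int] = {}
    sizes = np.bincount(labels)
    for i in order:
        seen.setdefault(int(labels[i]), int(i))
    reps = sorted(seen.values())
    out = dets.iloc[reps][
        ["x_um", "y_um", "z_index", "peak_intensity"]
    ].reset_index(drop=True)
    out["n_merged"] = [int(sizes[labels[i]]) for i in reps]
    return out
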