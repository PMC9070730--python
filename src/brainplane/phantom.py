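"""Synthetic phantoms: image stacks, atlas bundles and ground truth.

The phantom emulates the structure the pipeline assumes of a cleared-brain
light-sheet dataset, at desk scale:

* a strictly monotone, *nonlinear* z -> AP morph (linear ramp between the
  endpoint APs plus a smooth Gaussian bump, endpoint-exact and validated
  monotone) standing in for nonuniform tissue shrinkage and expansion;
* a miniature atlas of nested geometric regions — an elliptical tissue
  outline holding two mid-level bands that each contain two circular leaf
  regions — rendered at several AP plates with plate-to-plate variation;
* cells rendered as 3D Gaussian blobs sampled onto planes, so each cell is
  imaged on several adjacent planes (the duplicate-generation mechanism the
  cleanup stage exists for), over Gaussian background noise;
* an :func:`oracle_chooser` that plays the choice game truthfully from the
  phantom's true morph, standing in for the human player.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .atlas import (
    AtlasBundle,
    AtlasPlate,
    Ontology,
    RegionNode,
    canonicalize_contour,
    save_atlas,
)
from .errors import PhantomError
from .io_core import StackManifest, im_sort

# placement margins (um): keep planted cells clearly inside their region,
# away from AP bin boundaries, and separated enough that segmentation and
# cleanup can in principle recover each one individually
REGION_MARGIN_PX = 4
AP_BIN_MARGIN_MM = 0.025
MIN_SEP_XY_UM = 40.0
MIN_SEP_Z_UM = 30.0


# ---------------------------------------------------------------------------
# morph curves
# ---------------------------------------------------------------------------


def morph_curve(
    n_planes: int,
    ap_start_mm: float,
    ap_end_mm: float,
    bump_amp_mm: float = 0.0,
    bump_center: float = 0.5,
    bump_width: float = 0.25,
) -> np.ndarray:
    """True AP coordinate per plane: linear ramp plus a Gaussian bump.

    The bump (amplitude in mm, centre and width as fractions of the stack)
    is corrected by a linear ramp so the endpoint APs are met exactly.
    Raises :class:`PhantomError` if the requested bump breaks strict
    monotonicity.
    """
    if ap_end_mm >= ap_start_mm:
        raise PhantomError("ap_start_mm must be anterior to (>) ap_end_mm")
    t = np.linspace(0.0, 1.0, n_planes)
    bump = bump_amp_mm * np.exp(-0.5 * ((t - bump_center) / bump_width) ** 2)
    bump = bump - ((1 - t) * bump[0] + t * bump[-1])  # endpoint-exact
    ap = ap_start_mm + (ap_end_mm - ap_start_mm) * t + bump
    if np.any(np.diff(ap) >= 0):
        raise PhantomError(
            "morph is not strictly decreasing; reduce bump_amp_mm "
            f"({bump_amp_mm} mm over a {ap_start_mm - ap_end_mm} mm span)"
        )
    return ap


def random_morph(
    rng: np.random.Generator,
    n_planes: int,
    ap_start_mm: float,
    ap_end_mm: float,
    amp_range_mm: tuple[float, float] = (0.05, 0.15),
) -> np.ndarray:
    """A random valid morph: amplitude (random sign) in ``amp_range_mm``,
    centre in [0.25, 0.75], width in [0.15, 0.35]."""
    for _ in range(100):
        amp = rng.uniform(*amp_range_mm) * rng.choice([-1.0, 1.0])
        center = rng.uniform(0.25, 0.75)
        width = rng.uniform(0.15, 0.35)
        try:
            return morph_curve(
                n_planes, ap_start_mm, ap_end_mm, amp, center, width
            )
        except PhantomError:
            continue
    raise PhantomError("could not draw a monotone morph in 100 attempts")


# ---------------------------------------------------------------------------
# the miniature atlas
# ---------------------------------------------------------------------------

_ONTOLOGY_ROWS = [
    # (id, acronym, name, parent, color)
    (1, "BRAIN", "whole brain", None, "#bfbfbf"),
    (2, "CTX", "cortical band", 1, "#70ff71"),
    (3, "SUB", "subcortical band", 1, "#ff7080"),
    (4, "PL", "prelimbic-like disc", 2, "#2fa850"),
    (5, "IL", "infralimbic-like disc", 2, "#59b363"),
    (6, "ACB", "accumbens-like disc", 3, "#d06aa8"),
    (7, "TH", "thalamus-like disc", 3, "#ff909f"),
]


def phantom_ontology() -> Ontology:
    return Ontology(
        [RegionNode(i, a, n, p, c) for i, a, n, p, c in _ONTOLOGY_ROWS]
    )


def _ellipse_outline(cx, cy, a, b, n=256) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return canonicalize_contour(
        np.column_stack([cx + a * np.cos(th), cy + b * np.sin(th)])
    )


def _plate_mask(shape: tuple[int, int], k: int, n_plates: int) -> np.ndarray:
    """Label mask for plate ``k``: tissue ellipse, CTX/SUB split whose line
    drifts with k, and four leaf discs whose radii grow with k."""
    h, w = shape
    cy, cx = h / 2.0, w / 2.0
    a, b = 0.42 * w, 0.38 * h
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    frac = k / max(n_plates - 1, 1)
    split = cy + (frac - 0.5) * 0.08 * h  # drifts ~+-4% of height
    mask = np.zeros(shape, dtype=np.int64)
    mask[inside & (yy < split)] = 2
    mask[inside & (yy >= split)] = 3
    r = (0.06 + 0.03 * frac) * min(h, w)
    centers = {
        4: (cx - 0.18 * w, cy - 0.16 * h),
        5: (cx + 0.18 * w, cy - 0.16 * h),
        6: (cx - 0.18 * w, cy + 0.16 * h),
        7: (cx + 0.18 * w, cy + 0.16 * h),
    }
    for rid, (dx, dy) in centers.items():
        disc = (xx - dx) ** 2 + (yy - dy) ** 2 <= r**2
        mask[disc & inside] = rid
    return mask


def make_phantom_atlas(
    plate_aps: list[float],
    shape: tuple[int, int] = (256, 256),
) -> AtlasBundle:
    """A synthetic bundle: one plate per AP (strictly decreasing), nested
    regions from the fixed seven-region ontology."""
    h, w = shape
    outline = _ellipse_outline(w / 2.0, h / 2.0, 0.42 * w, 0.38 * h)
    plates = [
        AtlasPlate(
            ap_mm=float(ap),
            label_mask=_plate_mask(shape, k, len(plate_aps)),
            outline=outline.copy(),
            plate_number=k + 1,
        )
        for k, ap in enumerate(plate_aps)
    ]
    return AtlasBundle(plates=plates, ontology=phantom_ontology())


# ---------------------------------------------------------------------------
# phantom specification and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one synthetic dataset.

    Defaults describe the standard desk-scale study stack: 300 planes of
    256 x 256 px at 2.5 um pixels and 2.5 um z-step (so the stack spans
    0.75 mm of AP, matching the acquisition z-step of whole-brain
    light-sheet imaging), a nonlinear morph bump, and 60 cells whose axial
    spread covers several planes.
    """

    n_planes: int = 300
    plane_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 2.5
    z_step_um: float = 2.5
    ap_start_mm: float = 0.40
    ap_end_mm: float = -0.35
    bump_amp_mm: float = 0.08
    bump_center: float = 0.45
    bump_width: float = 0.22
    n_plates: int = 5
    n_cells: int = 60
    cell_sigma_xy_um: float = 5.0
    cell_sigma_z_um: float = 4.0
    cell_amplitude: float = 2000.0
    tissue_level: float = 200.0
    outside_level: float = 50.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.noise_sd < 0:
            raise PhantomError("n_cells and noise_sd must be >= 0")

    @property
    def plate_aps(self) -> list[float]:
        return [
            float(ap)
            for ap in np.linspace(
                self.ap_start_mm, self.ap_end_mm, self.n_plates + 2
            )[1:-1]
        ]

    def true_ap(self) -> np.ndarray:
        return morph_curve(
            self.n_planes,
            self.ap_start_mm,
            self.ap_end_mm,
            self.bump_amp_mm,
            self.bump_center,
            self.bump_width,
        )


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: per-plane true AP, the planted cells
    (physical coordinates plus their true region), and per-region counts."""

    true_ap: np.ndarray
    cells: pd.DataFrame  # x_um, y_um, z_center_um, region_id
    region_counts: dict[int, int]
    spec: PhantomSpec

    def save(self, truth_dir: str | Path) -> Path:
        d = Path(truth_dir)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"z_index": np.arange(len(self.true_ap)), "ap_mm": self.true_ap}
        ).to_csv(d / "true_ap.csv", index=False)
        self.cells.to_csv(d / "cells.csv", index=False)
        pd.DataFrame(
            sorted(self.region_counts.items()),
            columns=["region_id", "count"],
        ).to_csv(d / "region_counts.csv", index=False)
        return d

    @classmethod
    def load(cls, truth_dir: str | Path, spec: PhantomSpec | None = None):
        d = Path(truth_dir)
        ap = pd.read_csv(d / "true_ap.csv")["ap_mm"].to_numpy()
        cells = pd.read_csv(d / "cells.csv")
        counts = dict(
            pd.read_csv(d / "region_counts.csv").itertuples(index=False)
        )
        return cls(
            true_ap=ap,
            cells=cells,
            region_counts={int(k): int(v) for k, v in counts.items()},
            spec=spec or PhantomSpec(),
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _plant_cells(
    spec: PhantomSpec, atlas: AtlasBundle, true_ap: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place cells uniformly inside (eroded) regions, respecting AP bin
    margins and a minimum pairwise separation."""
    from scipy import ndimage

    z_step = spec.z_step_um
    plate_aps = np.array([p.ap_mm for p in atlas.plates])
    # AP bin edges: midpoints between consecutive plates, clamped by the
    # forward-warp cutoff at the two ends
    mids = (plate_aps[:-1] + plate_aps[1:]) / 2.0
    half_gap = float(np.max(plate_aps[:-1] - plate_aps[1:])) / 2.0
    hi_edges = np.concatenate([[plate_aps[0] + half_gap], mids])
    lo_edges = np.concatenate([mids, [plate_aps[-1] - half_gap]])
    z_margin_um = 3.5 * spec.cell_sigma_z_um
    ap_hi_lim = float(true_ap[0])
    ap_lo_lim = float(true_ap[-1])
    # candidate pixels per (plate, region): eroded so blobs stay inside
    struct = np.ones((2 * REGION_MARGIN_PX + 1,) * 2, dtype=bool)
    pools: dict[tuple[int, int], np.ndarray] = {}
    for k, plate in enumerate(atlas.plates):
        for rid in (2, 3, 4, 5, 6, 7):
            core = ndimage.binary_erosion(
                plate.label_mask == rid, structure=struct
            )
            pts = np.argwhere(core)  # (row, col)
            if len(pts):
                pools[(k, rid)] = pts
    if not pools:
        raise PhantomError("regions too small for any cell placement")
    region_choices = [4, 5, 6, 7, 2, 3]
    region_weights = np.array([0.2, 0.2, 0.2, 0.2, 0.1, 0.1])
    placed: list[dict] = []
    attempts = 0
    while len(placed) < spec.n_cells:
        attempts += 1
        if attempts > 200 * max(spec.n_cells, 1):
            raise PhantomError(
                f"could only place {len(placed)}/{spec.n_cells} cells; "
                "regions too small for the requested count"
            )
        k = int(rng.integers(len(atlas.plates)))
        rid = int(rng.choice(region_choices, p=region_weights))
        if (k, rid) not in pools:
            continue
        lo = max(lo_edges[k] + AP_BIN_MARGIN_MM, ap_lo_lim)
        hi = min(hi_edges[k] - AP_BIN_MARGIN_MM, ap_hi_lim)
        if hi <= lo:
            continue
        ap = rng.uniform(lo, hi)
        # invert the monotone morph: plane position as a float
        z_float = float(np.interp(-ap, -true_ap, np.arange(spec.n_planes)))
        z_center_um = z_float * z_step
        if not z_margin_um <= z_center_um <= (
            (spec.n_planes - 1) * z_step - z_margin_um
        ):
            continue
        row, col = pools[(k, rid)][int(rng.integers(len(pools[(k, rid)])))]
        x_um = (col + rng.uniform(-0.3, 0.3)) * spec.pixel_size_um
        y_um = (row + rng.uniform(-0.3, 0.3)) * spec.pixel_size_um
        ok = True
        for prev in placed:
            dxy = np.hypot(prev["x_um"] - x_um, prev["y_um"] - y_um)
            dz = abs(prev["z_center_um"] - z_center_um)
            if dxy < MIN_SEP_XY_UM and dz < MIN_SEP_Z_UM:
                ok = False
                break
        if not ok:
            continue
        # ground-truth region: look it up from the nearest plate, honestly
        from .atlas import nearest_plate

        plate = nearest_plate(atlas, ap)
        true_rid = int(
            plate.label_mask[
                int(round(y_um / spec.pixel_size_um)),
                int(round(x_um / spec.pixel_size_um)),
            ]
        )
        placed.append(
            {
                "x_um": x_um,
                "y_um": y_um,
                "z_center_um": z_center_um,
                "ap_mm": ap,
                "region_id": true_rid,
            }
        )
    return pd.DataFrame(placed)


def _render_stack(
    spec: PhantomSpec,
    atlas: AtlasBundle,
    cells: pd.DataFrame,
    rng: np.random.Generator,
    images_dir: Path,
) -> list[Path]:
    h, w = spec.plane_shape
    tissue = atlas.plates[0].label_mask > 0  # same ellipse on every plate
    base = np.where(tissue, spec.tissue_level, spec.outside_level)
    sig_xy_px = spec.cell_sigma_xy_um / spec.pixel_size_um
    win = max(2, int(np.ceil(4 * sig_xy_px)))
    paths = []
    cell_rows = list(cells.itertuples()) if len(cells) else []
    for z in range(spec.n_planes):
        img = base + rng.normal(0.0, spec.noise_sd, size=(h, w))
        z_um = z * spec.z_step_um
        for c in cell_rows:
            dz = z_um - c.z_center_um
            if abs(dz) > 4 * spec.cell_sigma_z_um:
                continue
            amp = spec.cell_amplitude * np.exp(
                -0.5 * (dz / spec.cell_sigma_z_um) ** 2
            )
            cx = c.x_um / spec.pixel_size_um
            cy = c.y_um / spec.pixel_size_um
            x0, x1 = max(0, int(cx) - win), min(w, int(cx) + win + 1)
            y0, y1 = max(0, int(cy) - win), min(h, int(cy) + win + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += amp * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig_xy_px**2)
            )
        out = np.clip(img, 0, 65535).astype(np.uint16)
        path = images_dir / f"phantom_Z{z:04d}.tif"
        tifffile.imwrite(path, out)
        paths.append(path)
    return paths


def make_phantom(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[StackManifest, AtlasBundle, PhantomTruth]:
    """Generate a complete phantom dataset under ``out_dir``.

    Writes ``images/`` (TIFF planes), ``atlas/`` (a saved bundle) and
    ``truth/`` (CSV ground truth); returns the in-memory triple.  The
    output is bit-identical across runs with the same spec.
    """
    out = Path(out_dir)
    images_dir = out / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    true_ap = spec.true_ap()
    atlas = make_phantom_atlas(spec.plate_aps, spec.plane_shape)
    cells = _plant_cells(spec, atlas, true_ap, rng)
    _render_stack(spec, atlas, cells, rng, images_dir)
    manifest = im_sort(
        sorted(str(p) for p in images_dir.glob("*.tif")),
        z_step_um=spec.z_step_um,
        pixel_size_um=spec.pixel_size_um,
        channel_tag="phantom",
    )
    counts = (
        cells["region_id"].value_counts().to_dict() if len(cells) else {}
    )
    truth = PhantomTruth(
        true_ap=true_ap,
        cells=cells,
        region_counts={int(k): int(v) for k, v in counts.items()},
        spec=spec,
    )
    save_atlas(atlas, out / "atlas")
    truth.save(out / "truth")
    return manifest, atlas, truth


# ---------------------------------------------------------------------------
# the truthful oracle
# ---------------------------------------------------------------------------


class OracleChooser:
    """Plays the choice game from the phantom's true morph.

    ``choose`` returns the candidate whose true AP is nearest the reference
    (exact ties go to the middle); ``accept_midpoint`` accepts when the
    interpolated AP is within ``ap_tol_mm`` of the plane's true AP.  Counts
    its calls for termination analyses.
    """

    def __init__(self, true_ap: np.ndarray, ap_tol_mm: float = 0.025):
        self.true_ap = np.asarray(true_ap, dtype=float)
        self.ap_tol_mm = float(ap_tol_mm)
        self.n_choose_calls = 0
        self.n_midpoint_calls = 0

    def choose(self, left, middle, right, reference_ap, context) -> str:
        self.n_choose_calls += 1
        d = {
            tok: abs(self.true_ap[idx] - reference_ap)
            for tok, idx in (
                ("left", left),
                ("middle", middle),
                ("right", right),
            )
        }
        best = min(d.values())
        if d["middle"] == best:  # ties toward middle
            return "middle"
        return "left" if d["left"] == best else "right"

    def accept_midpoint(self, z_index, ap_mm, context) -> bool:
        self.n_midpoint_calls += 1
        return abs(self.true_ap[int(z_index)] - ap_mm) <= self.ap_tol_mm


def oracle_chooser(
    truth: PhantomTruth | np.ndarray, ap_tol_mm: float = 0.025
) -> OracleChooser:
    """Build the truthful chooser from a phantom truth (or a raw true-AP
    array)."""
    true_ap = truth.true_ap if isinstance(truth, PhantomTruth) else truth
    return OracleChooser(true_ap, ap_tol_mm=ap_tol_mm)


def match_recovered(
    truth_cells: pd.DataFrame,
    recovered: pd.DataFrame,
    z_step_um: float,
) -> pd.DataFrame:
    """Greedy nearest-neighbour pairing of planted and recovered cells.

    For each planted cell, the recovered cell minimising in-plane distance
    plus axial distance is taken (one recovered cell may in principle match
    several planted ones; with well-separated phantoms the pairing is a
    bijection).  Returns the truth frame with ``matched_region_id`` and
    ``match_dist_um`` columns, for region-agreement scoring.
    """
    rec_xy = recovered[["x_um", "y_um"]].to_numpy(float)
    rec_z = recovered["z_index"].to_numpy(float) * z_step_um
    out = truth_cells.copy()
    matched, dists = [], []
    for r in truth_cells.itertuples():
        d = np.hypot(rec_xy[:, 0] - r.x_um, rec_xy[:, 1] - r.y_um) + np.abs(
            rec_z - r.z_center_um
        )
        j = int(np.argmin(d))
        matched.append(int(recovered["region_id"].iloc[j])
                       if "region_id" in recovered else -1)
        dists.append(float(d[j]))
    out["matched_region_id"] = matched
    out["match_dist_um"] = dists
    return out
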