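"""Per-plate 2D nonrigid registration from correspondence points.

Each registered atlas plate gets a :class:`Warp`: a pair of thin-plate
spline (TPS) transforms fitted independently in the two directions
(image -> plate pixels, plate -> image pixels) from the same ordered list of
correspondence point pairs.  Initial correspondences are seeded
automatically by sampling the tissue boundary of the image and the plate
outline at equal arc length, starting from the dorsal-most point and
proceeding clockwise on both curves; a corrector (console user or callback)
may then add, move or delete pairs, with single-step undo, before the warp
is fitted.

With regularization 0 the TPS interpolates: every control point is mapped
exactly (to numerical precision).  Increasing the regularization trades
control-point fidelity for a smoother, lower-bending-energy deformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .atlas import AtlasBundle, AtlasPlate, canonicalize_contour
from .errors import ChooserAborted, RegistrationError


# ---------------------------------------------------------------------------
# thin-plate spline core
# ---------------------------------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, with U(0) = 0; computed from squared distances as
    # 0.5 * r^2 log r^2 to avoid a square root
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


@dataclass
class ThinPlateSpline:
    """One fitted 2D -> 2D thin-plate spline f(src) ~= dst."""

    src: np.ndarray            # (n, 2) control sources
    weights: np.ndarray        # (n, 2) kernel weights
    affine: np.ndarray         # (3, 2) rows: constant, x, y
    regularization: float

    @classmethod
    def fit(
        cls, src: np.ndarray, dst: np.ndarray, regularization: float = 0.0
    ) -> "ThinPlateSpline":
        src = np.asarray(src, dtype=float)
        dst = np.asarray(dst, dtype=float)
        n = len(src)
        if n < 4:
            raise RegistrationError(
                f"TPS needs at least 4 control pairs, got {n}"
            )
        if regularization < 0:
            raise RegistrationError("regularization must be >= 0")
        # reject degenerate configurations up front: the affine part needs
        # full-rank [1 | x | y]
        P = np.column_stack([np.ones(n), src])
        if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
            raise RegistrationError(
                "control points are collinear; TPS system is singular"
            )
        d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
        if np.any(d2[~np.eye(n, dtype=bool)] == 0):
            raise RegistrationError("duplicate control points")
        K = _tps_kernel(d2) + regularization * np.eye(n)
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        b = np.zeros((n + 3, 2))
        b[:n] = dst
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise RegistrationError(f"TPS system is singular: {exc}") from exc
        return cls(
            src=src,
            weights=sol[:n],
            affine=sol[n:],
            regularization=regularization,
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        if len(pts) == 0:
            return pts.copy()
        d2 = np.sum((pts[:, None, :] - self.src[None, :, :]) ** 2, axis=-1)
        U = _tps_kernel(d2)
        out = (
            U @ self.weights
            + self.affine[0]
            + pts[:, :1] * self.affine[1]
            + pts[:, 1:2] * self.affine[2]
        )
        return out

    def bending_energy(self) -> float:
        """w^T K w, summed over the two output dimensions."""
        d2 = np.sum(
            (self.src[:, None, :] - self.src[None, :, :]) ** 2, axis=-1
        )
        K = _tps_kernel(d2)
        return float(np.sum(self.weights * (K @ self.weights)))


# ---------------------------------------------------------------------------
# correspondence point sets
# ---------------------------------------------------------------------------


class CorrespondencePointSet:
    """An ordered list of (atlas_xy, image_xy) pairs with undo history."""

    def __init__(self, atlas_xy: np.ndarray, image_xy: np.ndarray):
        atlas_xy = np.asarray(atlas_xy, dtype=float).reshape(-1, 2)
        image_xy = np.asarray(image_xy, dtype=float).reshape(-1, 2)
        if len(atlas_xy) != len(image_xy):
            raise ValueError("atlas and image point lists differ in length")
        self.atlas_xy = atlas_xy
        self.image_xy = image_xy
        self.history: list[tuple[np.ndarray, np.ndarray]] = []

    def __len__(self) -> int:
        return len(self.atlas_xy)

    @property
    def pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return list(zip(self.atlas_xy, self.image_xy))

    def _push(self) -> None:
        self.history.append((self.atlas_xy.copy(), self.image_xy.copy()))


def edit_points(
    ps: CorrespondencePointSet, action: str, payload=None
) -> CorrespondencePointSet:
    """Apply one edit: ``add``, ``remove``, ``move`` or ``undo``.

    Payloads: ``add`` -> (atlas_xy, image_xy); ``remove`` -> index;
    ``move`` -> (index, side, new_xy) with side ``"atlas"`` or ``"image"``.
    Every non-undo edit pushes the previous pair list onto the history
    stack; ``undo`` pops it, restoring the exact previous list.
    """
    if action == "undo":
        if not ps.history:
            raise IndexError("undo with empty history")
        ps.atlas_xy, ps.image_xy = ps.history.pop()
        return ps
    if action == "add":
        atlas_xy, image_xy = payload
        ps._push()
        ps.atlas_xy = np.vstack([ps.atlas_xy, np.asarray(atlas_xy, float)])
        ps.image_xy = np.vstack([ps.image_xy, np.asarray(image_xy, float)])
        return ps
    if action == "remove":
        idx = int(payload)
        if not 0 <= idx < len(ps):
            raise IndexError(f"pair index {idx} out of range 0..{len(ps)-1}")
        ps._push()
        ps.atlas_xy = np.delete(ps.atlas_xy, idx, axis=0)
        ps.image_xy = np.delete(ps.image_xy, idx, axis=0)
        return ps
    if action == "move":
        idx, side, new_xy = payload
        idx = int(idx)
        if not 0 <= idx < len(ps):
            raise IndexError(f"pair index {idx} out of range 0..{len(ps)-1}")
        if side not in ("atlas", "image"):
            raise ValueError(f"side must be 'atlas' or 'image', got {side!r}")
        ps._push()
        target = ps.atlas_xy if side == "atlas" else ps.image_xy
        target[idx] = np.asarray(new_xy, dtype=float)
        return ps
    raise ValueError(f"unknown edit action {action!r}")


# ---------------------------------------------------------------------------
# warps
# ---------------------------------------------------------------------------


@dataclass
class Warp:
    """Forward (image -> atlas) and inverse (atlas -> image) TPS pair
    fitted independently from the same control pairs."""

    kind: str
    control_atlas: np.ndarray
    control_image: np.ndarray
    regularization: float
    forward_tps: ThinPlateSpline
    inverse_tps: ThinPlateSpline

    def transform(self, points, direction: str = "forward") -> np.ndarray:
        if direction == "forward":
            return self.forward_tps(points)
        if direction == "inverse":
            return self.inverse_tps(points)
        raise ValueError(f"direction must be forward|inverse, got {direction!r}")


def fit_warp(
    ps: CorrespondencePointSet, regularization: float = 0.0
) -> Warp:
    """Fit the forward and inverse TPS from a point set (>= 4 pairs)."""
    fwd = ThinPlateSpline.fit(ps.image_xy, ps.atlas_xy, regularization)
    inv = ThinPlateSpline.fit(ps.atlas_xy, ps.image_xy, regularization)
    return Warp(
        kind="thin-plate-spline",
        control_atlas=ps.atlas_xy.copy(),
        control_image=ps.image_xy.copy(),
        regularization=regularization,
        forward_tps=fwd,
        inverse_tps=inv,
    )


def apply_warp(w: Warp, points, direction: str = "forward") -> np.ndarray:
    """Transform (n, 2) xy coordinates through a fitted warp."""
    return w.transform(points, direction)


# ---------------------------------------------------------------------------
# automatic contour correspondences
# ---------------------------------------------------------------------------


def _resample_closed(contour: np.ndarray, n_points: int) -> np.ndarray:
    """Sample a closed polygon at n equal arc-length positions, keeping the
    start vertex."""
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, arc, closed[:, 0])
    y = np.interp(targets, arc, closed[:, 1])
    return np.column_stack([x, y])


def tissue_mask(image: np.ndarray) -> np.ndarray:
    """Foreground tissue mask: Otsu threshold on log intensity, holes
    filled, largest connected component kept."""
    logim = np.log1p(np.asarray(image, dtype=float))
    if logim.min() == logim.max():
        raise RegistrationError(
            "image is constant; no foreground to threshold"
        )
    thr = filters.threshold_otsu(logim)
    mask = logim > thr
    if not mask.any():
        raise RegistrationError("no foreground found by automatic threshold")
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def init_correspondence(
    image: np.ndarray, plate: AtlasPlate, n_points: int = 32
) -> CorrespondencePointSet:
    """Seed correspondences from the tissue boundary.

    The image's tissue outline and the plate outline are each resampled at
    ``n_points`` equal arc-length positions from the dorsal-most point,
    clockwise, and paired by index.
    """
    if n_points < 8:
        raise ValueError("need n_points >= 8 for a stable boundary warp")
    mask = tissue_mask(image)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise RegistrationError("tissue mask has no boundary contour")
    rc = max(contours, key=len)
    if len(rc) < n_points:
        raise RegistrationError(
            f"tissue contour has only {len(rc)} vertices; cannot place "
            f"{n_points} correspondence points"
        )
    # smooth the rasterised contour (circular moving average): the raw
    # marching-squares polyline is a staircase whose arc length is locally
    # inflated, which would skew equal-arc-length sampling
    win = min(9, max(3, len(rc) // 16))
    rc = ndimage.uniform_filter1d(rc, size=win, axis=0, mode="wrap")
    image_contour = canonicalize_contour(np.column_stack([rc[:, 1], rc[:, 0]]))
    plate_contour = canonicalize_contour(plate.outline)
    image_pts = _resample_closed(image_contour, n_points)
    atlas_pts = _resample_closed(plate_contour, n_points)
    return CorrespondencePointSet(atlas_xy=atlas_pts, image_xy=image_pts)


# ---------------------------------------------------------------------------
# warp persistence (documented text format)
# ---------------------------------------------------------------------------
#
# plate_<AP>.warp is a plain-text file:
#   line 1: "tps <n_pairs> <regularization>"
#   then n_pairs lines: atlas_x atlas_y image_x image_y   (%.17g floats)
# The CSV twin (plate_<AP>.csv) duplicates the pairs for spreadsheet use.
# Coefficients are re-solved on load; the solve is deterministic, so a
# saved and reloaded warp transforms points identically.


def _plate_tag(ap_mm: float) -> str:
    return f"{ap_mm:+.3f}".replace("-", "m").replace("+", "p")


def save_warps(warps: dict[float, Warp], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ap, w in warps.items():
        tag = _plate_tag(ap)
        pairs = [
            (float(ax), float(ay), float(ix), float(iy))
            for (ax, ay), (ix, iy) in zip(w.control_atlas, w.control_image)
        ]
        with open(out / f"plate_{tag}.warp", "w") as fh:
            fh.write(
                f"tps {len(pairs)} {float(w.regularization)!r} {float(ap)!r}\n"
            )
            for ax, ay, ix, iy in pairs:
                fh.write(f"{ax!r} {ay!r} {ix!r} {iy!r}\n")
        with open(out / f"plate_{tag}.csv", "w") as fh:
            fh.write("atlas_x,atlas_y,image_x,image_y\n")
            for ax, ay, ix, iy in pairs:
                fh.write(f"{ax!r},{ay!r},{ix!r},{iy!r}\n")
    return out


def load_warps(in_dir: str | Path) -> dict[float, Warp]:
    warps: dict[float, Warp] = {}
    for path in sorted(Path(in_dir).glob("plate_*.warp")):
        with open(path) as fh:
            head = fh.readline().split()
            if len(head) != 4 or head[0] != "tps":
                raise ValueError(f"{path}: bad warp header {head}")
            n, lam, ap = int(head[1]), float(head[2]), float(head[3])
            rows = [
                [float(v) for v in fh.readline().split()] for _ in range(n)
            ]
        arr = np.array(rows)
        ps = CorrespondencePointSet(atlas_xy=arr[:, :2], image_xy=arr[:, 2:])
        warps[ap] = fit_warp(ps, lam)
    return dict(sorted(warps.items(), reverse=True))


# ---------------------------------------------------------------------------
# the registration loop
# ---------------------------------------------------------------------------

Corrector = Callable[
    [CorrespondencePointSet, np.ndarray, AtlasPlate],
    "CorrespondencePointSet | None",
]


def accept_corrector(
    ps: CorrespondencePointSet, image: np.ndarray, plate: AtlasPlate
) -> CorrespondencePointSet:
    """A corrector that accepts the automatic correspondences unchanged."""
    return ps


def regi_loop(
    stack,
    amap,
    atlas: AtlasBundle,
    plate_aps: Iterable[float],
    corrector: Corrector = accept_corrector,
    *,
    n_points: int = 32,
    regularization: float = 0.0,
    save_dir: str | Path | None = None,
    overwrite: bool = False,
    max_retries: int = 3,
) -> dict[float, Warp]:
    """Register the requested plates one by one and save each warp.

    For each plate AP the plane whose interpolated AP is nearest is loaded,
    correspondences are seeded from the tissue/plate contours, handed to the
    corrector for edits, and the warp fitted and saved.  Plates already
    saved under ``save_dir`` are skipped unless ``overwrite``; a corrector
    returning ``None`` (abort) marks the plate skipped and the loop
    continues; a singular fit re-prompts the corrector up to ``max_retries``
    times.
    """
    from .atlas import nearest_plate as _nearest

    existing: dict[float, Warp] = {}
    if save_dir is not None and Path(save_dir).is_dir():
        existing = load_warps(save_dir)
    warps: dict[float, Warp] = {}
    for ap in plate_aps:
        ap = float(ap)
        if not overwrite and ap in existing:
            warps[ap] = existing[ap]
            continue
        plate = _nearest(atlas, ap)
        plane = amap.plane_at_ap(ap)
        image = stack.read_plane(plane)
        ps = init_correspondence(image, plate, n_points=n_points)
        fitted = None
        for _attempt in range(max_retries):
            try:
                edited = corrector(ps, image, plate)
            except ChooserAborted:
                edited = None
            if edited is None:
                break  # plate skipped
            try:
                fitted = fit_warp(edited, regularization)
                break
            except RegistrationError:
                ps = edited
                continue
        if fitted is None:
            continue
        warps[ap] = fitted
    if save_dir is not None:
        save_warps(warps, save_dir)
    return dict(sorted(warps.items(), reverse=True))
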