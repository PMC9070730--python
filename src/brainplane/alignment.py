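"""Anchor-based anterior-posterior (AP) alignment.

Tissue clearing deforms brains nonuniformly along the AP axis, so the plane
index of a coronal stack is not linearly related to its atlas AP coordinate.
This module recovers the z -> AP mapping from a small set of *anchors*:
planes whose AP coordinate a user (or a programmatic oracle) has pinned by
matching them to reference atlas plates.  The mapping between anchors is
piecewise linear.

Anchors are found with the *choice game*, a coarse-to-fine ternary search:
the current best-guess plane is shown with a further-anterior and a
further-posterior alternative at a given plane offset; picking a side
recentres the guess, picking the middle advances to the next (smaller)
offset in the schedule.  A *midpoint check* then audits each inter-anchor
interval at its midpoint and, where interpolation is judged off, plays the
game again to insert an extra anchor.

The :class:`MorphProfile` quantifies the recovered nonuniformity as the
local plane-count-per-AP ratio normalised by the whole-stack average, and
:func:`linear_prediction_error` reports how far a naive two-endpoint linear
assignment would land from the anchored mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

from .errors import ChooserAborted, MonotonicityError
from .io_core import AlignConfig

ChoiceGameConfig = AlignConfig  # alias: the choice game reads the same block

ANCHOR_SOURCES = ("endpoint", "choice_game", "midpoint_check")


@dataclass(frozen=True)
class APAnchor:
    """One pinned plane: 0-based plane index, its AP coordinate in mm from
    bregma, and how the anchor was obtained."""

    z_index: int
    ap_mm: float
    source: str = "endpoint"

    def __post_init__(self) -> None:
        if self.source not in ANCHOR_SOURCES:
            raise ValueError(
                f"anchor source must be one of {ANCHOR_SOURCES}, "
                f"got {self.source!r}"
            )


class AlignmentMap:
    """An ordered set of anchors defining the piecewise-linear z <-> AP map.

    Anchors are kept sorted by ``z_index``; their AP coordinates must be
    strictly decreasing (the stack is acquired anterior first).  Both
    endpoints (planes 0 and ``n_planes - 1``) must be anchored before any
    interpolation is permitted.
    """

    def __init__(
        self,
        n_planes: int,
        z_step_um: float,
        anchors: list[APAnchor] | None = None,
    ):
        if n_planes < 2:
            raise ValueError("an alignment map needs at least 2 planes")
        if z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        self.n_planes = int(n_planes)
        self.z_step_um = float(z_step_um)
        self.anchors: list[APAnchor] = []
        for a in anchors or []:
            self.add_anchor(a)

    # -- anchor bookkeeping ------------------------------------------------

    def check_insertion(self, z_index: int, ap_mm: float) -> None:
        """Raise :class:`MonotonicityError` if anchoring ``(z_index, ap_mm)``
        would break strict AP monotonicity against existing anchors."""
        if not 0 <= z_index < self.n_planes:
            raise MonotonicityError(
                f"z_index {z_index} outside stack [0, {self.n_planes - 1}]"
            )
        for a in self.anchors:
            if a.z_index == z_index:
                if a.ap_mm != ap_mm:
                    raise MonotonicityError(
                        f"plane {z_index} already anchored at AP {a.ap_mm}"
                    )
            elif a.z_index < z_index and a.ap_mm <= ap_mm:
                raise MonotonicityError(
                    f"anchor ({z_index}, {ap_mm}) not posterior to "
                    f"({a.z_index}, {a.ap_mm})"
                )
            elif a.z_index > z_index and a.ap_mm >= ap_mm:
                raise MonotonicityError(
                    f"anchor ({z_index}, {ap_mm}) not anterior to "
                    f"({a.z_index}, {a.ap_mm})"
                )

    def add_anchor(self, anchor: APAnchor) -> APAnchor:
        self.check_insertion(anchor.z_index, anchor.ap_mm)
        if any(a.z_index == anchor.z_index for a in self.anchors):
            return anchor  # identical re-insertion is a no-op
        self.anchors.append(anchor)
        self.anchors.sort(key=lambda a: a.z_index)
        return anchor

    @property
    def has_endpoints(self) -> bool:
        return (
            len(self.anchors) >= 2
            and self.anchors[0].z_index == 0
            and self.anchors[-1].z_index == self.n_planes - 1
        )

    def _require_endpoints(self) -> None:
        if not self.has_endpoints:
            raise MonotonicityError(
                "both stack endpoints must be anchored before interpolation "
                f"(anchored planes: {[a.z_index for a in self.anchors]})"
            )

    # -- interpolation -----------------------------------------------------

    def interpolate(self, z_index) -> np.ndarray | float:
        """Piecewise-linear AP estimate at plane(s) ``z_index``."""
        self._require_endpoints()
        z = np.asarray(z_index)
        if np.any(z < 0) or np.any(z > self.n_planes - 1):
            raise IndexError(
                f"z_index {z_index} outside [0, {self.n_planes - 1}]"
            )
        zs = np.array([a.z_index for a in self.anchors], dtype=float)
        aps = np.array([a.ap_mm for a in self.anchors])
        out = np.interp(z.astype(float), zs, aps)
        return float(out) if np.isscalar(z_index) else out

    def all_plane_aps(self) -> np.ndarray:
        return self.interpolate(np.arange(self.n_planes))

    def plane_at_ap(self, ap_mm: float) -> int:
        """The plane whose interpolated AP is closest to ``ap_mm``."""
        aps = self.all_plane_aps()
        return int(np.argmin(np.abs(aps - ap_mm)))

    # -- serialisation -----------------------------------------------------

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "z_index": [a.z_index for a in self.anchors],
                "ap_mm": [a.ap_mm for a in self.anchors],
                "source": [a.source for a in self.anchors],
            }
        )
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# n_planes={self.n_planes} z_step_um={self.z_step_um!r}\n")
            df.to_csv(fh, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlignmentMap":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# n_planes="):
                raise ValueError(f"{path} is not an alignment checkpoint")
            fields = dict(
                kv.split("=") for kv in header[2:].strip().split(" ")
            )
            df = pd.read_csv(fh)
        anchors = [
            APAnchor(int(r.z_index), float(r.ap_mm), str(r.source))
            for r in df.itertuples()
        ]
        return cls(
            n_planes=int(fields["n_planes"]),
            z_step_um=float(fields["z_step_um"]),
            anchors=anchors,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AlignmentMap)
            and self.n_planes == other.n_planes
            and self.z_step_um == other.z_step_um
            and self.anchors == other.anchors
        )

    def __repr__(self) -> str:
        return (
            f"AlignmentMap(n_planes={self.n_planes}, "
            f"z_step_um={self.z_step_um}, anchors={len(self.anchors)})"
        )


def interpolate_ap(amap: AlignmentMap, z_index):
    """Functional alias for :meth:`AlignmentMap.interpolate`."""
    return amap.interpolate(z_index)


# ---------------------------------------------------------------------------
# chooser protocol
# ---------------------------------------------------------------------------


class Chooser(Protocol):
    """What the choice game needs from a human or programmatic player."""

    def choose(
        self,
        left: int,
        middle: int,
        right: int,
        reference_ap: float,
        context: dict,
    ) -> str:
        """Return ``"left"``, ``"middle"`` or ``"right"``."""

    def accept_midpoint(
        self, z_index: int, ap_mm: float, context: dict
    ) -> bool:
        """Whether the interpolated AP at an interval midpoint looks right."""


# ---------------------------------------------------------------------------
# the choice game
# ---------------------------------------------------------------------------


def choice_game(
    amap: AlignmentMap,
    reference_ap: float,
    chooser: Chooser,
    cfg: ChoiceGameConfig | None = None,
    *,
    source: str = "choice_game",
    context: dict | None = None,
) -> APAnchor:
    """Locate the plane matching one reference plate and anchor it.

    The initial middle plane is the one whose interpolated AP (from the
    current map, i.e. all anchors pinned so far) is closest to
    ``reference_ap``.  Each cycle presents ``(middle - s, middle, middle + s)``
    (clamped to the stack) at the current schedule step ``s``; a left/right
    choice recentres the middle at that candidate with the step unchanged,
    while choosing the middle advances to the next smaller step.  Choosing
    the middle at the final step terminates, and the final middle plane is
    anchored at exactly ``reference_ap`` — the chosen plane is *defined* to
    correspond to the reference plate.

    A side choice that could not be anchored without breaking AP
    monotonicity against existing anchors is rejected and the chooser is
    re-prompted; a terminal middle in that situation raises
    :class:`MonotonicityError`.
    """
    cfg = cfg or ChoiceGameConfig()
    amap._require_endpoints()
    lo, hi = amap.anchors[-1].ap_mm, amap.anchors[0].ap_mm
    if not lo < reference_ap < hi:
        raise ValueError(
            f"reference AP {reference_ap} not strictly inside the anchored "
            f"range ({lo}, {hi})"
        )
    ctx = dict(context or {})
    ctx.setdefault("reference_ap", reference_ap)
    schedule = cfg.step_schedule
    middle = amap.plane_at_ap(reference_ap)
    level = 0
    rejected: int | None = None
    while True:
        s = schedule[level]
        left = max(0, middle - s)
        right = min(amap.n_planes - 1, middle + s)
        token = chooser.choose(left, middle, right, reference_ap, ctx)
        if token not in ("left", "middle", "right"):
            raise ValueError(f"chooser returned invalid token {token!r}")
        if token == "middle":
            if level == len(schedule) - 1:
                break
            level += 1
            rejected = None
            continue
        candidate = left if token == "left" else right
        if candidate == middle:
            # clamping collapsed this side onto the middle; treat as middle
            if level == len(schedule) - 1:
                break
            level += 1
            continue
        try:
            amap.check_insertion(candidate, reference_ap)
        except MonotonicityError as exc:
            if rejected == candidate:
                raise MonotonicityError(
                    f"chooser insists on plane {candidate}, which cannot be "
                    f"anchored at AP {reference_ap}: {exc}"
                ) from exc
            rejected = candidate
            ctx["rejection"] = str(exc)
            continue  # re-prompt with the same presentation
        middle = candidate
        rejected = None
    anchor = APAnchor(z_index=middle, ap_mm=reference_ap, source=source)
    amap.add_anchor(anchor)
    return anchor


def midpoint_check(
    amap: AlignmentMap,
    atlas=None,
    chooser: Chooser | None = None,
    cfg: ChoiceGameConfig | None = None,
    *,
    context: dict | None = None,
) -> AlignmentMap:
    """Audit each inter-anchor interval at its midpoint (single pass).

    For every consecutive anchor pair present on entry, the midpoint plane
    and its interpolated AP are offered to the chooser; on rejection the
    choice game is played at that AP and the winning plane is inserted as a
    new anchor (source ``midpoint_check``).  Returns the (mutated) map.
    """
    if chooser is None:
        raise ValueError("midpoint_check needs a chooser")
    cfg = cfg or ChoiceGameConfig()
    ctx = dict(context or {})
    if atlas is not None:
        ctx.setdefault("atlas", atlas)
    pairs = list(zip(amap.anchors, amap.anchors[1:]))
    for a, b in pairs:
        if b.z_index - a.z_index < 2:
            continue  # no interior plane to check
        zm = (a.z_index + b.z_index) // 2
        apm = float(amap.interpolate(zm))
        if chooser.accept_midpoint(zm, apm, ctx):
            continue
        choice_game(
            amap, apm, chooser, cfg, source="midpoint_check", context=ctx
        )
    return amap


def refine_alignment(
    amap: AlignmentMap,
    atlas=None,
    chooser: Chooser | None = None,
    cfg: ChoiceGameConfig | None = None,
    max_rounds: int = 12,
) -> AlignmentMap:
    """Repeat :func:`midpoint_check` until a pass inserts no new anchor
    (or ``max_rounds`` passes have run)."""
    for _ in range(max_rounds):
        before = len(amap.anchors)
        midpoint_check(amap, atlas, chooser, cfg)
        if len(amap.anchors) == before:
            break
    return amap


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MorphInterval:
    ap_start_mm: float
    ap_end_mm: float
    morph_ratio: float


@dataclass
class MorphProfile:
    """Normalised local morph ratio per inter-anchor interval.

    For the interval between consecutive anchors, the ratio is the local
    planes-per-mm slope divided by the whole-stack (endpoint-to-endpoint)
    average, so a perfectly uniform stack scores 1 everywhere, compressed
    tissue scores < 1 and stretched tissue > 1.  The |dAP|-weighted mean of
    the ratios is identically 1.
    """

    intervals: list[MorphInterval]

    def weighted_mean(self) -> float:
        w = np.array([abs(i.ap_start_mm - i.ap_end_mm) for i in self.intervals])
        r = np.array([i.morph_ratio for i in self.intervals])
        return float(np.sum(w * r) / np.sum(w))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ap_start_mm": [i.ap_start_mm for i in self.intervals],
                "ap_end_mm": [i.ap_end_mm for i in self.intervals],
                "morph_ratio": [i.morph_ratio for i in self.intervals],
            }
        )


def morph_profile(amap: AlignmentMap) -> MorphProfile:
    """Morph-ratio profile of an anchored map (needs >= 2 anchors)."""
    if len(amap.anchors) < 2:
        raise ValueError("morph profile needs at least 2 anchors")
    first, last = amap.anchors[0], amap.anchors[-1]
    total_dz = last.z_index - first.z_index
    total_dap = abs(first.ap_mm - last.ap_mm)
    if total_dap == 0:
        raise ZeroDivisionError("endpoint anchors span zero AP distance")
    global_slope = total_dz / total_dap  # planes per mm
    intervals = []
    for a, b in zip(amap.anchors, amap.anchors[1:]):
        dap = abs(a.ap_mm - b.ap_mm)
        if dap == 0:
            raise ZeroDivisionError(
                f"zero-length AP interval between planes {a.z_index} and "
                f"{b.z_index}"
            )
        ratio = ((b.z_index - a.z_index) / dap) / global_slope
        intervals.append(MorphInterval(a.ap_mm, b.ap_mm, ratio))
    return MorphProfile(intervals)


def linear_prediction_error(amap: AlignmentMap) -> pd.DataFrame:
    """Per-plane difference between the anchored mapping and a naive linear
    (endpoints-only) assignment.

    Returns a frame with columns ``z_index``, ``ap_actual`` (all anchors),
    ``ap_linear`` (endpoints only), ``error_um`` = (actual - linear) x 1000,
    and ``is_anchor``.  A plane that is truly more posterior than its linear
    prediction has negative error.
    """
    amap._require_endpoints()
    z = np.arange(amap.n_planes)
    ap_actual = amap.all_plane_aps()
    endpoints = AlignmentMap(
        amap.n_planes,
        amap.z_step_um,
        anchors=[
            replace(amap.anchors[0]),
            replace(amap.anchors[-1]),
        ],
    )
    ap_linear = endpoints.all_plane_aps()
    anchor_z = {a.z_index for a in amap.anchors}
    return pd.DataFrame(
        {
            "z_index": z,
            "ap_actual": ap_actual,
            "ap_linear": ap_linear,
            "error_um": (ap_actual - ap_linear) * 1000.0,
            "is_anchor": [int(i) in anchor_z for i in z],
        }
    )
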