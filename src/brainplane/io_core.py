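"""Stack discovery, output layout, configuration, logging, and checkpoints.

A run of the pipeline is anchored by two objects defined here: the
:class:`StackManifest`, an ordered list of single-channel coronal TIFF planes
with their physical voxel spacing, and the :class:`PipelineConfig`, which
bundles the manifest with the per-stage parameter blocks and an output
directory.  Every stage writes its intermediate results to a fixed
subdirectory of the output root so that an analysis can be interrupted and
resumed, or split between several people, without recomputing earlier stages.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    CheckpointCorruptError,
    CheckpointMissingError,
    StackOrderError,
)

#: Pipeline stage names, in canonical execution order of their producers.
STAGES = (
    "alignment",
    "registrations",
    "segmentation",
    "cells",
    "tables",
    "figures",
    "logs",
)

#: Default z-index pattern: a ``Z``/``z`` or ``_`` immediately followed by the
#: numeric plane index, e.g. ``scan_Z0042.tif`` or ``plane_0042.tif``.
DEFAULT_Z_PATTERN = r"[Zz_](\d+)(?=\.|_|$)"


@dataclass(frozen=True)
class StackManifest:
    """An ordered single-channel image stack with physical spacing.

    Parameters
    ----------
    image_paths
        Plane files ordered by ascending z index (anterior acquired first).
    z_step_um
        Physical spacing between consecutive planes, micrometres.
    pixel_size_um
        In-plane pixel edge length, micrometres.
    channel_tag
        Free-text channel label (e.g. ``"autofluo"`` or ``"fos"``).
    """

    image_paths: tuple[str, ...]
    z_step_um: float = 2.5
    pixel_size_um: float = 2.5
    channel_tag: str = ""

    def __post_init__(self) -> None:
        if self.z_step_um <= 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        if self.pixel_size_um <= 0:
            raise ValueError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )

    @property
    def n_planes(self) -> int:
        return len(self.image_paths)

    def read_plane(self, z_index: int) -> np.ndarray:
        """Load one plane as a 2D array."""
        return tifffile.imread(self.image_paths[z_index])


def _extract_z(path: str, pattern: str) -> int:
    name = Path(path).name
    matches = re.findall(pattern, name)
    if len(matches) == 0:
        raise StackOrderError(
            f"path {path!r} does not match z pattern {pattern!r}"
        )
    if len(matches) > 1:
        raise StackOrderError(
            f"path {path!r} matches z pattern {pattern!r} "
            f"{len(matches)} times; expected exactly one match"
        )
    m = matches[0]
    # a pattern with several alternative groups returns a tuple
    if isinstance(m, tuple):
        m = next(g for g in m if g)
    return int(m)


def im_sort(
    paths: list[str] | list[Path],
    z_pattern: str = DEFAULT_Z_PATTERN,
    *,
    z_step_um: float = 2.5,
    pixel_size_um: float = 2.5,
    channel_tag: str = "",
) -> StackManifest:
    """Order plane files by their numeric z index (natural sort).

    ``z_pattern`` is a regular expression with one numeric capture group that
    must match each file name exactly once.  Indices are compared numerically,
    so ``Z2`` sorts before ``Z10``.

    Raises
    ------
    StackOrderError
        If a path does not match the pattern exactly once, or two paths carry
        the same z index.
    """
    indexed: list[tuple[int, str]] = []
    seen: dict[int, str] = {}
    for p in paths:
        z = _extract_z(str(p), z_pattern)
        if z in seen:
            raise StackOrderError(
                f"duplicate z index {z}: {seen[z]!r} and {str(p)!r}"
            )
        seen[z] = str(p)
        indexed.append((z, str(p)))
    indexed.sort(key=lambda t: t[0])
    return StackManifest(
        image_paths=tuple(p for _, p in indexed),
        z_step_um=z_step_um,
        pixel_size_um=pixel_size_um,
        channel_tag=channel_tag,
    )


def get_savepaths(output_root: str | Path) -> dict[str, Path]:
    """Create (idempotently) the standard stage subdirectories.

    Returns a mapping from stage name to its subdirectory path.  Calling this
    twice on the same root is a no-op and returns identical paths.
    """
    root = Path(output_root)
    try:
        root.mkdir(parents=True, exist_ok=True)
        paths = {}
        for stage in STAGES:
            d = root / stage
            d.mkdir(exist_ok=True)
            paths[stage] = d
        return paths
    except OSError as exc:
        raise OSError(f"output root {root} is not writable: {exc}") from exc


def log_message(savepaths: Mapping[str, Path], message: str) -> None:
    """Append a timestamped line to ``logs/run.log``."""
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    with open(Path(savepaths["logs"]) / "run.log", "a") as fh:
        fh.write(f"{stamp}  {message}\n")


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class AlignConfig:
    """Choice-game and midpoint-check parameters.

    ``step_schedule`` is the coarse-to-fine progression of plane offsets
    presented per refinement level.  ``reference_aps`` are the AP coordinates
    (mm from bregma, anterior positive, strictly decreasing) of the internal
    reference plates to anchor; ``None`` means the bundled default plates.
    ``endpoint_ap_start``/``endpoint_ap_end`` are the manually assigned AP
    coordinates of the first and last plane.  ``midpoint_tol_mm`` is the AP
    tolerance at which a midpoint is accepted during the check; the default
    equals the alignment resolution (finest step x z-step = 10 x 2.5 um).
    """

    step_schedule: tuple[int, ...] = (200, 100, 30, 10)
    reference_aps: tuple[float, ...] | None = None
    endpoint_ap_start: float | None = None
    endpoint_ap_end: float | None = None
    midpoint_tol_mm: float = 0.025

    def __post_init__(self) -> None:
        sched = tuple(int(s) for s in self.step_schedule)
        if any(s <= 0 for s in sched):
            raise ValueError("step_schedule entries must be positive")
        if any(a <= b for a, b in zip(sched, sched[1:])):
            raise ValueError("step_schedule must be strictly decreasing")
        object.__setattr__(self, "step_schedule", sched)
        if self.reference_aps is not None:
            aps = tuple(float(a) for a in self.reference_aps)
            if any(later >= earlier for earlier, later in zip(aps, aps[1:])):
                raise ValueError("reference_aps must be strictly decreasing")
            object.__setattr__(self, "reference_aps", aps)


@dataclass
class RegisterConfig:
    """Plate registration parameters: number of contour correspondence
    points, TPS regularization, and which plate APs to register (``None``
    means every plate in the atlas bundle)."""

    n_points: int = 32
    regularization: float = 0.0
    plate_aps: tuple[float, ...] | None = None


@dataclass
class SegmentationFilter:
    """Band-pass blob filter: difference-of-Gaussians scales (um), an
    absolute threshold on the filtered response (or a quantile of it), and
    object area bounds (um^2)."""

    dog_sigma_small_um: float = 3.0
    dog_sigma_large_um: float = 9.0
    intensity_threshold: float = 100.0
    threshold_quantile: float | None = None
    min_area_um2: float = 15.0
    max_area_um2: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.dog_sigma_small_um < self.dog_sigma_large_um:
            raise ValueError(
                "need 0 < dog_sigma_small_um < dog_sigma_large_um"
            )
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("need min_area_um2 < max_area_um2")
        if self.threshold_quantile is not None and not (
            0 < self.threshold_quantile < 1
        ):
            raise ValueError("threshold_quantile must be in (0, 1)")


@dataclass
class CleanupParams:
    """Distance thresholds for consolidating per-plane detections into 3D
    cells: maximum in-plane centroid distance and maximum axial separation,
    both in micrometres."""

    xy_thresh_um: float = 10.0
    z_thresh_um: float = 7.5

    def __post_init__(self) -> None:
        if self.xy_thresh_um <= 0 or self.z_thresh_um < 0:
            raise ValueError("cleanup thresholds must be positive")


@dataclass
class PipelineConfig:
    """Everything a full run needs, serialisable to a single YAML file."""

    stack: StackManifest
    output_root: Path
    atlas_dir: Path | None = None
    align: AlignConfig = field(default_factory=AlignConfig)
    register: RegisterConfig = field(default_factory=RegisterConfig)
    seg: SegmentationFilter = field(default_factory=SegmentationFilter)
    cleanup: CleanupParams = field(default_factory=CleanupParams)
    truth_dir: Path | None = None  # phantom ground truth, oracle modes only
    seed: int = 0

    def savepaths(self) -> dict[str, Path]:
        return get_savepaths(self.output_root)

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> Path:
        doc: dict[str, Any] = {
            "stack": {
                "image_paths": list(self.stack.image_paths),
                "z_step_um": self.stack.z_step_um,
                "pixel_size_um": self.stack.pixel_size_um,
                "channel_tag": self.stack.channel_tag,
            },
            "output_root": str(self.output_root),
            "atlas_dir": None if self.atlas_dir is None else str(self.atlas_dir),
            "truth_dir": None if self.truth_dir is None else str(self.truth_dir),
            "align": {
                **asdict(self.align),
                "step_schedule": list(self.align.step_schedule),
                "reference_aps": (
                    None
                    if self.align.reference_aps is None
                    else [float(a) for a in self.align.reference_aps]
                ),
            },
            "register": {
                **asdict(self.register),
                "plate_aps": (
                    None
                    if self.register.plate_aps is None
                    else list(self.register.plate_aps)
                ),
            },
            "seg": asdict(self.seg),
            "cleanup": asdict(self.cleanup),
            "seed": int(self.seed),
        }
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        stack = StackManifest(
            image_paths=tuple(doc["stack"]["image_paths"]),
            z_step_um=doc["stack"]["z_step_um"],
            pixel_size_um=doc["stack"]["pixel_size_um"],
            channel_tag=doc["stack"].get("channel_tag", ""),
        )
        align = doc.get("align") or {}
        if align.get("step_schedule") is not None:
            align["step_schedule"] = tuple(align["step_schedule"])
        if align.get("reference_aps") is not None:
            align["reference_aps"] = tuple(align["reference_aps"])
        register = doc.get("register") or {}
        if register.get("plate_aps") is not None:
            register["plate_aps"] = tuple(register["plate_aps"])
        return cls(
            stack=stack,
            output_root=Path(doc["output_root"]),
            atlas_dir=Path(doc["atlas_dir"]) if doc.get("atlas_dir") else None,
            truth_dir=Path(doc["truth_dir"]) if doc.get("truth_dir") else None,
            align=AlignConfig(**align),
            register=RegisterConfig(**register),
            seg=SegmentationFilter(**(doc.get("seg") or {})),
            cleanup=CleanupParams(**(doc.get("cleanup") or {})),
            seed=int(doc.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

# Checkpoints are deliberately human-readable: CSV for tabular payloads and
# YAML for structured ones, so users can eyeball (and hand-edit) intermediate
# results between sessions.

_CHECKPOINT_FILES = {
    "alignment": ("alignment", "anchors.csv"),
    "segmentation": ("segmentation", "detections.csv"),
    "cells": ("cells", "cells.csv"),
    "mapped_cells": ("tables", "cells_mapped.csv"),
    "region_table": ("tables", "region_counts.csv"),
}


def checkpoint_path(stage: str, config: PipelineConfig) -> Path:
    if stage == "registrations":
        return Path(config.output_root) / "registrations"
    if stage not in _CHECKPOINT_FILES:
        raise ValueError(
            f"unknown checkpoint stage {stage!r}; "
            f"known: {sorted(_CHECKPOINT_FILES) + ['registrations']}"
        )
    sub, name = _CHECKPOINT_FILES[stage]
    return Path(config.output_root) / sub / name


def save_checkpoint(stage: str, payload: Any, config: PipelineConfig) -> Path:
    """Persist one stage's result under the standard layout.

    ``alignment`` expects an :class:`~brainplane.alignment.AlignmentMap`,
    ``registrations`` a mapping of plate AP to
    :class:`~brainplane.registration.Warp`, and the tabular stages a
    :class:`pandas.DataFrame`.
    """
    config.savepaths()
    path = checkpoint_path(stage, config)
    if stage == "alignment":
        payload.to_csv(path)
    elif stage == "registrations":
        from .registration import save_warps

        save_warps(payload, path)
    else:
        payload.to_csv(path, index=False)
    return path


def load_checkpoint(stage: str, config: PipelineConfig) -> Any:
    """Load one stage's checkpoint, distinguishing "never run" (missing
    file, :class:`CheckpointMissingError`) from a corrupt file
    (:class:`CheckpointCorruptError`)."""
    path = checkpoint_path(stage, config)
    if stage == "registrations":
        from .registration import load_warps

        if not path.is_dir() or not any(path.glob("plate_*.warp")):
            raise CheckpointMissingError(
                "registration stage never run (no .warp files in "
                f"{path})"
            )
        try:
            return load_warps(path)
        except (ValueError, KeyError, OSError) as exc:
            raise CheckpointCorruptError(
                f"registration checkpoint in {path} is corrupt: {exc}"
            ) from exc
    if not path.exists():
        raise CheckpointMissingError(
            f"stage {stage!r} never run (missing {path})"
        )
    try:
        if stage == "alignment":
            from .alignment import AlignmentMap

            return AlignmentMap.from_csv(path)
        return pd.read_csv(path)
    except CheckpointMissingError:
        raise
    except Exception as exc:
        raise CheckpointCorruptError(
            f"checkpoint {path} is corrupt: {exc}"
        ) from exc
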