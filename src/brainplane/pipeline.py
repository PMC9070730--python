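"""Stage orchestration: canonical order, prerequisites, checkpoints.

The canonical order is align -> register -> segment -> clean -> warp ->
count.  Each stage reads its inputs from the previous stages' checkpoints
under the output root, so a run can stop after any stage and resume later,
and a partial-brain analysis simply restricts the registered plate APs.
"""

from __future__ import annotations

from pathlib import Path

from . import alignment, mapping, registration, segmentation
from .atlas import load_atlas
from .errors import CheckpointMissingError, StageOrderError
from .io_core import (
    PipelineConfig,
    load_checkpoint,
    log_message,
    save_checkpoint,
)
from .phantom import PhantomTruth, oracle_chooser

CANONICAL_STAGES = ("align", "register", "segment", "clean", "warp", "count")

#: checkpoint stage written by each pipeline stage
_PRODUCES = {
    "align": "alignment",
    "register": "registrations",
    "segment": "segmentation",
    "clean": "cells",
    "warp": "mapped_cells",
    "count": "region_table",
}

_PREREQS = {
    "align": (),
    "register": ("align",),
    "segment": (),
    "clean": ("segment",),
    "warp": ("align", "register", "clean"),
    "count": ("warp",),
}


def _have_checkpoint(stage: str, config: PipelineConfig) -> bool:
    try:
        load_checkpoint(_PRODUCES[stage], config)
        return True
    except CheckpointMissingError:
        return False


def _default_references(config: PipelineConfig, amap, atlas) -> list[float]:
    """Reference APs for the choice game: the configured list, else the
    bundled default plates restricted to the anchored AP range, else the
    atlas plate APs inside that range."""
    from .atlas import default_reference_plates

    lo, hi = amap.anchors[-1].ap_mm, amap.anchors[0].ap_mm
    if config.align.reference_aps is not None:
        return [ap for ap in config.align.reference_aps if lo < ap < hi]
    refs = [ap for ap, _ in default_reference_plates() if lo < ap < hi]
    if not refs and atlas is not None:
        refs = [ap for ap in atlas.plate_aps if lo < ap < hi]
    if not refs:
        raise StageOrderError(
            "no reference APs fall inside the anchored endpoint range; "
            "set align.reference_aps"
        )
    return refs


def run_pipeline(
    config: PipelineConfig,
    stages: list[str] | None = None,
    *,
    chooser=None,
    corrector=None,
) -> int:
    """Run the requested stages (default: all) in canonical order.

    ``chooser`` plays the choice game (defaults to the truthful oracle when
    the config points at phantom truth); ``corrector`` edits registration
    point sets (defaults to accepting the automatic contours).  Returns 0
    on success; raises :class:`StageOrderError` when a prerequisite stage
    has neither run before nor been requested.
    """
    requested = list(stages) if stages else list(CANONICAL_STAGES)
    unknown = [s for s in requested if s not in CANONICAL_STAGES]
    if unknown:
        raise StageOrderError(
            f"unknown stage(s) {unknown}; known: {list(CANONICAL_STAGES)}"
        )
    ordered = [s for s in CANONICAL_STAGES if s in requested]
    paths = config.savepaths()
    atlas = load_atlas(config.atlas_dir) if config.atlas_dir else None
    if chooser is None and config.truth_dir is not None:
        truth = PhantomTruth.load(config.truth_dir)
        chooser = oracle_chooser(truth, ap_tol_mm=config.align.midpoint_tol_mm)
    if corrector is None:
        corrector = registration.accept_corrector

    for stage in ordered:
        for pre in _PREREQS[stage]:
            if pre in ordered and ordered.index(pre) < ordered.index(stage):
                continue
            if not _have_checkpoint(pre, config):
                raise StageOrderError(
                    f"stage {stage!r} needs {pre!r} first; run it or add it "
                    "to --stages"
                )
        log_message(paths, f"stage {stage}: start")
        if stage == "align":
            _run_align(config, atlas, chooser, paths)
        elif stage == "register":
            _run_register(config, atlas, corrector, paths)
        elif stage == "segment":
            dets = segmentation.segment_loop(
                config.stack,
                config.seg,
                checkpoint_dir=paths["segmentation"],
                log=lambda m: log_message(paths, m),
            )
            save_checkpoint("segmentation", dets, config)
        elif stage == "clean":
            dets = load_checkpoint("segmentation", config)
            cells = segmentation.clean_duplicates(
                dets, config.cleanup, config.stack.z_step_um
            )
            save_checkpoint("cells", cells, config)
        elif stage == "warp":
            _run_warp(config, atlas)
        elif stage == "count":
            _run_count(config, atlas, paths)
        log_message(paths, f"stage {stage}: done")
    return 0


def _run_align(config, atlas, chooser, paths) -> None:
    a0 = config.align.endpoint_ap_start
    a1 = config.align.endpoint_ap_end
    if a0 is None or a1 is None:
        raise StageOrderError(
            "align needs endpoint APs: set align.endpoint_ap_start and "
            "align.endpoint_ap_end in the config"
        )
    if chooser is None:
        raise StageOrderError(
            "align needs a chooser (console mode, a callback, or truth_dir "
            "for the oracle)"
        )
    amap = alignment.AlignmentMap(
        n_planes=config.stack.n_planes,
        z_step_um=config.stack.z_step_um,
        anchors=[
            alignment.APAnchor(0, a0, "endpoint"),
            alignment.APAnchor(config.stack.n_planes - 1, a1, "endpoint"),
        ],
    )
    for ref in _default_references(config, amap, atlas):
        alignment.choice_game(amap, ref, chooser, config.align)
    alignment.refine_alignment(amap, atlas, chooser, config.align)
    save_checkpoint("alignment", amap, config)
    profile = alignment.morph_profile(amap)
    profile.to_frame().to_csv(
        paths["alignment"] / "morph_profile.csv", index=False
    )
    err = alignment.linear_prediction_error(amap)
    err.to_csv(paths["alignment"] / "linear_error.csv", index=False)
    from . import viz

    viz.plot_morph_profile(profile, paths["figures"] / "morph_profile.png")
    viz.plot_linear_error(err, paths["figures"] / "linear_error.png")


def _run_register(config, atlas, corrector, paths) -> None:
    if atlas is None:
        raise StageOrderError("register needs atlas_dir in the config")
    amap = load_checkpoint("alignment", config)
    lo, hi = amap.anchors[-1].ap_mm, amap.anchors[0].ap_mm
    plate_aps = config.register.plate_aps
    if plate_aps is None:
        plate_aps = [ap for ap in atlas.plate_aps if lo <= ap <= hi]
    registration.regi_loop(
        config.stack,
        amap,
        atlas,
        plate_aps,
        corrector,
        n_points=config.register.n_points,
        regularization=config.register.regularization,
        save_dir=paths["registrations"],
    )


def _run_warp(config, atlas) -> None:
    if atlas is None:
        raise StageOrderError("warp needs atlas_dir in the config")
    cells = load_checkpoint("cells", config)
    amap = load_checkpoint("alignment", config)
    warps = load_checkpoint("registrations", config)
    mapped = mapping.forward_warp_cells(
        cells, warps, amap, atlas, config.stack.pixel_size_um
    )
    mapped = mapping.assign_regions(mapped, atlas)
    save_checkpoint("mapped_cells", mapped, config)


def _run_count(config, atlas, paths) -> None:
    if atlas is None:
        raise StageOrderError("count needs atlas_dir in the config")
    mapped = load_checkpoint("mapped_cells", config)
    table = mapping.get_table(mapped, atlas.ontology)
    table.validate()
    save_checkpoint("region_table", table.frame, config)
    mapping.write_sunburst(
        table, atlas.ontology, paths["figures"] / "sunburst.json"
    )
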