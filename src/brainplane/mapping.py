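"""Forward warping of cells into atlas space and hierarchical counting.

Each cleaned cell gets an AP coordinate from the alignment map, is pushed
through the forward warp of the nearest *registered* plate into plate pixel
coordinates, and receives the region id under its warped position in that
plate's label mask.  Counts are then aggregated over the region ontology:
``direct_count`` is the number of cells whose mask label is exactly that
region, ``rolled_count`` additionally includes every descendant region, and
``percent`` is the rolled count over the total cell number (including
unassigned cells, so that the table always conserves the input count; users
preferring assigned-only percentages can renormalise from the same
columns).

Cells landing outside the tissue mask, outside the mask bounds, or farther
in AP from every registered plate than the cutoff are reported under the
synthetic ``unassigned`` row (region id 0).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignmentMap
from .atlas import AtlasBundle, Ontology

UNASSIGNED_ID = 0
UNASSIGNED_ACRONYM = "unassigned"


def _default_ap_cutoff(plate_aps: list[float]) -> float:
    """Half the largest AP gap between consecutive registered plates; a
    single plate accepts everything."""
    if len(plate_aps) < 2:
        return np.inf
    aps = sorted(plate_aps, reverse=True)
    gaps = [a - b for a, b in zip(aps, aps[1:])]
    return max(gaps) / 2.0


def forward_warp_cells(
    cells: pd.DataFrame,
    warps: dict,
    amap: AlignmentMap,
    atlas: AtlasBundle,
    pixel_size_um: float,
    ap_cutoff_mm: float | None = None,
) -> pd.DataFrame:
    """Attach ``ap_mm``, ``atlas_x``/``atlas_y`` (plate pixels) and an
    ``unmapped`` flag to a cells frame.

    Each cell uses the warp of the registered plate nearest to its AP
    (exact ties resolved toward the more anterior plate).  Cells whose
    nearest registered plate is farther than ``ap_cutoff_mm`` (default:
    half the largest inter-plate gap) are flagged unmapped and left
    untransformed.
    """
    if not warps:
        raise ValueError("no registered plate warps available")
    out = cells.copy()
    plate_aps = sorted(warps.keys(), reverse=True)  # anterior first
    cutoff = (
        _default_ap_cutoff(plate_aps) if ap_cutoff_mm is None else ap_cutoff_mm
    )
    out["ap_mm"] = amap.interpolate(out["z_index"].to_numpy())
    atlas_x = np.full(len(out), np.nan)
    atlas_y = np.full(len(out), np.nan)
    used_ap = np.full(len(out), np.nan)
    unmapped = np.zeros(len(out), dtype=bool)
    cell_ap = out["ap_mm"].to_numpy()
    # nearest registered plate per cell; iterating anterior->posterior with a
    # strict '<' keeps exact ties on the more anterior plate
    dists = np.abs(cell_ap[:, None] - np.array(plate_aps)[None, :])
    nearest_d = dists.min(axis=1)
    # first plate within a hair of the minimum: ties (up to floating-point
    # noise in the interpolated AP) resolve to the more anterior plate
    nearest_idx = np.argmax(dists <= nearest_d[:, None] + 1e-9, axis=1)
    unmapped = nearest_d > cutoff
    xy_px = out[["x_um", "y_um"]].to_numpy(float) / pixel_size_um
    for k, ap in enumerate(plate_aps):
        sel = (nearest_idx == k) & ~unmapped
        if not sel.any():
            continue
        warped = warps[ap].transform(xy_px[sel], "forward")
        atlas_x[sel] = warped[:, 0]
        atlas_y[sel] = warped[:, 1]
        used_ap[sel] = ap
    out["atlas_x"] = atlas_x
    out["atlas_y"] = atlas_y
    out["plate_ap_mm"] = used_ap
    out["unmapped"] = unmapped
    return out


def assign_regions(cells: pd.DataFrame, atlas: AtlasBundle) -> pd.DataFrame:
    """Attach ``region_id``: the label-mask value of the nearest plate at
    the warped position (nearest pixel).  Out-of-bounds, out-of-tissue and
    unmapped cells get region 0 (unassigned)."""
    out = cells.copy()
    region = np.zeros(len(out), dtype=int)
    plate_by_ap = {p.ap_mm: p for p in atlas.plates}
    for i, row in enumerate(out.itertuples()):
        if getattr(row, "unmapped", False) or not np.isfinite(row.atlas_x):
            continue
        ap = getattr(row, "plate_ap_mm", None)
        plate = plate_by_ap.get(ap)
        if plate is None:
            from .atlas import nearest_plate

            plate = nearest_plate(atlas, row.ap_mm)
        r = int(round(row.atlas_y))
        c = int(round(row.atlas_x))
        h, w = plate.label_mask.shape
        if 0 <= r < h and 0 <= c < w:
            region[i] = int(plate.label_mask[r, c])
    out["region_id"] = region
    return out


# ---------------------------------------------------------------------------
# hierarchical counting
# ---------------------------------------------------------------------------


class RegionCountTable:
    """Per-region direct and rolled-up counts with percentages.

    Wraps a frame with columns ``region_id, acronym, name, direct_count,
    rolled_count, percent`` sorted by rolled count descending.  The
    ``unassigned`` pseudo-region is its own row; percentages use all cells
    (assigned + unassigned) as the denominator.
    """

    def __init__(self, frame: pd.DataFrame, ontology: Ontology):
        self.frame = frame
        self.ontology = ontology

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_cells(self) -> int:
        return int(self.frame["direct_count"].sum())

    def row(self, acronym: str) -> pd.Series:
        hit = self.frame[self.frame["acronym"] == acronym]
        if hit.empty:
            raise KeyError(f"no row for acronym {acronym!r}")
        return hit.iloc[0]

    def validate(self) -> None:
        """Check the structural invariants (raises AssertionError)."""
        onto = self.ontology
        by_id = {
            int(r.region_id): r for r in self.frame.itertuples()
        }
        for rid, node in onto.nodes.items():
            row = by_id[rid]
            child_roll = sum(
                by_id[c].rolled_count for c in onto.children(rid)
            )
            assert row.rolled_count == row.direct_count + child_roll, (
                f"rolled count mismatch at {node.acronym}"
            )
        root_row = by_id[onto.root.region_id]
        assigned = self.total_cells - by_id[UNASSIGNED_ID].direct_count
        assert root_row.rolled_count == assigned, "root roll-up != assigned"
        if self.total_cells:
            expected = 100.0 * root_row.rolled_count / self.total_cells
            assert abs(root_row.percent - expected) < 1e-9

    def to_csv(self, path, index: bool = False) -> None:
        self.frame.to_csv(path, index=index)


def get_table(cells: pd.DataFrame, ontology: Ontology) -> RegionCountTable:
    """Aggregate assigned cells into the hierarchical count table."""
    direct = cells["region_id"].value_counts().to_dict() if len(cells) else {}
    total = int(len(cells))
    rows = []

    def rolled(rid: int) -> int:
        return int(direct.get(rid, 0)) + sum(
            rolled(c) for c in ontology.children(rid)
        )

    for rid, node in ontology.nodes.items():
        rows.append(
            {
                "region_id": rid,
                "acronym": node.acronym,
                "name": node.name,
                "direct_count": int(direct.get(rid, 0)),
                "rolled_count": rolled(rid),
            }
        )
    unknown = set(direct) - set(ontology.nodes) - {UNASSIGNED_ID}
    unassigned = int(direct.get(UNASSIGNED_ID, 0)) + sum(
        int(direct[u]) for u in unknown
    )
    rows.append(
        {
            "region_id": UNASSIGNED_ID,
            "acronym": UNASSIGNED_ACRONYM,
            "name": "outside tissue / unmapped",
            "direct_count": unassigned,
            "rolled_count": unassigned,
        }
    )
    frame = pd.DataFrame(rows)
    frame["percent"] = (
        100.0 * frame["rolled_count"] / total if total else 0.0
    )
    frame = frame.sort_values(
        ["rolled_count", "acronym"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return RegionCountTable(frame, ontology)


def get_rois(
    cells: pd.DataFrame, ontology: Ontology, acronyms: list[str]
) -> pd.DataFrame:
    """Cells falling inside the named regions or any of their descendants."""
    wanted: set[int] = set()
    for acr in acronyms:
        wanted |= ontology.descendants(acr)  # KeyError lists near-matches
    return cells[cells["region_id"].isin(wanted)].copy()


def sunburst_data(table: RegionCountTable, ontology: Ontology) -> dict:
    """Nested name/acronym/color/value/children hierarchy for sunburst
    plots; each node's value is its direct count, so any subtree sums to
    that node's rolled count."""
    by_id = {int(r.region_id): r for r in table.frame.itertuples()}

    def build(rid: int) -> dict:
        node = ontology.nodes[rid]
        row = by_id[rid]
        return {
            "name": node.name,
            "acronym": node.acronym,
            "color": node.color_hex,
            "value": int(row.direct_count),
            "children": [build(c) for c in ontology.children(rid)],
        }

    return build(ontology.root.region_id)


def write_sunburst(table: RegionCountTable, ontology: Ontology, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(sunburst_data(table, ontology), fh, indent=2)
    return path
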