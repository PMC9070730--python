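"""Atlas data model: coronal plates, region ontology, and the default
reference-plate table.

An atlas bundle is a directory holding

* ``ontology.csv`` — one row per brain region: ``region_id, acronym, name,
  parent_id, color_hex`` (empty ``parent_id`` marks the single root);
* ``plates.csv`` — one row per coronal plate: ``plate_number, ap_mm,
  mask_filename``, ordered anterior to posterior (``ap_mm`` strictly
  decreasing, mm from bregma, positive anterior);
* one integer-labelled TIFF mask per plate (pixel value = ``region_id``,
  0 = outside tissue) plus an ``outline_<plate>.csv`` boundary polygon.

The bundle shipped with the test suite is synthetic (see
:mod:`brainplane.phantom`); any bundle in this format — e.g. one exported
from a public reference atlas — is accepted.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .errors import AtlasFormatError

#: The seven default internal reference plates used by the choice game:
#: (AP coordinate in mm from bregma, plate number in the upstream plate set),
#: anterior to posterior.  ``landmarks`` gives a short cue for each.
_DEFAULT_REFERENCE_PLATES: tuple[tuple[float, int, str], ...] = (
    (1.91, 35, "teardrop-shaped aco; PIR/ORB fold spans half the hemisphere; no ACB yet"),
    (1.10, 43, "corpus-callosum anterior forceps wings about to touch; NDB present"),
    (-0.42, 58, "fx and sm just separated; och still one piece below hypothalamus"),
    (-0.93, 63, "CA3so first visible in fimbria; fx below top of third ventricle"),
    (-1.94, 73, "DG spans ~2/3 of hippocampal wing; fr/mtt/fx evenly spaced; ME visible"),
    (-2.95, 83, "MM receded on thin stalk; pc and aqueduct below V3"),
    (-3.96, 93, "TRN and PG split by cst/ml; bic protrudes past mcp"),
)


def default_reference_plates() -> list[tuple[float, int]]:
    """The seven default (AP mm, plate number) pairs, anterior -> posterior."""
    return [(ap, plate) for ap, plate, _ in _DEFAULT_REFERENCE_PLATES]


def default_reference_table() -> list[tuple[float, int, str]]:
    """As :func:`default_reference_plates` but with landmark cues."""
    return list(_DEFAULT_REFERENCE_PLATES)


@dataclass(frozen=True)
class RegionNode:
    region_id: int
    acronym: str
    name: str
    parent_id: int | None  # None marks the root
    color_hex: str = "#cccccc"


class Ontology:
    """A rooted tree of brain regions addressable by id or acronym."""

    def __init__(self, nodes: list[RegionNode]):
        self.nodes: dict[int, RegionNode] = {}
        self.by_acronym: dict[str, RegionNode] = {}
        for n in nodes:
            if n.region_id in self.nodes:
                raise AtlasFormatError(f"duplicate region_id {n.region_id}")
            if n.acronym in self.by_acronym:
                raise AtlasFormatError(f"duplicate acronym {n.acronym!r}")
            self.nodes[n.region_id] = n
            self.by_acronym[n.acronym] = n
        roots = [n for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise AtlasFormatError(
                f"ontology must have exactly one root, found {len(roots)}"
            )
        self.root = roots[0]
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.nodes)
        for n in nodes:
            if n.parent_id is not None:
                if n.parent_id not in self.nodes:
                    raise AtlasFormatError(
                        f"region {n.acronym!r} has unknown parent_id "
                        f"{n.parent_id}"
                    )
                self._graph.add_edge(n.parent_id, n.region_id)
        if not nx.is_arborescence(self._graph):
            raise AtlasFormatError("parent links do not form a tree")

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self.nodes

    def children(self, region_id: int) -> list[int]:
        return sorted(self._graph.successors(region_id))

    def resolve(self, acronym: str) -> RegionNode:
        try:
            return self.by_acronym[acronym]
        except KeyError:
            near = difflib.get_close_matches(
                acronym, self.by_acronym, n=3, cutoff=0.4
            )
            hint = f"; did you mean {near}?" if near else ""
            raise KeyError(f"unknown region acronym {acronym!r}{hint}") from None

    def descendants(self, acronym: str) -> set[int]:
        """The region's id plus all transitive children's ids."""
        node = self.resolve(acronym)
        return {node.region_id} | set(nx.descendants(self._graph, node.region_id))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_id": n.region_id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_id": n.parent_id,
                "color_hex": n.color_hex,
            }
            for n in self.nodes.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class AtlasPlate:
    """One coronal plate: AP coordinate, integer region mask, and the closed
    tissue-boundary polygon (``outline``, N x 2 array of (x, y) pixel
    coordinates, canonically oriented)."""

    ap_mm: float
    label_mask: np.ndarray
    outline: np.ndarray
    plate_number: int | None = None


@dataclass
class AtlasBundle:
    plates: list[AtlasPlate]
    ontology: Ontology
    reference_table: list[tuple[float, int, str]] = field(
        default_factory=default_reference_table
    )

    def __post_init__(self) -> None:
        aps = [p.ap_mm for p in self.plates]
        if any(b >= a for a, b in zip(aps, aps[1:])):
            raise AtlasFormatError(
                f"plate AP coordinates must be strictly decreasing, got {aps}"
            )
        for p in self.plates:
            orphan = set(np.unique(p.label_mask)) - {0} - set(self.ontology.nodes)
            if orphan:
                raise AtlasFormatError(
                    f"plate at AP {p.ap_mm}: mask values {sorted(orphan)} "
                    "absent from ontology"
                )

    @property
    def plate_aps(self) -> list[float]:
        return [p.ap_mm for p in self.plates]


def nearest_plate(atlas: AtlasBundle, ap_mm: float) -> AtlasPlate:
    """The plate closest in AP to ``ap_mm``; exact ties go to the more
    anterior plate, and queries beyond either end clamp to the end plate."""
    if not atlas.plates:
        raise AtlasFormatError("atlas bundle has no plates")
    best = atlas.plates[0]
    best_d = abs(best.ap_mm - ap_mm)
    for p in atlas.plates[1:]:
        d = abs(p.ap_mm - ap_mm)
        if d < best_d:  # strict: ties keep the earlier (more anterior) plate
            best, best_d = p, d
    return best


def descendants(ontology: Ontology, acronym: str) -> set[int]:
    """Convenience wrapper for :meth:`Ontology.descendants`."""
    return ontology.descendants(acronym)


# ---------------------------------------------------------------------------
# on-disk bundle format
# ---------------------------------------------------------------------------


def save_atlas(bundle: AtlasBundle, bundle_dir: str | Path) -> Path:
    """Write a bundle to its directory format (see module docstring)."""
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    onto = bundle.ontology.to_frame()
    onto.to_csv(d / "ontology.csv", index=False)
    rows = []
    for i, p in enumerate(bundle.plates):
        num = p.plate_number if p.plate_number is not None else i + 1
        mask_name = f"plate_{num:03d}.tif"
        tifffile.imwrite(d / mask_name, p.label_mask.astype(np.uint16))
        np.savetxt(
            d / f"outline_{num:03d}.csv",
            p.outline,
            delimiter=",",
            header="x,y",
            comments="",
        )
        rows.append(
            {"plate_number": num, "ap_mm": p.ap_mm, "mask_filename": mask_name}
        )
    pd.DataFrame(rows).to_csv(d / "plates.csv", index=False)
    return d


def load_atlas(bundle_dir: str | Path) -> AtlasBundle:
    """Load and validate an atlas bundle directory.

    Raises
    ------
    AtlasFormatError
        If required files are missing, a mask contains region ids absent from
        the ontology, or plate APs are not strictly decreasing.
    """
    d = Path(bundle_dir)
    for req in ("ontology.csv", "plates.csv"):
        if not (d / req).exists():
            raise AtlasFormatError(f"atlas bundle {d} is missing {req}")
    onto_df = pd.read_csv(d / "ontology.csv")
    nodes = [
        RegionNode(
            region_id=int(r.region_id),
            acronym=str(r.acronym),
            name=str(r.name),
            parent_id=None if pd.isna(r.parent_id) else int(r.parent_id),
            color_hex=str(r.color_hex),
        )
        for r in onto_df.itertuples()
    ]
    ontology = Ontology(nodes)
    plates_df = pd.read_csv(d / "plates.csv")
    plates = []
    for r in plates_df.itertuples():
        mask = tifffile.imread(d / str(r.mask_filename)).astype(np.int64)
        outline_path = d / f"outline_{int(r.plate_number):03d}.csv"
        if outline_path.exists():
            outline = np.loadtxt(outline_path, delimiter=",", skiprows=1)
        else:
            outline = outline_from_mask(mask > 0)
        plates.append(
            AtlasPlate(
                ap_mm=float(r.ap_mm),
                label_mask=mask,
                outline=outline,
                plate_number=int(r.plate_number),
            )
        )
    return AtlasBundle(plates=plates, ontology=ontology)


def outline_from_mask(mask: np.ndarray) -> np.ndarray:
    """Closed boundary polygon of a binary mask, as (x, y) pixel coordinates
    in canonical orientation (start at dorsal-most point, clockwise)."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise AtlasFormatError("mask has no foreground to outline")
    rc = max(contours, key=len)  # (row, col)
    xy = np.column_stack([rc[:, 1], rc[:, 0]])
    return canonicalize_contour(xy)


def canonicalize_contour(xy: np.ndarray) -> np.ndarray:
    """Orient a closed (x, y) polygon clockwise as displayed (y axis points
    down) and roll it to start at its dorsal point.  The start vertex is the
    one whose direction from the contour centroid is closest to straight up:
    unlike "minimum y", this is stable when the dorsal boundary is locally
    flat or pixelated, so the same anatomy yields the same start point on a
    rasterised mask and on an analytic outline.  A duplicated closing vertex
    is dropped."""
    pts = np.asarray(xy, dtype=float)
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("contour needs at least 3 distinct vertices")
    x, y = pts[:, 0], pts[:, 1]
    # shoelace in raw coordinates; with y pointing down, visually-clockwise
    # loops have positive signed area
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        pts = pts[::-1]
    cx, cy = pts.mean(axis=0)
    # exact dorsal start: intersect the upward vertical ray from the
    # centroid with the polygon (sub-vertex accurate, so rasterised and
    # analytic versions of the same shape start at the same spot)
    n = len(pts)
    best_y, best_i, best_pt = None, None, None
    for i in range(n):
        p, q = pts[i], pts[(i + 1) % n]
        if (p[0] - cx) * (q[0] - cx) <= 0 and p[0] != q[0]:
            t = (cx - p[0]) / (q[0] - p[0])
            y = p[1] + t * (q[1] - p[1])
            if y < cy and (best_y is None or y < best_y):
                best_y, best_i = y, i
                best_pt = np.array([cx, y])
    if best_y is None:  # degenerate polygon: fall back to the angle vertex
        ang = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
        start = int(np.argmin(np.abs(np.angle(np.exp(1j * (ang + np.pi / 2))))))
        return np.roll(pts, -start, axis=0)
    rolled = np.roll(pts, -(best_i + 1), axis=0)
    if np.linalg.norm(rolled[0] - best_pt) < 1e-9:
        return rolled
    if np.linalg.norm(rolled[-1] - best_pt) < 1e-9:
        return np.roll(rolled, 1, axis=0)
    return np.vstack([best_pt, rolled])
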