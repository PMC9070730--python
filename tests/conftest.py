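"""Shared fixtures: phantoms at two scales and a brute-force dedup oracle."""

import networkx as nx
import numpy as np
import pytest

from brainplane.phantom import PhantomSpec, make_phantom, make_phantom_atlas


@pytest.fixture(scope="session")
def small_phantom(tmp_path_factory):
    """A quick phantom: 60 planes, 12 cells (plus atlas and truth)."""
    spec = PhantomSpec(n_planes=60, n_cells=12, seed=11)
    out = tmp_path_factory.mktemp("small_phantom")
    manifest, atlas, truth = make_phantom(spec, out)
    return {
        "spec": spec,
        "dir": out,
        "manifest": manifest,
        "atlas": atlas,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def study_phantom(tmp_path_factory):
    """The standard study-scale phantom: 300 planes, 60 cells."""
    spec = PhantomSpec(seed=3)
    out = tmp_path_factory.mktemp("study_phantom")
    manifest, atlas, truth = make_phantom(spec, out)
    return {
        "spec": spec,
        "dir": out,
        "manifest": manifest,
        "atlas": atlas,
        "truth": truth,
    }


@pytest.fixture()
def mini_atlas():
    """An in-memory 5-plate, 7-region bundle on a 64 x 64 grid."""
    return make_phantom_atlas([0.3, 0.15, 0.0, -0.15, -0.3], shape=(64, 64))


def brute_force_groups(dets, xy_thresh_um, z_thresh_um, z_step_um):
    """All-pairs connected-components oracle for duplicate cleanup.

    Independent of the package's KD-tree path: a dense distance matrix and
    networkx components.  Returns a list of frozensets of row positions.
    """
    n = len(dets)
    xy = dets[["x_um", "y_um"]].to_numpy(float)
    z = dets["z_index"].to_numpy(float) * z_step_um
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n:
        dxy = np.hypot(
            xy[:, 0][:, None] - xy[:, 0][None, :],
            xy[:, 1][:, None] - xy[:, 1][None, :],
        )
        dz = np.abs(z[:, None] - z[None, :])
        link = (dxy <= xy_thresh_um) & (dz <= z_thresh_um)
        ii, jj = np.nonzero(np.triu(link, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return [frozenset(c) for c in nx.connected_components(g)]


def random_detections(rng, n, extent_um=500.0, n_planes=40):
    """A random detections frame for dedup tests."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x_um": rng.uniform(0, extent_um, n),
            "y_um": rng.uniform(0, extent_um, n),
            "z_index": rng.integers(0, n_planes, n),
            "peak_intensity": rng.uniform(1, 100, n),
            "area_um2": rng.uniform(20, 200, n),
        }
    )
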