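import numpy as np
import pandas as pd
import pytest

from vg3plexus.arbor import Skeleton, normalize_ipl_depth
from vg3plexus.synthetic import GeneratorConfig, generate_plexus


def make_skeleton(xyz, parents, diameters=None, cell_id="test", borders=None):
    """Build a Skeleton from raw arrays (µm)."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(n),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "diameter": np.full(n, 0.5) if diameters is None else diameters,
            "parent_id": parents,
        }
    )
    skel = Skeleton(cell_id=cell_id, nodes=nodes)
    if borders is not None:
        skel = normalize_ipl_depth(skel, *borders)
    return skel


def make_chain(n, spacing=0.1, diameter=0.5, borders=None):
    """Straight chain of n nodes along x."""
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * spacing
    return make_skeleton(xyz, [-1] + list(range(n - 1)),
                         np.full(n, diameter), borders=borders)


def synapse_row(sid, node, direction="input", partner="BCa-0", pclass="BC",
                tlabel="3a", pol="ON", ribbon=True, host="test"):
    return {
        "synapse_id": sid, "host_cell_id": host, "host_node_id": node,
        "direction": direction, "partner_cell_id": partner,
        "partner_class": pclass, "partner_type_label": tlabel,
        "polarity_class": pol, "ribbon": ribbon,
    }


def random_tree_skeleton(n, rng, spacing=1.0):
    """Random tree: each node attaches to a random earlier node."""
    xyz = [np.zeros(3)]
    parents = [-1]
    for i in range(1, n):
        p = int(rng.integers(i))
        step = rng.normal(size=3)
        step = step / np.linalg.norm(step) * spacing
        xyz.append(xyz[p] + step)
        parents.append(p)
    return make_skeleton(np.asarray(xyz), parents)


@pytest.fixture(scope="session")
def small_plexus():
    """Two modest synthetic cells with noise-free functional records."""
    cfg = GeneratorConfig(
        rng_seed=11, n_cells=2, target_cable_length_um=500.0,
        resample_spacing_um=0.2, noise_sd=0.0, trial_noise_sd=0.0,
        rois_per_cell=30,
    )
    cells = generate_plexus(cfg)
    return {
        "config": cfg,
        "cells": cells,
        "skels": {c["skeleton"].cell_id: c["skeleton"] for c in cells},
        "bc": pd.concat([c["synapses"][c["synapses"]["ribbon"]] for c in cells],
                        ignore_index=True),
    }
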