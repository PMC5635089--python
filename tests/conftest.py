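import warnings

import numpy as np
import pytest

from aaquant.phantom import rasterize
from aaquant.tree_model import AirwayTree, Branch

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", module="statsmodels")


def straight_tube_tree(inner_r=1.0, outer_r=2.0, artery_r=1.5, length=30.0,
                       direction=(0.0, 0.0, 1.0)) -> AirwayTree:
    """One straight branch with its paired artery; the minimal phantom."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    line = np.array([[0.0, 0.0, 0.0], d * length / 2, d * length])
    return AirwayTree([Branch("b0", None, line, inner_radius_mm=inner_r,
                              outer_radius_mm=outer_r, artery_radius_mm=artery_r)])


def random_bifurcating_tree(rng: np.random.Generator, max_depth: int = 6,
                            p_split: float = 0.7) -> AirwayTree:
    """Random rooted tree with every internal node bifurcating; segmental
    bronchi are flagged at a random generation per lobar stem."""
    branches = []
    counter = [0]

    def grow(parent_id, start, depth, lobe, seg_flag_depth):
        bid = f"n{counter[0]}"
        counter[0] += 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        end = start + direction * rng.uniform(3, 10)
        branches.append(Branch(
            bid, parent_id, np.vstack([start, end]),
            lobe=lobe, is_segmental_bronchus=(depth == seg_flag_depth),
        ))
        if depth < max_depth and (depth < seg_flag_depth or rng.random() < p_split):
            for _ in range(2):
                grow(bid, end, depth + 1, lobe if depth >= 1 else
                     rng.choice(["RUL", "RLL", "LUL", "LLL"]), seg_flag_depth)
        return bid

    root = grow(None, np.zeros(3), 0, "central", int(rng.integers(2, 4)))
    del root
    return AirwayTree(branches)


#: reduced tree depth/size for fast end-to-end runs
TINY_COHORT_OVERRIDES = dict(max_seg_gen=4, full_bifurcation_seg_gen=1,
                             artery_d0_mm=9.0, noise_sd_HU=15.0)


@pytest.fixture(scope="session")
def tube_volume_fine():
    """Noise-free 0.25 mm phantom of a 2/4 mm tube with a 3 mm artery."""
    tree = straight_tube_tree()
    vol = rasterize(tree, spacing_mm=0.25, noise_sd_HU=0.0)
    return vol, next(iter(tree))


@pytest.fixture(scope="session")
def small_cohort_measured():
    """A tiny rasterized two-cohort study plus its measurement table.

    Shared session-wide because simulation + measurement of 8 volumes is the
    most expensive fixture in the suite.
    """
    from aaquant.phantom import cf_params, control_params, generate_cohort
    from aaquant.pipeline import measure_cohort

    cohort = generate_cohort(cf_params(), control_params(), n_per_cohort=2,
                             rng_seed=11, rasterize_volumes=True)
    measured = measure_cohort(cohort)
    return cohort, measured
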