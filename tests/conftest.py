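import numpy as np
import pytest

from cellprox import PointSet, RegionMask, SyntheticSpec


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of any package NN code)


def brute_nn_distances(source_xy, target_xy):
    """All-pairs scan: per-source distance to the nearest target."""
    source_xy = np.asarray(source_xy, float)
    target_xy = np.asarray(target_xy, float)
    out = np.empty(len(source_xy))
    for i, (sx, sy) in enumerate(source_xy):
        dx = target_xy[:, 0] - sx
        dy = target_xy[:, 1] - sy
        out[i] = np.sqrt(np.min(dx * dx + dy * dy))
    return out


def brute_self_nn_distances(xy):
    """Self-excluded (by index) all-pairs scan."""
    xy = np.asarray(xy, float)
    out = np.empty(len(xy))
    for i, (sx, sy) in enumerate(xy):
        dx = xy[:, 0] - sx
        dy = xy[:, 1] - sy
        sq = dx * dx + dy * dy
        sq[i] = np.inf
        out[i] = np.sqrt(np.min(sq))
    return out


def match_f1(detected_xy, truth_xy, tol=3.0):
    """Precision/recall/F1 with optimal one-to-one matching at `tol`."""
    from scipy.optimize import linear_sum_assignment

    detected_xy = np.asarray(detected_xy, float)
    truth_xy = np.asarray(truth_xy, float)
    if len(detected_xy) == 0 or len(truth_xy) == 0:
        return 0.0, 0.0, 0.0
    cost = np.linalg.norm(
        detected_xy[:, None, :] - truth_xy[None, :, :], axis=2
    )
    ri, ci = linear_sum_assignment(cost)
    tp = int((cost[ri, ci] <= tol).sum())
    precision = tp / len(detected_xy)
    recall = tp / len(truth_xy)
    if precision + recall == 0:
        return 0.0, 0.0, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


def min_separation_points(mask, n, dmin, rng):
    """Uniform points in the mask with enforced pairwise separation."""
    valid_xy = mask.valid_pixel_coords()
    pts = []
    for _ in range(100_000):
        cand = valid_xy[rng.integers(0, len(valid_xy))] + rng.uniform(
            -0.5, 0.5, 2
        )
        if all(
            (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= dmin * dmin
            for p in pts
        ):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise RuntimeError("could not place separated points")


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def full_mask_64():
    return RegionMask(valid=np.ones((64, 64), dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def csr_sample():
    """One default synthetic CSR sample (mask + both point classes)."""
    import cellprox as cp

    spec = SyntheticSpec(pattern="csr", seed=11)
    mask = cp.generate_mask(spec)
    parents, offspring = cp.generate_points(spec, mask)
    return spec, mask, parents, offspring


def make_points(coords, **kw):
    return PointSet(np.asarray(coords, float), **kw)
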