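import numpy as np
import pytest

from speckpull import AcquisitionSettings


@pytest.fixture
def small_settings():
    """A compact FOV/acquisition for fast simulations."""
    return AcquisitionSettings(fov_px=(128, 128), n_frames=2000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flood_fill_components(mask: np.ndarray) -> np.ndarray:
    """Brute-force 8-connected component labelling by BFS flood fill.

    Independent oracle for the library's labelling path (scipy.ndimage).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = [(r0, c0)]
                labels[r0, c0] = current
                while queue:
                    r, c = queue.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and mask[rr, cc] and labels[rr, cc] == 0):
                                labels[rr, cc] = current
                                queue.append((rr, cc))
    return labels


def brute_force_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by enumerating every (positive, negative) pair; ties count 1/2."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_permutation_p(x, y) -> float:
    """Two-sided permutation p by bitmask enumeration of label assignments.

    Iterates all 2^(n+m) subsets and keeps those of size n — a deliberately
    different enumeration strategy from the implementation's
    itertools.combinations path.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    obs = abs(x.mean() - y.mean())
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    hits = total = 0
    for mask in range(1 << (n + m)):
        if bin(mask).count("1") != n:
            continue
        sel = [(mask >> i) & 1 for i in range(n + m)]
        sx = sum(v for v, s in zip(pooled, sel) if s)
        delta = sx / n - (pooled.sum() - sx) / m
        if abs(delta) >= obs - tol:
            hits += 1
        total += 1
    return hits / total
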