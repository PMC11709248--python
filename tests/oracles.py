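"""Independent brute-force reference implementations used only by tests."""

import sys

import numpy as np


def flood_fill_components(values: np.ndarray, connectivity: int) -> list[set]:
    """Recursive flood-fill connected components of the nonzero voxels."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    nonzero = {tuple(i) for i in np.argwhere(values > 0)}
    seen, comps = set(), []
    sys.setrecursionlimit(100000)

    def fill(v, comp):
        comp.add(v)
        seen.add(v)
        for o in offsets:
            w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if w in nonzero and w not in seen:
                fill(w, comp)

    for v in sorted(nonzero):
        if v not in seen:
            comp = set()
            fill(v, comp)
            comps.append(comp)
    return comps


def sort_quantile(values, q) -> float:
    """Linear-interpolation quantile from a full sort."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    h = (v.size - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, v.size - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def brute_force_divisor(shape, mask, max_p) -> int:
    """Scan all divisors, replicating the literal iterative stop rule."""
    shape = np.asarray(shape)
    nz = np.argwhere(mask)
    best = 1
    for n in range(2, int(shape.max()) + 1):
        block = np.ceil(shape / n).astype(int)
        occ = len({tuple(i) for i in nz // block})
        if occ > max_p:
            break
        best = n
    return best


def sort_rank(scores, true_class) -> int:
    """Rank via a full stable sort by (-score, class id)."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return order.index(true_class) + 1


def invariant_moments(points: np.ndarray) -> np.ndarray:
    """Rotation-invariant shape moments for the nearest-centroid oracle."""
    c = points.mean(axis=0)
    rel = points - c
    r = np.linalg.norm(rel, axis=1)
    evals = np.sort(np.linalg.eigvalsh(np.cov(rel.T)))[::-1]
    return np.array([r.mean(), r.std(), r.max(), *evals])


def nearest_centroid_accuracy(clouds, labels) -> float:
    """Leave-nothing-out nearest-centroid classification on shape moments."""
    feats = np.array([invariant_moments(c.coords) for c in clouds])
    mu, sd = feats.mean(axis=0), feats.std(axis=0) + 1e-12
    feats = (feats - mu) / sd
    labels = np.asarray(labels)
    centroids = {l: feats[labels == l].mean(axis=0) for l in np.unique(labels)}
    keys = sorted(centroids)
    pred = [
        keys[int(np.argmin([np.linalg.norm(f - centroids[k]) for k in keys]))] for f in feats
    ]
    return float(np.mean(np.asarray(pred) == labels))
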