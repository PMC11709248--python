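"""Rotation-invariant point-convolution classifier.

The network never sees raw Cartesian coordinates.  Each point is described by
informative rotation-invariant features (IRIF) computed from its distance to
the cloud centroid, the distance spectrum of its local neighborhood, the
eigenvalue profile of the neighborhood covariance, and the angle between the
local reference axis (LRA, the covariance eigenvector of smallest eigenvalue,
sign-disambiguated toward the centroid) and the centroid direction.  All of
these are functions of pairwise distances and relative angles, hence exactly
invariant under rigid rotation of the cloud.

The invariant features pass through five convolution layers - shared
per-point linear maps, each followed by batch normalization, ReLU and a
max-aggregation over the point's neighborhood - then a global max pool and
two fully connected layers ending in a softmax over ligand groups.

Neighborhoods are the k nearest points *inclusive of distance ties* (all
points within the k-th neighbor distance plus a small tolerance belong to the
neighborhood), which keeps the neighborhood a purely metric object: it is
unchanged by point reordering and by rotation, even on regular-grid clouds
where distance ties are exact.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import DegenerateBlobError
from ..point_sampling import PointCloud
from .autodiff import Tensor
from .base import ModelConfig
from .layers import BatchNorm, Linear, Module

_TIE_TOL = 1e-9

N_IRIF_FEATURES = 11
N_GLOBAL_FEATURES = 7


def _cloud_geometry(coords: np.ndarray, density: np.ndarray, k: int):
    """Neighborhood structure and IRIF features (pure numpy, not trained)."""
    n = coords.shape[0]
    centroid = coords.mean(axis=0)
    to_centroid = centroid - coords
    r = np.linalg.norm(to_centroid, axis=1)

    dist = cdist(coords, coords)
    k_eff = min(k, n - 1) if n > 1 else 0
    # k-th neighbor distance per point (excluding self), tie-inclusive cutoff
    if k_eff > 0:
        sorted_d = np.sort(dist, axis=1)
        cutoff = sorted_d[:, k_eff] + _TIE_TOL
    else:
        cutoff = np.zeros(n)
    nbr_mask = dist <= cutoff[:, None]

    point_ids, nbr_ids = np.nonzero(nbr_mask)

    feats = np.zeros((n, N_IRIF_FEATURES))
    feats[:, 0] = density
    feats[:, 1] = r
    # neighbor distance spectrum (excluding the zero self-distance)
    d_masked = np.where(nbr_mask, dist, np.nan)
    np.fill_diagonal(d_masked, np.nan)
    with np.errstate(invalid="ignore"):
        feats[:, 2] = np.nan_to_num(np.nanmean(d_masked, axis=1))
        feats[:, 3] = np.nan_to_num(np.nanmax(d_masked, axis=1))
        feats[:, 4] = np.nan_to_num(np.nanstd(d_masked, axis=1))

    # neighborhood covariance eigen-profile and LRA angle
    counts = nbr_mask.sum(axis=1)
    sums = nbr_mask.astype(np.float64) @ coords
    means = sums / counts[:, None]
    centered = coords[nbr_ids] - means[point_ids]
    outer = centered[:, :, None] * centered[:, None, :]
    cov = np.zeros((n, 3, 3))
    np.add.at(cov, point_ids, outer)
    cov /= counts[:, None, None]
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    feats[:, 5:8] = evals[:, ::-1]
    lra = evecs[:, :, 0]  # smallest-eigenvalue direction
    with np.errstate(invalid="ignore", divide="ignore"):
        unit_tc = np.where(r[:, None] > 0, to_centroid / np.maximum(r, 1e-300)[:, None], 0.0)
        # sign disambiguation toward the centroid makes cos >= 0
        feats[:, 8] = np.abs(np.einsum("ij,ij->i", lra, unit_tc))

    # mean cosine between neighbor offsets and the centroid direction
    offsets = coords[nbr_ids] - coords[point_ids]
    off_norm = np.linalg.norm(offsets, axis=1)
    good = off_norm > 0
    cosv = np.zeros(len(offsets))
    cosv[good] = np.einsum("ij,ij->i", offsets[good], unit_tc[point_ids[good]]) / off_norm[good]
    mean_cos = np.zeros(n)
    np.add.at(mean_cos, point_ids, cosv)
    feats[:, 9] = mean_cos / counts

    # neighbor density statistics
    nbr_dens_sum = np.zeros(n)
    np.add.at(nbr_dens_sum, point_ids, density[nbr_ids])
    feats[:, 10] = nbr_dens_sum / counts

    # global rotation-invariant cloud descriptors (absolute scale survives
    # here: the per-point path is instance-normalized, which removes it)
    glob = np.array(
        [
            np.log(n),
            r.max(),
            np.sqrt(np.mean(r**2)),
            r.mean(),
            density.mean(),
            density.std(),
            feats[:, 2].mean(),
        ]
    )
    return point_ids, nbr_ids, feats, glob


class RiConvClassifier(Module):
    """Five invariant convolution layers + two fully connected layers + softmax."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = [N_IRIF_FEATURES]
        chan = list(cfg.channels)
        for i in range(cfg.riconv_layers):
            widths.append(chan[min(i, len(chan) - 1)])
        self.conv_linears = [
            Linear(widths[i], widths[i + 1], rng) for i in range(cfg.riconv_layers)
        ]
        self.conv_norms = [BatchNorm(widths[i + 1]) for i in range(cfg.riconv_layers)]
        self.fc1 = Linear(widths[-1] + N_GLOBAL_FEATURES, cfg.fc_hidden, rng)
        # zero-initialized head: an untrained model scores all groups uniformly
        self.fc2 = Linear(cfg.fc_hidden, cfg.n_classes, rng, zero_init=True)
        self.training = True

    # -- forward ----------------------------------------------------------
    def forward(self, cloud: PointCloud) -> Tensor:
        if len(cloud) == 0:
            raise DegenerateBlobError("empty point cloud")
        cache = getattr(cloud, "_riconv_geom", None)
        if cache is None or cache[0] != self.cfg.neighborhood_k:
            geom = _cloud_geometry(cloud.coords, cloud.densities, self.cfg.neighborhood_k)
            cloud._riconv_geom = (self.cfg.neighborhood_k, geom)
        else:
            geom = cache[1]
        point_ids, nbr_ids, feats, glob = geom
        n = feats.shape[0]

        x = Tensor(feats)
        for lin, norm in zip(self.conv_linears, self.conv_norms):
            x = norm(lin(x)).relu()
            x = x.take(nbr_ids).segment_max(point_ids, n)
        pooled = x.max(axis=0)
        head_in = Tensor.concat([pooled, Tensor(glob)])
        hidden = self.fc1(head_in.reshape(1, -1)).relu()
        return self.fc2(hidden)

    def predict_proba(self, cloud: PointCloud) -> np.ndarray:
        self.set_training(False)
        logits = self.forward(cloud)
        logp = logits.log_softmax().data.ravel()
        return np.exp(logp)
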