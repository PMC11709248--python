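"""Sparse-voxel feature-pyramid classifier with a NetVLAD head.

The input point cloud is quantized onto a sparse integer lattice (default
step: one 0.2 Å voxel) with the density as the single input feature channel.
A bottom-up pathway of three sparse convolution blocks (kernel 3, stride 2,
each followed by batch normalization, ReLU and Efficient Channel Attention)
produces feature maps of increasing receptive field; a top-down pathway adds
transposed-convolution upsamplings of the coarser maps back onto lateral
1x1-convolved finer maps, U-Net / feature-pyramid style.  The merged
finest-level features are aggregated into a global descriptor by NetVLAD and
classified by a linear layer with softmax.

Only coordinates *relative* to the cloud's minimum corner enter the lattice,
so predictions are invariant to translations of the cloud (in particular to
translations by integer multiples of the quantization step, which leave even
the lattice alignment unchanged).  Voxels are processed in lexicographic
coordinate order, making the forward pass independent of point order.
"""

from __future__ import annotations

import itertools

import numpy as np

from ..errors import DegenerateBlobError
from ..point_sampling import PointCloud
from .autodiff import Tensor
from .base import ModelConfig
from .layers import BatchNorm, ECA, Linear, Module, NetVLAD

_OFFSETS3 = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=np.int64)


def canonical_orientation(coords: np.ndarray, density: np.ndarray) -> np.ndarray:
    """Rotate a cloud into its density-weighted principal-axis frame.

    Axes are covariance eigenvectors ordered by descending eigenvalue, with
    signs fixed so the density-weighted third moment along each axis is
    non-negative and the frame is right-handed.  The transform depends only
    on the point *set*, so it commutes with permutation and translation; it
    reduces (but does not formally guarantee) orientation variance of the
    quantized lattice, which otherwise dominates small-sample training.
    """
    center = np.average(coords, axis=0, weights=density)
    rel = coords - center
    cov = np.cov(rel.T, aweights=density)
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1]  # descending variance
    proj = rel @ axes
    skew = (density[:, None] * proj**3).sum(axis=0)
    signs = np.where(skew >= 0, 1.0, -1.0)
    axes = axes * signs
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return rel @ axes


def quantize(coords: np.ndarray, density: np.ndarray, step: float):
    """Map points onto a sparse integer lattice anchored at the cloud minimum.

    Multiple points landing in one lattice cell are reduced to the maximum
    density (an order-free choice).  Returns lexicographically sorted cell
    coordinates and per-cell features.
    """
    rel = coords - coords.min(axis=0)
    idx = np.floor(rel / step + 1e-6).astype(np.int64)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    idx_sorted = idx[order]
    dens_sorted = density[order]
    uniq, inverse = np.unique(idx_sorted, axis=0, return_inverse=True)
    feat = np.full(uniq.shape[0], -np.inf)
    np.maximum.at(feat, inverse, dens_sorted)
    return uniq, feat[:, None]


class _SparseConvBlock(Module):
    """Kernel-3 stride-2 sparse convolution + BN + ReLU + ECA."""

    def __init__(self, c_in: int, c_out: int, eca_kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (27 * c_in))
        from .autodiff import Parameter

        self.weights = [Parameter(rng.normal(0, scale, size=(c_in, c_out))) for _ in range(27)]
        self.bias = Parameter(np.zeros(c_out))
        self.norm = BatchNorm(c_out)
        self.eca = ECA(eca_kernel)

    def __call__(self, coords: np.ndarray, x: Tensor):
        out_coords = np.unique(coords // 2, axis=0)
        lut = {tuple(c): i for i, c in enumerate(coords)}
        m_out = out_coords.shape[0]
        acc = None
        for o_idx, off in enumerate(_OFFSETS3):
            probe = out_coords * 2 + off
            pairs_in, pairs_out = [], []
            for j in range(m_out):
                i = lut.get(tuple(probe[j]))
                if i is not None:
                    pairs_in.append(i)
                    pairs_out.append(j)
            if not pairs_in:
                continue
            term = (x.take(pairs_in) @ self.weights[o_idx]).index_add(m_out, pairs_out)
            acc = term if acc is None else acc + term
        y = self.eca(self.norm(acc + self.bias).relu())
        return out_coords, y


class _TransposedUp(Module):
    """Stride-2 transposed convolution: coarse voxel features pushed to the
    fine voxels whose half-resolution parent they are."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        from .autodiff import Parameter

        # one weight per child position within the parent cell (2^3)
        self.weights = [
            Parameter(rng.normal(0, np.sqrt(2.0 / c_in), size=(c_in, c_out))) for _ in range(8)
        ]

    def __call__(self, coarse_coords: np.ndarray, coarse_x: Tensor, fine_coords: np.ndarray):
        lut = {tuple(c): i for i, c in enumerate(coarse_coords)}
        parents = fine_coords // 2
        child_pos = fine_coords - parents * 2  # each component in {0,1}
        child_key = child_pos[:, 0] * 4 + child_pos[:, 1] * 2 + child_pos[:, 2]
        m_fine = fine_coords.shape[0]
        acc = None
        for key in range(8):
            rows = np.nonzero(child_key == key)[0]
            if rows.size == 0:
                continue
            src = [lut.get(tuple(p)) for p in parents[rows]]
            keep = [(r, s) for r, s in zip(rows, src) if s is not None]
            if not keep:
                continue
            fr = [r for r, _ in keep]
            cs = [s for _, s in keep]
            term = (coarse_x.take(cs) @ self.weights[key]).index_add(m_fine, fr)
            acc = term if acc is None else acc + term
        if acc is None:
            acc = Tensor(np.zeros((m_fine, self.weights[0].data.shape[1])))
        return acc


class MinkLocClassifier(Module):
    """Three-level sparse FPN with ECA, NetVLAD aggregation, linear softmax head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.channels
        self.block1 = _SparseConvBlock(1, c1, cfg.eca_kernel, rng)
        self.block2 = _SparseConvBlock(c1, c2, cfg.eca_kernel, rng)
        self.block3 = _SparseConvBlock(c2, c3, cfg.eca_kernel, rng)
        self.lateral2 = Linear(c2, c3, rng)
        self.lateral1 = Linear(c1, c3, rng)
        self.up32 = _TransposedUp(c3, c3, rng)
        self.up21 = _TransposedUp(c3, c3, rng)
        self.vlad = NetVLAD(c3, cfg.netvlad_clusters, rng)
        # zero-initialized head: untrained model scores uniformly
        self.head = Linear(cfg.netvlad_clusters * c3, cfg.n_classes, rng, zero_init=True)
        self.training = True

    def forward(self, cloud: PointCloud) -> Tensor:
        if len(cloud) == 0:
            raise DegenerateBlobError("empty point cloud")
        coords = cloud.coords
        if self.cfg.canonicalize_orientation:
            coords = canonical_orientation(coords, cloud.densities)
        coords0, feat0 = quantize(coords, cloud.densities, self.cfg.quantization_size)
        x0 = Tensor(feat0)
        coords1, x1 = self.block1(coords0, x0)
        coords2, x2 = self.block2(coords1, x1)
        coords3, x3 = self.block3(coords2, x2)
        # top-down additions at the corresponding levels
        m2 = self.lateral2(x2) + self.up32(coords3, x3, coords2)
        m1 = self.lateral1(x1) + self.up21(coords2, m2, coords1)
        descriptor = self.vlad(m1).reshape(1, -1)
        return self.head(descriptor)

    def predict_proba(self, cloud: PointCloud) -> np.ndarray:
        self.set_training(False)
        logits = self.forward(cloud)
        return np.exp(logits.log_softmax().data.ravel())
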