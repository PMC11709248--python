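"""Model/training configuration and the prediction contract."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DegenerateBlobError, ValidationError
from ..point_sampling import PointCloud

__all__ = ["ModelConfig", "TrainConfig", "PredictionResult", "build_model", "predict_ligand"]


@dataclass
class ModelConfig:
    """Hyperparameters of a point-cloud ligand classifier.

    ``architecture`` selects the rotation-invariant convolution stack
    (``riconvpp``) or the sparse-voxel feature-pyramid network with NetVLAD
    head (``minkloc``).  Channel widths, neighborhood size, quantization step
    and head sizes are exposed here; the layer counts (five invariant
    convolution layers, two fully connected layers) are the architecture's
    defining structure.
    """

    architecture: str = "riconvpp"
    n_classes: int = 2
    riconv_layers: int = 5
    fc_layers: int = 2
    neighborhood_k: int = 16
    quantization_size: float = 0.2  # Å, one canonical voxel
    channels: tuple = (32, 64, 128)
    netvlad_clusters: int = 32
    eca_kernel: int = 3
    fc_hidden: int = 64
    canonicalize_orientation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("riconvpp", "minkloc"):
            raise ValidationError("architecture must be 'riconvpp' or 'minkloc'")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.riconv_layers < 1 or self.fc_layers < 1:
            raise ValidationError("layer counts must be positive")
        if self.quantization_size <= 0:
            raise ValidationError("quantization_size must be positive")
        if self.eca_kernel % 2 != 1:
            raise ValidationError("eca_kernel must be odd")


@dataclass
class TrainConfig:
    """Training harness knobs (tuned on a validation split in practice)."""

    learning_rate: float = 1e-2
    grad_accumulation_batches: int = 8
    sampling_scheme: str = "none"  # none | undersample | oversample
    epochs: int = 30
    seed: int = 0
    loss: str = "cross_entropy"
    val_fraction: float = 0.25
    early_stop_accuracy: float = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.sampling_scheme not in ("none", "undersample", "oversample"):
            raise ValidationError("sampling_scheme must be none/undersample/oversample")
        if self.loss != "cross_entropy":
            raise ValidationError("only cross-entropy loss is supported")


@dataclass
class PredictionResult:
    """Full score vector over ligand groups plus the induced ranking."""

    class_scores: np.ndarray
    ranked_labels: np.ndarray

    def __post_init__(self) -> None:
        self.class_scores = np.asarray(self.class_scores, dtype=np.float64)
        self.ranked_labels = np.asarray(self.ranked_labels, dtype=np.int64)
        if not np.isclose(self.class_scores.sum(), 1.0, atol=1e-6):
            raise ValidationError("class scores must sum to 1")
        if np.any(self.class_scores < -1e-12):
            raise ValidationError("class scores must be non-negative")
        if sorted(self.ranked_labels.tolist()) != list(range(self.class_scores.size)):
            raise ValidationError("ranked_labels must be a permutation of all group ids")

    @classmethod
    def from_scores(cls, scores: np.ndarray) -> "PredictionResult":
        scores = np.asarray(scores, dtype=np.float64)
        # descending score, ties broken by lowest group id
        order = np.lexsort((np.arange(scores.size), -scores))
        return cls(class_scores=scores, ranked_labels=order)

    def top(self, k: int = 10) -> list[tuple[int, float]]:
        return [(int(i), float(self.class_scores[i])) for i in self.ranked_labels[:k]]


def build_model(cfg: ModelConfig):
    """Instantiate the classifier selected by ``cfg.architecture``."""
    from .minkloc import MinkLocClassifier
    from .riconv import RiConvClassifier

    if cfg.architecture == "riconvpp":
        return RiConvClassifier(cfg)
    return MinkLocClassifier(cfg)


def predict_ligand(classifier, cloud: PointCloud) -> PredictionResult:
    """Score a blob point cloud, returning probabilities and a full ranking."""
    if len(cloud) == 0:
        raise DegenerateBlobError("cannot classify an empty point cloud")
    scores = classifier.predict_proba(cloud)
    return PredictionResult.from_scores(scores)
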