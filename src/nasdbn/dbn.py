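"""Deep belief network: greedy RBM stacking and spatio-temporal readout.

Orientation matters and is easy to invert, so it is fixed here once: the
DBN treats **voxels as samples and time points as features**.  A subject's
T x V matrix is transposed to V samples of length T before training, so
the layer-1 weight matrix is T x m and its columns are directly
interpretable as temporal features (time courses).  Deeper layers live in
hidden-unit space; composing W_1 W_2 ... W_l maps layer-l atoms back to
time courses of length T.

Spatial maps are the hidden activations: propagating every voxel's time
series up the stack with deterministic mean-field probabilities gives, for
each atom, one value per voxel — an m x V atlas per layer, z-scored across
voxels, with binary supports thresholded at z > 1.65.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volume import FMRIMatrix
from .rbm import RBMParams, TrainConfig, hidden_given_visible, train_rbm, \
    visible_given_hidden

__all__ = [
    "Architecture",
    "DBNWeights",
    "SpatialMapSet",
    "train_greedy",
    "temporal_features",
    "spatial_maps",
    "propagate_up",
    "dbn_reconstruction_error",
    "Z_THRESHOLD",
]

Z_THRESHOLD = 1.65  # one-sided p ~ 0.05 on the standard normal


@dataclass(frozen=True)
class Architecture:
    """DBN hyperparameters: depth and (uniform) hidden-layer width.

    The search space is layers in [2, 10] and nodes in [100, 800]; tests
    may override via ``validate=False``.
    """

    n_layers: int
    n_nodes: int
    validate: bool = True

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.n_nodes < 1:
            raise ValueError("n_layers and n_nodes must be positive")
        if self.validate and not (2 <= self.n_layers <= 10 and 100 <= self.n_nodes <= 800):
            raise ValueError(
                f"architecture ({self.n_layers} layers, {self.n_nodes} nodes) "
                "outside the search ranges [2,10] x [100,800]; pass "
                "validate=False to override"
            )


@dataclass
class DBNWeights:
    """Ordered RBM stack plus the training provenance."""

    layers: list[RBMParams]
    input_dim: int
    configs: list[TrainConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("DBN needs at least one layer")
        if self.layers[0].n_visible != self.input_dim:
            raise ValueError("layer 1 visible dim must equal input_dim")
        for a, b in zip(self.layers, self.layers[1:]):
            if b.n_visible != a.n_hidden:
                raise ValueError("adjacent layer shapes are inconsistent")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def copy(self) -> "DBNWeights":
        return DBNWeights([p.copy() for p in self.layers], self.input_dim,
                          list(self.configs))


@dataclass
class SpatialMapSet:
    """Per-layer atlas: z-scored spatial maps and thresholded supports."""

    z_maps: np.ndarray        # m x V
    supports: np.ndarray      # m x V bool, z > threshold
    raw: np.ndarray           # m x V hidden probabilities
    layer: int
    z_threshold: float = Z_THRESHOLD

    @property
    def n_atoms(self) -> int:
        return int(self.z_maps.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.z_maps.shape[1])


def _as_samples(data: FMRIMatrix | np.ndarray) -> np.ndarray:
    """Voxels-as-samples view: V x T array from a T x V matrix."""
    if isinstance(data, FMRIMatrix):
        return data.values.T
    return np.atleast_2d(np.asarray(data, dtype=float))


def train_greedy(
    data: FMRIMatrix | np.ndarray,
    arch: Architecture,
    cfgs: list[TrainConfig] | TrainConfig,
    init: DBNWeights | None = None,
) -> DBNWeights:
    """Greedy layer-wise DBN training.

    Layer 1 (Gaussian visible, since inputs are z-scored) is trained on
    the voxel samples; each deeper Bernoulli layer is trained on the
    deterministic hidden probabilities of the layer below.  When ``init``
    is given, every layer starts from those parameters instead of random
    — the mechanism the two-stage pipeline uses to keep individual models
    index-aligned with the group model.

    If ``data`` is an ndarray it must already be samples x features.
    """
    x = _as_samples(data)
    if isinstance(cfgs, TrainConfig):
        cfgs = [cfgs] * arch.n_layers
    if len(cfgs) != arch.n_layers:
        raise ValueError(f"need {arch.n_layers} layer configs, got {len(cfgs)}")
    if init is not None:
        if init.n_layers != arch.n_layers or init.input_dim != x.shape[1]:
            raise ValueError("init weights do not match architecture/data")
        for l, p in enumerate(init.layers):
            if p.n_hidden != arch.n_nodes:
                raise ValueError(f"init layer {l + 1} width != arch.n_nodes")

    layers: list[RBMParams] = []
    current = x
    for l in range(arch.n_layers):
        kind = "gaussian" if l == 0 else "bernoulli"
        layer_init = init.layers[l] if init is not None else None
        p, _ = train_rbm(current, arch.n_nodes, cfgs[l], visible_kind=kind,
                         init=layer_init)
        layers.append(p)
        current = hidden_given_visible(current, p)
    return DBNWeights(layers=layers, input_dim=x.shape[1], configs=list(cfgs))


def propagate_up(x: np.ndarray, w: DBNWeights, layer: int) -> np.ndarray:
    """Deterministic mean-field hidden probabilities at ``layer`` (1-based)."""
    if not (1 <= layer <= w.n_layers):
        raise ValueError(f"layer {layer} out of range 1..{w.n_layers}")
    h = np.atleast_2d(np.asarray(x, dtype=float))
    for p in w.layers[:layer]:
        h = hidden_given_visible(h, p)
    return h


def temporal_features(w: DBNWeights, layer: int) -> np.ndarray:
    """Layer-l temporal features as a T x m matrix.

    Layer 1 returns W_1; layer l returns the composition W_1 W_2 ... W_l,
    which expresses deeper atoms as length-T time courses.  Columns are
    scaled to unit variance for cross-layer comparability (zero-variance
    columns are left at zero).
    """
    if not (1 <= layer <= w.n_layers):
        raise ValueError(f"layer {layer} out of range 1..{w.n_layers}")
    feat = w.layers[0].W
    for p in w.layers[1:layer]:
        feat = feat @ p.W
    feat = feat - feat.mean(axis=0, keepdims=True)
    sd = feat.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return feat / sd_safe


def spatial_maps(w: DBNWeights, data: FMRIMatrix | np.ndarray, layer: int) -> SpatialMapSet:
    """Spatial atlas of layer ``layer``: one z-scored map per atom.

    Each voxel's time series is propagated up the stack; atom a's map is
    its hidden probability per voxel, z-scored across voxels, with the
    support binarized at z > 1.65.  Fully deterministic given weights and
    data.
    """
    x = _as_samples(data)
    if x.shape[1] != w.input_dim:
        raise ValueError(
            f"data feature dim {x.shape[1]} != DBN input dim {w.input_dim}"
        )
    h = propagate_up(x, w, layer)  # V x m
    raw = h.T  # m x V
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=0, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (raw - mu) / sd_safe
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return SpatialMapSet(z_maps=z, supports=z > Z_THRESHOLD, raw=raw, layer=layer)


def dbn_reconstruction_error(w: DBNWeights, data: FMRIMatrix | np.ndarray) -> float:
    """Full-stack reconstruction MSE: up through all layers with mean-field
    probabilities, then down through all layers with conditional means."""
    x = _as_samples(data)
    h = x
    for p in w.layers:
        h = hidden_given_visible(h, p)
    v = h
    for p in reversed(w.layers):
        v = visible_given_hidden(v, p)
    return float(((x - v) ** 2).mean())
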