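"""Two-stage decomposition: group DBN, then group-initialized subject DBNs.

Stage one trains a single DBN on all subjects' data jointly; stage two
fine-tunes a copy of the group weights on each subject separately.
Because every individual model starts from the group parameters and moves
only a little (a reduced fine-tuning learning rate, 0.1x by default),
atom index a means the same network in the group model and in every
subject's model — no post-hoc re-matching is needed, which is what makes
atom-wise cross-subject statistics (ISC, ICC) straightforward.

Group-matrix geometry.  The subjects' T x V matrices are concatenated
along time into a sum(T_i) x V group matrix, reproducing the reported
group visible dimension (e.g. 9,010 rows for 17 subjects x 530 volumes).
For training, two interpretations of that geometry are supported:

* ``"stacked_subjects"`` (default): each subject-voxel time series
  (length T) is one training sample, so the group stage sees S*V samples
  of dimension T and the learned layer-1 weights are T x m — directly
  transferable to the individual models, which is what stage two
  requires.
* ``"concatenated_time"``: voxels are samples of dimension sum(T_i), the
  literal reading of the group matrix; layer-1 weights are sum(T_i) x m
  and each subject's initialization takes its own row band of W_1.

Both keep the atom indexing aligned; the default is the one that makes
the group-to-individual weight transfer exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dbn import (
    Architecture,
    DBNWeights,
    SpatialMapSet,
    dbn_reconstruction_error,
    spatial_maps,
    temporal_features,
    train_greedy,
)
from .io_volume import FMRIMatrix, concatenate_group
from .metrics import isc_table, isr
from .nas import SwarmConfig, aggregate_runs, run_nas
from .rbm import TrainConfig

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "DecompositionResult", "fit_group", "fit_individual",
           "run_pipeline"]


@dataclass
class StudyConfig:
    """Everything one decomposition run needs."""

    subjects: list[FMRIMatrix]
    architecture: Architecture | str = "search"   # explicit or "search"
    train_configs: list[TrainConfig] | TrainConfig = field(
        default_factory=TrainConfig
    )
    swarm: SwarmConfig | None = None
    n_nas_runs: int = 1
    group_input_mode: str = "stacked_subjects"
    individual_lr_factor: float = 0.1
    individual_epochs: int | None = None
    seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("study needs at least one subject")
        t0 = self.subjects[0].n_timepoints
        for s in self.subjects:
            if s.n_timepoints != t0:
                raise ValueError("all subjects must share T")
            if not s.normalized:
                raise ValueError(f"subject {s.subject_id!r} is not normalized")
        if self.group_input_mode not in ("stacked_subjects", "concatenated_time"):
            raise ValueError(f"unknown group_input_mode {self.group_input_mode!r}")


@dataclass
class DecompositionResult:
    group_weights: DBNWeights
    subject_weights: dict[str, DBNWeights]
    group_maps: dict[int, SpatialMapSet]            # layer -> maps
    group_features: dict[int, np.ndarray]           # layer -> T x m
    subject_maps: dict[str, dict[int, SpatialMapSet]]
    subject_features: dict[str, dict[int, np.ndarray]]
    architecture: Architecture
    isc: "object" = None                            # pandas DataFrame
    isr_spatial: dict[tuple[int, int], dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _layer_cfgs(cfgs: list[TrainConfig] | TrainConfig, arch: Architecture) -> list[TrainConfig]:
    if isinstance(cfgs, TrainConfig):
        return [cfgs] * arch.n_layers
    if len(cfgs) != arch.n_layers:
        raise ValueError("one TrainConfig per layer required")
    return list(cfgs)


def _group_training_array(cfg: StudyConfig) -> np.ndarray:
    """Samples-by-features array for the group stage (see module docstring)."""
    if cfg.group_input_mode == "stacked_subjects":
        return np.vstack([s.values.T for s in cfg.subjects])   # (S*V) x T
    group = concatenate_group(cfg.subjects)
    return group.values.T                                      # V x sum(T_i)


def fit_group(
    group_data: np.ndarray | FMRIMatrix,
    arch: Architecture,
    cfgs: list[TrainConfig] | TrainConfig,
) -> DBNWeights:
    """Stage one: train the group DBN from random initialization."""
    return train_greedy(group_data, arch, _layer_cfgs(cfgs, arch))


def fit_individual(
    subject: FMRIMatrix,
    group_weights: DBNWeights,
    cfgs: list[TrainConfig] | TrainConfig,
    lr_factor: float = 0.1,
    epochs: int | None = None,
    row_band: tuple[int, int] | None = None,
) -> DBNWeights:
    """Stage two: fine-tune one subject's DBN from the group weights.

    ``row_band`` handles the concatenated-time group mode, where the
    subject's layer-1 initialization is its own (start, stop) row slice of
    the group weight matrix.  The fine-tuning learning rate is scaled by
    ``lr_factor`` to stay close to the group solution (atom
    correspondence); ``epochs`` overrides the per-layer epoch counts.
    """
    t = subject.n_timepoints
    init_layers = [p.copy() for p in group_weights.layers]
    if group_weights.input_dim != t:
        if row_band is None:
            raise ValueError(
                f"subject T={t} does not match group input dim "
                f"{group_weights.input_dim}; pass row_band for "
                "concatenated-time group weights"
            )
        start, stop = row_band
        if stop - start != t:
            raise ValueError("row band length must equal subject T")
        first = init_layers[0]
        first.W = first.W[start:stop].copy()
        first.b_vis = first.b_vis[start:stop].copy()
        init_layers[0] = first
    init = DBNWeights(init_layers, input_dim=t, configs=group_weights.configs)

    arch = Architecture(
        n_layers=len(init_layers), n_nodes=init_layers[0].n_hidden, validate=False
    )
    base = _layer_cfgs(cfgs, arch)
    tuned = [
        replace(
            c,
            learning_rate=c.learning_rate * lr_factor,
            epochs=c.epochs if epochs is None else epochs,
        )
        for c in base
    ]
    return train_greedy(subject, arch, tuned, init=init)


def run_pipeline(cfg: StudyConfig) -> DecompositionResult:
    """NAS (optional) -> group fit -> per-subject fits -> metrics/exports."""
    group_array = _group_training_array(cfg)
    cfgs = cfg.train_configs

    # --- architecture ---------------------------------------------------
    if cfg.architecture == "search":
        swarm = cfg.swarm or SwarmConfig(rand_seed=cfg.seed)
        archs = []
        for r in range(cfg.n_nas_runs):
            run_cfg = replace(swarm, rand_seed=swarm.rand_seed + r)
            best, _ = run_nas(group_array, run_cfg)
            logger.info("NAS run %d -> %d layers, %d nodes", r, best.n_layers,
                        best.n_nodes)
            archs.append(best)
        arch = aggregate_runs(archs)
    elif isinstance(cfg.architecture, Architecture):
        arch = cfg.architecture
    else:
        raise ValueError("architecture must be an Architecture or 'search'")
    logger.info("architecture: %d layers x %d nodes", arch.n_layers, arch.n_nodes)

    # --- stage one ------------------------------------------------------
    group_weights = fit_group(group_array, arch, cfgs)

    # group readout needs T x m layer-1 weights; in concatenated mode the
    # group maps are computed on the concatenated matrix directly
    group_maps: dict[int, SpatialMapSet] = {}
    group_features: dict[int, np.ndarray] = {}
    if cfg.group_input_mode == "stacked_subjects":
        stack = group_array  # (S*V) x T
        v = cfg.subjects[0].n_voxels
        n_sub = len(cfg.subjects)
        for layer in range(1, arch.n_layers + 1):
            group_features[layer] = temporal_features(group_weights, layer)
            per_sub = spatial_maps(group_weights, stack, layer)
            # average subject blocks -> one group map per atom
            raw = per_sub.raw.reshape(per_sub.n_atoms, n_sub, v).mean(axis=1)
            mu = raw.mean(axis=1, keepdims=True)
            sd = raw.std(axis=1, ddof=0, keepdims=True)
            z = np.where(sd > 0, (raw - mu) / np.where(sd > 0, sd, 1.0), 0.0)
            group_maps[layer] = SpatialMapSet(
                z_maps=z, supports=z > per_sub.z_threshold, raw=raw, layer=layer
            )
    else:
        group = concatenate_group(cfg.subjects)
        for layer in range(1, arch.n_layers + 1):
            group_features[layer] = temporal_features(group_weights, layer)
            group_maps[layer] = spatial_maps(group_weights, group, layer)

    # --- stage two ------------------------------------------------------
    offsets = None
    if cfg.group_input_mode == "concatenated_time":
        offsets = concatenate_group(cfg.subjects).row_offsets
    subject_weights: dict[str, DBNWeights] = {}
    subject_maps: dict[str, dict[int, SpatialMapSet]] = {}
    subject_features: dict[str, dict[int, np.ndarray]] = {}
    for s in cfg.subjects:
        band = offsets[s.subject_id] if offsets is not None else None
        w = fit_individual(
            s, group_weights, cfgs, lr_factor=cfg.individual_lr_factor,
            epochs=cfg.individual_epochs, row_band=band,
        )
        subject_weights[s.subject_id] = w
        subject_maps[s.subject_id] = {
            layer: spatial_maps(w, s, layer) for layer in range(1, arch.n_layers + 1)
        }
        subject_features[s.subject_id] = {
            layer: temporal_features(w, layer) for layer in range(1, arch.n_layers + 1)
        }
        logger.info("fitted subject %s", s.subject_id)

    # --- metric suite ---------------------------------------------------
    import pandas as pd

    isc_frames = []
    for layer in range(1, arch.n_layers + 1):
        feats = [subject_features[s.subject_id][layer] for s in cfg.subjects]
        isc_frames.append(isc_table(feats, layer))
    isc_df = pd.concat(isc_frames, ignore_index=True)

    isr_spatial: dict[tuple[int, int], dict] = {}
    for layer in range(1, arch.n_layers):
        isr_spatial[(layer, layer + 1)] = isr(
            group_maps[layer].supports, group_maps[layer + 1].supports
        )

    result = DecompositionResult(
        group_weights=group_weights,
        subject_weights=subject_weights,
        group_maps=group_maps,
        group_features=group_features,
        subject_maps=subject_maps,
        subject_features=subject_features,
        architecture=arch,
        isc=isc_df,
        isr_spatial=isr_spatial,
        provenance={
            "seed": cfg.seed,
            "group_input_mode": cfg.group_input_mode,
            "n_subjects": len(cfg.subjects),
            "t_per_subject": cfg.subjects[0].n_timepoints,
            "n_voxels": cfg.subjects[0].n_voxels,
            "architecture": {"n_layers": arch.n_layers, "n_nodes": arch.n_nodes},
        },
    )
    if cfg.output_dir is not None:
        _export(result, cfg)
    return result


def _export(result: DecompositionResult, cfg: StudyConfig) -> None:
    """TSV/JSON export tree under the run directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.isc.to_csv(out / "isc.tsv", sep="\t", index=False)
    for layer, feats in result.group_features.items():
        np.savetxt(out / f"group_temporal_layer{layer}.tsv", feats, delimiter="\t",
                   fmt="%.8g")
        np.savetxt(out / f"group_zmaps_layer{layer}.tsv",
                   result.group_maps[layer].z_maps, delimiter="\t", fmt="%.8g")
    isr_rows = [
        {"lower": lo, "higher": hi, "isr": rec["aggregate"]}
        for (lo, hi), rec in result.isr_spatial.items()
    ]
    import pandas as pd

    pd.DataFrame(isr_rows).to_csv(out / "isr.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(result.provenance, indent=2))
    logger.info("exports written to %s", out)
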