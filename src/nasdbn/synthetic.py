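"""Synthetic naturalistic-fMRI generator with planted hierarchical networks.

Movie-watching fMRI has two properties this generator reproduces so the
decomposition pipeline can be validated without any real scan:

* **Group consistency with individual variability.**  Each planted network
  k has a group time course shared by all subjects plus a subject-specific
  idiosyncratic component, mixed as

      subject_tc_k = sqrt(1 - lambda_k^2) * group_tc_k + lambda_k * idio_k

  with ``lambda_k`` in [0, 1].  Small lambda mimics primary sensory
  networks (highly consistent across viewers); large lambda mimics
  heteromodal association networks, where inter-subject variability is
  high.

* **A two-level spatial hierarchy.**  "Primary" networks occupy disjoint
  contiguous voxel blocks; "composite" networks are unions of two or more
  primary supports with their own time course, standing in for the
  interactive networks (e.g. visual–auditory) that a hierarchical
  decomposition should place in deeper layers.

Signals are mixed as amplitude-weighted outer products of time courses and
binary supports, Gaussian noise is added at a configurable SNR, and each
voxel's series is z-normalized — the same convention the real pipeline
applies after preprocessing.  A paired-session mode plants a controlled
test–retest reliability in the per-subject amplitude patterns.

Randomness is split into a *structural* stream (supports, composite
membership, group time courses — shared by paired sessions) and a
*session* stream (idiosyncratic time courses, amplitudes, noise), both
derived deterministically from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_volume import BrainMask, FMRIMatrix, VolumeSpace, normalize_timeseries

__all__ = ["ConfigurationError", "GroundTruth", "make_dataset", "make_session_pair",
           "planted_isc"]


class ConfigurationError(ValueError):
    """Requested generator geometry cannot be realized."""


@dataclass
class GroundTruth:
    """Everything planted in a synthetic dataset, for downstream scoring."""

    maps: np.ndarray                 # K x V binary supports
    level: list[str]                 # per network: "primary" | "composite"
    constituents: list[tuple[int, ...]]  # composite -> indices of its primaries
    group_timecourses: np.ndarray    # T x K, unit variance columns
    subject_timecourses: np.ndarray  # S x T x K, unit variance columns
    subject_variability: np.ndarray  # lambda_k per network, in [0, 1]
    amplitudes: np.ndarray           # S x K per-subject network amplitudes
    snr: float
    seed: int
    amplitudes_b: np.ndarray | None = None  # second session (paired mode)
    reliability: float | None = None

    @property
    def n_networks(self) -> int:
        return int(self.maps.shape[0])

    def primary_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.level) if l == "primary"])

    def composite_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.level) if l == "composite"])


def _gp_timecourses(rng: np.random.Generator, t: int, k: int, lengthscale: float) -> np.ndarray:
    """Smooth band-limited time courses: squared-exponential GP draws.

    Hemodynamically filtered fMRI signals are smooth on the scale of a few
    TRs; a squared-exponential kernel with length-scale in TR units is the
    simplest stand-in.  Columns are standardized to zero mean / unit
    variance.
    """
    idx = np.arange(t, dtype=float)
    cov = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / lengthscale) ** 2)
    cov[np.diag_indices(t)] += 1e-8  # jitter for Cholesky
    chol = np.linalg.cholesky(cov)
    x = chol @ rng.standard_normal((t, k))
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _place_primary_supports(
    rng: np.random.Generator, n_voxels: int, k_primary: int, support_frac: float
) -> np.ndarray:
    """Disjoint contiguous blocks on the 1-D voxel index, random gaps."""
    block = max(int(round(n_voxels * support_frac)), 3)
    total = block * k_primary
    if total > n_voxels:
        raise ConfigurationError(
            f"cannot place {k_primary} disjoint supports of {block} voxels in "
            f"{n_voxels} voxels"
        )
    # distribute the leftover voxels as random gaps between blocks
    slack = n_voxels - total
    cuts = np.sort(rng.integers(0, slack + 1, size=k_primary))
    maps = np.zeros((k_primary, n_voxels), dtype=bool)
    for k in range(k_primary):
        start = cuts[k] + k * block
        maps[k, start : start + block] = True
    return maps


def _structure(
    seed: int,
    t_per_subject: int,
    n_voxels: int,
    k_primary: int,
    k_composite: int,
    support_frac: float,
    gp_lengthscale: float,
):
    """Session-invariant draws: supports, composite membership, group tcs."""
    rng = np.random.default_rng(seed)
    primary = _place_primary_supports(rng, n_voxels, k_primary, support_frac)
    k_total = k_primary + k_composite
    maps = np.zeros((k_total, n_voxels), dtype=bool)
    maps[:k_primary] = primary
    constituents: list[tuple[int, ...]] = [()] * k_primary
    for c in range(k_composite):
        picks = tuple(sorted(rng.choice(k_primary, size=2, replace=False).tolist()))
        constituents.append(picks)
        maps[k_primary + c] = primary[list(picks)].any(axis=0)
    group_tc = _gp_timecourses(rng, t_per_subject, k_total, gp_lengthscale)
    session_seeds = rng.integers(0, 2**31 - 1, size=8)  # one per potential session
    return maps, constituents, group_tc, session_seeds


def _render_session(
    session_rng: np.random.Generator,
    maps: np.ndarray,
    group_tc: np.ndarray,
    lambdas: np.ndarray,
    n_subjects: int,
    snr: float,
    amplitude_sd: float,
    gp_lengthscale: float,
    mask: BrainMask,
    session_id: str,
    amplitude_dev: np.ndarray | None,
) -> tuple[list[FMRIMatrix], np.ndarray, np.ndarray]:
    """Session-specific draws: idiosyncratic tcs, amplitudes, noise."""
    t, k_total = group_tc.shape
    subject_tc = np.empty((n_subjects, t, k_total))
    for s in range(n_subjects):
        idio = _gp_timecourses(session_rng, t, k_total, gp_lengthscale)
        subject_tc[s] = np.sqrt(1.0 - lambdas**2) * group_tc + lambdas * idio

    if amplitude_dev is None:
        amplitude_dev = session_rng.standard_normal((n_subjects, k_total))
    amplitudes = 1.0 + amplitude_sd * np.asarray(amplitude_dev, dtype=float)

    in_support = maps.any(axis=0)
    subjects: list[FMRIMatrix] = []
    for s in range(n_subjects):
        signal = (subject_tc[s] * amplitudes[s]) @ maps.astype(float)  # T x V
        sig_var = signal[:, in_support].var(axis=0, ddof=0).mean()
        noise_sd = np.sqrt(sig_var / snr)
        noisy = signal + noise_sd * session_rng.standard_normal(signal.shape)
        m = FMRIMatrix(
            values=noisy,
            mask=mask,
            subject_id=f"sub-{s + 1:02d}",
            session_id=session_id,
        )
        subjects.append(normalize_timeseries(m))
    return subjects, subject_tc, amplitudes


def _check_args(k_primary, k_composite, lambda_primary, lambda_composite, snr) -> None:
    if k_primary < 2:
        raise ConfigurationError("need at least 2 primary networks")
    if not (0 <= lambda_primary <= 1 and 0 <= lambda_composite <= 1):
        raise ConfigurationError("lambda values must lie in [0, 1]")
    if lambda_primary >= lambda_composite and k_composite > 0:
        raise ConfigurationError(
            "lambda_primary must be < lambda_composite (sensory networks are "
            "more consistent than heteromodal ones)"
        )
    if snr <= 0:
        raise ConfigurationError("snr must be positive")


def _default_mask(n_voxels: int) -> BrainMask:
    return BrainMask(
        space=VolumeSpace(shape=(n_voxels, 1, 1), affine=np.eye(4)),
        voxel_index=np.arange(n_voxels),
    )


def make_dataset(
    n_subjects: int = 17,
    t_per_subject: int = 530,
    n_voxels: int = 2000,
    k_primary: int = 5,
    k_composite: int = 2,
    lambda_primary: float = 0.2,
    lambda_composite: float = 0.6,
    snr: float = 5.0,
    seed: int = 0,
    support_frac: float = 0.08,
    amplitude_sd: float = 0.3,
    gp_lengthscale: float = 5.0,
    mask: BrainMask | None = None,
    session_id: str = "A",
) -> tuple[list[FMRIMatrix], GroundTruth]:
    """Generate one multi-subject synthetic session.

    Defaults mirror the study design the pipeline targets: 17 subjects at
    530 time points, sensory-like networks (low ``lambda_primary``) that
    are more consistent across subjects than heteromodal composite
    networks (``lambda_composite``), and per-voxel SNR of 5 averaged over
    in-support voxels.  Identical seed => bit-identical output.
    """
    _check_args(k_primary, k_composite, lambda_primary, lambda_composite, snr)
    maps, constituents, group_tc, session_seeds = _structure(
        seed, t_per_subject, n_voxels, k_primary, k_composite, support_frac,
        gp_lengthscale,
    )
    lambdas = np.array(
        [lambda_primary] * k_primary + [lambda_composite] * k_composite, dtype=float
    )
    if mask is None:
        mask = _default_mask(n_voxels)
    elif mask.n_voxels != n_voxels:
        raise ConfigurationError("supplied mask voxel count != n_voxels")

    session_rng = np.random.default_rng(int(session_seeds[0]))
    subjects, subject_tc, amplitudes = _render_session(
        session_rng, maps, group_tc, lambdas, n_subjects, snr, amplitude_sd,
        gp_lengthscale, mask, session_id, amplitude_dev=None,
    )
    truth = GroundTruth(
        maps=maps,
        level=["primary"] * k_primary + ["composite"] * k_composite,
        constituents=constituents,
        group_timecourses=group_tc,
        subject_timecourses=subject_tc,
        subject_variability=lambdas,
        amplitudes=amplitudes,
        snr=snr,
        seed=seed,
    )
    return subjects, truth


def make_session_pair(
    reliability: float,
    seed: int = 0,
    n_subjects: int = 17,
    t_per_subject: int = 530,
    n_voxels: int = 2000,
    k_primary: int = 5,
    k_composite: int = 2,
    lambda_primary: float = 0.2,
    lambda_composite: float = 0.6,
    snr: float = 5.0,
    support_frac: float = 0.08,
    amplitude_sd: float = 0.3,
    gp_lengthscale: float = 5.0,
    mask: BrainMask | None = None,
) -> tuple[list[FMRIMatrix], list[FMRIMatrix], GroundTruth]:
    """Two sessions of the same subjects with planted test–retest reliability.

    Both sessions share planted maps and group time courses (same movie,
    same brains); idiosyncratic components and noise are drawn fresh per
    session.  Per-subject amplitude deviations are correlated between
    sessions at ``reliability``:

        dev_A = sqrt(r) * shared + sqrt(1 - r) * e_A
        dev_B = sqrt(r) * shared + sqrt(1 - r) * e_B

    so across subjects corr(dev_A, dev_B) -> ``reliability``, which is the
    quantity a voxel-wise ICC of the amplitude patterns estimates.  With
    ``reliability=1`` the amplitude patterns are identical in expectation;
    residual session differences come only from idiosyncratic components
    and noise.
    """
    if not (0.0 <= reliability <= 1.0):
        raise ConfigurationError("reliability must lie in [0, 1]")
    _check_args(k_primary, k_composite, lambda_primary, lambda_composite, snr)

    maps, constituents, group_tc, session_seeds = _structure(
        seed, t_per_subject, n_voxels, k_primary, k_composite, support_frac,
        gp_lengthscale,
    )
    k_total = k_primary + k_composite
    lambdas = np.array(
        [lambda_primary] * k_primary + [lambda_composite] * k_composite, dtype=float
    )
    if mask is None:
        mask = _default_mask(n_voxels)
    elif mask.n_voxels != n_voxels:
        raise ConfigurationError("supplied mask voxel count != n_voxels")

    amp_rng = np.random.default_rng(int(session_seeds[2]))
    shared = amp_rng.standard_normal((n_subjects, k_total))
    e_a = amp_rng.standard_normal((n_subjects, k_total))
    e_b = amp_rng.standard_normal((n_subjects, k_total))
    dev_a = np.sqrt(reliability) * shared + np.sqrt(1.0 - reliability) * e_a
    dev_b = np.sqrt(reliability) * shared + np.sqrt(1.0 - reliability) * e_b

    rng_a = np.random.default_rng(int(session_seeds[0]))
    rng_b = np.random.default_rng(int(session_seeds[1]))
    sess_a, subject_tc_a, amps_a = _render_session(
        rng_a, maps, group_tc, lambdas, n_subjects, snr, amplitude_sd,
        gp_lengthscale, mask, "A", dev_a,
    )
    sess_b, _, amps_b = _render_session(
        rng_b, maps, group_tc, lambdas, n_subjects, snr, amplitude_sd,
        gp_lengthscale, mask, "B", dev_b,
    )
    truth = GroundTruth(
        maps=maps,
        level=["primary"] * k_primary + ["composite"] * k_composite,
        constituents=constituents,
        group_timecourses=group_tc,
        subject_timecourses=subject_tc_a,
        subject_variability=lambdas,
        amplitudes=amps_a,
        snr=snr,
        seed=seed,
        amplitudes_b=amps_b,
        reliability=reliability,
    )
    return sess_a, sess_b, truth


def planted_isc(truth: GroundTruth) -> np.ndarray:
    """Leave-one-out ISC of the planted subject time courses, per network.

    Returns an (S, K) array: entry (i, k) is the mean Pearson correlation
    of subject i's time course for network k with every other subject's.
    Used to verify the lambda ordering (primary > composite consistency).
    """
    s, t, k = truth.subject_timecourses.shape
    out = np.empty((s, k))
    for kk in range(k):
        x = truth.subject_timecourses[:, :, kk]
        xc = x - x.mean(axis=1, keepdims=True)
        xc /= np.linalg.norm(xc, axis=1, keepdims=True)
        r = xc @ xc.T
        out[:, kk] = (r.sum(axis=1) - 1.0) / (s - 1)
    return out
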