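"""Evaluation statistics for decomposed functional brain networks.

Implements the study's five quantitative instruments:

* **Overlap rate** O(S, T) = |S ∩ T| / |T| — fraction of a reference
  template T covered by a detected network S.
* **Inter-subject correlation (ISC)** — for one atom's time course,
  ISC_i = mean over j != i of Pearson r between subjects i and j;
  aggregated over atoms per layer and over subjects per group.
* **Voxel-wise ICC** — one-way random-effects intraclass correlation
  ICC = (MSP - MSe) / (MSP + (d - 1) MSe) between d sessions, with the
  conventional five reliability levels (poor/fair/moderate/good/excellent).
* **Inheritance similarity rate (ISR)** — between a lower layer's supports
  N^(L) and a higher layer's N^(H):
  ISR = sum_i |N_i^(L) ∩ N_i^(H)| / sum_i |N_i^(H)| over matched pairs,
  quantifying how much deeper-layer networks inherit from shallower ones.
* **Group comparisons** — two-sample t / one-way ANOVA with
  Benjamini–Hochberg FDR correction.

Supports are mask-aligned binary vectors obtained by thresholding
z-scored maps at z > 1.65; cross-session or cross-method network
correspondence is established by greedy maximum-overlap matching.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dbn import Z_THRESHOLD, SpatialMapSet

__all__ = [
    "overlap_rate",
    "isc",
    "isc_table",
    "icc_voxelwise",
    "icc_label",
    "isr",
    "match_networks",
    "group_compare",
    "fdr_bh",
    "binarize_z",
    "group_zmap",
]

ICC_LEVELS = (
    (0.8, "excellent"),
    (0.6, "good"),
    (0.4, "moderate"),
    (0.2, "fair"),
)


def overlap_rate(s: np.ndarray, t: np.ndarray) -> float:
    """|S ∩ T| / |T|: how much of template ``t`` the network ``s`` covers."""
    s = np.asarray(s, dtype=bool).ravel()
    t = np.asarray(t, dtype=bool).ravel()
    if s.size != t.size:
        raise ValueError("support vectors must share voxel count")
    nt = int(t.sum())
    if nt == 0:
        raise ValueError("template support is empty (undefined denominator)")
    return float((s & t).sum() / nt)


def binarize_z(z_values: np.ndarray, threshold: float = Z_THRESHOLD) -> np.ndarray:
    """Binary support of a z-scored map (or time course) at ``z > threshold``."""
    return np.asarray(z_values, dtype=float) > threshold


def isc(timecourses: np.ndarray) -> np.ndarray:
    """Leave-one-out inter-subject correlation for one atom.

    ``timecourses`` is N subjects x T.  Returns the N per-subject values
    ISC_i = (1/(N-1)) sum_{j != i} r_ij.  Constant series are excluded
    (their Pearson r is undefined) with a warning; their entries are NaN.
    """
    x = np.atleast_2d(np.asarray(timecourses, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("ISC needs at least 2 subjects")
    sd = x.std(axis=1)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"isc: {int((~ok).sum())} constant series excluded", stacklevel=2
        )
    out = np.full(n, np.nan)
    idx = np.flatnonzero(ok)
    if idx.size >= 2:
        r = np.corrcoef(x[idx])
        out[idx] = (r.sum(axis=1) - 1.0) / (idx.size - 1)
    return out


def isc_table(
    subject_features: list[np.ndarray], layer: int
) -> pd.DataFrame:
    """Tidy per-(atom, subject) ISC records for one layer.

    ``subject_features`` holds one T x m temporal-feature matrix per
    subject (index-aligned atoms, as the two-stage pipeline guarantees).
    """
    n_atoms = subject_features[0].shape[1]
    rows = []
    for atom in range(n_atoms):
        series = np.stack([f[:, atom] for f in subject_features])
        vals = isc(series)
        for subject, v in enumerate(vals):
            rows.append(
                {"layer": layer, "atom": atom, "subject": subject, "isc": v}
            )
    return pd.DataFrame(rows)


def icc_voxelwise(
    session_values: list[np.ndarray],
    support: np.ndarray | None = None,
) -> dict:
    """One-way random-effects ICC per voxel across repeated sessions.

    ``session_values`` holds one n_subjects x V array per session (d >= 2
    sessions, same subjects in the same order).  Per voxel, subjects are
    the random targets and sessions the repeated measures:

        MSP = d * sum_s (rowmean_s - grand)^2 / (n - 1)
        MSe = sum_{s,d} (x - rowmean_s)^2 / (n * (d - 1))
        ICC = (MSP - MSe) / (MSP + (d - 1) * MSe)

    Voxels with zero total variance are undefined and excluded (count
    reported).  Returns per-voxel ICCs, the mean over ``support`` voxels
    (all voxels when no support is given), and its reliability level.
    """
    d = len(session_values)
    if d < 2:
        raise ValueError("need at least 2 sessions")
    x = np.stack([np.atleast_2d(np.asarray(v, dtype=float)) for v in session_values])
    # x: d x n x V
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    subj_mean = x.mean(axis=0)               # n x V
    grand = subj_mean.mean(axis=0)           # V
    msp = d * ((subj_mean - grand) ** 2).sum(axis=0) / (n - 1)
    mse = ((x - subj_mean) ** 2).sum(axis=(0, 1)) / (n * (d - 1))
    denom = msp + (d - 1) * mse
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msp - mse) / denom, np.nan)
    undefined = int(np.isnan(icc).sum())

    sel = np.ones(icc.size, dtype=bool) if support is None else np.asarray(support, bool)
    vals = icc[sel & ~np.isnan(icc)]
    mean_icc = float(vals.mean()) if vals.size else np.nan
    return {
        "icc": icc,
        "mean_icc": mean_icc,
        "level": icc_label(mean_icc) if np.isfinite(mean_icc) else "undefined",
        "n_undefined_voxels": undefined,
    }


def icc_label(value: float) -> str:
    """Five-level reliability label: excellent (> 0.8), good (0.6-0.79),
    moderate (0.4-0.59), fair (0.2-0.39), poor (< 0.2)."""
    for cut, name in ICC_LEVELS:
        if value >= cut:
            return name
    return "poor"


def match_networks(
    set_a: SpatialMapSet | np.ndarray,
    set_b: SpatialMapSet | np.ndarray,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one pairing of two support sets by overlap voxels.

    Pairs are taken in descending order of intersection size; ties break
    toward higher overlap rate (relative to the B support), then lower
    atom index.  Returns (pairs as (a, b) index tuples, unmatched A
    indices, unmatched B indices).
    """
    a = set_a.supports if isinstance(set_a, SpatialMapSet) else np.asarray(set_a, bool)
    b = set_b.supports if isinstance(set_b, SpatialMapSet) else np.asarray(set_b, bool)
    if a.shape[1] != b.shape[1]:
        raise ValueError("support sets must share voxel count")
    inter = a.astype(int) @ b.T.astype(int)          # nA x nB
    b_sizes = b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(b_sizes > 0, inter / b_sizes, 0.0)
    candidates = sorted(
        ((int(inter[i, j]), float(rate[i, j]), i, j)
         for i in range(a.shape[0]) for j in range(b.shape[0])),
        key=lambda c: (-c[0], -c[1], c[2], c[3]),
    )
    pairs: list[tuple[int, int]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for n_overlap, _, i, j in candidates:
        if n_overlap == 0:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    unmatched_a = [i for i in range(a.shape[0]) if i not in used_a]
    unmatched_b = [j for j in range(b.shape[0]) if j not in used_b]
    return pairs, unmatched_a, unmatched_b


def isr(
    lower_supports: np.ndarray,
    higher_supports: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
) -> dict:
    """Inheritance similarity rate between two layers' support sets.

    Returns the full pairwise matrix (entry (a, b) = |N_a^(L) ∩ N_b^(H)| /
    |N_b^(H)|) and the aggregate over index pairs: pairs are formed by
    maximal-overlap matching unless supplied.  Empty higher-layer supports
    are excluded from the aggregate and counted.
    """
    low = np.asarray(lower_supports, dtype=bool)
    high = np.asarray(higher_supports, dtype=bool)
    if low.shape[1] != high.shape[1]:
        raise ValueError("support sets must share voxel count")
    inter = low.astype(int) @ high.T.astype(int)
    high_sizes = high.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pairwise = np.where(high_sizes > 0, inter / high_sizes, np.nan)

    if pairs is None:
        pairs, _, _ = match_networks(low, high)
    kept = [(i, j) for i, j in pairs if high_sizes[j] > 0]
    n_empty = int((high_sizes == 0).sum())
    if kept:
        num = sum(int(inter[i, j]) for i, j in kept)
        den = sum(int(high_sizes[j]) for i, j in kept)
        aggregate = num / den
    else:
        aggregate = np.nan
    return {
        "pairwise": pairwise,
        "pairs": pairs,
        "aggregate": float(aggregate) if kept else np.nan,
        "n_empty_higher": n_empty,
    }


def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray | list[np.ndarray],
    test: str = "two_sample_t",
    fdr: bool = True,
) -> pd.DataFrame:
    """Family of group tests with optional Benjamini–Hochberg correction.

    ``values_a``/``values_b`` are families of samples: 1-D arrays are a
    family of one; 2-D arrays run one test per column.  For ``anova``,
    ``values_b`` may be a list of further groups.
    """
    rows = []
    if test == "two_sample_t":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if b.ndim == 1:
            b = b[:, None]
        for col in range(a.shape[1]):
            ga, gb = a[:, col], b[:, col]
            if ga.size < 2 or gb.size < 2:
                raise ValueError("each group needs n >= 2")
            if ga.std(ddof=1) == 0 and gb.std(ddof=1) == 0:
                rows.append({"family_member": col, "statistic": np.nan, "p": np.nan})
                continue
            t, p = sps.ttest_ind(ga, gb)
            rows.append({"family_member": col, "statistic": float(t), "p": float(p)})
    elif test == "anova":
        groups = [np.asarray(g, dtype=float) for g in ([values_a] + list(values_b))]
        if any(g.size < 2 for g in groups):
            raise ValueError("each group needs n >= 2")
        f, p = sps.f_oneway(*groups)
        rows.append({"family_member": 0, "statistic": float(f), "p": float(p)})
    else:
        raise ValueError(f"unknown test {test!r}")

    out = pd.DataFrame(rows)
    if fdr:
        out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values for one test family.

    NaN entries (degenerate tests) are left NaN and do not count toward
    the family size.
    """
    pvals = np.asarray(pvals, dtype=float)
    ok = np.isfinite(pvals)
    adj = np.full_like(pvals, np.nan)
    if ok.any():
        adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return adj


def group_zmap(subject_maps: np.ndarray) -> np.ndarray:
    """Group z map from per-subject spatial values via one-sample t -> z.

    ``subject_maps`` is n_subjects x V.  Each voxel's t statistic against
    zero is converted to the standard-normal deviate with the same tail
    probability.  One interpretation of a statistical coefficient map;
    exposed as a helper, not used for the index-aligned two-stage flow.
    """
    x = np.atleast_2d(np.asarray(subject_maps, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = x.mean(axis=0)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    # map through matching tail probability, guarding extreme tails
    p = sps.t.sf(t, df=n - 1)
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return sps.norm.isf(p)
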