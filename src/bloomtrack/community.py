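"""Community-structure analyses implemented from first principles.

Rarefaction (subsampling without replacement), Bray-Curtis dissimilarity,
principal coordinates analysis, ANOSIM with permutation p-values, Bonferroni
correction, the Mann-Whitney U test (exact for small samples), and the
phase-wise comparison of flow-cytometry totals between treatments.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import Phase, Treatment

logger = logging.getLogger("bloomtrack")


def rarefy(counts: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample column to exactly ``depth`` reads without
    replacement.  Deterministic for a fixed seed (columns are processed in
    table order).  Raises if any column total is below ``depth``, listing
    the offending samples.
    """
    totals = counts.sum(axis=0)
    low = [str(s) for s in totals.index[totals < depth]]
    if low:
        raise ValueError(
            f"samples below rarefaction depth {depth}: {', '.join(low)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(counts.shape, dtype=np.int64)
    arr = counts.to_numpy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        total = int(col.sum())
        if total == depth:
            out[:, j] = col
            continue
        cum = np.cumsum(col)
        picks = rng.choice(total, size=depth, replace=False)
        idx = np.searchsorted(cum, picks, side="right")
        out[:, j] = np.bincount(idx, minlength=len(col))
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns:
    BC(x, y) = sum|x_f - y_f| / sum(x_f + y_f)."""
    arr = counts.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero) >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    n = arr.shape[1]
    dm = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(arr[:, i:i + 1] - arr[:, i + 1:]).sum(axis=0)
        denom = (arr[:, i:i + 1] + arr[:, i + 1:]).sum(axis=0)
        dm[i, i + 1:] = diff / denom
    dm = dm + dm.T
    return pd.DataFrame(dm, index=counts.columns, columns=counts.columns)


@dataclass
class Ordination:
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray


def pcoa(distance_matrix: pd.DataFrame) -> Ordination:
    """Principal coordinates analysis of a symmetric distance matrix.

    Eigendecomposition of the double-centred Gower matrix
    B = -1/2 J D^2 J.  Negative eigenvalues (non-Euclidean input, as with
    Bray-Curtis) are dropped with a warning and excluded from the
    proportion-explained denominator.
    """
    d = distance_matrix.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(1.0, np.abs(eigval).max())
    if (eigval < -tol).any():
        logger.warning(
            "PCoA: dropping %d negative eigenvalue(s) (non-Euclidean distances)",
            int((eigval < -tol).sum()),
        )
    keep = eigval > tol
    eigval = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=distance_matrix.index, columns=axes),
        eigenvalues=eigval,
        proportion_explained=eigval / eigval.sum() if eigval.size else eigval,
    )


def _condensed_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def anosim(
    distance_matrix: pd.DataFrame,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; the permutation p-value includes the observed labelling
    in both numerator and denominator, so p is never 0.
    """
    labels = np.asarray(list(grouping))
    n = len(labels)
    if distance_matrix.shape[0] != n:
        raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group '{small}' has fewer than 2 members")
    ii, jj = _condensed_pairs(n)
    dist = distance_matrix.to_numpy()[ii, jj]
    ranks = stats.rankdata(dist)
    m = len(ranks)

    def r_stat(lab: np.ndarray) -> float:
        within = lab[ii] == lab[jj]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    # batch the label permutations: R is a linear function of the mean
    # within-group and between-group ranks
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_labels = labels[perm_idx]  # (P, n)
    within = perm_labels[:, ii] == perm_labels[:, jj]  # (P, M)
    n_within = within.sum(axis=1)
    sum_within = (within * ranks).sum(axis=1)
    total = ranks.sum()
    mean_within = sum_within / n_within
    mean_between = (total - sum_within) / (m - n_within)
    r_perm = (mean_between - mean_within) / (m / 2)
    hits = int((r_perm >= observed - 1e-12).sum())
    p = (1 + hits) / (1 + n_permutations)
    return float(observed), float(p)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni family-wise correction: min(1, p * m)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


def _u_statistic(values: np.ndarray, n_a: int) -> float:
    ranks = stats.rankdata(values)
    r_a = ranks[:n_a].sum()
    n_b = len(values) - n_a
    u_a = r_a - n_a * (n_a + 1) / 2
    u_b = n_a * n_b - u_a
    return min(u_a, u_b)


def mann_whitney_u(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U = min(U_a, U_b).  The p-value is exact (enumeration of all label
    assignments of the pooled values, so ties are handled exactly) when
    n_a + n_b <= 12, otherwise a tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    u_obs = _u_statistic(pooled, n_a)
    if n <= 12:
        total = math.comb(n, n_a)
        hits = 0
        for combo in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            perm = np.concatenate([pooled[mask], pooled[~mask]])
            if _u_statistic(perm, n_a) <= u_obs + 1e-12:
                hits += 1
        return float(u_obs), hits / total
    n_b = n - n_a
    mu = n_a * n_b / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n_a * n_b / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return float(u_obs), 1.0
    z = (u_obs - mu + 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2 * stats.norm.cdf(z))
    return float(u_obs), float(p)


def phase_compare(
    cytometry: pd.DataFrame,
    metadata: pd.DataFrame,
    metric: str = "cells",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Mann-Whitney comparison of total cell or particle counts between
    treatments within each culture phase.

    All (replicate, day) observations of a phase are pooled per treatment.
    Returns one row per (phase, treatment pair) with U, p and a
    significance flag at ``alpha`` (P < 0.01 by default).
    """
    col = {"cells": "cells_per_ml", "particles": "particles_per_ml"}[metric]
    treatments = [Treatment.CONTROL.value, Treatment.CIF.value, Treatment.HIF.value]
    rows = []
    for phase in Phase:
        in_phase = metadata.index[metadata["phase"] == phase.value]
        in_phase = [s for s in in_phase if s in cytometry.index]
        if not in_phase:
            logger.info("phase_compare: no observations in %s phase, skipped", phase.value)
            continue
        by_treat = {
            t: cytometry.loc[
                [s for s in in_phase if metadata.at[s, "treatment"] == t], col
            ].to_numpy()
            for t in treatments
        }
        for t1, t2 in itertools.combinations(treatments, 2):
            va, vb = by_treat[t1], by_treat[t2]
            if va.size == 0 or vb.size == 0:
                logger.info(
                    "phase_compare: %s phase lacks %s observations, pair skipped",
                    phase.value, t1 if va.size == 0 else t2,
                )
                continue
            u, p = mann_whitney_u(va, vb)
            rows.append(
                {
                    "phase": phase.value,
                    "treatment_a": t1,
                    "treatment_b": t2,
                    "n_a": len(va),
                    "n_b": len(vb),
                    "U": u,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)
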