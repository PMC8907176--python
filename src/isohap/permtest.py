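"""Distance-based permutational MANOVA and within-group variance permutation
tests for high-dimensional colour-measurement matrices.

PERMANOVA partitions the total sum of squared pairwise Euclidean distances

    SS_total  = Σ_{i<j} d²_ij / N
    SS_within = Σ_g Σ_{i<j in g} d²_ij / n_g
    SS_between = SS_total - SS_within
    pseudo-F  = (SS_between / (a-1)) / (SS_within / (N-a))

and compares the observed pseudo-F with its permutation distribution under
random relabelling; p-values use the (1 + count)/(B + 1) convention and can
therefore never be exactly 0. In one dimension the statistic coincides with
the classical one-way ANOVA F.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def pc_reduce(matrix: np.ndarray, n_pc: int = 17) -> tuple[np.ndarray, float]:
    """Centred PCA scores for the top ``n_pc`` components plus the fraction
    of total variance they explain. Component signs are fixed so each
    loading vector's largest-magnitude entry is positive."""
    x = np.asarray(matrix, dtype=float)
    if n_pc > min(x.shape):
        raise ValueError("n_pc exceeds matrix rank bound")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for comp in range(n_pc):
        pivot = vt[comp, np.argmax(np.abs(vt[comp]))]
        if pivot < 0:
            vt[comp] = -vt[comp]
            u[:, comp] = -u[:, comp]
    scores = u[:, :n_pc] * s[:n_pc]
    var = s**2
    explained = float(var[:n_pc].sum() / var.sum()) if var.sum() > 0 else 0.0
    return scores, explained


def _ss_partition(d2: np.ndarray, labels: np.ndarray):
    """(SS_between, SS_within, df_between, df_within) from squared distances."""
    n = len(labels)
    ss_total = d2.sum() / (2.0 * n)  # d2 is the full symmetric matrix
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = labels == g
        ng = idx.sum()
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * ng)
    return ss_total - ss_within, ss_within, len(groups) - 1, n - len(groups)


def _pseudo_f(d2, labels):
    ss_b, ss_w, df_b, df_w = _ss_partition(d2, labels)
    if ss_w == 0:
        raise ZeroDivisionError("zero within-group sum of squares")
    return (ss_b / df_b) / (ss_w / df_w)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    n_permutations: int
    seed: int
    pairwise: pd.DataFrame | None = None
    centroid_distances: pd.DataFrame | None = None


def permanova(
    scores: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
    pairwise: bool = False,
) -> PermanovaResult:
    """Permutational MANOVA on Euclidean distances among observations.

    With ``pairwise=True``, post-hoc two-group tests are rerun on each group
    pair (same B and seed stream) and centroid distances in score space are
    reported.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members")
    if n_permutations < 1:
        raise ValueError("need >= 1 permutation")

    d2 = squareform(pdist(scores, metric="sqeuclidean"))
    if d2.max() == 0:
        raise ValueError("all observations identical; pseudo-F undefined")
    ss_b, ss_w, df_b, df_w = _ss_partition(d2, labels)
    f_obs = (ss_b / df_b) / (ss_w / df_w)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm) >= f_obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)

    pw = None
    cent = None
    if pairwise:
        rows = []
        for g1, g2 in combinations(groups, 2):
            idx = (labels == g1) | (labels == g2)
            sub = permanova(
                scores[idx], labels[idx], n_permutations=n_permutations, seed=seed
            )
            rows.append(
                {"group1": g1, "group2": g2, "pseudo_f": sub.pseudo_f, "p": sub.p_value}
            )
        pw = pd.DataFrame(rows)
        crows = []
        centroids = {g: scores[labels == g].mean(axis=0) for g in groups}
        for g1, g2 in combinations(groups, 2):
            crows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "distance": float(np.linalg.norm(centroids[g1] - centroids[g2])),
                }
            )
        cent = pd.DataFrame(crows)

    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        ss_between=float(ss_b),
        ss_within=float(ss_w),
        ss_total=float(ss_b + ss_w),
        df_between=int(df_b),
        df_within=int(df_w),
        n_permutations=n_permutations,
        seed=seed,
        pairwise=pw,
        centroid_distances=cent,
    )


def within_group_trace(matrix: np.ndarray, labels: np.ndarray, group) -> float:
    """Trace of the within-group sample covariance (sum of per-measurement
    sample variances) — a rotation-invariant total-variance measure."""
    x = np.asarray(matrix, dtype=float)[np.asarray(labels) == group]
    if x.shape[0] < 2:
        raise ValueError("group needs >= 2 members")
    return float(x.var(axis=0, ddof=1).sum())


def permutation_variance_test(
    matrix: np.ndarray,
    labels: np.ndarray,
    pair: tuple,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-tailed permutation test for a difference in within-group variance.

    Statistic: difference of within-group covariance traces. Whole
    individuals (rows) are permuted between the two groups, preserving the
    dependence among measurements on the same individual. Returns
    (observed difference, two-tailed p)."""
    if n_permutations < 1:
        raise ValueError("need >= 1 permutation")
    labels = np.asarray(labels)
    g1, g2 = pair
    idx = (labels == g1) | (labels == g2)
    x = np.asarray(matrix, dtype=float)[idx]
    lab = labels[idx]
    obs = within_group_trace(x, lab, g1) - within_group_trace(x, lab, g2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        delta = within_group_trace(x, perm, g1) - within_group_trace(x, perm, g2)
        if abs(delta) >= abs(obs):
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return float(obs), float(p)
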