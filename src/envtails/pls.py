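"""Mean-centered partial least squares (task PLS) across groups.

The centered matrix of group means is decomposed with the SVD into latent
variables (LVs): each LV pairs a group contrast (left singular vector), a
salience per feature (right singular vector) and a singular value whose
square is the LV's share of the between-group variance.  Inference follows
the standard task-PLS recipe: a permutation test on the singular values
(participants shuffled across groups) gives one p-value per LV, and a
within-group bootstrap with Procrustes alignment of each resampled SVD gives
a bootstrap ratio per feature, interpreted like a z-score for how robustly
that feature supports the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

from envtails.errors import ValidationError


@dataclass
class PLSModel:
    group_means: np.ndarray  # G x F
    centered: np.ndarray  # G x F
    contrasts: np.ndarray  # G x L (columns: group saliences / contrast per LV)
    singular_values: np.ndarray  # L
    saliences: np.ndarray  # F x L
    explained: np.ndarray  # L, S^2 / sum(S^2)

    @property
    def n_latent(self) -> int:
        return len(self.singular_values)


@dataclass
class PermutationResult:
    n_perm: int
    p_values: np.ndarray  # per LV
    null_singulars: np.ndarray  # n_perm x L


@dataclass
class BootstrapResult:
    n_boot: int
    bsr: np.ndarray  # F x L, NaN where the bootstrap SE is zero
    se: np.ndarray  # F x L


def _labels_of(design) -> np.ndarray:
    labels = np.asarray(getattr(design, "group_label", design))
    if labels.ndim != 1:
        raise ValidationError("group labels must be a 1-D vector")
    return labels


def mean_centered_svd(X: np.ndarray, design) -> PLSModel:
    """SVD of the column-centered group-mean matrix.

    Group means are centered with the unweighted mean across groups (the
    standard mean-centered task-PLS convention; with near-equal group sizes
    this is close to the participant grand mean).  LVs are ordered by
    decreasing singular value and truncated to the rank bound
    min(G - 1, F).  Sign convention: each LV is flipped so that the contrast
    entry of largest magnitude is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("X must be participants x features with F >= 1")
    labels = _labels_of(design)
    if len(labels) != X.shape[0]:
        raise ValidationError("one group label per row of X is required")
    groups = np.unique(labels)
    G = len(groups)
    if G < 2:
        raise ValidationError("need at least two groups")
    means = np.empty((G, X.shape[1]))
    for i, g in enumerate(groups):
        rows = labels == g
        if not rows.any():
            raise ValidationError(f"group {g} is empty")
        means[i] = X[rows].mean(axis=0)
    centered = means - means.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    L = min(G - 1, X.shape[1])
    U, S, V = U[:, :L], S[:L], Vt[:L].T
    for k in range(L):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    total = float(np.sum(S**2))
    explained = S**2 / total if total > 0 else np.zeros_like(S)
    return PLSModel(
        group_means=means,
        centered=centered,
        contrasts=U,
        singular_values=S,
        saliences=V,
        explained=explained,
    )


def permutation_test(X: np.ndarray, design, n_perm: int, seed) -> PermutationResult:
    """Permutation p-values for each LV's singular value.

    Participants are reassigned to groups by uniform random permutations
    that preserve the group sizes; the k-th permuted singular value is
    compared with the k-th observed one (greedy matching), and
    p_k = (1 + #{S_k^perm >= S_k^obs}) / (n_perm + 1), so the smallest
    attainable p-value is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    labels = _labels_of(design)
    observed = mean_centered_svd(X, labels)
    S_obs = observed.singular_values
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(S_obs)))
    n = len(labels)
    for b in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        null[b] = mean_centered_svd(X, perm_labels).singular_values
    exceed = (null >= S_obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(n_perm=n_perm, p_values=p, null_singulars=null)


def bootstrap_test(X: np.ndarray, design, n_boot: int, seed) -> BootstrapResult:
    """Bootstrap ratios (salience / bootstrap SE) per feature and LV.

    Participants are resampled with replacement within their groups; each
    bootstrap SVD is aligned to the original by an orthogonal Procrustes
    rotation of the saliences (removing sign and rotation indeterminacy of
    the SVD), and the statistic is the weighted salience V @ diag(S).  The
    bootstrap ratio is the original weighted salience divided by the SD of
    the aligned bootstrap replicates; entries with zero bootstrap SE are
    flagged as NaN.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    X = np.asarray(X, dtype=float)
    labels = _labels_of(design)
    groups = np.unique(labels)
    group_rows = {g: np.flatnonzero(labels == g) for g in groups}
    for g, rows in group_rows.items():
        if len(rows) < 2:
            raise ValidationError(f"group {g} has fewer than 2 participants")
    observed = mean_centered_svd(X, labels)
    V, S = observed.saliences, observed.singular_values
    w_obs = V * S  # weighted saliences, F x L
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot,) + w_obs.shape)
    for b in range(n_boot):
        idx = np.concatenate(
            [rows[rng.integers(0, len(rows), len(rows))] for rows in group_rows.values()]
        )
        boot_labels = labels[idx]
        model_b = mean_centered_svd(X[idx], boot_labels)
        R, _ = orthogonal_procrustes(model_b.saliences, V)
        reps[b] = (model_b.saliences * model_b.singular_values) @ R
    se = reps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, w_obs / se, np.nan)
    return BootstrapResult(n_boot=n_boot, bsr=bsr, se=se)


def average_site_scores(values: np.ndarray, site_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average per-channel values over channels sharing a site.

    Returns ``(site_ids, site_values)`` with sites in ascending id order;
    singleton sites pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    site_id = np.asarray(site_id)
    if len(values) != len(site_id):
        raise ValidationError("site_id must have one entry per channel")
    sites, inverse = np.unique(site_id, return_inverse=True)
    sums = np.bincount(inverse, weights=values, minlength=len(sites))
    counts = np.bincount(inverse, minlength=len(sites))
    return sites, sums / counts
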