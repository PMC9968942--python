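"""Beta diversity: Bray–Curtis distances, PCoA, and PERMANOVA.

The distance container is scikit-bio's :class:`~skbio.DistanceMatrix`
(symmetric, zero-diagonal, id-aware, TSV round-trip). PCoA uses Gower
double-centering with negative eigenvalues reported as-is (proportion
explained is taken over the positive part of the spectrum). PERMANOVA is
the one-factor Adonis test: pseudo-F from within/between sums of squared
distances, p-value from unrestricted label permutations with the +1
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import CountTable


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between all sample pairs.

    d(x, y) = 1 − 2·Σ min(x_i, y_i) / (Σx + Σy), computed on counts; with
    the uniform post-rarefaction depth this equals the proportion-based
    form exactly.
    """
    data = table.counts.to_numpy().T.astype(float)  # samples x taxa
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.sample_ids))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Principal co-ordinate analysis of a distance matrix.

    ``eigenvalues`` carries the full spectrum in descending order, negative
    values included (they flag non-Euclidean structure and are never
    silently corrected). Coordinates exist only for positive eigenvalues;
    ``proportion_explained`` is each positive eigenvalue over the sum of
    positive eigenvalues.
    """

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame  # samples x retained axes
    proportion_explained: pd.Series

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d ** 2) @ j


def cailliez_constant(dm: DistanceMatrix) -> float:
    """Smallest additive constant making the distances Euclidean.

    Largest real eigenvalue of the 2n x 2n block matrix
    ``[[0, 2*delta1], [-I, -4*delta2]]`` with delta1 = −½ J D² J and
    delta2 = −½ J D J.
    """
    d = dm.data
    n = d.shape[0]
    delta1 = _gower_center(d)
    j = np.eye(n) - np.ones((n, n)) / n
    delta2 = -0.5 * j @ d @ j
    block = np.block([
        [np.zeros((n, n)), 2.0 * delta1],
        [-np.eye(n), -4.0 * delta2],
    ])
    eig = np.linalg.eigvals(block)
    return float(np.max(eig.real))


def pcoa(dm: DistanceMatrix, cailliez: bool = False, eig_tol: float = 1e-9) -> PcoaResult:
    """Metric ordination of ``dm`` via double-centering and eigendecomposition.

    With ``cailliez=True`` the Cailliez constant is first added to all
    off-diagonal distances, removing negative eigenvalues.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d = dm.data.copy()
    if cailliez:
        c = cailliez_constant(dm)
        if c > 0:
            d = d + c
            np.fill_diagonal(d, 0.0)
    b = _gower_center(d)
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    positive = eigval > eig_tol * max(abs(eigval[0]), 1.0)
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    axes = [f"PC{i + 1}" for i in range(int(positive.sum()))]
    prop = pd.Series(eigval[positive] / eigval[positive].sum(), index=axes,
                     name="proportion_explained")
    coordinates = pd.DataFrame(coords, index=ids, columns=axes)
    return PcoaResult(eigenvalues=eigval, coordinates=coordinates,
                      proportion_explained=prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None
    ss_total: float
    ss_within: float


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * idx.size)
    return ss


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA (Adonis) on a distance matrix.

    ``grouping`` is a mapping/Series from sample id to group label, or a
    sequence aligned with ``dm.ids``. The p-value uses unrestricted label
    permutations with the +1 correction, so its floor is
    1/(n_permutations + 1).
    """
    ids = list(dm.ids)
    if isinstance(grouping, (pd.Series, dict)):
        series = pd.Series(grouping)
        labels = series.loc[ids].to_numpy()
    else:
        labels = np.asarray(list(grouping))
        if labels.size != len(ids):
            raise ValueError("grouping length does not match distance matrix")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    n = len(ids)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = [str(uniques[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with a single sample: {small}")

    d2 = dm.data ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, a)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ss_w = _ss_within(d2, perm, a)
        f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs), R2=float(r2), p_value=float(p),
        n_permutations=n_permutations, seed=seed,
        ss_total=float(ss_total), ss_within=float(ss_within),
    )
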