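"""Ordination and permutation inference for delimiting floristic districts.

NMDS embeds a dissimilarity matrix in two dimensions by minimizing
Kruskal's stress-1 (non-metric SMACOF with isotonic regression); the best
of many random starts is kept.  MRPP tests whether user-supplied groups
of plots are more internally similar than random relabelings would be,
reporting the observed weighted mean within-group dissimilarity (delta),
its permutation expectation, the chance-corrected A statistic and a
permutation p-value.  The Mantel test measures the correlation between two
dissimilarity matrices against a null of simultaneous row/column
permutation.

Permutation p-values always carry the +1 correction (the observed
labelling counts as one permutation), so p is never exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import smacof

from .beta import DissimilarityMatrix

__all__ = [
    "Ordination",
    "nmds",
    "GroupTestResult",
    "mrpp",
    "MantelResult",
    "mantel",
    "k_medoids",
]


# ----------------------------------------------------------------------
# NMDS
# ----------------------------------------------------------------------
@dataclass
class Ordination:
    """A 2-D (or k-D) NMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame  # plot_id x axis1..axisk, centred at the origin
    stress: float
    n_starts: int
    converged: bool

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stress-1 = {self.stress:.8f}\n")
            self.coordinates.to_csv(fh, index_label="plot_id")


def _classical_mds(D: np.ndarray, n_dim: int) -> np.ndarray:
    """Classical (Torgerson) metric scaling used as the first NMDS start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_dim]
    lam = np.clip(evals[order], 0, None)
    return evecs[:, order] * np.sqrt(lam)[None, :]


def nmds(
    D: DissimilarityMatrix,
    n_dim: int = 2,
    n_starts: int = 50,
    seed: int | None = None,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> Ordination:
    """Non-metric multidimensional scaling with multiple random starts.

    Start 1 is initialized from classical metric scaling; the remaining
    ``n_starts - 1`` starts are random.  Per-start seeds are drawn from a
    nested sequence, so increasing ``n_starts`` with the same seed can only
    lower (never raise) the best stress.  Stress is Kruskal's stress-1,
    ``sqrt(sum (dhat - f(d))^2 / sum dhat^2)`` with monotone-regression
    disparities f(d).
    """
    if n_starts < 1:
        raise ValueError("need at least one start")
    vals = D.values
    if not np.any(vals > 0):
        raise ValueError("all-zero dissimilarity matrix cannot be ordinated")

    seeds = np.random.SeedSequence(seed).generate_state(max(n_starts, 1))
    best_X, best_stress, best_iter = None, np.inf, 0
    for i in range(n_starts):
        init = _classical_mds(vals, n_dim) if i == 0 else None
        X, stress, n_it = smacof(
            vals,
            metric=False,
            n_components=n_dim,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            random_state=int(seeds[i]),
            normalized_stress=True,
            return_n_iter=True,
        )
        if stress < best_stress:
            best_X, best_stress, best_iter = X, float(stress), n_it
    best_X = best_X - best_X.mean(axis=0, keepdims=True)
    coords = pd.DataFrame(
        best_X,
        index=pd.Index(D.plot_ids, name="plot_id"),
        columns=[f"axis{k+1}" for k in range(n_dim)],
    )
    return Ordination(
        coordinates=coords,
        stress=best_stress,
        n_starts=n_starts,
        converged=best_iter < max_iter,
    )


# ----------------------------------------------------------------------
# MRPP
# ----------------------------------------------------------------------
@dataclass
class GroupTestResult:
    """MRPP result: observed and expected delta, A statistic, p-value."""

    delta_obs: float
    delta_exp: float
    a_statistic: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "delta_obs": self.delta_obs,
            "delta_exp": self.delta_exp,
            "A": self.a_statistic,
            "p": self.p_value,
            "n_perm": self.n_permutations,
        }


def _delta(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Weighted mean within-group dissimilarity, weights C_g = n_g / N."""
    n = codes.size
    delta = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        m = members.size
        sub = values[np.ix_(members, members)]
        mean_within = sub.sum() / (m * (m - 1))
        delta += (m / n) * mean_within
    return delta


def mrpp(
    D: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "random",
) -> GroupTestResult:
    """Multi-response permutation procedure on a dissimilarity matrix.

    ``groups`` maps plot id -> label (mapping or pandas Series); every
    group needs at least two plots.  ``method="exact"`` enumerates all
    label permutations (feasible for <= 8 plots or so) instead of sampling;
    the exact p-value is the proportion of permutations with
    delta <= delta_obs (the identity permutation makes the numerator at
    least 1, the exact analogue of the +1 correction).
    """
    groups = dict(groups) if not isinstance(groups, dict) else groups
    labels = [groups[p] for p in D.plot_ids]
    uniq = sorted(set(labels), key=str)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    codes = np.array([uniq.index(l) for l in labels])
    counts = np.bincount(codes, minlength=len(uniq))
    if np.any(counts < 2):
        small = [uniq[g] for g in np.flatnonzero(counts < 2)]
        raise ValueError(f"singleton group(s): {small}")

    values = D.values
    n_groups = len(uniq)
    delta_obs = _delta(values, codes, n_groups)

    if method == "exact":
        perms = itertools.permutations(range(codes.size))
        deltas = np.array(
            [_delta(values, codes[list(p)], n_groups) for p in perms]
        )
        n_total = deltas.size
        p_value = float((deltas <= delta_obs + 1e-12).sum() / n_total)
        delta_exp = float(deltas.mean())
        n_reported = n_total
    elif method == "random":
        rng = np.random.default_rng(seed)
        deltas = np.empty(n_perm)
        for k in range(n_perm):
            deltas[k] = _delta(values, rng.permutation(codes), n_groups)
        p_value = float(((deltas <= delta_obs + 1e-12).sum() + 1) / (n_perm + 1))
        delta_exp = float(deltas.mean())
        n_reported = n_perm
    else:
        raise ValueError("method must be 'random' or 'exact'")

    a_stat = 1.0 - delta_obs / delta_exp if delta_exp > 0 else np.nan
    return GroupTestResult(
        delta_obs=float(delta_obs),
        delta_exp=delta_exp,
        a_statistic=float(a_stat),
        p_value=p_value,
        n_permutations=n_reported,
    )


# ----------------------------------------------------------------------
# Mantel
# ----------------------------------------------------------------------
@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def _offdiag_corr(v1: np.ndarray, m2: np.ndarray, tri: tuple) -> float:
    v2 = m2[tri]
    return float(np.corrcoef(v1, v2)[0, 1])


def mantel(
    D1: DissimilarityMatrix,
    D2: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "random",
) -> MantelResult:
    """Mantel correlation between two dissimilarity matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    one-tailed (greater) p-value permutes the rows and columns of ``D2``
    simultaneously.  ``method="exact"`` enumerates all n! permutations.
    Raises on constant matrices (undefined correlation) or mismatched
    plot sets.
    """
    if D1.plot_ids != D2.plot_ids:
        raise ValueError("matrices must index the same plots in the same order")
    m1, m2 = D1.values, D2.values
    n = D1.n
    tri = np.tril_indices(n, k=-1)
    v1 = m1[tri]
    if np.std(v1) == 0 or np.std(m2[tri]) == 0:
        raise ValueError("constant dissimilarity matrix: correlation undefined")
    r_obs = _offdiag_corr(v1, m2, tri)

    if method == "exact":
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            r = _offdiag_corr(v1, m2[np.ix_(idx, idx)], tri)
            count += r >= r_obs - 1e-12
            total += 1
        return MantelResult(r=r_obs, p_value=count / total, n_permutations=total)
    if method != "random":
        raise ValueError("method must be 'random' or 'exact'")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r = _offdiag_corr(v1, m2[np.ix_(idx, idx)], tri)
        count += r >= r_obs - 1e-12
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_perm)


# ----------------------------------------------------------------------
# k-medoids (provisional district labels)
# ----------------------------------------------------------------------
def k_medoids(D: DissimilarityMatrix, k: int, max_iter: int = 100) -> pd.Series:
    """Simple PAM-style k-medoids on a precomputed dissimilarity matrix.

    Used only to derive provisional group labels when none are supplied;
    districts confirmed by MRPP should ultimately come from the analyst.
    Initialization is greedy (best single medoid, then farthest-point);
    assignment and medoid-update steps alternate until stable.
    """
    vals = D.values
    n = D.n
    if not 2 <= k <= n // 2:
        raise ValueError("k must be between 2 and n_plots / 2")
    medoids = [int(np.argmin(vals.sum(axis=0)))]
    while len(medoids) < k:
        dist_to_nearest = vals[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(dist_to_nearest)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(vals[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for g in range(k):
            members = np.flatnonzero(assign == g)
            if members.size == 0:
                continue
            within = vals[np.ix_(members, members)].sum(axis=1)
            new_medoids[g] = members[int(np.argmin(within))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(vals[:, medoids], axis=1)
    return pd.Series(
        [f"derived_{g + 1}" for g in assign],
        index=pd.Index(D.plot_ids, name="plot_id"),
        name="group",
    )
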