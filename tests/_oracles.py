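"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths it checks: trophic levels
by exhaustive path enumeration and damped fixed-point iteration, similarity by
a double loop over python sets, between-class inertia by an explicit
sum-of-squares decomposition, PCA via an SVD route.
"""

from __future__ import annotations

import numpy as np


def enumerate_shortest_tl(web) -> dict[str, float]:
    """Shortest trophic level by exhaustive enumeration of simple paths to basal."""
    basal = web.basal_ids()
    prey = {t.id: web.prey_of(t.id, include_self=False) for t in web.taxa}

    def shortest_from(tid: str, visited: frozenset) -> float:
        if tid in basal:
            return 0.0
        best = np.inf
        for p in prey[tid]:
            if p in visited:
                continue
            best = min(best, 1.0 + shortest_from(p, visited | {p}))
        return best

    return {t.id: 1.0 + shortest_from(t.id, frozenset({t.id})) for t in web.taxa}


def fixed_point_prey_averaged(web, tol: float = 1e-10, damp: float = 0.5,
                              max_iter: int = 100000) -> dict[str, float]:
    """Prey-averaged trophic level by damped fixed-point iteration."""
    prey = {t.id: web.prey_of(t.id, include_self=False) for t in web.taxa}
    tl = {t.id: 1.0 for t in web.taxa}
    for _ in range(max_iter):
        delta = 0.0
        new = {}
        for tid, ps in prey.items():
            target = 1.0 if not ps else 1.0 + sum(tl[p] for p in ps) / len(ps)
            new[tid] = (1 - damp) * tl[tid] + damp * target
            delta = max(delta, abs(new[tid] - tl[tid]))
        tl = new
        if delta < tol:
            return tl
    raise RuntimeError("fixed point did not converge")


def loop_similarity(web) -> tuple[float, float]:
    """Mean/max Jaccardian trophic similarity by a double loop over sets."""
    ids = web.ids
    preds = {i: web.predators_of(i) for i in ids}
    prey = {i: web.prey_of(i) for i in ids}
    vals = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            num = len(preds[i] & preds[j]) + len(prey[i] & prey[j])
            den = len(preds[i] | preds[j]) + len(prey[i] | prey[j])
            vals.append(num / den if den else 0.0)
    return float(np.mean(vals)), float(np.max(vals))


def two_group_between_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """Between/total inertia by explicit SS decomposition (population scaling)."""
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    total = np.sum(Z**2)
    between = 0.0
    for g in np.unique(labels):
        sub = Z[labels == g]
        between += len(sub) * np.sum(sub.mean(axis=0) ** 2)
    return between / total


def svd_correlation_eigenvalues(X: np.ndarray) -> np.ndarray:
    """Correlation-PCA eigenvalues via the SVD of the standardized matrix."""
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    s = np.linalg.svd(Z / np.sqrt(X.shape[0]), compute_uv=False)
    return np.sort(s**2)[::-1]
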