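"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the logistic MLE is
re-derived by a coarse-to-fine grid search of the Bernoulli
log-likelihood, and the gene transfer by a brute-force double loop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def grid_mle(
    t: np.ndarray,
    y: np.ndarray,
    half_width: float = 60.0,
    n_iter: int = 14,
    n_grid: int = 33,
) -> tuple[float, float]:
    """Maximise sum_i [y_i eta_i - log(1 + e^eta_i)], eta = k + a t,
    by iteratively refined grid search over (kappa, alpha)."""
    ck = ca = 0.0
    hw = half_width
    for _ in range(n_iter):
        ks = np.linspace(ck - hw, ck + hw, n_grid)
        al = np.linspace(ca - hw, ca + hw, n_grid)
        K, A = np.meshgrid(ks, al, indexing="ij")
        eta = K.ravel()[:, None] + A.ravel()[:, None] * t[None, :]
        ll = (y[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        best = int(np.argmax(ll))
        ck, ca = float(K.ravel()[best]), float(A.ravel()[best])
        hw = 3.0 * (2.0 * hw / (n_grid - 1))
    return ck, ca


def brute_force_transfer(
    ranking: pd.Series, tm: pd.DataFrame
) -> dict[str, float]:
    """Gene scores by an explicit double loop over all (miRNA, gene) pairs."""
    weights = tm["weight"] if "weight" in tm.columns else pd.Series(1.0, index=tm.index)
    out: dict[str, float] = {g: 0.0 for g in tm["gene_id"]}
    for gene in sorted(out):
        total = 0.0
        for mirna, g, w in sorted(
            zip(tm["mirna_id"], tm["gene_id"], weights), key=lambda x: (x[0], x[2])
        ):
            if g == gene and mirna in ranking.index:
                total += float(w) * float(ranking[mirna])
        out[gene] = total
    return out


def random_logistic_instance(
    rng: np.random.Generator, n_max: int = 12
) -> tuple[np.ndarray, np.ndarray] | None:
    """A small non-separable two-class instance, or None if degenerate."""
    n = int(rng.integers(6, n_max + 1))
    t = rng.normal(size=n)
    kappa, alpha = rng.uniform(-2, 2, size=2)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(kappa + alpha * t)))).astype(float)
    if y.sum() == 0 or y.sum() == n:
        return None
    if t[y == 1].min() > t[y == 0].max() or t[y == 1].max() < t[y == 0].min():
        return None
    return t, y
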