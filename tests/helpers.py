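"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: alpha from
the raw covariance matrix, marginal likelihood by adaptive Gauss–Hermite
quadrature, and cell-mean contrasts by direct group averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from edhloc.mixed_models import _nb_inner_mode, _nb_loglik_terms


def alpha_from_covariance(matrix: np.ndarray) -> float:
    """Brute-force Cronbach's alpha from the item covariance matrix.

    alpha = k/(k-1) * (1 - tr(C) / sum(C)), population covariances.
    """
    arr = np.asarray(matrix, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    k = arr.shape[1]
    C = np.cov(arr, rowvar=False, ddof=0)
    return k / (k - 1) * (1.0 - np.trace(C) / C.sum())


def agq_loglik(beta, sigma2_b, theta, y, X, groups, nodes: int = 31) -> float:
    """Adaptive Gauss–Hermite marginal log-likelihood of the NB2 GLMM.

    Quadrature is centered at each participant's penalized mode with the
    curvature-based scale, which makes 31 nodes effectively exact and
    independent of the Laplace formula it checks (the mode/curvature are
    shared inputs; the integral itself is evaluated by quadrature, not by
    the Gaussian approximation).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, uniq = pd.factorize(np.asarray(groups))
    eta0 = X @ np.asarray(beta, dtype=float)
    xs, ws = np.polynomial.hermite.hermgauss(nodes)
    bhat, h = _nb_inner_mode(eta0, y, codes, len(uniq), sigma2_b, theta)
    scale = 1.0 / np.sqrt(h)
    total = 0.0
    for i in range(len(uniq)):
        idx = codes == i
        bs = bhat[i] + np.sqrt(2.0) * scale[i] * xs
        vals = np.array([
            _nb_loglik_terms(y[idx], np.exp(eta0[idx] + bb), theta).sum()
            - 0.5 * bb * bb / sigma2_b - 0.5 * np.log(2.0 * np.pi * sigma2_b)
            for bb in bs
        ])
        mx = vals.max()
        total += (mx + np.log(np.sum(ws * np.exp(vals - mx + xs ** 2)))
                  + 0.5 * np.log(2.0) + np.log(scale[i]))
    return float(total)


def simulate_lmm(rng, n_groups: int, beta, sigma2_b: float, sigma2_e: float,
                 n_per_group=(2, 6)):
    """Small random unbalanced random-intercept dataset for oracle checks."""
    beta = np.asarray(beta, dtype=float)
    sizes = rng.integers(n_per_group[0], n_per_group[1] + 1, n_groups)
    groups = np.repeat(np.arange(n_groups), sizes)
    n = len(groups)
    X = np.column_stack([np.ones(n)] +
                        [rng.normal(size=n) for _ in range(len(beta) - 1)])
    b = rng.normal(0.0, np.sqrt(sigma2_b), n_groups)
    y = X @ beta + b[groups] + rng.normal(0.0, np.sqrt(sigma2_e), n)
    return y, X, groups
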