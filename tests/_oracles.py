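"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own estimation code paths: the
variance-component oracle maximizes the REML log-likelihood of the
two-way mixed model (fixed sample, random run, random sample-by-run
interaction, residual) by direct dense linear algebra and scipy
optimization.  On balanced designs the REML solution coincides with the
ANOVA method-of-moments estimators whenever those are inside the
parameter space, which is exactly the regime the comparison tests use.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def reml_components(y: np.ndarray) -> dict:
    """Numerical REML fit of sigma2_run, sigma2_interaction, sigma2_residual.

    ``y`` has shape (I, J, K): samples x runs x replicates, balanced.
    """
    i_n, j_n, k_n = y.shape
    n = y.size
    yy = y.reshape(-1)

    # design matrices in the same flattened order
    sample_ix, run_ix = np.meshgrid(np.arange(i_n), np.arange(j_n), indexing="ij")
    sample_ix = np.repeat(sample_ix.reshape(-1), k_n)
    run_ix = np.repeat(run_ix.reshape(-1), k_n)
    X = np.eye(i_n)[sample_ix]  # fixed sample effects
    Zr = np.eye(j_n)[run_ix]
    Zi = np.eye(i_n * j_n)[sample_ix * j_n + run_ix]

    def neg_reml(log_s2: np.ndarray) -> float:
        s2r, s2i, s2e = np.exp(log_s2)
        V = s2r * (Zr @ Zr.T) + s2i * (Zi @ Zi.T) + s2e * np.eye(n)
        sign, logdet_v = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e12
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        A = XtVi @ X
        sign_a, logdet_a = np.linalg.slogdet(A)
        if sign_a <= 0:
            return 1e12
        beta = np.linalg.solve(A, XtVi @ yy)
        r = yy - X @ beta
        return 0.5 * (logdet_v + logdet_a + r @ Vi @ r)

    best = None
    for start in ([0.0, 0.0, 0.0], [-3.0, -3.0, -3.0], [1.0, -1.0, -2.0]):
        res = minimize(neg_reml, np.array(start), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    s2r, s2i, s2e = np.exp(best.x)
    return {"sigma2_run": s2r, "sigma2_interaction": s2i, "sigma2_residual": s2e}
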