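"""Parallel-mediator path analysis with bootstrap confidence intervals.

For exposure x, mediators m1..mk and outcome y the model is the standard
product-of-coefficients decomposition estimated by OLS path regressions
(for a just-identified parallel-mediator model these coincide with the
saturated-path SEM estimates):

    a_j:  m_j ~ x                     (one regression per mediator)
    b_j, c': y ~ x + m_1 + ... + m_k  (mediators entered jointly, so each
                                       b_j controls for x and the others)

indirect_j = a_j * b_j, total = c' + sum_j indirect_j.  Uncertainty comes
from a percentile bootstrap over participants; all coefficients are also
reported on z-scored (standardised) variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MediationResult", "parallel_mediation"]


@dataclass
class MediationResult:
    """Path coefficients, indirect effects and bootstrap CIs."""

    paths: pd.DataFrame        # effect, estimate, std_estimate, ci_low, ci_high, p
    mediator_names: list[str]
    n: int
    n_boot: int
    seed: int

    def effect(self, name: str, column: str = "std_estimate") -> float:
        return float(self.paths.set_index("effect").loc[name, column])

    def indirect(self, mediator: str) -> float:
        return self.effect(f"indirect_{mediator}")

    def summary(self) -> str:
        lines = ["Parallel mediation (percentile bootstrap)",
                 f"n = {self.n}, bootstraps = {self.n_boot}", "-" * 72,
                 f"{'effect':<24}{'std est':>10}{'CI low':>10}{'CI high':>10}{'p':>9}"]
        for _, r in self.paths.iterrows():
            lines.append(
                f"{r['effect']:<24}{r['std_estimate']:>10.4f}"
                f"{r['ci_low']:>10.4f}{r['ci_high']:>10.4f}{r['p']:>9.4f}"
            )
        return "\n".join(lines)


def _path_estimates(x, M, y):
    """All path coefficients for one (x, M, y) sample.

    Returns (a_1..a_k, b_1..b_k, c_prime, total, indirect_1..indirect_k).
    """
    n, k = M.shape
    ones = np.ones(n)
    a = np.empty(k)
    Xa = np.column_stack([ones, x])
    for j in range(k):
        a[j] = np.linalg.lstsq(Xa, M[:, j], rcond=None)[0][1]
    Xb = np.column_stack([ones, x, M])
    coef = np.linalg.lstsq(Xb, y, rcond=None)[0]
    c_prime = coef[1]
    b = coef[2:]
    indirect = a * b
    total = c_prime + indirect.sum()
    return np.concatenate([a, b, [c_prime, total], indirect])


def parallel_mediation(
    x,
    mediators,
    y,
    n_boot: int = 2000,
    seed: int = 0,
    mediator_names: list[str] | None = None,
) -> MediationResult:
    """Estimate a parallel-mediator model with percentile-bootstrap CIs.

    ``mediators`` is an (n, k) array, DataFrame, or list of columns; the
    mediators are allowed to covary (each b-path controls for the others).
    Rows with any missing value are dropped (listwise deletion).  Bootstrap
    p-values are two-sided, ``(count + 1) / (n_boot + 1)`` doubling the
    smaller tail of the sign distribution.
    """
    if isinstance(mediators, pd.DataFrame):
        mediator_names = mediator_names or list(mediators.columns)
        M = mediators.to_numpy(float)
    elif isinstance(mediators, (list, tuple)):
        M = np.column_stack([np.asarray(m, dtype=float) for m in mediators])
    else:
        M = np.asarray(mediators, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if M.shape[0] != len(x) or len(y) != len(x):
        raise ValueError("x, mediators and y must share the first dimension")
    k = M.shape[1]
    mediator_names = mediator_names or [f"m{j + 1}" for j in range(k)]

    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(M), axis=1)
    n_dropped = int(np.sum(~keep))
    x, y, M = x[keep], y[keep], M[keep]
    n = len(x)
    if n < 30:
        raise ValueError(f"need n >= 30 complete cases, have {n}")
    R = np.corrcoef(M, rowvar=False) if k > 1 else np.ones((1, 1))
    if k > 1 and np.any(np.abs(R[~np.eye(k, dtype=bool)]) > 0.99):
        raise ValueError("mediators are collinear (|r| > 0.99)")
    if n_boot < 500:
        warnings.warn("n_boot < 500: bootstrap CIs will be unstable")

    def zscore(v):
        return (v - v.mean()) / v.std(ddof=0)

    xs, ys = zscore(x), zscore(y)
    Ms = (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)

    est_raw = _path_estimates(x, M, y)
    est_std = _path_estimates(xs, Ms, ys)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(est_std)))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, Mb, yb = xs[idx], Ms[idx], ys[idx]
        if xb.std() == 0 or yb.std() == 0 or np.any(Mb.std(axis=0) == 0):
            boot[b] = est_std
            continue
        boot[b] = _path_estimates(xb, Mb, yb)

    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    p_pos = (np.sum(boot >= 0, axis=0) + 1) / (n_boot + 1)
    p_neg = (np.sum(boot <= 0, axis=0) + 1) / (n_boot + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(p_pos, p_neg))

    names = ([f"a_{m}" for m in mediator_names]
             + [f"b_{m}" for m in mediator_names]
             + ["direct", "total"]
             + [f"indirect_{m}" for m in mediator_names])
    paths = pd.DataFrame({
        "effect": names, "estimate": est_raw, "std_estimate": est_std,
        "ci_low": lo, "ci_high": hi, "p": p,
    })
    paths.attrs["n_dropped"] = n_dropped
    return MediationResult(paths, mediator_names, n, n_boot, seed)
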