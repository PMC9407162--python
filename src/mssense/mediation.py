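"""Parallel two-mediator mediation with bias-corrected bootstrap CIs.

The model regresses, by ordinary least squares with intercepts,

    M1 ~ X            (slope a1)
    M2 ~ X            (slope a2)
    Y  ~ X + M1 + M2  (slopes c', b1, b2)
    Y  ~ X            (slope c, the total effect)

and reports the indirect effects a1*b1 and a2*b2. In this package X is the
period-averaged global MS symptom burden (MSRS-R), M1 fatigue (MFIS-5), M2
sleep quality (PSQI) and Y depression (PHQ-9), all nondichotomized. For OLS
point estimates the decomposition c = c' + a1*b1 + a2*b2 holds exactly.

Confidence intervals use case-resampling bootstrap with bias-corrected (BC,
not accelerated) percentile limits: with z0 the normal quantile of the
fraction of bootstrap estimates below the point estimate, the interval takes
the bootstrap quantiles at Phi(2*z0 +/- z_{alpha/2}).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

_PATHS = ("a1", "a2", "b1", "b2", "c", "c_prime", "a1b1", "a2b2")


@dataclasses.dataclass
class MediationReport:
    estimates: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n: int
    n_boot: int
    seed: int

    def __getattr__(self, name):
        est = object.__getattribute__(self, "estimates")
        if name in est:
            return est[name]
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "path": p,
                "estimate": self.estimates[p],
                "ci_lower": self.ci[p][0],
                "ci_upper": self.ci[p][1],
            }
            for p in _PATHS
        ]
        return pd.DataFrame(rows)


def _paths_from_data(x, m1, m2, y) -> dict[str, float]:
    """All path coefficients for one sample, via least squares."""
    n = len(x)
    one = np.ones(n)
    Zx = np.column_stack([one, x])
    Zf = np.column_stack([one, x, m1, m2])
    a1 = np.linalg.lstsq(Zx, m1, rcond=None)[0][1]
    a2 = np.linalg.lstsq(Zx, m2, rcond=None)[0][1]
    bf = np.linalg.lstsq(Zf, y, rcond=None)[0]
    c = np.linalg.lstsq(Zx, y, rcond=None)[0][1]
    return {
        "a1": a1, "a2": a2, "b1": bf[2], "b2": bf[3],
        "c": c, "c_prime": bf[1], "a1b1": a1 * bf[2], "a2b2": a2 * bf[3],
    }


def _batched_paths(D: np.ndarray, idx: np.ndarray) -> dict[str, np.ndarray]:
    """Path coefficients for a batch of bootstrap resamples.

    ``D`` is the (n, 4) data matrix [x, m1, m2, y]; ``idx`` (b, n) row
    indices. Solves the normal equations batched.
    """
    S = D[idx]  # (b, n, 4)
    b, n, _ = S.shape
    one = np.ones((b, n, 1))
    x, m1, m2, y = S[..., 0], S[..., 1], S[..., 2], S[..., 3]
    Zx = np.concatenate([one, x[..., None]], axis=2)
    Zf = np.concatenate([one, x[..., None], m1[..., None], m2[..., None]], axis=2)

    def solve(Z, t):
        G = np.einsum("bnk,bnl->bkl", Z, Z)
        h = np.einsum("bnk,bn->bk", Z, t)
        return np.linalg.solve(G, h[..., None])[..., 0]

    a1 = solve(Zx, m1)[:, 1]
    a2 = solve(Zx, m2)[:, 1]
    bf = solve(Zf, y)
    c = solve(Zx, y)[:, 1]
    return {
        "a1": a1, "a2": a2, "b1": bf[:, 2], "b2": bf[:, 3],
        "c": c, "c_prime": bf[:, 1], "a1b1": a1 * bf[:, 2], "a2b2": a2 * bf[:, 3],
    }


def _bc_interval(boot: np.ndarray, point: float, alpha: float) -> tuple[float, float]:
    boot = boot[np.isfinite(boot)]
    B = len(boot)
    if B == 0:
        return (np.nan, np.nan)
    frac = np.clip(np.mean(boot < point), 1.0 / (B + 1), B / (B + 1))
    z0 = ndtri(frac)
    lo = ndtr(2 * z0 + ndtri(alpha / 2))
    hi = ndtr(2 * z0 + ndtri(1 - alpha / 2))
    return (float(np.quantile(boot, lo)), float(np.quantile(boot, hi)))


def parallel_mediation(
    x,
    m1,
    m2,
    y,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    chunk: int = 512,
) -> MediationReport:
    """Parallel two-mediator mediation of ``x`` on ``y`` through ``m1`` and
    ``m2`` with BC bootstrap confidence intervals.

    Requires continuous inputs with at least 10 cases; raises on
    zero-variance inputs or perfectly collinear mediators. Deterministic
    under the seed.
    """
    arrays = [np.asarray(v, dtype=float) for v in (x, m1, m2, y)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("x, m1, m2, y must have equal length")
    if n < 10:
        raise ValueError("mediation requires at least 10 cases")
    if any(np.any(~np.isfinite(a)) for a in arrays):
        raise ValueError("mediation inputs must be finite")
    for name, a in zip(("x", "m1", "m2", "y"), arrays):
        if np.std(a) == 0:
            raise ValueError(f"zero-variance input {name}")
    x, m1, m2, y = arrays
    r12 = np.corrcoef(m1, m2)[0, 1]
    if np.isclose(abs(r12), 1.0):
        raise ValueError("mediators are perfectly collinear")

    estimates = {k: float(v) for k, v in _paths_from_data(x, m1, m2, y).items()}

    rng = np.random.default_rng(seed)
    boot: dict[str, list[np.ndarray]] = {p: [] for p in _PATHS}
    D = np.column_stack([x, m1, m2, y])
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        try:
            batch = _batched_paths(D, idx)
        except np.linalg.LinAlgError:
            # degenerate resample batch: fall back to per-resample solves
            batch = {p: np.full(b, np.nan) for p in _PATHS}
        for p in _PATHS:
            boot[p].append(batch[p])
        done += b
    ci = {
        p: _bc_interval(np.concatenate(boot[p]), estimates[p], alpha)
        for p in _PATHS
    }
    return MediationReport(estimates=estimates, ci=ci, n=n, n_boot=n_boot, seed=seed)
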