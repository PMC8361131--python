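"""Maximum-likelihood fitting of difference scales and conjoint models.

Both tasks reduce to a Bernoulli probit model: the probability of the
observed choice is Phi(X beta), where the design matrix X encodes which
perceptual-scale values enter each trial's decision variable and beta holds
the scale values.  Identifiability follows the standard signal-detection
parameterization: the first level of each dimension is anchored at 0 and
the decision-noise SD is fixed at 1, so estimates are in d-prime units.

The conjoint hypotheses are nested:

* independent — only one dimension contributes, Delta = psi_S(s1) -
  psi_S(s2) (K-1 parameters);
* additive — Delta = (psi_S(s1) + psi_B(b1)) - (psi_S(s2) + psi_B(b2))
  (2(K-1) parameters for a KxK grid);
* saturated — one value per grid cell, Delta = psi(s1,b1) - psi(s2,b2)
  (K^2 - 1 parameters).

Difference scaling uses the signed-difference linearization: for ordered
quadruples a<b<c<d of a monotone scale, |psi_d - psi_c| - |psi_b - psi_a|
is linear in psi, so the probit likelihood is that of a GLM.  A direct
optimizer over the non-smooth absolute-value likelihood is available as a
fallback for non-monotone scales.

The likelihood is maximized with L-BFGS-B on the exact negative
log-likelihood with analytic gradients; complete separation is reported as
a warning with estimates clipped to the box bounds.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .trials import PairTrial, QuadrupleTrial

__all__ = [
    "PerceptualScale",
    "ConjointFit",
    "LRTestResult",
    "SeparationWarning",
    "fit_mlds",
    "fit_mlcm",
    "lr_test",
    "bootstrap_ci",
    "normalize_and_average",
]

_BOUND = 10.0  # box bound on scale values (d-prime units)


class SeparationWarning(UserWarning):
    """The data are (near) perfectly separated; estimates hit the bounds."""


@dataclass
class PerceptualScale:
    """Difference-scaling estimate: per-level scale values in d-prime
    units, psi[0] anchored at 0, decision-noise SD fixed at 1."""

    psi: np.ndarray
    dimension: str
    log_likelihood: float
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def n_levels(self) -> int:
        return len(self.psi)


@dataclass
class ConjointFit:
    """Fitted conjoint model.

    For independent/additive fits, ``psi_s``/``psi_b`` hold the
    per-dimension contributions (anchored entries exactly 0; an
    independent fit carries the inactive dimension as all zeros).  A
    saturated fit stores the full per-cell grid in ``psi_cell``.
    """

    model_class: str
    psi_s: np.ndarray | None
    psi_b: np.ndarray | None
    psi_cell: np.ndarray | None
    log_likelihood: float
    n_parameters: int
    n_trials: int
    independent_dimension: str | None = None
    ci: dict | None = None

    def cell_values(self) -> np.ndarray:
        """Predicted decision-scale value for every grid cell."""
        if self.model_class == "saturated":
            return self.psi_cell
        return self.psi_s[:, None] + self.psi_b[None, :]


@dataclass
class LRTestResult:
    statistic: float
    df: int
    p_value: float


def _fit_probit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximize sum log Phi((2y-1) * X beta); returns (beta, loglik)."""
    sgn = 2.0 * y - 1.0
    Xs = X * sgn[:, None]

    def nll_grad(beta):
        z = Xs @ beta
        logphi = stats.norm.logcdf(z)
        # ratio phi/Phi computed stably via exp(logpdf - logcdf)
        ratio = np.exp(stats.norm.logpdf(z) - logphi)
        return -logphi.sum(), -(Xs.T @ ratio)

    beta0 = np.zeros(X.shape[1])
    res = optimize.minimize(
        nll_grad, beta0, jac=True, method="L-BFGS-B",
        bounds=[(-_BOUND, _BOUND)] * X.shape[1],
        options=dict(maxiter=500, ftol=1e-12, gtol=1e-9),
    )
    beta = res.x
    if np.any(np.abs(beta) >= _BOUND - 1e-6):
        warnings.warn(
            "complete or quasi-complete separation: estimates clipped to "
            f"+/-{_BOUND} d'",
            SeparationWarning,
            stacklevel=3,
        )
    return beta, -float(res.fun)


def fit_mlds(
    quadruple_trials: Sequence[QuadrupleTrial], method: str = "signed"
) -> PerceptualScale:
    """Fit a difference scale to quadruple judgments.

    ``method='signed'`` uses the GLM linearization (valid for monotone
    scales); ``method='direct'`` optimizes the exact absolute-value
    likelihood by Nelder-Mead refinement of the linearized solution.
    """
    trials = list(quadruple_trials)
    if not trials:
        raise ValueError("no trials")
    dims = {t.dimension for t in trials}
    if len(dims) != 1:
        raise ValueError(f"mixed dimensions in one fit: {dims}")
    levels = sorted({lvl for t in trials for lvl in t.levels})
    n_levels = len(levels)
    if n_levels < 4:
        raise ValueError(
            f"difference scaling needs at least 4 distinct levels, got {n_levels}"
        )
    index = {lvl: i for i, lvl in enumerate(levels)}
    # Free parameters: psi for levels 1..K-1 (level 0 anchored at 0).
    X = np.zeros((len(trials), n_levels - 1))
    y = np.empty(len(trials))
    for r, t in enumerate(trials):
        if t.response is None:
            raise ValueError("trials must carry responses")
        a, b, c, d = (index[lvl] for lvl in t.levels)
        # response 1 = pair (a,b) greater: z = (psi_b - psi_a) - (psi_d - psi_c)
        for lvl, w in ((b, 1.0), (a, -1.0), (c, 1.0), (d, -1.0)):
            if lvl > 0:
                X[r, lvl - 1] += w
        y[r] = t.response
    beta, ll = _fit_probit(X, y)
    psi = np.concatenate([[0.0], beta])
    if method == "direct":
        psi, ll = _refine_mlds_direct(trials, index, psi)
    elif method != "signed":
        raise ValueError(f"unknown MLDS method {method!r}")
    return PerceptualScale(psi=psi, dimension=dims.pop(), log_likelihood=ll)


def _refine_mlds_direct(trials, index, psi0):
    y = np.array([t.response for t in trials], dtype=float)
    quads = np.array([[index[lvl] for lvl in t.levels] for t in trials])

    def nll(free):
        psi = np.concatenate([[0.0], free])
        pa, pb, pc, pd = (psi[quads[:, i]] for i in range(4))
        z = np.abs(pb - pa) - np.abs(pd - pc)  # respond 1 iff this wins
        return -stats.norm.logcdf((2 * y - 1) * z).sum()

    res = optimize.minimize(nll, psi0[1:], method="Nelder-Mead",
                            bounds=[(-_BOUND, _BOUND)] * (len(psi0) - 1),
                            options=dict(maxiter=20000, xatol=1e-6, fatol=1e-9))
    return np.concatenate([[0.0], res.x]), -float(res.fun)


def _mlcm_design(trials: Sequence[PairTrial], model_class: str,
                 n_s: int, n_b: int, dimension: str):
    """Design matrix for one conjoint model class."""
    n_trials = len(trials)
    if model_class == "independent":
        k = n_s if dimension == "smoothness" else n_b
        X = np.zeros((n_trials, k - 1))
        for r, t in enumerate(trials):
            l1 = t.cond_1[0] if dimension == "smoothness" else t.cond_1[1]
            l2 = t.cond_2[0] if dimension == "smoothness" else t.cond_2[1]
            if l1 > 0:
                X[r, l1 - 1] += 1
            if l2 > 0:
                X[r, l2 - 1] -= 1
        return X
    if model_class == "additive":
        X = np.zeros((n_trials, (n_s - 1) + (n_b - 1)))
        for r, t in enumerate(trials):
            for (s, b), w in ((t.cond_1, 1.0), (t.cond_2, -1.0)):
                if s > 0:
                    X[r, s - 1] += w
                if b > 0:
                    X[r, n_s - 1 + b - 1] += w
        return X
    if model_class == "saturated":
        X = np.zeros((n_trials, n_s * n_b - 1))
        for r, t in enumerate(trials):
            for (s, b), w in ((t.cond_1, 1.0), (t.cond_2, -1.0)):
                cell = s * n_b + b
                if cell > 0:
                    X[r, cell - 1] += w
        return X
    raise ValueError(f"unknown model class {model_class!r}")


def fit_mlcm(
    pair_trials: Sequence[PairTrial],
    model_class: str = "additive",
    grid_shape: tuple[int, int] | None = None,
    independent_dimension: str = "auto",
) -> ConjointFit:
    """Fit a conjoint model to paired metallicity judgments.

    ``independent_dimension`` selects which dimension the independent model
    uses; ``'auto'`` fits both and keeps the higher likelihood.  Fits are
    invariant to trial order.
    """
    trials = list(pair_trials)
    if not trials:
        raise ValueError("no trials")
    if any(t.response is None for t in trials):
        raise ValueError("trials must carry responses")
    if grid_shape is None:
        n_s = max(max(t.cond_1[0], t.cond_2[0]) for t in trials) + 1
        n_b = max(max(t.cond_1[1], t.cond_2[1]) for t in trials) + 1
    else:
        n_s, n_b = grid_shape
    y = np.array([t.response for t in trials], dtype=float)

    if model_class == "independent" and independent_dimension == "auto":
        fits = [
            fit_mlcm(trials, "independent", (n_s, n_b), dim)
            for dim in ("smoothness", "bumpiness")
        ]
        return max(fits, key=lambda f: f.log_likelihood)

    X = _mlcm_design(trials, model_class, n_s, n_b,
                     independent_dimension if model_class == "independent" else "")
    beta, ll = _fit_probit(X, y)

    psi_s = np.zeros(n_s)
    psi_b = np.zeros(n_b)
    psi_cell = None
    if model_class == "independent":
        if independent_dimension == "smoothness":
            psi_s[1:] = beta
        else:
            psi_b[1:] = beta
    elif model_class == "additive":
        psi_s[1:] = beta[: n_s - 1]
        psi_b[1:] = beta[n_s - 1 :]
    else:  # saturated
        psi_cell = np.concatenate([[0.0], beta]).reshape(n_s, n_b)
        psi_s = psi_b = None
    return ConjointFit(
        model_class=model_class,
        psi_s=psi_s,
        psi_b=psi_b,
        psi_cell=psi_cell,
        log_likelihood=ll,
        n_parameters=X.shape[1],
        n_trials=len(trials),
        independent_dimension=(
            independent_dimension if model_class == "independent" else None
        ),
    )


def lr_test(nested: ConjointFit, full: ConjointFit) -> LRTestResult:
    """Likelihood-ratio test of a nested conjoint model against a fuller
    one; the chi-square statistic is clipped at 0 against optimizer
    noise."""
    if nested.n_parameters >= full.n_parameters:
        raise ValueError("nested model must have fewer parameters")
    if nested.n_trials != full.n_trials:
        raise ValueError("fits must come from the same trials")
    statistic = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    df = full.n_parameters - nested.n_parameters
    return LRTestResult(
        statistic=statistic, df=df, p_value=float(stats.chi2.sf(statistic, df))
    )


def bootstrap_ci(
    trials: Sequence,
    model_class: str = "additive",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    **fit_kwargs,
):
    """Case-resampling bootstrap percentile intervals.

    Dispatches on trial type: PairTrial sequences are refit with
    :func:`fit_mlcm` (returns the fit with a ``ci`` dict of per-parameter
    low/high arrays); QuadrupleTrial sequences with :func:`fit_mlds`
    (returns the scale with ``ci_low``/``ci_high`` filled in).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    trials = list(trials)
    rng = np.random.default_rng(seed)
    n = len(trials)
    is_mlds = isinstance(trials[0], QuadrupleTrial)

    def refit(sample):
        if is_mlds:
            return fit_mlds(sample, **fit_kwargs).psi
        f = fit_mlcm(sample, model_class, **fit_kwargs)
        if f.model_class == "saturated":
            return f.psi_cell.ravel()
        return np.concatenate([f.psi_s, f.psi_b])

    point = refit(trials)
    reps = np.empty((n_boot, len(point)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            reps[i] = refit([trials[idx_i] for idx_i in idx])
    lo = np.percentile(reps, 100 * alpha / 2, axis=0)
    hi = np.percentile(reps, 100 * (1 - alpha / 2), axis=0)

    if is_mlds:
        fit = fit_mlds(trials, **fit_kwargs)
        return dataclasses.replace(fit, ci_low=lo, ci_high=hi)
    fit = fit_mlcm(trials, model_class, **fit_kwargs)
    if fit.model_class == "saturated":
        ci = dict(cell_low=lo.reshape(fit.psi_cell.shape),
                  cell_high=hi.reshape(fit.psi_cell.shape))
    else:
        k = len(fit.psi_s)
        ci = dict(psi_s_low=lo[:k], psi_s_high=hi[:k],
                  psi_b_low=lo[k:], psi_b_high=hi[k:])
    return dataclasses.replace(fit, ci=ci)


def normalize_and_average(fits: Sequence[ConjointFit]) -> dict:
    """Average conjoint scales across observers.

    Each observer's pooled (psi_s, psi_b) vector is divided by its RMS
    (making the average invariant to each observer's overall sensitivity),
    then averaged elementwise; returns mean and SEM per dimension.
    """
    if not fits:
        raise ValueError("no fits to average")
    ss, bs = [], []
    for f in fits:
        if f.psi_s is None:
            raise ValueError("normalize_and_average needs per-dimension fits")
        pooled = np.concatenate([f.psi_s, f.psi_b])
        norm = np.sqrt(np.mean(pooled**2))
        if norm == 0:
            norm = 1.0
        ss.append(f.psi_s / norm)
        bs.append(f.psi_b / norm)
    ss = np.array(ss)
    bs = np.array(bs)
    n = len(fits)
    return dict(
        psi_s_mean=ss.mean(axis=0),
        psi_b_mean=bs.mean(axis=0),
        psi_s_sem=ss.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(ss.shape[1]),
        psi_b_sem=bs.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(bs.shape[1]),
        n_observers=n,
    )
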