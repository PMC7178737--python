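"""Classical twin-design variance decomposition by maximum likelihood.

Phenotypic variance is partitioned into additive-genetic (A), shared-
environment (C) and non-shared-environment (E) components using MZ/DZ
pair data.  Path (Cholesky) parameterization is used throughout, so every
implied component covariance is positive semi-definite by construction;
reported quantities are squared/standardized, which removes the sign
indeterminacy of the raw paths.

Expected pair covariance: within-twin block AA' + CC' + EE'; cross-twin
block k AA' + CC' with k = 1 for MZ and 0.5 for DZ (the additive-genetic
correlation of DZ co-twins).

Continuous traits use full-information maximum likelihood: each pair
contributes the multivariate-normal log density of its *observed*
sub-vector, so pairs with a missing co-twin are retained.  Binary traits
use the liability-threshold model: total liability variance is fixed at 1,
the threshold is tau, and concordance-cell probabilities are bivariate
normal orthant probabilities at liability correlation a^2 + c^2 (MZ) or
0.5 a^2 + c^2 (DZ).

Fit bookkeeping follows the OpenMx convention used in twin-study reports:
df = (number of non-missing trait observations) - (free parameters) and
AIC = -2LL - 2 df.  This differs from the common -2LL + 2k form by a
data-dependent constant, which cancels in model comparisons on the same
data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "expected_pair_covariance",
    "bivariate_normal_cdf",
    "concordance_cell_probs",
    "neg2ll_continuous",
    "neg2ll_binary_liability",
    "UnivariateTwinModel",
    "BivariateCholeskyModel",
    "CorrelatedFactorsView",
    "fit_model",
    "lrt",
    "fit_bivariate_ladder",
    "homogeneity_ladder",
]

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1e12
_ZYGOSITY_K = {"MZ": 1.0, "DZ": 0.5}


# ---------------------------------------------------------------------------
# expected covariance structure


def _as_lower(mat, p: int) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(mat, dtype=float))
    if arr.shape != (p, p):
        raise ValueError(f"path matrix must be {p}x{p}, got {arr.shape}")
    return np.tril(arr)


def expected_pair_covariance(A, C, E, zygosity: str) -> np.ndarray:
    """Implied covariance of a twin pair's stacked phenotype vector.

    ``A``, ``C``, ``E`` are lower-triangular path matrices (scalars are
    treated as 1x1).  Returns the symmetric 2p x 2p matrix with within-twin
    blocks AA' + CC' + EE' and cross-twin blocks k AA' + CC'.
    """
    if zygosity not in _ZYGOSITY_K:
        raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    k = _ZYGOSITY_K[zygosity]
    p = np.atleast_2d(np.asarray(A, dtype=float)).shape[0]
    A, C, E = (_as_lower(m, p) for m in (A, C, E))
    aa, cc, ee = A @ A.T, C @ C.T, E @ E.T
    within = aa + cc + ee
    cross = k * aa + cc
    return np.block([[within, cross], [cross.T, within]])


# ---------------------------------------------------------------------------
# Gaussian FIML engine


def _fiml_neg2ll(Y: np.ndarray, mu: np.ndarray, sigma_of, keys: np.ndarray) -> float:
    """-2 log likelihood of rows of Y under per-key Gaussian models.

    ``Y`` is (n, d) with NaN for missing entries; ``mu`` is (n, d) or (d,);
    ``sigma_of(key)`` returns the (d, d) covariance for that key; ``keys``
    labels each row.  Rows are grouped by (key, missingness pattern) and
    each group's contribution is evaluated on its observed sub-vector.

    A non-positive-definite covariance returns a large finite penalty so
    gradient-based optimizers back away rather than abort.
    """
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n, d))
    obs = ~np.isnan(Y)
    pattern = obs @ (1 << np.arange(d))
    total = 0.0
    for key in pd.unique(keys):
        sigma = np.asarray(sigma_of(key), dtype=float)
        in_key = keys == key
        for pid in np.unique(pattern[in_key]):
            if pid == 0:
                continue
            rows = in_key & (pattern == pid)
            dims = np.flatnonzero(obs[np.argmax(rows)])
            sub = sigma[np.ix_(dims, dims)]
            try:
                L = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return _PENALTY
            resid = Y[np.ix_(rows, dims)] - mu[np.ix_(rows, dims)]
            x = np.linalg.solve(L, resid.T)
            quad = float(np.sum(x * x))
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            m = int(rows.sum())
            total += m * (len(dims) * _LOG2PI + logdet) + quad
    return total


class _GaussianPairData:
    """Pre-grouped sufficient statistics for repeated FIML evaluations.

    Rows are grouped by (key, missingness pattern, mean label); within a
    group the mean vector is constant, so the group's -2LL contribution is

        m (d log 2pi + log|S|) + tr(S^-1 S0) + m (ybar-mu)' S^-1 (ybar-mu)

    with S0 the scatter about the group mean ybar.  This makes each
    likelihood evaluation independent of the number of pairs.
    """

    def __init__(self, Y, keys, mean_labels=None):
        Y = np.asarray(Y, dtype=float)
        n, d = Y.shape
        if mean_labels is None:
            mean_labels = np.zeros(n, dtype=int)
        obs = ~np.isnan(Y)
        pattern = obs @ (1 << np.arange(d))
        self.n_obs = int(obs.sum())
        self.groups = []
        for key in pd.unique(keys):
            in_key = keys == key
            for pid in np.unique(pattern[in_key]):
                if pid == 0:
                    continue
                in_pat = in_key & (pattern == pid)
                dims = np.flatnonzero(obs[np.argmax(in_pat)])
                for ml in np.unique(mean_labels[in_pat]):
                    rows = in_pat & (mean_labels == ml)
                    sub = Y[np.ix_(rows, dims)]
                    m = sub.shape[0]
                    ybar = sub.mean(axis=0)
                    centered = sub - ybar
                    s0 = centered.T @ centered
                    self.groups.append((key, int(ml), dims, m, ybar, s0))

    def neg2ll(self, sigma_for, mu_for) -> float:
        total = 0.0
        for key, ml, dims, m, ybar, s0 in self.groups:
            sigma = np.asarray(sigma_for(key), dtype=float)[np.ix_(dims, dims)]
            try:
                L = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return _PENALTY
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            inv = np.linalg.inv(sigma)
            mu = np.asarray(mu_for(key, ml), dtype=float)[dims]
            dev = ybar - mu
            quad = float(np.sum(inv * s0)) + m * float(dev @ inv @ dev)
            total += m * (len(dims) * _LOG2PI + logdet) + quad
        return total


def neg2ll_continuous(
    pairs: pd.DataFrame,
    paths: dict,
    means,
    cols: Sequence[str] = ("y_t1", "y_t2"),
    zygosity_col: str = "zygosity",
) -> float:
    """FIML -2 log likelihood of twin-pair data at given A/C/E paths.

    ``paths`` maps "A"/"C"/"E" to lower-triangular path matrices (scalars
    for a univariate trait); ``means`` is the per-trait mean vector (length
    p), repeated for both twins.  ``cols`` lists the 2p data columns in
    twin-major order (all of twin 1's traits, then twin 2's).
    """
    mu_trait = np.atleast_1d(np.asarray(means, dtype=float))
    mu = np.concatenate([mu_trait, mu_trait])
    Y = pairs[list(cols)].to_numpy(dtype=float)
    zyg = pairs[zygosity_col].to_numpy()
    sigmas = {
        z: expected_pair_covariance(paths["A"], paths["C"], paths["E"], z)
        for z in ("MZ", "DZ")
    }
    return _fiml_neg2ll(Y, mu, lambda z: sigmas[z], zyg)


# ---------------------------------------------------------------------------
# bivariate-normal orthants for the liability model


def _phi(x):
    return special.ndtr(x)


def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen's-T formula; exact up to the accuracy of scipy's owens_t, which
    is well inside 1e-10 absolute.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    if rho == 1.0:
        return float(_phi(min(h, k)))
    if rho == -1.0:
        return float(max(0.0, _phi(h) + _phi(k) - 1.0))
    if rho == 0.0:
        return float(_phi(h) * _phi(k))
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    # nudge an exactly-zero argument off the removable singularity of the
    # Owen's-T form; the CDF is smooth there, so the error is ~1e-16
    if h == 0.0:
        h = 1e-14
    if k == 0.0:
        k = 1e-14
    denom = math.sqrt(1.0 - rho * rho)
    # Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,ah) - T(k,ak) - delta
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    t_h = float(special.owens_t(h, ah))
    t_k = float(special.owens_t(k, ak))
    delta = 0.0 if h * k > 0 else 0.5
    return float(0.5 * (_phi(h) + _phi(k)) - t_h - t_k - delta)


def concordance_cell_probs(tau: float, r: float) -> dict:
    """Cell probabilities of a twin pair's binary concordance table.

    The trait is coded 1 when liability exceeds ``tau``; ``r`` is the
    liability correlation.  Returns ordered-pair probabilities p11, p10
    (= p01) and p00.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("liability correlation must be in (-1, 1)")
    p00 = bivariate_normal_cdf(tau, tau, r)
    marg0 = float(_phi(tau))
    p10 = marg0 - p00
    p11 = 1.0 - 2.0 * marg0 + p00
    return {"p11": max(p11, 0.0), "p10": max(p10, 0.0), "p00": max(p00, 0.0)}


def neg2ll_binary_liability(
    pairs: pd.DataFrame,
    a2: float,
    c2: float,
    tau: float,
    cols: Sequence[str] = ("y_t1", "y_t2"),
    zygosity_col: str = "zygosity",
) -> float:
    """-2 log likelihood of binary twin data under the liability model."""
    counts = _binary_counts(pairs, cols, zygosity_col)
    return _binary_neg2ll_from_counts(counts, a2, c2, tau)


def _binary_counts(pairs, cols, zygosity_col):
    Y = pairs[list(cols)].to_numpy(dtype=float)
    zyg = pairs[zygosity_col].to_numpy()
    if not len(Y):
        raise ValueError("no twin pairs provided")
    counts = {}
    for z in ("MZ", "DZ"):
        sub = Y[zyg == z]
        both = sub[~np.isnan(sub).any(axis=1)]
        counts[z] = {
            "n11": int(np.sum((both[:, 0] == 1) & (both[:, 1] == 1))),
            "ndisc": int(np.sum(both[:, 0] != both[:, 1])),
            "n00": int(np.sum((both[:, 0] == 0) & (both[:, 1] == 0))),
        }
    singles = Y[np.isnan(Y).any(axis=1)]
    vals = singles[~np.isnan(singles)]
    counts["singles"] = {"n1": int(np.sum(vals == 1)), "n0": int(np.sum(vals == 0))}
    counts["n_obs"] = int(np.sum(~np.isnan(Y)))
    return counts


def _binary_neg2ll_from_counts(counts, a2, c2, tau):
    ll = 0.0
    for z, k in (("MZ", 1.0), ("DZ", 0.5)):
        r = k * a2 + c2
        r = min(max(r, -0.999999), 0.999999)
        p = concordance_cell_probs(tau, r)
        c = counts[z]
        for n, pr in ((c["n11"], p["p11"]), (c["ndisc"], p["p10"]), (c["n00"], p["p00"])):
            if n:
                if pr <= 0:
                    return _PENALTY
                ll += n * math.log(pr)
    s = counts["singles"]
    marg0 = float(_phi(tau))
    if s["n0"]:
        ll += s["n0"] * math.log(max(marg0, 1e-300))
    if s["n1"]:
        ll += s["n1"] * math.log(max(1.0 - marg0, 1e-300))
    return -2.0 * ll


# ---------------------------------------------------------------------------
# optimizer plumbing


def _minimize_restarts(fun, x0, n_restarts, rng, method="L-BFGS-B"):
    best = None
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(n_restarts):
        jitter = rng.normal(0.0, 0.3, size=len(x0))
        starts.append(starts[0] * (1.0 + jitter) + 0.1 * rng.normal(size=len(x0)))
    any_success = False
    for xi in starts:
        res = optimize.minimize(fun, xi, method=method)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    # polish the winner with Nelder-Mead to shake off finite-difference noise
    polish = optimize.minimize(
        fun,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400},
    )
    if polish.fun < best.fun:
        best = polish
    converged = any_success and best.fun < _PENALTY
    return best, converged


# ---------------------------------------------------------------------------
# univariate estimator


_COMPONENT_SETS = {"ACE": ("A", "C", "E"), "AE": ("A", "E"), "CE": ("C", "E"), "E": ("E",)}


class UnivariateTwinModel(BaseEstimator):
    """ACE-family variance decomposition for one trait on twin pairs.

    Parameters
    ----------
    components : {"ACE", "AE", "CE", "E"}
        Which variance components are free; E is always included.
    trait_kind : {"continuous", "binary_liability"}
        Continuous traits are fit by Gaussian FIML (free mean, free total
        variance).  Binary traits use the liability-threshold model with
        total liability variance fixed at 1 and a free threshold.
    n_restarts : int
        Random restarts around the moment-based start (the best of all
        runs is kept).
    random_state : int
        Seed for the restart jitter.

    Attributes (after ``fit``)
    --------------------------
    a2_, c2_, e2_ : standardized variance proportions (sum to 1)
    mu_ or tau_   : trait mean (continuous) or liability threshold (binary)
    minus2ll_, n_obs_, n_free_params_, df_, aic_, converged_
    """

    def __init__(
        self,
        components: str = "ACE",
        trait_kind: str = "continuous",
        n_restarts: int = 5,
        random_state: int = 0,
    ):
        self.components = components
        self.trait_kind = trait_kind
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- parameter packing ---------------------------------------------------

    def _paths_from_vector(self, theta):
        comps = _COMPONENT_SETS[self.components]
        paths = {"A": 0.0, "C": 0.0, "E": 0.0}
        for name, value in zip(comps, theta):
            paths[name] = float(value)
        return paths

    def fit(self, pairs: pd.DataFrame, cols=("y_t1", "y_t2"), zygosity_col="zygosity"):
        if self.components not in _COMPONENT_SETS:
            raise ValueError(f"unknown component set {self.components!r}")
        if self.trait_kind not in ("continuous", "binary_liability"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        Y = pairs[list(cols)].to_numpy(dtype=float)
        keep = ~np.isnan(Y).all(axis=1)
        Y = Y[keep]
        zyg = pairs[zygosity_col].to_numpy()[keep]
        bad = set(np.unique(zyg)) - set(_ZYGOSITY_K)
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")
        for z in ("MZ", "DZ"):
            if np.sum(zyg == z) < 2:
                raise ValueError(f"need at least 2 {z} pairs with data")
        rng = np.random.default_rng(self.random_state)
        if self.trait_kind == "continuous":
            self._fit_continuous(Y, zyg, rng)
        else:
            self._fit_binary(Y, zyg, rng)
        self.n_obs_ = int(np.sum(~np.isnan(Y)))
        self.df_ = self.n_obs_ - self.n_free_params_
        self.aic_ = self.minus2ll_ - 2.0 * self.df_
        return self

    def _fit_continuous(self, Y, zyg, rng):
        comps = _COMPONENT_SETS[self.components]
        n_paths = len(comps)
        vals = Y[~np.isnan(Y)]
        mu0, v0 = float(vals.mean()), float(vals.var())
        shares = {"ACE": (0.3, 0.2, 0.5), "AE": (0.4, 0.6), "CE": (0.4, 0.6), "E": (1.0,)}
        x0 = np.concatenate([[mu0], np.sqrt(np.asarray(shares[self.components]) * v0)])
        data = _GaussianPairData(Y, zyg)

        def objective(theta):
            paths = self._paths_from_vector(theta[1:])
            sigmas = {
                z: expected_pair_covariance(paths["A"], paths["C"], paths["E"], z)
                for z in ("MZ", "DZ")
            }
            mu = np.array([theta[0], theta[0]])
            return data.neg2ll(lambda z: sigmas[z], lambda k, ml: mu)

        best, converged = _minimize_restarts(objective, x0, self.n_restarts, rng)
        theta = best.x
        paths = self._paths_from_vector(theta[1:])
        a, c, e = paths["A"], paths["C"], paths["E"]
        total = a * a + c * c + e * e
        self.mu_ = float(theta[0])
        self.paths_ = {"A": abs(a), "C": abs(c), "E": abs(e)}
        self.a2_ = a * a / total
        self.c2_ = c * c / total
        self.e2_ = e * e / total
        self.variance_ = total
        self.minus2ll_ = float(best.fun)
        self.n_free_params_ = 1 + n_paths
        self.converged_ = converged

    # binary: spherical angles keep a^2 + c^2 + e^2 = 1 exactly
    def _binary_components(self, angles):
        if self.components == "ACE":
            a = math.sin(angles[0])
            c = math.cos(angles[0]) * math.sin(angles[1])
        elif self.components == "AE":
            a, c = math.sin(angles[0]), 0.0
        elif self.components == "CE":
            a, c = 0.0, math.sin(angles[0])
        else:
            a, c = 0.0, 0.0
        return a * a, c * c

    def _fit_binary(self, Y, zyg, rng):
        bad = ~np.isin(Y[~np.isnan(Y)], (0.0, 1.0))
        if bad.any():
            raise ValueError("binary trait values must be 0/1 (or missing)")
        counts = _binary_counts(
            pd.DataFrame({"y_t1": Y[:, 0], "y_t2": Y[:, 1], "zygosity": zyg}),
            ("y_t1", "y_t2"),
            "zygosity",
        )
        p1 = np.nanmean(Y)
        tau0 = float(stats.norm.ppf(1.0 - min(max(p1, 0.01), 0.99)))
        n_angles = {"ACE": 2, "AE": 1, "CE": 1, "E": 0}[self.components]
        x0 = np.concatenate([[tau0], np.full(n_angles, 0.6)])

        def objective(theta):
            a2, c2 = self._binary_components(theta[1:])
            return _binary_neg2ll_from_counts(counts, a2, c2, theta[0])

        best, converged = _minimize_restarts(
            objective, x0, self.n_restarts, rng, method="Nelder-Mead"
        )
        a2, c2 = self._binary_components(best.x[1:])
        self.tau_ = float(best.x[0])
        self.a2_ = a2
        self.c2_ = c2
        self.e2_ = 1.0 - a2 - c2
        self.paths_ = {"A": math.sqrt(a2), "C": math.sqrt(c2), "E": math.sqrt(self.e2_)}
        self.minus2ll_ = float(best.fun)
        self.n_free_params_ = 1 + n_angles
        self.converged_ = converged


# ---------------------------------------------------------------------------
# bivariate Cholesky estimator


_BIV_ENTRIES = ((0, 0), (1, 0), (1, 1))
_ENTRY_NAMES = {(0, 0): "11", (1, 0): "21", (1, 1): "22"}


@dataclass(frozen=True)
class CorrelatedFactorsView:
    """Correlated-factors reparameterization of a bivariate Cholesky fit.

    Per-trait standardized components plus the correlations between
    trait-specific latent A, C and E factors.  Algebraically equivalent to
    the Cholesky form: the implied covariance is identical.
    """

    a2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    r_a: float
    r_c: float
    r_e: float


class BivariateCholeskyModel(BaseEstimator):
    """Bivariate ACE Cholesky decomposition for two traits on twin pairs.

    Each included component X in {A, C, E} carries a free 2x2 lower-
    triangular path matrix [[x11, 0], [x21, x22]]; ``drop`` fixes named
    entries to zero (e.g. ``("a21",)`` removes the cross path — the path
    from the first trait's factor to the second trait, often written a_12
    in path diagrams).

    Attributes (after ``fit``): ``A_``, ``C_``, ``E_`` (lower-triangular,
    diagonals made non-negative), ``means_``, ``minus2ll_``, ``n_obs_``,
    ``n_free_params_``, ``df_``, ``aic_``, ``converged_``, standardized
    per-trait components ``a2_``, ``c2_``, ``e2_``.
    """

    def __init__(
        self,
        components: str = "ACE",
        drop: Sequence[str] = (),
        n_restarts: int = 5,
        random_state: int = 0,
    ):
        self.components = components
        self.drop = tuple(drop)
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _free_entries(self):
        comps = _COMPONENT_SETS[self.components]
        free = []
        for comp in comps:
            for ij in _BIV_ENTRIES:
                name = comp.lower() + _ENTRY_NAMES[ij]
                if name not in self.drop:
                    free.append((comp, ij))
        return free

    def _matrices_from_vector(self, theta, free):
        mats = {"A": np.zeros((2, 2)), "C": np.zeros((2, 2)), "E": np.zeros((2, 2))}
        for (comp, ij), val in zip(free, theta):
            mats[comp][ij] = val
        return mats

    def fit(
        self,
        pairs: pd.DataFrame,
        cols=(("y1_t1", "y1_t2"), ("y2_t1", "y2_t2")),
        zygosity_col="zygosity",
    ):
        if self.components not in _COMPONENT_SETS:
            raise ValueError(f"unknown component set {self.components!r}")
        valid = {c.lower() + _ENTRY_NAMES[ij] for c in "ACE" for ij in _BIV_ENTRIES}
        unknown = set(self.drop) - valid
        if unknown:
            raise ValueError(f"unknown drop entries: {sorted(unknown)}")
        (t1c1, t1c2), (t2c1, t2c2) = cols
        # twin-major order: (trait1_tw1, trait2_tw1, trait1_tw2, trait2_tw2)
        Y = pairs[[t1c1, t2c1, t1c2, t2c2]].to_numpy(dtype=float)
        keep = ~np.isnan(Y).all(axis=1)
        Y = Y[keep]
        zyg = pairs[zygosity_col].to_numpy()[keep]
        free = self._free_entries()
        rng = np.random.default_rng(self.random_state)

        mu0 = np.array([np.nanmean(Y[:, [0, 2]]), np.nanmean(Y[:, [1, 3]])])
        v1 = np.nanvar(Y[:, [0, 2]])
        v2 = np.nanvar(Y[:, [1, 3]])
        cov12 = np.nanmean(
            (Y[:, 0] - mu0[0]) * (Y[:, 1] - mu0[1])
        )
        V = np.array([[v1, cov12], [cov12, v2]])
        # guard against a non-PD moment matrix on tiny samples
        if np.linalg.eigvalsh(V).min() <= 1e-10:
            V = np.diag([max(v1, 1e-6), max(v2, 1e-6)])
        shares = {"ACE": (0.3, 0.2, 0.5), "AE": (0.4, 0.6), "CE": (0.4, 0.6), "E": (1.0,)}
        comps = _COMPONENT_SETS[self.components]
        start_mats = {
            comp: np.linalg.cholesky(share * V)
            for comp, share in zip(comps, shares[self.components])
        }
        x0 = np.concatenate(
            [mu0, [start_mats[comp][ij] for comp, ij in free]]
        )
        data = _GaussianPairData(Y, zyg)

        def objective(theta):
            mats = self._matrices_from_vector(theta[2:], free)
            sigmas = {
                z: expected_pair_covariance(mats["A"], mats["C"], mats["E"], z)
                for z in ("MZ", "DZ")
            }
            mu = np.array([theta[0], theta[1], theta[0], theta[1]])
            return data.neg2ll(lambda z: sigmas[z], lambda k, ml: mu)

        best, converged = _minimize_restarts(objective, x0, self.n_restarts, rng)
        mats = self._matrices_from_vector(best.x[2:], free)
        # canonical sign: non-negative diagonals (likelihood-invariant)
        for comp in mats:
            for j in range(2):
                if mats[comp][j, j] < 0:
                    mats[comp][:, j] *= -1.0
        self.A_, self.C_, self.E_ = mats["A"], mats["C"], mats["E"]
        self.means_ = np.array([best.x[0], best.x[1]])
        var = np.diag(self.A_ @ self.A_.T + self.C_ @ self.C_.T + self.E_ @ self.E_.T)
        self.a2_ = np.diag(self.A_ @ self.A_.T) / var
        self.c2_ = np.diag(self.C_ @ self.C_.T) / var
        self.e2_ = np.diag(self.E_ @ self.E_.T) / var
        self.minus2ll_ = float(best.fun)
        self.n_free_params_ = 2 + len(free)
        self.n_obs_ = int(np.sum(~np.isnan(Y)))
        self.df_ = self.n_obs_ - self.n_free_params_
        self.aic_ = self.minus2ll_ - 2.0 * self.df_
        self.converged_ = converged
        return self

    def implied_covariance(self, zygosity: str) -> np.ndarray:
        return expected_pair_covariance(self.A_, self.C_, self.E_, zygosity)

    def to_correlated_factors(self) -> CorrelatedFactorsView:
        """Factor correlations rX = (XX')_12 / sqrt((XX')_11 (XX')_22).

        Undefined (NaN) when either trait has zero variance from that
        component."""
        rs = {}
        for name, mat in (("A", self.A_), ("C", self.C_), ("E", self.E_)):
            cov = mat @ mat.T
            d = cov[0, 0] * cov[1, 1]
            rs[name] = float(cov[0, 1] / math.sqrt(d)) if d > 1e-24 else float("nan")
        return CorrelatedFactorsView(
            a2=self.a2_, c2=self.c2_, e2=self.e2_,
            r_a=rs["A"], r_c=rs["C"], r_e=rs["E"],
        )


# ---------------------------------------------------------------------------
# model comparison


def fit_model(
    pairs: pd.DataFrame,
    components: str = "ACE",
    trait_kind: str = "continuous",
    **kwargs,
) -> UnivariateTwinModel:
    """Fit a univariate ACE-family model; thin wrapper over the estimator."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("cols", "zygosity_col") if k in kwargs}
    model = UnivariateTwinModel(components=components, trait_kind=trait_kind, **kwargs)
    return model.fit(pairs, **fit_kwargs)


def lrt(full, nested, tol: float = 1e-4) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested fit against its parent.

    Returns (delta_minus2ll, delta_df, p) with p from the chi-square upper
    tail on delta_df.  A materially negative delta signals an optimizer
    failure on the parent and raises.
    """
    delta = nested.minus2ll_ - full.minus2ll_
    ddf = full.n_free_params_ - nested.n_free_params_
    if ddf < 0:
        raise ValueError("nested model has more free parameters than the full model")
    if delta < -tol:
        raise RuntimeError(
            f"nested -2LL below full's by {-delta:.3g}: refit with more restarts"
        )
    delta = max(delta, 0.0)
    if ddf == 0:
        return delta, 0, 1.0
    return delta, ddf, float(stats.chi2.sf(delta, ddf))


_LADDER = (
    ("ACE", "ACE", ()),
    ("AE", "AE", ()),
    ("AE1", "AE", ("a21",)),
    ("AE2", "AE", ("a22",)),
    ("CE", "CE", ()),
    ("E", "E", ()),
)


@dataclass
class BivariateLadderResult:
    fits: dict
    comparison: pd.DataFrame
    best: str


def fit_bivariate_ladder(
    pairs: pd.DataFrame,
    cols=(("y1_t1", "y1_t2"), ("y2_t1", "y2_t2")),
    zygosity_col: str = "zygosity",
    n_restarts: int = 5,
    random_state: int = 0,
) -> BivariateLadderResult:
    """Fit the nested bivariate model ladder and select by minimum AIC.

    Models: full ACE; AE (drop both C factors); AE1 (AE with the genetic
    cross path a21 = 0 — independent genetic factors); AE2 (AE with
    a22 = 0 — a single shared genetic factor); CE (drop A); E.  Each row
    of the comparison table carries -2LL, df, AIC and the LRT against the
    full ACE model.
    """
    fits = {}
    rows = []
    for name, comps, drop in _LADDER:
        model = BivariateCholeskyModel(
            components=comps, drop=drop, n_restarts=n_restarts, random_state=random_state
        ).fit(pairs, cols=cols, zygosity_col=zygosity_col)
        fits[name] = model
        if name == "ACE":
            delta, ddf, p = 0.0, 0, float("nan")
        else:
            delta, ddf, p = lrt(fits["ACE"], model)
        rows.append(
            {
                "model": name,
                "minus2ll": model.minus2ll_,
                "df": model.df_,
                "aic": model.aic_,
                "delta_ll": delta,
                "delta_df": ddf,
                "p": p,
                "converged": model.converged_,
            }
        )
    comparison = pd.DataFrame(rows)
    best = comparison.loc[comparison["aic"].idxmin(), "model"]
    return BivariateLadderResult(fits=fits, comparison=comparison, best=str(best))


# ---------------------------------------------------------------------------
# homogeneity ladder (saturated Gaussian models with equality constraints)


def _saturated_neg2ll_factory(Y, zyg, female, equal_order, equal_zyg, sex_effect):
    """Objective over a saturated bivariate-normal pair model.

    Parameter layout (all unconstrained): group means, log standard
    deviations, atanh correlations per zygosity, optionally a sex
    coefficient on the mean.
    """
    zlevels = ("MZ", "DZ")

    def unpack(theta):
        i = 0
        if equal_zyg:
            mus = {("MZ", 0): theta[0], ("MZ", 1): theta[0],
                   ("DZ", 0): theta[0], ("DZ", 1): theta[0]}
            sds = {k: math.exp(theta[1]) for k in mus}
            i = 2
        elif equal_order:
            mus = {("MZ", 0): theta[0], ("MZ", 1): theta[0],
                   ("DZ", 0): theta[1], ("DZ", 1): theta[1]}
            sds = {("MZ", 0): math.exp(theta[2]), ("MZ", 1): math.exp(theta[2]),
                   ("DZ", 0): math.exp(theta[3]), ("DZ", 1): math.exp(theta[3])}
            i = 4
        else:
            mus = {("MZ", 0): theta[0], ("MZ", 1): theta[1],
                   ("DZ", 0): theta[2], ("DZ", 1): theta[3]}
            sds = {("MZ", 0): math.exp(theta[4]), ("MZ", 1): math.exp(theta[5]),
                   ("DZ", 0): math.exp(theta[6]), ("DZ", 1): math.exp(theta[7])}
            i = 8
        rhos = {"MZ": math.tanh(theta[i]), "DZ": math.tanh(theta[i + 1])}
        i += 2
        beta = theta[i] if sex_effect else 0.0
        return mus, sds, rhos, beta

    labels = (female[:, 0] + 2.0 * female[:, 1]).astype(int)
    data = _GaussianPairData(Y, zyg, mean_labels=labels)

    def objective(theta):
        mus, sds, rhos, beta = unpack(theta)

        def sigma_for(z):
            s1, s2 = sds[(z, 0)], sds[(z, 1)]
            rho = rhos[z]
            return np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])

        def mu_for(z, ml):
            f1, f2 = ml & 1, ml >> 1
            return np.array([mus[(z, 0)] + beta * f1, mus[(z, 1)] + beta * f2])

        return data.neg2ll(sigma_for, mu_for)

    n_params = (2 if equal_zyg else 4 if equal_order else 8) + 2 + (1 if sex_effect else 0)
    return objective, n_params


def homogeneity_ladder(
    pairs: pd.DataFrame,
    cols=("y_t1", "y_t2"),
    zygosity_col: str = "zygosity",
    sex_cols: Optional[Sequence[str]] = ("sex1", "sex2"),
    n_restarts: int = 2,
    random_state: int = 0,
) -> pd.DataFrame:
    """Sequential equality tests on a saturated twin-pair Gaussian model.

    Starts from group-specific means/variances (by zygosity and twin
    order, with a sex term on the mean) and successively equates across
    twin order, zygosity, and sex, reporting the LRT of each step against
    the previous model.  Steps whose grouping has fewer than 2 pairs are
    skipped with a warning.
    """
    Y = pairs[list(cols)].to_numpy(dtype=float)
    zyg = pairs[zygosity_col].to_numpy()
    keep = ~np.isnan(Y).all(axis=1)
    Y, zyg = Y[keep], zyg[keep]
    if sex_cols is not None and all(c in pairs.columns for c in sex_cols):
        female = (
            pairs.loc[keep, list(sex_cols)].to_numpy() == "female"
        ).astype(float)
        sex_available = True
    else:
        female = np.zeros_like(Y)
        sex_available = False

    for z in ("MZ", "DZ"):
        if np.sum(zyg == z) < 2:
            warnings.warn(f"fewer than 2 {z} pairs; homogeneity ladder skipped")
            return pd.DataFrame()

    steps = [
        ("saturated", dict(equal_order=False, equal_zyg=False, sex_effect=sex_available)),
        ("equal_twin_order", dict(equal_order=True, equal_zyg=False, sex_effect=sex_available)),
        ("equal_zygosity", dict(equal_order=True, equal_zyg=True, sex_effect=sex_available)),
    ]
    if sex_available:
        steps.append(("equal_sex", dict(equal_order=True, equal_zyg=True, sex_effect=False)))

    rng = np.random.default_rng(random_state)
    vals = Y[~np.isnan(Y)]
    mu0, sd0 = float(vals.mean()), float(vals.std())
    rows = []
    prev = None
    for name, kw in steps:
        objective, n_params = _saturated_neg2ll_factory(Y, zyg, female, **kw)
        n_mu = 2 if kw["equal_zyg"] else 4 if kw["equal_order"] else 8
        x0 = np.concatenate(
            [
                np.full(n_mu // 2, mu0),
                np.full(n_mu // 2, math.log(max(sd0, 1e-6))),
                [0.3, 0.15],
                [0.0] if kw["sex_effect"] else [],
            ]
        )
        best, converged = _minimize_restarts(objective, x0, n_restarts, rng)
        row = {
            "step": name,
            "minus2ll": float(best.fun),
            "n_free_params": n_params,
            "converged": converged,
        }
        if prev is not None:
            delta = max(row["minus2ll"] - prev["minus2ll"], 0.0)
            ddf = prev["n_free_params"] - n_params
            row["delta_ll"] = delta
            row["delta_df"] = ddf
            row["p"] = float(stats.chi2.sf(delta, ddf)) if ddf > 0 else 1.0
        prev = row
        rows.append(row)
    return pd.DataFrame(rows)
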