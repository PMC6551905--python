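"""Multivariate calibration: PLS1 regression, PCA, grouped cross-validation
and the spectral-region evaluation workflow.

The calibration model is single-response partial least squares (PLS1) fit
by the classical NIPALS deflation scheme: with column-centred X and centred
y, each factor k takes the weight vector w_k proportional to X'y, scores
t_k = X w_k, x-loading p_k = X't_k / t_k't_k and y-loading
q_k = y't_k / t_k't_k, after which X and y are deflated by the rank-one
fits. The regression vector for K factors is B = W (P'W)^{-1} q, and
predictions are yhat = (X - x_mean) B + y_mean. No scaling beyond mean
centring is applied: spectral channels share units.

Model order is chosen from leave-one-biological-replicate-out
cross-validation — every spectrum of a biological replicate culture is
held out together, so technical replicates can never leak between folds.
RMSECV and R2_CV are computed from the pooled out-of-fold predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import extract_regions
from .spectra import RegionSpec, ReferenceTable, SpectraError, SpectrumSet

__all__ = [
    "PLS1Regression",
    "PLSModel",
    "PCAResult",
    "CVResult",
    "REGION_PRESETS",
    "RESPONSE_REGIONS",
    "PCA_REGIONS",
    "fit_pca",
    "fit_plsr",
    "predict",
    "cross_validate",
    "select_factors",
    "metrics",
    "split_calibration_test",
    "evaluate_regions",
]

#: The seven examined spectral regions (labels a-g). (a)-(e) combine the
#: acyl C-H stretch region with carbonyl windows; (f)-(g) are fingerprint
#: regions alone. Region (d)'s 1700-1715 and (e)'s 1800-1715 bounds are as
#: printed in the source tables.
REGION_PRESETS: dict[str, RegionSpec] = {
    "a": RegionSpec(((3100, 2800),), label="a"),
    "b": RegionSpec(((3100, 2800), (1800, 700)), label="b"),
    "c": RegionSpec(((3100, 2800), (1800, 1700)), label="c"),
    "d": RegionSpec(((3100, 2800), (1715, 1700)), label="d"),
    "e": RegionSpec(((3100, 2800), (1800, 1715)), label="e"),
    "f": RegionSpec(((1800, 1700),), label="f"),
    "g": RegionSpec(((1800, 700),), label="g"),
}

#: Regions examined per response: total lipid uses only (a) and (b).
RESPONSE_REGIONS: dict[str, tuple[str, ...]] = {
    "total_lipid": ("a", "b"),
    "sat": ("a", "b", "c", "d", "e", "f", "g"),
    "mufa": ("a", "b", "c", "d", "e", "f", "g"),
    "pufa": ("a", "b", "c", "d", "e", "f", "g"),
}

#: Score-plot regions for biochemical profiling by PCA.
PCA_REGIONS: dict[str, RegionSpec] = {
    "lipid": RegionSpec(((3100, 2800), (1800, 1700)), label="lipid"),
    "protein": RegionSpec(((1700, 1500),), label="protein"),
    "carbohydrate": RegionSpec(((1200, 700),), label="carbohydrate"),
}


# ---------------------------------------------------------------------------
# PLS1
# ---------------------------------------------------------------------------


class PLS1Regression(BaseEstimator, RegressorMixin):
    """PLS1 regression via NIPALS deflation (deterministic, no random
    initialisation).

    Parameters
    ----------
    n_factors : int
        Requested number of latent factors K. If the effective rank of the
        training data is exhausted earlier, fitting stops with a warning
        and ``n_factors_`` reports the realised count.

    Attributes
    ----------
    x_mean_ : ndarray (C,)
    y_mean_ : float
    W_ : ndarray (C, K) — weight vectors
    P_ : ndarray (C, K) — x-loadings
    q_ : ndarray (K,) — y-loadings
    T_ : ndarray (S, K) — training scores (mutually orthogonal)
    coef_ : ndarray (C,) — regression vector at K factors
    n_factors_ : int
    """

    def __init__(self, n_factors: int = 2):
        self.n_factors = n_factors

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        S, C = X.shape
        if y.size != S:
            raise SpectraError(f"y length {y.size} != {S} samples")
        if np.allclose(y, y[0]):
            raise SpectraError("response has zero variance; cannot calibrate")
        k_req = int(self.n_factors)
        if k_req < 1:
            raise SpectraError("n_factors must be >= 1")
        k_cap = min(S - 1, C) if S > 1 else 1
        if k_req > k_cap:
            raise SpectraError(
                f"n_factors={k_req} exceeds min(S-1, C)={k_cap}"
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        # deflation tolerance relative to the initial problem scale
        x_scale = np.linalg.norm(Xc)
        W = np.zeros((C, k_req))
        P = np.zeros((C, k_req))
        q = np.zeros(k_req)
        T = np.zeros((S, k_req))
        k_done = 0
        for k in range(k_req):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn <= 1e-13 * max(x_scale, 1.0):
                warnings.warn(
                    f"PLS1: effective rank exhausted at {k_done} factors "
                    f"(requested {k_req})",
                    stacklevel=2,
                )
                break
            w /= wn
            t = Xc @ w
            tt = float(t @ t)
            if tt <= (1e-13 * max(x_scale, 1.0)) ** 2:
                warnings.warn(
                    f"PLS1: degenerate score at factor {k + 1}; stopping at "
                    f"{k_done} factors",
                    stacklevel=2,
                )
                break
            p = Xc.T @ t / tt
            qk = float(yc @ t) / tt
            Xc = Xc - np.outer(t, p)
            yc = yc - qk * t
            W[:, k], P[:, k], q[k], T[:, k] = w, p, qk, t
            k_done += 1
        if k_done == 0:
            raise SpectraError("PLS1 could not extract any factor")
        self.W_, self.P_, self.q_, self.T_ = (
            W[:, :k_done], P[:, :k_done], q[:k_done], T[:, :k_done]
        )
        self.n_factors_ = k_done
        self.coef_ = self.coefficients_for(k_done)
        return self

    def coefficients_for(self, k: int) -> np.ndarray:
        """Regression vector using only the first ``k`` factors."""
        if not 1 <= k <= self.n_factors_:
            raise SpectraError(f"k must be in [1, {self.n_factors_}], got {k}")
        Wk, Pk, qk = self.W_[:, :k], self.P_[:, :k], self.q_[:k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, qk)

    def predict(self, X, k: int | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean_.size:
            raise SpectraError(
                f"X has {X.shape[1]} channels, model expects {self.x_mean_.size}"
            )
        B = self.coef_ if k is None else self.coefficients_for(k)
        return (X - self.x_mean_) @ B + self.y_mean_

    def prediction_matrix(self, X) -> np.ndarray:
        """Predictions for every factor count 1..n_factors_ at once,
        shape (S, n_factors_)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.x_mean_
        out = np.empty((X.shape[0], self.n_factors_))
        for k in range(1, self.n_factors_ + 1):
            out[:, k - 1] = Xc @ self.coefficients_for(k) + self.y_mean_
        return out


@dataclass
class PLSModel:
    """Frozen view of a fitted PLS1 calibration (centring vectors, weight
    and loading matrices, regression vector, factor count)."""

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    B: np.ndarray
    n_factors: int

    @classmethod
    def from_estimator(cls, est: PLS1Regression) -> "PLSModel":
        return cls(est.x_mean_, est.y_mean_, est.W_, est.P_, est.q_,
                   est.coef_, est.n_factors_)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise SpectraError(
                f"X has {X.shape[1]} channels, model expects {self.x_mean.size}"
            )
        return (X - self.x_mean) @ self.B + self.y_mean


def fit_plsr(X, y, n_factors: int) -> PLSModel:
    """Fit PLS1 and return the frozen model."""
    est = PLS1Regression(n_factors=n_factors).fit(X, y)
    return PLSModel.from_estimator(est)


def predict(model: PLSModel, X) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray          # (S, K)
    loadings: np.ndarray        # (C, K)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def fit_pca(data, n_components: int) -> PCAResult:
    """Column-mean-centred PCA via singular value decomposition.

    ``data`` may be a SpectrumSet or an S x C array. Loadings have a
    deterministic sign convention (largest-magnitude element positive).
    """
    X = data.absorbance if isinstance(data, SpectrumSet) else np.asarray(data, float)
    X = np.atleast_2d(X)
    S, C = X.shape
    if S < 2:
        raise SpectraError("PCA needs at least 2 samples")
    if n_components > min(S - 1, C):
        raise SpectraError(
            f"n_components={n_components} exceeds min(S-1, C)={min(S - 1, C)}"
        )
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    # sign convention: per component, largest |loading| element is positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2 / (S - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    k = n_components
    return PCAResult(
        scores=(U[:, :k] * s[:k]),
        loadings=Vt[:k].T,
        explained_variance=var[:k],
        explained_variance_ratio=ratio[:k],
        mean=mean,
    )


# ---------------------------------------------------------------------------
# Metrics, cross-validation, factor selection
# ---------------------------------------------------------------------------


def metrics(y, y_hat) -> tuple[float, float]:
    """(RMSE, R2) with R2 = 1 - SS_res/SS_tot. Zero-variance y gives
    R2 = nan with a warning."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size or y.size < 2:
        raise SpectraError("metrics needs two equal-length vectors of size >= 2")
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R2 undefined: response has zero variance", stacklevel=2)
        return rmse, float("nan")
    r2 = 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot
    return rmse, r2


@dataclass
class CVResult:
    """Pooled leave-one-group-out cross-validation curves.

    ``rmsecv[k-1]`` and ``r2_cv[k-1]`` are computed from the pooled
    out-of-fold predictions at k factors; ``fold_rmse`` holds the per-fold
    RMSE used for the one-standard-error rule.
    """

    rmsecv: np.ndarray            # (K,)
    r2_cv: np.ndarray             # (K,)
    fold_rmse: np.ndarray         # (n_folds, K)
    predictions: np.ndarray       # (S, K) out-of-fold
    groups: list                  # group label per sample
    k_max: int
    chosen_factors: int | None = None


def cross_validate(X, y, groups, k_max: int) -> CVResult:
    """Leave-one-group-out CV of PLS1 over factor counts 1..k_max.

    Every sample of a group is held out together. ``k_max`` is reduced
    (with a warning) if a training fold cannot support it.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    groups = list(groups)
    if len(groups) != X.shape[0]:
        raise SpectraError("groups length must match sample count")
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise SpectraError("grouped CV needs at least 2 distinct groups")
    idx_by_group = {g: [i for i, gi in enumerate(groups) if gi == g] for g in uniq}
    min_train = min(X.shape[0] - len(v) for v in idx_by_group.values())
    k_eff = min(int(k_max), min_train - 1, X.shape[1])
    if k_eff < int(k_max):
        warnings.warn(
            f"k_max reduced from {k_max} to {k_eff} (training-fold size or "
            "channel count limit)",
            stacklevel=2,
        )
    if k_eff < 1:
        raise SpectraError("cannot cross-validate: no factor is estimable")

    preds = np.full((X.shape[0], k_eff), np.nan)
    fold_rmse = np.full((len(uniq), k_eff), np.nan)
    for f, g in enumerate(uniq):
        test_idx = idx_by_group[g]
        train_idx = [i for i in range(X.shape[0]) if groups[i] != g]
        est = PLS1Regression(n_factors=k_eff).fit(X[train_idx], y[train_idx])
        pm = est.prediction_matrix(X[test_idx])
        if est.n_factors_ < k_eff:  # rank ran out: carry last column forward
            pm = np.column_stack(
                [pm] + [pm[:, -1]] * (k_eff - est.n_factors_)
            )
        preds[test_idx, :] = pm
        fold_rmse[f] = np.sqrt(np.mean((pm - y[test_idx, None]) ** 2, axis=0))

    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((preds - y[:, None]) ** 2, axis=0) / ss_tot
    return CVResult(rmsecv=rmsecv, r2_cv=r2, fold_rmse=fold_rmse,
                    predictions=preds, groups=groups, k_max=k_eff)


def select_factors(cv: CVResult, rule: str = "one_se") -> int:
    """Pick the factor count from an RMSECV curve.

    ``min``: argmin, ties resolved toward fewer factors. ``one_se``
    (default): the smallest K whose RMSECV is within one standard error
    (over folds, at the minimising K) of the minimum — a deterministic
    stand-in for visual inspection of the RMSECV curve, biased toward
    parsimony.
    """
    rmsecv = np.asarray(cv.rmsecv, dtype=float)
    if rmsecv.size == 0:
        raise SpectraError("empty RMSECV curve")
    k_min = int(np.argmin(rmsecv))  # first occurrence = fewest factors
    if rule == "min":
        return k_min + 1
    if rule != "one_se":
        raise SpectraError(f"unknown factor-selection rule {rule!r}")
    fold = cv.fold_rmse[:, k_min]
    fold = fold[np.isfinite(fold)]
    se = float(np.std(fold, ddof=1) / np.sqrt(fold.size)) if fold.size > 1 else 0.0
    threshold = rmsecv[k_min] + se
    k = int(np.argmax(rmsecv <= threshold))  # smallest qualifying K
    return k + 1


# ---------------------------------------------------------------------------
# Calibration/test split and region evaluation
# ---------------------------------------------------------------------------


def split_calibration_test(sset: SpectrumSet, reference: ReferenceTable,
                           test_fraction: float = 0.25, seed: int | None = None,
                           test_groups=None):
    """Split at the biological-replicate-group level, stratified by strain.

    A (strain, substrate, bio_rep) group never straddles the split. The
    total number of test groups is round(n_groups * test_fraction) (half
    up), apportioned to strains by largest remainder. Deterministic under
    a fixed seed. ``test_groups`` overrides the random choice.
    """
    groups = sset.groups()
    uniq = sorted(set(groups))
    if test_groups is None:
        n_total = len(uniq)
        n_test = int(np.floor(n_total * float(test_fraction) + 0.5))
        by_strain: dict[str, list] = {}
        for g in uniq:
            by_strain.setdefault(g[0], []).append(g)
        if any(len(v) < 2 for v in by_strain.values()):
            warnings.warn(
                "some strains have fewer than 2 replicate groups; "
                "stratification relaxed",
                stacklevel=2,
            )
        strains = sorted(by_strain)
        quota = {s: len(by_strain[s]) * n_test / n_total for s in strains}
        base = {s: int(np.floor(quota[s])) for s in strains}
        rest = n_test - sum(base.values())
        for s in sorted(strains, key=lambda s: (-(quota[s] - base[s]), s))[:rest]:
            base[s] += 1
        rng = np.random.default_rng(seed)
        test_groups = set()
        for s in strains:
            cand = by_strain[s]
            take = min(base[s], len(cand))
            chosen = rng.choice(len(cand), size=take, replace=False)
            test_groups.update(cand[i] for i in chosen)
    else:
        test_groups = set(tuple(g) for g in test_groups)

    test_idx = [i for i, g in enumerate(groups) if g in test_groups]
    cal_idx = [i for i, g in enumerate(groups) if g not in test_groups]
    if not cal_idx or not test_idx:
        raise SpectraError("split left one side empty; adjust test_fraction")
    # every sample must carry a reference value
    for part in (cal_idx, test_idx):
        for i in part:
            s = sset.samples[i]
            reference.align_to(sset.subset([i]), "total_lipid")
    return sset.subset(cal_idx), sset.subset(test_idx)


def evaluate_regions(sset: SpectrumSet, reference: ReferenceTable,
                     response: str, regions=None, test_fraction: float = 0.25,
                     seed: int | None = 0, k_max: int = 12,
                     rule: str = "one_se",
                     split=None) -> pd.DataFrame:
    """Evaluate spectral regions for predicting one response.

    For each region the calibration half is cross-validated (leave one
    biological-replicate group out), the factor count selected, the model
    refit on the whole calibration half and scored on the held-out test
    half. Returns one row per region with columns
    ``region, rmsecv, rmse_test, r2_cv, r2_test, n_factors`` — the schema
    of the region-evaluation result tables.

    ``regions`` may be RegionSpec objects or preset labels (a-g); the
    default is the response-specific preset list. ``split`` may carry a
    precomputed ``(calibration_set, test_set)`` pair.
    """
    if response not in RESPONSE_REGIONS:
        raise SpectraError(f"unknown response {response!r}")
    if regions is None:
        regions = RESPONSE_REGIONS[response]
    specs = [REGION_PRESETS[r] if isinstance(r, str) else r for r in regions]

    if split is None:
        cal, test = split_calibration_test(sset, reference, test_fraction, seed)
    else:
        cal, test = split
    y_cal = reference.align_to(cal, response)
    y_test = reference.align_to(test, response)
    groups = cal.groups()

    rows = []
    for spec in specs:
        cal_r = extract_regions(cal, spec)
        test_r = extract_regions(test, spec)
        cv = cross_validate(cal_r.absorbance, y_cal, groups, k_max)
        k = select_factors(cv, rule=rule)
        cv.chosen_factors = k
        model = fit_plsr(cal_r.absorbance, y_cal, n_factors=k)
        rmse_test, r2_test = metrics(y_test, model.predict(test_r.absorbance))
        rows.append({
            "region": spec.label or str(spec.intervals),
            "rmsecv": float(cv.rmsecv[k - 1]),
            "rmse_test": rmse_test,
            "r2_cv": float(cv.r2_cv[k - 1]),
            "r2_test": r2_test,
            "n_factors": int(k),
        })
    return pd.DataFrame(rows)
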