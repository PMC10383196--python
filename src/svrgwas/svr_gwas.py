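"""SVR-mediated GWAS: cross-validated support-vector-regression variable
importance per SNP with a global empirical permutation threshold.

Each SNP's raw importance is the magnitude of its weight in an
epsilon-SVR fitted on standardized dosages (|w_j| with w = sum_i a_i x_i
for the linear kernel; a kernel-gradient sensitivity norm for rbf),
averaged over a repeated k-fold cross-validation (default five folds,
ten repetitions). Scores are min-max scaled to 0-100.

Significance uses the global empirical threshold: the phenotype is
permuted, the importance recomputed, and the maximum over SNPs recorded;
the (1 - alpha) quantile of these maxima — mapped through the ORIGINAL
scaling so both sides live on one scale — is the genome-wide cutoff.
Each permutation runs one cross-validation repetition by default
(``perm_cv_repeats=1``) so the null maxima are maxima of the same
CV-averaged statistic that is thresholded; ``perm_cv_repeats=0``
switches to a single full-data fit per permutation (cheaper, but the
single-fit maximum is stochastically larger than a CV mean, which makes
the threshold conservative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "SvrConfig",
    "ImportanceResult",
    "svr_importance",
    "scale_importance",
    "empirical_threshold",
    "svr_gwas_run",
]


@dataclass
class SvrConfig:
    kernel: str = "linear"  # "linear" or "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    n_folds: int = 5
    n_repeats: int = 10
    n_permutations: int = 1000
    alpha: float = 0.05
    # CV repetitions per permutation: 0 = one full-data fit,
    # n_repeats = the full observed CV scheme
    perm_cv_repeats: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.C <= 0 or self.epsilon < 0:
            raise ValueError("need C > 0 and epsilon >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_permutations < 20:
            raise ValueError("n_permutations must be >= 20")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.perm_cv_repeats < 0:
            raise ValueError("perm_cv_repeats must be >= 0")


@dataclass
class ImportanceResult:
    raw_importance: np.ndarray
    scaled_importance: np.ndarray
    threshold_scaled: float
    threshold_raw: float
    significant: np.ndarray  # SNP indices
    null_max_distribution: np.ndarray = field(default_factory=lambda: np.empty(0))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; returns (Z, mask of non-constant columns)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance SNPs get importance 0", stacklevel=3)
    z = np.zeros_like(X)
    z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return z, ok


class _SvrEngine:
    """One dataset's standardized dosages with a precomputed linear Gram
    matrix, so repeated fits (CV splits, permutations) avoid recomputing
    kernels. The rbf path fits directly on the feature matrix."""

    def __init__(self, X: np.ndarray, config: SvrConfig):
        self.config = config
        self.z, self.ok = _standardize(X)
        self.n, self.m = self.z.shape
        self.gram = self.z @ self.z.T if config.kernel == "linear" else None

    def fit_importance(self, y: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
        """|w_j| (linear) or gradient-sensitivity (rbf) from one fit on
        the samples in ``idx`` (all samples when None)."""
        cfg = self.config
        if idx is None:
            idx = np.arange(self.n)
        if cfg.kernel == "linear":
            svr = SVR(kernel="precomputed", C=cfg.C, epsilon=cfg.epsilon)
            svr.fit(self.gram[np.ix_(idx, idx)], y[idx])
            alpha = np.zeros(len(idx))
            alpha[svr.support_] = svr.dual_coef_.ravel()
            w = self.z[idx].T @ alpha
            return np.abs(w)
        return self._rbf_importance(y, idx)

    def _rbf_importance(self, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
        cfg = self.config
        zt = self.z[idx]
        svr = SVR(kernel="rbf", C=cfg.C, epsilon=cfg.epsilon, gamma="scale")
        svr.fit(zt, y[idx])
        gamma = svr._gamma
        sv = svr.support_vectors_
        alpha = svr.dual_coef_.ravel()
        diff = zt[:, None, :] - sv[None, :, :]  # (n, n_sv, m)
        k = np.exp(-gamma * np.sum(diff**2, axis=2))
        grad = -2.0 * gamma * np.einsum("s,ns,nsm->nm", alpha, k, diff)
        return np.sqrt(np.mean(grad**2, axis=0))

    def cv_importance(self, y: np.ndarray, n_repeats: int, seed: int) -> np.ndarray:
        """Importance averaged over n_repeats x n_folds training splits."""
        total = np.zeros(self.m)
        n_fits = 0
        for rep in range(n_repeats):
            kf = KFold(n_splits=self.config.n_folds, shuffle=True, random_state=seed + rep)
            for train_idx, _ in kf.split(np.empty(self.n)):
                total += self.fit_importance(y, train_idx)
                n_fits += 1
        return total / n_fits


def svr_importance(X: np.ndarray, y: np.ndarray, config: SvrConfig | None = None) -> np.ndarray:
    """Mean per-SNP SVR importance over repeated k-fold training splits."""
    config = config or SvrConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("y length does not match samples")
    if X.shape[0] < config.n_folds:
        raise ValueError("fewer samples than CV folds")
    eng = _SvrEngine(X, config)
    raw = eng.cv_importance(y, config.n_repeats, config.seed)
    raw[~eng.ok] = 0.0
    return raw


def scale_importance(raw: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 100]; an all-equal vector maps to all zeros."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty importance vector")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("all importances equal; scaled scores set to 0", stacklevel=2)
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo) * 100.0


def _null_maxima(eng: _SvrEngine, y: np.ndarray, config: SvrConfig) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    maxima = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        yp = rng.permutation(y)
        if config.perm_cv_repeats == 0:
            imp = eng.fit_importance(yp)
        else:
            imp = eng.cv_importance(yp, config.perm_cv_repeats, config.seed + 7919 * (b + 1))
        imp = imp.copy()
        imp[~eng.ok] = 0.0
        maxima[b] = imp.max()
    return maxima


def empirical_threshold(
    X: np.ndarray, y: np.ndarray, config: SvrConfig | None = None
) -> tuple[float, np.ndarray]:
    """Global empirical threshold on the raw-importance scale.

    For each seeded permutation of y the importance is recomputed and
    its maximum over SNPs recorded; the threshold is the (1 - alpha)
    empirical quantile of those maxima.
    """
    config = config or SvrConfig()
    config.validate()
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype: permutation threshold undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eng = _SvrEngine(X, config)
        maxima = _null_maxima(eng, y, config)
    threshold = float(np.quantile(maxima, 1.0 - config.alpha, method="higher"))
    return threshold, maxima


def svr_gwas_run(X: np.ndarray, y: np.ndarray, config: SvrConfig | None = None) -> ImportanceResult:
    """Full SVR-mediated scan: CV importance, 0-100 scaling, permutation
    threshold mapped onto the original scale, significant SNP set."""
    config = config or SvrConfig()
    config.validate()
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    eng = _SvrEngine(np.asarray(X, dtype=float), config)
    raw = eng.cv_importance(y, config.n_repeats, config.seed)
    raw[~eng.ok] = 0.0
    scaled = scale_importance(raw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        maxima = _null_maxima(eng, y, config)
    thr_raw = float(np.quantile(maxima, 1.0 - config.alpha, method="higher"))
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        thr_scaled = (thr_raw - lo) / (hi - lo) * 100.0
    else:
        thr_scaled = np.inf
    significant = np.flatnonzero(scaled >= thr_scaled)
    return ImportanceResult(
        raw_importance=raw,
        scaled_importance=scaled,
        threshold_scaled=float(thr_scaled),
        threshold_raw=thr_raw,
        significant=significant,
        null_max_distribution=maxima,
    )
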