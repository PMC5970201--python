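"""Compositionally-aware correlation inference (SparCC procedure).

Sequencing counts carry only relative-abundance information, so naive
correlations between proportions are confounded by the closure constraint.
The SparCC approach estimates correlations between the latent ("basis")
absolute abundances from the variation matrix

    t_ij = Var over samples of log(x_i / x_j),

which is invariant to per-sample scaling.  Under a sparsity assumption
(most pairs uncorrelated), the basis log-variances ω² solve the linear
system

    (d - 2) ω_i² + Σ_j ω_j² = Σ_j t_ij ,

and correlations follow from ρ_ij = (ω_i² + ω_j² − t_ij) / (2 ω_i ω_j).
The sparsity assumption is refined iteratively by excluding the most
strongly correlated pair and re-solving.  The final estimate is the
elementwise median over repeated Dirichlet draws of the fraction matrix,
which propagates counting uncertainty.

Significance is assessed by a permutation pseudo-p value: each OTU's counts
are shuffled independently across samples, the full estimate recomputed,
and a two-sided add-one tail probability assigned; Benjamini–Hochberg
controls the FDR over the unique OTU pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.stats.multitest import multipletests

from .otu_table import OTUTable

__all__ = [
    "FractionMatrix",
    "BasisEstimate",
    "CorrelationResult",
    "SparCC",
    "to_fractions",
    "variation_matrix",
    "solve_basis",
    "sparcc_once",
    "sparcc",
    "permutation_pvalues",
    "bh_adjust",
    "correlation_result",
]

OMEGA_FLOOR = 1e-12


@dataclass
class FractionMatrix:
    """Strictly positive relative abundances (OTU × sample), columns sum to 1."""

    values: np.ndarray
    source_seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v <= 0).any():
            raise ValueError("fractions must be strictly positive")
        if not np.allclose(v.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("fraction columns must sum to 1")
        self.values = v


@dataclass
class BasisEstimate:
    """Basis variances and the correlation matrix they imply."""

    omega_sq: np.ndarray
    rho: np.ndarray
    excluded_pairs: set = field(default_factory=set)
    excluded_components: set = field(default_factory=set)
    degenerate: bool = False


def to_fractions(counts, mode: str = "dirichlet", seed=None) -> FractionMatrix:
    """Convert counts (OTU × sample) to strictly positive fractions.

    ``dirichlet`` draws each sample's fraction vector from Dirichlet(counts+1)
    (the Bayesian posterior under a uniform prior); ``pseudocount`` returns
    the deterministic (counts + 1) / column-sum fractions.
    """
    if isinstance(counts, OTUTable):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if mode == "pseudocount":
        shifted = counts + 1.0
        return FractionMatrix(shifted / shifted.sum(axis=0, keepdims=True))
    if mode == "dirichlet":
        rng = np.random.default_rng(seed)
        gammas = rng.standard_gamma(counts + 1.0)
        return FractionMatrix(gammas / gammas.sum(axis=0, keepdims=True))
    raise ValueError(f"unknown mode: {mode!r}")


def variation_matrix(fractions: FractionMatrix | np.ndarray) -> np.ndarray:
    """t_ij = sample variance (n−1 denominator) of log(x_i / x_j).

    Computed via the log-abundance covariance matrix:
    Var(log x_i − log x_j) = Var(log x_i) + Var(log x_j) − 2 Cov(log x_i, log x_j).
    """
    values = fractions.values if isinstance(fractions, FractionMatrix) else np.asarray(fractions)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute a variation matrix")
    log_x = np.log(values)
    cov = np.cov(log_x, ddof=1)
    cov = np.atleast_2d(cov)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov
    t = np.clip((t + t.T) / 2.0, 0.0, None)
    np.fill_diagonal(t, 0.0)
    return t


def _drop_overexcluded(d: int, excluded_pairs: set) -> set:
    """Components excluded from more than d−3 pairs can no longer be estimated."""
    counts = np.zeros(d, dtype=int)
    for i, j in excluded_pairs:
        counts[i] += 1
        counts[j] += 1
    return {int(i) for i in np.nonzero(counts > d - 3)[0]}


def solve_basis(t: np.ndarray, excluded_pairs: set | None = None) -> BasisEstimate:
    """Solve the sparsity-approximation linear system for basis variances.

    Excluded pairs have their t_ij removed from the row sums and the system
    matrix M = (d−2)·I + 1 adjusted accordingly.  Components excluded from
    more than d−3 pairs are dropped from the solve; their correlations are
    reported as 0.
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if d < 3:
        raise ValueError("basis estimation needs at least 3 components")
    if d == 3:
        warnings.warn("d = 3: the sparsity approximation is at its minimum size", stacklevel=2)
    excluded_pairs = {tuple(sorted(p)) for p in (excluded_pairs or set())}
    dropped = _drop_overexcluded(d, excluded_pairs)
    kept = [i for i in range(d) if i not in dropped]
    dk = len(kept)
    if dk < 3:
        raise ValueError("exclusion refinement dropped too many components to solve the basis system")
    pos = {c: k for k, c in enumerate(kept)}

    t_k = t[np.ix_(kept, kept)]
    m = np.ones((dk, dk))
    np.fill_diagonal(m, dk - 1.0)  # (d−2)·I + ones has diagonal d−1
    row_sums = t_k.sum(axis=1)
    for i, j in excluded_pairs:
        if i in dropped or j in dropped:
            continue
        a, b = pos[i], pos[j]
        m[a, a] -= 1.0
        m[b, b] -= 1.0
        m[a, b] -= 1.0
        m[b, a] -= 1.0
        row_sums[a] -= t_k[a, b]
        row_sums[b] -= t_k[a, b]

    try:
        omega_sq_k = np.linalg.solve(m, row_sums)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular basis system (components {kept}, {len(excluded_pairs)} excluded pairs)"
        ) from exc

    degenerate = False
    if (omega_sq_k < OMEGA_FLOOR).any():
        n_neg = int((omega_sq_k < OMEGA_FLOOR).sum())
        warnings.warn(
            f"{n_neg} basis variance(s) below floor; clamped to {OMEGA_FLOOR}",
            stacklevel=2,
        )
        omega_sq_k = np.maximum(omega_sq_k, OMEGA_FLOOR)
        degenerate = True

    omega_sq = np.full(d, OMEGA_FLOOR)
    omega_sq[kept] = omega_sq_k
    omega = np.sqrt(omega_sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (omega_sq[:, None] + omega_sq[None, :] - t) / (2.0 * np.outer(omega, omega))
    rho = np.clip(rho, -1.0, 1.0)
    if dropped:
        idx = sorted(dropped)
        rho[idx, :] = 0.0
        rho[:, idx] = 0.0
    np.fill_diagonal(rho, 1.0)
    return BasisEstimate(omega_sq, rho, set(excluded_pairs), dropped, degenerate)


def sparcc_once(
    fractions: FractionMatrix | np.ndarray,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
) -> BasisEstimate:
    """One SparCC estimate: iterative strong-pair exclusion on a fraction draw."""
    if n_exclusion_iter < 0:
        raise ValueError("n_exclusion_iter must be >= 0")
    if not (0.0 < exclusion_threshold < 1.0):
        raise ValueError("exclusion_threshold must lie in (0, 1)")
    t = variation_matrix(fractions)
    d = t.shape[0]
    excluded: set = set()
    est = solve_basis(t, excluded)
    for _ in range(n_exclusion_iter):
        candidate = np.abs(est.rho).copy()
        np.fill_diagonal(candidate, 0.0)
        for i, j in excluded:
            candidate[i, j] = candidate[j, i] = 0.0
        if est.excluded_components:
            idx = sorted(est.excluded_components)
            candidate[idx, :] = 0.0
            candidate[:, idx] = 0.0
        i, j = np.unravel_index(int(np.argmax(candidate)), candidate.shape)
        if candidate[i, j] <= exclusion_threshold:
            break
        excluded.add(tuple(sorted((int(i), int(j)))))
        est = solve_basis(t, excluded)
    return est


def sparcc(
    table,
    n_estimation_iter: int = 20,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    seed=None,
) -> np.ndarray:
    """Median correlation estimate over repeated Dirichlet fraction draws.

    Parameters
    ----------
    table : OTUTable or ndarray of shape (n_otus, n_samples)
        Count matrix (typically filtered and rarefied).
    n_estimation_iter : int
        Number of independent Dirichlet resampling iterations; the returned
        matrix is the elementwise median of the per-draw estimates.
    """
    counts = table.counts if isinstance(table, OTUTable) else np.asarray(table)
    if n_estimation_iter < 1:
        raise ValueError("n_estimation_iter must be >= 1")
    rng = np.random.default_rng(seed)
    estimates = np.empty((n_estimation_iter, counts.shape[0], counts.shape[0]))
    for k in range(n_estimation_iter):
        fractions = to_fractions(counts, mode="dirichlet", seed=rng)
        estimates[k] = sparcc_once(fractions, n_exclusion_iter, exclusion_threshold).rho
    rho = np.median(estimates, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def permutation_pvalues(
    table,
    observed: np.ndarray,
    n_permutations: int = 1000,
    seed=None,
    n_estimation_iter: int = 5,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
) -> np.ndarray:
    """Two-sided permutation pseudo-p values for each correlation.

    Every permutation shuffles each OTU's counts independently across samples
    (destroying inter-OTU dependence while preserving marginals) and recomputes
    the full estimate.  p = (1 + #{perm : |ρ_perm| ≥ |ρ_obs|}) / (1 + B).
    The per-permutation estimate uses ``n_estimation_iter`` Dirichlet draws
    (fewer than the observed estimate, for tractability).
    """
    counts = table.counts if isinstance(table, OTUTable) else np.asarray(table)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = np.asarray(observed, dtype=float)
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed)
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_permutations):
        permuted = rng.permuted(counts, axis=1)
        rho_perm = sparcc(
            permuted,
            n_estimation_iter=n_estimation_iter,
            n_exclusion_iter=n_exclusion_iter,
            exclusion_threshold=exclusion_threshold,
            seed=rng,
        )
        exceed += np.abs(rho_perm) >= abs_obs
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    pvals = (pvals + pvals.T) / 2.0
    np.fill_diagonal(pvals, 1.0)
    return pvals


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment of a vector of p values."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector of unique-pair p values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationResult:
    """Final correlations with permutation p values and BH q values."""

    otu_ids: list[str]
    rho: np.ndarray
    pvals: np.ndarray
    qvals: np.ndarray
    n_permutations: int
    n_estimation_iter: int
    n_exclusion_iter: int
    seed: int | None = None

    def pair_table(self):
        """Long-format table of unique OTU pairs (otu_a, otu_b, rho, p, q)."""
        import pandas as pd

        rows = []
        d = len(self.otu_ids)
        for i in range(d):
            for j in range(i + 1, d):
                rows.append(
                    (self.otu_ids[i], self.otu_ids[j],
                     self.rho[i, j], self.pvals[i, j], self.qvals[i, j])
                )
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "q"])


def _qvals_from_pvals(pvals: np.ndarray) -> np.ndarray:
    """BH over the unique-pair upper triangle, mirrored back to a full matrix."""
    d = pvals.shape[0]
    iu = np.triu_indices(d, k=1)
    q_flat = bh_adjust(pvals[iu])
    qvals = np.ones_like(pvals)
    qvals[iu] = q_flat
    qvals[(iu[1], iu[0])] = q_flat
    return qvals


def correlation_result(
    table,
    otu_ids: list[str] | None = None,
    n_estimation_iter: int = 20,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    n_permutations: int = 1000,
    permutation_estimation_iter: int = 5,
    seed=None,
) -> CorrelationResult:
    """Full inference: SparCC estimate, permutation p values, BH q values."""
    if isinstance(table, OTUTable):
        ids = list(table.otu_ids)
        counts = table.counts
    else:
        counts = np.asarray(table)
        ids = otu_ids if otu_ids is not None else [f"OTU_{i:02d}" for i in range(1, counts.shape[0] + 1)]
    rng = np.random.default_rng(seed)
    rho = sparcc(counts, n_estimation_iter, n_exclusion_iter, exclusion_threshold, seed=rng)
    pvals = permutation_pvalues(
        counts, rho, n_permutations, seed=rng,
        n_estimation_iter=permutation_estimation_iter,
        n_exclusion_iter=n_exclusion_iter,
        exclusion_threshold=exclusion_threshold,
    )
    qvals = _qvals_from_pvals(pvals)
    return CorrelationResult(
        ids, rho, pvals, qvals,
        n_permutations=n_permutations,
        n_estimation_iter=n_estimation_iter,
        n_exclusion_iter=n_exclusion_iter,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


class SparCC(BaseEstimator):
    """Scikit-learn style estimator for compositional correlation inference.

    Fits the SparCC basis-correlation estimate on a count matrix of shape
    (n_samples, n_otus) — note the sklearn sample-major orientation — and,
    when ``n_permutations`` is set, permutation pseudo-p values with BH
    adjustment.

    Parameters
    ----------
    n_estimation_iter : int, default=20
        Dirichlet resampling iterations; the estimate is their median.
    n_exclusion_iter : int, default=10
        Strong-pair exclusion refinement rounds per iteration.
    exclusion_threshold : float, default=0.1
        |ρ| above which the strongest pair is excluded from the sparsity
        approximation.
    n_permutations : int or None, default=None
        Number of row-shuffle permutations for pseudo-p values; None skips
        significance testing.
    permutation_estimation_iter : int, default=5
        Dirichlet iterations used inside each permutation.
    random_state : int or None
        Seed for all randomness (Dirichlet draws and permutations).

    Attributes
    ----------
    rho_ : ndarray of shape (n_otus, n_otus)
        Estimated basis correlation matrix.
    pvals_, qvals_ : ndarray
        Permutation pseudo-p values and BH-adjusted q values (only when
        ``n_permutations`` is set).
    n_features_in_ : int
    """

    def __init__(
        self,
        n_estimation_iter: int = 20,
        n_exclusion_iter: int = 10,
        exclusion_threshold: float = 0.1,
        n_permutations: int | None = None,
        permutation_estimation_iter: int = 5,
        random_state: int | None = None,
    ):
        self.n_estimation_iter = n_estimation_iter
        self.n_exclusion_iter = n_exclusion_iter
        self.exclusion_threshold = exclusion_threshold
        self.n_permutations = n_permutations
        self.permutation_estimation_iter = permutation_estimation_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_features=3, ensure_min_samples=2)
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        counts = X.T  # internal orientation is OTU x sample
        rng = np.random.default_rng(self.random_state)
        self.rho_ = sparcc(
            counts,
            n_estimation_iter=self.n_estimation_iter,
            n_exclusion_iter=self.n_exclusion_iter,
            exclusion_threshold=self.exclusion_threshold,
            seed=rng,
        )
        if self.n_permutations is not None:
            self.pvals_ = permutation_pvalues(
                counts,
                self.rho_,
                n_permutations=self.n_permutations,
                seed=rng,
                n_estimation_iter=self.permutation_estimation_iter,
                n_exclusion_iter=self.n_exclusion_iter,
                exclusion_threshold=self.exclusion_threshold,
            )
            self.qvals_ = _qvals_from_pvals(self.pvals_)
        self.n_features_in_ = counts.shape[0]
        return self

    def result(self, otu_ids: list[str] | None = None) -> CorrelationResult:
        """Package fitted attributes as a :class:`CorrelationResult`."""
        check_is_fitted(self, "rho_")
        if self.n_permutations is None:
            raise ValueError("fit with n_permutations set to obtain p/q values")
        d = self.n_features_in_
        ids = otu_ids if otu_ids is not None else [f"OTU_{i:02d}" for i in range(1, d + 1)]
        return CorrelationResult(
            list(ids), self.rho_, self.pvals_, self.qvals_,
            n_permutations=self.n_permutations,
            n_estimation_iter=self.n_estimation_iter,
            n_exclusion_iter=self.n_exclusion_iter,
            seed=self.random_state,
        )
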