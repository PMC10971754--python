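"""Signed co-occurrence network inference from compositional count data.

The estimator is neighborhood selection: each taxon's CLR profile is
regressed on all others with an L1 penalty along a log-spaced
regularization path, the penalty is chosen by subsampled stability
selection (edge instability 2*theta*(1-theta), threshold 0.05), and the
two directed coefficient estimates per pair are symmetrized into one
signed, undirected edge.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datatypes import AbundanceTable, SignedNetwork

logger = logging.getLogger(__name__)

CD_TOL = 1e-7
CD_MAX_SWEEPS = 100_000


class InferenceError(RuntimeError):
    pass


@dataclass
class ClrMatrix:
    """Samples x taxa centered log-ratio matrix (every row sums to 0)."""

    values: np.ndarray
    taxon_ids: list
    sample_ids: list
    pseudocount: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("CLR matrix must be 2-D")
        if v.size and np.abs(v.sum(axis=1)).max() > 1e-9:
            raise ValueError("CLR rows must sum to 0")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


def clr(counts: np.ndarray, pseudocount: float = 1.0, taxon_ids=None, sample_ids=None) -> ClrMatrix:
    """Centered log-ratio transform of a taxa x samples count matrix.

    Per sample: ``x -> log((x + pc) / g)`` with ``g`` the geometric mean of
    ``x + pc``.  A zero pseudocount is allowed only for strictly positive
    input.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise InferenceError("empty count table")
    if counts.min() < 0:
        raise InferenceError("negative counts")
    shifted = counts + pseudocount
    if shifted.min() <= 0:
        raise InferenceError("counts + pseudocount must be strictly positive")
    logx = np.log(shifted.T)  # samples x taxa
    vals = logx - logx.mean(axis=1, keepdims=True)
    p, n = counts.shape
    return ClrMatrix(
        values=vals,
        taxon_ids=list(taxon_ids) if taxon_ids is not None else list(range(p)),
        sample_ids=list(sample_ids) if sample_ids is not None else list(range(n)),
        pseudocount=float(pseudocount),
    )


def default_pseudocount(counts: np.ndarray) -> float:
    """1 for integer tables; the smallest positive value for fractional ones."""
    counts = np.asarray(counts, dtype=float)
    pos = counts[counts > 0]
    if pos.size == 0:
        return 1.0
    if np.allclose(counts, np.round(counts)):
        return 1.0
    return float(pos.min())


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center columns and scale to unit (population) variance.

    Returns the standardized matrix and a boolean mask of non-constant
    columns; constant columns come back as all-zero.
    """
    x = values - values.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(x)
    z[:, ok] = x[:, ok] / sd[ok]
    return z, ok


def lambda_path(clr_mat: ClrMatrix, n_lambda: int = 20, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing penalty path from ``lambda_max`` down to
    ``lambda_max * min_ratio``.

    ``lambda_max`` is the largest absolute pairwise inner product / n on
    column-standardized CLR data (= max |correlation|), the smallest
    penalty at which every neighborhood is empty.
    """
    if clr_mat.n_taxa < 2:
        raise InferenceError("need at least 2 taxa for a path")
    if n_lambda < 1:
        raise InferenceError("n_lambda must be >= 1")
    if not (0 < min_ratio <= 1):
        raise InferenceError("min_ratio must be in (0, 1]")
    z, ok = _standardize(clr_mat.values)
    if not ok.all():
        logger.info("dropping %d constant columns from path construction", int((~ok).sum()))
    z = z[:, ok]
    if z.shape[1] < 2:
        raise InferenceError("fewer than 2 non-constant taxa")
    n = z.shape[0]
    corr = (z.T @ z) / n
    np.fill_diagonal(corr, 0.0)
    lam_max = float(np.abs(corr).max())
    if lam_max <= 0:
        lam_max = 1e-3
    if n_lambda == 1:
        return np.array([lam_max])
    return lam_max * np.logspace(0.0, math.log10(min_ratio), n_lambda)


@njit(cache=True)
def _cd_gram_path(G, j, alphas, n, tol, max_sweeps):  # pragma: no cover - jitted
    """Coordinate-descent lasso of column j on the others, along a
    decreasing alpha path with warm starts, using only the Gram matrix.

    Objective per alpha: (1/2n)||y - Xb||^2 + alpha*||b||_1 with
    standardized columns, so G[k, k] == n for active columns.
    Returns (coefs, converged_flags).
    """
    p = G.shape[0]
    beta = np.zeros(p)
    out = np.zeros((alphas.size, p))
    converged = np.ones(alphas.size, dtype=np.bool_)
    kkt_tol = 1e-5
    active = np.zeros(p, dtype=np.bool_)
    # r[k] = <x_k, y - X beta> maintained incrementally
    r = G[:, j].copy()
    for ai in range(alphas.size):
        alpha = alphas[ai]
        lam_n = alpha * n
        done = False
        sweeps = 0
        while sweeps < max_sweeps:
            # full sweep over every coordinate
            maxd = 0.0
            for k in range(p):
                if k == j or G[k, k] == 0.0:
                    continue
                bk_old = beta[k]
                rho = r[k] + G[k, k] * bk_old
                if rho > lam_n:
                    bk = (rho - lam_n) / G[k, k]
                elif rho < -lam_n:
                    bk = (rho + lam_n) / G[k, k]
                else:
                    bk = 0.0
                d = bk - bk_old
                if d != 0.0:
                    beta[k] = bk
                    for m in range(p):
                        r[m] -= G[m, k] * d
                    if abs(d) > maxd:
                        maxd = abs(d)
                active[k] = beta[k] != 0.0
            sweeps += 1
            if maxd < tol:
                done = True
                break
            # stationarity certificate: handles ill-conditioned dense path
            # ends (p >> n) where coefficient changes stall above tol
            viol = 0.0
            for k in range(p):
                if k == j or G[k, k] == 0.0:
                    continue
                grad = r[k] / n
                if beta[k] == 0.0:
                    v = abs(grad) - alpha
                elif beta[k] > 0.0:
                    v = abs(grad - alpha)
                else:
                    v = abs(grad + alpha)
                if v > viol:
                    viol = v
            if viol < kkt_tol:
                done = True
                break
            # inner iterations restricted to the current active set
            # (capped so the outer stationarity check runs periodically)
            inner = 0
            while sweeps < max_sweeps and inner < 200:
                inner += 1
                maxd_a = 0.0
                for k in range(p):
                    if not active[k]:
                        continue
                    bk_old = beta[k]
                    rho = r[k] + G[k, k] * bk_old
                    if rho > lam_n:
                        bk = (rho - lam_n) / G[k, k]
                    elif rho < -lam_n:
                        bk = (rho + lam_n) / G[k, k]
                    else:
                        bk = 0.0
                    d = bk - bk_old
                    if d != 0.0:
                        beta[k] = bk
                        for m in range(p):
                            r[m] -= G[m, k] * d
                        if abs(d) > maxd_a:
                            maxd_a = abs(d)
                sweeps += 1
                if maxd_a < tol:
                    break
        if not done:
            converged[ai] = False
        out[ai] = beta
    return out, converged


def _neighborhood_paths(z: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """All p neighborhood lasso paths from one shared Gram matrix.

    Returns an array of shape (n_alphas, p, p); entry [a, j, k] is the
    coefficient of predictor k in the regression of column j at alphas[a].
    """
    n, p = z.shape
    G = z.T @ z
    coefs = np.zeros((alphas.size, p, p))
    for j in range(p):
        if G[j, j] == 0.0:
            continue
        out, converged = _cd_gram_path(G, j, alphas, n, CD_TOL, CD_MAX_SWEEPS)
        if not converged.all():
            bad = alphas[~converged]
            raise InferenceError(
                f"coordinate descent did not converge for node {j} at "
                f"alphas {bad.tolist()} after {CD_MAX_SWEEPS} sweeps"
            )
        coefs[:, j, :] = out
    return coefs


def neighborhood_lasso(clr_mat: ClrMatrix, lam: float) -> np.ndarray:
    """p x p coefficient matrix at a single penalty; zero diagonal.

    Row j holds the L1-penalized regression of (standardized) column j on
    all other standardized columns.
    """
    if clr_mat.n_samples < 3:
        raise InferenceError("need at least 3 samples")
    z, _ = _standardize(clr_mat.values)
    coefs = _neighborhood_paths(z, np.array([float(lam)]))
    return coefs[0]


def kkt_violation(z: np.ndarray, j: int, beta_j: np.ndarray, lam: float) -> float:
    """Max KKT violation for node j's lasso at penalty ``lam`` (test hook)."""
    n = z.shape[0]
    resid = z[:, j] - z @ beta_j
    grad = (z.T @ resid) / n
    viol = 0.0
    for k in range(z.shape[1]):
        if k == j or z[:, k].std() == 0:
            continue
        if beta_j[k] == 0.0:
            viol = max(viol, abs(grad[k]) - lam)
        else:
            viol = max(viol, abs(grad[k] - lam * np.sign(beta_j[k])))
    return viol


def _adjacency_from_coefs(coefs: np.ndarray) -> np.ndarray:
    """OR-rule symmetric boolean adjacency from a stack of coefficient
    matrices of shape (..., p, p)."""
    nz = coefs != 0.0
    return nz | np.swapaxes(nz, -1, -2)


@dataclass
class StarsResult:
    selected_lambda: float
    selected_index: int
    path: np.ndarray
    instability: np.ndarray
    monotone_instability: np.ndarray
    edge_frequencies: np.ndarray  # (n_lambda, p, p) inclusion frequencies
    subsample_size: int
    n_reps: int
    seed: int
    warning: str | None = None


def stars_select(
    clr_mat: ClrMatrix,
    path: np.ndarray,
    n_reps: int = 20,
    instability_threshold: float = 0.05,
    seed: int = 0,
) -> StarsResult:
    """Stability-based penalty selection over subsampled refits.

    Draws ``n_reps`` subsamples without replacement of size
    ``b = min(floor(10*sqrt(n)), floor(0.8*n))``, computes OR-rule
    edge-inclusion frequencies per penalty, and the instability
    ``D(lambda) = mean over possible edges of 2*theta*(1-theta)``.
    ``D`` is monotonized by a running maximum from the sparse (large
    penalty) end and the selected penalty is the smallest one whose
    monotonized instability stays at or below the threshold — i.e. the
    densest stable network.  If no penalty qualifies the sparsest one is
    returned with a warning.
    """
    path = np.asarray(path, dtype=float)
    if path.size == 0 or np.any(np.diff(path) > 0):
        raise InferenceError("path must be non-increasing and non-empty")
    n, p = clr_mat.n_samples, clr_mat.n_taxa
    b = min(int(10 * math.sqrt(n)), int(0.8 * n))
    b = max(b, 2)
    rng = np.random.default_rng(seed)
    freq = np.zeros((path.size, p, p))
    for _ in range(n_reps):
        idx = rng.choice(n, size=b, replace=False)
        z, _ = _standardize(clr_mat.values[idx])
        coefs = _neighborhood_paths(z, path)
        freq += _adjacency_from_coefs(coefs)
    freq /= n_reps
    iu = np.triu_indices(p, k=1)
    theta = freq[:, iu[0], iu[1]]
    instability = (2.0 * theta * (1.0 - theta)).mean(axis=1)
    monotone = np.maximum.accumulate(instability)
    ok = np.flatnonzero(monotone <= instability_threshold)
    warning = None
    if ok.size:
        sel = int(ok[-1])
    else:
        sel = 0
        warning = "no penalty met the instability threshold; returning sparsest"
        logger.warning(warning)
    return StarsResult(
        selected_lambda=float(path[sel]),
        selected_index=sel,
        path=path,
        instability=instability,
        monotone_instability=monotone,
        edge_frequencies=freq,
        subsample_size=b,
        n_reps=n_reps,
        seed=seed,
        warning=warning,
    )


def symmetrize(beta: np.ndarray, taxon_ids=None, selected_lambda=None, provenance=None) -> SignedNetwork:
    """Average the two directed coefficients per pair into one signed edge.

    An edge exists when either directed coefficient is nonzero; its weight
    is the mean of the two entries and its sign the sign of that mean.
    Exactly-opposed pairs (zero mean) are dropped and logged.
    """
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[0]
    if beta.shape != (p, p):
        raise ValueError("beta must be square")
    if np.any(np.diag(beta) != 0):
        raise ValueError("beta must have zero diagonal")
    ids = list(taxon_ids) if taxon_ids is not None else list(range(p))
    edges = {}
    conflicts = []
    for i in range(p):
        for j in range(i + 1, p):
            if beta[i, j] == 0.0 and beta[j, i] == 0.0:
                continue
            w = 0.5 * (beta[i, j] + beta[j, i])
            if w == 0.0:
                conflicts.append((ids[i], ids[j]))
                continue
            edges[(ids[i], ids[j])] = w
    if conflicts:
        logger.info("dropped %d sign-conflicting edges: %s", len(conflicts), conflicts)
    prov = dict(provenance or {})
    if conflicts:
        prov["sign_conflicts"] = conflicts
    return SignedNetwork(
        nodes=ids, edges=edges, selected_lambda=selected_lambda, provenance=prov
    )


def infer_network(
    table: AbundanceTable,
    pseudocount: float | None = None,
    n_lambda: int = 20,
    min_ratio: float = 0.01,
    n_reps: int = 20,
    instability_threshold: float = 0.05,
    seed: int = 0,
) -> SignedNetwork:
    """Full inference: CLR -> path -> stability selection -> refit -> symmetrize.

    Taxa with zero variance across the given samples are removed first and
    recorded in provenance; this defines the replicate's node set.  Sample
    columns are processed in sorted-ID order so permuting the input column
    order cannot change the result.
    """
    if table.n_samples < 10:
        raise InferenceError("need at least 10 samples to infer a network")
    order = sorted(table.sample_ids, key=str)
    counts = table.counts.loc[:, order].to_numpy(dtype=float)
    variances = counts.var(axis=1)
    keep = variances > 0
    dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
    taxon_ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    counts = counts[keep]
    if counts.shape[0] < 2:
        raise InferenceError("fewer than 2 taxa with nonzero variance")
    pc = default_pseudocount(counts) if pseudocount is None else float(pseudocount)
    cm = clr(counts, pc, taxon_ids=taxon_ids, sample_ids=order)
    path = lambda_path(cm, n_lambda=n_lambda, min_ratio=min_ratio)
    stars = stars_select(
        cm, path, n_reps=n_reps,
        instability_threshold=instability_threshold, seed=seed,
    )
    z, _ = _standardize(cm.values)
    coefs = _neighborhood_paths(z, np.array([stars.selected_lambda]))[0]
    provenance = {
        "seed": seed,
        "pseudocount": pc,
        "dropped_zero_variance": dropped,
        "lambda_path": stars.path.tolist(),
        "instability": stars.instability.tolist(),
        "selected_lambda": stars.selected_lambda,
        "subsample_size": stars.subsample_size,
        "stability_reps": stars.n_reps,
    }
    if stars.warning:
        provenance["warning"] = stars.warning
    return symmetrize(
        coefs,
        taxon_ids=taxon_ids,
        selected_lambda=stars.selected_lambda,
        provenance=provenance,
    )
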