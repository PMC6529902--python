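"""Mass-univariate statistical parametric mapping on the template mesh.

At every vertex an ordinary least-squares model relates one phenotype to a
predictor of interest, adjusting for clinical covariates. The reported effect
is the standardized partial regression coefficient (response and predictor
z-scored, covariates entered in their native units).

Inference is stabilised by parcellation consensus: the mesh is partitioned
into K connected parcels grown from random seeds, the phenotype is averaged
within parcels, a permutation p-value is computed per parcel under the
reduced-model residual-permutation scheme (Freedman-Lane: permute residuals
of the covariates-only model, re-add its fitted values, recompute the
statistic), the parcel p is broadcast to member vertices, and the per-vertex
consensus is the median over many independent parcellations. Multiplicity is
controlled by Benjamini-Hochberg FDR applied jointly to the pooled p-values
of all models in the run. Significant regions are summarised by the maximum
standardized beta and the percentage of RV free-wall area reached.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from .mesh import SurfaceMesh, vertex_voronoi_areas
from .rng import stage_rng

__all__ = ["DesignMatrix", "Parcellation", "SpmResult", "build_design",
           "fit_vertexwise_glm", "random_parcellation",
           "permutation_consensus_test", "bh_fdr", "summarize_region",
           "run_spm_model", "run_spm_models"]

DEFAULT_COVARIATES = ("age", "sex", "ethnicity", "bsa", "ph_group",
                      "time_from_diagnosis")
METABOLITE_EXTRA_COVARIATES = ("creatinine", "bilirubin")


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Predictor of interest + adjustment covariates, intercept first.

    The predictor column is stored z-scored so its coefficient on a z-scored
    response is the standardized partial regression coefficient. Categorical
    covariates are dummy-coded against their most frequent level (recorded in
    ``reference_levels``).
    """

    X: np.ndarray                   # (n, p)
    columns: list[str]
    predictor_index: int
    rows: np.ndarray                # index of retained (complete-case) rows
    reference_levels: dict[str, str] = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def reduced(self) -> np.ndarray:
        """Design with the predictor of interest removed (covariates only)."""
        keep = [j for j in range(self.X.shape[1]) if j != self.predictor_index]
        return self.X[:, keep]


def build_design(table: pd.DataFrame, predictor: str,
                 covariates: Sequence[str] = DEFAULT_COVARIATES) -> DesignMatrix:
    """Complete-case design matrix with dummy-coded categoricals.

    Subjects missing the predictor or any covariate are dropped (the row
    index of retained subjects is kept for aligning the response matrix).
    """
    used = [predictor] + [c for c in covariates if c != predictor]
    missing_cols = [c for c in used if c not in table.columns]
    if missing_cols:
        raise ValueError(f"columns not in subject table: {missing_cols}")
    sub = table[used]
    complete = ~sub.isna().any(axis=1)
    rows = np.nonzero(complete.to_numpy())[0]
    sub = sub.iloc[rows]

    cols: list[np.ndarray] = [np.ones(len(sub))]
    names = ["intercept"]
    refs: dict[str, str] = {}

    pred_vals = sub[predictor]
    if not pd.api.types.is_numeric_dtype(pred_vals):
        raise ValueError("predictor of interest must be numeric")
    pv = pred_vals.to_numpy(dtype=float)
    sd = pv.std(ddof=1)
    if sd == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    cols.append((pv - pv.mean()) / sd)
    names.append(predictor)
    predictor_index = 1

    for c in covariates:
        if c == predictor:
            continue
        v = sub[c]
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 2:
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
        else:
            levels = v.astype(str)
            ref = levels.mode().iloc[0]
            refs[c] = ref
            for lev in sorted(levels.unique()):
                if lev == ref:
                    continue
                cols.append((levels == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")

    X = np.column_stack(cols)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"not enough subjects (n={n}) for {p} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        culprits = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")
    return DesignMatrix(X=X, columns=names, predictor_index=predictor_index,
                        rows=rows, reference_levels=refs)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    q, r = np.linalg.qr(X)
    small = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
    return [names[j] for j in np.nonzero(small)[0]]


# ---------------------------------------------------------------------------
# vertex-wise GLM
# ---------------------------------------------------------------------------

def fit_vertexwise_glm(Y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each vertex column of ``Y`` on the design.

    Returns the standardized beta of the predictor of interest per vertex and
    the residual matrix. ``Y`` rows must already be aligned to ``design.rows``.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] != design.n:
        raise ValueError("response rows must align with the design matrix")
    sd = Y.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Yz = (Y - Y.mean(axis=0)) / sd_safe
    coef, *_ = np.linalg.lstsq(design.X, Yz, rcond=None)
    beta = coef[design.predictor_index]
    resid = Yz - design.X @ coef
    beta = np.where(sd > 0, beta, 0.0)
    return beta, resid


def _predictor_contrast(design: DesignMatrix) -> np.ndarray:
    """Row of the pseudoinverse extracting the predictor coefficient."""
    return np.linalg.pinv(design.X)[design.predictor_index]


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

@dataclass
class Parcellation:
    parcel_of: np.ndarray           # (V,) parcel id per vertex
    n_parcels: int
    seed: int

    def members(self, k: int) -> np.ndarray:
        return np.nonzero(self.parcel_of == k)[0]


def mesh_adjacency_lists(mesh: SurfaceMesh) -> list[np.ndarray]:
    f = mesh.faces
    pairs = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    pairs = np.unique(np.vstack([pairs, pairs[:, ::-1]]), axis=0)
    out: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for a, b in pairs:
        out[a].append(b)
    return [np.asarray(x) for x in out]


def random_parcellation(mesh: SurfaceMesh, K: int, seed: int,
                        adjacency: list[np.ndarray] | None = None) -> Parcellation:
    """K connected parcels by multi-source breadth-first region growing."""
    V = mesh.n_vertices
    if not 1 <= K <= V:
        raise ValueError("K must be between 1 and the vertex count")
    adj = adjacency if adjacency is not None else mesh_adjacency_lists(mesh)
    rng = stage_rng(seed, "parcellation")
    seeds = rng.choice(V, size=K, replace=False)
    parcel = np.full(V, -1, dtype=np.int64)
    queue: deque[int] = deque()
    for k, s in enumerate(seeds):
        parcel[s] = k
        queue.append(int(s))
    while queue:
        v = queue.popleft()
        pv = parcel[v]
        for w in adj[v]:
            if parcel[w] < 0:
                parcel[w] = pv
                queue.append(int(w))
    if np.any(parcel < 0):
        n_unreached = int(np.sum(parcel < 0))
        raise ValueError(f"mesh graph is disconnected: {n_unreached} vertices "
                         "unreachable from the parcel seeds")
    return Parcellation(parcel_of=parcel, n_parcels=K, seed=seed)


def _parcel_means(Y: np.ndarray, parcel_of: np.ndarray, K: int) -> np.ndarray:
    """(n, K) matrix of within-parcel vertex means."""
    counts = np.bincount(parcel_of, minlength=K).astype(float)
    ind = sparse.csr_matrix((np.ones(len(parcel_of)),
                             (parcel_of, np.arange(len(parcel_of)))),
                            shape=(K, len(parcel_of)))
    sums = (ind @ Y.T).T                      # (n, K)
    return sums / counts[None, :]


# ---------------------------------------------------------------------------
# permutation consensus
# ---------------------------------------------------------------------------

def permutation_consensus_test(Y: np.ndarray, design: DesignMatrix,
                               mesh: SurfaceMesh, n_parcellations: int = 50,
                               K: int | None = None, n_permutations: int = 1000,
                               seed: int = 0,
                               adjacency: list[np.ndarray] | None = None) -> dict:
    """Consensus permutation p-value per vertex.

    For each random parcellation the parcel-mean response is tested with a
    two-sided Freedman-Lane permutation p-value on the standardized beta of
    the predictor; parcel p-values are broadcast to member vertices and the
    consensus across parcellations is the (lower) median. Deterministic given
    ``seed``. The smallest attainable p is 1/(n_permutations+1); a warning
    flag is set in the metadata when that resolution is coarse relative to
    the number of vertices.
    """
    Y = np.asarray(Y, dtype=np.float64)
    V = Y.shape[1]
    if K is None:
        K = max(2, V // 20)
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    adj = adjacency if adjacency is not None else mesh_adjacency_lists(mesh)
    rng = stage_rng(seed, "permutation")
    n = design.n

    c = _predictor_contrast(design)                   # (n,)
    Z = design.reduced
    Hz = Z @ np.linalg.pinv(Z)                        # reduced-model hat matrix

    # one permutation index matrix shared by all parcellations of this run
    perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])

    p_stack = np.empty((n_parcellations, V))
    beta_stack = np.empty((n_parcellations, V))
    parc_seeds = rng.integers(0, 2 ** 31 - 1, size=n_parcellations)
    for t in range(n_parcellations):
        parc = random_parcellation(mesh, K, int(parc_seeds[t]), adjacency=adj)
        Yp = _parcel_means(Y, parc.parcel_of, K)      # (n, K)
        stat_obs = _standardized_beta(Yp, c)
        fitted = Hz @ Yp
        resid = Yp - fitted
        Ystar = fitted[None, :, :] + resid[perms]     # (P, n, K)
        stat_perm = _standardized_beta_batch(Ystar, c)
        exceed = (np.abs(stat_perm) >= np.abs(stat_obs)[None, :]).sum(axis=0)
        p_parcel = (1.0 + exceed) / (n_permutations + 1.0)
        p_stack[t] = p_parcel[parc.parcel_of]
        beta_stack[t] = stat_obs[parc.parcel_of]
    order = np.sort(p_stack, axis=0)
    consensus = order[(n_parcellations - 1) // 2]     # lower median
    return {
        "p_consensus": consensus,
        "beta_parcel_mean": beta_stack.mean(axis=0),
        "n_permutations": n_permutations,
        "n_parcellations": n_parcellations,
        "K": K,
        "min_attainable_p": 1.0 / (n_permutations + 1.0),
        "resolution_warning": (n_permutations + 1) < V,
        "seed": seed,
    }


def _standardized_beta(Y: np.ndarray, c: np.ndarray) -> np.ndarray:
    sd = Y.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    return (c @ Y) / sd


def _standardized_beta_batch(Y: np.ndarray, c: np.ndarray) -> np.ndarray:
    sd = Y.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    return np.einsum("n,pnk->pk", c, Y) / sd


# ---------------------------------------------------------------------------
# FDR and region summaries
# ---------------------------------------------------------------------------

def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask on a pooled p-vector."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class SpmResult:
    model_id: str
    beta: np.ndarray                # per-vertex standardized beta
    p_consensus: np.ndarray
    significant: np.ndarray         # after joint FDR
    max_beta: float | None          # within significant free wall
    area_percent: float             # % of free-wall area significant
    n_subjects: int
    metadata: dict = dc_field(default_factory=dict)


def summarize_region(beta: np.ndarray, significant: np.ndarray,
                     free_wall_mask: np.ndarray,
                     vertex_areas: np.ndarray) -> tuple[float | None, float]:
    """(max |beta| signed, % free-wall area) within the significance mask."""
    sel = significant & free_wall_mask
    total = vertex_areas[free_wall_mask].sum()
    area_pct = 100.0 * vertex_areas[sel].sum() / total if total > 0 else 0.0
    if not np.any(sel):
        return None, 0.0
    b = beta[sel]
    return float(b[np.argmax(np.abs(b))]), float(area_pct)


def run_spm_model(Y: np.ndarray, table: pd.DataFrame, predictor: str,
                  mesh: SurfaceMesh, covariates: Sequence[str] = DEFAULT_COVARIATES,
                  n_parcellations: int = 50, K: int | None = None,
                  n_permutations: int = 1000, seed: int = 0,
                  adjacency: list[np.ndarray] | None = None,
                  model_id: str | None = None) -> SpmResult:
    """Fit one phenotype ~ predictor model: vertex betas + consensus p-values.

    FDR is NOT applied here; use :func:`run_spm_models` to correct a batch of
    models jointly (single models are corrected as a batch of one).
    """
    design = build_design(table, predictor, covariates)
    Yc = np.asarray(Y, dtype=np.float64)[design.rows]
    beta, _ = fit_vertexwise_glm(Yc, design)
    cons = permutation_consensus_test(Yc, design, mesh,
                                      n_parcellations=n_parcellations, K=K,
                                      n_permutations=n_permutations, seed=seed,
                                      adjacency=adjacency)
    return SpmResult(model_id=model_id or predictor, beta=beta,
                     p_consensus=cons["p_consensus"],
                     significant=np.zeros(len(beta), dtype=bool),
                     max_beta=None, area_percent=0.0,
                     n_subjects=design.n, metadata=cons)


def run_spm_models(results: list[SpmResult], free_wall_mask: np.ndarray,
                   vertex_areas: np.ndarray, q: float = 0.05) -> list[SpmResult]:
    """Joint BH correction across models, then per-model region summaries."""
    pooled = np.concatenate([r.p_consensus for r in results])
    reject = bh_fdr(pooled, q=q)
    start = 0
    for r in results:
        V = len(r.p_consensus)
        r.significant = reject[start:start + V]
        start += V
        r.max_beta, r.area_percent = summarize_region(
            r.beta, r.significant, free_wall_mask, vertex_areas)
    return results
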