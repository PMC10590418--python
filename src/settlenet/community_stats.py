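"""Ordination and multivariate statistics for community tables.

Implements the statistics layer the settlement analysis relies on:
compartment pooling (surface + crevice + bottom → one sample per
tetrapod), ln(x+1) transform, Bray-Curtis dissimilarity, nonmetric MDS
(Kruskal stress-1 minimised by SMACOF majorisation with isotonic
disparities), PERMANOVA with a permutation pseudo-F, and pairwise
PERMANOVA with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .io import CountTable, DataError, SampleMetadata


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise DataError(f"distance matrix shape {v.shape} != ({n},{n})")
        if not np.isfinite(v).all():
            raise DataError("non-finite dissimilarity")
        if not np.allclose(v, v.T):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise DataError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_among: int
    df_within: int
    R2: float
    p_perm: float
    n_permutations: int
    seed: int | None


# ---------------------------------------------------------------------------
# Pooling and transforms
# ---------------------------------------------------------------------------


def pool_compartments(table: CountTable, metadata: SampleMetadata
                      ) -> tuple[CountTable, SampleMetadata]:
    """Sum compartment samples (surface/crevice/bottom) into one sample per tetrapod.

    The pooled sample takes its tetrapod's id; pooled metadata keeps the
    tetrapod-level fields and sets compartment to "pooled".
    """
    meta = metadata.for_samples(table.sample_ids)
    if meta["tetrapod_id"].isna().any():
        bad = meta.loc[meta["tetrapod_id"].isna(), "sample_id"].tolist()
        raise DataError(f"compartment sample(s) mapped to no tetrapod: {bad}")
    pooled_cols = {}
    meta_rows = []
    for tet, grp in meta.groupby("tetrapod_id", sort=False):
        pooled_cols[str(tet)] = table.counts[grp["sample_id"]].sum(axis=1)
        first = grp.iloc[0]
        meta_rows.append({"sample_id": str(tet), "conditioning": first["conditioning"],
                          "time_months": first["time_months"], "tank_id": first["tank_id"],
                          "tetrapod_id": str(tet), "compartment": "pooled"})
    pooled = CountTable(pd.DataFrame(pooled_cols, index=table.asv_ids))
    return pooled, SampleMetadata(pd.DataFrame(meta_rows))


def log_transform(table: CountTable | pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise ln(x + 1)."""
    if isinstance(table, CountTable):
        return np.log1p(table.counts.astype(float))
    return np.log1p(np.asarray(table, dtype=float)) if isinstance(table, np.ndarray) \
        else np.log1p(table.astype(float))


def bray_curtis(matrix: pd.DataFrame | np.ndarray, sample_ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    d(x, y) = 1 - 2 * sum_i min(x_i, y_i) / sum_i (x_i + y_i).
    """
    if isinstance(matrix, pd.DataFrame):
        sample_ids = list(matrix.columns) if sample_ids is None else sample_ids
        mat = matrix.to_numpy(dtype=float)
    else:
        mat = np.asarray(matrix, dtype=float)
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(mat.shape[1])]
    if (mat < 0).any():
        raise DataError("Bray-Curtis requires non-negative abundances")
    zero = mat.sum(axis=0) == 0
    if zero.any():
        raise DataError(f"all-zero sample(s): {[sample_ids[i] for i in np.where(zero)[0]]}")
    d = squareform(pdist(mat.T, metric="braycurtis"))
    return DistanceMatrix(list(sample_ids), d)


# ---------------------------------------------------------------------------
# Nonmetric MDS
# ---------------------------------------------------------------------------


def _stress1(d: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(d ** 2))
    return float(np.sqrt(np.sum((d - disp) ** 2) / denom)) if denom > 0 else 0.0


def nmds(dist: DistanceMatrix, k: int = 2, n_restarts: int = 4, max_iter: int = 300,
         tol: float = 1e-7, seed: int | None = 0
         ) -> tuple[pd.DataFrame, float, list[float]]:
    """Nonmetric MDS by SMACOF with isotonic-regression disparities.

    Returns (coordinates DataFrame indexed by sample, Kruskal stress-1 of the
    best restart, per-iteration stress trace of that restart). Stress along
    the trace is non-increasing by construction: iteration stops as soon as
    the update fails to improve.
    """
    n = dist.n
    if n < k + 1:
        raise DataError(f"need at least k+1={k + 1} samples, got {n}")
    delta = squareform(dist.values, checks=False)
    if np.all(delta == 0):
        raise DataError("all dissimilarities are zero")
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)

    best = (np.inf, None, None)
    for restart in range(n_restarts):
        X = _init_config(dist.values, k, rng, classical=(restart == 0))
        trace: list[float] = []
        stress = np.inf
        X_at_stress = X
        for _ in range(max_iter):
            d = pdist(X)
            # monotone disparities in the rank order of the input dissimilarities
            disp = np.empty_like(d)
            disp[order] = isotonic_regression(d[order]).x
            # scale so that sum disp^2 = sum d^2 (Kruskal's normalisation)
            ss = np.sum(disp ** 2)
            if ss > 0:
                disp = disp * np.sqrt(np.sum(d ** 2) / ss)
            new_stress = _stress1(d, disp)
            if new_stress > stress - tol:
                break
            stress = new_stress
            trace.append(stress)
            X_at_stress = X
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, disp / d, 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio
            B.T[iu] = -ratio
            B[np.diag_indices(n)] = -B.sum(axis=1)
            X = B @ X / n
        if stress < best[0]:
            best = (stress, X_at_stress, trace)

    stress, X, trace = best
    coords = pd.DataFrame(X, index=dist.sample_ids,
                          columns=[f"nmds{i + 1}" for i in range(k)])
    return coords, float(stress), trace


def _init_config(dvals: np.ndarray, k: int, rng: np.random.Generator,
                 classical: bool) -> np.ndarray:
    n = dvals.shape[0]
    if classical:
        # classical (Torgerson) scaling start
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (dvals ** 2) @ J
        w, v = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:k]
        X = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
        if np.allclose(X, 0):
            X = rng.normal(size=(n, k))
        return X
    return rng.normal(size=(n, k))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _group_indicator(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, inv = np.unique(groups, return_inverse=True)
    return labels, inv


def permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = 0) -> PermanovaResult:
    """One-way PERMANOVA: permutation test of the pseudo-F statistic.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums within-group pairs
    scaled by group size; pseudo-F = (SS_among/(g-1)) / (SS_within/(n-g));
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1) over label permutations.
    """
    groups = np.asarray(groups)
    n = dist.n
    if len(groups) != n:
        raise DataError(f"{len(groups)} group labels for {n} samples")
    labels, inv = _group_indicator(groups)
    g = len(labels)
    if g < 2:
        raise DataError("need at least 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        small = [str(labels[i]) for i in np.where(sizes < 2)[0]]
        raise DataError(f"group(s) with fewer than 2 samples: {small}")

    d2 = dist.values ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for grp in range(g):
        mask = inv == grp
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(int(mask.sum()), 1)].sum() / mask.sum()
    ss_among = ss_total - ss_within
    F_obs = (ss_among / (g - 1)) / (ss_within / (n - g))
    R2 = ss_among / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    # vectorised permutation null: einsum over a batch of permuted indicators
    perms = np.empty((n_perm, n), dtype=np.int64)
    for b in range(n_perm):
        perms[b] = inv[rng.permutation(n)]
    ss_w_perm = np.zeros(n_perm)
    for grp in range(g):
        I = (perms == grp).astype(float)  # (n_perm, n)
        ss_w_perm += np.einsum("pn,nm,pm->p", I, d2, I) / (2.0 * sizes[grp])
    F_perm = ((ss_total - ss_w_perm) / (g - 1)) / (ss_w_perm / (n - g))
    p = (np.sum(F_perm >= F_obs - 1e-12) + 1) / (n_perm + 1)

    return PermanovaResult(float(F_obs), g - 1, n - g, float(R2), float(p),
                           n_perm, seed)


def pairwise_permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
                       seed: int | None = 0, correction: str = "bonferroni"
                       ) -> pd.DataFrame:
    """PERMANOVA for every group pair on its sub-matrix, Bonferroni-adjusted."""
    if correction not in ("bonferroni",):
        raise ValueError(f"unknown correction {correction!r}")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    rows = []
    for j, (a, b) in enumerate(pairs):
        mask = np.isin(groups, [a, b])
        ids = [s for s, m in zip(dist.sample_ids, mask) if m]
        sub = dist.submatrix(ids)
        res = permanova(sub, groups[mask], n_perm=n_perm,
                        seed=None if seed is None else seed + j)
        rows.append({"group_a": a, "group_b": b, "pseudo_F": res.pseudo_F,
                     "R2": res.R2, "p": res.p_perm,
                     "p_adjusted": min(1.0, res.p_perm * len(pairs))})
    return pd.DataFrame(rows)
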