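"""Population comparison statistics.

One-way ANOVA and Tukey's HSD over population hormone contents — accepting
either raw replicate values or published-style summaries (mean, SE, n),
which is how profile tables are usually reported — plus nonmetric
multidimensional scaling (nMDS) of Bray-Curtis dissimilarities between
population profiles, the standard ordination for abundance-like data.

Tukey's studentized-range adjustment is computed directly from
scipy.stats.studentized_range so that the summary-statistics path and the
raw path share one formula.  The nMDS solver is Kruskal's: minimize
stress-1 by SMACOF majorization with isotonic regression of embedded
distances on dissimilarity ranks, best of several seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import braycurtis, pdist, squareform

__all__ = [
    "GroupSummary",
    "TukeyResult",
    "OrdinationResult",
    "anova_oneway",
    "tukey_hsd",
    "bray_curtis",
    "nmds",
    "StatsError",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    """Published-style group summary: mean, standard error, replicate count."""

    name: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StatsError(f"{self.name}: summary mode needs n >= 2")
        if self.se < 0:
            raise StatsError(f"{self.name}: negative SE")

    @property
    def variance(self) -> float:
        # SE = sd/sqrt(n)  =>  sd^2 = n * SE^2
        return self.n * self.se**2


@dataclass
class TukeyResult:
    pair: tuple[str, str]
    mean_diff: float
    q: float
    p_adj: float
    significant: bool


@dataclass
class OrdinationResult:
    names: list[str]
    coordinates: np.ndarray  # (n, k)
    stress: float            # Kruskal stress-1
    seed: int
    n_restarts: int


def _group_stats(groups) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Normalize raw-vector or GroupSummary input to (names, means, vars, ns)."""
    names, means, variances, ns = [], [], [], []
    if isinstance(groups, dict):
        groups = [(k, v) for k, v in groups.items()]
    for i, g in enumerate(groups):
        if isinstance(g, GroupSummary):
            names.append(g.name)
            means.append(g.mean)
            variances.append(g.variance)
            ns.append(g.n)
        else:
            if isinstance(g, tuple) and len(g) == 2 and not np.isscalar(g[1]):
                name, vals = g
            else:
                name, vals = f"group{i + 1}", g
            vals = np.asarray(vals, dtype=float)
            if vals.size < 2:
                raise StatsError(f"{name}: need >= 2 replicates")
            names.append(str(name))
            means.append(float(vals.mean()))
            variances.append(float(vals.var(ddof=1)))
            ns.append(int(vals.size))
    if len(names) < 2:
        raise StatsError("need at least 2 groups")
    return names, np.asarray(means), np.asarray(variances), np.asarray(ns)


def anova_oneway(groups) -> tuple[float, tuple[int, int], float]:
    """Classic one-way F test; returns (F, (df_between, df_within), p).

    ``groups`` is a list of replicate vectors, (name, vector) pairs, or
    :class:`GroupSummary` objects; summaries reconstruct within-group sums
    of squares from the standard errors, which is algebraically identical
    to the raw computation.
    """
    names, means, variances, ns = _group_stats(groups)
    k = len(names)
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * variances).sum())
    dfb, dfw = k - 1, N - k
    if dfw <= 0:
        raise StatsError("no within-group degrees of freedom")
    if ssw == 0:
        if ssb == 0:
            return 0.0, (dfb, dfw), 1.0
        return float("inf"), (dfb, dfw), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return F, (dfb, dfw), p


def tukey_hsd(groups, alpha: float = 0.05) -> list[TukeyResult]:
    """All-pairs Tukey HSD with studentized-range adjusted p values.

    q_ij = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) (Tukey-Kramer for
    unequal n); p_adj = P(Q_{k,df} >= q).
    """
    names, means, variances, ns = _group_stats(groups)
    k = len(names)
    dfw = int(ns.sum()) - k
    msw = float(((ns - 1) * variances).sum()) / dfw
    out: list[TukeyResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(np.clip(stats.studentized_range.sf(q, k, dfw), 0.0, 1.0))
            out.append(TukeyResult(pair=(names[i], names[j]), mean_diff=diff,
                                   q=q, p_adj=p, significant=bool(p < alpha)))
    return out


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) on nonnegative profiles."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise StatsError("profiles must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise StatsError("Bray-Curtis requires nonnegative entries")
    if u.sum() + v.sum() == 0:
        raise StatsError("both profiles all-zero")
    return float(braycurtis(u, v))


def bray_curtis_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis matrix for rows of a nonnegative profile matrix."""
    profiles = np.asarray(profiles, dtype=float)
    if (profiles < 0).any():
        raise StatsError("Bray-Curtis requires nonnegative entries")
    return squareform(pdist(profiles, metric="braycurtis"))


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _stress1(d_emb: np.ndarray, d_hat: np.ndarray) -> float:
    denom = float((d_emb**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_emb - d_hat) ** 2).sum() / denom))


def _nmds_single(D: np.ndarray, k: int, X0: np.ndarray,
                 max_iter: int = 300, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """One SMACOF run with monotone (primary-ties) regression on ranks."""
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")  # primary tie treatment: stable order
    X = X0.copy()
    last = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        # isotonic fit of embedded distances against dissimilarity ranks
        fit = isotonic_regression(d[order]).x
        d_hat = np.empty_like(d)
        d_hat[order] = fit
        s = _stress1(d, d_hat)
        if last - s < tol:
            last = s
            break
        last = s
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, d_hat / d, 0.0)
        R = squareform(ratio)
        B = -R
        B[np.diag_indices(n)] = R.sum(axis=1)
        X = (B @ X) / n
    return X, last


def nmds(D: np.ndarray, k: int = 2, seed: int = 0, n_restarts: int = 8,
         names: list[str] | None = None) -> OrdinationResult:
    """Nonmetric MDS of a dissimilarity matrix, best of seeded restarts.

    The first start is classical (metric) scaling of D; the remaining
    restarts are random Gaussian configurations.  Stress is Kruskal's
    stress-1; it is non-increasing within each majorization run.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise StatsError("D must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise StatsError("D must have a zero diagonal")
    if names is not None and len(names) != n:
        raise StatsError("names length must match D")
    rng = np.random.default_rng(seed)
    starts = [_classical_mds(D, k)]
    scale = max(D.max(), 1e-12)
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.normal(0.0, scale, size=(n, k)))
    best_X, best_s = None, np.inf
    for X0 in starts:
        X, s = _nmds_single(D, k, X0)
        if s < best_s:
            best_X, best_s = X, s
    return OrdinationResult(
        names=list(names) if names is not None else [str(i) for i in range(n)],
        coordinates=best_X, stress=best_s, seed=seed, n_restarts=n_restarts,
    )
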