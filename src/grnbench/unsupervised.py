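"""Unsupervised network inference: every method maps an ExpressionMatrix to a
symmetric WeightMatrix obeying "larger weight = more confident edge".

Roster (see :data:`METHODS`): correlation flavors (pearson / spearman /
kendall), hub-corrected spearman, softpower post-transform, mutual-information
relevance networks with CLR background correction and ARACNE/DPI pruning,
partial-correlation pruning (PCIT), MRMR-based selection (MRNET, MRNET-B),
tree-ensemble importances (GENIE), a soft-threshold linear fit (SIGMOID),
mass-distance, mutual rank, normalized euclidean distance, and a generalized
knockout z-score.

Orientation conventions for distance-like scores: euclid weights are negated
distances, mutual-rank weights are reciprocal ranks, mass-distance weights are
negated log-mass (all monotone, so AUC is unaffected by the choice of
transform).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

from .netio import ExpressionMatrix, WeightMatrix

__all__ = [
    "MIMatrix",
    "MethodSpec",
    "METHODS",
    "correlation_weights",
    "spearman_c",
    "softpower",
    "discretize_equal_width",
    "mutual_info_matrix",
    "relevance_network",
    "clr",
    "aracne",
    "pcit",
    "mrmr_select",
    "mrnet",
    "mrnet_b",
    "genie",
    "sigmoid_fit",
    "mass_distance",
    "mass_distance_matrix",
    "mutual_rank",
    "euclid",
    "zscore_generalized",
    "infer",
    "default_bins",
]


@dataclass
class MIMatrix:
    """Symmetric matrix of pairwise mutual information (nats); the diagonal
    holds per-gene entropies."""

    gene_ids: list[str]
    mi: np.ndarray

    def __post_init__(self) -> None:
        self.mi = np.asarray(self.mi, dtype=float)
        n = len(self.gene_ids)
        if self.mi.shape != (n, n):
            raise ValueError("MI matrix shape mismatch")
        if not np.allclose(self.mi, self.mi.T, atol=1e-10):
            raise ValueError("MI matrix must be symmetric")
        if self.mi.min() < -1e-9:
            raise ValueError("mutual information must be nonnegative")


@dataclass
class MethodSpec:
    """Name + parameters of an unsupervised method, for the dispatcher."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in METHODS:
            raise ValueError(
                f"unknown method {self.name!r}; known: {sorted(METHODS)}")


def default_bins(n_samples: int) -> int:
    """Equal-width bin count used for MI estimation: ceil(sqrt(n))."""
    return max(2, math.ceil(math.sqrt(n_samples)))


# ---------------------------------------------------------------------------
# correlation family


def _signed_pearson(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix; pairs involving a constant gene get 0."""
    sd = values.std(axis=1)
    ok = sd > 0
    n = values.shape[0]
    corr = np.zeros((n, n))
    if ok.sum() >= 2:
        sub = np.corrcoef(values[ok])
        corr[np.ix_(ok, ok)] = sub
    corr[np.arange(n), np.arange(n)] = np.where(ok, 1.0, 0.0)
    return np.clip(corr, -1.0, 1.0)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.vstack([rankdata(row) for row in values])


def _signed_spearman(values: np.ndarray) -> np.ndarray:
    return _signed_pearson(_rank_rows(values))


def _kendall_tau_a(values: np.ndarray) -> np.ndarray:
    """Kendall tau-a matrix: (n_c - n_d) / (n(n-1)/2), computed from sign
    tensors so it matches the concordance-counting definition exactly."""
    N, n = values.shape
    S = np.sign(values[:, :, None] - values[:, None, :]).reshape(N, n * n)
    tau = (S @ S.T) / (n * (n - 1))
    return np.clip(tau, -1.0, 1.0)


def correlation_weights(X: ExpressionMatrix, flavor: str = "pearson") -> WeightMatrix:
    """|correlation| weights; flavor in {pearson, spearman, kendall}.

    Spearman is pearson on within-gene ranks; kendall is the concordance
    count normalized by n(n-1)/2 (tau-a). Pairs involving a constant gene
    score 0 rather than erroring.
    """
    if X.n_samples < 3:
        raise ValueError("correlation weights need n >= 3 samples")
    if flavor == "pearson":
        corr = _signed_pearson(X.values)
    elif flavor == "spearman":
        corr = _signed_spearman(X.values)
    elif flavor == "kendall":
        corr = _kendall_tau_a(X.values)
        sd = X.values.std(axis=1)
        corr[sd == 0, :] = 0.0
        corr[:, sd == 0] = 0.0
    else:
        raise ValueError(f"unknown correlation flavor {flavor!r}")
    w = np.abs(corr)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


def spearman_c(X: ExpressionMatrix) -> WeightMatrix:
    """Hub-corrected spearman: |rho_ij * mean_{k != i} rho_ik|, symmetrized
    by the maximum of the two orientations."""
    if X.n_samples < 3:
        raise ValueError("spearman_c needs n >= 3 samples")
    rho = _signed_spearman(X.values)
    n = rho.shape[0]
    # mean over k != i of rho_ik (diagonal rho_ii contributes 1, excluded)
    row_mean = (rho.sum(axis=1) - np.diag(rho)) / (n - 1)
    directed = np.abs(rho * row_mean[:, None])
    w = np.maximum(directed, directed.T)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


def softpower(w: WeightMatrix, beta: float) -> WeightMatrix:
    """Elementwise power transform w**beta; monotone, so AUC-invariant."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if w.weights.min() < 0 or w.weights.max() > 1:
        raise ValueError("softpower expects weights in [0, 1]")
    return WeightMatrix(list(w.gene_ids), np.power(w.weights, beta))


# ---------------------------------------------------------------------------
# mutual information family


def discretize_equal_width(X: ExpressionMatrix, bins: int) -> np.ndarray:
    """Per-gene equal-width binning of [min, max] into `bins` intervals.

    The maximum value is assigned to the top bin; constant genes map to all
    zeros.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    V = X.values
    lo = V.min(axis=1, keepdims=True)
    hi = V.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.floor((V - lo) / span * bins)
    D = np.where(span == 0, 0.0, D)
    return np.clip(D, 0, bins - 1).astype(np.int64)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_info_matrix(D: np.ndarray, gene_ids: list[str] | None = None) -> MIMatrix:
    """Empirical (maximum-likelihood) MI in nats from a discretized matrix.

    I(X;Y) = H(X) + H(Y) - H(X,Y); the diagonal is the per-gene entropy.
    """
    D = np.asarray(D, dtype=np.int64)
    N, n = D.shape
    bins = int(D.max()) + 1
    H = np.array([_entropy(np.bincount(D[i], minlength=bins)) for i in range(N)])
    mi = np.zeros((N, N))
    for i in range(N):
        mi[i, i] = H[i]
        for j in range(i + 1, N):
            joint = np.bincount(D[i] * bins + D[j], minlength=bins * bins)
            val = H[i] + H[j] - _entropy(joint)
            mi[i, j] = mi[j, i] = max(val, 0.0)
    ids = gene_ids if gene_ids is not None else [f"g{i}" for i in range(N)]
    return MIMatrix(list(ids), mi)


def _mi_from_expression(X: ExpressionMatrix, bins: int | None) -> MIMatrix:
    b = bins if bins is not None else default_bins(X.n_samples)
    return mutual_info_matrix(discretize_equal_width(X, b), list(X.gene_ids))


def relevance_network(X: ExpressionMatrix, bins: int | None = None) -> WeightMatrix:
    """Raw pairwise MI as interaction weights (diagonal zeroed)."""
    mim = _mi_from_expression(X, bins)
    w = mim.mi.copy()
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


def clr_weights_from_mi(mi: np.ndarray) -> np.ndarray:
    """CLR combination on a precomputed MI matrix (diagonal ignored)."""
    mi = mi.astype(float).copy()
    np.fill_diagonal(mi, np.nan)  # row stats exclude the diagonal
    mu = np.nanmean(mi, axis=1)
    sigma = np.nanstd(mi, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (mi - mu[:, None]) / sigma[:, None]
    z = np.where((sigma[:, None] == 0) | ~np.isfinite(z), 0.0, z)
    z = np.maximum(z, 0.0)
    w = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(w, 0.0)
    return w


def clr(X: ExpressionMatrix, bins: int | None = None) -> WeightMatrix:
    """Background-corrected MI: per-gene z-scores against the gene's own MI
    distribution, combined as sqrt(z_i^2 + z_j^2)."""
    if X.n_genes < 3:
        raise ValueError("clr needs N >= 3 genes")
    mim = _mi_from_expression(X, bins)
    return WeightMatrix(list(X.gene_ids), clr_weights_from_mi(mim.mi))


def aracne_prune_from_mi(mi: np.ndarray, eps: float) -> np.ndarray:
    """DPI pruning on a precomputed MI matrix: in every triple the strictly
    smallest MI is zeroed when it is below min(other two) - eps."""
    mi = mi.astype(float).copy()
    np.fill_diagonal(mi, 0.0)
    N = mi.shape[0]
    pruned = np.zeros((N, N), dtype=bool)
    for i in range(N):
        for j in range(i + 1, N):
            # prune if SOME third gene k forms a triangle in which {i,j} is
            # the strictly weakest link by more than eps
            others = np.minimum(mi[i], mi[j])
            others[i] = others[j] = -np.inf
            if N > 2 and mi[i, j] < others.max() - eps:
                pruned[i, j] = pruned[j, i] = True
    w = np.where(pruned, 0.0, mi)
    np.fill_diagonal(w, 0.0)
    return w


def aracne(X: ExpressionMatrix, bins: int | None = None, eps: float = 0.1) -> WeightMatrix:
    """MI weights with DPI pruning (tolerance eps, default 0.1)."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    mim = _mi_from_expression(X, bins)
    return WeightMatrix(list(X.gene_ids), aracne_prune_from_mi(mim.mi, eps))


# ---------------------------------------------------------------------------
# PCIT


def pcit(X: ExpressionMatrix) -> WeightMatrix:
    """DPI-style pruning on first-order partial correlations.

    For each triple (i, j, k) the partial r_ij.k = (r_ij - r_ik r_jk) /
    sqrt((1 - r_ik^2)(1 - r_jk^2)) is computed; the triple's tolerance is the
    mean ratio of partial to raw correlation over its three edges, and edge
    {i, j} is flagged when |r_ij| <= tol * |r_ik| and |r_ij| <= tol * |r_jk|
    for some k. Surviving edges are weighted |r_ij|; pairs with |r| = 1
    denominators are treated as degenerate-kept.
    """
    if X.n_genes < 3:
        raise ValueError("pcit needs N >= 3 genes")
    if X.n_samples < 4:
        raise ValueError("pcit needs n >= 4 samples")
    r = _signed_pearson(X.values)
    N = r.shape[0]
    keep = np.zeros((N, N), dtype=bool)
    flagged = np.zeros((N, N), dtype=bool)

    def partial(a: float, b: float, c: float) -> float:
        den = math.sqrt(max((1 - b * b) * (1 - c * c), 0.0))
        if den == 0:
            return math.nan  # degenerate: |r| = 1 somewhere
        return (a - b * c) / den

    for i in range(N):
        for j in range(i + 1, N):
            for k in range(N):
                if k == i or k == j:
                    continue
                rij, rik, rjk = r[i, j], r[i, k], r[j, k]
                p_ij = partial(rij, rik, rjk)
                p_ik = partial(rik, rij, rjk)
                p_jk = partial(rjk, rij, rik)
                if any(math.isnan(p) for p in (p_ij, p_ik, p_jk)):
                    continue  # degenerate triple: no pruning evidence
                ratios = []
                for p, raw in ((p_ij, rij), (p_ik, rik), (p_jk, rjk)):
                    if raw != 0:
                        ratios.append(abs(p / raw))
                if not ratios:
                    continue
                tol = float(np.mean(ratios))
                if abs(rij) <= tol * abs(rik) and abs(rij) <= tol * abs(rjk):
                    flagged[i, j] = flagged[j, i] = True
                else:
                    keep[i, j] = keep[j, i] = True
    w = np.where(flagged & ~keep, 0.0, np.abs(r))
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


# ---------------------------------------------------------------------------
# MRMR family


def mrmr_select(target: str, X: ExpressionMatrix, bins: int | None = None,
                max_regulators: int | None = None,
                _mi: np.ndarray | None = None) -> list[tuple[str, float]]:
    """Greedy forward MRMR selection of regulators for one target gene.

    Step score of candidate i: I(i, target) - mean_{k in S} I(i, k), where S
    is the already-selected set (the first pick is pure relevance). Returns
    (gene, step score) in selection order.
    """
    t = X.gene_index(target)
    mi = _mi_from_expression(X, bins).mi if _mi is None else _mi
    N = X.n_genes
    limit = N - 1 if max_regulators is None else min(max_regulators, N - 1)
    rel = mi[:, t].copy()
    selected: list[int] = []
    red_sum = np.zeros(N)
    out: list[tuple[str, float]] = []
    avail = np.ones(N, dtype=bool)
    avail[t] = False
    for _ in range(limit):
        red = red_sum / len(selected) if selected else 0.0
        score = np.where(avail, rel - red, -np.inf)
        pick = int(np.argmax(score))
        out.append((X.gene_ids[pick], float(score[pick])))
        avail[pick] = False
        selected.append(pick)
        red_sum += mi[:, pick]
    return out


def mrnet(X: ExpressionMatrix, bins: int | None = None) -> WeightMatrix:
    """MRMR forward selection with every gene as target; directional step
    scores combined by the maximum and clipped at 0."""
    mi = _mi_from_expression(X, bins).mi
    N = X.n_genes
    directed = np.zeros((N, N))  # directed[i, j]: score of i for target j
    for t, tg in enumerate(X.gene_ids):
        for g, s in mrmr_select(tg, X, _mi=mi):
            directed[X.gene_index(g), t] = s
    w = np.maximum(np.maximum(directed, directed.T), 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


def _set_score(rel: np.ndarray, mi: np.ndarray, members: list[int]) -> float:
    """Sum of relevance minus mean pairwise redundancy of a candidate set."""
    if not members:
        return 0.0
    s = float(rel[members].sum())
    if len(members) > 1:
        sub = mi[np.ix_(members, members)]
        n_pairs = len(members) * (len(members) - 1) / 2
        s -= float(np.triu(sub, 1).sum()) / n_pairs
    return s


def _backward_select(rel: np.ndarray, mi: np.ndarray, cand: list[int]) -> list[int]:
    members = list(cand)
    best = _set_score(rel, mi, members)
    # backward: drop while some removal improves the set score
    while len(members) > 1:
        scores = [_set_score(rel, mi, members[:m] + members[m + 1:])
                  for m in range(len(members))]
        m_best = int(np.argmax(scores))
        if scores[m_best] > best + 1e-12:
            best = scores[m_best]
            members.pop(m_best)
        else:
            break
    # sequential replacement: single swaps until no improvement
    outside = [c for c in cand if c not in members]
    improved = True
    while improved and outside:
        improved = False
        for m in range(len(members)):
            for o_idx, o in enumerate(outside):
                trial = members.copy()
                trial[m] = o
                s = _set_score(rel, mi, trial)
                if s > best + 1e-12:
                    outside[o_idx] = members[m]
                    members[m] = o
                    best = s
                    improved = True
    return members


def mrnet_b(X: ExpressionMatrix, bins: int | None = None) -> WeightMatrix:
    """MRNET with backward selection plus sequential replacement per target.

    Genes in the final subset are weighted by their MRMR-style step score
    within that subset; dropped genes score 0. Directions combined by max.
    """
    mi = _mi_from_expression(X, bins).mi
    N = X.n_genes
    directed = np.zeros((N, N))
    for t in range(N):
        cand = [i for i in range(N) if i != t]
        rel = mi[:, t]
        members = _backward_select(rel, mi, cand)
        for i in members:
            others = [k for k in members if k != i]
            red = float(mi[i, others].mean()) if others else 0.0
            directed[i, t] = rel[i] - red
    w = np.maximum(np.maximum(directed, directed.T), 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


# ---------------------------------------------------------------------------
# tree ensembles


def genie(X: ExpressionMatrix, n_trees: int = 100, seed: int = 0) -> WeightMatrix:
    """Per-target tree-ensemble regression; weight = max of the two
    directional importances. Importances per target sum to 1 (or are all 0
    for a constant target)."""
    if X.n_samples < 5:
        raise ValueError("genie needs n >= 5 samples")
    N = X.n_genes
    V = X.values
    directed = np.zeros((N, N))
    for t in range(N):
        y = V[t]
        if np.ptp(y) == 0:
            continue
        feats = np.delete(np.arange(N), t)
        model = RandomForestRegressor(
            n_estimators=n_trees, max_features="sqrt",
            random_state=seed * 100003 + t)
        model.fit(V[feats].T, y)
        imp = model.feature_importances_
        directed[feats, t] = imp
    w = np.maximum(directed, directed.T)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


# ---------------------------------------------------------------------------
# SIGMOID


def _sig(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def _scale01(values: np.ndarray) -> np.ndarray:
    """Min-max scale each profile into [0, 1]; profiles already inside
    [0, 1] are left unchanged so exactly-sigmoidal data stay exact."""
    out = values.copy()
    for i, row in enumerate(values):
        lo, hi = row.min(), row.max()
        if lo >= 0.0 and hi <= 1.0:
            continue
        out[i] = (row - lo) / (hi - lo) if hi > lo else 0.0
    return out


def sigmoid_fit_directed(X: ExpressionMatrix, max_iter: int = 5000,
                         tol: float = 1e-6) -> np.ndarray:
    """Directed soft-threshold fit: row i holds the weights of all genes in
    the reconstruction of profile i (diagonal fixed at 0)."""
    V = _scale01(X.values)
    N, n = V.shape
    W = np.zeros((N, N))
    lr = np.full(N, 1.0)
    active = np.ones(N, dtype=bool)

    def objective(Wm: np.ndarray) -> np.ndarray:
        P = _sig(Wm @ V)
        return ((P - V) ** 2).sum(axis=1)

    obj = objective(W)
    converged_all = False
    for _ in range(max_iter):
        P = _sig(W @ V)
        G = 2.0 * ((P - V) * P * (1.0 - P)) @ V.T
        np.fill_diagonal(G, 0.0)  # no self-regulation term
        W_try = W - lr[:, None] * G
        np.fill_diagonal(W_try, 0.0)
        obj_try = objective(W_try)
        better = obj_try <= obj
        step = better & active
        W[step] = W_try[step]
        small_change = np.abs(obj - obj_try) < tol * np.maximum(obj, 1e-12)
        obj = np.where(step, obj_try, obj)
        # halve the step on an objective increase, grow it mildly on success
        lr = np.where(better, np.minimum(lr * 1.2, 1e3), lr * 0.5)
        active &= ~(better & small_change)
        active &= lr > 1e-12
        if not active.any():
            converged_all = True
            break
    if not converged_all:
        warnings.warn("sigmoid_fit: gradient descent hit max_iter for some "
                      "genes; returning best iterate", RuntimeWarning)
    return W


def sigmoid_fit(X: ExpressionMatrix, max_iter: int = 5000,
                tol: float = 1e-6) -> WeightMatrix:
    """Fit each profile as a soft-thresholded linear mix of the others.

    Per gene i, minimize sum_k (sig(w_i . X_k) - X_ik)^2 by gradient descent
    (zero init, per-gene step halving on objective increase); the undirected
    weight is the mean of the two directional magnitudes.
    """
    W = sigmoid_fit_directed(X, max_iter, tol)
    w = (np.abs(W) + np.abs(W.T)) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


# ---------------------------------------------------------------------------
# distance-like scores


def mass_distance_matrix(X: ExpressionMatrix) -> np.ndarray:
    """Raw mass-distance md_ij = prod_k M_k(i, j), where M_k is the fraction
    of all genes' values at coordinate k lying in the closed interval bounded
    by X_ik and X_jk. Small md = similar profiles."""
    V = X.values
    N, n = V.shape
    log_md = np.zeros((N, N))
    for k in range(n):
        col = np.sort(V[:, k])
        lo = np.minimum(V[:, k][:, None], V[:, k][None, :])
        hi = np.maximum(V[:, k][:, None], V[:, k][None, :])
        # closed-interval counts via sorted column
        cnt = (np.searchsorted(col, hi.ravel(), side="right")
               - np.searchsorted(col, lo.ravel(), side="left")).reshape(N, N)
        log_md += np.log(cnt / N)
    return np.exp(log_md)


def mass_distance(X: ExpressionMatrix) -> WeightMatrix:
    """Mass-distance weights, oriented larger = stronger.

    The weight is -log(md_ij) (a monotone transform of the raw product, which
    underflows for long profiles); small bounded mass means similar profiles
    and therefore a large weight.
    """
    V = X.values
    N, n = V.shape
    log_md = np.zeros((N, N))
    for k in range(n):
        col = np.sort(V[:, k])
        lo = np.minimum(V[:, k][:, None], V[:, k][None, :])
        hi = np.maximum(V[:, k][:, None], V[:, k][None, :])
        cnt = (np.searchsorted(col, hi.ravel(), side="right")
               - np.searchsorted(col, lo.ravel(), side="left")).reshape(N, N)
        log_md += np.log(cnt / N)
    w = -log_md
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # symmetric up to float noise already
    return WeightMatrix(list(X.gene_ids), w)


def mutual_rank(X: ExpressionMatrix) -> WeightMatrix:
    """Geometric mean of the two per-row ranks of |pearson| (rank 1 =
    strongest, average ranks on ties), reported as 1/MR so larger = stronger."""
    if X.n_genes < 3:
        raise ValueError("mutual_rank needs N >= 3 genes")
    r = np.abs(_signed_pearson(X.values))
    N = r.shape[0]
    ranks = np.zeros((N, N))
    for i in range(N):
        row = np.delete(r[i], i)
        rk = rankdata(-row)  # descending: strongest correlate gets rank 1
        idx = np.delete(np.arange(N), i)
        ranks[i, idx] = rk
    mr = np.sqrt(ranks * ranks.T)
    with np.errstate(divide="ignore"):
        w = np.where(mr > 0, 1.0 / mr, 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


def euclid(X: ExpressionMatrix) -> WeightMatrix:
    """Negated euclidean distance between median-normalized profiles
    (X_hat_ik = |X_ik - median(X_i)|)."""
    V = X.values
    Xh = np.abs(V - np.median(V, axis=1, keepdims=True))
    sq = (Xh ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Xh @ Xh.T)
    d = np.sqrt(np.maximum(d2, 0.0))
    w = -(d + d.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


def zscore_generalized(X: ExpressionMatrix) -> WeightMatrix:
    """Generalized knockout z-score.

    The minimum of profile i marks the sample where gene i was presumably
    perturbed (first index on ties); z_ij measures how far gene j deviates
    from its mean in that sample, in units of its own sd (zero-variance
    profiles contribute 0). The weight is max(z_ij, z_ji).
    """
    if X.n_samples < 3:
        raise ValueError("zscore needs n >= 3 samples")
    V = X.values
    N = V.shape[0]
    kstar = np.argmin(V, axis=1)  # first index on ties (np.argmin contract)
    mean = V.mean(axis=1)
    sd = V.std(axis=1)
    at_kstar = V[:, kstar].T  # [i, j] = X_j at k*(i)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(at_kstar - mean[None, :]) / sd[None, :]
    z = np.where(sd[None, :] == 0, 0.0, z)
    w = np.maximum(z, z.T)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(list(X.gene_ids), w)


# ---------------------------------------------------------------------------
# dispatcher

METHODS: dict[str, dict] = {
    "pearson": {},
    "spearman": {},
    "kendall": {},
    "spearman_c": {},
    "rn": {"bins": None},
    "clr": {"bins": None},
    "aracne": {"bins": None, "eps": 0.1},
    "pcit": {},
    "mrnet": {"bins": None},
    "mrnet_b": {"bins": None},
    "genie": {"n_trees": 100, "seed": 0},
    "sigmoid": {"max_iter": 5000, "tol": 1e-6},
    "md": {},
    "mr": {},
    "euclid": {},
    "zscore": {},
}


def infer(method: MethodSpec | str, X: ExpressionMatrix) -> WeightMatrix:
    """Dispatch an unsupervised method by name with documented defaults."""
    if isinstance(method, str):
        method = MethodSpec(method)
    name, params = method.name, dict(method.params)
    defaults = dict(METHODS[name])
    unknown = set(params) - set(defaults)
    if name in ("pearson", "spearman", "kendall") and unknown:
        raise ValueError(f"{name} takes no parameters, got {sorted(unknown)}")
    if unknown and name not in ("pearson", "spearman", "kendall"):
        raise ValueError(f"unknown params for {name}: {sorted(unknown)}")
    defaults.update(params)
    p = defaults
    if name in ("pearson", "spearman", "kendall"):
        return correlation_weights(X, name)
    if name == "spearman_c":
        return spearman_c(X)
    if name == "rn":
        return relevance_network(X, p["bins"])
    if name == "clr":
        return clr(X, p["bins"])
    if name == "aracne":
        return aracne(X, p["bins"], p["eps"])
    if name == "pcit":
        return pcit(X)
    if name == "mrnet":
        return mrnet(X, p["bins"])
    if name == "mrnet_b":
        return mrnet_b(X, p["bins"])
    if name == "genie":
        return genie(X, p["n_trees"], p["seed"])
    if name == "sigmoid":
        return sigmoid_fit(X, p["max_iter"], p["tol"])
    if name == "md":
        return mass_distance(X)
    if name == "mr":
        return mutual_rank(X)
    if name == "euclid":
        return euclid(X)
    if name == "zscore":
        return zscore_generalized(X)
    raise ValueError(f"unknown method {name!r}")  # pragma: no cover
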