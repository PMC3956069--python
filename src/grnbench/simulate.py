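"""Steady-state expression simulator.

Lightweight stand-in for full kinetic simulators: signed source networks are
sampled by preferential attachment, subnetworks are extracted by greedy
neighborhood expansion, and expression is the fixed point of

    x_i = g(basal_i + sum_j strength_ji * sign_ji * x_j)

with g a saturating positive response, g(u) = u_max * u / (K + u) for u > 0
and a small leak otherwise. Perturbation designs:

* knockout   — each gene in turn clamped to 0 (one sample per gene);
* knockdown  — each gene in turn clamped to half its unperturbed steady level;
* multifactorial — a random subset of genes gets a basal-rate offset per
  sample.

Multiplicative lognormal measurement noise is applied to every entry. No
metadata about which gene was perturbed is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netio import ExpressionMatrix, SignedNetwork

__all__ = [
    "SimulatorParams",
    "ExperimentDesign",
    "generate_source_network",
    "sample_subnetwork",
    "steady_state",
    "simulate_experiments",
]

DESIGNS = ("knockout", "knockdown", "multifactorial")


@dataclass
class SimulatorParams:
    """Kinetic and noise parameters of the fixed-point simulator."""

    basal: float = 0.6
    strength_range: tuple[float, float] = (0.5, 1.0)
    steepness: float = 1.0
    u_max: float = 1.0
    K: float = 1.0
    hill: float = 1.0
    leak: float = 1e-3
    noise_sd: float = 0.02
    outlier_prob: float = 0.03
    outlier_sd: float = 0.6
    perturb_fraction: float = 0.2
    perturb_sd: float = 0.15
    max_iter: int = 1000
    tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.strength_range
        if not (self.basal > 0 and self.steepness > 0 and self.u_max > 0
                and self.K > 0 and 0 < lo <= hi):
            raise ValueError("basal, steepness, u_max, K and strength_range "
                             "must be positive")
        if self.noise_sd < 0 or self.perturb_sd < 0 or self.outlier_sd < 0:
            raise ValueError("noise_sd, perturb_sd and outlier_sd must be >= 0")
        if not (0 <= self.outlier_prob <= 1):
            raise ValueError("outlier_prob must be in [0, 1]")
        if not (0 < self.perturb_fraction <= 1):
            raise ValueError("perturb_fraction must be in (0, 1]")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid solver controls")


@dataclass
class ExperimentDesign:
    kind: str
    n_samples: int

    def __post_init__(self) -> None:
        if self.kind not in DESIGNS:
            raise ValueError(f"design kind must be one of {DESIGNS}, got {self.kind!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


# ---------------------------------------------------------------------------
# network generation


def generate_source_network(n_genes: int, mean_degree: float,
                            activating_fraction: float = 0.55,
                            seed: int = 0) -> SignedNetwork:
    """Sample a weakly connected, scale-free-leaning directed signed network.

    Preferential attachment: each new node links to an existing node chosen
    with probability proportional to degree + 1, then extra edges are added
    the same way until ``round(n_genes * mean_degree / 2)`` edges exist.
    Hubs are preferentially placed as regulators.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if mean_degree >= n_genes:
        raise ValueError(f"mean_degree ({mean_degree}) must be < n_genes ({n_genes})")
    if not (0 <= activating_fraction <= 1):
        raise ValueError("activating_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1}" for i in range(n_genes)]
    degree = np.zeros(n_genes)
    pairs: set[tuple[int, int]] = set()

    def add_edge(u: int, v: int) -> bool:
        if u == v or (u, v) in pairs or (v, u) in pairs:
            return False
        pairs.add((u, v))
        degree[u] += 1
        degree[v] += 1
        return True

    # growth phase: node t attaches to one earlier node (degree-proportional);
    # the higher-degree endpoint becomes the regulator, so hubs become TFs
    add_edge(0, 1)
    for t in range(2, n_genes):
        p = degree[:t] + 1.0
        other = int(rng.choice(t, p=p / p.sum()))
        if degree[other] >= 1 and rng.random() < 0.75:
            add_edge(other, t)
        else:
            add_edge(t, other)
    n_edges = max(n_genes - 1, int(round(n_genes * mean_degree / 2)))
    attempts = 0
    while len(pairs) < n_edges and attempts < 100 * n_edges:
        attempts += 1
        p = degree + 1.0
        u = int(rng.choice(n_genes, p=p / p.sum()))
        v = int(rng.integers(n_genes))
        add_edge(u, v)
    edges = set()
    for u, v in sorted(pairs):
        sign = +1 if rng.random() < activating_fraction else -1
        edges.add((gene_ids[u], gene_ids[v], sign))
    return SignedNetwork(gene_ids, edges)


def sample_subnetwork(source: SignedNetwork, n_nodes: int, seed: int = 0) -> SignedNetwork:
    """Greedy neighborhood expansion from a random seed node.

    Repeatedly adds the outside node with the most (undirected) links to the
    current node set, breaking ties by a seeded draw, then returns the induced
    signed subgraph.
    """
    if not (2 <= n_nodes <= source.n_genes):
        raise ValueError(f"n_nodes must be in [2, {source.n_genes}]")
    rng = np.random.default_rng(seed)
    ids = source.gene_ids
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for reg, tgt, _ in source.edges:
        if reg != tgt:
            adj[index[reg], index[tgt]] = True
            adj[index[tgt], index[reg]] = True
    chosen = np.zeros(n, dtype=bool)
    start = int(rng.integers(n))
    chosen[start] = True
    links = adj[start].astype(int).copy()
    while chosen.sum() < n_nodes:
        links_masked = np.where(chosen, -1, links)
        best = links_masked.max()
        if best <= 0:
            raise ValueError(
                "cannot grow subnetwork: no outside node is linked to the "
                "current set; use a source with a larger connected component")
        cands = np.flatnonzero(links_masked == best)
        pick = int(cands[rng.integers(len(cands))])
        chosen[pick] = True
        links = links + adj[pick].astype(int)
    keep = {ids[i] for i in np.flatnonzero(chosen)}
    sub_ids = [g for g in ids if g in keep]
    sub_edges = {(r, t, s) for r, t, s in source.edges if r in keep and t in keep}
    return SignedNetwork(sub_ids, sub_edges)


# ---------------------------------------------------------------------------
# steady state


def _interaction_matrix(net: SignedNetwork, params: SimulatorParams) -> np.ndarray:
    """Signed strength matrix A with A[j, i] = strength * sign of edge j->i.

    Strengths are part of the network model: sampled once, deterministically
    from params.seed and the (sorted) edge list, so every experiment on the
    same network sees the same kinetics.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xA11CE)))
    index = {g: i for i, g in enumerate(net.gene_ids)}
    n = net.n_genes
    A = np.zeros((n, n))
    lo, hi = params.strength_range
    for reg, tgt, sign in sorted(net.edges):
        A[index[reg], index[tgt]] = sign * rng.uniform(lo, hi)
    return A


def _g(u: np.ndarray, params: SimulatorParams) -> np.ndarray:
    """Saturating positive response; small leak for non-positive input.

    hill > 1 gives a cooperative, switch-like response around K, which makes
    regulator removal flip targets across most of the dynamic range (the
    regime where knockout designs are informative).
    """
    u = np.asarray(u, dtype=float)
    out = np.full_like(u, params.leak)
    pos = u > 0
    up = (u[pos] * params.steepness) ** params.hill
    out[pos] = params.u_max * up / (params.K ** params.hill + up)
    return out


def steady_state(net: SignedNetwork, params: SimulatorParams,
                 clamp: dict[str, float] | None = None,
                 basal_offsets: dict[str, float] | None = None,
                 _A: np.ndarray | None = None) -> np.ndarray:
    """Solve the fixed point x = g(basal + A^T x) with optional clamps.

    Clamped genes are held at their clamp level exactly. Damped iteration
    from x = basal; raises on non-convergence, reporting the residual.
    """
    if net.n_genes == 0:
        raise ValueError("empty network")
    index = {g: i for i, g in enumerate(net.gene_ids)}
    A = _interaction_matrix(net, params) if _A is None else _A
    n = net.n_genes
    basal = np.full(n, params.basal)
    if basal_offsets:
        for g, off in basal_offsets.items():
            basal[index[g]] += off
    clamp_idx = np.zeros(n, dtype=bool)
    clamp_val = np.zeros(n)
    if clamp:
        for g, level in clamp.items():
            clamp_idx[index[g]] = True
            clamp_val[index[g]] = level
    x = basal.copy()
    x[clamp_idx] = clamp_val[clamp_idx]
    for _ in range(params.max_iter):
        x_new = _g(basal + A.T @ x, params)
        x_new[clamp_idx] = clamp_val[clamp_idx]
        x_next = 0.5 * (x + x_new)  # damping guards against oscillation
        x_next[clamp_idx] = clamp_val[clamp_idx]
        resid = float(np.max(np.abs(x_next - x)))
        x = x_next
        if resid < params.tol:
            return x
    raise RuntimeError(f"steady state did not converge in {params.max_iter} "
                       f"iterations (residual {resid:.3g})")


def simulate_experiments(net: SignedNetwork, design: ExperimentDesign,
                         params: SimulatorParams) -> tuple[ExpressionMatrix, SignedNetwork]:
    """Simulate one expression matrix under the given design.

    Returns the (noisy) matrix and the ground-truth network. Column order for
    knockout/knockdown follows gene order (gene k perturbed in sample k);
    sample count equals n_genes for those designs.
    """
    n = net.n_genes
    if design.kind in ("knockout", "knockdown") and design.n_samples > n:
        raise ValueError(f"{design.kind} design needs n_samples <= {n}")
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xDA7A)))
    A = _interaction_matrix(net, params)
    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    if design.kind == "knockout":
        for k in range(design.n_samples):
            g = net.gene_ids[k]
            cols.append(steady_state(net, params, clamp={g: 0.0}, _A=A))
            sample_ids.append(f"ko_{g}")
    elif design.kind == "knockdown":
        base = steady_state(net, params, _A=A)
        for k in range(design.n_samples):
            g = net.gene_ids[k]
            cols.append(steady_state(net, params, clamp={g: base[k] / 2.0}, _A=A))
            sample_ids.append(f"kd_{g}")
    else:
        n_perturb = max(1, int(round(params.perturb_fraction * n)))
        for k in range(design.n_samples):
            which = rng.choice(n, size=n_perturb, replace=False)
            offsets = {net.gene_ids[i]: rng.normal(0.0, params.perturb_sd)
                       for i in which}
            cols.append(steady_state(net, params, basal_offsets=offsets, _A=A))
            sample_ids.append(f"mf_{k + 1}")
    values = np.column_stack(cols)
    if params.noise_sd > 0:
        values = values * rng.lognormal(0.0, params.noise_sd, size=values.shape)
    if params.outlier_prob > 0 and params.outlier_sd > 0:
        # heavy-tailed measurement component: occasional large multiplicative
        # deviations on a small fraction of entries
        mask = rng.random(values.shape) < params.outlier_prob
        values[mask] *= rng.lognormal(0.0, params.outlier_sd, size=int(mask.sum()))
    return ExpressionMatrix(list(net.gene_ids), sample_ids, values), net
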