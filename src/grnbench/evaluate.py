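"""Topology-agreement metrics and the benchmark harness.

AUC over the complete ranked list of unordered gene pairs is computed via the
Mann-Whitney / midrank formulation, which equals the trapezoidal area under
the ROC curve of the ranked list and handles ties robustly. F1 and Matthews
correlation are threshold-based companions.

The benchmark harness sweeps method x experiment design x network size x
sample number with seeded repeats, recording one row per cell per repeat.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .netio import UndirectedTruth, WeightMatrix, to_undirected_truth
from .simulate import (ExperimentDesign, SimulatorParams, generate_source_network,
                       sample_subnetwork, simulate_experiments)

__all__ = [
    "pair_auc",
    "auc",
    "f1_mcc",
    "max_f1_threshold",
    "BenchmarkConfig",
    "run_benchmark",
    "rank_methods",
]


def pair_auc(scores, labels) -> float:
    """Mann-Whitney AUC of scores against +/-1 (or bool) labels, midranks on
    ties. Requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == +1 if labels.dtype != bool else labels
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative pairs")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _pair_scores_labels(w: WeightMatrix, truth: UndirectedTruth):
    index = {g: i for i, g in enumerate(w.gene_ids)}
    unknown = set(truth.gene_ids) - set(w.gene_ids)
    if unknown:
        raise ValueError(f"truth genes absent from weight matrix: {unknown}")
    n = len(w.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    scores = w.weights[iu, ju]
    labels = np.zeros(len(iu), dtype=bool)
    for p in truth.pairs:
        a, b = tuple(p)
        i, j = sorted((index[a], index[b]))
        labels[(iu == i) & (ju == j)] = True
    return scores, labels


def auc(w: WeightMatrix, truth: UndirectedTruth) -> float:
    """AUC of the predicted weights over all unordered pairs (self-pairs and
    edge direction excluded by construction)."""
    scores, labels = _pair_scores_labels(w, truth)
    if labels.sum() == 0:
        raise ValueError("truth is empty: no positive pairs")
    if labels.all():
        raise ValueError("truth covers all pairs: no negative pairs")
    return pair_auc(scores, labels.astype(int) * 2 - 1)


def f1_mcc(w: WeightMatrix, truth: UndirectedTruth,
           threshold: float) -> tuple[float, float]:
    """F1 and Matthews correlation at weight >= threshold; zero-denominator
    cases return 0 by convention."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores, labels = _pair_scores_labels(w, truth)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(den) if den > 0 else 0.0
    return float(f1), float(mcc)


def max_f1_threshold(w: WeightMatrix, truth: UndirectedTruth) -> float:
    """Threshold (among observed weights) that maximizes F1."""
    scores, labels = _pair_scores_labels(w, truth)
    best_t, best_f1 = float(scores.max()), -1.0
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        if f1 > best_f1:
            best_f1, best_t = f1, float(t)
    return best_t


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass
class BenchmarkConfig:
    """Sweep definition: methods x designs x node sizes x sample sizes,
    with seeded repeats.

    `methods` entries are unsupervised MethodSpec / method-name strings, or
    supervised TrainConfig objects (optionally (name, TrainConfig) tuples).
    For knockout/knockdown designs the sample number is coupled to the node
    number and `sample_sizes` is ignored.
    """

    methods: list = field(default_factory=lambda: ["pearson"])
    designs: list[str] = field(default_factory=lambda: ["multifactorial"])
    node_sizes: list[int] = field(default_factory=lambda: [30])
    sample_sizes: list[int] = field(default_factory=lambda: [30])
    repeats: int = 1
    simulator: SimulatorParams = field(default_factory=SimulatorParams)
    seed: int = 0
    source_genes: int = 300
    source_mean_degree: float = 3.0
    source_activating_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (self.methods and self.designs and self.node_sizes
                and self.sample_sizes):
            raise ValueError("methods, designs, node_sizes and sample_sizes "
                             "must be nonempty")


def cell_seed(base_seed: int, *parts) -> int:
    """Stable per-cell seed: sha256 of the cell coordinates."""
    text = "|".join(str(p) for p in (base_seed,) + parts)
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big")


def _method_name(m) -> str:
    from .supervised import TrainConfig
    from .unsupervised import MethodSpec
    if isinstance(m, str):
        return m
    if isinstance(m, MethodSpec):
        return m.name
    if isinstance(m, tuple) and len(m) == 2:
        return str(m[0])
    if isinstance(m, TrainConfig):
        frac = int(round(m.label_fraction * 100))
        return {"full": "svm_full", "pos_neg": f"svm_{frac}pn",
                "pos_only": f"svm_{frac}p"}[m.label_mode]
    raise TypeError(f"unsupported method entry: {m!r}")


def run_benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Run the sweep; one row per (method, design, nodes, samples, repeat).

    Per-cell seeds are derived deterministically from cfg.seed so any cell is
    reproducible in isolation. A failing method is recorded with NaN metrics
    and the error message; the run continues.
    """
    from .supervised import TrainConfig, crossval_score
    from .unsupervised import MethodSpec, infer

    source = generate_source_network(cfg.source_genes, cfg.source_mean_degree,
                                     cfg.source_activating_fraction,
                                     seed=cfg.seed)
    rows = []
    for design_kind in cfg.designs:
        for n_nodes in cfg.node_sizes:
            sample_list = (cfg.sample_sizes
                           if design_kind == "multifactorial" else [n_nodes])
            for n_samples in sample_list:
                for rep in range(cfg.repeats):
                    net_seed = cell_seed(cfg.seed, "net", design_kind,
                                         n_nodes, n_samples, rep)
                    net = sample_subnetwork(source, n_nodes, seed=net_seed)
                    truth = to_undirected_truth(net)
                    sim = SimulatorParams(**{**cfg.simulator.__dict__,
                                             "seed": net_seed})
                    design = ExperimentDesign(design_kind, n_samples)
                    X, _ = simulate_experiments(net, design, sim)
                    for m in cfg.methods:
                        name = _method_name(m)
                        row = {"method": name, "design": design_kind,
                               "n_nodes": n_nodes, "n_samples": X.n_samples,
                               "repeat": rep, "auc": np.nan, "f1": np.nan,
                               "mcc": np.nan, "error": ""}
                        try:
                            row.update(_score_method(m, X, truth, cfg, rep))
                        except Exception as exc:  # record-and-continue policy
                            row["error"] = f"{type(exc).__name__}: {exc}"
                        rows.append(row)
    return pd.DataFrame(rows)


def _score_method(m, X, truth, cfg, rep) -> dict:
    from .supervised import TrainConfig, crossval_score
    from .unsupervised import MethodSpec, infer

    entry = m[1] if isinstance(m, tuple) else m
    if isinstance(entry, TrainConfig):
        run_cfg = TrainConfig(entry.C_grid, entry.folds, entry.label_fraction,
                              entry.label_mode,
                              cell_seed(cfg.seed, "cv", _method_name(m), rep),
                              entry.standardize)
        w, mean_auc, _ = crossval_score(X, truth, run_cfg)
        auc_val = auc(w, truth)  # AUC of the assembled out-of-fold weights
    else:
        spec = MethodSpec(entry) if isinstance(entry, str) else entry
        if spec.name == "genie" and "seed" not in spec.params:
            spec = MethodSpec(spec.name, {**spec.params,
                                          "seed": cell_seed(cfg.seed, "genie", rep)})
        w = infer(spec, X)
        auc_val = auc(w, truth)
    t = max_f1_threshold(w, truth)
    f1, mcc = f1_mcc(w, truth, t)
    return {"auc": auc_val, "f1": f1, "mcc": mcc}


def rank_methods(res: pd.DataFrame, group_by: list[str] | None = None) -> pd.DataFrame:
    """Mean/sd AUC and rank per method within each group (rank 1 = best mean
    AUC; ties broken stably by method name)."""
    if res.empty:
        raise ValueError("empty benchmark result")
    keys = list(group_by or [])
    g = res.groupby(keys + ["method"], dropna=False)["auc"]
    out = g.agg(mean_auc="mean", sd_auc="std", n="count").reset_index()
    out["sd_auc"] = out["sd_auc"].fillna(0.0)
    out = out.sort_values(keys + ["mean_auc", "method"],
                          ascending=[True] * len(keys) + [False, True],
                          kind="mergesort")
    if keys:
        out["rank"] = out.groupby(keys).cumcount() + 1
    else:
        out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
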