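# grnbench

Gene regulatory network (GRN) inference toolkit: sixteen unsupervised
co-expression / information-theoretic scoring methods, a supervised and
semi-supervised gene-pair classifier, an AUC-based topology evaluation
protocol, and a lightweight steady-state expression simulator so the whole
benchmark (method × experiment design × network size × sample number) runs
end-to-end with no external data.

## What's inside

| Module | Contents |
|---|---|
| `grnbench.netio` | TSV readers/writers for expression matrices, signed edge lists, gold standards and ranked predictions; the core domain types (`ExpressionMatrix`, `SignedNetwork`, `UndirectedTruth`, `WeightMatrix`) |
| `grnbench.simulate` | Preferential-attachment source networks, greedy subnetwork extraction, saturating fixed-point steady states, knockout / knockdown / multifactorial designs with lognormal + heavy-tail measurement noise |
| `grnbench.unsupervised` | `pearson`, `spearman`, `kendall`, `spearman_c`, softpower post-transform, `rn` (mutual information), `clr`, `aracne`, `pcit`, `mrnet`, `mrnet_b`, `genie`, `sigmoid`, `md` (mass-distance), `mr` (mutual rank), `euclid`, `zscore` — all behind one `infer(method, X)` dispatcher |
| `grnbench.supervised` | Symmetrized outer-product pair features, linear max-margin training with C grid search, positives-only / partial-label relabeling, 5-fold cross-validated whole-network scoring |
| `grnbench.evaluate` | Midrank (Mann–Whitney) AUC over the complete ranked pair list, F1 / Matthews correlation, benchmark sweep harness with per-cell deterministic seeding |

Every method returns a symmetric `WeightMatrix` obeying "larger weight =
more confident edge"; distance-like scores are orientation-normalized
(negated or reciprocal), which leaves AUC untouched.

## CLI

```bash
# simulate a 30-node knockout benchmark instance
grnbench simulate --nodes 30 --design knockout --seed 1 --out-prefix demo

# run an unsupervised method, write a DREAM-style ranked edge list
grnbench infer --method clr --expr demo_expression.tsv --out demo_pred.tsv

# score a prediction against the gold standard
grnbench evaluate --pred demo_pred.tsv --truth demo_network.tsv

# cross-validated (semi-)supervised scoring
grnbench supervised --expr demo_expression.tsv --truth demo_network.tsv \
    --label-fraction 0.1 --label-mode pos_only --seed 1 --out demo_svm.tsv

# full sweep from a JSON config (see BenchmarkConfig fields)
grnbench bench --config bench.json --out-dir bench_out
```

`bench.json` mirrors `BenchmarkConfig`, e.g.

```json
{"methods": ["pearson", "zscore", {"kind": "supervised", "label_fraction": 0.1,
             "label_mode": "pos_only"}],
 "designs": ["knockout", "multifactorial"],
 "node_sizes": [10, 30], "sample_sizes": [30], "repeats": 10, "seed": 1}
```

## Notes on conventions

* AUC uses the midrank / Mann–Whitney formulation (tie-robust, identical to
  the trapezoidal area over the ranked list); an AUC of 0.5 is random, 1.0
  perfect. Direction and self-interactions are ignored throughout.
* Mutual information uses per-gene equal-width binning with
  `ceil(sqrt(n))` bins and the empirical (plug-in) estimator, in nats.
* ARACNE's DPI tolerance defaults to `eps = 0.1`; PCIT uses the
  mean-ratio-of-partials tolerance test on first-order partial correlations.
* Constant genes score 0 with every correlation-type method rather than
  raising mid-benchmark.
* The simulator is a qualitative stand-in: a damped fixed-point of a
  saturating response `g(u) = u_max·u/(K+u)` with clamp-based knockouts
  (`x = 0`), knockdowns (half the unperturbed steady level) and
  basal-offset multifactorial perturbations. No bit-compatibility with any
  published simulator is attempted.
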