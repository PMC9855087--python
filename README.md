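# circuitrank

Rank known drug-target (KDT) genes by their regulatory relevance over a
mechanistic map of signaling circuits.

The pipeline:

1. **Circuit activities** — gene expression is quantile-truncated and
   min–max normalized per gene, then propagated through each
   receptor→effector circuit DAG (probabilistic OR over activating parents,
   AND-NOT over inhibiting parents). One activity column per circuit forms
   the multi-output response `Y`.
2. **Relevance model** — a multi-output random forest maps the KDT
   expression columns `X` to `Y`; per-circuit predictability is scored with
   out-of-fold cross-validated R².
3. **Shapley ranking** — per-gene, per-circuit relevance is the mean
   absolute interventional Shapley contribution across samples, computed
   *exactly* for tree ensembles by an internal leaf-path algorithm (no
   sampling; local accuracy holds to float precision). A global score (mean
   over circuits) yields the per-KDT ranking.
4. **R²-gated selection** — for each circuit, the selected fraction of the
   ranking interpolates convexly with R²: the top 5% at R² = 1, shrinking
   linearly to nothing as predictability drops.
5. **Stability** — the selection procedure is refit on seeded subsamples;
   the binary selection matrix is scored with the variance-based stability
   estimate Φ̂ (1 = identical selections, ≈0 = random), a percentile
   bootstrap 95% CI, and an effect size against a matched random-selection
   null.

A synthetic-data generator plants driver KDTs inside circuit nodes (decoys
and background genes stay outside every circuit), so driver recovery
end-to-end is a genuine test of the model. A small `dose` utility computes
per-fatty-acid daily doses from an oil-supplement composition table and a
gavage dose rate (bundled batch table included).

## CLI

```bash
# end-to-end run from a config file (writes activities, relevance, R²,
# selection, stability and a reproducibility manifest)
circuitrank run --config configs/quickstart.yaml --outdir out/

# individual stages
circuitrank simulate --outdir data/ --seed 1 --n-kdts 20 --n-drivers 4
circuitrank activities --expression data/expression.tsv --pathways data/pathways.json --out acts.tsv
circuitrank relevance --expression data/expression.tsv --pathways data/pathways.json \
    --kdt-list data/kdt_list.txt --outdir rel/
circuitrank select --relevance-tsv rel/relevance.tsv --r2-tsv rel/r2.tsv --out selection.tsv
circuitrank stability --config configs/quickstart.yaml --outdir stab/ -m 30

# dose table for the bundled supplement batch at 2.82 mg oil per g bw
circuitrank dose
```

Pathway collections use a small JSON schema (see
`circuitrank.graphio`); single circuits can be imported from SIF plus a
sidecar receptor/effector table. Expression TSVs are genes × samples with a
header row of sample ids.

## Reproducibility

Every stochastic stage is seeded from a single top-level seed via
counter-based derivation; `manifest.json` records the config snapshot,
per-stage seeds, output SHA-256 digests and timings. Re-running a config
reproduces byte-identical TSV/JSON outputs.
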