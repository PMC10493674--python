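# braincomm

Integrated ligand–receptor cell–cell communication analysis for brain
single-cell and single-nucleus RNA-seq data, with condition-specific
communication calling, rank-based edge-perturbation subtyping of disease
samples, and a communication-gene disease classifier.

## The problem

Glia–neuron signaling runs through ligand–receptor (LR) interactions: a
*sender* cell type expresses a ligand, a *receiver* cell type expresses the
matching receptor (possibly a multi-subunit complex such as
`BMPR1A+ACVR2A`). Published scoring tools disagree on how strongly any given
(pair, sender, receiver) triple communicates, so this package scores every
triple with four complementary schemes and integrates them into a single
**ISIscore**:

- **hill** — mass-action with half-saturation on Tukey trimeans:
  `s = l·r / (0.5 + l·r)`
- **regularized** — `s = √(l·r) / (μ + √(l·r))` with `μ` the global mean of
  the normalized matrix
- **product** — product of per-gene expression min–max scaled to `[0, 10]`
  across cell types
- **gated** — product of means, reported only when ligand and receptor pass
  a detection (≥10%) and type-enrichment gate

Per sub-dataset (the cells sharing one combination of disease / sex / brain
region), each method's scores are min–max normalized to `[0, 1]`, absent
entries are imputed as 0, and

```
ISIscore = (hill + regularized + product + gated) / 4 ∈ [0, 1].
```

Downstream, a (pair, sender, receiver) triple is called **condition-specific**
when a two-sided Wilcoxon rank-sum test between condition groups gives
`p < 0.05` *and* `|log2((mean_A + ε)/(mean_B + ε))| > 3` (ε = 10⁻³). Disease
samples are subtyped from a perturbation matrix of per-sample
`rank(ligand) − rank(receptor)` deviations from a normal reference, clustered
by subsampled PAM consensus clustering with CDF delta-area selection of K.
A gradient-boosted classifier on the specific-communication genes closes the
pipeline.

Everything is exercised on synthetic data with known ground truth
(`braincomm.simulate`), so every stage is testable without downloading any
cohort.

## Worked example

Plant one AD-induced microglia→neurons signal at fold 8, simulate five AD and
five normal sub-datasets, and call AD-specific communications:

```python
from braincomm import LRPair, differential, preprocess, simulate
from braincomm.workflow import integrate_subdatasets, partition_subdatasets

planted = (simulate.PlantedPair("G0001", "G0002", "microglia", "neurons",
                                "AD", signal_fold=8.0),)
cfg = simulate.SimConfig(seed=0, n_cells_per_type=40, planted_pairs=planted)
conditions = ([{"sample": f"AD{i}", "disease": "AD"} for i in range(5)]
              + [{"sample": f"N{i}", "disease": "normal"} for i in range(5)])

adata = simulate.simulate_sc(cfg, conditions)
adata = preprocess.filter_cells(adata)        # drop cells with >20% mito counts
adata = preprocess.normalize_log(adata)       # log-normalize to 10,000 per cell
adata.obs["cell_type"] = adata.obs["true_cell_type"]

pairs = [LRPair(("G0001",), ("G0002",)), LRPair(("G0011",), ("G0012",))]
subs = partition_subdatasets(adata, by=["sample", "disease"])
tables = integrate_subdatasets(subs, pairs)
ad = [t for t in tables if t.labels["disease"] == "AD"]
nl = [t for t in tables if t.labels["disease"] == "normal"]
calls = differential.call_specific(differential.compare_conditions(ad, nl))
print(calls.sort_values("log2_ratio", ascending=False).head(4).to_string())
```

Top of the output (72 triples tested):

```
    pair_id    sender          receiver  mean_a  mean_b      p  log2_ratio         call
G0001_G0002 microglia           neurons  0.8406  0.0000 0.0079      9.7169   A-specific
G0001_G0002 microglia endothelial cells  0.4715  0.0649 0.0079      2.8412 not-specific
G0001_G0002 microglia         microglia  0.4444  0.0625 0.0079      2.8091 not-specific
G0001_G0002 microglia               OPC  0.4731  0.0673 0.0079      2.7944 not-specific
```

The planted microglia→neurons key is recovered with mean ISIscore 0.84 in AD
versus 0.00 in normal (log2 ratio 9.7, Wilcoxon exact p = 2/252); the same
pair on unplanted receiver types shows elevated but sub-threshold ratios and
is correctly left uncalled.

A `braincomm` CLI wraps the stages (`simulate-sc`, `preprocess`, `integrate`,
`diff`, `subtype`, `predict`, `run`); `braincomm run --config demo.yaml`
executes the whole pipeline from a flat YAML file and writes a manifest of
every artifact and seed.

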