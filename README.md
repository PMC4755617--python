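# edi — ecosystem diversity index for tumor microenvironments

Solid tumors are ecosystems: cancer cells, lymphocytes and stromal cells
coexist with very different degrees of spatial intermixing from one tumor
to the next.  This package quantifies that *microenvironmental
heterogeneity* from classified cell positions in histology sections (the
output of any H&E cell-classification pipeline), for pathologists and
computational biologists studying how spatial tissue organisation relates
to outcome and genomics.

## The index

1. **Tile.** Each section is divided into square regions of side
   r = 200 μm (configurable).
2. **Score.** Each region j with enough cells gets a Shannon diversity
   score of its cell-type proportions, `d_j = −Σ_i p_i ln p_i`, ranging
   from 0 (one class) to ln 3 (equal thirds of 3 classes).
3. **Cluster.** The tumor's pooled scores D = (d_1..d_n) are fitted with
   univariate Gaussian mixtures `D ~ Σ_k ω_k N(μ_k, σ_k²)` for
   K = 1..5, and `BIC(K) = −2 log L + (3K−1) ln n` selects K.

The selected K is the **EDI**: the number of distinct diversity levels
coexisting in the tumor.  EDI = 5 defines the "EDI-high" subtype.
Companion modules cover region-size scans, bootstrap clustering
instability, subtyping stability under region subsampling, Kaplan–Meier /
log-rank / Cox survival stratification (including the combined EDI + TP53
three-level index), Fisher's-exact copy-number enrichment, an expression
screen with tail-area q-values, and synthetic-data generators with known
ground truth.  See `docs/methods.md` for the full model description.

## Worked example

Simulate a three-habitat tumor (ground truth: three diversity levels) and
score it:

```sh
edi simulate tumor --k 3 --seed 42 --out tumor_k3.csv
edi score --cells tumor_k3.csv --seed 42 --out demo
# EDI = 3 (180 regions)
```

`demo.json` then contains (abridged):

```json
{
  "edi": 3,
  "bic_table": {
    "1": 168.79112319913978,
    "2": -62.2930114097422,
    "3": -263.1707015330968,
    "4": -248.8875189114173,
    "5": -245.4898705890966
  },
  "qq_correlation": 0.9999180397744393,
  "n_regions": 180
}
```

BIC is minimised at K = 3, so the tumor scores EDI = 3 — the three
habitat diversity levels are recovered.  The fitted component means
(0.144, 0.610, 1.059 nats) sit on the generator's target Shannon levels,
and the Q-Q correlation near 1 says the mixture fits the score
distribution well.  `demo_regions.csv` maps every region back to space
with its cluster label (cluster 0 = lowest diversity).  The same
analyses are available from Python:

```python
import edi
cm, truth = edi.simulate_cellmap(edi.mosaic_spec(3), seed=42)
res = edi.compute_edi(cm, random_state=42)   # res.edi == 3
```

Other subcommands: `edi scan` (region-size sweep), `edi stability`
(subtype agreement under region loss), `edi survive` (Cox/log-rank on a
cohort CSV), `edi enrich` (copy-number enrichment), `edi simulate cohort`.

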