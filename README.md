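# thermonorm

Reaction-norm analysis of gene-expression plasticity across developmental
temperatures, for transcriptomics researchers working with multi-condition
bulk RNA-seq count data.

## The problem

When genetically identical individuals develop at different temperatures,
most genes change expression — each gene traces a *reaction norm*, a curve
of expression against temperature. `thermonorm` takes a gene × library
count matrix measured at several temperatures (e.g. 13, 18, 23 and 29 °C
with replicated libraries) and characterizes three components of each
gene's plasticity:

1. **Dynamics** — the *sum of change* (SOC), the accumulated magnitude of
   expression change along the gradient:
   `SOC = Σᵢ |log₂ E(Tᵢ₊₁) − log₂ E(Tᵢ)|` over consecutive temperatures no
   more than 6 °C apart;
2. **Direction** — whether expression increases or decreases with
   temperature, or follows a U-shaped / bell-shaped curve with its extremum
   inside the temperature range;
3. **Curvature** — whether the reaction norm is linear,
   `e = E_a + g₁(t − T_a)`, or quadratic, `e = E_m + g₂(t − T_m)²`, with
   optimum temperature `T_m = −b₁/(2b₂)`.

Counts are TMM-normalized (trimmed mean of M-values; effective library
size = total count × scaling factor enters the GLM as an offset), each
gene is fit with a negative-binomial GLM (log link, variance μ + φμ²)
treating temperature as a continuous covariate, and nested designs
{1} ⊂ {1, T} ⊂ {1, T, T²} are compared by likelihood-ratio tests with
Benjamini–Hochberg FDR control. A gene is *differential* when its
temperature term is significant (FDR ≤ 0.05) **and** its max/min fitted
expression ratio exceeds 1.25; all others are *conserved*.

Downstream, plasticity is linked to the gene's regulatory architecture
(number of distinct TFs and microRNAs with verified interactions, 5′/3′-UTR
lengths, first-intron length) through a Gaussian GLM of SOC^(1/4) with a
deviance-R² decomposition, linear discriminant analysis and a random
forest on a 60/40 train/holdout split, and each plasticity class is tested
for GO over-representation (hypergeometric against the expressed
background; minimum-hypergeometric with permutation p-values for ranked
analyses).

Because real multi-temperature data sets require a cluster-scale alignment
pipeline, the package ships a first-class synthetic-data generator
(`thermonorm.simulate`) that draws NB counts with known reaction-norm
structure and a matched architecture table, so every stage is verifiable
against recorded ground truth.

## Worked example

```python
import thermonorm as tn
from thermonorm.classify import build_profiles, tabulate_classes

cfg = tn.SimulationConfig(n_genes=2000, seed=0)       # 4 temps × 6 replicates
matrix, truth = tn.simulate_counts(cfg)

matrix, report = tn.filter_expressed(matrix)           # ≥1 read everywhere, ≥20 somewhere
norm = tn.tmm_factors(matrix)
model = tn.ReactionNormModel(alpha=0.05, min_fold=1.25).fit(matrix, norm)

cpm = matrix.counts / norm.effective_library_sizes.to_numpy() * 1e6
profiles = build_profiles(model.results_, cpm, matrix.temperatures)
print(tabulate_classes(profiles))
```

Output:

```
1970/2000 genes expressed
1650 differential genes (83.8%)
{"conserved": 320, "U": 166, "bell": 142,
 "increasing": {"linear": 284, "quadratic": 383, "total": 667},
 "decreasing": {"linear": 382, "quadratic": 293, "total": 675}, "total": 1970}
```

1,970 of 2,000 simulated genes pass the expressed-gene filter; 83.8% of
them are plastic. The class table partitions every gene by direction and
curvature. Linking plasticity to the (simulated) regulatory architecture:

```python
arch = tn.simulate_architecture(truth.loc[matrix.gene_ids], seed=1)
link = tn.link_architecture(profiles, arch, seed=2)
print(link.soc_model.summary.round(4))
```

```
             coefficient  p_value  r2_share
const             1.3390      0.0       NaN
n_tfs            -0.0149      0.0    0.1157
n_mirnas          0.0160      0.0    0.0996
...
direction LDA accuracy 0.797 (baseline 0.492), RF 0.840
```

The TF coefficient is negative (genes bound by more TFs change less) and
the microRNA coefficient positive, the couplings the generator embeds;
the direction of change is predictable from the five architecture
covariates well above the majority-class baseline.

The same pipeline is available from the shell:

```sh
thermonorm simulate --n-genes 2000 --seed 0 --out-dir synthetic
thermonorm run-all --config config.yaml
```

with subcommands `simulate`, `validate`, `normalize`, `fit`, `classify`,
`link`, `enrich` and `run-all` (YAML config, per-stage TSV/JSON outputs,
all seeds recorded in the run report).

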