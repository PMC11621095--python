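# fcnet

Graph-theoretic analysis of resting-state functional brain connectomes,
built for case-control studies such as comparing patients with anterior
ischemic optic neuropathy (AION) against healthy controls. The package
takes per-subject region-of-interest (ROI) BOLD time series (90 regions of
the AAL atlas), and carries them through ROI-level denoising, functional
network construction, small-world/efficiency graph analysis across a
sparsity sweep, covariate-adjusted group inference on metric AUCs, and
network-based statistics (NBS) on individual connections. A synthetic
cohort generator with injectable patient effects stands in for clinical
data, so every stage can be validated end to end.

## The analysis

For each subject the pairwise Pearson correlations between the 90 regional
mean time series form a 90 x 90 matrix, Fisher r-to-z transformed. At each
sparsity *S* in 0.032, 0.042, ..., 0.492 (47 levels) the k = round(S x 4005)
strongest connections are kept as the edges of a binary undirected network,
so all subjects are compared at equal edge count. Per network the pipeline
computes:

* global metrics — clustering coefficient Cp, characteristic path length
  Lp, global and local efficiency E_glob/E_loc, and the small-world ratios
  gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda against
  degree-matched Maslov-Sneppen random networks;
* nodal metrics — degree, nodal efficiency, betweenness, and nodal local
  efficiency.

Each metric curve is summarised by its area under the curve (AUC) over the
sweep, and AUCs are compared between groups with an ordinary-least-squares
GLM (group indicator + age, sex, education, mean framewise displacement),
uncorrected at p < 0.05 for the global metrics and Bonferroni-corrected
over the 90 nodes for the nodal metrics. Edge-level group differences are
assessed with NBS: edge-wise GLM t maps, a primary threshold (edge-level
p < 0.01), connected-component extraction, and family-wise-corrected
p-values from the max-component-size permutation distribution.

## Worked example

```python
import fcnet
from fcnet.pipeline import RunConfig, analyze_cohort
from fcnet import stats as S

cfg = RunConfig(seed=42, cohort=dict(n_patients=15, n_controls=12), n_nulls=20)
analysis = analyze_cohort(cfg)          # simulate -> denoise -> networks -> AUCs
for r in S.test_global(analysis.auc_table, analysis.design):
    print(f"{r.metric_name:7s} t = {r.t_value:6.2f}  p = {r.p_value:.4f}")
```

prints (seed 42):

```
Cp      t =  -5.33  p = 0.0000
Lp      t =  -3.91  p = 0.0008
Eglob   t =   6.43  p = 0.0000
Eloc    t =  -4.43  p = 0.0002
gamma   t =  -1.51  p = 0.1467
lambda  t =  -6.05  p = 0.0000
sigma   t =  -0.90  p = 0.3781
```

The synthetic patient group is generated with reduced within-module
coupling, so its thresholded networks are noisier and less locally
clustered: the clustering coefficient and local efficiency AUCs come out
significantly lower in patients (negative t for the patient-vs-control
contrast). The same randomization makes the patient networks slightly
*more* integrated (shorter paths, higher global efficiency) — the classic
signature of a connectome drifting from ordered toward random topology.
The planted nodal deficit at the right amygdala and the planted
connection clusters are recovered by the nodal tests and NBS respectively
(see `tests/test_acceptance.py`).

The same pipeline is available from the shell:

```bash
fcnet run-all --seed 42 --out runs/demo          # full pipeline
fcnet simulate --seed 1 --out cohort/            # stages individually
fcnet construct --cohort cohort/ --out conn/
```

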