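# perfnet

Cerebral blood flow (CBF) correlation network analysis for 3D
pseudo-continuous arterial spin labeling (PCASL) MRI.

Resting perfusion covaries across brain regions: when one region's CBF is
high in a subject, anatomically and functionally related regions tend to be
high too. Correlating regional CBF **across subjects** therefore yields a
group-level "perfusion covariance" network whose topology can be compared
between diagnostic groups — e.g., cognitively normal (CN) elderly, mild
cognitive impairment (MCI), and Alzheimer's disease (AD). `perfnet` is for
researchers who have co-registered PCASL/proton-density volumes (or
precomputed subjects × regions CBF tables) and want a tested, reproducible
implementation of that whole analysis.

## What it computes

1. **Quantification** — voxelwise CBF from control/label ASL and a
   proton-density image with the single-compartment model
   `CBF = 6000·λ·ΔM·e^(PLD/T1b) / (2·α·T1b·SI_PD·(1−e^(−τ/T1b)))`
   (defaults T1b = 1.4 s, τ = 1.5 s, λ = 0.9 ml/g, PLD = 2.025 s, α = 0.8).
2. **Parcellation** — regional mean CBF under an integer atlas label volume
   (246-region whole-brain convention), assembled into per-group
   subjects × regions tables.
3. **Networks** — per group, the Pearson correlation matrix of regional CBF
   across subjects, binarized over a sparsity grid (default 0.65–0.83,
   step 0.02, sparsity = fraction of edges removed).
4. **Topology** — global efficiency, clustering coefficient, characteristic
   path length, small-world σ = (C/C_rand)/(L/L_rand) against 100
   degree-preserving random references, betweenness centrality (BC), and
   hubs (BC > 2× mean).
5. **Inference** — permutation tests (1,000 reassignments, networks rebuilt
   per permutation) for global and nodal metric differences; Fisher-z
   per-edge correlation comparison `Z = (atanh r_A − atanh r_B)/√(1/(n_A−3)
   + 1/(n_B−3))` with Benjamini–Hochberg FDR (q = 0.001); per-region Welch
   t-tests with FDR (q = 0.05).

Because matched clinical ASL cohorts are restricted-access, the package
ships a first-class synthetic generator (`perfnet.synthetic`) producing
three groups (n = 53/43/30) over 246 regions with modular covariance,
planted regional hypoperfusion, and planted edge decoupling — with the
ground truth recorded, so every stage of the pipeline is testable.
See `docs/methods.md` for the full model and design rationale.

## Worked example

```python
from perfnet import *

truth = make_default_models(R=246, seed=1)          # CN/MCI/AD generative truth
cn = sample_regional_cbf(truth.models["CN"], seed=1001)   # 53 x 246
ad = sample_regional_cbf(truth.models["AD"], seed=3003)   # 30 x 246

net_cn = pearson_network(normalize_regional_cbf(cn))
g = threshold_by_sparsity(net_cn, 0.83)
m = compute_global_metrics(g, n_refs=100, seed=7)
hubs = detect_hubs(betweenness_centrality(g))

tt = regional_ttests(cn, ad, alpha=0.05)
ez = edge_z_comparison(net_cn, pearson_network(normalize_regional_cbf(ad)),
                       sparsity=0.83, alpha=0.001)
```

Output of this exact script:

```
CN graph: 246 regions, 5123 edges (density 0.17)
E_glob=0.552  C=0.592  L=2.028  sigma=3.07
hubs (BC > 2x mean): 22 regions, threshold 251.8
regions with significant CBF differences (FDR 0.05): 63
edges tested: 7178, surviving FDR 0.001: 12
planted decoupled edges recovered: 12 / 12
```

Reading: at sparsity 0.83 the CN network keeps the 5,123 strongest of
30,135 possible edges; σ = 3.07 > 1 means it is clearly small-world (much
more clustered than degree-matched random graphs at similar path length).
The CN-vs-AD regional t-tests flag 63 regions — the 62 regions with planted
10–20% hypoperfusion plus one false positive, consistent with FDR 0.05 —
and the edge test recovers exactly the 12 planted decoupled pairs among
7,178 tested edges at q = 0.001.

## Command line

Each stage is also a subcommand of the `perfnet` CLI:

```sh
perfnet simulate --regions 246 --seed 1 --out-dir sim/
perfnet quantify --control C.nii.gz --label L.nii.gz --pd PD.nii.gz --out cbf.nii.gz
perfnet parcellate --cbf cbf.nii.gz --labels atlas.nii.gz --subject S01 --group CN --append matrix.tsv
perfnet network  --matrix sim/regional_cbf.tsv --group CN --out-dir nets/
perfnet metrics  --matrix sim/regional_cbf.tsv --group CN --sparsity 0.83 --out CN.json
perfnet compare  --matrix-a sim/regional_cbf.tsv --matrix-b sim/regional_cbf.tsv \
                 --group-a CN --group-b AD --out cmp/
perfnet run      --out-dir run/         # full three-group comparison design
```

`perfnet run` archives the effective configuration and a config hash beside
its outputs; identical configs reproduce every number bit-identically.

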