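# kbinet

Persistent-homology network indices for group-wise metabolic brain networks.

Neurodegenerative disease disrupts the coordination of glucose metabolism
across brain regions. Given FDG-PET mean uptake (SUV) per atlas region for a
group of subjects, one can build a *group-wise metabolic network*: nodes are
regions of interest (ROIs), and the edge between regions *i* and *j* carries
the correlation distance

```
w_ij = 1 − corr(SUV_i, SUV_j)
```

across subjects (Pearson by default; Spearman/Kendall available). Any single
threshold on such a network is arbitrary, so `kbinet` instead analyses the
whole *graph filtration* — the nested family of binary graphs obtained by
admitting every edge with weight ≤ λ as λ grows — via zeroth persistent
homology. For a connected N-node network the component-merge events occur at
the single-linkage merge heights λ₁ ≤ … ≤ λ_{N−1} (the minimum spanning
tree's edge weights), giving the maximal filtration λ₀ = 0 ≤ λ₁ ≤ … ≤ λ_{m−1}.

Three univariate indices summarize the filtration:

- **BNP** — |OLS slope| of the Betti number plot β₀(λ) (component count vs λ);
- **SIP** — |OLS slope| of the *integrated persistent feature* (IPF) plot

  ```
  IPF(λ_i) = (m − i) / (m (m − 1)) · Σ_{k=i+1}^{m−1} λ_k    for i ≤ m − 2,
  IPF(λ_{m−1}) = 0,
  ```

  which couples the number of components still alive with the aggregation
  cost still to be paid; both slopes measure how fast the network integrates;
- **KBI** — the kernel-based IPF index, a persistence-weighted Gaussian
  kernel similarity between a network's IPF point set X = {x_i = (λ_i, IPF_i)}
  and a control-derived template T = {t_i}:

  ```
  KBI(X) = (1/N) Σ_i arctan(C (λ_i^X)^p) · arctan(C (λ_i^T)^p) · exp(−‖x_i − t_i‖² / (2σ²))
  ```

  with p = 5, σ = median over plots of the within-plot median pairwise point
  distance, and C = (median over plots of the within-plot median positive
  λ)^(−p). Long-lived topological features are weighted toward π/2, noisy
  ones toward 0, so KBI compares the *shape* of network integration against
  healthy controls rather than a single fitted slope.

Around this core the package provides the full comparative pipeline:
classical graph indices (characteristic path length, network diameter,
modularity) on Bonferroni-filtered networks, group-wise permutation
inference, subject-resampling plus leave-one-out linear-SVM classification,
a block-modular synthetic cohort generator, and SUV/network text I/O with
optional ROI extraction from NIfTI volume + label-atlas pairs.

## Worked example

Simulate three cohorts differing only in cross-module coupling strength
(an AD-like, an MCI-like and a control-like group), build their group-wise
networks, and compare indices against the control template:

```python
from kbinet import (CohortSpec, simulate_three_groups, correlation_distance,
                    graph_filtration, ipf, sip, kernel_params, kbi,
                    permutation_test, network_index_fn)

base = CohortSpec(n_subjects=120, n_roi=45, n_blocks=9, seed=7)
ad, mci, nc = simulate_three_groups(base, scales=(0.3, 0.6, 0.9),
                                    labels=("AD-like", "MCI-like", "NC-like"))
plots = {}
for g in (ad, mci, nc):
    net, _ = correlation_distance(g)
    plots[g.group] = ipf(graph_filtration(net))

params = kernel_params(plots.values())
print(f"kernel: p={params.p}, sigma={params.sigma:.4f}, C={params.c_weight:.4f}")
for name, plot in plots.items():
    print(f"{name:9s} SIP={sip(plot):.4f}  KBI={kbi(plot, plots['NC-like'], params):.4f}")

res = permutation_test(ad, nc, network_index_fn("sip"), n_perm=1000, seed=11)
print(f"SIP permutation test AD-like vs NC-like: "
      f"observed diff={res.observed_diff:.4f}, p={res.p_value:.4f}")
```

prints

```
kernel: p=5, sigma=0.1350, C=583.9559
AD-like   SIP=0.4894  KBI=0.5896
MCI-like  SIP=0.6314  KBI=0.6903
NC-like   SIP=1.0308  KBI=0.9109
SIP permutation test AD-like vs NC-like: observed diff=0.5414, p=0.0000
```

Both indices order the groups AD-like < MCI-like < NC-like: weaker
cross-module coupling slows network integration (lower SIP) and pulls the
IPF plot away from the control template (lower KBI). The permutation p-value
is the fraction of 1000 random subject reassignments whose rebuilt networks
show an index difference at least as large as the observed 0.5414 — none
here, hence p = 0 (an add-one smoothed estimator is available).

The same pipeline is scriptable from the shell:

```sh
kbinet simulate --spec spec.json --out nc.csv --group NC
kbinet build-network --suv nc.csv --method pearson --out nc_net.csv --pvals pv.csv
kbinet persistence --net nc_net.csv --out filt.csv --ipf-out ipf.csv
kbinet index --net ad_net.csv --measure kbi --template nc_net.csv --out kbi.json
kbinet graph-metrics --net nc_net.csv --filter-pvals pv.csv --out metrics.json
kbinet permtest --group-a ad.csv --group-b nc.csv --measure sip --nperm 10000 --seed 7 --out perm.json
kbinet classify --groups ad.csv --groups nc.csv --measure sip --n 5000 --seed 7 --out report.json
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter choices,
numerical conventions, what the synthetic generator does and does not
emulate, and known limitations.
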