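# flowrosetta

Statistical replication of 2-D flow-cytometry cell clusters.

Flow cytometry produces event tables (one row per cell) whose 2-D scatter
projections — e.g. forward scatter (FSC-A) vs side scatter (SSC-A) — form
overlapping, asymmetric cell-population clusters.  There is no ground truth
for cluster membership in real data, which makes it hard to validate gating
strategies and clustering algorithms.  `flowrosetta` addresses this by
*replicating* real clusters synthetically: it deciphers the statistical
properties of each cluster (its analysis routine) and translates them into
arguments for a support-line synthetic cluster generator, producing fully
synthetic, labelled datasets that are statistically equivalent to the
original — every event's cluster of origin known by construction.

## The model

Each cluster, after rotation to its principal axis, is modelled per
dimension as a weighted mixture of components from two modulated-Gaussian
families with location μ, scale σ and one shape parameter:

* **X axis (skew family)** — the skew-normal
  `f(x) = (2/σ) φ(z) Φ(αz)`, `z=(x−μ)/σ`, capturing directional asymmetry;
* **Y axis (kurtosis family)** — the symmetric tail-weight family
  `f(y) = (2/σ) φ(z) Φ(β|z|) / C(β)`, `C(β) = 1 + (2/π) arctan β`,
  capturing heavier or lighter tails without asymmetry.

Fitting is a constrained EM: histogram-based initialization, joint
responsibilities coupling the two dimensions, a 5 %-of-scale cap on each
mean update per iteration, and likelihoods renormalized over the recorded
outlier-trimming window.  The Bayesian information criterion
`BIC = k ln n − 2 loglik` selects the component configuration.  Derived
statistics (mean, SD, skewness, excess kurtosis per dimension; rotation;
silhouette) are translated into generator arguments: points are placed
along a support line via the skew family and displaced laterally (mirrored
above/below the line) via the kurtosis family.

For real, overlapping clusters the package adds the gated-replication
corrections — SD scaling with doubled percent difference, skew/kurtosis
compensation by the cube/fourth power of the SD scale, in-gate density
matching — and the dual-pass PASKC method (Principal Axis and
Skewness–Kurtosis based Covariance), which analyses a cluster in two
orientations and overlays the two variance-weighted component clusters.

## Worked example

```python
import flowrosetta as fr

# built-in benchmark: 5000-event main cluster + 1000-event satellite,
# with known rotation, spread, skewness and kurtosis
events = fr.two_cluster_benchmark(seed=1)

result = fr.analyze_dataset(events, seed=1)     # full routine
row = result.report.clusters[1]                  # the 5000-event cluster
print(f"silhouette {result.silhouette:.3f}")
print(f"rotation {row.rotation_deg:.2f} deg; "
      f"X mean {row.x_mean:.0f}, SD {row.x_sd:.1f}, skew {row.x_skew:.3f}; "
      f"Y SD {row.y_sd:.1f}, kurtosis {row.y_kurtosis:.3f}")

replica = fr.replicate_report(result.report, seed=2)   # synthetic replicate
print(fr.distribution_compare(events, replica))
```

Output:

```
silhouette 0.833
rotation 323.56 deg; X mean 99996, SD 198.5, skew 0.100; Y SD 397.7, kurtosis 0.402
  channel  ks_statistic  ks_pvalue   overlap
0   FSC-A      0.017167   0.339617  0.960667
1   SSC-A      0.019000   0.228937  0.958000
```

The cluster was generated at rotation 325°, X SD 200 with skewness 0.100
and Y SD 400 with excess kurtosis 0.400; the routine recovers all of them
from the unlabelled events (rotation within noise of the axis estimate),
and the regenerated replicate is distributionally indistinguishable from
the original (high histogram overlap, non-significant KS).

A CLI mirrors the library: `flowrosetta fixtures | analyze | generate |
replicate | validate` (see `flowrosetta --help`).

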