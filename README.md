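# bindnet

Graph-based functional-connectivity analysis of **feature binding in working
memory** — for cognitive-neuroscience researchers who want the full method
chain of a two-condition, within-subject task-fMRI network study as a tested,
reusable Python library.

The scientific question: when people must remember the *conjunction* of
features (which color was at which location) rather than the features
separately, which brain regions change how they communicate? The package
answers it with network tools rather than activation maps:

* **Network construction** — regional time series → Pearson FC matrix →
  maximum-weight spanning-tree backbone (connected, acyclic, N−1 edges) →
  densification with the strongest remaining edges to fixed sparsity
  (10% → 1990 edges at N = 200) → weighted masking.
* **Nodal local efficiency** —
  E_loc(v) = 1/(|N(v)|(|N(v)|−1)) · Σ_{i≠j∈N(v)} 1/d_ij on the binary mask,
  compared between conditions with paired t-tests and Benjamini–Hochberg FDR.
* **Network-based statistic (NBS)** — edge-wise paired t-matrix on the
  subnetwork of implicated regions, suprathreshold connected components,
  and component-level inference from a sign-flip permutation null of the
  maximal component size (add-one p-values).
* **Intrinsic neural timescales** — τ = TR · Σ_{k=0}^{L−1} ρ̂(k), the
  TR-scaled area under the sample ACF before its first non-positive lag,
  with pairwise region comparisons.
* **Behavior** — equal-variance signal-detection d′ = Φ⁻¹(H) − Φ⁻¹(F),
  reaction times, 2×2 repeated-measures ANOVA, and Spearman brain–behavior
  correlations; framewise-displacement motion QC (mean FD > 0.5 mm excludes).
* **Synthetic study generator** — a 40-subject, two-condition, 200-region
  design at TR = 1.5 s with planted subnetwork coupling, region-specific
  AR(1) temporal structure, and signal-detection behavior, so every stage is
  testable with known ground truth and no data downloads.

## Worked example

Detect a planted 3-edge subnetwork effect with the network-based statistic
(`examples/04_network_based_statistic.py`; 20 synthetic subjects, edges
0–1, 1–2, 2–3 coupled more strongly in the binding condition):

```
component 0: 3 edges over nodes [0, 1, 2, 3], p = 0.0440
null max-component sizes (counts): {0: 807, 1: 140, 2: 10, 3: 36, 4: 7}

per-edge follow-up (paired t, BH-FDR within the component):
 component  component_p node_i node_j       t   p  p_adjusted  significant      direction
         0        0.044     n0     n1 24.4088 0.0         0.0         True binding>either
         0        0.044     n1     n2 19.2938 0.0         0.0         True binding>either
         0        0.044     n2     n3 20.1943 0.0         0.0         True binding>either
```

The three planted edges survive the p < 0.05 primary threshold and form one
connected component of size 3; a null component at least that large arose in
only 43 of 1000 permutations (add-one p = 44/1001 = 0.044), so the component
is significant at the component level, and every edge individually
strengthens in the binding direction.

The other examples follow the same pattern, one per capability: dataset
simulation with motion QC and the d′ ANOVA (`01`), study-scale network
construction printing the 199-edge backbone and 1990-edge densified network
(`02`), recovery of 8 planted regions by the local-efficiency comparison
(`03`), the planted timescale hierarchy (`05`), and the one-call pipeline
(`06`). A thin CLI covers the shell use cases:
`bindnet simulate --out data/` and `bindnet run-all --out results/`.

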