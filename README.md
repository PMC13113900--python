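# ergraph

Graph signal processing of short transient electrophysiological waveforms,
built for light-adapted electroretinogram (ERG) analysis in
neurodevelopmental-disorder screening research.

A photopic ERG is a ~250 ms retinal response (a-wave trough, b-wave peak,
oscillatory potentials, photopic negative response) sampled at 2 kHz.
`ergraph` turns each waveform into a weighted undirected graph and
classifies diagnostic groups from the graph's topology:

1. **Normalize** x(t) = (x̃(t) − min x̃)/(max x̃ − min x̃) ∈ [0, 1].
2. **Quantize** onto Q amplitude levels, q(t) = round(x(t)(Q−1))/(Q−1).
3. **Connect** consecutive samples' levels with inverse-distance weights
   w(vᵢ, vⱼ) = 1/(|lᵢ − lⱼ| + ε), ε = 1/(Q−1); repeated transitions
   accumulate an edge count, dwell at a level gives a self-loop.

From each graph, nine features are extracted: total load centrality (TLC),
total harmonic centrality (THC), number of maximal cliques (GNC), diameter,
radius, average clustering coefficient (CC), average path length (APL),
algebraic connectivity (λ₂, the Fiedler value of the weighted Laplacian
L = D − A), and density ρ = 2E/(V(V−1)). Five alternative time-series-to-
graph constructions (visibility graph, recurrence network, k-NN graph,
ε-ball graph, ordinal partition network) are included for controlled
comparison.

On top of the features sit nonparametric group statistics (Kruskal–Wallis,
Dunn/Bonferroni post hoc, Cliff's delta with negligible/small/medium/large
bins) and a leakage-proof classification pipeline: subject-wise 10-fold
outer cross-validation around random-forest feature selection, 3-fold
subject-wise inner model selection over seven classifiers, and SMOTE
oversampling confined to training partitions. Because the motivating
clinical dataset is private, a parametric synthetic cohort generator
(`ergraph.synth`) produces ERG-like waveforms with group-specific
"compact" vs "expansive" amplitude dynamics so the entire stack is
testable end to end.

## Worked example

```python
import ergraph as eg
from ergraph.synth import CohortSpec, GroupSpec, preset, generate_cohort
from ergraph.group_stats import feature_stats_table
from ergraph.pipeline import ScenarioSpec, build_scenario, run_nested_cv

# Two synthetic groups: compact (ASD-like) vs expansive (ADHD-like) dynamics
spec = CohortSpec(
    groups={"ASD": GroupSpec(preset("COMPACT"), n_subjects=20, between_sd=0.08),
            "CONTROL": GroupSpec(preset("EXPANSIVE"), n_subjects=20, between_sd=0.08)},
    recordings_per_subject=2, eyes=[eg.Eye.RIGHT], flashes=[113.0], seed=3)
waves = generate_cohort(spec)                  # 80 waveforms, N = 500 each

table = eg.feature_table(waves, Q=50)          # 80 rows x 9 graph features
r = feature_stats_table(table, feature_cols=["diameter"])[0]
print("diameter means:", {g: round(m, 2) for g, m in r.group_means.items()})
print("Cliff's delta (ASD vs CONTROL):", round(r.pairwise[0][3], 2))

data = build_scenario(table, ScenarioSpec(scenario="asd_vs_ctrl"))
res = run_nested_cv(data, classifiers=["knn"], top_k="all", seed=1)
print(f"balanced accuracy: {res.mean_ba:.2f} +/- {res.sd_ba:.2f}")
```

Output:

```
diameter means: {'ASD': 12.18, 'CONTROL': 21.43}
Cliff's delta (ASD vs CONTROL): -1.0
balanced accuracy: 1.00 +/- 0.00
```

The compact group's graphs have roughly half the diameter of the expansive
group's (its waveforms flicker within a wider relative noise band, creating
short-cut edges between amplitude levels), the effect is complete
separation (δ = −1), and the subject-wise nested CV classifies the two
planted styles perfectly.

The same workflow is available from the shell:

```bash
ergraph simulate --seed 42 --scale 0.2 --out waves.csv
ergraph extract  --in waves.csv --q 50 --out features.csv
ergraph stats    --in features.csv --out stats.csv
ergraph classify --in features.csv --scenario three_group --classifiers knn \
                 --top-k all --seed 7 --out result.json
ergraph sweep-q  --in waves.csv --grid 10:80:10 --out sweep.csv
ergraph compare  --in waves.csv --methods erg,vg,rn,knn,eball,opn --out cmp.csv
```

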