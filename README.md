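# poicoloc

Colocation analysis for categorical point patterns — the spatial statistics
used to ask how urban facilities of different types (pharmacies, clinics,
hospitals, …) arrange themselves relative to one another.

Given a set of labelled points (e.g. POI records of medical facilities) in a
study region, the package answers three questions:

1. **Is each category clustered?** The Clark–Evans nearest-neighbour index

   NNI = (Σᵢ min_j d_ij / n) / (0.5 √(A/n)),

   the observed mean nearest-neighbour distance over its expectation under
   complete spatial randomness in a region of area A.  NNI < 1 means
   clustering, 1 randomness, > 1 dispersion, with the classical Z-test
   (SE = 0.26136/√(n²/A); Z < −2.58 flags clustering at the 1% level).

2. **Does category A seek out category B globally?** The global colocation
   quotient

   GCLQ_{A→B} = (N_{A→B}/N_A) / (N_B/(N−1)),  N_{A→B} = Σᵢ Σⱼ f_ij / nnᵢ,

   the fraction of type-B points among A points' k nearest neighbours
   (exact distance ties all included with equal weight 1/nnᵢ), normalised by
   the share expected under random labelling.  GCLQ is directional:
   A→B need not equal B→A.  Significance comes from a random-labelling
   Monte-Carlo test (label vector permuted over fixed locations, 1000
   repetitions by default), swept over bandwidths k = 1, 2, ….

3. **Where does the colocation happen?** The geographically weighted local
   colocation quotient per type-A point, with Gaussian kernel
   w_ij = exp(−½ d_ij²/d_ib²) under an adaptive bandwidth d_ib (distance to
   the k-th neighbour):

   LCLQ_{Aᵢ→B} = (Σⱼ w_ij f_ij / Σⱼ w_ij) / (N_B/(N−1)),

   with per-point Monte-Carlo p-values and the standard map-layer filter
   (keep p < 0.05 and LCLQ > 1).

The package also provides Gaussian kernel-density surfaces per category,
per-district provision summaries (counts, per-area and per-capita rates),
and — because real POI inventories are rarely redistributable — seeded
synthetic scene generators (CSR, Thomas clusters, planted attraction,
planted inhibition) with known ground truth for validating every statistic.

## Worked example

```python
import poicoloc as pc

scene = pc.simulate_scene(pc.SyntheticSceneConfig(
    region=(0, 0, 1, 1), seed=7, categories=(
        pc.CategoryProcessSpec("clinic", "thomas", 300, n_parents=12, sigma=0.02),
        pc.CategoryProcessSpec("pharmacy", "attracted", 200,
                               target_label="clinic", sigma=0.005),
        pc.CategoryProcessSpec("hospital", "csr", 60),
    )))

print(pc.nni_table(scene).to_string(index=False))
```

```
category   n      NNI          Z             p
  clinic 300 0.280357 -23.845613 1.124530e-125
hospital  60 1.071950   1.066191  2.863374e-01
pharmacy 200 0.246306 -20.391114  2.005295e-92
     all 560 0.489669 -23.103450 4.274605e-118
```

Clinics and pharmacies — generated as clustered processes — come out
strongly clustered (NNI ≈ 0.25–0.28, Z far below −2.58), while the CSR
hospitals are indistinguishable from random (NNI ≈ 1.07, p ≈ 0.29).

```python
cfg = pc.MonteCarloConfig(n_permutations=999, seed=1)
results, k = pc.bandwidth_sweep(scene, "pharmacy", "clinic", k_max=3, config=cfg)
for r in results:
    print(r.k, round(r.value, 3), r.p_value, r.significance)
print("selected k:", k)
```

```
1 1.379 0.002 ***
2 1.328 0.002 ***
3 1.326 0.002 ***
selected k: 1
```

The planted pharmacy→clinic attraction is recovered: the quotient exceeds 1
at every bandwidth, significant at the 1% level, and the sweep selects the
first-order neighbour where the planted association is strongest.

Per-point local quotients and the map-layer filter:

```python
lres = pc.lclq_all(scene, "pharmacy", "clinic", pc.BandwidthSpec(k=5), cfg)
sig  = pc.significant_colocated(lres)       # p < 0.05 and LCLQ > 1
print("significant pharmacies:", len(sig), "of", len(lres))
```

```
significant pharmacies: 10 of 200
```

A command-line surface wraps the same pipeline
(`poicoloc simulate | nni | gclq | lclq | kde | report`); outputs are CSV
tables (including the compact `k(value)stars` matrix dialect, e.g.
`1(2.279)***`), GeoJSON layers and ESRI-ASCII density grids, each stamped
with the run's seed and configuration hash.

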