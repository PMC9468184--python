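# vasctda

Quantitative 3D phenotyping of blood and lymphatic vasculature from
tissue-cleared, light-sheet-imaged organs.

Whole-organ clearing protocols produce volumes in which vessels are
classified voxel-by-voxel (e.g. by ilastik) into "target signal"
probabilities. What is missing downstream is a principled way to *compare*
the resulting 3D structures — across organs, disease models, anatomical
regions, or vessel markers (α-SMA⁺ mature vessels, VE-cadherin⁺ capillaries,
Prox1⁺ lymphatics) — without reducing them to a single hand-picked scalar.
`vasctda` implements that quantitative layer for researchers analysing such
volumes:

1. **Extraction** — threshold classified volumes into point clouds in
   physical μm coordinates, attach atlas region labels, compute signal
   volumes.
2. **Topology** — Vietoris–Rips persistent homology of the point cloud
   S = {xᵢ} ⊂ ℝ³ on the ball-radius scale: each feature is a pair
   (r_b, r_d) of birth/death radii, with H₀ components, H₁ loops, H₂ voids.
   Diagrams are compared with the Sliced Wasserstein distance
   SW(Dg₁, Dg₂) = (1/π)∫ W₁(μ₁^θ + μ₂Δ^θ, μ₂^θ + μ₁Δ^θ) dθ, the kernel
   k_SW = exp(−SW/2σ²), and embedded with classical MDS for at-a-glance
   structural maps.
3. **Point-process modelling** — a non-homogeneous Poisson process with
   separable logistic kernels, g(u) = Πᵢ a·bᵢ/(e^{bᵢuᵢ} + 2 + e^{−bᵢuᵢ}),
   λ(u) = Σⱼ g(u − xⱼ), fitted by maximum likelihood with the window
   integral in closed form. Strength and per-axis directionality (1/bᵢ)
   are compared between channels block by block; per-region enrichment of
   ≥2-fold changes is tested with Fisher's exact test.
4. **Proximity** — nearest-neighbour distance distributions between two
   structures (e.g. tumour colonies vs lymphatic vessels) with Tukey
   five-number summaries.
5. **Phantoms** — seeded generators (tubes, rings, shells, bifurcating
   trees, uniform clutter, plus structured degradation) so every stage is
   testable end-to-end without imaging data.

The persistence engine, the Sliced Wasserstein machinery, the NHPP model and
the block/Fisher procedure are implemented in this package and validated in
the test suite against independent brute-force oracles (Z/2 rank-based
persistent Betti numbers, adaptive quadrature, hypergeometric enumeration).

## Worked example

Generate two vessel phantoms (one intact tree, one with 40% of its length
destroyed in contiguous stretches), compute their persistence diagrams, and
compare:

```python
from vasctda import rips_persistence, subsample, SWConfig, pairwise_distance_matrix
from vasctda.phantoms import tree_phantom, degrade_phantom

intact = tree_phantom(depth=3, seed=0)          # 1351 points
damaged = degrade_phantom(intact, 0.4, seed=0)  # 811 points

dg_a = rips_persistence(subsample(intact, 120, seed=0), max_dim=2)
dg_b = rips_persistence(subsample(damaged, 120, seed=0), max_dim=2)

print(len(dg_a.in_dim(0)), len(dg_a.array(1)))   # components, loops
dm = pairwise_distance_matrix([dg_a, dg_b], SWConfig(n_slices=50, dims=(0, 1)),
                              labels=["intact", "damaged"])
print(round(dm.values[0, 1], 1))
```

```
120 2
340.7
```

The intact tree's diagram has 120 H₀ features (119 finite component merges
plus the one component still alive at the cutoff, which is excluded from
comparisons) and 2 small loops; the SW distance of 340.7 μm against its
damaged twin is dominated by the gap-scale component deaths that
fragmentation introduces — the same comparison the pipelines apply to real
organs.

Fitting the point-process model to an anisotropic simulated pattern:

```python
from vasctda.nhpp import NHPPParams, DomainBox, simulate, fit

true = NHPPParams(a=1.5, b=(0.05, 0.05, 0.2))       # vessels along x/y
box = DomainBox((0, 0, 0), (1000, 1000, 1000))       # 1 mm³ window
cloud = simulate(n_centers=593, p=true, box=box, seed=1)   # N = 1842
res = fit(cloud, box, seed=1)
print([round(v, 4) for v in res.params.b], round(res.mean_intensity * 1e9))
```

```
[0.041, 0.0404, 0.1695] 1842
```

The fitted concentrations recover the anisotropy (b_z ≈ 4× b_x: the pattern
spreads in x and y, not z), and the fitted mean intensity reproduces the
observed density (1842 points per mm³). See `docs/methods.md` for why
*ratios and orderings* of these parameters — not their absolute scales —
are the recommended comparison currency, and for the strength/intensity
distinction.

Command-line equivalents (`vasctda extract`, `phantom`, `ph`, `sw`, `mds`,
`nhpp fit|simulate|compare`, `distances`, `run` with a YAML config) cover
the same operations; `vasctda run` writes tidy CSV/JSON outputs plus a
manifest with every seed, threshold and input hash of the run.

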