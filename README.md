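# ehugs — groupwise registration by hierarchical graph shrinkage

`ehugs` spatially normalizes a *population* of images to a hidden common
space without ever choosing one image as the template.  It targets
heterogeneous cohorts — elderly brains with large anatomical variation,
longitudinal infant series — where registering two arbitrary images
directly is unreliable, but registering *similar* images is easy.

## The method

Given N affinely pre-aligned images **I** = {I_i}, with pairwise distances
d_ij = ‖I_i − I_j‖² (SSD; mutual information optional):

1. **Cluster** the images into Ω subgroups G_α with affinity propagation on
   the similarities s_ij = −d_ij, using one shared preference
   p = (1/N²) Σ_ij s_ij, so Ω emerges from the data.
2. **Build a two-level graph.**  The global center
   I_o = argmin_I Σ_i ‖I_i − I‖² approximates the common space; each
   subgroup's *representative* I_{i_α} is its member nearest I_o.  Members
   connect to their representative (low level) and representatives connect
   to I_o (high level): a connected graph with exactly N − 1 edges for any
   partition.
3. **Shrink the graph.**  Each edge carries a stationary velocity field
   v_ij (estimated by diffeomorphic-demons-style registration) whose
   exponential exp(v_ij) is the geodesic warp between neighbors.  The
   energy F(t) = Σ_ij e_ij ‖v_ij(t)‖² is driven down by moving every node
   along its averaged velocity v̂_i = (1/N_i) Σ_j e_ij v_ij for a time step

   Δt = min{ 1 / max_i ‖v̂_i‖ , Σ N_i‖v̂_i‖² / Σ (N_i+1)‖v̂_i‖² },

   alternating a within-subgroup pass with a between-subgroup pass in
   which each representative's warp carries its whole subgroup.  Each
   image's pathway to the common space is the composition
   φ_i = exp(v̂_i Δt_K) ∘ … ∘ exp(v̂_i Δt_0), and images are always
   resampled once from their originals through φ_i.
4. **Evaluate and build the atlas.**  The common-space ground truth is the
   per-voxel majority vote of all aligned tissue maps; accuracy is the
   Dice overlap 2|A∩B|/(|A|+|B|) per tissue.  The atlas is the voxelwise
   mean image plus per-tissue probability (frequency) maps.

A star-graph baseline (`--mode star`, every image connected directly to
I_o) runs the identical machinery with clustering bypassed, for
group-mean-style comparisons.

## Worked example

A built-in generator makes heterogeneous labeled phantom populations: two
anatomical templates (different head and ventricle sizes, misphased
cortical folds), six subjects each, every subject a random smooth
diffeomorphic warp of its template plus noise and bias field.

```python
from ehugs import (PhantomSpec, sample_population, cluster_images, run_groupwise,
                   dice_report, apply_warp_labels, build_atlas, atlas_sharpness)

pop = sample_population(PhantomSpec(seed=0))
images = [img for img, lab, prov in pop]
labels = [lab for img, lab, prov in pop]

clustering = cluster_images(images)
print("subgroups:", clustering.n_clusters, "assignment:", clustering.labels.tolist())

result = run_groupwise(images)
print("iterations:", result.n_iterations, "| converged:", result.converged)
print("energy trace:", " ".join(f"{f:.1f}" for f in result.energy_trace))

aligned = [apply_warp_labels(lab, w) for lab, w in zip(labels, result.warps)]
before = dice_report(labels).per_image.mean()
after = dice_report(aligned).per_image.mean()
for tissue in ("WM", "GM", "CSF", "overall"):
    print(f"Dice {tissue}: {before[tissue]:.3f} -> {after[tissue]:.3f}")

atlas = build_atlas(result.images, aligned)
print(f"atlas sharpness: {atlas_sharpness(atlas.mean_image):.4f}")
```

Output (about two minutes on one CPU):

```
subgroups: 2 assignment: [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
iterations: 13 | converged: True
energy trace: 213.4 153.9 97.2 80.8 76.0 55.4 48.4 41.1 39.5 38.3 37.5 36.1 34.8
Dice WM: 0.817 -> 0.936
Dice GM: 0.797 -> 0.942
Dice CSF: 0.451 -> 0.927
Dice overall: 0.688 -> 0.935
atlas sharpness: 0.0530
```

The clustering recovers the two planted anatomical groups exactly; the
graph energy falls monotonically to ~16 % of its initial value; and the
Dice overlap of every tissue against the majority-vote common-space truth
rises substantially (CSF most, because the ventricle differs most between
the groups).

The same pipeline runs from the shell:

```
ehugs synth --out data --grid 64x64 --templates 2 --subjects 6
ehugs run --images data/images --labels data/labels --out out
ehugs atlas --images out/warped --labels data/labels --out out/atlas
```

`run` writes the energy trace, the per-iteration graph edge lists and
subgroup assignments, the warped images, the cumulative warps (vector
NIfTI), the Dice CSV and the atlas.

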