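# scaffoldnet

AI-aided design of tissue-engineering scaffolds: predict the
mechanical behaviour of porous lattice unit cells directly from their
geometry with a 3D convolutional network trained on "digital
tomographies".

Tissue-engineering scaffolds are porous implants whose stiffness must
mimic the tissue they replace. Their unit cells (here 5 × 5 × 5 mm³)
are geometrically complex, so screening candidate designs with full
finite-element simulation is slow. `scaffoldnet` implements the
alternative workflow end to end:

1. **generate** a library of lattice unit cells (strut grids, random
   trusses, gyroid-like implicit surfaces, and inverse cells) as
   watertight STL meshes;
2. **slice** each mesh into a z-ordered stack of binary images — a
   virtual CT scan (default: 20 slices at 0.25 mm, 1440 × 1440 px,
   white = material) — and resize to the 32 × 32 × 20 occupancy tensor;
3. **characterize** each cell with a voxel finite-element homogenizer:
   porosity P (% void), relative compression modulus
   E_rel = 100·E_lattice/E_bulk and relative shear modulus
   G_rel = 100·G_lattice/G_bulk, both geometry-only quantities;
4. **augment** the training set with six cumulative strategies
   (z-rotations, zooms, flips, x/y-rotations) that expand 20 base
   lattices to 20/120/240/360/480/680 records;
5. **train** a 3D CNN (conv 16 → 32 → 64 with 3³ kernels, max-pooling,
   batch-norm and dropout 0.3, dense 32 → 64 → 3) to regress
   (P, E_rel, G_rel) from the binary tensor, minimizing MSE on
   min-max-scaled targets;
6. **evaluate** on held-out lattices with per-output MAE and the
   global MAE (mean of the three).

The network and its gradients are implemented directly on numpy; the
geometry, imaging and linear-algebra layers use trimesh, scikit-image,
Pillow and scipy. See `docs/methods.md` for the models, conventions
and numerical choices.

## Worked example

```python
import scaffoldnet as sn

# a strut-grid unit cell: 1.1 mm struts on a 2.5 mm grid
mesh = sn.make_strut_grid(period=2.5, strut_width=1.1)

# virtual tomography -> CNN input tensor
stack = sn.slice_mesh(mesh, resolution=160)
grid = sn.stack_to_grid(sn.downscale_stack(stack, 32))

# voxel homogenization -> the three labels
props = sn.characterize(mesh)
print(f"porosity = {props.porosity:.2f} %")
print(f"e_rel    = {props.e_rel:.2f} %")
print(f"g_rel    = {props.g_rel:.2f} %")
```

prints

```
porosity = 55.94 %
e_rel    = 26.85 %
g_rel    = 6.32 %
```

i.e. this cell is 55.9 % void, carries 26.9 % of the bulk material's
compressive stiffness and 6.3 % of its shear stiffness — the kind of
label triple every library lattice receives before training.

Training and evaluation follow a model/results pattern:

```python
from scaffoldnet import ScaffoldPropertyCNN, build_strategy

dataset = build_strategy(base_records, strategy_id=6, seed=7)  # 680 records
model = ScaffoldPropertyCNN.from_dataset(dataset)
results = model.fit(epochs=200, seed=11)
print(results.summary())            # split sizes, scaled MSEs, scaler ranges
predictions = results.predict(test_grids)   # (n, 3) in %, clipped to [0, 100]
```

The full six-strategy experiment (library → labels → six trained
networks → comparison table) is one call,
`sn.run_experiment(sn.ExperimentConfig(out_dir="out"))`, or
`scaffoldnet run --out out` from the shell. The CLI also exposes the
individual stages (`generate`, `slice`, `characterize`, `augment`,
`train`).

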