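# halotile

Exact tile-based (out-of-core) inference for fully convolutional
segmentation networks.

Fully convolutional networks (FCNs) such as U-Net or FC-DenseNet can be
applied to images of any size, but a single forward pass over a
gigapixel whole-slide microscopy image does not fit in accelerator
memory. The standard workaround — sliding overlapping windows and
blending — leaves seam artifacts. `halotile` implements the exact
alternative: partition the image into non-overlapping **Zones of
Responsibility** (ZoRs), expand each by a **halo** of extra context equal
to half the network's receptive field, run the network tile by tile, crop
each prediction back to its ZoR, and stitch. With the right halo the
stitched output is *identical* to a single whole-image pass — bitwise,
under this package's deterministic forward engine — so tiling introduces
no error at all.

The package is aimed at people building segmentation pipelines for
whole-slide or stitched microscopy data who need to verify that their
tiling scheme is exact, and at anyone who wants the receptive-field
arithmetic of an encoder–decoder FCN done carefully.

## The arithmetic

For a network described by its convolutions `c = 0, …, N−1` along the
longest input→output path, each with square kernel `k_c` at pyramid level
`l_c` (levels count max-pools minus up-convolutions), the classical halo
is

    Halo = Σ_c 2^{l_c} · ⌊k_c / 2⌋

and `F = 2^{max l}` is the ratio between the input and the smallest
feature map. Input sizes, strides, ZoRs and halos must all be multiples
of `F`; values are rounded up with `Halo* = F·⌈Halo/F⌉`. For the
published U-Net this gives Halo = 92, F = 16, Halo* = 96 (and the
VALID-convolution shrinkage 572 → 388 = 572 − 2·92 of the original
architecture); FC-DenseNet-56 gives 377 → 384 with F = 32.

`halotile` additionally computes the *exact* context requirement
(`exact_halo`) by walking the layer graph backward with integer interval
arithmetic over all `F` output phases. This can exceed the per-conv sum:
pooling shares each coarse cell among `F` sibling pixels, and 3×3
stride-2 transposed convolutions reach one extra coarse cell on the
trailing side. For U-Net the rounding to 96 already covers the true
requirement (94), so the published numbers stand; for toy networks where
it does not, the tiler plans with `exact_halo` and the test suite
verifies bitwise equality. Brute-force perturbation probes
(`support_radius_oracle`) confirm the walk.

## Worked example

```python
import halotile as ht

arch = ht.build_unet(depth=5)          # published U-Net, SAME convs
print(ht.compute_halo(arch))           # 92
print(ht.compute_F(arch))              # 16
print(ht.adjust_to_multiple(92, 16))   # 96
print(ht.exact_halo(arch))             # 96
print(ht.valid_output_size(arch, 572)) # 388

# verify exactness on a seeded untrained model and a noise image
arch = ht.build_unet(5, base_channels=4)
weights = ht.seeded_weights(arch, seed=1)
image = ht.generate_noise_image(1024, 1024, seed=2)

ref = ht.reference_forward(arch, weights, image)      # one whole-image pass
params = ht.tiling_params(arch, tile_size=512)        # halo 96, ZoR 320
plan = ht.make_tile_plan(1024, 1024, 512, params)
out = ht.run_tiled_inference(ht.make_model(arch, weights), image, plan)

me, _ = ht.misclassification_error(ht.argmax_mask(ref), ht.argmax_mask(out))
print(me, ht.rmse(ref, out))           # 0.0 0.0  — tiled == single pass
```

The misclassification error (ME) counts pixels whose class labels differ
between the tiled and the single-pass result; 0.0 means the segmentations
are identical. The RMSE compares the softmax maps themselves and is 0.0
here because the engine's fixed accumulation order makes the two routes
bit-identical. Run the same comparison with `halo=0` in `tiling_params`
and both become positive — those are the seam artifacts the halo exists
to remove.

The same operations are available from a shell:

```
halotile describe --arch unet
halotile plan --arch unet --height 3584 --width 3584 --tile 512
halotile verify --arch unet-d2 --base-channels 4 --size 96 --tile 32
halotile sweep --arch unet-d2 --base-channels 4 --size 96 --tile 32 --output metrics.csv
```

`verify` exits 0 exactly when ME = 0, so it can guard a CI pipeline.

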