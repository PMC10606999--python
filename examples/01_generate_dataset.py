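"""Generate a synthetic shape dataset with ground-truth masks.

Each class is a distinct colored shape on a noisy gray background; the shape
is the only class-correlated content, and its pixel mask is the ground truth
that later examples use to judge heatmap localization and crop quality.
"""

from simexplain import SyntheticSpec, generate_shape_dataset, write_image_folder, write_masks

spec = SyntheticSpec(n_classes=5, n_per_class=8, image_size=(64, 64), seed=0)
dataset, masks = generate_shape_dataset(spec)

print(f"generated {len(dataset)} images in {len(dataset.classes)} classes:")
for cls in dataset.classes:
    n = sum(im.class_label == cls for im in dataset.images)
    print(f"  {cls}: {n} images")
area = sum(m.mask.mean() for m in masks) / len(masks)
print(f"mean shape area fraction: {area:.3f}  (fraction of pixels that are ground truth)")

write_image_folder(dataset, "scratch/demo_data/images")
write_masks(masks, "scratch/demo_data/masks")
print("wrote directory-per-class images and mask PNGs under scratch/demo_data/")
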