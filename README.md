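# canopykit

Machine-vision tooling for tree-fruit orchards, downstream of instance
segmentation. Given per-fruit and per-branch masks on RGB-D imagery of
mango canopies, `canopykit` answers three production questions:

1. **How big is each fruit?** Mask pixel extents are converted to
   millimetres through the pinhole model using the camera-to-fruit range
   taken from the aligned depth image, with an ellipse filter that rejects
   partly occluded fruit (a non-symmetric fruit cannot be sized from a
   partial outline).
2. **How many fruit are on the tree?** Detections are counted above a
   confidence threshold and scaled by an occlusion correction factor
   calibrated against manual counts, because fully hidden fruit are
   invisible to any detector.
3. **Is the picking path clear?** Segmented branch pixels are
   back-projected into a 3D point cloud and tested for inclusion in the
   harvester arm's swept workspace — a rectangular prism for a stationary
   arm platform, a trapezoidal prism when the platform travels vertically
   during the pick — via a half-space parity test on the prism's six face
   planes.

It also ships the evaluation stack used to compare segmentation models
(IoU matching, P/R/F1, AP by 101-point interpolation, mAP50 and mAP50-95,
and the repeated-training coefficient of variation CV = SD/mean × 100),
annotation I/O (VIA 2.x polygon JSON ↔ COCO-style JSON, 640×540 tiling,
16-bit depth PNGs, ascii PLY clouds), and a synthetic RGB-D canopy scene
generator with exact ground truth so the whole pipeline is testable
without field data.

## The core geometry

With pinhole intrinsics (fx, fy, cx, cy), a pixel (u, v) with depth Z mm
back-projects to x = (u − cx)Z/fx, y = (v − cy)Z/fy, z = Z. A fruit mask
of pixel height h and width w at range Z has estimated length h·Z/fy and
width w·Z/fx, with Z the MAD-filtered median of depths under the mask.
Accuracy is summarised by bias (mean error), RMSE, and bias-corrected
RMSE-bc = √(RMSE² − bias²).

A workspace prism is built from 8 vertices; each face plane is found from
three of its vertices A, B, C as n = AB × AC = (a, b, c) with
d = −n·A, oriented so the prism centroid evaluates negative in
ax + by + cz + d. A branch point is inside the workspace iff it evaluates
≤ 0 on all six planes (boundary counts as inside — conservative for
collision avoidance); any inside point flags the pick cycle obstructed.

## Worked example

```python
import canopykit as ck
from canopykit.annotation_io import instance_masks_from_map

config = ck.SceneConfig(n_fruit=10, n_branches=0, depth_range=(2000, 2000))
scene = ck.generate_scene(config, seed=1)
frame = ck.render(scene)
K = config.intrinsics

masks = instance_masks_from_map(
    frame.instance_map, {p.instance_id: "fruit" for p in scene.primitives})
est = [ck.size_from_mask(m, frame.depth, K).length_mm for m in masks]
truth = [frame.truth.loc[m.instance_id, "true_length_mm"] for m in masks]
s = ck.sizing_stats(est, truth)
print(f"bias {s.bias:.2f} mm  rmse {s.rmse:.2f} mm  rmse_bc {s.rmse_bc:.2f} mm")
```

prints

```
bias -0.10 mm  rmse 1.71 mm  rmse_bc 1.71 mm
```

i.e. sizing ten synthetic fruit at 2 m recovers true lengths with a bias
of −0.10 mm and an RMSE of 1.71 mm — about half of the 3.3 mm that a
single pixel subtends at that range — and the identity
rmse² = bias² + rmse_bc² holds by construction.

The same pipeline is available from the shell:

```
canopykit simulate --seed 1 --out scene/
canopykit size --depth scene/frame_depth.png --masks scene/frame_instances.png --out sizes.csv
canopykit filter --depth scene/frame_depth.png --mask branch_mask.png --pick pick.yaml
```

The `filter` subcommand prints a JSON verdict such as
`{"obstructed": false, "n_inside": 0, "n_points": 0, "strategy": "trap_after_rect"}`.

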