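# wafernoise

Intrinsic-noise evaluation of 3D intra-oral scanners from repeated scans of
an ultra-flat reference wafer.

Intra-oral scanners produce triangle meshes of teeth for CAD-CAM prosthesis
design. Scanning an ultra-flat, ultra-smooth alumina wafer (75 mm square,
optical flatness λ/2 at 550 nm — nanometre-scale, i.e. flat relative to the
~35 µm scanner resolution) is a blank test: everything the mesh deviates
from a plane is scanner noise. `wafernoise` quantifies that noise and runs
the statistical protocol to compare acquisition conditions (wafer
angulation 0°/30°/45°, tilt direction 1/2) and scanners. It is aimed at
dental-metrology and biomedical-imaging groups who want a reproducible,
hardware-independent noise benchmark.

## Method

For every vertex *v*, all vertices within a ball kernel of radius *r*
(default 20 mm, which covers the whole cropped wafer mesh) define a
neighborhood. A mean plane is fitted by total least squares (orthogonal
distance regression: the plane through the centroid whose normal is the
direction of least variance), and the signed orthogonal distance
*x<sub>i</sub>* of the vertex to the plane is recorded in micrometres. The
noise statistic is the RMS roughness

&nbsp;&nbsp;&nbsp;&nbsp;*R<sub>q</sub>* = √( (x₁² + x₂² + … + x<sub>n</sub>²) / n )

which is zero for a perfect plane and invariant under rigid motion, so
tilted and untilted acquisitions are directly comparable. Vertices are
additionally classified by |x<sub>i</sub>| into 0–5, 5–10, 10–20 and
&gt;20 µm bins. Meshes are cropped (default 5 % per side, in the frame of
the fitted plane) to eliminate wafer edges, and a central region of
interest (default 50 % per axis) separates border behaviour from the
middle of the scan — the *edge effect*. Replicate R<sub>q</sub> values per
condition are summarized (mean, SD, IQR, CV, confidence interval) and
compared with Kruskal-Wallis across conditions and two-sided Mann-Whitney
tests pairwise (reported as significance letters a–e) and whole-mesh vs
central ROI.

A virtual-wafer simulator (`simulate_wafer_scan` / `simulate_protocol`)
generates the full 5-condition × 10-replicate protocol with configurable
Gaussian noise, an edge-amplified border band, sparse outliers and a
sub-resolution waviness bounded by the wafer's flatness spec, so every
pipeline stage can be validated against a known ground truth without
scanner hardware.

## Worked example

```python
import wafernoise as wn

base = wn.WaferScanConfig(resolution=81, sigma_um=8.0)   # 75 mm wafer,
scans = wn.simulate_protocol(base, replicates=10, seed=0)  # 5 cond x 10 reps
report = wn.build_report({"virtual": scans},
                         wn.PipelineConfig(kernel_radius_mm=1000.0))
cols = ["condition", "region", "mean_rq_um", "sd_um", "iqr_um", "cv_pct", "letters"]
print(report.to_frame()[cols].round(2).to_string(index=False))
```

```
condition  region  mean_rq_um  sd_um  iqr_um  cv_pct letters
        0   whole       13.09   0.22    0.21    1.66
     30.1   whole       13.18   0.20    0.25    1.52
     30.2   whole       13.09   0.16    0.20    1.26
     45.1   whole       13.11   0.21    0.37    1.61
     45.2   whole       13.05   0.20    0.24    1.51
        0 central        8.22   0.22    0.22    2.71
     30.1 central        8.05   0.18    0.32    2.28
     30.2 central        8.07   0.24    0.37    2.99
     45.1 central        8.14   0.20    0.22    2.42
     45.2 central        8.10   0.22    0.42    2.72
```

The simulated scanner adds 8 µm Gaussian noise, tripled inside a 10 %
border band. The central ROI recovers ≈8 µm (slightly above, from the
sparse 40 µm outliers), while the whole mesh reads ≈13 µm — the edge
effect. The empty `letters` column says no condition differs from another
(the simulator is tilt-invariant by construction), while
`report.whole_vs_central` holds the per-condition Mann-Whitney results
(here p ≈ 1.8 × 10⁻⁴ for every condition: whole vs central is
significant).

The same workflow is available from the shell:

```bash
wafernoise simulate --out scans/ --seed 0 --replicates 10
wafernoise evaluate scans/angle0_dir0_rep0.stl --out eval/   # field CSV + colored PLY
wafernoise report --manifest scans/manifest.json --out report/
```

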