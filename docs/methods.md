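# Methods

## Model and procedure

A flat reference wafer scanned by an ideal device yields a plane; the
recorded mesh's deviation from a plane is the device's intrinsic noise.
`wafernoise` measures it as follows, per scan:

1. **Weld** the imported mesh (STL stores unshared triangle corners);
   positions closer than 1e-6 mm are merged. The tolerance is ~7 orders of
   magnitude below scanner resolution and exists to absorb float32
   round-off, not to repair geometry.
2. **Crop** the wafer border: the mesh is projected onto the in-plane axes
   of a global total-least-squares (TLS) plane fit and the bounding
   rectangle is shrunk by `crop_margin` (default 0.05) per side. Cropping
   in the fitted-plane frame — not world coordinates — is what makes 30°
   and 45° acquisitions crop the same physical region as 0° ones.
3. **Roughness field**: for each vertex, all vertices within the ball
   kernel radius (default 20 mm) are gathered, a TLS plane fitted
   (centroid + direction of least variance; minimizes orthogonal
   distances), and the vertex's signed distance recorded in µm. Local
   normals are oriented to agree with the global plane normal so the sign
   field is coherent. When the radius covers the whole mesh — the default
   on the wafer — every neighborhood is the full vertex set and a fast
   path computes residuals from the single global fit; it is exactly
   equivalent to the general path and is verified against an exhaustive
   O(n²) neighbor-scan oracle in the tests.
4. **Statistics**: Rq = √(Σxᵢ²/n) (population form, sign-insensitive),
   plus the proportion of vertices with |x| in [0,5), [5,10), [10,20) and
   [20,∞) µm. Bins are half-open and lower-inclusive: exactly 5 µm falls
   in the 5–10 bin. The same quantities are recomputed on the central ROI
   (centered rectangle covering `roi_fraction` = 0.5 of each in-plane
   axis) to expose the edge effect.

Replicates of one acquisition condition are aggregated: mean, sample SD
(n−1 denominator), IQR with linearly interpolated percentiles,
CV = 100·SD/mean, and a CI half-width t(1−α/2, n−1)·SD/√n (α = 0.05;
switchable to a normal quantile — published tables of this protocol print
CI values whose formula is not recoverable, so CIs are never used as a
test oracle). Conditions are compared with Kruskal-Wallis (tie-corrected,
χ² approximation) and pairwise two-sided Mann-Whitney tests; pairwise
outcomes become letter sets in the fixed condition order
0°=a, 30.1=b, 30.2=c, 45.1=d, 45.2=e. No multiple-testing correction is
applied by default (the protocol reports raw pairwise outcomes); Holm
adjustment is available behind a flag. The Mann-Whitney test is
permutation-exact (full enumeration over splits, correct under ties) when
C(n1+n2, n1) ≤ 400, otherwise the tie-corrected normal approximation with
continuity correction is used. Two degenerate cases are defined
explicitly: two all-identical samples give U = n₁n₂/2 and p = 1, and
Kruskal-Wallis on entirely identical data is undefined (the tie
correction divides by zero) and is reported as such.

## Parameters

| parameter | default | unit | why |
|---|---|---|---|
| kernel radius | 20 | mm | covers the cropped wafer mesh, reducing the local fit to a global one; kept configurable for smaller targets |
| weld tolerance | 1e-6 | mm | float32 round-off scale, ≪ 35 µm resolution |
| crop margin | 0.05 | per side | removes wafer-edge artefacts before analysis |
| ROI fraction | 0.5 | per axis | central half of the cropped scan |
| bin edges | 5, 10, 20 | µm | standard vertex-classification thresholds |
| α | 0.05 | — | significance level for tests and CIs |
| LUT range | ±20 | µm | signed color scale for distance maps |

## The virtual wafer

`simulate_wafer_scan` builds a regular triangulated grid over the 75 mm
square wafer and displaces each vertex along the surface normal by:

- **waviness** — one low-frequency 2D sinusoid of 275 nm amplitude (λ/2 of
  550 nm light, the wafer's optical flatness spec). It is three orders of
  magnitude below scanner noise; it exists so tests can confirm that
  reference-surface error is negligible, mirroring the physical argument
  for using the wafer as a blank.
- **Gaussian noise** — zero-mean, σ = 8 µm by default (the middle of the
  5–12.5 µm range commercial scanners show on this target), multiplied by
  3 inside a 10 % border band to emulate the edge effect.
- **outliers** — Bernoulli(0.002) vertices displaced ±40 µm.

The mesh is then rigidly rotated by the acquisition tilt (0/30/45°) about
an in-plane axis, with the sign flipped between directions 1 and 2. Noise
is drawn in the wafer frame *before* tilting; real scanner noise lies
along the optical axis after tilting, but Rq is rigid-motion invariant, so
the two conventions give identical statistics and the simpler one is
used. `simulate_protocol` derives one child seed per
(condition index, replicate) via `numpy.random.SeedSequence((seed, ci, r))`
(folded below 2³¹), so the 50-scan protocol is reproducible scan by scan.

What the simulator does **not** emulate: spatial correlation of scanner
noise (real noise is of unknown origin and likely correlated; here it is
white, with the waviness term the only correlated component), optical
physics of confocal acquisition, saliva/powder artefacts, and non-flat
targets. Passing tests therefore demonstrate that the *pipeline* recovers
known noise parameters and detects constructed edge effects — not that
any particular hardware has a given noise level.

## Numerical choices

- Distances with |x| < 1e-7 µm are snapped to exactly 0. A perfectly
  planar but tilted mesh leaves ~1e-11 µm of SVD residue; snapping makes
  "noiseless scan → Rq exactly 0" true and keeps the rank tests on
  noiseless replicates at p = 1 instead of ranking float dust.
- Plane normals get a canonical sign (largest-magnitude component
  positive); local kernel normals are then re-oriented along the global
  normal.
- Collinearity in a plane fit is declared when the second singular value
  is ≤ 1e-12 of the first.
- Crop/ROI rectangle bounds are inclusive with a 1e-9-relative slack so
  grid vertices sitting exactly on a boundary are kept deterministically.
- The Rq-linearity property (scaling normal offsets by c scales Rq by c)
  holds only to second order under TLS, because the fitted normal itself
  shifts with the noise amplitude; the property test asserts it at 1e-5
  relative.

## Problem sizes

The test-suite and acceptance runs use 101×101-vertex scans (~10⁴
vertices) for parameter recovery, 81×81 for the edge-effect runs and
smaller grids for unit tests. At n = 10⁴ the relative standard error of a
single-mesh Rq is ≈ 1/√(2n) < 1 %, far below the 3 % recovery tolerance,
so denser grids would only add runtime, not information.

## Known limitations

- Only flat reference surfaces: no curved targets, no mesh-to-mesh
  registration, no trueness/precision against a second scanner.
- DCM (3Shape native) files are not parsed; convert to STL/PLY first.
- The exact central-ROI size used in published tables of this protocol is
  not stated; absolute central-region values are therefore
  convention-dependent (the whole-mesh values are not).
- With the default 20 mm kernel on targets much larger than the wafer,
  neighborhoods no longer saturate and the per-vertex loop is O(n·k);
  fine for wafer-sized meshes, slow for full-arch scans.
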