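# ciliadyn

Quantification of cilia dynamics and planar cell polarity from fluorescence
microscopy: automated primary-cilium detection and axoneme length
measurement, disassembly time courses, rotational/translational basal-body
polarity by circular statistics, bead-flow velocity and tortuosity, and a
hit filter for duplicate luminescence-based (LUMIER) interaction screens.

It is written for cell biologists studying ciliogenesis — e.g. serum-induced
primary-cilium disassembly in hTERT-RPE1 cells, or the polarization of
motile cilia in multiciliated epithelia — who need the image quantification
behind such experiments as a tested, scriptable library instead of a
one-off high-content-screening macro.

## What it computes

**Cilium detection (six steps per field).** From a two-channel z-stack
(centrosome marker such as pericentrin, and axoneme marker such as
acetylated α-tubulin): (1) maximum-intensity projection along z;
(2) centrosome spot detection (difference-of-Gaussians band-pass, robust
median + k·MAD threshold, non-maximum suppression); (3) an 11 × 11 µm crop
around each centrosome in the axoneme channel; (4) segmentation of the
bright proximal axoneme cluster (quantile threshold, component nearest the
crop centre); (5) region growing while border pixels keep intensity
≥ ratio × local background median; (6) skeletonization and length = longest
geodesic path through the skeleton (1 / √2 step costs) × pixel size. A
centrosome is ciliated when length ≥ 1 µm; fields aggregate to
%ciliated, and replicate fields to time courses (mean ± s.e.m., Welch's
t-test vs a control condition).

**Circular statistics for polarity.** For basal-rootlet orientation vectors
(BROVs, per cell — rotational polarity) and basal-body orientation vectors
(BBOVs, per field of view — translational polarity): the circular standard
deviation CSD = √(−2 ln R) where R is the mean resultant length of the unit
vectors; per-group angles re-centred to a 90° circular mean
(θ′ = θ − θ̄ + 90°, mod 360) for rose-plot display; conditions compared with
a two-sided Mann–Whitney U test on the per-group CSDs (exact enumeration
for small tie-free samples). BBOVs point from a cell outline's area centroid
to the centroid of the basal-body patch segmented by adaptive mean
thresholding of the γ-tubulin channel.

**Bead flow.** Per-frame detections link into trajectories by mutual
nearest neighbours; each track yields velocity = path length / elapsed time
(µm/s) and tortuosity = path length / chord length (≥ 1; 1 is perfectly
straight), summarized per condition relative to a control.

**Interaction screen.** A prey is a hit when its luminescence intensity
ratio is ≥ 3 in both biological replicates (boundary inclusive).

Because the underlying raw microscopy of such studies is rarely deposited,
the package ships a first-class synthetic-data module (`ciliadyn.synthdata`)
that generates two-channel fields, orientation vectors, bead tracks and
screen tables with known ground truth, so every stage is validated by
parameter recovery; see `docs/methods.md` for the generator model and its
limits.

## Worked example

Simulate a field with known 70% ciliation, then quantify it:

```sh
$ ciliadyn simulate field --seed 42 --out demo
wrote demo/field.tif (70 ciliated of 100 centrosomes)
$ ciliadyn detect --stack demo/field.tif --condition siCTL --out records.csv
field: 100 centrosomes, 70.0% ciliated, mean length 4.30 um
```

All 100 centrosomes are found and the detected ciliation matches the
simulated 70%; `records.csv` holds one row per centrosome (`field_id,
centrosome_x, centrosome_y, ciliated, length_um`). The mean length (4.30 µm)
estimates the 2–6 µm simulated range's mean with the pipeline's ~0.4 µm
mean absolute error. The same works for traced polarity vectors and bead
tracks:

```sh
$ ciliadyn simulate polarity --seed 42 --out demo --n-cells 12 --kappa 4
$ ciliadyn rotational --vectors demo/vectors.csv --out rot.csv
all: mean CSD 31.30 deg (s.d. 5.27, n=12 cells)
$ ciliadyn simulate tracks --seed 42 --out demo --n-tracks 20
$ ciliadyn flow --tracks demo/tracks.csv --control ctl --out flow.csv
ctl: v=11.55 um/s, tortuosity=1.156 (n=20)
```

The mean CSD of 31.3° is what a von Mises concentration of κ = 4 implies
(the closed form √(−2 ln(I₁(κ)/I₀(κ))) gives 31.0°), and the tracks
simulated at 10 µm/s drift plus 0.1 µm jitter per frame read out as
11.6 µm/s path-length velocity with tortuosity slightly above 1.

The same analyses are available as library calls
(`ciliaquant.quantify_field`, `polarity.rotational_polarity_summary`,
`flow.flow_summary`, `stats.filter_lumier_hits`, …) returning typed records
and pandas DataFrames.

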