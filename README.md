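# sarcotom

Quantitative analysis of sarcomere architecture from cryo-electron
tomography filament data: myofilament lattice packing statistics,
reference-free thin-filament subtomogram averaging, statistical actin
polarity assignment, and the polarity-derived sarcomere metrics (Z-disk and
M-line positions, thin-filament overlap, helical rise and twist,
tropomyosin azimuth).

The package is aimed at structural biologists working with traced filament
centerlines and subtomogram averages from muscle tomograms.  Because real
tomograms are large and scarce, it ships a first-class synthetic-data
module that generates filament networks and density volumes with the same
geometric and statistical structure — hexagonal thick-filament lattices
with trigonal and interstitial thin filaments, polarity-segmented
sarcomeres with plantable M-line overlap, and helical thin-filament
densities — so every analysis stage can be validated end to end against
planted ground truth.

## The analyses

**Near-neighbor packing statistics.**  Filament centerlines are resampled
every 3 nm; for every point of a reference filament, the closest point of
each neighboring filament is characterized by its distance *d* and the
unsigned acute angle *θ* between the local tangents.  The (*d*, *θ*)
occurrences form a 2D histogram whose ridge at small *θ* (< 10°) reveals
equidistant, nearly parallel filaments; the mean interfilament spacing is
the mean of the distances above two-thirds of the first-shell peak.  A
local frame (**e1**, **e2**, **e3**) — **e2** along the filament, **e1**
toward the nearest parallel neighbor, **e3** = **e1** × **e2** — aligns all
points, and the neighbor occurrences in the **e1e3** plane map the lattice
symmetry (six-fold around thick filaments at spacing *a*; trigonal thin
filaments at *a*/√3).

**Polarity assignment.**  Actin filaments are polar, but the polarity is
invisible in a raw tomogram.  Subvolumes sampled every 1.38 nm (half the
actin rise) along each filament, with zxz Euler angles (φ, θ, ψ) carrying
the centerline onto the z axis and the in-plane angle φ randomized on a 30°
grid, are aligned against two references related by a 180° rotation about
x.  Per filament, the two score samples are compared with an unpaired
Student's t-test: *p* < 0.05 assigns the polarity of the higher-scoring
reference, otherwise the filament stays unassigned.  On polarity-free input
the false-assignment rate equals α by construction.

**Sarcomere metrics.**  With polarity labels in hand, gaps where thin
filaments face each other with their barbed (+) ends locate Z-disks;
encounters of pointed (−) ends locate M-lines; the axial interpenetration
of opposite-polarity arrays at an M-line is the thin-filament overlap — the
structural signature of contraction.  Refined subunit poses yield the
helical rise (≈ 2.76 nm) and signed twist (≈ −167.0°) per actin subunit and
the 13-subunit crossover repeat (≈ 35.9 nm); cylindrical-shell
cross-correlation between two averages measures an azimuthal shift of the
tropomyosin strands on the actin surface.

## Worked example

```python
from sarcotom.workflows import (
    recover_thick_spacing, recover_helical_parameters, recover_overlap_metrics,
)

est = recover_thick_spacing(seed=1)          # ~200 jittered thick filaments
print(f"thick-thick spacing: {est.mean:.1f} +/- {est.sd:.1f} nm (n={est.n})")

hel = recover_helical_parameters()           # noise-free subunit poses
print(f"rise {hel.rise:.2f} nm, twist {hel.twist:.1f} deg, "
      f"repeat {hel.repeat:.1f} nm ({hel.subunits_per_repeat} subunits)")

ov, frac = recover_overlap_metrics(1650.0, 281.0, 800.0, seed=1)
print(f"overlap {ov:.0f} nm = {frac:.0f}% of the 1650 nm sarcomere")
```

prints

```
thick-thick spacing: 45.3 +/- 1.8 nm  (n=61610)
rise 2.76 nm, twist -167.0 deg, repeat 35.9 nm (13 subunits)
overlap 281 nm = 17% of the 1650 nm sarcomere
```

The spacing is the first-shell mean read from the (d, θ) histogram of a
synthetic hexagonal lattice built with lattice constant 45.1 nm and a
3.8 nm spacing spread (the ± value is the spread of the distances averaged,
not an uncertainty of the mean); the helical parameters are recovered
exactly from noise-free poses; the overlap is the planted M-line
interpenetration recovered through Z-disk/M-line annotation.

The same pipelines are available from the shell:

```sh
sarcotom simulate lattice --config lattice.json --seed 1 --out net.csv
sarcotom pack --network net.csv --ref thick --nbr thick --dmax 60 --out packdir
sarcotom simulate sarcomere --config sarc.json --seed 2 --out sarc.csv
sarcotom metrics --network sarc.csv --out metricsdir
```

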