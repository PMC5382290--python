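# ccmigrate

Quantitative 3D analysis of collectively migrating cell clusters in 4D
(3D + time) fluorescence movies, built around the *Drosophila* border
cell system: a closely packed ball of two non-motile polar cells
surrounded by ~6–10 migratory border cells, crawling between large
nurse cells.  The package segments and tracks every nucleus and cell,
then quantifies how the cells coordinate — and it ships a
ground-truthed synthetic movie generator so that every stage is
testable without microscopy data.

## What it computes

**Segmentation and tracking.** Raw anisotropic two/three-channel
stacks are resampled to isotropic voxels, bleach-corrected (constant
total fluorescence assumption) and denoised.  The fixed number of
nuclei is segmented per frame by a brightness-weighted Gaussian
mixture fitted with EM over voxel coordinates; frame-to-frame identity
is a global assignment (Hungarian algorithm) over the confidence
matrix

    S_ij = (|Ω_i(t) ∩ Ω_j(t+1)| + 1) / (‖c_i(t) − c_j(t+1)‖ + ε)

Cell bodies are recovered by a marker-controlled watershed of an
oriented second-derivative (plate) filter bank response, restricted to
a volume-constrained cluster mask, with the tracked nuclei as seeds.

**Coordination.** Per frame, with unit movement directions d̂_k and
unit radius vectors r̂_k from the cluster center,

    group polarization   P(t) = |Σ_k d̂_k| / K            (running → 1)
    angular momentum     M(t) = |Σ_k r̂_k × d̂_k| / K      (rotating → 1)

A two-class bivariate Gaussian classifier over (P, M) separates the
running and rotating migration modes; the polar-axis orientation and
its per-step rotation angle are tracked from the two polar cells.

**Neighbour exchange.** The temporal topology change metric
`g(t, s) = max_ij |D(t+s) − D(t)|_ij` over pairwise center-distance
matrices is invariant to rigid cluster motion but spikes when a border
cell slides past its neighbours; events above τ = 30 voxels (9.9 μm)
are detected with their onset and duration.

**Protrusions and morphodynamics.** Cluster external protrusions are
the residue `B \ opening(B, ball(r))` of the cluster mask, with `r`
from fitting the mean border-cell volume to a sphere; their alignment
(PA), combined-direction coupling (CD) and size coupling (CS) with
cluster motion are reported.  Per-cell surface deformation between
consecutive frames is mapped by bidirectional nearest-surface
distances, giving MPD/MND (maximum positive/negative deformation) and
PDE/NDE (deformation energies), plus the angle between the combined
cluster rotating vector `R = Σ r̂_k × v_k` and the combined protrusion
rotating vector `Q = Σ r̂_k × u_k`.

## Worked example

```python
import numpy as np
from ccmigrate import SceneConfig, MotionSegment, generate_movie
from ccmigrate.coordination import coordination_series

cfg = SceneConfig(
    motion_schedule=[MotionSegment("running", 5, 1.5, (0, 0, 1.0)),
                     MotionSegment("rotating", 5, 5.0, (1.0, 0, 0))],
    seed=11)
movie, truth = generate_movie(cfg)
series = coordination_series(truth.true_tracks)
for t, (P, M) in enumerate(zip(series.polarization, series.momentum)):
    print(f"frame {t}: P={P:.3f} M={M:.3f}")
```

prints

```
frame 0: P=1.000 M=0.000
frame 1: P=1.000 M=0.000
frame 2: P=1.000 M=0.000
frame 3: P=1.000 M=0.000
frame 4: P=1.000 M=0.000
frame 5: P=0.000 M=0.999
frame 6: P=0.000 M=0.999
frame 7: P=0.000 M=0.999
frame 8: P=0.000 M=0.999
frame 9: P=0.000 M=0.999
```

— a perfectly coherent translation has P = 1 and M = 0; rigid
equatorial rotation has M ≈ 1 (0.999 rather than 1.0 because the
movement direction over a finite 5° step is the chord, not the
tangent) and P = 0.

The same works end-to-end from the shell:

```bash
ccmigrate simulate --out scene/ --seed 1
ccmigrate run --in scene/ --out results/ --seed 1
```

which writes the nuclei/cell label TIFFs and CSV tables (tracks,
coordination, interfaces, exchange events, protrusions, mobility) plus
a JSON run manifest with the config hash and per-file digests.

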