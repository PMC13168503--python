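# polarsmolm

Single-molecule orientation and localization microscopy (SMOLM) with four
polarized, NA-filtered detection channels — simulation, retrieval and
analysis.

## The problem

Standard single-molecule localization microscopy reports positions but not
orientations, yet in dense protein assemblies (actin networks in
lamellipodia, podosome cores, labelled lipid membranes) the 3D orientation
of each fluorophore carries the structural information. Most orientation
methods engineer the point-spread function, which enlarges the PSF and
makes retrieval slow. The approach implemented here instead splits the
emission into four polarization channels with two different effective
numerical apertures and works purely with **integrated intensities**: the
emission of a dipole tilted out of the sample plane concentrates at the rim
of the pupil, so the ratio between a low-NA and a high-NA channel encodes
the off-plane angle, while the Wollaston polarization splits encode the
in-plane angle and the rotational mobility.

Each molecule is described by a mean dipole direction and a wobble cone:
polar angle η (η = 0° vertical/off-plane, 90° in-plane), azimuth
ξ ∈ [0°, 180°), and cone full apex angle δ ∈ [0°, 180°]. Time-averaged
emission is governed by the second-order moments
m = (m_xx, m_yy, m_zz, m_xy) with

    m = γ(δ) u uᵀ + (1 − γ(δ))/3 · 1,   γ(δ) = c(1+c)/2,  c = cos(δ/2),

and the four integrated channel intensities are linear in m,

    ⟨I⟩ = ⟨K⟩ · m,   I = (I0, I90, I45, I135)ᵀ,

with ⟨K⟩ a 4×4 matrix fixed by the detection apertures (computed here from
a vectorial dipole-near-interface model, or measured by a nanobead +
rotating-polarizer calibration). Retrieval inverts ⟨K⟩, renormalises to
unit trace and recovers (η, ξ, δ) in closed form:

    ξ = ½ atan2(2 m_xy, m_xx − m_yy),
    γ̂ = (3(a + m_zz) − 1)/2,  a = √((m_xx−m_yy)² + 4 m_xy²),
    η = asin √(a/γ̂),   δ = 2 acos((−1 + √(1+8γ̂))/2).

The package provides every stage: the vectorial forward model (pupil
fields, basis PSFs, collection fractions), the exact orientation↔moment
maps, GLRT spot detection with three intensity estimators (symmetric
Gaussian, rotated Gaussian, box integration), channel pairing and
registration, synthetic nanobead calibration, Fisher-information/CRLB
analysis, a Monte-Carlo scene generator (random orientations, lipid-coated
spheres, filament networks), drift correction, and post-retrieval
statistics (η population binning, radiality profiles, stick maps).

## Worked example

```python
import polarsmolm as pm

cfg = pm.OpticalConfig()                    # NA_low 1.1 / NA_high 1.3, 130 nm px
scene = pm.make_scene_random_orientations(10, 50, delta_fixed=100.0,
                                          photons=5000.0, seed=1)
stack = pm.render_stack(scene, cfg, pm.NoiseModel(background=10.0), seed=2)
table, report = pm.run_pipeline(stack, cfg)
print(len(table), report["detections"])
```

prints

```
molecules retrieved: 344 / 500
detections per channel: {'I0': 572, 'I90': 565, 'I45': 566, 'I135': 559}
 frame   x_nm   y_nm  intensity_total  eta    xi  delta
     0 6240.7  810.0           1247.5 10.8  76.3  106.1
     0 1297.1 1228.9           1797.8 68.5 124.3  102.6
     0 3931.2 3230.8           1212.6 23.8  25.7  116.7
```

500 molecules were simulated at 5000 photons each (defined before the
channel split and NA reduction) on 10 background photons/pixel; 344 survive
detection in all four channels, pairing and the confidence filter
(5° < η < 88°, 5° < δ < 175°, > 1000 detected photons). Each row is one
molecule: position in nm, summed four-channel intensity, and the retrieved
orientation/wobble in degrees.

The theoretical precision floor and the aperture throughput:

```python
from polarsmolm.crlb import crlb_orientation, background_per_channel
bset = pm.basis_psfs(cfg)
Bc = background_per_channel(10.0, 0.88)     # 10 bg ph/px over the PSF footprint
crlb_orientation((45.0, 0.0, 100.0), bset, 5000.0, Bc)
# sd_eta = 3.2 deg, sd_xi = 3.4 deg, sd_delta = 9.1 deg
pm.collection_fraction(cfg, 1.3, emitter="transverse")
# 0.600  (the NA 1.3 diaphragm keeps 60% of an unpolarized emitter's signal)
```

A command-line interface wraps the same chain
(`polarsmolm simulate / calibrate / register / retrieve / analyze / render`).

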