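# nucleopol

Quantitative analysis of the nanoscale organisation and dynamics of nuclear
proteins, built for the kind of data produced when myosin VI (MVI) and RNA
polymerase II are imaged by single-molecule localisation microscopy (STORM)
and 3D single-particle tracking. The package is aimed at microscopists and
quantitative biologists who have per-molecule coordinate tables (not raw
images) and want reproducible cluster, colocalisation, mobility and
enzyme-kinetics statistics.

## What it computes

**Point-pattern clustering.** For localisations in a nuclear region of
interest, Ripley's K function

    K̂(r) = (A / n(n−1)) · Σᵢ Σ_{j≠i} w᷈ᵢⱼ · 1[dᵢⱼ ≤ r]

with isotropic edge correction, and its linearisation L(r) − r =
√(K̂/π) − r, which is zero under complete spatial randomness and positive
under clustering; the argmax radius summarises the dominant clustering
scale. Clusters themselves are detected by DBSCAN (core point = ≥ MinPts
other molecules within ε, with ε defaulting to the dye's mean localisation
precision and a 10-molecule minimum cluster size), with per-cluster
centroid, molecule count and kernel-density-contour area (7 nm smoothing).

**Coordinate-based colocalisation.** Per-molecule degree-of-colocalisation
(DoC) scores: the Spearman correlation of the two channels' local density
gradients across radii, damped by exp(−d/r_max) with d the distance to the
nearest molecule of the other channel. Scores span [−1, 1]; molecules above
a 0.4 threshold count as colocalised, and clusters are split into
colocalised / non-colocalised subpopulations.

**Anomalous diffusion.** Per-track time-averaged MSD and a log-log fit of
MSD(τ) = 2·d·D·τ^α giving the diffusion constant D and anomalous exponent
α; tracks classify as static (D < 0.1 µm² s⁻¹), diffusive (0.1–5) or
hypermobile (> 5, reported but not quantified further).

**Enzyme kinetics.** Actin-activated ATPase titrations fitted to
Rate = V₀ + k_cat·[A]/(K_actin + [A]) by bounded nonlinear least squares,
and mean-residue-ellipticity conversion for CD spectra.

**Synthetic data.** Thomas-process point patterns, two-channel patterns
with a controllable colocalised fraction, fractional-Brownian-motion track
mixtures and kinetics titrations — all seeded, with ground truth emitted on
a separate stream — so every analysis stage has parameter-recovery
benchmarks without any raw microscopy data.

## Worked example

```python
import nucleopol as npol

roi = npol.rectangle_roi(10_000, 10_000)          # 10 × 10 µm nucleus-scale ROI
spec = npol.PatternSpec(roi=roi, n_clusters=120, molecules_per_cluster=40,
                        cluster_sigma=20, background_fraction=0.15, seed=42)
table, truth = npol.simulate_clustered(spec)      # 5632 localisations

est = npol.RipleyK().fit(table, roi=roi)
print(est.peak_radius_)                           # 100 nm clustering peak

cl = npol.DensityClusterer().fit(table)           # epsilon = mean precision (20 nm)
print(cl.summary_)
# 120 clusters, 29.9 molecules/cluster, mean area 3577 nm², 63.7% clustered

doc = npol.doc_scores(table, table.copy())        # channel vs its own copy
print(doc.percent_A)                              # 100.0 (everything colocalised)
```

The Ripley peak (100 nm) reflects the ~20 nm cluster spread plus 20 nm
localisation jitter; DBSCAN recovers every generated cluster (120/120) but
counts only the molecules inside the ε-dense cores, so the per-cluster
molecule count (29.9) and clustered percentage (63.7%) sit below the
generator's nominal values — the expected behaviour of density-based
detection on Gaussian clusters. Against an exact copy of itself, every
molecule scores DoC ≈ 1 and 100% pass the 0.4 threshold.

Tracking and kinetics work the same way:

```python
spec = npol.TrackSimSpec(n_tracks=100, frames=100,
                         mixture=[(0.5, 0.02, 1.0), (0.5, 0.8, 1.0)], seed=7)
traj, truth = npol.simulate_tracks(spec)
fits = npol.AnomalousDiffusionMSD().fit(traj)
print(fits.summary_)   # mean D 0.45 µm²/s, static fraction 0.47 (truth 0.5)

kin = npol.simulate_atpase(npol.KineticsSimSpec(noise_sd=0.05, seed=3))
print(npol.fit_atpase(kin))  # V0 0.171 s⁻¹, kcat 5.74 s⁻¹, K_actin 12.4 µM
```

A `nucleopol` command-line interface exposes the same stages
(`nucleopol simulate …`, `ripley`, `cluster`, `coloc`, `track-analyze`,
`track-link`, `atpase-fit`, `cd-mrw`, `run`, `compare`); see
`nucleopol --help`.

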