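# polholo

Polarization-interference holography toolkit for birefringent fibrillar
media: it simulates coherent scattering by tissue-like phantoms, records and
demodulates off-axis polarization interferograms, isolates the
single-scattering phase plane, maps polarization azimuth/ellipticity,
extracts scale-selective Mexican-hat wavelet markers, and grades binary
diagnostic accuracy.

## What is in here

| module | role |
| --- | --- |
| `polholo.polarization` | Stokes/Mueller/Jones algebra for linear-birefringence elements; azimuth/ellipticity conversions |
| `polholo.phantom` | seeded fibrillar-tissue phantoms, per-pixel Jones cascades, calibrated depolarized backgrounds, bimodal phase phantoms |
| `polholo.holography` | analyzer-resolved off-axis interferogram synthesis and Fourier-sideband demodulation |
| `polholo.phase_scan` | inter-component phase sections, moment trajectories, single-scattering plane detection |
| `polholo.wavelet` | row-wise Mexican-hat CWT, per-scale Z1/Z2 markers, discriminative-scale selection |
| `polholo.diagnostics` | LOOCV midpoint-threshold classification, Se/Sp/Ac, balanced-accuracy grades |
| `polholo.io`, `polholo.config`, `polholo.pipeline`, `polholo.cli` | formats, run configs, the end-to-end cohort pipeline, and the CLI |

## CLI

Every stage is a subcommand of `polholo` (see `polholo --help`):

```bash
polholo simulate --preset myocardium_aci --seed 7 --size 256 --out run/sim
polholo record --field run/sim/field.npz --carrier 0.25 0.25 --ref-amplitude 6 --out run/igs
polholo reconstruct --in run/igs --out run/rec.npz
polholo scan --field run/rec.npz --dstep 0.0785 --tol 0.05 --out run/scan.json
polholo wavelet --field run/rec.npz --delta-t 6.283 --component beta --scales 2:60 --out run/stats.csv
polholo classify --markers run/markers.csv --marker 'z2@a=15/beta' --out run/report.json
polholo pipeline --seed 0 --out run/cohort     # full 12+12 two-cohort study
```

Presets: `myocardium_chd`, `myocardium_aci`, `lung_ba`, `lung_pf`.

## Conventions

Angles in radians; azimuth in [−π/2, π/2) from the laboratory x-axis,
ellipticity in [−π/4, π/4]; right-circular illumination (1, i)/√2 with Stokes
vector (1, 0, 0, 1); rasters row-major with x = column index; spatial
frequencies in cycles/pixel; default grid 256×256 at 1.1625 µm/pixel.
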