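# trichotrack

Selective cell tracking and motility analysis for protist–bacteria
co-culture time-lapse microscopy.

When a flagellated protist such as *Trichomonas gallinae* is grown with
bacteria, its motility is a sensitive fitness readout — but movies of
co-cultures contain two populations, and only the protist should be
tracked. trichotrack implements the full selective-tracking pipeline as a
tested Python library: segmentation of pixel-classifier probability maps
with a fixed operator chain (subtract 50 → Gaussian σ = 2.0 → global
histogram-minimum threshold → exclude particles with area > 40 px or
circularity < 0.25 → 3-D Gaussian blur σ = 1.0), greedy nearest-neighbour
spot linking, the eight standard per-track motility metrics, ROUT
(FDR-controlled robust) outlier trimming, and nonparametric condition
comparison. Because real co-culture imaging comes without per-cell ground
truth, the package includes a synthetic movie generator — persistent
random walks of fast ellipsoidal flagellates and slow rod-shaped bacteria,
rendered to 8-bit stacks and classifier-style probability maps — on which
every stage is validated against known truth.

For each track with positions p₁..p_N at frames f₁..f_N and steps
dᵢ = ‖pᵢ₊₁ − pᵢ‖, the reported metrics are duration f_N − f₁, mean speed
Σdᵢ/duration, total distance Σdᵢ, maximum distance maxᵢ‖pᵢ − p₁‖,
confinement ratio ‖p_N − p₁‖/Σdᵢ, mean straight-line speed
‖p_N − p₁‖/duration, linearity of forward progression, and mean
directional change rate (mean |turn angle| per second), each in px/frame
and calibrated µm/s units. Condition comparisons use tie-corrected
Kruskal–Wallis tests per timepoint on track speeds, and unpaired t-tests
plus fold change on culture densities.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. `analysis/03_full_study.py` simulates two conditions (monoculture,
flagellate median speed 6.6 µm/s; co-culture, 10.2 µm/s) at four
timepoints in triplicate, then segments, tracks, trims and compares:

```text
$ python analysis/03_full_study.py
1750 tracks across 24 movies (6 ROUT outliers trimmed)
t = 0 h: median speed 10.04 (co) vs 7.01 (mono) um/s, Kruskal-Wallis H = 81.4, p = 1.85e-19
t = 4 h: median speed 11.96 (co) vs 5.84 (mono) um/s, Kruskal-Wallis H = 221.5, p = 4.32e-50
t = 24 h: median speed 10.34 (co) vs 7.22 (mono) um/s, Kruskal-Wallis H = 136.4, p = 1.62e-31
t = 48 h: median speed 10.12 (co) vs 6.44 (mono) um/s, Kruskal-Wallis H = 144.9, p = 2.31e-33
```

Recovered per-timepoint medians scatter around the configured 10.2 and
6.6 µm/s (60 cells per condition-timepoint; sampling spread plus a small
upward fragmentation bias, see `docs/methods.md`), and the two conditions
separate decisively at every timepoint. `analysis/02_segment_and_track.py`
quantifies selectivity — on a stress scene with ten bacteria per
flagellate, 100% of retained particles lie on true flagellates and 0% of
bacteria survive the filters — and `analysis/04_growth_curve_stats.py`
reproduces the density contracts (2.30-fold co-culture excess at 48 h,
t-test p < 0.001 on triplicates).

The same stages are available as a CLI (`trichotrack simulate | segment |
track | metrics | trim | compare | run`) operating on multi-frame 8-bit
TIFF stacks and CSV tables, with a YAML config; `trichotrack run`
executes the full grid and writes a manifest with config hash and output
checksums (two runs with the same config and seed are byte-identical).

## Layout

- `src/trichotrack/` — library: `simulate`, `segmentation`, `tracking`,
  `metrics`, `rout`, `stats`, `evaluate`, `experiments`, `pipeline`, `cli`
- `analysis/01–04_*.py` — narrative drivers writing tables to `results/`
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — model, parameter and design documentation
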