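"""Canonical synthetic study scenarios.

The default scenario mirrors the co-culture motility experiment: two
conditions (monoculture vs co-culture with bacteria) imaged at four
timepoints (0, 4, 24, 48 h) in triplicate.  Configured flagellate median
speeds are 6.6 um/s (monoculture) and 10.2 um/s (co-culture) — the
reported 4 h medians — applied at every timepoint, since co-culture cells
were faster throughout.

Analysis-scale imaging parameters: 384 x 384 px fields at 1.8 um/px
(~0.69 x 0.69 mm), 40 frames at 0.45 s intervals (every fifth frame of the
0.09 s acquisition cadence, so per-frame displacements of ~1-3 px sit well
above centroid localization noise), 20 flagellates and 2 bacteria per
field (protists at ~2.5e5 cells/mL for a ~100 um deep field; 1:10
bacteria-to-protist count ratio).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import SimulationConfig

DEFAULT_CONDITIONS: dict[str, float] = {"monoculture": 6.6, "coculture": 10.2}
DEFAULT_TIMEPOINTS_H: tuple[float, ...] = (0.0, 4.0, 24.0, 48.0)
DEFAULT_REPLICATES = 3

ANALYSIS_BASE = SimulationConfig(
    field_width_px=384, field_height_px=384, n_frames=40,
    pixel_size_um=1.8, frame_interval_s=0.45,
    n_flagellates=20, n_bacteria=2,
)


def child_seed(seed: int, *key: int) -> int:
    """Deterministic per-movie seed below 2**31 derived from the run seed."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def study_grid(seed: int,
               conditions: dict[str, float] | None = None,
               timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H,
               replicates: int = DEFAULT_REPLICATES,
               base: SimulationConfig = ANALYSIS_BASE,
               ) -> list[tuple[str, float, int, SimulationConfig]]:
    """(condition, timepoint_h, replicate, config) for every movie of the study."""
    conditions = dict(conditions or DEFAULT_CONDITIONS)
    grid = []
    for ci, (cond, median) in enumerate(sorted(conditions.items())):
        for ti, tp in enumerate(timepoints_h):
            for rep in range(replicates):
                cfg = replace(
                    base,
                    flagellate_speed_dist=(median, base.flagellate_speed_dist[1]),
                    n_bacteria=base.n_bacteria if cond != "monoculture" else 0,
                    seed=child_seed(seed, ci, ti, rep))
                grid.append((cond, tp, rep, cfg))
    return grid


def selectivity_scene(seed: int, n_flagellates: int = 15,
                      base: SimulationConfig = ANALYSIS_BASE) -> SimulationConfig:
    """Mixed stress scene with ten bacteria per flagellate.

    The culture design has ten protists per bacterium; the selectivity
    check deliberately inverts the ratio so that mis-segmented bacteria
    cannot hide in small numbers.
    """
    return replace(base, n_flagellates=n_flagellates,
                   n_bacteria=10 * n_flagellates,
                   seed=child_seed(seed, 999))


# Hemocytometry-style growth-curve emulation (cells/mL, triplicate).
# Means chosen to reproduce the qualitative course: both conditions seeded
# at 2.5e5 cells/mL; monoculture ahead at 24 h; co-culture ~2.3-fold higher
# at 48 h.
DENSITY_MEANS = {
    "monoculture": {0.0: 2.5e5, 4.0: 3.2e5, 24.0: 9.0e5, 48.0: 1.1e6},
    "coculture": {0.0: 2.5e5, 4.0: 3.0e5, 24.0: 6.5e5, 48.0: 2.53e6},
}
DENSITY_CV = 0.08


def synthetic_densities(seed: int, n_replicates: int = 3,
                        means: dict[str, dict[float, float]] | None = None,
                        cv: float = DENSITY_CV) -> dict[str, dict[float, np.ndarray]]:
    """Triplicate cell-density counts per condition and timepoint."""
    means = means or DENSITY_MEANS
    rng = np.random.default_rng(child_seed(seed, 777))
    out: dict[str, dict[float, np.ndarray]] = {}
    for cond in sorted(means):
        out[cond] = {}
        for tp in sorted(means[cond]):
            mu = means[cond][tp]
            out[cond][tp] = mu * rng.lognormal(0.0, cv, size=n_replicates)
    return out
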