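"""Seeded generators emulating the study's recordings and cell counts.

Everything downstream of the slice rig is emulated statistically so that
the full analysis pipeline runs without any experimental data:

* ``make_sweeps`` — evoked input-output recordings.  Axonal recruitment
  follows a saturating hyperbola of stimulus intensity with a per-slice
  gain factor; the fEPSP slope and the single-cell EPSC are linear in the
  realized fiber volley, with the group effect entering only through the
  EPSC gain (fiber volleys and fEPSPs do not differ between groups, as in
  the recordings the generator emulates).  Noise is multiplicative.
* ``make_event_trains`` — spontaneous/asynchronous EPSC trains as
  homogeneous Poisson processes with lognormal amplitudes.
* ``make_paired_pulses`` — paired-pulse trials around a true depression
  factor.
* ``make_count_pair`` — stereology-like count samples for percent-change
  demonstrations.

All generators require an explicit seed and are fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ephys import SWEEP_COLUMNS, EventTrain
from .params import GAIN_PRESETS, GeneratorConfig

__all__ = [
    "make_sweeps",
    "make_event_trains",
    "make_paired_pulses",
    "make_count_pair",
    "preset_config",
]


def preset_config(preset: str, seed: int, **overrides) -> GeneratorConfig:
    """A GeneratorConfig whose EPSC gains match a named experimental preset.

    Presets: ``control`` (mature control only), ``baxko_im``, ``immature``,
    ``ablated_im``, ``ee``.  Gains are the published overall EPSC/FV ratios
    for the corresponding conditions.
    """
    try:
        gains = GAIN_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; expected one of {sorted(GAIN_PRESETS)}"
        ) from None
    return GeneratorConfig(epsc_gain_by_group=dict(gains), seed=seed, **overrides)


def _noise_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise 1 + cv*z, truncated at 0.1 to keep magnitudes positive."""
    return np.maximum(1.0 + cv * rng.standard_normal(size), 0.1)


def make_sweeps(config: GeneratorConfig) -> pd.DataFrame:
    """Synthesize an evoked-response sweep table.

    For every group, slice and stimulus intensity I the generator draws
    ``sweeps_per_intensity`` sweeps with

        FV    = slice_gain * fv_max * I / (I + fv_half_sat) * noise
        fEPSP = fepsp_gain * FV * noise
        EPSC  = epsc_gain[group] * FV * noise

    and flags a sweep saturated when its FV exceeds
    ``saturation_threshold * fv_max``.  With ``noise_cv=0`` the EPSC/FV
    ratio of every row equals the group gain exactly.
    """
    seed = config.require_seed()
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    intensities = np.asarray(config.intensities, dtype=float)
    n_sweeps = config.sweeps_per_intensity
    n_per_slice = intensities.size * n_sweeps
    for group in sorted(config.epsc_gain_by_group):
        gain = config.epsc_gain_by_group[group]
        for s in range(config.n_slices_per_group):
            slice_gain = max(
                1.0 + config.slice_gain_cv * rng.standard_normal(), 0.1
            )
            stim = np.repeat(intensities, n_sweeps)
            drive = slice_gain * config.fv_max * stim / (stim + config.fv_half_sat)
            fv = drive * _noise_factor(rng, config.noise_cv, n_per_slice)
            fepsp = config.fepsp_gain * fv * _noise_factor(
                rng, config.noise_cv, n_per_slice
            )
            epsc = gain * fv * _noise_factor(rng, config.noise_cv, n_per_slice)
            rows.append(
                pd.DataFrame(
                    {
                        "slice_id": f"{group}-s{s:02d}",
                        "group": group,
                        "cell_id": f"{group}-c{s:02d}",
                        "stimulus_v": stim,
                        "fv_uv": fv,
                        "fepsp_slope": fepsp,
                        "epsc_pa": epsc,
                        "saturated": fv > config.saturation_threshold * config.fv_max,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)[list(SWEEP_COLUMNS)]


def make_event_trains(
    config: GeneratorConfig,
    n_cells: int,
    duration: float,
    group: str = "control",
) -> list[EventTrain]:
    """Homogeneous Poisson event trains with lognormal amplitudes.

    Each cell's event count is Poisson(rate * duration); event times are
    uniform on [0, duration) and sorted; amplitudes are lognormal with
    log-median ``event_amp_mu`` and log-sd ``event_amp_sigma``.
    """
    if duration <= 0:
        raise ValueError("duration must be strictly positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    try:
        rate = config.event_rate_by_group[group]
    except KeyError:
        raise ValueError(f"no event rate configured for group {group!r}") from None
    rng = np.random.default_rng(config.require_seed())
    trains = []
    for c in range(n_cells):
        n = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration, n))
        amps = rng.lognormal(config.event_amp_mu, config.event_amp_sigma, n)
        trains.append(
            EventTrain(cell_id=f"{group}-e{c:02d}", duration=duration,
                       times=times, amplitudes=amps)
        )
    return trains


def make_paired_pulses(
    config: GeneratorConfig, n_trials: int, amp1_mean: float = 100.0
) -> pd.DataFrame:
    """Paired-pulse trials: amp2 = ppr_true * amp1 up to multiplicative noise."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(config.require_seed())
    amp1 = amp1_mean * _noise_factor(rng, config.noise_cv, n_trials)
    amp2 = config.ppr_true * amp1 * _noise_factor(rng, config.noise_cv, n_trials)
    return pd.DataFrame({"amp1_pa": amp1, "amp2_pa": amp2})


def make_count_pair(
    mean_ref: float,
    mean_test: float,
    cv: float,
    n: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two samples of rounded normal counts around reference and test means.

    Emulates per-animal stereological cell counts (sd = cv * mean) for
    percent-change demonstrations.  With ``cv=0`` every draw equals its
    mean exactly.
    """
    if mean_ref <= 0 or mean_test <= 0:
        raise ValueError("means must be strictly positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    ref = np.round(rng.normal(mean_ref, cv * mean_ref, n)).astype(int)
    test = np.round(rng.normal(mean_test, cv * mean_test, n)).astype(int)
    return ref, test
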