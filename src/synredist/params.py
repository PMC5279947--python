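"""Parameter containers for the redistribution model and the synthetic-data generator.

Both containers are plain dataclasses with eager validation; they are the
single source of default values for the whole package.  Defaults of
:class:`ModelParams` encode the published parameterization of the dentate
granule-cell network: ~200,000 granule cells per hemisphere, 95% of them
mature with 100 synapses each, an integration curve fitted to evoked-EPSC
amplitudes of adult-born cells at progressive ages, a power-law decline of
progenitor proliferation, and survival rates of 20% (wild type) versus 70%
(Bax-deleted lineage, effective from day 14).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = ["ModelParams", "GeneratorConfig", "CONTROL", "BAX_KO", "CONDITIONS"]

CONTROL = "control"
BAX_KO = "bax_ko"
CONDITIONS = (CONTROL, BAX_KO)


def _fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def _reject_unknown(cls, mapping: Mapping[str, Any]) -> None:
    unknown = set(mapping) - _fields(cls)
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} key(s): {', '.join(sorted(unknown))}"
        )


@dataclass(frozen=True)
class ModelParams:
    """Constants of the deterministic synapse-redistribution simulation.

    Attributes
    ----------
    total_cells
        Granule cells in one dentate gyrus at t=0.
    mature_fraction
        Fraction of those cells that are mature (>8 weeks old).
    synapses_per_mature_cell
        Synapses held by one fully mature cell; defines 100% strength.
    strength_slope, strength_intercept, strength_age_offset
        Coefficients of the integration curve
        Y(d) = slope * ln(age_offset + d) - intercept, in percent of the
        mature synapse complement, clamped to [0, 100].
    maturation_span
        Days from integration onset to full maturity (43 d); also the
        number of distinct strengths in the pre-existing immature pool.
    prolif_scale, prolif_age_offset, prolif_exponent
        Progenitor proliferation P(t) = scale * (age_offset + t)**exponent,
        cells per day.
    survival_wt, survival_ko
        Fraction of newborn cells that survive to integrate, wild type vs
        Bax-deleted lineage.
    ko_onset_day
        First simulation day on which Bax-deleted cells incorporate
        (recombination-to-integration lag, 14 d).
    ko_strength_factor
        Multiplier on per-cell synapse number for Bax-deleted cohorts
        (impaired pruning leaves ~35% more synapses).
    horizon
        Last simulated day (inclusive); must not exceed maturation_span so
        no cohort matures within the window.
    include_baseline_in_numerator
        If True, the pre-existing immature synapse pool counts toward the
        immature share; the literal published formula (False) counts only
        newly appropriated synapses.
    """

    total_cells: float = 200_000.0
    mature_fraction: float = 0.95
    synapses_per_mature_cell: float = 100.0
    strength_slope: float = 71.1
    strength_intercept: float = 187.7
    strength_age_offset: float = 14.0
    maturation_span: int = 43
    prolif_scale: float = 4.0e6
    prolif_age_offset: float = 42.0
    prolif_exponent: float = -1.5
    survival_wt: float = 0.20
    survival_ko: float = 0.70
    ko_onset_day: int = 14
    ko_strength_factor: float = 1.35
    horizon: int = 43
    include_baseline_in_numerator: bool = False

    def __post_init__(self) -> None:
        for name in ("mature_fraction", "survival_wt", "survival_ko"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "total_cells",
            "synapses_per_mature_cell",
            "strength_age_offset",
            "prolif_scale",
            "prolif_age_offset",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("maturation_span", "ko_onset_day", "horizon"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.ko_strength_factor < 1.0:
            raise ValueError("ko_strength_factor must be >= 1")
        if self.horizon > self.maturation_span:
            # cohorts must never mature inside the simulated window
            raise ValueError(
                "horizon must not exceed maturation_span "
                f"({self.horizon} > {self.maturation_span})"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ModelParams":
        """Build params from a flat key-value mapping; unknown keys raise."""
        _reject_unknown(cls, mapping)
        return cls(**dict(mapping))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)


#: EPSC/FV gain presets (pA/uV), one per experimental condition, taken from
#: the published overall ratios: mature control 2.44, immature control 1.24,
#: Bax-deleted immature 1.59, ablated-neurogenesis mature 3.7 (control 2.2),
#: enriched-environment mature 2.6 (control 1.6).
GAIN_PRESETS: dict[str, dict[str, float]] = {
    "control": {"control": 2.44},
    "baxko_im": {"control": 2.44, "baxko_im": 1.6},
    "immature": {"control": 1.24, "baxko_im": 1.59},
    "ablated_im": {"control": 2.2, "ablated_im": 3.7},
    "ee": {"control": 1.6, "ee": 2.6},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the seeded synthetic-recording generator.

    The generator emulates the statistical structure of simultaneous
    field/whole-cell recordings: a saturating fiber-volley input-output
    curve per slice, linear fEPSP-slope and EPSC responses proportional to
    the realized fiber volley with group-specific EPSC gain, multiplicative
    noise, saturation at high intensity, and Poisson event trains with
    lognormal amplitudes.
    """

    n_slices_per_group: int = 15
    intensities: tuple[float, ...] = (5, 10, 15, 20, 30, 40, 60, 80, 100)
    sweeps_per_intensity: int = 10
    fv_max: float = 400.0            # uV, asymptotic fiber-volley amplitude
    fv_half_sat: float = 20.0        # V, intensity at half-maximal FV
    slice_gain_cv: float = 0.2       # between-slice gain variability
    fepsp_gain: float = 0.01         # slope units per uV of FV
    epsc_gain_by_group: Mapping[str, float] = field(
        default_factory=lambda: dict(GAIN_PRESETS["control"])
    )
    noise_cv: float = 0.15           # multiplicative noise CV on each measure
    saturation_threshold: float = 0.9  # fraction of fv_max flagged saturated
    ppr_true: float = 0.9            # mildly depressing paired-pulse ratio
    event_rate_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.5}
    )
    event_amp_mu: float = 3.0        # lognormal log-median (~20 pA)
    event_amp_sigma: float = 0.4
    seed: int | None = None          # mandatory at generation time

    def __post_init__(self) -> None:
        if self.n_slices_per_group < 1:
            raise ValueError("n_slices_per_group must be >= 1")
        if self.sweeps_per_intensity < 1:
            raise ValueError("sweeps_per_intensity must be >= 1")
        if not self.intensities:
            raise ValueError("intensities must be non-empty")
        if any(i < 0 or i > 100 for i in self.intensities):
            raise ValueError("stimulus intensities must lie in [0, 100] V")
        for name in ("fv_max", "fv_half_sat", "fepsp_gain", "event_amp_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("slice_gain_cv", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.saturation_threshold <= 1:
            raise ValueError("saturation_threshold must be in (0, 1]")
        if any(g <= 0 for g in self.epsc_gain_by_group.values()):
            raise ValueError("EPSC gains must be strictly positive")
        if any(r < 0 for r in self.event_rate_by_group.values()):
            raise ValueError("event rates must be non-negative")
        if self.ppr_true <= 0:
            raise ValueError("ppr_true must be strictly positive")
        object.__setattr__(self, "intensities", tuple(self.intensities))
        object.__setattr__(
            self, "epsc_gain_by_group", dict(self.epsc_gain_by_group)
        )
        object.__setattr__(
            self, "event_rate_by_group", dict(self.event_rate_by_group)
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "GeneratorConfig":
        _reject_unknown(cls, mapping)
        return cls(**dict(mapping))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["intensities"] = list(self.intensities)
        d["epsc_gain_by_group"] = dict(self.epsc_gain_by_group)
        d["event_rate_by_group"] = dict(self.event_rate_by_group)
        return d

    def replace(self, **changes: Any) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("GeneratorConfig.seed must be set (no implicit entropy)")
        return int(self.seed)
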