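"""Seeded synthetic-data generators for cores, incubations, and ASV tables.

Each generator is a pure function of (scenario, seed) and returns its dataset
together with a *truth record* — the noise-free curves and parameters needed
to score downstream estimators (onset depth, release day, guild ramp) without
peeking at generator internals. A single root seed is split into independent
per-stream sub-seeds, so adding a noise stream never perturbs the others.

The default scenarios emulate an organic-rich coastal sediment setting:
two ~42 cm cores sectioned at 2 cm where methane stays near zero until
~32-34 cmbsf and then rises toward saturation (1.5 mM) while sulfate is
still at 6-8 mM (declining exponentially toward a ~5 mM floor) and sulfide
grows as sulfate is consumed; porosity drifts from 0.85 down to 0.70.
Incubation scenarios have BES-free controls rising to ~1,500 ppm CH4 by day
28 (or ~6,750 ppm by day 35 for the long preset) while treated vials stay
flat until an inhibition-release day, with the delta-13C decline lagging the
methane rise by ~20 days. Community scenarios ramp the methanogen/ANME guild
from ~0.6% to ~2% of reads across the methane onset depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from smtzkit.io import (
    ASVTable,
    DepthProfile,
    GuildDefinition,
    IncubationSeries,
    TaxonomyTable,
    TAXONOMY_RANKS,
)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent generators derived from one root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# sediment cores
# ---------------------------------------------------------------------------


@dataclass
class CoreScenario:
    """Parameters of a synthetic core profile (2-cm section resolution)."""

    core_id: str = "core1"
    n_sections: int = 21
    so4_surface_mM: float = 25.0
    so4_floor_mM: float = 5.0
    so4_decay_per_cm: float = 0.09
    sulfide_yield: float = 0.8  # mol sulfide per mol sulfate consumed
    ch4_onset_cmbsf: float = 32.0
    ch4_slope_mM_per_cm: float = 0.15
    ch4_saturation_mM: float = 1.5
    profile_style: str = "clb_linear"  # or "aom_sigmoidal"
    sigmoid_width_cm: float = 3.0
    porosity_top: float = 0.85
    porosity_bottom: float = 0.70
    ch4_noise_sd_mM: float = 0.02
    so4_noise_sd_mM: float = 0.3
    h2s_noise_sd_uM: float = 50.0
    porosity_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_style not in ("clb_linear", "aom_sigmoidal"):
            raise ValueError(f"unknown profile_style {self.profile_style!r}")
        if self.ch4_saturation_mM <= 0:
            raise ValueError("saturation must be positive")
        max_depth = 2.0 * self.n_sections
        if not (0 < self.ch4_onset_cmbsf < max_depth):
            raise ValueError("onset must lie within the core")
        for name in ("ch4_noise_sd_mM", "so4_noise_sd_mM", "h2s_noise_sd_uM", "porosity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def core_curves(s: CoreScenario) -> dict[str, np.ndarray]:
    """Noise-free closed-form curves at the section midpoints."""
    depth = 2.0 * np.arange(s.n_sections) + 1.0  # midpoints of 2-cm sections
    so4 = s.so4_floor_mM + (s.so4_surface_mM - s.so4_floor_mM) * np.exp(
        -s.so4_decay_per_cm * depth
    )
    h2s = s.sulfide_yield * (s.so4_surface_mM - so4) * 1000.0  # mM loss -> uM
    if s.profile_style == "clb_linear":
        ch4 = np.clip(
            s.ch4_slope_mM_per_cm * (depth - s.ch4_onset_cmbsf),
            0.0,
            s.ch4_saturation_mM,
        )
    else:  # sigmoidal rise: concave up above the inflection, concave down below
        midpoint = s.ch4_onset_cmbsf + 3.0 * s.sigmoid_width_cm
        ch4 = s.ch4_saturation_mM / (
            1.0 + np.exp(-(depth - midpoint) / s.sigmoid_width_cm)
        )
    porosity = s.porosity_top + (s.porosity_bottom - s.porosity_top) * (
        depth / depth[-1]
    )
    return {"depth": depth, "so4": so4, "h2s": h2s, "ch4": ch4, "porosity": porosity}


def generate_core(s: CoreScenario) -> tuple[DepthProfile, dict]:
    """Simulate one core; returns (profile, truth record).

    Gaussian noise is added per analyte and truncated at zero (porosity also
    clipped into (0, 1)); with all noise SDs zero the output equals the
    closed-form curves exactly.
    """
    curves = core_curves(s)
    rng_ch4, rng_so4, rng_h2s, rng_por = _rngs(s.seed, 4)
    n = s.n_sections
    ch4 = np.maximum(curves["ch4"] + rng_ch4.normal(0, s.ch4_noise_sd_mM, n), 0.0)
    so4 = np.maximum(curves["so4"] + rng_so4.normal(0, s.so4_noise_sd_mM, n), 0.0)
    h2s = np.maximum(curves["h2s"] + rng_h2s.normal(0, s.h2s_noise_sd_uM, n), 0.0)
    por = np.clip(
        curves["porosity"] + rng_por.normal(0, s.porosity_noise_sd, n),
        1e-6,
        1 - 1e-6,
    )
    profile = DepthProfile(
        pd.DataFrame(
            {
                "core_id": s.core_id,
                "depth_cmbsf": curves["depth"],
                "ch4_mM": ch4,
                "so4_mM": so4,
                "h2s_uM": h2s,
                "porosity": por,
            }
        )
    )
    truth = {
        "scenario": s,
        "onset_cmbsf": s.ch4_onset_cmbsf,
        "so4_at_onset_mM": float(
            np.interp(s.ch4_onset_cmbsf, curves["depth"], curves["so4"])
        ),
        "curves": curves,
    }
    return profile, truth


def clb_preset(seed: int = 0, core_id: str = "core1", onset: float = 32.0) -> CoreScenario:
    """Linear methanocline, sulfate floored near 5 mM: methane saturates while
    sulfate is still millimolar, so there is no equimolar crossing."""
    return CoreScenario(core_id=core_id, ch4_onset_cmbsf=onset, seed=seed)


def aom_preset(seed: int = 0, core_id: str = "core1") -> CoreScenario:
    """Canonical SMTZ: sulfate drawn down toward zero and a sigmoidal
    methanocline whose observed portion is mostly concave-up, producing an
    equimolar CH4/SO4 crossing."""
    return CoreScenario(
        core_id=core_id,
        profile_style="aom_sigmoidal",
        ch4_onset_cmbsf=28.0,
        sigmoid_width_cm=4.0,
        so4_floor_mM=0.2,
        so4_decay_per_cm=0.12,
        ch4_noise_sd_mM=0.005,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# incubations
# ---------------------------------------------------------------------------


@dataclass
class IncubationScenario:
    """Parameters of a BES-inhibition incubation experiment."""

    n_control: int = 3
    n_treated_per_dose: int = 7
    doses_mM: tuple[float, ...] = (20.0, 30.0)
    sampling_days: tuple[float, ...] = (
        0, 3, 7, 10, 14, 17, 21, 24, 28, 31, 35, 38, 42, 45, 49, 52, 56,
    )
    control_lag_days: float = 0.0
    ch4_target_ppm: float = 1500.0
    ch4_target_day: float = 28.0
    baseline_ch4_ppm: float = 10.0
    release_day: float = 30.0
    co2_rate_ppm_per_day: float = 100.0
    d13c_baseline_permil: float = -50.0
    d13c_decline_permil_per_day: float = 2.0
    isotope_lag_days: float = 20.0
    ch4_noise_sd_ppm: float = 20.0
    co2_noise_sd_ppm: float = 50.0
    d13c_noise_sd_permil: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_treated_per_dose < 2:
            raise ValueError("need >= 2 replicates per group")
        if not (self.sampling_days[0] <= self.release_day <= self.sampling_days[-1]):
            raise ValueError("release_day must fall within the sampling range")

    @property
    def ch4_rate_ppm_per_day(self) -> float:
        return (self.ch4_target_ppm - self.baseline_ch4_ppm) / (
            self.ch4_target_day - self.control_lag_days
        )


def experiment1_preset(seed: int = 0) -> IncubationScenario:
    """Short incubation: 3 controls rising to ~1,500 ppm by day 28; 7+7 vials
    at 20 and 30 mM BES flat until release around day 30."""
    return IncubationScenario(seed=seed)


def experiment2_preset(seed: int = 0) -> IncubationScenario:
    """Long incubation: controls rising to ~6,750 ppm by day 35; 20 mM BES
    only, 3 treated and 2 controls per depth layer."""
    return IncubationScenario(
        n_control=2,
        n_treated_per_dose=3,
        doses_mM=(20.0,),
        ch4_target_ppm=6750.0,
        ch4_target_day=35.0,
        release_day=25.0,
        sampling_days=(0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60),
        seed=seed,
    )


def incubation_curves(
    s: IncubationScenario, rise_start: float
) -> dict[str, np.ndarray]:
    """Noise-free vial trajectories for a given CH4 rise-start day."""
    t = np.asarray(s.sampling_days, float)
    ch4 = s.baseline_ch4_ppm + s.ch4_rate_ppm_per_day * np.maximum(
        t - rise_start, 0.0
    )
    co2 = s.co2_rate_ppm_per_day * t
    iso_start = rise_start + s.isotope_lag_days
    d13c = s.d13c_baseline_permil - s.d13c_decline_permil_per_day * np.maximum(
        t - iso_start, 0.0
    )
    return {"day": t, "ch4": ch4, "co2": co2, "d13c": d13c}


def generate_incubation(
    s: IncubationScenario,
) -> tuple[list[IncubationSeries], dict]:
    """Simulate all vials of an incubation experiment.

    Controls start producing methane at ``control_lag_days``; treated vials
    stay at baseline until ``release_day`` and then rise at the same rate.
    CO2 rises identically in all vials (BES does not suppress heterotrophy),
    and delta-13C declines ``isotope_lag_days`` after each vial's methane
    rise begins.
    """
    n_vials = s.n_control + s.n_treated_per_dose * len(s.doses_mM)
    rngs = _rngs(s.seed, 3 * n_vials)
    series: list[IncubationSeries] = []
    truth_vials = {}
    idx = 0

    def make_vial(vial_id: str, dose: float, rise_start: float) -> None:
        nonlocal idx
        curves = incubation_curves(s, rise_start)
        r_ch4, r_co2, r_iso = rngs[3 * idx : 3 * idx + 3]
        n = len(curves["day"])
        ch4 = np.maximum(
            curves["ch4"] + r_ch4.normal(0, s.ch4_noise_sd_ppm, n),
            0.0,
        )
        co2 = np.maximum(
            curves["co2"] + r_co2.normal(0, s.co2_noise_sd_ppm, n),
            0.0,
        )
        d13c = curves["d13c"] + r_iso.normal(0, s.d13c_noise_sd_permil, n)
        series.append(
            IncubationSeries(vial_id, dose, curves["day"], ch4, co2, d13c)
        )
        truth_vials[vial_id] = {
            "dose_mM": dose,
            "rise_start_day": rise_start,
            "isotope_onset_day": rise_start + s.isotope_lag_days,
        }
        idx += 1

    for i in range(s.n_control):
        make_vial(f"ctrl{i + 1}", 0.0, s.control_lag_days)
    for dose in s.doses_mM:
        for i in range(s.n_treated_per_dose):
            make_vial(f"bes{int(dose)}_{i + 1}", dose, s.release_day)
    truth = {
        "scenario": s,
        "release_day": s.release_day,
        "isotope_lag_days": s.isotope_lag_days,
        "control_rate_ppm_per_day": s.ch4_rate_ppm_per_day,
        "vials": truth_vials,
    }
    return series, truth


# ---------------------------------------------------------------------------
# ASV community tables
# ---------------------------------------------------------------------------

#: Taxonomy templates for synthetic ASVs, keyed by guild role.
_TAX_TEMPLATES = {
    "methanogen": [
        ("Archaea", "Halobacterota", "Methanosarcinia", "ANME-1", "ANME-1b", "ANME-1b"),
        ("Archaea", "Halobacterota", "Methanosarcinia", "Methanosarciniales", "Methanosaetaceae", "Methanosaeta"),
        ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales", "Methanomicrobiaceae", "Methanogenium"),
        ("Archaea", "Thermoplasmatota", "Thermoplasmata", "Methanomassiliicoccales", None, None),
        ("Archaea", "Halobacterota", "Methanofastidiosia", "Methanofastidiosales", None, None),
    ],
    "srb": [
        ("Bacteria", "Desulfobacterota", "Desulfobacteria", "Desulfatiglandales", "Desulfatiglandaceae", "Desulfatiglans"),
        ("Bacteria", "Desulfobacterota", "Desulfobacteria", "Desulfobacterales", "Desulfosarcinaceae", "SEEP-SRB1"),
        ("Bacteria", "Desulfobacterota", "Desulfobacteria", "Desulfobacterales", "Desulfosarcinaceae", "Sva0081 sediment group"),
    ],
    "other": [
        ("Bacteria", "Chloroflexi", "Anaerolineae", "Anaerolineales", "Anaerolineaceae", None),
        ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", None, None),
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Steroidobacterales", "Woeseiaceae", "Woeseia"),
        ("Archaea", "Crenarchaeota", "Bathyarchaeia", None, None, None),
        ("Bacteria", "Planctomycetota", "Phycisphaerae", None, None, None),
    ],
}


@dataclass
class CommunityScenario:
    """Parameters of a synthetic ASV table tied to core depths.

    The methanogen/ANME guild fraction follows a logistic ramp in depth from
    ``guild_floor`` to ``guild_ceiling`` with midpoint at the methane onset;
    sulfate reducers hold a constant expected share. Counts are
    Dirichlet-multinomial around the expected composition.
    """

    n_asvs: int = 300
    n_methanogen_asvs: int = 20
    n_srb_asvs: int = 30
    guild_floor: float = 0.006
    guild_ceiling: float = 0.020
    ramp_width_cm: float = 2.0
    srb_fraction: float = 0.07
    reads_per_sample: int = 130_000
    dirichlet_concentration: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_methanogen_asvs + self.n_srb_asvs >= self.n_asvs:
            raise ValueError("guild ASVs must leave room for background taxa")
        if not (0 < self.guild_floor < self.guild_ceiling < 1):
            raise ValueError("need 0 < floor < ceiling < 1")
        if self.guild_ceiling + self.srb_fraction >= 1:
            raise ValueError("guild fractions must sum below 1")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")


def expected_guild_fraction(
    s: CommunityScenario, depth: np.ndarray, onset_cmbsf: float
) -> np.ndarray:
    """Programmed methanogen-guild fraction at each depth (logistic ramp)."""
    depth = np.asarray(depth, float)
    return s.guild_floor + (s.guild_ceiling - s.guild_floor) / (
        1.0 + np.exp(-(depth - onset_cmbsf) / s.ramp_width_cm)
    )


def generate_asv_table(
    s: CommunityScenario,
    depths: np.ndarray,
    onset_cmbsf: float = 32.0,
    core_id: str = "core1",
) -> tuple[ASVTable, TaxonomyTable, dict]:
    """Simulate an ASV count table for samples at the given depths.

    Within-guild weights are drawn once per table; per-sample compositions
    are Dirichlet-multinomial around the expected guild split. Taxonomy rows
    carry guild-consistent rank assignments so the shipped default guild
    definitions recover the programmed structure.
    """
    depths = np.asarray(depths, float)
    rng_w, rng_counts = _rngs(s.seed, 2)
    n_other = s.n_asvs - s.n_methanogen_asvs - s.n_srb_asvs
    roles = (
        ["methanogen"] * s.n_methanogen_asvs
        + ["srb"] * s.n_srb_asvs
        + ["other"] * n_other
    )
    asv_ids = [f"ASV{i + 1:04d}" for i in range(s.n_asvs)]
    tax_rows = []
    for i, role in enumerate(roles):
        template = _TAX_TEMPLATES[role][i % len(_TAX_TEMPLATES[role])]
        tax_rows.append(template)
    taxonomy = TaxonomyTable(
        pd.DataFrame(tax_rows, columns=TAXONOMY_RANKS, index=asv_ids)
    )

    # fixed within-guild weights (Dirichlet(1) once per table)
    weights = {
        role: rng_w.dirichlet(np.ones(n))
        for role, n in (
            ("methanogen", s.n_methanogen_asvs),
            ("srb", s.n_srb_asvs),
            ("other", n_other),
        )
    }
    meth_frac = expected_guild_fraction(s, depths, onset_cmbsf)
    counts = np.zeros((len(depths), s.n_asvs), dtype=np.int64)
    for j, mf in enumerate(meth_frac):
        p = np.concatenate(
            [
                mf * weights["methanogen"],
                s.srb_fraction * weights["srb"],
                (1.0 - mf - s.srb_fraction) * weights["other"],
            ]
        )
        alpha = s.dirichlet_concentration * p
        p_sample = rng_counts.dirichlet(alpha)
        counts[j] = rng_counts.multinomial(s.reads_per_sample, p_sample)
    sample_ids = [f"{core_id}_d{int(round(d)):02d}" for d in depths]
    table = ASVTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=asv_ids),
        sample_metadata=pd.DataFrame(
            {"core_id": core_id, "depth_cmbsf": depths}, index=sample_ids
        ),
    )
    truth = {
        "scenario": s,
        "onset_cmbsf": onset_cmbsf,
        "depths": depths,
        "expected_methanogen_fraction": meth_frac,
        "expected_srb_fraction": np.full(len(depths), s.srb_fraction),
    }
    return table, taxonomy, truth


def default_guilds() -> GuildDefinition:
    """The shipped guild definitions (methane-cycling archaea and sulfate
    reducers) used by both the generators and the analysis defaults."""
    from smtzkit.io import DEFAULT_GUILDS

    return replace(DEFAULT_GUILDS)
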