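"""Analysis of methanogenesis-inhibitor (BES) incubation time series.

BES (2-bromoethanesulfonic acid) blocks the methyl-coenzyme M reductase
enzyme shared by methanogenesis and AOM. In whole-sediment incubations,
biotic methane production shows up as headspace CH4 rising in BES-free
controls while BES-amended vials stay flat — until the inhibitor loses
potency and the treated vials release. The functions here quantify that
story: per-vial production rates, control-vs-treated significance tests,
release-day detection, and the onset of the 13C-depletion that marks
isotopically fractionating methanogenesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from smtzkit.io import IncubationSeries


@dataclass
class RateEstimate:
    vial_id: str
    window: tuple[float, float]
    rate: float  # ppm/day
    intercept: float  # ppm
    r_squared: float


@dataclass
class InhibitionTest:
    n_control: int
    n_treated: int
    mean_difference: float  # control minus treated, ppm or ppm/day
    t_value: float
    df: float
    p_value: float
    basis: str  # "endpoint_concentration" or "rate"
    variant: str  # "welch" or "pooled"


@dataclass
class ReleaseEvent:
    vial_id: str
    release_day: float | None

    @property
    def released(self) -> bool:
        return self.release_day is not None


def production_rate(
    series: IncubationSeries,
    analyte: str = "ch4",
    window: tuple[float, float] | None = None,
) -> RateEstimate:
    """OLS slope of headspace concentration (ppm) vs day over a time window.

    ``analyte`` is ``"ch4"`` or ``"co2"``; the window defaults to the full
    observed range. Needs at least 3 timepoints in the window.
    """
    if analyte not in ("ch4", "co2"):
        raise ValueError("analyte must be 'ch4' or 'co2'")
    y_all = series.ch4_ppm if analyte == "ch4" else series.co2_ppm
    if window is None:
        window = (float(series.day[0]), float(series.day[-1]))
    mask = (series.day >= window[0]) & (series.day <= window[1])
    t, y = series.day[mask], y_all[mask]
    if t.size < 3:
        raise ValueError(
            f"vial {series.vial_id}: need >= 3 timepoints in window {window}, got {t.size}"
        )
    res = stats.linregress(t, y)
    return RateEstimate(
        vial_id=series.vial_id,
        window=window,
        rate=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2) if np.std(y) > 0 else 1.0,
    )


def _value_at_day(series: IncubationSeries, day: float) -> float:
    if day < series.day[0] or day > series.day[-1]:
        raise ValueError(
            f"vial {series.vial_id}: day {day} outside observed range "
            f"[{series.day[0]}, {series.day[-1]}]"
        )
    return float(np.interp(day, series.day, series.ch4_ppm))


def inhibition_test(
    controls: Sequence[IncubationSeries],
    treated: Sequence[IncubationSeries],
    day: float,
    basis: str = "endpoint_concentration",
    variant: str = "welch",
) -> InhibitionTest:
    """Two-tailed two-sample t-test of controls vs BES-treated vials.

    ``basis="endpoint_concentration"`` compares headspace CH4 interpolated to
    the given day; ``basis="rate"`` compares per-vial production rates fitted
    from day 0 to that day. The Welch (unequal-variance) variant is the
    default; the pooled-variance variant is available for comparison with
    studies that report it. Each group needs at least 2 vials.
    """
    if basis not in ("endpoint_concentration", "rate"):
        raise ValueError("basis must be 'endpoint_concentration' or 'rate'")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if len(controls) < 2 or len(treated) < 2:
        raise ValueError("each group needs >= 2 vials")
    if basis == "endpoint_concentration":
        a = np.array([_value_at_day(s, day) for s in controls])
        b = np.array([_value_at_day(s, day) for s in treated])
    else:
        a = np.array(
            [production_rate(s, "ch4", (0.0, day)).rate for s in controls]
        )
        b = np.array(
            [production_rate(s, "ch4", (0.0, day)).rate for s in treated]
        )
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return InhibitionTest(
        n_control=len(a),
        n_treated=len(b),
        mean_difference=float(a.mean() - b.mean()),
        t_value=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        basis=basis,
        variant=variant,
    )


def detect_release(
    series: IncubationSeries,
    baseline_window: tuple[float, float] | None = None,
    n_baseline: int = 3,
    sd_multiplier: float = 3.0,
    min_rise_ppm: float = 1.0,
) -> ReleaseEvent:
    """First day a BES-treated vial escapes inhibition.

    The baseline is the mean and SD of CH4 over ``baseline_window`` (default:
    the first ``n_baseline`` observations). The release day is the first
    observation where CH4 exceeds ``mean + sd_multiplier * SD`` (but by at
    least ``min_rise_ppm``, so a zero-noise flat baseline does not trigger on
    rounding) and stays above that level for every later observation. Returns
    an absent event if the series never escapes. Never fires inside the
    baseline window, and is invariant to shifting all values by a constant.
    """
    if baseline_window is None:
        if len(series) < n_baseline:
            raise ValueError("need at least the baseline observations")
        base_mask = np.zeros(len(series), bool)
        base_mask[:n_baseline] = True
    else:
        base_mask = (series.day >= baseline_window[0]) & (
            series.day <= baseline_window[1]
        )
    base = series.ch4_ppm[base_mask]
    if base.size < 3:
        raise ValueError("need >= 3 baseline points")
    thresh = base.mean() + max(
        sd_multiplier * base.std(ddof=1), min_rise_ppm
    )
    last_base_day = series.day[base_mask][-1]
    above = series.ch4_ppm > thresh
    for i in range(len(series)):
        if series.day[i] <= last_base_day:
            continue
        if np.all(above[i:]):
            return ReleaseEvent(series.vial_id, float(series.day[i]))
    return ReleaseEvent(series.vial_id, None)


def isotope_shift_onset(
    series: IncubationSeries,
    min_drop_permil: float = 5.0,
    min_sustained: int = 2,
    min_step_permil: float = 2.0,
) -> float | None:
    """Day on which a sustained decline in delta-13C of methane begins.

    Finds the first observation that starts a monotone decrease sustained
    over at least ``min_sustained`` subsequent observations with a total drop
    of at least ``min_drop_permil`` per-mil. The very first step must fall by
    at least ``min_step_permil`` so that instrument noise on the flat baseline
    cannot pull the detected onset earlier. Methanogenesis discriminates
    against 13C, so the onset marks the point where isotopically light
    methane starts to dominate the headspace. Returns None if no qualifying
    decline exists.
    """
    y = series.d13ch4_permil
    finite = np.isfinite(y)
    days = series.day[finite]
    y = y[finite]
    if y.size < 4:
        raise ValueError("need >= 4 delta-13C observations")
    n = y.size
    for i in range(n - min_sustained):
        if y[i] - y[i + 1] < min_step_permil:
            continue
        j = i + 1
        while j + 1 < n and y[j + 1] < y[j]:
            j += 1
        if j - i >= min_sustained and (y[i] - y[j]) >= min_drop_permil:
            return float(days[i])
    return None


def group_by_treatment(
    series: Iterable[IncubationSeries],
) -> dict[float, list[IncubationSeries]]:
    """Split vials into dose groups keyed by BES concentration (mM)."""
    out: dict[float, list[IncubationSeries]] = {}
    for s in series:
        out.setdefault(s.treatment_bes_mM, []).append(s)
    return dict(sorted(out.items()))
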