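"""Depth-profile diagnostics for sediment cores.

Answers the four questions a porewater geochemist asks of a methane/sulfate
profile:

* where does methane start to accumulate (the onset depth), and how much
  sulfate is left there?
* is the methanocline concave-up (the net-AOM signature), linear, or
  concave-down?
* is there an equimolar CH4/SO4 crossing (a canonical SMTZ)?
* how strongly do two downcore quantities co-vary (OLS with slope t-test)?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from smtzkit.io import DepthProfile


@dataclass
class OnsetResult:
    """Methane onset depth with linearly interpolated sulfate at that depth.

    ``onset_depth_cmbsf`` is None when no depth qualifies (e.g. methane stays
    below threshold throughout the core).
    """

    onset_depth_cmbsf: float | None
    so4_at_onset_mM: float | None
    threshold_mM: float

    @property
    def present(self) -> bool:
        return self.onset_depth_cmbsf is not None


@dataclass
class ConcavityResult:
    """Second-derivative diagnostics of the methanocline.

    ``second_differences`` holds a three-point second-derivative estimate
    (mM/cm^2) at each interior depth of the analyzed window; on a uniform
    grid of spacing h this equals the plain second difference divided by h^2.
    ``classification`` is concave_up / linear / concave_down / mixed, and
    ``r_squared_linear`` reports how well a straight line fits CH4 vs depth
    over the window.
    """

    depths: np.ndarray
    second_differences: np.ndarray
    classification: str
    r_squared_linear: float


@dataclass
class RegressionResult:
    """Ordinary least squares y on x with a two-sided t-test on the slope."""

    slope: float
    intercept: float
    r_squared: float
    t_value: float
    df: int
    p_value: float


def methane_onset(
    profile: DepthProfile | pd.DataFrame,
    threshold_mM: float = 0.1,
    persistence: int = 3,
    noise_tol_mM: float = 0.05,
) -> OnsetResult:
    """Find the shallowest depth where methane begins to accumulate.

    The onset is the shallowest depth at which CH4 reaches ``threshold_mM``
    and stays at or above it, non-decreasing (allowing dips up to
    ``noise_tol_mM``), over the next ``persistence`` sections. The persistence
    window guards against single-point noise triggers: an isolated spike does
    not qualify, and adding below-threshold depths above the onset never
    changes the result. Sulfate at the onset is read off the profile by
    linear interpolation.

    Returns an absent-onset result (not an error) when no depth qualifies.
    """
    df = profile.data if isinstance(profile, DepthProfile) else profile
    depth = df["depth_cmbsf"].to_numpy(float)
    ch4 = df["ch4_mM"].to_numpy(float)
    if len(depth) < 4:
        raise ValueError("need at least 4 depths with CH4 values")
    n = len(depth)
    for i in range(n):
        if ch4[i] < threshold_mM:
            continue
        window = ch4[i : min(i + persistence, n)]
        if np.all(window >= threshold_mM) and np.all(
            np.diff(window) >= -noise_tol_mM
        ):
            so4 = float(np.interp(depth[i], depth, df["so4_mM"].to_numpy(float)))
            return OnsetResult(float(depth[i]), so4, threshold_mM)
    return OnsetResult(None, None, threshold_mM)


def _second_derivatives(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Three-point second-derivative estimates at interior nodes of a
    possibly irregular grid (exact for quadratics)."""
    h1 = x[1:-1] - x[:-2]
    h2 = x[2:] - x[1:-1]
    return 2.0 * (h1 * y[2:] - (h1 + h2) * y[1:-1] + h2 * y[:-2]) / (
        h1 * h2 * (h1 + h2)
    )


def methanocline_concavity(
    profile: DepthProfile | pd.DataFrame,
    below_depth: float = 0.0,
    alpha: float = 0.05,
    majority: float = 0.7,
) -> ConcavityResult:
    """Classify the curvature of the CH4 profile below a given depth.

    Second differences of CH4 vs depth are evaluated at every interior depth
    of the window and their mean is tested against zero with a one-sample
    two-sided t-test: the profile is called ``linear`` unless zero curvature
    is rejected at level ``alpha``. When it is rejected, the sign of the mean
    gives ``concave_up`` or ``concave_down``, demoted to ``mixed`` when fewer
    than ``majority`` of the individual second differences agree with it
    (e.g. a sigmoid sampled across its inflection). Concave-up (accelerating
    with depth) is the classical signature of net methane consumption above a
    production zone.
    """
    df = profile.data if isinstance(profile, DepthProfile) else profile
    sub = df[df["depth_cmbsf"] >= below_depth]
    depth = sub["depth_cmbsf"].to_numpy(float)
    ch4 = sub["ch4_mM"].to_numpy(float)
    if len(depth) < 4:
        raise ValueError(
            f"need at least 4 depths below {below_depth:g} cmbsf, got {len(depth)}"
        )
    d2 = _second_derivatives(depth, ch4)
    mean = float(np.mean(d2))
    se = float(np.std(d2, ddof=1) / np.sqrt(len(d2))) if len(d2) > 1 else 0.0
    if se == 0.0:
        curved = mean != 0.0  # noise-free: any exact curvature counts
    else:
        t = mean / se
        curved = 2.0 * stats.t.sf(abs(t), df=len(d2) - 1) < alpha
    if not curved:
        cls = "linear"
    else:
        agree = np.mean(np.sign(d2) == np.sign(mean))
        if agree >= majority:
            cls = "concave_up" if mean > 0 else "concave_down"
        else:
            cls = "mixed"
    lin = stats.linregress(depth, ch4)
    return ConcavityResult(
        depths=depth[1:-1],
        second_differences=d2,
        classification=cls,
        r_squared_linear=float(lin.rvalue**2),
    )


def smtz_depth(profile: DepthProfile | pd.DataFrame) -> float | None:
    """Depth (cmbsf) of the equimolar CH4/SO4 crossing, or None.

    Both profiles are interpolated piecewise-linearly in depth; the first
    (shallowest) crossing is reported when there are several. Organic-rich
    cores where methane saturates while sulfate stays at millimolar levels
    have no crossing.
    """
    df = profile.data if isinstance(profile, DepthProfile) else profile
    sub = df.dropna(subset=["ch4_mM", "so4_mM"])
    depth = sub["depth_cmbsf"].to_numpy(float)
    diff = sub["ch4_mM"].to_numpy(float) - sub["so4_mM"].to_numpy(float)
    if len(depth) < 2:
        raise ValueError("need CH4 and SO4 at >= 2 common depths")
    for i in range(len(depth) - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0:
            return float(depth[i])
        if a * b < 0:
            frac = a / (a - b)
            return float(depth[i] + frac * (depth[i + 1] - depth[i]))
    if diff[-1] == 0:
        return float(depth[-1])
    return None


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with the two-sided t-test on the slope (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length x and y with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression is degenerate")
    res = stats.linregress(x, y)
    df = x.size - 2
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        t_value=float(t),
        df=df,
        p_value=float(res.pvalue),
    )


def sulfate_sulfide_regression(
    profile: DepthProfile, pooled: bool = True
) -> dict[str, RegressionResult]:
    """Regress sulfide (uM) on sulfate (mM), pooled across cores (matching
    how replicate cores are usually reported together) or per core."""
    if pooled:
        df = profile.data.dropna(subset=["so4_mM", "h2s_uM"])
        return {"pooled": linear_regression(df["h2s_uM"], df["so4_mM"])}
    out = {}
    for cid in profile.core_ids:
        sub = profile.core(cid).dropna(subset=["so4_mM", "h2s_uM"])
        out[cid] = linear_regression(sub["h2s_uM"], sub["so4_mM"])
    return out


def diagnose_core(
    profile: DepthProfile | pd.DataFrame,
    threshold_mM: float = 0.1,
) -> dict:
    """One-call summary of a single core: onset, concavity below the onset,
    and SMTZ crossing, as a JSON-serializable dict."""
    onset = methane_onset(profile, threshold_mM=threshold_mM)
    report: dict = {
        "onset_depth_cmbsf": onset.onset_depth_cmbsf,
        "so4_at_onset_mM": onset.so4_at_onset_mM,
        "threshold_mM": onset.threshold_mM,
        "smtz_depth_cmbsf": smtz_depth(profile),
    }
    if onset.present:
        try:
            conc = methanocline_concavity(profile, below_depth=onset.onset_depth_cmbsf)
        except ValueError:
            conc = None
        if conc is not None:
            report["concavity"] = conc.classification
            report["methanocline_linear_r2"] = conc.r_squared_linear
    return report
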