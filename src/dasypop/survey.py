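"""Stratified-sample validation of zone-population estimators.

The dasymetric estimators are validated by drawing a stratified simple
random sample of partially vulnerable blocks, observing the true count
of units in the zone for each sampled block, and forming the *combined
ratio estimator* of observed to model-estimated units across strata
(Cochran, Sampling Techniques, §6.11-6.12), with its large-sample
variance and finite-population correction:

    R = sum_h N_h ybar_h / sum_h N_h xbar_h
    V(R) = Xhat^-2 * sum_h N_h^2 (1-f_h)/n_h * (s_yh^2 + R^2 s_xh^2 - 2 R s_yxh)

where y is the observed and x the estimated count, f_h = n_h/N_h, and
Xhat = sum_h N_h xbar_h.  Multiplying a method's full-frame estimated
total by R gives a ratio-adjusted population total; its coefficient of
variation (se/estimate) is read as a 66% confidence range.

Strata follow housing-unit density per hectare, with a "tiny block"
class below an area cutoff and user-defined special classes (e.g. diked
blocks).  Blocks entirely inside or entirely outside the zone carry no
interpolation error and are excluded from ratio estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class StratumRules:
    """Stratification rules for candidate (partially vulnerable) blocks.

    ``density_bands`` are (label, lo, hi) housing-unit densities in
    units/ha, applied as lo <= density < hi; they must not overlap.
    Blocks smaller than ``tiny_block_ha`` go to the tiny-block stratum
    regardless of density.  ``special`` predicates (label, f(blocks) ->
    bool array) are applied first, in order.
    """

    density_bands: Sequence[tuple[str, float, float]] = (
        (">10", 10.0, math.inf),
        ("3-10", 3.0, 10.0),
        ("<3", 0.0, 3.0),
    )
    tiny_block_ha: float = 0.25
    special: Sequence[tuple[str, Callable[[pd.DataFrame], np.ndarray]]] = ()

    def validate(self) -> None:
        bands = sorted(self.density_bands, key=lambda b: b[1])
        for (l1, lo1, hi1), (l2, lo2, hi2) in zip(bands, bands[1:]):
            if hi1 > lo2:
                raise ValueError(f"overlapping density bands {l1!r} and {l2!r}")


def stratify_blocks(
    blocks: pd.DataFrame,
    fractions: pd.DataFrame,
    rules: StratumRules | None = None,
) -> pd.DataFrame:
    """Assign partially vulnerable blocks to strata.

    Candidates are blocks with 0 < frac_area < 1 (blocks entirely below
    or entirely above the threshold are excluded — their interpolated
    population has no interpolation error).  Returns the candidate rows
    with a ``stratum`` column; every candidate lands in exactly one
    stratum.
    """
    rules = rules or StratumRules()
    rules.validate()
    fr = fractions.set_index("block_id")
    frac = blocks["block_id"].map(fr["frac_area"]).to_numpy()
    cand = blocks.loc[(frac > 0) & (frac < 1 - 1e-9)].copy()
    if "dry_area_m2" in fr.columns:
        area_ha = cand["block_id"].map(fr["dry_area_m2"]).to_numpy() / 1e4
    else:
        area_ha = np.array([g.area for g in cand["geometry"]]) / 1e4
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(area_ha > 0, cand["housing_units"].to_numpy() / np.maximum(area_ha, 1e-12), np.inf)

    stratum = np.array([None] * len(cand), dtype=object)
    for label, pred in rules.special:
        sel = np.asarray(pred(cand), dtype=bool) & (stratum == None)  # noqa: E711
        stratum[sel] = label
    tiny = (area_ha < rules.tiny_block_ha) & (stratum == None)  # noqa: E711
    stratum[tiny] = "tiny"
    for label, lo, hi in rules.density_bands:
        sel = (density >= lo) & (density < hi) & (stratum == None)  # noqa: E711
        stratum[sel] = label
    if (stratum == None).any():  # noqa: E711
        # density bands left a gap; put leftovers in the nearest band
        raise ValueError("stratification rules do not cover all candidate blocks")
    cand["stratum"] = stratum
    cand["density_units_per_ha"] = density
    return cand


def draw_sample(
    strata: pd.DataFrame,
    sizes: dict[str, int],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Stratified simple random sample without replacement.

    ``sizes`` maps stratum label to n_h; a missing label samples the
    whole stratum.  Reproducible for a fixed integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = []
    for label, grp in strata.groupby("stratum", sort=True):
        n_h = sizes.get(label, len(grp))
        if n_h > len(grp):
            raise ValueError(f"sample size {n_h} exceeds stratum {label!r} size {len(grp)}")
        idx = rng.choice(len(grp), size=n_h, replace=False)
        parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


@dataclass
class RatioEstimate:
    """Combined ratio estimate with per-stratum detail."""

    strata: pd.DataFrame  # label, N, n, ybar, xbar, ratio, se
    ratio: float
    se: float
    estimated_total: float
    adjusted_total: float
    adjusted_se: float
    cv: float
    excluded: list[str] = field(default_factory=list)

    def interval(self, k: float = 1.0) -> tuple[float, float]:
        """ratio +- k*se; k = 1 corresponds to the 66% range."""
        return (self.ratio - k * self.se, self.ratio + k * self.se)


def combined_ratio_estimate(
    sample: pd.DataFrame,
    stratum_sizes: dict[str, int],
    observed: str = "observed",
    estimated: str = "estimated",
    estimated_total: float | None = None,
) -> RatioEstimate:
    """Combined ratio estimator of observed to estimated units.

    ``sample`` holds one row per sampled block with its stratum label
    and the observed (true) and estimated unit counts.  ``stratum_sizes``
    gives the population count N_h of every stratum.  A stratum whose
    sample mean estimate is zero while observations are nonzero cannot
    enter a ratio and is excluded with a warning.  ``estimated_total``
    is the method's estimated total over the whole frame (defaults to
    the sample-expanded Xhat); the ratio-adjusted total is
    estimated_total * R.
    """
    rows = []
    excluded: list[str] = []
    for label, grp in sample.groupby("stratum", sort=True):
        y = grp[observed].to_numpy(dtype=float)
        x = grp[estimated].to_numpy(dtype=float)
        n_h = len(grp)
        N_h = stratum_sizes[label]
        ybar, xbar = y.mean(), x.mean()
        if xbar == 0 and ybar != 0:
            log.warning("stratum %r: zero estimated units but nonzero observed; excluded", label)
            excluded.append(label)
            continue
        if n_h > 1:
            s_y2 = y.var(ddof=1)
            s_x2 = x.var(ddof=1)
            s_yx = np.cov(y, x, ddof=1)[0, 1]
        else:
            log.warning("stratum %r has n_h = 1; its variance contribution is zero", label)
            s_y2 = s_x2 = s_yx = 0.0
        f_h = n_h / N_h
        r_h = ybar / xbar if xbar != 0 else np.nan
        if xbar != 0 and n_h > 1:
            v_h = (1 - f_h) / (n_h * xbar**2) * (s_y2 + r_h**2 * s_x2 - 2 * r_h * s_yx)
            se_h = math.sqrt(max(v_h, 0.0))
        else:
            se_h = 0.0
        rows.append(
            {
                "stratum": label, "N": N_h, "n": n_h, "ybar": ybar, "xbar": xbar,
                "s_y2": s_y2, "s_x2": s_x2, "s_yx": s_yx,
                "ratio": r_h, "se": se_h, "fpc": 1 - f_h,
            }
        )
    st = pd.DataFrame(rows)
    if not len(st):
        raise ValueError("no usable strata for the combined ratio")
    Yhat = float((st["N"] * st["ybar"]).sum())
    Xhat = float((st["N"] * st["xbar"]).sum())
    if Xhat == 0:
        raise ValueError("estimated totals are zero in every stratum; ratio undefined")
    R = Yhat / Xhat
    var = 0.0
    for _, h in st.iterrows():
        var += h["N"] ** 2 * h["fpc"] / h["n"] * (h["s_y2"] + R**2 * h["s_x2"] - 2 * R * h["s_yx"])
    var = max(var, 0.0) / Xhat**2
    se = math.sqrt(var)
    x_total = Xhat if estimated_total is None else float(estimated_total)
    adjusted = x_total * R
    adjusted_se = x_total * se
    cv = se / R if R != 0 else math.inf
    return RatioEstimate(
        strata=st.drop(columns=["s_y2", "s_x2", "s_yx", "fpc"]),
        ratio=R,
        se=se,
        estimated_total=x_total,
        adjusted_total=adjusted,
        adjusted_se=adjusted_se,
        cv=cv,
        excluded=excluded,
    )


def cv_report(estimates: dict[str, RatioEstimate]) -> pd.DataFrame:
    """Coefficients of variation per scope, flagging ratios whose
    66% interval (ratio +- se) excludes 1."""
    rows = []
    for scope, est in estimates.items():
        lo, hi = est.interval(1.0)
        rows.append(
            {
                "scope": scope,
                "ratio": est.ratio,
                "se": est.se,
                "cv": est.cv,
                "adjusted_total": est.adjusted_total,
                "adjusted_se": est.adjusted_se,
                "interval_lo": lo,
                "interval_hi": hi,
                "excludes_one": bool(lo > 1.0 or hi < 1.0),
            }
        )
    return pd.DataFrame(rows)
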