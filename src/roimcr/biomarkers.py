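"""Statistical screening of resolved components as candidate biomarkers.

After multi-run resolution, each component has one elution profile per run
(its block of the C matrix) and one shared spectrum.  Per run, the component
is quantified by numerical summation of its elution block (peak area, in
a.u.*scan) and by the block maximum (peak height).  Group differences are
then tested component by component with a two-sample t-test (pooled-variance
Student by default, Welch on request), optionally adjusted across components
by Benjamini-Hochberg, and effect sizes are reported as fold changes
(exposed group mean / control group mean, on areas and on heights).

Blocks without a chromatographic peak shape (background, solvent and other
spurious contributions) are flagged — not dropped — by a heuristic: a single
dominant maximum whose contiguous window concentrates a configurable
fraction of the block's area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcrals import MCRModel
from .msio import ValidationError

__all__ = [
    "ComponentAreas",
    "BiomarkerTable",
    "peak_areas",
    "test_components",
    "fold_changes",
    "screen_biomarkers",
]


@dataclass
class ComponentAreas:
    """Per-sample, per-component quantification of a fitted model.

    ``areas`` and ``heights`` are samples x components DataFrames;
    ``peak_shaped`` is a boolean DataFrame of the same shape flagging blocks
    that look like a chromatographic peak.
    """

    areas: pd.DataFrame
    heights: pd.DataFrame
    peak_shaped: pd.DataFrame


def _is_peak_shaped(
    profile: np.ndarray,
    area_fraction: float,
    rel_height: float,
    max_width_fraction: float = 0.5,
) -> bool:
    """True when the contiguous window around the global maximum (cells above
    ``rel_height`` of the max) holds at least ``area_fraction`` of the block's
    area while spanning at most ``max_width_fraction`` of the block — i.e. a
    single dominant, localized peak rather than flat background (window too
    wide) or a split profile (window area too small)."""
    total = profile.sum()
    if total <= 0 or profile.max() <= 0:
        return False
    peak = int(np.argmax(profile))
    floor = rel_height * profile[peak]
    lo = peak
    while lo > 0 and profile[lo - 1] > floor:
        lo -= 1
    hi = peak
    while hi < len(profile) - 1 and profile[hi + 1] > floor:
        hi += 1
    if hi - lo + 1 > max_width_fraction * len(profile):
        return False
    return profile[lo : hi + 1].sum() >= area_fraction * total


def peak_areas(
    model: MCRModel,
    area_fraction: float = 0.6,
    rel_height: float = 0.05,
) -> ComponentAreas:
    """Integrate each component's elution profile within each sample block.

    Area is the plain numerical summation of the block's C entries (no peak
    model is fitted); height is the block maximum.  Requires the model to
    carry sample boundaries (fits of augmented matrices do).
    """
    if model.boundaries is None:
        raise ValidationError("model carries no sample boundaries")
    ids = model.sample_ids or [f"sample{k}" for k in range(len(model.boundaries))]
    n = model.n_components
    areas = np.zeros((len(ids), n))
    heights = np.zeros((len(ids), n))
    shaped = np.zeros((len(ids), n), dtype=bool)
    for k, (a, b) in enumerate(model.boundaries):
        block = model.C[a:b]
        areas[k] = block.sum(axis=0)
        heights[k] = block.max(axis=0) if b > a else 0.0
        for c in range(n):
            shaped[k, c] = _is_peak_shaped(block[:, c], area_fraction, rel_height)
    cols = list(range(n))
    return ComponentAreas(
        areas=pd.DataFrame(areas, index=ids, columns=cols),
        heights=pd.DataFrame(heights, index=ids, columns=cols),
        peak_shaped=pd.DataFrame(shaped, index=ids, columns=cols),
    )


def _split_groups(values: pd.DataFrame, groups, control_label):
    groups = list(groups)
    if len(groups) != len(values.index):
        raise ValidationError("one group label per sample is required")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValidationError(f"exactly two group labels required, got {labels}")
    if control_label is None:
        control_label = labels[0]
    elif control_label not in labels:
        raise ValidationError(f"control label {control_label!r} not in {labels}")
    other = next(lab for lab in labels if lab != control_label)
    mask = np.array([g == control_label for g in groups])
    ctrl = values.loc[mask.tolist()]
    expo = values.loc[(~mask).tolist()]
    if len(ctrl) < 2 or len(expo) < 2:
        raise ValidationError("each group needs at least two samples")
    return ctrl, expo, control_label, other


def test_components(
    areas: pd.DataFrame,
    groups,
    test: str = "student",
    mcp: str = "none",
    alpha: float = 0.05,
    control_label=None,
) -> pd.DataFrame:
    """Two-sample t-test of each component's per-sample quantities.

    ``test="student"`` is the classical pooled-variance t (default);
    ``test="welch"`` drops the equal-variance assumption.  ``mcp`` selects
    the multiple-comparison correction across components: ``"none"`` or
    ``"benjamini_hochberg"``.  Components with zero variance in both groups
    and equal means get p = 1 by convention.  Returns a DataFrame with one
    row per component: group means, t, raw and adjusted p, significance at
    ``alpha`` (on the adjusted p when a correction is applied).
    """
    if test not in {"student", "welch"}:
        raise ValidationError("test must be 'student' or 'welch'")
    if mcp not in {"none", "benjamini_hochberg"}:
        raise ValidationError("mcp must be 'none' or 'benjamini_hochberg'")
    ctrl, expo, control_label, other = _split_groups(areas, groups, control_label)

    t_stat = np.empty(areas.shape[1])
    p_raw = np.empty(areas.shape[1])
    for i, col in enumerate(areas.columns):
        x, y = ctrl[col].to_numpy(float), expo[col].to_numpy(float)
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            t_stat[i], p_raw[i] = 0.0, 1.0
            continue
        res = stats.ttest_ind(y, x, equal_var=(test == "student"))
        t_stat[i], p_raw[i] = float(res.statistic), float(res.pvalue)

    if mcp == "benjamini_hochberg":
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    else:
        p_adj = p_raw.copy()

    return pd.DataFrame(
        {
            "component": list(areas.columns),
            f"mean_{control_label}": ctrl.mean(axis=0).to_numpy(),
            f"mean_{other}": expo.mean(axis=0).to_numpy(),
            "t_stat": t_stat,
            "p_value": p_raw,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )


def fold_changes(
    areas: pd.DataFrame, groups, control_label=None
) -> pd.Series:
    """Per-component ratio of exposed to control group means.

    Undefined ratios (control mean not strictly positive) are reported as
    NaN rather than raising, so a single empty component does not abort a
    screen.
    """
    ctrl, expo, _, _ = _split_groups(areas, groups, control_label)
    ctrl_mean = ctrl.mean(axis=0).to_numpy(float)
    expo_mean = expo.mean(axis=0).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(ctrl_mean > 0, expo_mean / ctrl_mean, np.nan)
    return pd.Series(fc, index=areas.columns, name="fold_change")


@dataclass
class BiomarkerTable:
    """Ranked per-component screening result plus the underlying areas."""

    table: pd.DataFrame
    areas: pd.DataFrame
    groups: list
    sample_ids: list
    control_label: str
    alpha: float
    test: str
    mcp: str


def _mz_signature(model: MCRModel, component: int, top: int = 3) -> str:
    if model.mzroi is None:
        return ""
    spec = model.S_T[component]
    order = np.argsort(spec)[::-1][:top]
    # keep only peaks that are a real part of the spectrum, not cross-talk
    order = [i for i in order if spec[i] > 0.1 * spec.max()]
    return ";".join(f"{model.mzroi[i]:.4f}" for i in order)


def screen_biomarkers(
    model: MCRModel,
    groups,
    test: str = "student",
    mcp: str = "none",
    alpha: float = 0.05,
    control_label=None,
    area_fraction: float = 0.6,
    rel_height: float = 0.05,
) -> BiomarkerTable:
    """Full screen: quantify components, test group differences, compute fold
    changes on areas and heights, and annotate each component with its top
    spectral m/z values and peak-shape flag.  Rows are sorted by raw p."""
    quant = peak_areas(model, area_fraction, rel_height)
    table = test_components(
        quant.areas, groups, test=test, mcp=mcp, alpha=alpha,
        control_label=control_label,
    )
    table["fold_change"] = fold_changes(
        quant.areas, groups, control_label
    ).to_numpy()
    table["fold_change_height"] = fold_changes(
        quant.heights, groups, control_label
    ).to_numpy()
    table["mz_signature"] = [
        _mz_signature(model, c) for c in table["component"]
    ]
    table["peak_shaped_fraction"] = quant.peak_shaped.mean(axis=0).to_numpy()
    table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    labels = list(dict.fromkeys(groups))
    ctrl = control_label if control_label is not None else labels[0]
    return BiomarkerTable(
        table=table,
        areas=quant.areas,
        groups=list(groups),
        sample_ids=list(quant.areas.index),
        control_label=ctrl,
        alpha=alpha,
        test=test,
        mcp=mcp,
    )
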