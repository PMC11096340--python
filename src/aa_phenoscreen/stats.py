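"""Motility-index and peak statistics, plus the group-comparison tests.

Motility is the per-bin distance travelled (mm per 1-s bin by default). The
relative motility index expresses a treated group's motility as percent change
versus same-plate controls:

    MI_R(c_x) [%] = 100 * (Mc_x - Mc_0) / Mc_0

The 60-s startle string is partitioned into six peak windows P1..P6 (by
default the six 10-s light epochs: darkness, red, blue, purple, white,
flicker); the relative peak analysis reports MI_R per peak, aggregated over
all cycles.

Feature distributions by dose are compared to controls with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test and Benjamini-Hochberg adjustment;
ANOVA with Tukey or Dunnett post-hoc contrasts is available for the motility
panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .tracking import AnalysisWindow, StimulusSchedule, Track


@dataclass
class MotilitySeries:
    """Binned motility of one fish in one window (mm per bin)."""

    fish_id: str
    window: AnalysisWindow
    motility: np.ndarray
    bin_s: float = 1.0


def binned_motility(track: Track, window: AnalysisWindow, bin_s: float = 1.0) -> MotilitySeries:
    """Sum step distances into ``bin_s``-second bins tiling the window."""
    sl = track.window_slice(window.start_s, window.end_s)
    n_bins = int(np.ceil(window.duration_s / bin_s - 1e-9))
    t = track.t[sl] - window.start_s
    idx = np.minimum((t / bin_s).astype(int), n_bins - 1)
    m = np.bincount(idx, weights=track.step_dist[sl], minlength=n_bins)
    return MotilitySeries(track.fish_id, window, m, bin_s)


def motility_index(mcx: float, mc0: float) -> float:
    """Relative motility index: percent change of treated vs control motility."""
    if mc0 == 0:
        raise ValueError("control motility Mc_0 is 0; motility index undefined")
    return 100.0 * (mcx - mc0) / mc0


@dataclass(frozen=True)
class PeakWindows:
    """Six labelled intervals P1..P6 in seconds relative to startle onset."""

    bounds: tuple[tuple[float, float], ...] = tuple((10.0 * i, 10.0 * (i + 1)) for i in range(6))

    def __post_init__(self) -> None:
        if len(self.bounds) != 6:
            raise ValueError("exactly six peak windows expected")
        prev_end = 0.0
        for a, b in self.bounds:
            if a < prev_end or b <= a or b > 60.0 + 1e-9:
                raise ValueError("peak windows must be ordered, disjoint and within [0, 60]")
            prev_end = b

    @property
    def labels(self) -> list[str]:
        return [f"P{i+1}" for i in range(6)]


def _peak_motility(tracks: Sequence[Track], schedule: StimulusSchedule,
                   peaks: PeakWindows) -> np.ndarray:
    """Mean per-observation motility (mm) in each peak, pooled over all fish
    and all startle cycles. Returns shape (6,)."""
    sums = np.zeros(6)
    n = 0
    for tr in tracks:
        for k in range(1, schedule.n_cycles + 1):
            s0 = schedule.cycle_start(k)
            for j, (a, b) in enumerate(peaks.bounds):
                sl = tr.window_slice(s0 + a, s0 + b)
                sums[j] += tr.step_dist[sl].sum()
            n += 1
    if n == 0:
        raise ValueError("no observations")
    return sums / n


def relative_peak_analysis(
    treated: Sequence[Track],
    control: Sequence[Track],
    schedule: StimulusSchedule,
    peaks: PeakWindows | None = None,
) -> pd.Series:
    """MI_R per peak P1..P6 of the treated group versus the control group,
    aggregated over all startle cycles."""
    if len(control) == 0:
        raise ValueError("empty control group")
    peaks = peaks or PeakWindows()
    m_treated = _peak_motility(treated, schedule, peaks)
    m_control = _peak_motility(control, schedule, peaks)
    vals = [motility_index(mx, m0) for mx, m0 in zip(m_treated, m_control)]
    return pd.Series(vals, index=peaks.labels, name="MI_R_pct")


def ranksum_bh(
    groups: Mapping[object, Sequence[float]],
    control: Sequence[float],
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p of each group vs control, BH-adjusted
    across the whole family.

    Uses the exact null distribution for small tie-free samples and the
    normal approximation with tie correction otherwise. Degenerate all-tied
    comparisons return p = 1.
    """
    control = np.asarray(control, dtype=float)
    labels, p_raw, estimates, ns = [], [], [], []
    for label, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2 or control.size < 2:
            raise ValueError(f"group {label}: need >= 2 observations per group")
        pooled = np.concatenate([vals, control])
        if np.all(pooled == pooled[0]):
            p = 1.0
        else:
            method = "exact" if (max(vals.size, control.size) <= 20
                                 and np.unique(pooled).size == pooled.size) else "asymptotic"
            p = float(sps.mannwhitneyu(vals, control, alternative="two-sided",
                                       method=method).pvalue)
        labels.append(label)
        p_raw.append(min(p, 1.0))
        estimates.append(float(np.median(vals) - np.median(control)))
        ns.append(vals.size)
    p_adj = bh_adjust(np.asarray(p_raw))
    return pd.DataFrame(
        {"group": labels, "estimate": estimates, "n": ns, "p_raw": p_raw, "p_adj": p_adj}
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def anova_posthoc(
    groups: Mapping[object, Sequence[float]],
    design: str = "oneway_tukey",
    control: object | None = None,
    factor2: Mapping[object, Sequence[object]] | None = None,
) -> pd.DataFrame:
    """ANOVA F-test with the named post-hoc family.

    ``oneway_tukey``
        one-way ANOVA over all groups with Tukey's HSD on every pair.
    ``twoway_dunnett``
        two-way layout (group x second factor); the ANOVA is fitted with both
        factors and Dunnett contrasts compare every non-control group to the
        ``control`` group within each level of the second factor (or overall
        when ``factor2`` is omitted, reducing to one-way Dunnett).

    Returns a tidy table of contrasts with family-wise-adjusted p-values and
    attaches the ANOVA p in ``df.attrs['anova_p']``.
    """
    keys = list(groups.keys())
    if len(keys) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]

    if design == "oneway_tukey":
        f_p = float(sps.f_oneway(*arrays).pvalue)
        res = sps.tukey_hsd(*arrays)
        rows = []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                rows.append(
                    {"contrast": f"{keys[i]} vs {keys[j]}",
                     "estimate": float(arrays[i].mean() - arrays[j].mean()),
                     "p_adj": float(res.pvalue[i, j])}
                )
        out = pd.DataFrame(rows)
        out.attrs["anova_p"] = f_p
        return out

    if design == "twoway_dunnett":
        if control is None or control not in groups:
            raise ValueError("twoway_dunnett requires a control group key")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        frames = []
        for k in keys:
            lv = (list(factor2[k]) if factor2 is not None else ["all"] * len(groups[k]))
            frames.append(pd.DataFrame({"y": np.asarray(groups[k], dtype=float),
                                        "grp": str(k), "lvl": [str(v) for v in lv]}))
        df = pd.concat(frames, ignore_index=True)
        formula = "y ~ C(grp)" if df["lvl"].nunique() == 1 else "y ~ C(grp) + C(lvl)"
        fit = smf.ols(formula, data=df).fit()
        f_p = float(anova_lm(fit, typ=2).loc["C(grp)", "PR(>F)"])
        rows = []
        for lvl, sub in df.groupby("lvl"):
            ctrl_vals = sub.loc[sub["grp"] == str(control), "y"].to_numpy()
            others = [k for k in keys if k != control and (sub["grp"] == str(k)).any()]
            if ctrl_vals.size < 2 or not others:
                continue
            samples = [sub.loc[sub["grp"] == str(k), "y"].to_numpy() for k in others]
            res = sps.dunnett(*samples, control=ctrl_vals)
            for k, est, p in zip(others,
                                 [s.mean() - ctrl_vals.mean() for s in samples],
                                 res.pvalue):
                rows.append({"contrast": f"{k} vs {control}", "level": lvl,
                             "estimate": float(est), "p_adj": float(p)})
        out = pd.DataFrame(rows)
        out.attrs["anova_p"] = f_p
        return out

    raise ValueError(f"unknown design {design!r}")


def feature_ranksum_panel(
    normalized: pd.DataFrame,
    feature_names: Iterable[str],
    window_label: str,
) -> pd.DataFrame:
    """Rank-sum p (vs dose-0 controls) for every (feature, treatment, dose) of
    one window panel, BH-adjusted across the whole panel family."""
    sub = normalized[normalized["window_label"] == window_label]
    rows = []
    pvals = []
    ctrl_mask = sub["dose_level"] == 0
    for name in feature_names:
        col = name + "_pct" if name + "_pct" in sub.columns else name
        control = sub.loc[ctrl_mask, col].dropna().to_numpy()
        for (treatment, dose), grp in sub[~ctrl_mask].groupby(["treatment", "dose_level"]):
            vals = grp[col].dropna().to_numpy()
            if vals.size < 2 or control.size < 2:
                continue
            res = ranksum_bh({"g": vals}, control)
            rows.append({"feature": name, "treatment": treatment, "dose_level": dose,
                         "estimate": res["estimate"].iloc[0], "n": vals.size,
                         "p_raw": res["p_raw"].iloc[0]})
            pvals.append(res["p_raw"].iloc[0])
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(np.asarray(pvals))
    return out
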