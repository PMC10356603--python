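"""Group-level statistics and figure-style summaries.

The statistical unit is the cell (n_cells is always reported alongside
n_images so nesting of cells within images/roots stays visible).  Provided
here: distribution summaries with the ±1.58×IQR whisker convention,
Pearson correlation, Welch's two-sample t-test, and one-way ANOVA followed
by Tukey HSD pairwise comparisons (optionally one-sided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "summarize_group",
    "pearson_r2",
    "two_sample_ttest",
    "anova_tukey",
    "build_report",
]

WHISKER_FACTOR = 1.58  # boxplot whisker rule: Q1 - 1.58*IQR, Q3 + 1.58*IQR


@dataclass
class GroupSummary:
    """Distribution summary of one group of per-cell values."""

    label: str
    n_cells: int
    n_images: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    density_support: np.ndarray = field(repr=False, default=None)
    density_values: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("label", "n_cells", "n_images", "mean", "sd", "median",
              "q25", "q75", "whisker_low", "whisker_high")}
        return d


def summarize_group(values, label: str = "", n_images: int = 1) -> GroupSummary:
    """Moments, quantiles, whiskers and a kernel-density estimate.

    Quantiles use the linear-interpolation definition; whiskers are
    Q1 − 1.58·IQR and Q3 + 1.58·IQR clipped to the data range; the KDE
    bandwidth follows Silverman's rule (degenerate/constant samples skip the
    KDE).
    """
    v = np.asarray(values, float)
    v = np.sort(v[np.isfinite(v)])  # sorting makes summaries order-invariant
    if v.size == 0:
        raise ValueError("empty group")
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q75 - q25
    wlo = max(q25 - WHISKER_FACTOR * iqr, v.min())
    whi = min(q75 + WHISKER_FACTOR * iqr, v.max())
    support = density = None
    if v.size >= 3 and np.std(v) > 0:
        kde = sps.gaussian_kde(v, bw_method="silverman")
        support = np.linspace(v.min(), v.max(), 256)
        density = kde(support)
    return GroupSummary(
        label=label, n_cells=int(v.size), n_images=int(n_images),
        mean=float(v.mean()), sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=float(wlo), whisker_high=float(whi),
        density_support=support, density_values=density,
    )


def pearson_r2(x, y) -> tuple[float, float, float]:
    """Pearson correlation: returns (r, R², two-sided p).

    p comes from the exact t transform t = r·sqrt((n−2)/(1−r²)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def two_sample_ttest(a, b, sides: str = "two-sided", equal_var: bool = False):
    """Two-sample t-test, Welch's unequal-variance form by default.

    ``sides`` is "two-sided", "greater" (a > b) or "less".  Returns
    (t, df, p).  When both groups are constant with equal means, p = 1 by
    convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=sides)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anova_tukey(groups: dict[str, np.ndarray] | list, sides: str = "two-sided"):
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` is a dict label -> values (or a list of arrays).  The global
    test is the classical F; pairwise p-values come from the studentized
    range distribution.  With ``sides="greater"``/"less" the appropriate
    tail is halved for pairs whose observed difference matches the requested
    direction (later group minus earlier group), and set to 1 − p/2
    otherwise; the direction must be supplied explicitly by the caller.

    Returns ``(F, p_global, pairwise)`` where ``pairwise`` is a DataFrame
    with columns (group_a, group_b, diff, p).
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        arrays = [np.asarray(groups[k], float) for k in labels]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs >= 2 values")

    if all(np.var(g) == 0 for g in arrays) and len({float(g.mean()) for g in arrays}) == 1:
        pairwise = pd.DataFrame(
            [(labels[i], labels[j], 0.0, 1.0)
             for i in range(len(arrays)) for j in range(i + 1, len(arrays))],
            columns=["group_a", "group_b", "diff", "p"])
        return 0.0, 1.0, pairwise

    f_stat, p_global = sps.f_oneway(*arrays)
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            diff = float(arrays[j].mean() - arrays[i].mean())
            p = float(res.pvalue[i, j])
            if sides in ("greater", "less"):
                want_positive = sides == "greater"
                if (diff > 0) == want_positive or diff == 0:
                    p = p / 2.0
                else:
                    p = 1.0 - p / 2.0
            rows.append((labels[i], labels[j], diff, p))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p"])
    return float(f_stat), float(p_global), pairwise


def build_report(
    cell_tables: dict[str, pd.DataFrame],
    value_col: str,
    out_dir,
    n_images: dict[str, int] | None = None,
    tukey_sides: str = "two-sided",
) -> dict:
    """Write a per-group summary bundle for one per-cell quantity.

    For each group: a GroupSummary row, density curve CSV; across groups:
    ANOVA + Tukey table and a markdown report.  n_cells and n_images are
    always reported per group.  Outputs carry no timestamps, so re-runs are
    byte-identical.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_images = n_images or {}
    summaries = []
    groups = {}
    for label, table in cell_tables.items():
        vals = table[value_col].dropna().to_numpy(float)
        groups[label] = vals
        s = summarize_group(vals, label, n_images.get(label, 1))
        summaries.append(s)
        if s.density_support is not None:
            pd.DataFrame({"support": s.density_support, "density": s.density_values}) \
                .to_csv(out / f"density_{label}.csv", index=False)

    summary_df = pd.DataFrame([s.to_dict() for s in summaries])
    summary_df.to_csv(out / "group_summary.csv", index=False)

    result = {"groups": {s.label: s.to_dict() for s in summaries}}
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        f_stat, p_global, pairwise = anova_tukey(groups, sides=tukey_sides)
        pairwise.to_csv(out / "tukey_pairwise.csv", index=False)
        result["anova"] = {"F": f_stat, "p": p_global}
        result["tukey"] = pairwise.to_dict(orient="records")
    with open(out / "report.json", "w") as fh:
        json.dump(result, fh, indent=2, default=float)

    lines = [f"# Group report: {value_col}", ""]
    for s in summaries:
        lines.append(f"- **{s.label}**: n = {s.n_cells} cells over {s.n_images} image(s); "
                     f"mean {s.mean:.3g}, median {s.median:.3g}, IQR [{s.q25:.3g}, {s.q75:.3g}]")
    if "anova" in result:
        lines += ["", f"ANOVA: F = {result['anova']['F']:.4g}, p = {result['anova']['p']:.3g}",
                  "", "| pair | diff | Tukey p |", "|---|---|---|"]
        for row in result["tukey"]:
            lines.append(f"| {row['group_a']} vs {row['group_b']} | "
                         f"{row['diff']:.4g} | {row['p']:.3g} |")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return result
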