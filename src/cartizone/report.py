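"""Formatted comparison tables and site-mean rollups.

Rollups follow the convention of averaging site means, not pooling
subjects: a knee average is the unweighted mean of its three site means,
a region (lateral/middle/medial) average is the unweighted mean of that
region's two knee-side means, and the overall average is the unweighted
mean of all six site means.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .compare import (
    GroupSummary,
    anova_from_summary,
    format_p,
    kruskal_wallis_posthoc,
    t_between,
    tukey_hsd,
    variance_homogeneity,
)

REGIONS = ("lateral", "middle", "medial")
SIDES = ("right", "left")


def _split(site: str) -> tuple[str, str]:
    side, region = site.split("_", 1)
    return side, region


def knee_rollup(site_means: Mapping[str, float], side: str) -> float:
    """Unweighted mean of the three site means of one knee."""
    vals = [v for s, v in site_means.items() if _split(s)[0] == side]
    if not vals:
        raise ValueError(f"no sites for side {side!r}")
    return float(np.mean(vals))


def region_rollup(site_means: Mapping[str, float], region: str) -> float:
    """Unweighted mean of one region's site means across knees."""
    vals = [v for s, v in site_means.items() if _split(s)[1] == region]
    if not vals:
        raise ValueError(f"no sites for region {region!r}")
    return float(np.mean(vals))


def overall_rollup(site_means: Mapping[str, float]) -> float:
    """Unweighted mean of all site means."""
    return float(np.mean(list(site_means.values())))


def rollup_report(site_means: Mapping[str, float]) -> dict[str, float]:
    sides = sorted({_split(s)[0] for s in site_means})
    regions = sorted({_split(s)[1] for s in site_means})
    out = {"overall": overall_rollup(site_means)}
    for side in sides:
        out[f"knee_{side}"] = knee_rollup(site_means, side)
    for region in regions:
        out[f"region_{region}"] = region_rollup(site_means, region)
    return out


def _fmt_ms(mean: float, sd: float) -> str:
    return f"{mean:.3f} ± {sd:.3f}"


def sex_comparison_table(
    summaries: Mapping[str, GroupSummary],
    variant: str = "pooled",
    tiers: tuple[float, float] = (0.05, 0.001),
) -> pd.DataFrame:
    """Per-site female/male means with independent-t p values."""
    rows = []
    for site, summ in summaries.items():
        res = t_between(summary=summ, variant=variant)
        rows.append({
            "site": site,
            summ.labels[0]: _fmt_ms(summ.means[0], summ.sds[0]),
            summ.labels[1]: _fmt_ms(summ.means[1], summ.sds[1]),
            "p": format_p(res.p),
            "sig": res.markers(tiers),
        })
    return pd.DataFrame(rows)


def age_comparison_table(
    summaries: Mapping[str, GroupSummary],
    raw_groups: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    alpha: float = 0.05,
    tiers: tuple[float, float] = (0.05, 0.001),
) -> pd.DataFrame:
    """Per-site k-group comparison in the normative-table layout.

    From summaries alone the parametric path (ANOVA + Tukey-Kramer) is
    reported.  When raw per-group values are supplied the Brown-Forsythe
    gate is applied per site and, for sites that fail it, the rank path
    (Kruskal-Wallis + Dunn/Bonferroni) is reported alongside; both results
    are kept since the parametric F remains informative.
    """
    rows = []
    for site, summ in summaries.items():
        an = anova_from_summary(summ)
        tk = tukey_hsd(summary=summ, anova=an)
        sig = tk.significant_pairs(alpha)
        row = {
            "site": site,
            **{lab: _fmt_ms(m, s) for lab, m, s
               in zip(summ.labels, summ.means, summ.sds)},
            "F": round(an.f, 3),
            "p": format_p(an.p),
            "sig_pairs": ", ".join(sig) if sig else "NS",
            "method": "anova_tukey",
        }
        if raw_groups is not None and site in raw_groups:
            gate = variance_homogeneity(raw_groups[site], alpha=alpha)
            row["variance_homogeneous"] = "homogeneous" in gate.notes
            if "heterogeneous" in gate.notes:
                kw = kruskal_wallis_posthoc(raw_groups[site], alpha=alpha)
                ksig = kw.significant_pairs(alpha)
                row["H"] = round(kw.statistic, 3)
                row["p_kruskal"] = format_p(kw.p)
                row["sig_pairs_dunn"] = ", ".join(ksig) if ksig else "NS"
                row["method"] = "anova_tukey+kruskal_dunn"
        rows.append(row)
    return pd.DataFrame(rows)


def reliability_table(results: list) -> pd.DataFrame:
    """Tabulate ReliabilityResult objects (one row per site)."""
    rows = []
    for r in results:
        rows.append({
            "site": r.site, "n": r.n, "k": r.k,
            "icc": round(r.icc.icc, 3),
            "icc_95ci": f"[{r.icc.ci_low:.3f}, {r.icc.ci_high:.3f}]",
            "icc_lower_1sided": round(r.icc.lower_one_sided, 3),
            "icc_acceptable": r.icc.acceptable,
            "sem_pct": round(r.sem.sem_pct, 2),
            "sem_pct_95ci": f"[{r.sem.ci_low_pct:.2f}, {r.sem.ci_high_pct:.2f}]",
            "cv_pct": round(r.cv.cv_pct, 2),
            "cv_pct_95ci": f"[{r.cv.ci_low_pct:.2f}, {r.cv.ci_high_pct:.2f}]",
            "grand_mean_mm": round(r.anova.grand_mean, 3),
        })
    return pd.DataFrame(rows)


def to_markdown(df: pd.DataFrame) -> str:
    return df.to_markdown(index=False)
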