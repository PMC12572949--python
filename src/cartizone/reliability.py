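"""Intra-rater reliability of repeated thickness readings.

Readings form a subjects x readings matrix (k = 3 in the standard
protocol).  A two-way decomposition (subjects crossed with reading
occasions, no replication) yields the mean squares from which the
consistency-type single-measure intraclass correlation is computed:

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS)

where BMS is the between-subjects mean square and EMS the residual mean
square; the reading-occasion (systematic trial order) mean square is
excluded from the denominator, i.e. consistency rather than absolute
agreement.  Confidence intervals come from the F = BMS/EMS pivot with
(n - 1, (n - 1)(k - 1)) degrees of freedom; the one-sided 95% lower bound
is compared with the 0.70 acceptability threshold.

Absolute reliability is summarised by SEM% = 100 * sqrt(EMS) / grand mean
with a chi-square interval on the error sum of squares, and by the
log-method within-subject CV%: the same decomposition on log readings gives
the residual variance s^2, and CV% = 100 * sqrt(exp(s^2) - 1), which
reduces to 100*s for small s.  Both carry a < 10% acceptability flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ICC_THRESHOLD = 0.70
PCT_ACCEPTABLE = 10.0


@dataclass
class AnovaDecomposition:
    """Two-way (subjects x readings) mean squares, no replication."""

    n: int
    k: int
    bms: float  # between-subjects mean square, df n-1
    rms: float  # between-readings mean square, df k-1
    ems: float  # residual mean square, df (n-1)(k-1)
    ssb: float
    ssr: float
    sse: float
    grand_mean: float
    degenerate: bool = False

    @property
    def df_subjects(self) -> int:
        return self.n - 1

    @property
    def df_readings(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    lower_one_sided: float
    acceptable: bool  # one-sided lower bound > 0.70
    alpha: float = 0.05
    degenerate: bool = False


@dataclass
class SemResult:
    sem: float  # mm
    sem_pct: float
    ci_low_pct: float
    ci_high_pct: float
    acceptable: bool  # SEM% < 10


@dataclass
class CvResult:
    cv_pct: float
    ci_low_pct: float
    ci_high_pct: float
    acceptable: bool  # CV% < 10
    variant: str = "sqrt_expm1"


@dataclass
class ReliabilityResult:
    site: str
    n: int
    k: int
    anova: AnovaDecomposition
    icc: IccResult
    sem: SemResult
    cv: CvResult
    n_dropped_incomplete: int = 0


def two_way_anova(data: np.ndarray) -> AnovaDecomposition:
    """Decompose a complete subjects x readings matrix.

    Sum-of-squares identity SST = SSB + SSR + SSE holds to floating
    tolerance; a zero-total-variance matrix is flagged degenerate with all
    mean squares zero.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 2")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing cells; drop incomplete "
                         "subjects first (see complete_cases)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssb = k * float(((row_means - grand) ** 2).sum())
    ssr = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssb - ssr
    if sse <= 1e-12 * sst:  # round-off from the subtraction, not real error
        sse = 0.0
    degenerate = sst == 0.0
    return AnovaDecomposition(
        n=n, k=k,
        bms=ssb / (n - 1), rms=ssr / (k - 1), ems=sse / ((n - 1) * (k - 1)),
        ssb=ssb, ssr=ssr, sse=sse,
        grand_mean=float(grand), degenerate=degenerate,
    )


def complete_cases(data: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop subjects with any missing reading; return (matrix, n_dropped)."""
    x = np.asarray(data, dtype=float)
    keep = ~np.isnan(x).any(axis=1)
    return x[keep], int((~keep).sum())


def icc_3_1(anova: AnovaDecomposition, alpha: float = 0.05) -> IccResult:
    """Consistency single-measure ICC with F-pivot confidence bounds."""
    n, k = anova.n, anova.k
    if anova.ems == 0.0:
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0,
                         lower_one_sided=1.0, acceptable=True,
                         alpha=alpha, degenerate=True)
    icc = (anova.bms - anova.ems) / (anova.bms + (k - 1) * anova.ems)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = anova.bms / anova.ems

    def _from_f(f: float) -> float:
        return (f - 1.0) / (f + k - 1.0)

    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lower1 = f_obs / stats.f.ppf(1 - alpha, df1, df2)
    return IccResult(
        icc=float(icc),
        ci_low=float(_from_f(fl)),
        ci_high=float(_from_f(fu)),
        lower_one_sided=float(_from_f(lower1)),
        acceptable=bool(_from_f(lower1) > ICC_THRESHOLD),
        alpha=alpha,
    )


def sem_pct(anova: AnovaDecomposition, alpha: float = 0.05) -> SemResult:
    """SEM = sqrt(EMS), as a percentage of the grand mean.

    The interval maps the chi-square interval for the error variance,
    [SSE/chi2_{1-a/2,df}, SSE/chi2_{a/2,df}], through sqrt and the percent
    scale.
    """
    if anova.grand_mean <= 0:
        raise ValueError("grand mean must be > 0 for SEM%")
    sem = float(np.sqrt(anova.ems))
    scale = 100.0 / anova.grand_mean
    df = anova.df_error
    if anova.sse == 0.0:
        lo = hi = 0.0
    else:
        lo = scale * float(np.sqrt(anova.sse / stats.chi2.ppf(1 - alpha / 2, df)))
        hi = scale * float(np.sqrt(anova.sse / stats.chi2.ppf(alpha / 2, df)))
    pct = scale * sem
    return SemResult(sem=sem, sem_pct=pct, ci_low_pct=lo, ci_high_pct=hi,
                     acceptable=bool(pct < PCT_ACCEPTABLE))


def cv_pct_log(
    data: np.ndarray, alpha: float = 0.05, variant: str = "sqrt_expm1"
) -> CvResult:
    """Within-subject CV% from the residual variance of log readings.

    The default variant is the log-normal within-subject CV,
    100*sqrt(exp(s^2) - 1); ``expm1_s`` gives 100*(exp(s) - 1).  The
    interval maps the chi-square interval of s^2 through the same formula.
    """
    x = np.asarray(data, dtype=float)
    if np.any(x <= 0):
        r, c = map(int, np.argwhere(x <= 0)[0])
        raise ValueError(
            f"nonpositive reading at subject {r}, reading {c}: "
            "log-method CV undefined"
        )
    dec = two_way_anova(np.log(x))
    df = dec.df_error
    s2 = dec.ems

    def to_cv(v: float) -> float:
        if variant == "sqrt_expm1":
            return 100.0 * float(np.sqrt(np.expm1(v)))
        if variant == "expm1_s":
            return 100.0 * float(np.expm1(np.sqrt(v)))
        raise ValueError(f"unknown CV variant {variant!r}")

    if dec.sse == 0.0:
        lo = hi = 0.0
    else:
        lo = to_cv(dec.sse / stats.chi2.ppf(1 - alpha / 2, df))
        hi = to_cv(dec.sse / stats.chi2.ppf(alpha / 2, df))
    cv = to_cv(s2)
    return CvResult(cv_pct=cv, ci_low_pct=lo, ci_high_pct=hi,
                    acceptable=bool(cv < PCT_ACCEPTABLE), variant=variant)


def analyze_repeated(
    data: np.ndarray,
    site: str = "",
    alpha: float = 0.05,
    cv_variant: str = "sqrt_expm1",
) -> ReliabilityResult:
    """Full reliability report for one site's subjects x readings matrix."""
    x, dropped = complete_cases(data)
    dec = two_way_anova(x)
    return ReliabilityResult(
        site=site, n=dec.n, k=dec.k, anova=dec,
        icc=icc_3_1(dec, alpha),
        sem=sem_pct(dec, alpha),
        cv=cv_pct_log(x, alpha, cv_variant),
        n_dropped_incomplete=dropped,
    )
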