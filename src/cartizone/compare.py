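"""Between-group inference for cartilage-thickness tables.

Implements the comparison toolchain used for normative thickness data: sex
differences by independent-samples t (pooled by default, Welch by flag) or
Mann-Whitney U when normality fails; age-group differences by one-way ANOVA
with Tukey-Kramer HSD post hoc when group variances are homogeneous
(Brown-Forsythe gate), else Kruskal-Wallis with Dunn pairwise comparisons
under Bonferroni correction; and Fisher's exact test (Freeman-Halton
generalisation) for categorical baselines.

Every parametric test has twin engines: a raw-data engine and a
summary-statistics engine that works from per-group (n, mean, sd) alone,
so results printed only as summary tables can be recomputed exactly.  On
exact-moments synthetic data the two engines agree to floating precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

SIG_TIERS = (0.05, 0.001)


@dataclass
class GroupSummary:
    """Per-group sample moments: labels with (n, mean, sd) triples."""

    labels: list[str]
    ns: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    site: str = ""

    def __post_init__(self) -> None:
        self.ns = np.asarray(self.ns, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = len(self.labels)
        if not (len(self.ns) == len(self.means) == len(self.sds) == k):
            raise ValueError("labels, ns, means, sds must have equal length")
        if k < 2:
            raise ValueError("need at least 2 groups")
        if np.any(self.ns < 2):
            raise ValueError("every group needs n >= 2")
        if np.any(self.sds < 0):
            raise ValueError("SDs must be >= 0")

    @classmethod
    def from_groups(
        cls, groups: Mapping[str, Sequence[float]], site: str = ""
    ) -> "GroupSummary":
        labels = list(groups)
        arrs = [np.asarray(groups[g], dtype=float) for g in labels]
        return cls(
            labels=labels,
            ns=np.array([len(a) for a in arrs]),
            means=np.array([a.mean() for a in arrs]),
            sds=np.array([a.std(ddof=1) for a in arrs]),
            site=site,
        )

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n_total(self) -> int:
        return int(self.ns.sum())


@dataclass
class AnovaTable:
    ssb: float
    ssw: float
    df_between: int
    df_within: int
    msb: float
    msw: float
    f: float
    p: float
    degenerate: bool = False


@dataclass
class PairResult:
    group_a: str
    group_b: str
    mean_diff: float  # mean_a - mean_b
    statistic: float
    p: float

    @property
    def direction(self) -> str:
        """e.g. '4 > 2' -- the larger group's label first."""
        hi, lo = ((self.group_a, self.group_b) if self.mean_diff >= 0
                  else (self.group_b, self.group_a))
        return f"{hi} > {lo}"

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: tuple[float, ...] | None
    p: float
    pairs: list[PairResult] = field(default_factory=list)
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    def significant_pairs(self, alpha: float = 0.05) -> list[str]:
        return [pr.direction for pr in self.pairs if pr.significant(alpha)]

    def markers(self, tiers: Sequence[float] = SIG_TIERS) -> str:
        """Two-tier significance markers: '*' below tiers[0], '**' below
        tiers[1]."""
        if self.p < tiers[1]:
            return "**"
        if self.p < tiers[0]:
            return "*"
        return ""


def format_p(p: float, decimals: int = 3) -> str:
    """Table-style p: 3 decimals, '<0.001' below the lower tier."""
    floor = 10.0 ** (-decimals)
    if p < floor:
        return f"<{floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


# --------------------------------------------------------------------------
# one-way ANOVA, twin engines


def anova_from_summary(summary: GroupSummary) -> AnovaTable:
    """Classical one-way decomposition from per-group (n, mean, sd).

    SSB = sum n_i (xbar_i - grand)^2 with grand = sum n_i xbar_i / N;
    SSW = sum (n_i - 1) s_i^2.  Reproduces raw-data ANOVA exactly.
    """
    ns, means, sds = summary.ns, summary.means, summary.sds
    k, N = summary.k, summary.n_total
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    dfb, dfw = k - 1, N - k
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0.0:
        f = math.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
        return AnovaTable(ssb, ssw, dfb, dfw, msb, msw, f, p, degenerate=True)
    f = msb / msw
    return AnovaTable(ssb, ssw, dfb, dfw, msb, msw, f,
                      float(stats.f.sf(f, dfb, dfw)))


def anova_raw(groups: Mapping[str, Sequence[float]]) -> AnovaTable:
    """Raw-data one-way ANOVA (delegates to the summary engine, which is
    exact given the sufficient statistics)."""
    return anova_from_summary(GroupSummary.from_groups(groups))


def tukey_hsd(
    summary: GroupSummary | None = None,
    groups: Mapping[str, Sequence[float]] | None = None,
    anova: AnovaTable | None = None,
) -> ComparisonResult:
    """Tukey-Kramer pairwise comparisons after one-way ANOVA.

    For groups i, j: q = |xbar_i - xbar_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)),
    with p from the studentized-range distribution with (k, N - k).  The
    Kramer form handles unequal group sizes.
    """
    if summary is None:
        if groups is None:
            raise ValueError("provide summary or groups")
        summary = GroupSummary.from_groups(groups)
    if anova is None:
        anova = anova_from_summary(summary)
    k, dfw = summary.k, anova.df_within
    pairs = []
    for i, j in itertools.combinations(range(k), 2):
        diff = float(summary.means[i] - summary.means[j])
        if anova.msw == 0.0:
            q = math.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(anova.msw / 2.0
                           * (1.0 / summary.ns[i] + 1.0 / summary.ns[j]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, dfw))
        pairs.append(PairResult(summary.labels[i], summary.labels[j],
                                diff, q, p))
    return ComparisonResult(test="tukey_hsd", statistic=anova.f,
                            df=(anova.df_between, dfw), p=anova.p,
                            pairs=pairs, degenerate=anova.degenerate)


# --------------------------------------------------------------------------
# two-sample tests


def t_between(
    summary: GroupSummary | None = None,
    groups: Mapping[str, Sequence[float]] | None = None,
    variant: str = "pooled",
) -> ComparisonResult:
    """Independent-samples t between two groups, from moments alone.

    ``pooled`` is the classical equal-variance Student t; ``welch`` by
    flag.  Zero variance in both groups with equal means is reported as
    p = 1 and flagged degenerate.
    """
    if summary is None:
        if groups is None:
            raise ValueError("provide summary or groups")
        summary = GroupSummary.from_groups(groups)
    if summary.k != 2:
        raise ValueError("t test needs exactly 2 groups")
    (n1, n2), (m1, m2), (s1, s2) = summary.ns, summary.means, summary.sds
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            res = ComparisonResult("t_" + variant, 0.0, (float(n1 + n2 - 2),),
                                   1.0, degenerate=True)
            res.notes.append("zero variance in both groups")
            return res
        return ComparisonResult("t_" + variant, math.inf,
                                (float(n1 + n2 - 2),), 0.0, degenerate=True)
    if variant == "pooled":
        df = n1 + n2 - 2.0
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown t variant {variant!r}")
    t = (m1 - m2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    pair = PairResult(summary.labels[0], summary.labels[1],
                      float(m1 - m2), t, p)
    return ComparisonResult("t_" + variant, float(t), (float(df),), p,
                            pairs=[pair])


def mann_whitney(
    a: Sequence[float], b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Mann-Whitney U, exact when both n <= 10 and there are no ties,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult("mann_whitney", float(len(a) * len(b) / 2),
                                None, 1.0, degenerate=True,
                                notes=["all values tied"])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    diff = float(np.median(a) - np.median(b))
    pair = PairResult(labels[0], labels[1], diff, float(res.statistic),
                      float(res.pvalue))
    return ComparisonResult("mann_whitney", float(res.statistic), None,
                            float(res.pvalue), pairs=[pair],
                            notes=[f"method={method}"])


# --------------------------------------------------------------------------
# rank-based k-group path


def kruskal_wallis_posthoc(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis H with Dunn pairwise post hoc tests
    under Bonferroni correction over all unordered pairs."""
    labels = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(arrs)
    N = len(pooled)
    if np.all(pooled == pooled[0]):
        return ComparisonResult("kruskal_wallis", 0.0,
                                (float(len(labels) - 1),), 1.0,
                                degenerate=True, notes=["all values tied"])
    h, p = stats.kruskal(*arrs)

    # Dunn: pairwise z on mean ranks with tie correction
    ranks = stats.rankdata(pooled)
    sizes = [len(a) for a in arrs]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(arrs))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    pairs = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_adj = min(1.0, 2.0 * float(stats.norm.sf(abs(z))) * n_pairs)
        pairs.append(PairResult(labels[i], labels[j],
                                float(mean_ranks[i] - mean_ranks[j]),
                                float(z), p_adj))
    return ComparisonResult("kruskal_wallis", float(h),
                            (float(len(labels) - 1),), float(p), pairs=pairs)


# --------------------------------------------------------------------------
# gates


def variance_homogeneity(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    center: str = "median",
) -> ComparisonResult:
    """Brown-Forsythe (median-centred Levene) homogeneity-of-variance gate.

    ``homogeneous`` (p >= alpha) routes to ANOVA + Tukey HSD; failure
    routes to Kruskal-Wallis + Dunn/Bonferroni.  Mean-centred Levene by
    flag.
    """
    arrs = [np.asarray(v, dtype=float) for v in groups.values()]
    if all(np.all(a == a[0]) for a in arrs):
        res = ComparisonResult("levene_" + center, 0.0, None, 1.0,
                               degenerate=True)
        res.notes.append("homogeneous")
        return res
    w, p = stats.levene(*arrs, center=center)
    res = ComparisonResult("levene_" + center, float(w), None, float(p))
    res.notes.append("homogeneous" if p >= alpha else "heterogeneous")
    return res


def normality_gate(values: Sequence[float], alpha: float = 0.05
                   ) -> ComparisonResult:
    """Shapiro-Wilk normality gate; routes t vs Mann-Whitney and
    mean (SD) vs median (IQR) reporting."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    w, p = stats.shapiro(x)
    res = ComparisonResult("shapiro_wilk", float(w), None, float(p))
    res.notes.append("normal" if p >= alpha else "non-normal")
    return res


# --------------------------------------------------------------------------
# Fisher's exact, r x 2 (Freeman-Halton)

_ENUM_CAP = 2_000_000  # max tables to enumerate before Monte Carlo


def fisher_exact_rxc(
    table: Sequence[Sequence[int]],
    n_mc: int = 200_000,
    seed: int = 0,
) -> ComparisonResult:
    """Exact test of independence for an r x 2 contingency table.

    Enumerates all tables with the observed margins over the r - 1 free
    cells, summing the conditional multivariate-hypergeometric
    probabilities no larger than the observed one (Freeman-Halton rule).
    Falls back to Monte-Carlo sampling of tables from the null when the
    enumeration would exceed the feasibility cap; the replicate count and
    seed are recorded in the result notes.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2D array of nonnegative counts")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    notes = []
    if not keep_r.all() or not keep_c.all():
        notes.append("empty rows/columns dropped")
        t = t[keep_r][:, keep_c]
    if t.shape[1] == 1 or t.shape[0] == 1:
        return ComparisonResult("fisher_exact", 0.0, None, 1.0,
                                degenerate=True, notes=notes)
    if t.shape[1] != 2:
        raise ValueError("only r x 2 tables are supported")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    N = int(t.sum())
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(N + 1)

    def log_prob(first_col: np.ndarray) -> np.ndarray:
        a = first_col
        b = row[None, :] - a if a.ndim == 2 else row - a
        return const - gammaln(a + 1).sum(-1) - gammaln(b + 1).sum(-1)

    lp_obs = float(log_prob(t[:, 0]))
    n_tables = int(np.prod(row[:-1] + 1.0))
    if n_tables <= _ENUM_CAP:
        grids = np.meshgrid(*[np.arange(r + 1) for r in row[:-1]],
                            indexing="ij")
        first = np.stack([g.ravel() for g in grids], axis=1)
        last = col[0] - first.sum(axis=1)
        ok = (last >= 0) & (last <= row[-1])
        first = np.column_stack([first[ok], last[ok]])
        lp = log_prob(first)
        p = float(np.exp(lp[lp <= lp_obs + 1e-9]).sum())
        notes.append(f"enumeration over {int(ok.sum())} tables")
    else:
        rng = np.random.default_rng(seed)
        # sample first-column allocations from the null by permuting a
        # 0/1 membership vector across rows with fixed margins
        members = np.repeat(np.arange(len(row)), row)
        hits = 0
        batch = 2000
        done = 0
        while done < n_mc:
            m = min(batch, n_mc - done)
            sel = np.stack([
                np.bincount(rng.permutation(members)[: col[0]],
                            minlength=len(row))
                for _ in range(m)
            ])
            hits += int((log_prob(sel) <= lp_obs + 1e-9).sum())
            done += m
        p = (hits + 1) / (n_mc + 1)
        notes.append(f"monte-carlo with {n_mc} replicates, seed {seed}")
    return ComparisonResult("fisher_exact", lp_obs, None, min(p, 1.0),
                            notes=notes)
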