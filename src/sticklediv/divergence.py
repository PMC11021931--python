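"""Univariate and multivariate divergence statistics.

Trait-by-trait comparisons use the Wilcoxon rank-sum U statistic oriented so
that U counts (first, last) pairs in which the *later* specimen has the
larger value: the common-language effect size U / (n_first * n_last) is then
near 0 for traits that have been reduced.  Significance uses a Bonferroni
family threshold alpha / n_traits.

Multivariate divergence is the Euclidean distance d between two groups' trait
mean vectors, with uncertainty from resampling specimens with replacement
within each group (B = 99 bootstrap replicates) and a permutation test that
shuffles group identity (P = 99 shuffles, add-one p-value rule).  Divergence
trajectories compute d between the first temporal sample and every later one
and locate when the fossil bootstrap interval first overlaps a reference
(species-pair) divergence.  Correlated trait evolution is summarized by the
Pearson correlation matrix of per-trait temporal mean vectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_model import SpecimenTable
from .streams import substream

logger = logging.getLogger(__name__)

__all__ = [
    "TraitDivergence",
    "TraitDivergenceTable",
    "MultivariateDivergence",
    "DivergenceTrajectory",
    "TrajectoryPoint",
    "TraitCorrelationSummary",
    "wilcoxon_u",
    "cles",
    "trait_divergence_table",
    "mean_vector",
    "euclidean_d",
    "bootstrap_d",
    "permutation_test_d",
    "divergence_report",
    "compare_d_distributions",
    "divergence_trajectory",
    "first_overlap_time",
    "trait_mean_correlations",
]

DEFAULT_B = 99
DEFAULT_P = 99
DEFAULT_ALPHA_TOTAL = 0.05
#: years per generation used to convert stratigraphic ages
YEARS_PER_GENERATION = 2.0
#: exact rank-sum null used when the pooled sample is this small and tie-free
_EXACT_LIMIT = 20


# ---------------------------------------------------------------------------
# univariate


def wilcoxon_u(first: np.ndarray, last: np.ndarray) -> tuple[float, float]:
    """Rank-sum U of the last sample over the first, with two-sided p.

    U counts cross-group pairs with ``last > first`` plus half the ties.  The
    p-value uses the tie-corrected normal approximation with continuity
    correction; the exact null distribution is used automatically when the
    pooled sample has at most 20 tie-free values.
    """
    first = np.asarray(first, dtype=float)
    last = np.asarray(last, dtype=float)
    first = first[~np.isnan(first)]
    last = last[~np.isnan(last)]
    if first.size == 0 or last.size == 0:
        raise ValueError("each side needs at least one non-missing value")

    pooled = np.concatenate([first, last])
    if np.unique(pooled).size == 1:
        # all values identical: no ordering information at all
        return first.size * last.size / 2.0, 1.0

    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        last, first, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def cles(U: float, n_first: int, n_last: int) -> float:
    """Common-language effect size: U over the product of the sample sizes.

    The proportion of cross-group comparisons in which the later specimen has
    the larger value; near 0 means the last sample is consistently smaller.
    """
    if n_first < 1 or n_last < 1:
        raise ValueError("sample sizes must be >= 1")
    prod = n_first * n_last
    if not (0.0 <= U <= prod):
        raise ValueError(f"U = {U} outside [0, {prod}]")
    return U / prod


def _t_interval(vals: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    n = vals.size
    m = float(np.mean(vals))
    if n < 2:
        return (math.nan, math.nan)
    half = stats.t.ppf(0.5 + conf / 2.0, n - 1) * float(np.std(vals, ddof=1)) / math.sqrt(n)
    return (m - half, m + half)


@dataclass(frozen=True)
class TraitDivergence:
    """First-vs-last comparison of one trait."""

    trait: str
    n_first: int
    n_last: int
    U: float
    p: float
    effect_size: float  # CLES in [0, 1]
    median_diff: float  # last - first, trait units
    mean_diff: float
    pooled_variance: float
    significant: bool
    testable: bool = True
    mean_first: float = math.nan
    mean_last: float = math.nan
    ci95_first: tuple[float, float] = (math.nan, math.nan)
    ci95_last: tuple[float, float] = (math.nan, math.nan)


@dataclass(frozen=True)
class TraitDivergenceTable:
    rows: tuple[TraitDivergence, ...]
    alpha_family: float
    group_first: str
    group_last: str

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.rows if r.testable)


def trait_divergence_table(
    table: SpecimenTable,
    group_first: str,
    group_last: str,
    alpha_total: float = DEFAULT_ALPHA_TOTAL,
) -> TraitDivergenceTable:
    """Per-trait rank-sum comparison between two groups.

    The family threshold is ``alpha_total`` divided by the number of registry
    traits (0.05 / 16 = 0.003125 by default).  A trait with fewer than two
    values in either group is flagged untestable rather than dropped.
    """
    codes = table.registry.codes
    alpha_family = alpha_total / len(codes)
    rows: list[TraitDivergence] = []
    for code in codes:
        first = table.values(code, group_first)
        last = table.values(code, group_last)
        if first.size < 2 or last.size < 2:
            logger.warning(
                "trait %s untestable: %d/%d values in %s/%s",
                code, first.size, last.size, group_first, group_last,
            )
            rows.append(
                TraitDivergence(
                    trait=code, n_first=first.size, n_last=last.size,
                    U=math.nan, p=math.nan, effect_size=math.nan,
                    median_diff=math.nan, mean_diff=math.nan,
                    pooled_variance=math.nan, significant=False, testable=False,
                )
            )
            continue
        U, p = wilcoxon_u(first, last)
        n1, n2 = first.size, last.size
        pooled_var = (
            (n1 - 1) * np.var(first, ddof=1) + (n2 - 1) * np.var(last, ddof=1)
        ) / (n1 + n2 - 2)
        rows.append(
            TraitDivergence(
                trait=code,
                n_first=n1,
                n_last=n2,
                U=U,
                p=p,
                effect_size=cles(U, n1, n2),
                median_diff=float(np.median(last) - np.median(first)),
                mean_diff=float(np.mean(last) - np.mean(first)),
                pooled_variance=float(pooled_var),
                significant=bool(p < alpha_family),
                mean_first=float(np.mean(first)),
                mean_last=float(np.mean(last)),
                ci95_first=_t_interval(first),
                ci95_last=_t_interval(last),
            )
        )
    return TraitDivergenceTable(tuple(rows), alpha_family, group_first, group_last)


# ---------------------------------------------------------------------------
# multivariate


def mean_vector(
    table: SpecimenTable, group: str, traits: tuple[str, ...] | None = None
) -> np.ndarray:
    """Per-trait means of one group, missingness handled trait-wise."""
    traits = tuple(traits) if traits is not None else table.registry.codes
    out = np.empty(len(traits))
    for i, code in enumerate(traits):
        vals = table.values(code, group)
        if vals.size == 0:
            raise ValueError(f"trait {code!r} entirely missing in group {group!r}")
        out[i] = vals.mean()
    return out


def euclidean_d(v1: np.ndarray, v2: np.ndarray) -> float:
    """Euclidean distance between two trait-mean vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal length")
    if np.isnan(v1).any() or np.isnan(v2).any():
        raise ValueError("mean vectors must not contain missing entries")
    return float(np.linalg.norm(v1 - v2))


@dataclass(frozen=True)
class MultivariateDivergence:
    """Point estimate of d with bootstrap and permutation summaries."""

    d: float
    boot_values: tuple[float, ...]
    boot_mean: float
    boot_sd: float
    perm_values: tuple[float, ...] = ()
    perm_p: float = math.nan
    traits_used: tuple[str, ...] = ()
    groups: tuple[str, str] = ("", "")
    n_redrawn: int = 0


def _group_matrix(table: SpecimenTable, group: str, traits: tuple[str, ...]) -> np.ndarray:
    sub = table.data[table.data["group"] == group]
    if sub.empty:
        raise KeyError(f"unknown group {group!r}")
    return sub[list(traits)].to_numpy(dtype=float)


def _matrix_mean(m: np.ndarray) -> np.ndarray:
    """Column means over non-missing values; NaN where a column is empty."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(m, axis=0)


def _resolve_traits(
    table: SpecimenTable, traits: tuple[str, ...] | None, drop_traits: tuple[str, ...] = ()
) -> tuple[str, ...]:
    traits = tuple(traits) if traits is not None else table.registry.codes
    return tuple(c for c in traits if c not in drop_traits)


def bootstrap_d(
    table: SpecimenTable,
    group_first: str,
    group_last: str,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
    traits: tuple[str, ...] | None = None,
) -> MultivariateDivergence:
    """Bootstrap distribution of d.

    Each replicate resamples specimens with replacement independently within
    each group (same sizes) and recomputes the mean vectors and d.  A
    replicate in which some trait ends up entirely missing in either group is
    redrawn (the count of redraws is recorded), keeping B fixed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "bootstrap")
    traits = _resolve_traits(table, traits)
    m1 = _group_matrix(table, group_first, traits)
    m2 = _group_matrix(table, group_last, traits)
    if m1.shape[0] < 2 or m2.shape[0] < 2:
        raise ValueError("both groups need at least two specimens")

    d_obs = euclidean_d(_matrix_mean(m1), _matrix_mean(m2))
    boots = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(1000):
            i1 = rng.integers(0, m1.shape[0], m1.shape[0])
            i2 = rng.integers(0, m2.shape[0], m2.shape[0])
            mu1 = _matrix_mean(m1[i1])
            mu2 = _matrix_mean(m2[i2])
            if not (np.isnan(mu1).any() or np.isnan(mu2).any()):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("bootstrap replicate kept drawing an all-missing trait")
        boots[b] = np.linalg.norm(mu1 - mu2)
    if n_redrawn:
        logger.info("bootstrap_d: %d replicate(s) redrawn", n_redrawn)

    return MultivariateDivergence(
        d=d_obs,
        boot_values=tuple(boots.tolist()),
        boot_mean=float(boots.mean()),
        boot_sd=float(boots.std(ddof=1)),
        traits_used=traits,
        groups=(group_first, group_last),
        n_redrawn=n_redrawn,
    )


def permutation_test_d(
    table: SpecimenTable,
    group_first: str,
    group_last: str,
    P: int = DEFAULT_P,
    seed: int | np.random.Generator = 0,
    traits: tuple[str, ...] | None = None,
) -> tuple[float, tuple[float, ...]]:
    """Permutation p-value for d.

    Group labels are shuffled over the pooled specimens, preserving group
    sizes; p = (1 + #{d_perm >= d_obs}) / (P + 1), so the smallest attainable
    p at P = 99 is 0.01.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "permutation")
    traits = _resolve_traits(table, traits)
    m1 = _group_matrix(table, group_first, traits)
    m2 = _group_matrix(table, group_last, traits)
    if m1.shape[0] < 2 or m2.shape[0] < 2:
        raise ValueError("both groups need at least two specimens")

    d_obs = euclidean_d(_matrix_mean(m1), _matrix_mean(m2))
    pooled = np.vstack([m1, m2])
    n1 = m1.shape[0]
    perms = np.empty(P)
    for j in range(P):
        idx = rng.permutation(pooled.shape[0])
        mu1 = _matrix_mean(pooled[idx[:n1]])
        mu2 = _matrix_mean(pooled[idx[n1:]])
        perms[j] = np.linalg.norm(mu1 - mu2)
    n_ge = int(np.sum(perms >= d_obs))
    p = (1 + n_ge) / (P + 1)
    return float(p), tuple(perms.tolist())


def divergence_report(
    table: SpecimenTable,
    group_first: str,
    group_last: str,
    B: int = DEFAULT_B,
    P: int = DEFAULT_P,
    seed: int = 0,
    traits: tuple[str, ...] | None = None,
    drop_traits: tuple[str, ...] = (),
) -> MultivariateDivergence:
    """Point d plus bootstrap and permutation summaries in one record."""
    traits = _resolve_traits(table, traits, drop_traits)
    boot = bootstrap_d(table, group_first, group_last, B=B, seed=seed, traits=traits)
    perm_p, perm_values = permutation_test_d(
        table, group_first, group_last, P=P, seed=seed, traits=traits
    )
    return MultivariateDivergence(
        d=boot.d,
        boot_values=boot.boot_values,
        boot_mean=boot.boot_mean,
        boot_sd=boot.boot_sd,
        perm_values=perm_values,
        perm_p=perm_p,
        traits_used=traits,
        groups=(group_first, group_last),
        n_redrawn=boot.n_redrawn,
    )


def compare_d_distributions(
    boot_a: np.ndarray, boot_b: np.ndarray
) -> tuple[float, float, float]:
    """Welch two-sample t-test between two bootstrap d distributions.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    boot_a = np.asarray(boot_a, dtype=float)
    boot_b = np.asarray(boot_b, dtype=float)
    if boot_a.size < 2 or boot_b.size < 2:
        raise ValueError("each distribution needs at least two values")
    res = stats.ttest_ind(boot_a, boot_b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# timing


@dataclass(frozen=True)
class TrajectoryPoint:
    group: str
    age_years: float
    generations: float
    d: float
    boot_mean: float
    boot_sd: float


@dataclass(frozen=True)
class DivergenceTrajectory:
    """d between the first temporal sample and each subsequent one."""

    points: tuple[TrajectoryPoint, ...]
    group_first: str
    traits_used: tuple[str, ...]
    references: tuple[MultivariateDivergence, ...] = ()

    def __post_init__(self) -> None:
        ages = [p.age_years for p in self.points]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("trajectory ages must be strictly increasing")


def divergence_trajectory(
    table: SpecimenTable,
    ordered_groups: list[str] | None = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    references: tuple[MultivariateDivergence, ...] = (),
    traits: tuple[str, ...] | None = None,
    drop_traits: tuple[str, ...] = (),
) -> DivergenceTrajectory:
    """Iterative d between the first sample and each later sample.

    ``ordered_groups`` defaults to the table's fossil samples in stratigraphic
    order.  Any specimens that should not contribute (e.g. the earlier
    lineage co-occurring in the replacement sample) must be excluded before
    calling.  One bootstrap summary (B replicates) is attached per entry.
    """
    if ordered_groups is None:
        ordered_groups = table.ordered_fossil_groups()
    if len(ordered_groups) < 2:
        raise ValueError("need at least two ordered groups")
    traits = _resolve_traits(table, traits, drop_traits)
    rng = substream(int(seed), "bootstrap")
    first = ordered_groups[0]
    points = []
    for group in ordered_groups[1:]:
        boot = bootstrap_d(table, first, group, B=B, seed=rng, traits=traits)
        age = table.group_age(group)
        points.append(
            TrajectoryPoint(
                group=group,
                age_years=age,
                generations=age / YEARS_PER_GENERATION,
                d=boot.d,
                boot_mean=boot.boot_mean,
                boot_sd=boot.boot_sd,
            )
        )
    return DivergenceTrajectory(tuple(points), first, traits, tuple(references))


def first_overlap_time(
    traj: DivergenceTrajectory,
    reference: MultivariateDivergence,
    criterion: str = "sd-interval",
) -> tuple[float | None, float | None]:
    """Earliest age at which the fossil divergence reaches a reference level.

    ``sd-interval`` (default): the fossil interval boot_mean +/- boot_sd
    intersects the reference boot_mean +/- boot_sd (matching the mean and
    standard deviation bars of the trajectory plot; a zero-s.d. reference
    reduces to an interval-contains-point test).  ``range``: the fossil point
    d falls inside the min-max range of the reference bootstrap values.
    Returns ``(age_years, generations)`` or ``(None, None)`` if never.
    """
    if criterion == "sd-interval":
        ref_lo = reference.boot_mean - reference.boot_sd
        ref_hi = reference.boot_mean + reference.boot_sd
        for p in traj.points:
            lo, hi = p.boot_mean - p.boot_sd, p.boot_mean + p.boot_sd
            if lo <= ref_hi and ref_lo <= hi:
                return p.age_years, p.generations
        return None, None
    if criterion == "range":
        if not reference.boot_values:
            raise ValueError("'range' criterion needs the reference bootstrap values")
        ref_lo, ref_hi = min(reference.boot_values), max(reference.boot_values)
        for p in traj.points:
            if ref_lo <= p.d <= ref_hi:
                return p.age_years, p.generations
        return None, None
    raise ValueError(f"unknown overlap criterion {criterion!r}")


# ---------------------------------------------------------------------------
# correlated trait evolution


@dataclass(frozen=True)
class TraitCorrelationSummary:
    """Pearson correlations among per-trait temporal mean vectors."""

    traits: tuple[str, ...]
    matrix: tuple[tuple[float, ...], ...]  # symmetric, unit diagonal
    offdiag_mean: float
    offdiag_sd: float
    offdiag_median: float


def trait_mean_correlations(
    table: SpecimenTable, ordered_groups: list[str] | None = None
) -> TraitCorrelationSummary:
    """Correlation matrix of trait-mean time-vectors plus off-diagonal summary.

    Each trait contributes a vector of per-sample means (length = number of
    groups); traits whose vector is constant give undefined correlations
    (NaN), excluded from the off-diagonal summary.
    """
    if ordered_groups is None:
        ordered_groups = table.ordered_fossil_groups()
    if len(ordered_groups) < 3:
        raise ValueError("need at least three ordered groups")
    codes = table.registry.codes
    means = np.empty((len(codes), len(ordered_groups)))
    for j, g in enumerate(ordered_groups):
        means[:, j] = mean_vector(table, g, codes)

    k = len(codes)
    mat = np.full((k, k), np.nan)
    sds = means.std(axis=1)
    for i in range(k):
        mat[i, i] = 1.0
        for j in range(i + 1, k):
            if sds[i] == 0.0 or sds[j] == 0.0:
                continue
            r = float(np.corrcoef(means[i], means[j])[0, 1])
            mat[i, j] = mat[j, i] = r

    iu = np.triu_indices(k, 1)
    off = mat[iu]
    off = off[~np.isnan(off)]
    if off.size == 0:
        raise ValueError("no defined off-diagonal correlations")
    return TraitCorrelationSummary(
        traits=codes,
        matrix=tuple(tuple(row) for row in mat.tolist()),
        offdiag_mean=float(off.mean()),
        offdiag_sd=float(off.std(ddof=1)),
        offdiag_median=float(np.median(off)),
    )
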