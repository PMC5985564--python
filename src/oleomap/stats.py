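"""The statistical battery for comparing factor levels.

Class-count distributions across the nine radial classes are compared
between factor levels with rank tests — the Friedman test for factors
with three or more levels, the paired Wilcoxon signed-rank test for
two-level factors — with the nine classes as blocks. Per-slice total
densities are compared with one-way ANOVA (two levels: t test), followed
by a Student–Newman–Keuls (SNK) stepwise studentized-range procedure that
emits compact letter displays. Significance is taken at α = 0.05; p
values are reported raw (no cross-factor multiplicity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import UsageError

__all__ = [
    "TestResult",
    "friedman_test",
    "wilcoxon_paired",
    "anova_density",
    "t_test_density",
    "snk_letters",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    name: str  # friedman | wilcoxon | anova | t_test | snk
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    letters: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise UsageError(f"p-value {self.p_value} outside [0, 1]")


def friedman_test(matrix: np.ndarray, groups: tuple[str, ...] = ()) -> TestResult:
    """Friedman chi-square over a levels × blocks matrix.

    Rows are the treatments (factor levels), columns the blocks (the nine
    radial classes). Mid-ranks with the standard tie correction; p from
    the chi-square approximation. With every block fully tied the
    statistic is 0 and p = 1.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 3:
        raise UsageError("friedman_test needs >= 3 levels; use wilcoxon_paired for 2")
    if m.shape[1] < 2:
        raise UsageError("friedman_test needs >= 2 blocks")
    if np.all(m == m[0]):  # all treatments identical in every block
        return TestResult("friedman", 0.0, 1.0, groups)
    stat, p = sps.friedmanchisquare(*m)
    return TestResult("friedman", float(stat), float(p), groups)


def wilcoxon_paired(
    level_a: np.ndarray,
    level_b: np.ndarray,
    variant: str = "signed_rank",
    groups: tuple[str, ...] = (),
) -> TestResult:
    """Two-level comparison over the class blocks.

    ``variant="signed_rank"`` (default): paired Wilcoxon signed-rank on
    the aligned class vectors, zero differences dropped (Wilcoxon rule),
    exact null distribution for n ≤ 25 when untied. ``variant="rank_sum"``
    treats the two vectors as independent samples (Mann–Whitney U).
    """
    a = np.asarray(level_a, dtype=np.float64)
    b = np.asarray(level_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise UsageError("level vectors must be 1-D and aligned by class")
    if variant == "rank_sum":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult("wilcoxon", float(stat), float(p), groups)
    if variant != "signed_rank":
        raise UsageError(f"unknown wilcoxon variant {variant!r}")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult("wilcoxon", 0.0, 1.0, groups)
    untied = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 25 and untied) else "approx"
    stat, p = sps.wilcoxon(d, zero_method="wilcox", method=method)
    return TestResult("wilcoxon", float(stat), float(p), groups)


def _clean_groups(
    samples: dict[str, np.ndarray], min_n: int
) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in samples.items():
        v = np.asarray(vals, dtype=np.float64)
        if v.size < min_n:
            warnings.warn(
                f"level {name!r} has {v.size} < {min_n} observations; excluded",
                stacklevel=3,
            )
            continue
        out[name] = v
    return out


def anova_density(samples: dict[str, np.ndarray]) -> TestResult:
    """One-way fixed-effects ANOVA on per-slice total densities.

    Levels with fewer than two slices are excluded with a warning. If all
    observations are equal the F statistic is 0 and p = 1 (guarding the
    0/0 form).
    """
    groups = _clean_groups(samples, min_n=2)
    if len(groups) < 2:
        raise UsageError("anova needs >= 2 levels with >= 2 observations each")
    arrays = list(groups.values())
    allvals = np.concatenate(arrays)
    if np.all(allvals == allvals[0]):
        return TestResult("anova", 0.0, 1.0, tuple(groups))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        stat, p = sps.f_oneway(*arrays)
    if not np.isfinite(stat):
        return TestResult("anova", 0.0, 1.0, tuple(groups))
    return TestResult("anova", float(stat), float(p), tuple(groups))


def t_test_density(
    sample_a: np.ndarray, sample_b: np.ndarray, welch: bool = False,
    groups: tuple[str, ...] = (),
) -> TestResult:
    """Two-sample t test on densities (pooled by default, so F = t²)."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise UsageError("t test needs >= 2 observations per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return TestResult("t_test", 0.0, 1.0, groups)
    stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult("t_test", float(stat), float(p), groups)


def anova_mse(samples: dict[str, np.ndarray]) -> tuple[float, int]:
    """Within-group mean square and its degrees of freedom (for SNK)."""
    groups = _clean_groups(samples, min_n=2)
    if len(groups) < 2:
        raise UsageError("need >= 2 levels with >= 2 observations each")
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    df = sum(v.size for v in groups.values()) - len(groups)
    return sse / df, df


def snk_letters(
    means: dict[str, float],
    ns: dict[str, int],
    mse: float,
    df: int,
    alpha: float = ALPHA_DEFAULT,
) -> TestResult:
    """Student–Newman–Keuls compact letter display.

    Means are sorted; stretches of p adjacent means are tested outward-in
    with the studentized range at (p, df), using the harmonic mean of the
    two extreme groups' sizes for unbalanced designs. A non-significant
    stretch shields all its sub-stretches (the SNK stepwise rule). Groups
    sharing a letter are not significantly different at ``alpha``.
    """
    if df <= 0:
        raise UsageError("error degrees of freedom must be positive")
    if mse < 0:
        raise UsageError("mean-square error must be non-negative")
    names = list(means)
    k = len(names)
    if k < 2:
        raise UsageError("need >= 2 groups")
    order = sorted(range(k), key=lambda i: means[names[i]])
    sorted_names = [names[i] for i in order]
    m = np.array([means[n] for n in sorted_names])
    n_arr = np.array([ns[n] for n in sorted_names], dtype=np.float64)

    # nonsig[i][j]: stretch of sorted means i..j accepted as homogeneous
    nonsig: set[tuple[int, int]] = set()
    max_q = 0.0
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in nonsig):
                nonsig.add((i, j))
                continue
            n_h = 2.0 / (1.0 / n_arr[i] + 1.0 / n_arr[j])
            se = np.sqrt(mse / n_h) if mse > 0 else 0.0
            if se == 0.0:
                significant = m[j] > m[i]
            else:
                q_obs = (m[j] - m[i]) / se
                max_q = max(max_q, q_obs)
                q_crit = sps.studentized_range.ppf(1.0 - alpha, span, df)
                significant = q_obs > q_crit
            if not significant:
                nonsig.add((i, j))

    # maximal homogeneous stretches -> letters; uncovered groups get their own
    maximal = [
        (a, b)
        for a, b in nonsig
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in nonsig)
    ]
    covered = {g for a, b in maximal for g in range(a, b + 1)}
    maximal += [(g, g) for g in range(k) if g not in covered]
    maximal.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {n: "" for n in sorted_names}
    for letter, (a, b) in zip(alphabet, maximal):
        for g in range(a, b + 1):
            letters[sorted_names[g]] += letter
    # p_value is not a single number for a stepwise procedure; report NaN
    return TestResult(
        "snk", statistic=max_q, p_value=float("nan"),
        groups=tuple(sorted_names), letters={n: letters[n] for n in names},
    )
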