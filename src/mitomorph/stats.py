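"""Group comparisons: one-way ANOVA with Tukey HSD post-hoc tests.

Every endpoint (mean branch length, footprint, membrane potential,
respiratory components, ...) is compared across treatment groups with a
classical equal-variance one-way ANOVA, followed by all-pairs Tukey
honestly-significant-difference tests with the Tukey–Kramer unequal-n
correction.  Significance is called at α = 0.05 by default.

The studentized-range tail probability is computed here by numerical
integration of its standard double-integral representation

    P(Q ≤ q) = ∫₀^∞ f_ν(s) · k ∫ φ(z) [Φ(z) − Φ(z − q·s)]^{k−1} dz ds

where s is the square root of a χ²_ν/ν variate, rather than delegated
to any particular library's q-distribution, so the implementation can
be cross-validated against independent references.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as spstats


@dataclass
class GroupedMeasurements:
    """One endpoint's measurements, grouped by treatment label."""

    endpoint: str
    groups: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        cleaned = []
        for label, values in self.groups:
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError(f"group {label!r} needs >= 2 values")
            if not np.isfinite(arr).all():
                raise ValueError(f"group {label!r} contains non-finite values")
            cleaned.append((str(label), arr))
        self.groups = cleaned

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value_col: str, group_col: str = "group"
    ) -> "GroupedMeasurements":
        """Build from a tidy table, dropping NaN values (flagged cells)."""
        groups = []
        for label, sub in df.groupby(group_col, sort=False):
            vals = sub[value_col].dropna().to_numpy()
            groups.append((str(label), vals))
        return cls(endpoint=value_col, groups=groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_total(self) -> int:
        return sum(v.size for _, v in self.groups)


def _sums_of_squares(data: GroupedMeasurements):
    values = [v for _, v in data.groups]
    ns = np.array([v.size for v in values])
    means = np.array([v.mean() for v in values])
    grand = np.concatenate(values).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((v - m) ** 2).sum() for v, m in zip(values, means)))
    return ss_between, ss_within, ns, means


def one_way_anova(data: GroupedMeasurements) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns ``(F, p)`` with F the between/within mean-square ratio and p
    from the F distribution with (k − 1, N − k) degrees of freedom.

    Raises
    ------
    ValueError
        If both between- and within-group variance are zero (all values
        identical — no test is possible).
    """
    ss_between, ss_within, ns, _ = _sums_of_squares(data)
    k, n_tot = data.k, data.n_total
    if n_tot <= k:
        raise ValueError("need more observations than groups")
    df_between, df_within = k - 1, n_tot - k
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("degenerate input: zero variance everywhere")
    if ss_within == 0.0:
        return float("inf"), 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(spstats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


# --------------------------------------------------------------------------
# studentized-range distribution (numerical double integral)
# --------------------------------------------------------------------------

_GL_NODES: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre(n: int, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_NODES:
        _GL_NODES[n] = np.polynomial.legendre.leggauss(n)
    x, w = _GL_NODES[n]
    mid, half = 0.5 * (a + b), 0.5 * (b - a)
    return mid + half * x, half * w

_NORM_CONST = 1.0 / np.sqrt(2.0 * np.pi)


def _range_cdf(r: np.ndarray, k: int, n_nodes: int = 240) -> np.ndarray:
    """P(range of k iid standard normals <= r), vectorized over r.

    Gauss–Legendre quadrature of k·∫ φ(z)[Φ(z) − Φ(z − r)]^{k−1} dz on
    z ∈ [−9, 9] (the Gaussian factor is ~1e-18 beyond).
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    z, w = _gauss_legendre(n_nodes, -9.0, 9.0)
    phi = _NORM_CONST * np.exp(-0.5 * z * z)
    inner = (special.ndtr(z)[None, :]
             - special.ndtr(z[None, :] - r[:, None])) ** (k - 1)
    out = k * (inner * (w * phi)[None, :]).sum(axis=1)
    return np.clip(out, 0.0, 1.0)


def studentized_range_sf(q: float, k: int, df: float,
                         n_nodes: int = 240) -> float:
    """Upper tail P(Q_{k,df} > q) of the studentized range.

    Numerically integrates the standard double-integral form: the range
    CDF of k standard normals, mixed over the scale s = sqrt(χ²_df/df).
    ``df = inf`` gives the plain normal range.
    """
    if q <= 0:
        return 1.0
    if k < 2:
        raise ValueError("k must be >= 2")
    if not np.isfinite(df):
        return float(1.0 - _range_cdf(np.array([q]), k)[0])

    # the scale density is concentrated around 1 with sd ~ 1/sqrt(2 df)
    half_width = 12.0 / np.sqrt(2.0 * df)
    lo, hi = max(0.0, 1.0 - half_width), 1.0 + half_width
    s, w = _gauss_legendre(n_nodes, lo, hi)
    ln_norm = (np.log(2.0) + 0.5 * df * np.log(df / 2.0)
               - special.gammaln(df / 2.0))
    log_f = ln_norm + (df - 1.0) * np.log(s) - df * s * s / 2.0
    cdf = float((np.exp(log_f) * _range_cdf(q * s, k) * w).sum())
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def studentized_range_ppf(upper_prob: float, k: int, df: float) -> float:
    """Critical value q with P(Q_{k,df} > q) = upper_prob."""
    if not 0 < upper_prob < 1:
        raise ValueError("upper_prob must be in (0, 1)")
    return float(
        optimize.brentq(
            lambda q: studentized_range_sf(q, k, df) - upper_prob, 1e-6, 100.0,
            xtol=1e-10,
        )
    )


# --------------------------------------------------------------------------
# Tukey HSD
# --------------------------------------------------------------------------

@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    p_adjusted: float
    significant: bool


@dataclass
class ComparisonResult:
    """ANOVA F/p plus all Tukey-adjusted pairwise comparisons."""

    endpoint: str
    f_statistic: float
    anova_p: float
    pairwise: list[PairwiseComparison]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "endpoint": self.endpoint,
                "group_a": pc.pair[0],
                "group_b": pc.pair[1],
                "mean_difference": pc.mean_difference,
                "p_adjusted": pc.p_adjusted,
                "significant": pc.significant,
                "f_statistic": self.f_statistic,
                "anova_p": self.anova_p,
            }
            for pc in self.pairwise
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"endpoint: {self.endpoint}",
            f"one-way ANOVA: F = {self.f_statistic:.4g}, p = {self.anova_p:.4g}",
            f"Tukey HSD (alpha = {self.alpha}):",
        ]
        for pc in self.pairwise:
            star = " *" if pc.significant else ""
            lines.append(
                f"  {pc.pair[0]} vs {pc.pair[1]}: diff = "
                f"{pc.mean_difference:+.4g}, p_adj = {pc.p_adjusted:.4g}{star}"
            )
        return "\n".join(lines)


def tukey_hsd(data: GroupedMeasurements, alpha: float = 0.05) -> ComparisonResult:
    """All-pairs Tukey HSD with the Tukey–Kramer unequal-n correction.

    Each pair's studentized range statistic is
    ``q = |m_i − m_j| / sqrt(MSW/2 · (1/n_i + 1/n_j))`` with MSW the
    within-group mean square; the adjusted p-value is the upper tail of
    the studentized-range distribution with (k, N − k) parameters.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    f_stat, anova_p = one_way_anova(data)
    _, ss_within, ns, means = _sums_of_squares(data)
    k, n_tot = data.k, data.n_total
    msw = ss_within / (n_tot - k)
    labels = [lbl for lbl, _ in data.groups]

    pairwise = []
    for i, j in combinations(range(k), 2):
        diff = float(means[i] - means[j])
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = studentized_range_sf(q, k, n_tot - k)
        pairwise.append(
            PairwiseComparison(
                pair=(labels[i], labels[j]),
                mean_difference=diff,
                p_adjusted=p_adj,
                significant=p_adj <= alpha,
            )
        )
    return ComparisonResult(data.endpoint, f_stat, anova_p, pairwise, alpha)


def compare_endpoints(
    df: pd.DataFrame,
    endpoints: list[str],
    group_col: str = "group",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Run ANOVA + Tukey for every endpoint column of a tidy table."""
    return [
        tukey_hsd(GroupedMeasurements.from_frame(df, ep, group_col), alpha)
        for ep in endpoints
    ]


# --------------------------------------------------------------------------
# calibration simulations (vectorized)
# --------------------------------------------------------------------------

def _anova_f_vectorized(x: np.ndarray) -> np.ndarray:
    """F statistics for a (reps, k, n) array of equal-n groups."""
    reps, k, n = x.shape
    gm = x.mean(axis=2)                      # (reps, k)
    grand = x.mean(axis=(1, 2))              # (reps,)
    ssb = n * ((gm - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((x - gm[:, :, None]) ** 2).sum(axis=(1, 2))
    return (ssb / (k - 1)) / (ssw / (k * n - k))


def simulate_null_anova_rejection(
    n_groups: int = 3,
    n_per_group: int = 10,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    effect: float = 0.0,
) -> float:
    """Fraction of replicates whose ANOVA rejects at ``alpha``.

    Groups are standard normal; ``effect`` adds a linear mean trend of
    that total magnitude across groups (0 = null calibration).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_reps, n_groups, n_per_group))
    if effect != 0.0:
        shift = np.linspace(0.0, effect, n_groups)
        x = x + shift[None, :, None]
    f = _anova_f_vectorized(x)
    crit = spstats.f.isf(alpha, n_groups - 1, n_groups * (n_per_group - 1))
    return float((f > crit).mean())


def simulate_tukey_familywise_error(
    n_groups: int = 3,
    n_per_group: int = 10,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Familywise error rate of Tukey HSD under the complete null.

    With equal n, at least one pair is (falsely) declared significant
    exactly when the overall studentized range statistic exceeds the
    critical value, so the rate is P(q_max > q_crit) over replicates.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_reps, n_groups, n_per_group))
    gm = x.mean(axis=2)
    msw = ((x - gm[:, :, None]) ** 2).sum(axis=(1, 2)) / (
        n_groups * (n_per_group - 1)
    )
    q_max = (gm.max(axis=1) - gm.min(axis=1)) / np.sqrt(msw / n_per_group)
    q_crit = studentized_range_ppf(alpha, n_groups,
                                   n_groups * (n_per_group - 1))
    return float((q_max > q_crit).mean())
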