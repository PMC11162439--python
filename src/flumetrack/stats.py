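"""Nonparametric test battery for group-size and velocity effects.

The battery mirrors a repeated-measures flume design: group size (1 < 2 < 6)
is a between-subject factor tested per velocity with a one-sided
Jonckheere-Terpstra trend test (activity measures EA and TL, where larger
groups are expected to score higher) or a Kruskal-Wallis test (positional
medians, where only differences are expected); flow velocity (10, 20,
35 cm/s) is a within-subject factor tested per group-size cluster with a
Friedman test, followed where significant by paired Wilcoxon signed-rank
post-hoc tests with Bonferroni correction over the three velocity pairs.

The Jonckheere-Terpstra statistic is the sum over ordered group pairs of
Mann-Whitney counts, J = sum_{i<j} #{a in G_i, b in G_j : a < b} + ties/2,
with mean mu = (N^2 - sum n_k^2)/4 and the tie-corrected variance of
Hollander & Wolfe; the one-sided p for an increasing trend is the upper
normal tail of z = (J - mu)/sigma.  A permutation mode (label reshuffling)
is available as a small-sample alternative to the normal approximation.

Also included are the reference swimming-speed computations: Videler's
empirical sustained-speed relation U_ms = 0.15 + 2.4 L (metres, seconds)
and the body-lengths-per-second conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "jonckheere_terpstra",
    "kruskal_wallis",
    "friedman",
    "wilcoxon_signed_rank",
    "bonferroni",
    "run_battery",
    "videler_ums",
    "bl_rate_to_speed",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of one nonparametric test."""

    test: str
    statistic: float
    p: float
    z_or_chi2: float | None = None
    df: int | None = None
    p_adj: float | None = None
    alternative: str | None = None
    method: str = "normal-approx"
    n: int = 0


def _jt_statistic(groups: list[np.ndarray]) -> float:
    J = 0.0
    for gi, gj in combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        J += float((diff > 0).sum()) + 0.5 * float((diff == 0).sum())
    return J


def jonckheere_terpstra(
    groups,
    alternative: str = "increasing",
    method: str = "normal",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """One-sided Jonckheere-Terpstra trend test across ordered groups.

    ``groups`` is a sequence of 1-D arrays in the stated order; the order is
    part of the hypothesis, never inferred from the data.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two ordered groups are required")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if alternative not in ("increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")
    ns = np.array([len(g) for g in groups], dtype=float)
    N = ns.sum()
    if N < 3:
        raise ValueError("need at least three observations in total")

    J = _jt_statistic(groups)
    mu = (N**2 - (ns**2).sum()) / 4.0

    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (ns * (ns - 1) * (ns - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
        / (36.0 * N * (N - 1) * (N - 2))
    )
    term3 = (ns * (ns - 1)).sum() * (t * (t - 1)).sum() / (8.0 * N * (N - 1))
    var = term1 + term2 + term3

    if var <= 0:  # all observations identical
        z = 0.0
        p = 0.5
    else:
        z = (J - mu) / np.sqrt(var)
        p = float(sps.norm.sf(z)) if alternative == "increasing" else float(sps.norm.cdf(z))

    used = "normal-approx"
    if method == "permutation":
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(groups)), ns.astype(int))
        count = 0
        for _ in range(n_perm):
            rng.shuffle(labels)
            perm_groups = [pooled[labels == k] for k in range(len(groups))]
            Jp = _jt_statistic(perm_groups)
            if alternative == "increasing":
                count += Jp >= J
            else:
                count += Jp <= J
        p = (1 + count) / (1 + n_perm)
        used = "permutation"
    elif method != "normal":
        raise ValueError(f"unknown method {method!r}")

    return TestResult(
        test="jonckheere-terpstra", statistic=J, z_or_chi2=z, p=float(p),
        alternative=alternative, method=used, n=int(N),
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank test for location differences among k groups."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if np.ptp(np.concatenate(groups)) == 0:
        # identical data: H = 0 by definition; scipy raises instead
        return TestResult(test="kruskal-wallis", statistic=0.0, z_or_chi2=0.0,
                          df=len(groups) - 1, p=1.0, method="chi2",
                          n=sum(len(g) for g in groups))
    H, p = sps.kruskal(*groups)
    return TestResult(
        test="kruskal-wallis", statistic=float(H), z_or_chi2=float(H),
        df=len(groups) - 1, p=float(p), method="chi2",
        n=sum(len(g) for g in groups),
    )


def _friedman_statistic(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square for a blocks x treatments matrix."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, matrix)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * (R**2).sum() - 3.0 * n * (k + 1)
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:  # every block constant
        return 0.0
    return chi2 / c


def friedman(
    matrix,
    method: str = "chi2",
    max_exhaustive: int = 100_000,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Friedman test for a complete blocks (trials) x treatments matrix.

    Rows with missing values are dropped (incomplete blocks).  ``method``
    'chi2' uses the chi-square approximation with tie correction;
    'permutation' compares against within-block permutations of the
    treatment labels (exhaustive when k!^n is small enough, else sampled).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D blocks x treatments matrix")
    complete = ~np.isnan(matrix).any(axis=1)
    n_dropped = int((~complete).sum())
    matrix = matrix[complete]
    n, k = matrix.shape
    if n < 2:
        raise ValueError("need at least two complete blocks")
    chi2 = _friedman_statistic(matrix)
    df = k - 1

    if method == "chi2":
        p = float(sps.chi2.sf(chi2, df))
        used = "chi2"
    elif method == "permutation":
        from math import factorial

        perms = list(__import__("itertools").permutations(range(k)))
        total = factorial(k) ** n
        if total <= max_exhaustive:
            count = 0
            for combo in product(range(len(perms)), repeat=n):
                pm = np.array([matrix[i, list(perms[c])] for i, c in enumerate(combo)])
                if _friedman_statistic(pm) >= chi2 - 1e-12:
                    count += 1
            p = count / total
            used = "permutation-exhaustive"
        else:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                pm = matrix.copy()
                for i in range(n):
                    rng.shuffle(pm[i])
                if _friedman_statistic(pm) >= chi2 - 1e-12:
                    count += 1
            p = (1 + count) / (1 + n_perm)
            used = "permutation"
    else:
        raise ValueError(f"unknown method {method!r}")

    res = TestResult(test="friedman", statistic=chi2, z_or_chi2=chi2, df=df,
                     p=float(p), method=used, n=n)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info("friedman: dropped %d incomplete blocks", n_dropped)
    return res


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zeros are discarded (classical Wilcoxon); the statistic reported is W+,
    the rank sum of positive differences on mid-ranks of |d|.  The p-value is
    exact for n <= 25 without ties, else a continuity-corrected normal
    approximation (scipy's 'auto' policy).
    """
    d = np.asarray(differences, dtype=float).ravel()
    d = d[d != 0.0]
    if len(d) == 0:
        return TestResult(test="wilcoxon", statistic=float("nan"), p=1.0,
                          alternative="two-sided", method="degenerate", n=0)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method="auto")
    method = "exact" if len(d) <= 25 and len(np.unique(np.abs(d))) == len(d) else "normal-approx"
    return TestResult(test="wilcoxon", statistic=w_plus, p=float(res.pvalue),
                      alternative="two-sided", method=method, n=len(d))


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p), order preserved."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


# ---------------------------------------------------------------------------
# the full battery


GROUP_ORDER = (1, 2, 6)
VELOCITY_ORDER = (10.0, 20.0, 35.0)
ACTIVITY_VARS = ("EA", "TL_m")
MEDIAN_VARS = ("median_x", "median_y", "median_z")


def run_battery(
    metrics: pd.DataFrame,
    alpha: float = ALPHA,
    velocities=VELOCITY_ORDER,
    group_order=None,
) -> pd.DataFrame:
    """Run the full test layout on a per-trial metrics table.

    Expected columns: trial_id, group_size, velocity, EA, TL_m, median_x,
    median_y, median_z.  Rows of the result: one per test, with columns
    test, variable, cluster, statistic, df, z_or_chi2, p, p_adj, method, n.

    Layout: JT (one-sided, increasing with group size) on EA and TL at each
    velocity; Kruskal-Wallis on the three positional medians at each
    velocity; Friedman on every variable within each group-size cluster;
    paired Wilcoxon with Bonferroni (m = 3) over velocity pairs wherever the
    Friedman test is significant at ``alpha``.
    """
    if group_order is None:
        # ascending group size; the stated trend direction is increasing
        group_order = tuple(sorted(metrics["group_size"].unique()))
    if len(group_order) < 2:
        raise ValueError("the battery needs at least two group sizes")

    rows: list[dict] = []

    def emit(res: TestResult, variable: str, cluster: str) -> None:
        rows.append(
            {
                "test": res.test, "variable": variable, "cluster": cluster,
                "statistic": res.statistic, "df": res.df,
                "z_or_chi2": res.z_or_chi2, "p": res.p, "p_adj": res.p_adj,
                "method": res.method, "n": res.n,
            }
        )

    # group-size trend on activity measures, per velocity
    for vel in velocities:
        sub = metrics.loc[metrics["velocity"] == vel]
        for var in ACTIVITY_VARS:
            groups = [sub.loc[sub["group_size"] == g, var].dropna().to_numpy()
                      for g in group_order]
            emit(jonckheere_terpstra(groups), var, f"{vel:g} cm/s")

    # group-size differences on positional medians, per velocity
    for vel in velocities:
        sub = metrics.loc[metrics["velocity"] == vel]
        for var in MEDIAN_VARS:
            groups = [sub.loc[sub["group_size"] == g, var].dropna().to_numpy()
                      for g in group_order]
            emit(kruskal_wallis(groups), var, f"{vel:g} cm/s")

    # velocity effect within each group-size cluster (repeated measures)
    for g in group_order:
        sub = metrics.loc[metrics["group_size"] == g]
        for var in ACTIVITY_VARS + MEDIAN_VARS:
            pivot = sub.pivot_table(index="trial_id", columns="velocity",
                                    values=var, aggfunc="first")
            pivot = pivot.reindex(columns=list(velocities))
            mat = pivot.to_numpy(dtype=float)
            if (~np.isnan(mat).any(axis=1)).sum() < 2:
                import logging

                logging.getLogger(__name__).info(
                    "battery: skipping Friedman on %s for %d-fish cluster "
                    "(fewer than two complete blocks)", var, g)
                continue
            fr = friedman(mat)
            emit(fr, var, f"{g} fish")
            if fr.p < alpha:
                complete = pivot.dropna()
                pair_results = []
                for va, vb in combinations(velocities, 2):
                    d = (complete[vb] - complete[va]).to_numpy()
                    pair_results.append((va, vb, wilcoxon_signed_rank(d)))
                adj = bonferroni([r.p for _, _, r in pair_results], m=3)
                for (va, vb, r), pa in zip(pair_results, adj):
                    rows.append(
                        {
                            "test": "wilcoxon", "variable": var,
                            "cluster": f"{g} fish: {va:g} vs {vb:g} cm/s",
                            "statistic": r.statistic, "df": None,
                            "z_or_chi2": None, "p": r.p, "p_adj": pa,
                            "method": r.method, "n": r.n,
                        }
                    )

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference swimming speeds


def videler_ums(body_length_cm: float) -> float:
    """Maximum sustained swimming speed (cm/s) from Videler's relation.

    U_ms[m/s] = 0.15 + 2.4 * L[m]; returns cm/s.  For a 5-cm fish this gives
    27 cm/s, the boundary between aerobic sustained swimming and the more
    demanding prolonged range.
    """
    if body_length_cm <= 0:
        raise ValueError(f"body length must be > 0, got {body_length_cm}")
    return (0.15 + 2.4 * body_length_cm / 100.0) * 100.0


def bl_rate_to_speed(rate_bl_s: float, body_length_cm: float,
                     round_cm_s: bool = False) -> float:
    """Convert a speed in body lengths per second to cm/s."""
    if rate_bl_s < 0 or body_length_cm <= 0:
        raise ValueError("rate must be >= 0 and body length > 0")
    speed = rate_bl_s * body_length_cm
    return float(round(speed)) if round_cm_s else speed
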