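"""Statistical battery for the reward / effort learning analysis.

Covers: the effort-modulation statistic (press-speed difference between
high- and low-reward trials at matched effort) with single-pass +/- k SD
outlier removal and a one-tailed one-sample t-test; Spearman and partial
Spearman correlations (partials are Pearson partial correlations on ranks);
Benjamini-Hochberg FDR adjustment applied within configurable families;
the Pearson-Filon z test for two dependent correlations sharing a variable;
the two rating/accuracy ANOVAs; and an a priori sample-size calculation for
a correlation test using the exact sampling distribution of r under a
bivariate-normal model (with the Fisher-z approximation as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .task import SessionData

# ---------------------------------------------------------------------------
# Effort modulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffortModulation:
    """Mean press speeds on high- vs low-reward trials at high effort demand."""

    participant_id: str
    speed_high: float
    speed_low: float | None
    diff: float | None
    n_high: int
    n_low: int
    outlier_flag: bool = False


def effort_modulation(session: SessionData) -> EffortModulation:
    """Press-speed difference: high-reward/high-effort minus low-reward/high-effort.

    Averages span the whole task. Effort-block high-effort trials count as
    high-reward/high-effort because the reward there is fixed at its high
    level; low-reward/high-effort trials only occur in the reward block. A
    participant who never saw a low-reward outcome has an undefined
    difference (``diff=None``) and is flagged.
    """
    high, low = [], []
    for t in session.trials:
        if t.press_speed is None:
            raise ValueError("trials must carry press speeds for effort modulation")
        if t.effort_level != "high":
            continue
        (high if t.reward_level == "high" else low).append(t.press_speed)
    if not high:
        raise ValueError("no high-reward/high-effort trials in session")
    speed_high = float(np.mean(high))
    if not low:
        return EffortModulation(session.participant_id, speed_high, None, None,
                                len(high), 0, outlier_flag=True)
    speed_low = float(np.mean(low))
    return EffortModulation(
        session.participant_id, speed_high, speed_low, speed_high - speed_low,
        len(high), len(low),
    )


def filter_outliers(values, k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Remove values at least ``k`` sample SDs from the mean (single pass).

    Mean and SD are computed once on the full input; removal is not
    iterated. Returns ``(retained, removed_indices)``. With zero variance
    nothing is removed.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    if k <= 0:
        raise ValueError("k must be positive")
    sd = values.std(ddof=1)
    if sd == 0.0:
        return values.copy(), np.array([], dtype=np.int64)
    keep = np.abs(values - values.mean()) < k * sd
    return values[keep], np.flatnonzero(~keep)


def one_sample_t_one_tailed(values, mu0: float = 0.0) -> tuple[float, int, float]:
    """Upper-tailed one-sample t-test of the mean against ``mu0``.

    Returns ``(t, df, p)`` with ``p = P(T_df > t)``, testing whether the
    population mean exceeds ``mu0``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance: t statistic undefined")
    n = values.size
    t = (values.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    return float(t), df, float(sps.t.sf(t, df))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    covariates: tuple[str, ...]
    method: str
    rho: float
    p: float
    n: int
    p_adjusted: float | None = None


def spearman_partial(
    x, y, covariates=None, pair: str = "x~y", covariate_names: tuple[str, ...] = ()
) -> CorrelationResult:
    """Spearman correlation, optionally partialling out covariates.

    With covariates, all variables are rank-transformed and a Pearson
    partial correlation is computed on the ranks (residualising both x and
    y on the covariates); the p-value uses the t-approximation with
    ``df = n - 2 - n_covariates``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input vector: correlation undefined")
    n = x.size
    if covariates is None or len(covariates) == 0:
        if n <= 2:
            raise ValueError("need n > 2")
        res = sps.spearmanr(x, y)
        return CorrelationResult(pair, (), "spearman", float(res.statistic),
                                 float(res.pvalue), n)
    Z = np.column_stack([np.asarray(c, dtype=float) for c in covariates])
    if Z.shape[0] != n:
        raise ValueError("covariates must match x/y length")
    ncov = Z.shape[1]
    if n <= ncov + 2:
        raise ValueError("need n > number of covariates + 2")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    Zr = np.column_stack([sps.rankdata(Z[:, j]) for j in range(ncov)])
    design = np.column_stack([np.ones(n), Zr])
    rx = xr - design @ np.linalg.lstsq(design, xr, rcond=None)[0]
    ry = yr - design @ np.linalg.lstsq(design, yr, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0.0:
        raise ValueError("residual variance is zero: partial correlation undefined")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - ncov
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(pair, tuple(covariate_names) or tuple(f"z{j}" for j in range(ncov)),
                             "spearman_partial", r, p, n)


def bh_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(adjusted_p, reject)`` where rejection is at level ``q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass(frozen=True)
class DependentCorrelationTest:
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z: float
    p: float


def pearson_filon_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> DependentCorrelationTest:
    """Pearson-Filon z test comparing two dependent correlations sharing variable j.

    Tests rho_jk = rho_jh given the correlation r_kh between the two
    non-shared variables; two-sided p from the standard normal.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    if n <= 3:
        raise ValueError("need n > 3")
    C = np.array([[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]])
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")
    k = r_kh * (1 - r_jk**2 - r_jh**2) - 0.5 * r_jk * r_jh * (1 - r_jk**2 - r_jh**2 - r_kh**2)
    denom = (1 - r_jk**2) ** 2 + (1 - r_jh**2) ** 2 - 2 * k
    if denom <= 0.0:
        raise ValueError("degenerate correlation structure: variance estimate nonpositive")
    z = (r_jk - r_jh) * np.sqrt(n) / np.sqrt(denom)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DependentCorrelationTest(r_jk, r_jh, r_kh, n, float(z), p)


# ---------------------------------------------------------------------------
# ANOVAs
# ---------------------------------------------------------------------------


def rating_anova(ratings_diff: pd.DataFrame, within_subject: bool = False) -> pd.DataFrame:
    """ANOVA on rating differences (high minus low reward) by type and time.

    ``ratings_diff`` is long-format with columns ``participant_id``,
    ``rating_type`` (3 levels), ``time`` (pre/post) and ``diff``. The
    default is a fixed-effects two-way ANOVA on the pooled observations
    (error df = N*6 - 6); ``within_subject=True`` instead runs a two-way
    repeated-measures ANOVA.
    """
    required = {"participant_id", "rating_type", "time", "diff"}
    missing = required - set(ratings_diff.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    n_types = ratings_diff["rating_type"].nunique()
    n_times = ratings_diff["time"].nunique()
    cell_counts = ratings_diff.groupby(
        ["participant_id", "rating_type", "time"], sort=False
    ).size().unstack(["rating_type", "time"])
    if cell_counts.isna().any().any() or (cell_counts != 1).any().any():
        raise ValueError(
            "every participant needs exactly one observation per rating_type x time cell "
            f"({n_types} x {n_times})"
        )
    if ratings_diff["diff"].std(ddof=1) == 0.0:
        raise ValueError("constant dependent variable: F undefined")
    if within_subject:
        import pingouin as pg

        table = pg.rm_anova(
            data=ratings_diff, dv="diff", within=["rating_type", "time"],
            subject="participant_id", detailed=True,
        )
        return pd.DataFrame(
            {
                "effect": table["Source"],
                "F": table["F"],
                "df1": table["ddof1"],
                "df2": table["ddof2"],
                "p": table[_p_col(table)],
            }
        )
    model = ols("diff ~ C(rating_type) * C(time)", data=ratings_diff).fit()
    aov = anova_lm(model, typ=2)
    df_err = float(aov.loc["Residual", "df"])
    rows = []
    labels = {
        "C(rating_type)": "rating_type",
        "C(time)": "time",
        "C(rating_type):C(time)": "rating_type:time",
    }
    for key, label in labels.items():
        rows.append(
            {
                "effect": label,
                "F": float(aov.loc[key, "F"]),
                "df1": float(aov.loc[key, "df"]),
                "df2": df_err,
                "p": float(aov.loc[key, "PR(>F)"]),
            }
        )
    return pd.DataFrame(rows)


def block_order_anova(accuracies: pd.DataFrame) -> pd.DataFrame:
    """Mixed ANOVA: block type (within) by block order (between) on accuracy.

    ``accuracies`` is long-format with columns ``participant_id``, ``block``
    (reward/effort), ``block_order`` and ``accuracy``; two rows per
    participant.
    """
    import pingouin as pg

    required = {"participant_id", "block", "block_order", "accuracy"}
    missing = required - set(accuracies.columns)
    if missing:
        raise ValueError(f"accuracy table missing columns: {sorted(missing)}")
    if accuracies["block_order"].nunique() < 2:
        raise ValueError("need both block orders for the between-subject factor")
    counts = accuracies.groupby("participant_id")["block"].nunique()
    if (counts != 2).any():
        raise ValueError("every participant needs both block accuracies")
    table = pg.mixed_anova(
        data=accuracies, dv="accuracy", within="block", between="block_order",
        subject="participant_id",
    )
    return pd.DataFrame(
        {
            "effect": table["Source"].replace({"block_order": "order", "Interaction": "block:order"}),
            "F": table["F"],
            "df1": table["DF1"],
            "df2": table["DF2"],
            "p": table[_p_col(table)],
        }
    )


def _p_col(table: pd.DataFrame) -> str:
    return "p_unc" if "p_unc" in table.columns else "p-unc"


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------


def _log_pdf_r(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Log of the exact density of the sample correlation coefficient.

    Hotelling's hypergeometric form for a bivariate-normal sample of size n
    with population correlation rho.
    """
    return (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2 * np.log1p(-rho**2)
        + (n - 4) / 2 * np.log1p(-(r**2))
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2))
    )


def correlation_power(rho: float, n: int, alpha: float = 0.05, method: str = "exact") -> float:
    """Power of the two-sided test of zero correlation at sample size n."""
    if n < 4:
        raise ValueError("need n >= 4")
    if method == "fisher":
        za = sps.norm.ppf(1 - alpha / 2)
        zrho = np.arctanh(rho) * np.sqrt(n - 3)
        return float(sps.norm.sf(za - zrho) + sps.norm.cdf(-za - zrho))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'fisher'")
    tc = sps.t.ppf(1 - alpha / 2, n - 2)
    rc = tc / np.sqrt(n - 2 + tc**2)
    pdf = lambda r: np.exp(_log_pdf_r(r, rho, n))
    upper, _ = integrate.quad(pdf, rc, 1.0, limit=200)
    lower, _ = integrate.quad(pdf, -1.0, -rc, limit=200)
    return float(upper + lower)


def power_min_n(rho: float, power: float = 0.80, alpha: float = 0.05,
                method: str = "exact") -> int:
    """Smallest n at which the zero-correlation test reaches the target power.

    The default evaluates the exact sampling distribution of r under a
    bivariate-normal model with true correlation ``rho``; ``method="fisher"``
    uses the Fisher-z approximation instead.
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must be strictly between 0 and 1 (exclusive); "
                         "at rho=0 no finite sample size attains the power")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie in (0, 1)")
    rho = abs(rho)
    n = 4
    # power is monotone in n; jump ahead with the Fisher approximation then refine
    approx = int(((sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)) / np.arctanh(rho)) ** 2) - 2
    n = max(4, approx)
    while correlation_power(rho, n, alpha, method) < power:
        n += 1
    while n > 4 and correlation_power(rho, n - 1, alpha, method) >= power:
        n -= 1
    return n
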