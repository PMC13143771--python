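"""Cohort-level reliability and effect analyses.

The rank statistics (Spearman, Friedman, Wilcoxon signed-rank) are written
from first principles with explicit midrank tie handling: cohort data here
are heavily tied across five discrete frequency levels, and the tie
behaviour is exactly what determines the reported correlations.  The mixed
model is delegated to statsmodels (participant random intercept, frequency
categorical against the 0.50 Hz reference, head-turn direction binary, age
centred and scaled per decade).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, t as t_dist

from .errors import DataError, InsufficientDataError, ParameterError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rank machinery


def midrank(values) -> np.ndarray:
    """Ranks 1..n with ties receiving the average of their rank positions."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ParameterError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 pairs")
    rx, ry = midrank(x), midrank(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DataError("correlation undefined for constant input")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


@dataclass(frozen=True)
class FriedmanResult:
    chi_square: float
    df: int
    p_value: float


def friedman_test(block_matrix) -> FriedmanResult:
    """Friedman rank test over a participants x conditions matrix.

    Within-block midranks with the standard tie correction; the p-value is
    the chi-square upper tail on (conditions - 1) degrees of freedom.
    Blocks must be complete (no missing cells).
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ParameterError("need at least 2 blocks and 2 conditions")
    if not np.isfinite(m).all():
        raise DataError("incomplete blocks: listwise completeness required")
    n, k = m.shape
    ranks = np.vstack([midrank(row) for row in m])
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums ** 2)) - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_term / (n * k * (k ** 2 - 1))
    if correction <= 0:
        return FriedmanResult(0.0, k - 1, 1.0)
    stat /= correction
    return FriedmanResult(float(stat), k - 1, float(chi2.sf(stat, k - 1)))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float   # min(W+, W-)
    p_value: float
    n_used: int        # pairs remaining after dropping zero differences


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by dynamic programming over sign assignments.

    Midranks may be half-integers; doubling makes every rank an integer so
    the distribution of 2*W+ lives on a small integer lattice.
    """
    scaled = np.round(ranks * 2).astype(int)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    lower = float(dist[:w2 + 1].sum())
    upper = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(paired_a, paired_b, exact_max_n: int = 25) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; |differences| are midranked.  The p-value
    is exact (enumeration over sign assignments) for n <= ``exact_max_n``,
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b):
        raise ParameterError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise DataError("degenerate input: all differences are zero")
    if len(d) < 5:
        raise InsufficientDataError("need at least 5 non-zero differences")
    ranks = midrank(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    n = len(d)
    if n <= exact_max_n:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(counts ** 3 - counts)) / 48.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(stat, p, n)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """min(1, p*m) per value; m defaults to the number of tests supplied."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ParameterError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# cohort model


@dataclass
class CohortModelResult:
    test_type: str
    outcome: str
    direction_effect: dict          # estimate/se/ci/p of right vs left
    age_slope_per_decade: dict
    frequency_contrasts: pd.DataFrame  # vs the reference level, Bonferroni-adjusted
    reference_frequency_hz: float
    random_effects_used: bool
    converged: bool
    fixed_effects: pd.DataFrame


def fit_cohort_model(table: pd.DataFrame, test_type: str,
                     outcome: str = "gain",
                     reference_frequency_hz: float = 0.5) -> CohortModelResult:
    """Linear mixed model for a cohort table of one test type.

    Fixed effects: frequency (categorical, Treatment-coded against the
    reference level), head-turn direction (right = 1), age centred per
    decade.  Random effect: participant intercept.  A singular or
    non-converging fit falls back to an ordinary fixed-effects model with a
    logged warning.
    """
    import statsmodels.formula.api as smf

    if outcome != "gain":
        raise ParameterError(f"unsupported outcome {outcome!r}")
    df = table[table["test_type"] == test_type].copy()
    needed = {"participant_id", "age_years", "intended_frequency_hz",
              "direction", outcome}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"cohort table missing columns: {sorted(missing)}")
    df = df.dropna(subset=list(needed))
    if df.empty:
        raise InsufficientDataError(f"no rows for test type {test_type!r}")
    levels = sorted(df["intended_frequency_hz"].unique())
    if reference_frequency_hz not in levels:
        raise ParameterError(
            f"reference frequency {reference_frequency_hz} not among levels {levels}")
    df["direction_right"] = (df["direction"] == "right").astype(float)
    df["age_decades_c"] = (df["age_years"] - df["age_years"].mean()) / 10.0
    formula = (f"{outcome} ~ C(intended_frequency_hz, "
               f"Treatment({reference_frequency_hz})) + direction_right + age_decades_c")

    random_used, converged = True, True
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["participant_id"])
            fit = model.fit(reml=True)
            converged = bool(getattr(fit, "converged", True))
        except Exception:
            fit = None
    if fit is None or not converged:
        log.warning("mixed model singular or non-converging for %s; "
                    "falling back to fixed effects only", test_type)
        random_used = False
        fit = smf.ols(formula, df).fit()
        converged = True

    params, bse, pvals = fit.params, fit.bse, fit.pvalues
    conf = fit.conf_int()

    def effect(name: str) -> dict:
        return {"estimate": float(params[name]), "se": float(bse[name]),
                "ci_low": float(conf.loc[name, 0]), "ci_high": float(conf.loc[name, 1]),
                "p": float(pvals[name])}

    prefix = f"C(intended_frequency_hz, Treatment({reference_frequency_hz}))[T."
    contrast_rows = []
    for name in params.index:
        if name.startswith(prefix):
            level = float(name[len(prefix):].rstrip("]"))
            row = effect(name)
            row["frequency_hz"] = level
            contrast_rows.append(row)
    contrasts = pd.DataFrame(contrast_rows).sort_values("frequency_hz").reset_index(drop=True)
    if len(contrasts):
        contrasts["p_bonferroni"] = bonferroni_adjust(contrasts["p"].to_numpy())

    fixed = pd.DataFrame({"estimate": params, "se": bse, "p": pvals})
    fixed = fixed[~fixed.index.str.contains("Group Var")]
    return CohortModelResult(
        test_type=test_type,
        outcome=outcome,
        direction_effect=effect("direction_right"),
        age_slope_per_decade=effect("age_decades_c"),
        frequency_contrasts=contrasts,
        reference_frequency_hz=reference_frequency_hz,
        random_effects_used=random_used,
        converged=converged,
        fixed_effects=fixed,
    )


# ---------------------------------------------------------------------------
# reliability / descriptive report


@dataclass
class TestTypeReport:
    rho_intended_vs_actual_frequency: float | None
    rho_intended_frequency_vs_peak_velocity: float | None
    per_level: pd.DataFrame          # actual frequency / velocity mean +- SD
    gain_descriptives: pd.DataFrame  # by frequency x direction
    saccade_descriptives: pd.DataFrame
    flags: list = field(default_factory=list)


@dataclass
class ReliabilityReport:
    by_test_type: dict
    n_rows: int


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, mean
    half = float(t_dist.ppf(0.5 + level / 2, n - 1) * np.std(values, ddof=1) / np.sqrt(n))
    return mean - half, mean + half


def reliability_report(table: pd.DataFrame) -> ReliabilityReport:
    """Pure descriptive/reliability summary of a cohort table.

    Per test type: Spearman correlations of intended frequency with the
    recovered frequency and with the mean peak head velocity; per-level
    mean +- SD of both; gain descriptives (mean, 95% t-CI, median, range)
    by frequency x direction and saccade-rate descriptives by frequency.
    """
    reports = {}
    for test_type, df in table.groupby("test_type"):
        flags = []
        per_rec = df.drop_duplicates(
            subset=["participant_id", "intended_frequency_hz"])
        if per_rec["intended_frequency_hz"].nunique() < 2:
            rho_f = rho_v = None
            flags.append("correlation_not_computable:single_frequency_level")
        else:
            rho_f = spearman_rho(per_rec["intended_frequency_hz"],
                                 per_rec["actual_frequency_hz"])
            rho_v = spearman_rho(per_rec["intended_frequency_hz"],
                                 per_rec["mean_peak_head_velocity_dps"])
        per_level = per_rec.groupby("intended_frequency_hz").agg(
            actual_frequency_mean=("actual_frequency_hz", "mean"),
            actual_frequency_sd=("actual_frequency_hz", "std"),
            peak_velocity_mean=("mean_peak_head_velocity_dps", "mean"),
            peak_velocity_sd=("mean_peak_head_velocity_dps", "std"),
            n=("participant_id", "count"),
        ).reset_index()

        gain_rows = []
        for (f, d), sub in df.groupby(["intended_frequency_hz", "direction"]):
            vals = sub["gain"].to_numpy()
            lo, hi = _t_ci(vals)
            gain_rows.append({"intended_frequency_hz": f, "direction": d,
                              "mean": float(np.mean(vals)),
                              "ci95_low": lo, "ci95_high": hi,
                              "median": float(np.median(vals)),
                              "min": float(np.min(vals)),
                              "max": float(np.max(vals)),
                              "n": len(vals)})
        sac_rows = []
        for f, sub in per_rec.groupby("intended_frequency_hz"):
            vals = sub["saccade_rate_per_s"].to_numpy()
            sac_rows.append({"intended_frequency_hz": f,
                             "median": float(np.median(vals)),
                             "mean": float(np.mean(vals)),
                             "min": float(np.min(vals)),
                             "max": float(np.max(vals)),
                             "n": len(vals)})
        reports[test_type] = TestTypeReport(
            rho_intended_vs_actual_frequency=rho_f,
            rho_intended_frequency_vs_peak_velocity=rho_v,
            per_level=per_level,
            gain_descriptives=pd.DataFrame(gain_rows),
            saccade_descriptives=pd.DataFrame(sac_rows),
            flags=flags,
        )
    return ReliabilityReport(by_test_type=reports, n_rows=len(table))
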