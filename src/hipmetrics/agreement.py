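"""Bland-Altman agreement, sample size, and descriptive summaries.

Method-comparison statistics for paired measurements (e.g. an automated
reader against a human reader):

* bias = mean difference, 95% limits of agreement LoA = bias ± 1.96·SD;
* CIs for the bias (exact t) and for the LoA, either the classic
  approximate form (± t·SD·√(3/n)) or an exact MOVER construction, which is
  asymmetric because the SD's sampling distribution is;
* the Lu et al. (2016) sample-size procedure: the smallest n such that both
  LoA confidence bounds fall inside a clinically acceptable limit ±δ with
  the requested power;
* descriptive summaries of long-format measurement tables.

The LoA multiplier is the normal quantile 1.96 (not a t quantile) — the
same convention under which the repeatability coefficient constant is
2.77 = 1.96·√2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedDifferences",
    "BlandAltmanResult",
    "paired_differences",
    "bland_altman",
    "bland_altman_plot",
    "ba_power",
    "ba_power_mc",
    "ba_sample_size",
    "patients_from_measurements",
    "summarize_measurements",
    "difference_summary",
]

LOA_Z = 1.96  # normal-quantile convention for 95% limits of agreement


@dataclass
class PairedDifferences:
    """Complete paired measurements of two methods, matched by id."""

    ids: list
    values_a: np.ndarray
    values_b: np.ndarray
    n_excluded: int = 0  # ids dropped because one method was missing

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if not (len(self.ids) == self.values_a.size == self.values_b.size):
            raise ValueError("ids, values_a and values_b must have equal length")
        if self.values_a.size < 2:
            raise ValueError("at least 2 complete pairs are required")

    @property
    def diffs(self) -> np.ndarray:
        return self.values_a - self.values_b

    @property
    def means(self) -> np.ndarray:
        return 0.5 * (self.values_a + self.values_b)

    @property
    def n(self) -> int:
        return self.values_a.size


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    bias_ci: tuple[float, float]
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    n: int
    method: str
    n_excluded: int = 0
    warnings: list = field(default_factory=list)


def paired_differences(df: pd.DataFrame, id_col="patient_id", method_col="reader_id", value_col="value", method_a="algorithm", method_b=None) -> PairedDifferences:
    """Build complete pairs from a long table; incomplete ids are counted,
    not imputed (mirrors how unreadable images are excluded from agreement)."""
    a = df[df[method_col] == method_a].set_index(id_col)[value_col]
    b = df[df[method_col] == method_b].set_index(id_col)[value_col]
    if a.index.has_duplicates or b.index.has_duplicates:
        raise ValueError("agreement pairing requires one value per id and method (filter replicate/metric/side first)")
    common = a.index.intersection(b.index)
    n_excluded = len(a.index.union(b.index)) - len(common)
    return PairedDifferences(ids=list(common), values_a=a.loc[common].to_numpy(), values_b=b.loc[common].to_numpy(), n_excluded=n_excluded)


def bland_altman(pairs, alpha: float = 0.05, method: str = "exact") -> BlandAltmanResult:
    """Bland-Altman limits of agreement with confidence intervals.

    ``pairs`` is a :class:`PairedDifferences` or an array of differences.
    ``method`` selects the LoA CI construction: ``"exact"`` (MOVER, default;
    asymmetric) or ``"approximate"`` (± t·SD·√(3/n), symmetric).
    """
    if isinstance(pairs, PairedDifferences):
        diffs = pairs.diffs
        n_excluded = pairs.n_excluded
    else:
        diffs = np.asarray(pairs, dtype=float)
        n_excluded = 0
    n = diffs.size
    if n < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 paired differences")
    if method not in ("exact", "approximate"):
        raise ValueError(f"unknown LoA CI method {method!r}")
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    warnings = []
    df_t = n - 1
    tq = float(stats.t.ppf(1 - alpha / 2, df_t))

    if sd == 0.0:
        warnings.append("zero variance of differences; LoA and CIs are degenerate")
        pt = (bias, bias)
        return BlandAltmanResult(bias, 0.0, pt, bias, bias, pt, pt, n, method, n_excluded, warnings)

    se_mean = sd / math.sqrt(n)
    bias_ci = (bias - tq * se_mean, bias + tq * se_mean)
    loa_l = bias - LOA_Z * sd
    loa_u = bias + LOA_Z * sd

    if method == "approximate":
        half = tq * sd * math.sqrt(3.0 / n)
        loa_l_ci = (loa_l - half, loa_l + half)
        loa_u_ci = (loa_u - half, loa_u + half)
    else:  # exact MOVER: combine the mean CI with the chi-square CI of the SD
        sd_lo = sd * math.sqrt(df_t / stats.chi2.ppf(1 - alpha / 2, df_t))
        sd_hi = sd * math.sqrt(df_t / stats.chi2.ppf(alpha / 2, df_t))
        l_mean = tq * se_mean
        l_sd = LOA_Z * (sd - sd_lo)
        u_sd = LOA_Z * (sd_hi - sd)
        loa_u_ci = (
            loa_u - math.sqrt(l_mean**2 + l_sd**2),
            loa_u + math.sqrt(l_mean**2 + u_sd**2),
        )
        loa_l_ci = (
            loa_l - math.sqrt(l_mean**2 + u_sd**2),
            loa_l + math.sqrt(l_mean**2 + l_sd**2),
        )

    return BlandAltmanResult(bias, sd, bias_ci, loa_l, loa_u, loa_l_ci, loa_u_ci, n, method, n_excluded, warnings)


def bland_altman_plot(pairs: PairedDifferences, result: BlandAltmanResult | None = None, path=None, title: str = ""):
    """Difference-vs-mean plot with LoA lines and shaded CI bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result is None:
        result = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(pairs.means, pairs.diffs, s=14, color="tab:blue", alpha=0.7)
    x0, x1 = float(np.min(pairs.means)), float(np.max(pairs.means))
    ax.axhline(result.bias, color="black", linestyle=":")
    ax.fill_between([x0, x1], result.bias_ci[0], result.bias_ci[1], color="tab:green", alpha=0.25, lw=0)
    for loa, ci in ((result.loa_lower, result.loa_lower_ci), (result.loa_upper, result.loa_upper_ci)):
        ax.axhline(loa, color="black")
        ax.fill_between([x0, x1], ci[0], ci[1], color="tab:blue", alpha=0.2, lw=0)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference between methods")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _loa_se_factor(n: int) -> float:
    """sqrt(1/n + z²/(2(n-1))): SE of an estimated LoA in units of sigma."""
    return math.sqrt(1.0 / n + LOA_Z**2 / (2.0 * (n - 1)))


def ba_power(n: int, sd: float, delta: float, alpha: float = 0.05, bias: float = 0.0) -> float:
    """Power that both LoA 95% confidence bounds fall inside ±delta.

    Per-side probabilities use the normal approximation of the estimated
    LoA with a t-quantile confidence bound; sides combine as
    p_upper + p_lower − 1 (the Lu et al. construction).
    """
    if n < 3:
        return 0.0
    se = sd * _loa_se_factor(n)
    tq = stats.t.ppf(1 - alpha / 2, n - 1)
    tau_u = (delta - bias - LOA_Z * sd) / se
    tau_l = (delta + bias - LOA_Z * sd) / se
    p = stats.norm.cdf(tau_u - tq) + stats.norm.cdf(tau_l - tq) - 1.0
    return float(max(p, 0.0))


def ba_power_mc(n: int, sd: float, delta: float, alpha: float = 0.05, bias: float = 0.0, n_sim: int = 20000, seed: int = 0) -> float:
    """Monte-Carlo joint probability that both LoA confidence bounds fall
    inside ±delta (cross-check of :func:`ba_power`)."""
    rng = np.random.default_rng(seed)
    tq = stats.t.ppf(1 - alpha / 2, n - 1)
    fac = _loa_se_factor(n)
    means = rng.normal(bias, sd / math.sqrt(n), n_sim)
    sds = sd * np.sqrt(rng.chisquare(n - 1, n_sim) / (n - 1))
    upper_bound = means + LOA_Z * sds + tq * sds * fac
    lower_bound = means - LOA_Z * sds - tq * sds * fac
    return float(np.mean((upper_bound < delta) & (lower_bound > -delta)))


def ba_sample_size(sd: float, delta: float, alpha: float = 0.05, power: float = 0.80, bias: float = 0.0, max_n: int = 1_000_000) -> int:
    """Smallest number of paired measurements for a conclusive LoA study.

    Searches ascending n for the first with :func:`ba_power` ≥ ``power``.
    Raises when the spec is unattainable (the true LoA already reach ±delta).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if delta <= LOA_Z * sd + abs(bias):
        raise ValueError(
            f"unattainable: delta={delta} must exceed {LOA_Z}*sd + |bias| = {LOA_Z * sd + abs(bias):.4g}"
        )
    for n in range(3, max_n + 1):
        if ba_power(n, sd, delta, alpha, bias) >= power:
            return n
    raise ValueError(f"no n ≤ {max_n} reaches the requested power")


def patients_from_measurements(n_measurements: int, hips_per_patient: int = 2, n_triple_read_patients: int = 5, n_reads: int = 3) -> int:
    """Patients needed to deliver ``n_measurements`` paired measurements.

    Each patient contributes ``hips_per_patient`` measurements per read;
    ``n_triple_read_patients`` are read ``n_reads`` times, contributing
    ``(n_reads - 1) * hips_per_patient`` extra measurements each.
    """
    if n_measurements <= 0 or hips_per_patient <= 0:
        raise ValueError("counts must be positive")
    extra = n_triple_read_patients * (n_reads - 1) * hips_per_patient
    if extra >= n_measurements:
        raise ValueError(f"extra replicate measurements ({extra}) already exceed the requested total ({n_measurements})")
    return math.ceil((n_measurements - extra) / hips_per_patient)


def summarize_measurements(table: pd.DataFrame, by=("metric", "side", "reader_id"), value_col: str = "value") -> pd.DataFrame:
    """Mean, SD (n−1), min, max, Q1, Q3 per group.

    Quantiles use the linear-interpolation convention (numpy default), e.g.
    Q1 of 1..100 is 25.75.
    """
    if table.empty:
        raise ValueError("empty measurement table")
    by = [b for b in by if b in table.columns]

    def _agg(s: pd.Series) -> pd.Series:
        v = s.to_numpy(dtype=float)
        return pd.Series(
            {
                "n": v.size,
                "mean": np.mean(v),
                "sd": np.std(v, ddof=1) if v.size > 1 else 0.0,
                "min": np.min(v),
                "max": np.max(v),
                "q1": np.quantile(v, 0.25),
                "q3": np.quantile(v, 0.75),
            }
        )

    if not by:
        return _agg(table[value_col]).to_frame().T
    out = table.groupby(list(by), sort=True)[value_col].apply(_agg).unstack()
    return out.reset_index()


def difference_summary(first: pd.DataFrame, second: pd.DataFrame, keys=("patient_id", "reader_id", "replicate", "side", "metric"), value_col: str = "value") -> pd.DataFrame:
    """Summary of first-minus-second differences of two matched runs.

    Used for double-read consistency checks: a deterministic measurement
    engine must produce all-zero difference statistics.
    """
    keys = [k for k in keys if k in first.columns and k in second.columns]
    merged = first.merge(second, on=keys, suffixes=("_1", "_2"), validate="one_to_one")
    merged["diff"] = merged[f"{value_col}_1"] - merged[f"{value_col}_2"]
    group_cols = [k for k in ("metric", "side") if k in keys]
    if group_cols:
        return summarize_measurements(merged.rename(columns={"diff": value_col}), by=group_cols, value_col=value_col)
    return summarize_measurements(merged.rename(columns={"diff": value_col}), by=(), value_col=value_col)
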