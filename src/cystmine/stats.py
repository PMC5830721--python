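"""Cohort statistics comparing labile disulfides with the reference set.

The comparisons mirror the descriptive machinery used when contrasting
labile bonds against all disulfides: configuration and secondary-structure
frequency tables with Pearson χ² tests, Welch (or pooled) and paired t tests
on the strain metrics (DSE, S–S distance, α angles), Pearson correlation
between strain measures, and a separate summary of the labile bonds that
adopt one of the three allosteric configurations.

The test statistics are computed from their closed forms here (scipy is used
only for the χ² and t distribution tails), so they can be validated against
an independent statistical library.  All tests are two-sided and p values
are reported raw, without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist

from .configuration import ALLOSTERIC_CONFIGURATIONS, CONFIGURATION_NAMES

__all__ = [
    "StatsError",
    "TestResult",
    "CohortSummary",
    "chi_square",
    "welch_t",
    "student_t",
    "paired_t",
    "pearson_r",
    "summarize",
    "render_report",
]

#: histogram specifications matching the descriptive figure axes
HISTOGRAM_SPECS = {
    "dse": (0.0, 60.0, 24),      # kJ/mol
    "d": (1.96, 2.14, 18),       # Å
    "alpha_avg": (95.0, 120.0, 25),  # degrees
}

SS_STATES = ("helix", "strand", "loop")


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.statistic, self.df, self.p)


def chi_square(table) -> TestResult:
    """Pearson χ² test of independence on an r×c contingency table.

    Expected counts come from the marginal products; df = (r−1)(c−1); the p
    value is the upper tail of the χ² distribution.  A zero expected cell is
    an error (merge sparse bins first).
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2:
        raise StatsError("contingency table must be two-dimensional")
    if np.any(observed < 0):
        raise StatsError("counts must be non-negative")
    total = observed.sum()
    if total == 0:
        raise StatsError("empty table")
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    if np.any(expected == 0):
        raise StatsError("zero expected count: merge sparse bins before testing")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    if df == 0:
        raise StatsError("degenerate table: fewer than two rows or columns")
    return TestResult(statistic, float(df), float(chi2_dist.sf(statistic, df)))


def _check_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise StatsError(f"{name} must be one-dimensional with n >= 2")
    if not np.all(np.isfinite(arr)):
        raise StatsError(f"{name} contains non-finite values")
    return arr


def welch_t(sample_a, sample_b) -> TestResult:
    """Welch two-sample t test with Satterthwaite degrees of freedom."""
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise StatsError("zero variance in both samples")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    statistic = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2 * t_dist.sf(abs(statistic), df))
    return TestResult(statistic, float(df), p)


def student_t(sample_a, sample_b) -> TestResult:
    """Pooled-variance two-sample t test (available by flag; Welch is the default)."""
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise StatsError("zero variance in both samples")
    statistic = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))
    df = na + nb - 2
    return TestResult(statistic, float(df), float(2 * t_dist.sf(abs(statistic), df)))


def paired_t(sample_a, sample_b) -> TestResult:
    """Paired t test on the element-wise differences.

    All-zero differences give t = 0, p = 1 (no effect, by continuity);
    constant non-zero differences are a zero-variance error.
    """
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    if a.size != b.size:
        raise StatsError("paired samples must have equal length")
    diff = a - b
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:
            return TestResult(0.0, float(n - 1), 1.0)
        raise StatsError("zero variance of non-zero differences")
    statistic = float(diff.mean() / (sd / np.sqrt(n)))
    return TestResult(statistic, float(n - 1), float(2 * t_dist.sf(abs(statistic), n - 1)))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p value via the t transform."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise StatsError("need paired samples with n >= 3")
    xc, yc = xa - xa.mean(), ya - ya.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise StatsError("zero variance")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    n = xa.size
    if abs(r) == 1.0:
        return r, 0.0
    t_stat = r * np.sqrt((n - 2) / (1 - r**2))
    return r, float(2 * t_dist.sf(abs(t_stat), n - 2))


@dataclass
class CohortSummary:
    """Distributions and summary statistics of one bond cohort."""

    name: str
    n: int
    config_counts: pd.Series
    ss_pair_counts: pd.DataFrame
    means: dict[str, float]
    sds: dict[str, float]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class CohortComparison:
    reference: CohortSummary
    labile: CohortSummary
    tests: dict[str, TestResult]
    correlations: dict[str, tuple[float, float]]
    allosteric: Optional[dict] = None


def _prepare(bonds: pd.DataFrame) -> pd.DataFrame:
    df = bonds.copy()
    required = {"dse", "d", "alpha1", "alpha2", "config", "ss_pair", "labile"}
    missing = required - set(df.columns)
    if missing:
        raise StatsError(f"bond table is missing column(s): {sorted(missing)}")
    df = df.dropna(subset=["dse", "d", "alpha1", "alpha2", "config"])
    df["alpha_avg"] = 0.5 * (df["alpha1"] + df["alpha2"])
    if "config_boundary" in df.columns:
        df["config_valid"] = ~df["config_boundary"].astype(bool)
    else:
        df["config_valid"] = True
    if "in_reference" in df.columns:
        df = df[df["in_reference"].astype(bool)]
    return df


def _summarize_cohort(df: pd.DataFrame, name: str) -> CohortSummary:
    if df.empty:
        raise StatsError(f"empty cohort: {name}")
    config_counts = (
        df.loc[df["config_valid"], "config"]
        .value_counts()
        .reindex(CONFIGURATION_NAMES, fill_value=0)
    )
    ss_table = pd.DataFrame(0, index=SS_STATES, columns=SS_STATES, dtype=int)
    for label, count in df["ss_pair"].value_counts().items():
        if not isinstance(label, str) or "/" not in label:
            continue
        s1, s2 = label.split("/")
        ss_table.loc[s1, s2] += count
        if s1 != s2:
            ss_table.loc[s2, s1] += count
    means = {k: float(df[k].mean()) for k in ("dse", "d", "alpha_avg")}
    sds = {k: float(df[k].std(ddof=1)) if len(df) > 1 else 0.0 for k in ("dse", "d", "alpha_avg")}
    histograms = {}
    for key, (lo, hi, nbins) in HISTOGRAM_SPECS.items():
        counts, edges = np.histogram(df[key], bins=nbins, range=(lo, hi))
        total = counts.sum()
        rel = counts / total if total else counts.astype(float)
        histograms[key] = (rel, edges)
    return CohortSummary(
        name=name, n=int(len(df)), config_counts=config_counts,
        ss_pair_counts=ss_table, means=means, sds=sds, histograms=histograms,
    )


def summarize(
    bonds: pd.DataFrame,
    allosteric_names: Sequence[str] = ALLOSTERIC_CONFIGURATIONS,
    pooled: bool = False,
) -> CohortComparison:
    """Compare the reference cohort (all bonds) with the labile subset.

    ``bonds`` is the bonds table from a scan (one row per unique bond with
    representative geometry).  Configuration and secondary-structure-pair
    distributions are compared by χ² (bins empty in both cohorts are dropped
    first); DSE, S–S distance and mean α angle by Welch t (or pooled Student
    t with ``pooled=True``); and the labile bonds restricted to the
    allosteric configurations are compared against the reference on DSE.
    """
    df = _prepare(bonds)
    reference = _summarize_cohort(df, "all")
    labile_df = df[df["labile"].astype(bool)]
    labile = _summarize_cohort(labile_df, "labile")

    two_sample = student_t if pooled else welch_t
    tests: dict[str, TestResult] = {}
    for key in ("dse", "d", "alpha_avg"):
        tests[key] = two_sample(labile_df[key], df[key])

    config_table = np.vstack([reference.config_counts.values, labile.config_counts.values])
    keep = config_table.sum(axis=0) > 0
    if keep.sum() >= 2:
        tests["config"] = chi_square(config_table[:, keep])
    ss_ref = _ss_pair_vector(reference)
    ss_lab = _ss_pair_vector(labile)
    ss_table = np.vstack([ss_ref, ss_lab])
    keep = ss_table.sum(axis=0) > 0
    if keep.sum() >= 2:
        tests["ss_pair"] = chi_square(ss_table[:, keep])

    correlations = {
        "dse_vs_alpha": pearson_r(df["dse"], df["alpha_avg"]),
        "dse_vs_d": pearson_r(df["dse"], df["d"]),
        "d_vs_alpha": pearson_r(df["d"], df["alpha_avg"]),
    }

    allosteric = None
    allo_df = labile_df[labile_df["config"].isin(set(allosteric_names))]
    if len(allo_df) >= 2:
        allosteric = {
            "n": int(len(allo_df)),
            "mean_dse": float(allo_df["dse"].mean()),
            "reference_mean_dse": reference.means["dse"],
            "test": two_sample(allo_df["dse"], df["dse"]),
        }
    return CohortComparison(
        reference=reference, labile=labile, tests=tests,
        correlations=correlations, allosteric=allosteric,
    )


def _ss_pair_vector(summary: CohortSummary) -> np.ndarray:
    """Upper-triangle (unordered-pair) counts of the 3×3 table, fixed order."""
    table = summary.ss_pair_counts
    out = []
    for i, s1 in enumerate(SS_STATES):
        for s2 in SS_STATES[i:]:
            out.append(table.loc[s1, s2])
    return np.asarray(out, dtype=float)


def render_report(comparison: CohortComparison) -> str:
    """Plain-text summary of a cohort comparison."""
    ref, lab = comparison.reference, comparison.labile
    lines = [
        f"reference bonds: n = {ref.n}",
        f"labile bonds:    n = {lab.n}",
        "",
        "metric            all        labile     test",
    ]
    for key, label, unit in (
        ("dse", "DSE", "kJ/mol"),
        ("d", "S-S distance", "A"),
        ("alpha_avg", "alpha (mean)", "deg"),
    ):
        test = comparison.tests.get(key)
        stat = f"t = {test.statistic:+.3f}, p = {test.p:.4g}" if test else ""
        lines.append(
            f"{label:<16s} {ref.means[key]:>9.3f}  {lab.means[key]:>9.3f}  {stat} ({unit})"
        )
    for key, label in (("config", "configuration distribution"), ("ss_pair", "ss-pair distribution")):
        test = comparison.tests.get(key)
        if test:
            lines.append(f"{label}: chi2 = {test.statistic:.3f}, df = {test.df:.0f}, p = {test.p:.4g}")
    for key, (r, p) in comparison.correlations.items():
        lines.append(f"correlation {key}: r = {r:+.3f}, p = {p:.4g}")
    if comparison.allosteric:
        a = comparison.allosteric
        lines.append(
            "allosteric-configuration labile bonds: "
            f"n = {a['n']}, mean DSE = {a['mean_dse']:.2f} vs {a['reference_mean_dse']:.2f} kJ/mol, "
            f"p = {a['test'].p:.4g}"
        )
    return "\n".join(lines) + "\n"
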