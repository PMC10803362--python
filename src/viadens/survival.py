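"""Cohort stratification by density cut-off and the survival analyses.

The cohort is split into high (density >= cutoff) and low groups; each
candidate cut-off on a 50 cells/mm² ladder is scored by two-sided log-rank
tests on both endpoints (disease-specific survival, DSS, and
metastasis-free survival, MFS). Among cut-offs significant on BOTH
endpoints, the one that best balances group sizes is selected. Univariate
Cox regression quantifies the hazard ratio of the high group. No
multiple-testing correction is applied across the scan — a known
limitation of the cut-off–scanning approach, kept deliberately.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "CutoffScanRow",
    "CoxResult",
    "CrosstabResult",
    "stratify",
    "km_logrank",
    "cox_univariate",
    "cutoff_scan",
    "select_cutoff",
    "crosstab_necrosis",
    "compare_distributions",
    "necrosis_grade_to_pct",
]


@dataclasses.dataclass(frozen=True)
class CutoffScanRow:
    cutoff: float
    n_low: int
    n_high: int
    p_dss: float  # nan when not evaluable
    p_mfs: float
    evaluable: bool


@dataclasses.dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    ok: bool = True
    message: str = ""


@dataclasses.dataclass(frozen=True)
class KMComparison:
    fitters: dict  # group label -> fitted KaplanMeierFitter
    statistic: float
    p: float
    evaluable: bool


@dataclasses.dataclass(frozen=True)
class CrosstabResult:
    """2x2 case counts over density group x necrosis response.

    ``discordance_fraction`` is the share of necrosis-poor-response cases
    (< threshold) that the density method nevertheless calls low density,
    i.e. predicts a better prognosis than the conventional grading does.
    """

    n_low_good: int
    n_high_good: int
    n_low_poor: int
    n_high_poor: int
    discordance_fraction: float

    @property
    def total(self) -> int:
        return self.n_low_good + self.n_high_good + self.n_low_poor + self.n_high_poor


def stratify(cohort: pd.DataFrame, cutoff: float) -> np.ndarray:
    """Boolean high-density labels: density >= cutoff (tie counts as high)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return (cohort["density_per_mm2"].to_numpy(dtype=float) >= cutoff)


def km_logrank(times, events, groups) -> KMComparison:
    """Kaplan–Meier product-limit curves per group plus two-sided log-rank p.

    With no events at all the test is undefined; the result is flagged
    non-evaluable with p = nan rather than raising.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {len(labels)}")
    fitters = {}
    for lab in labels:
        kmf = KaplanMeierFitter()
        mask = groups == lab
        kmf.fit(times[mask], events[mask], label=str(lab))
        fitters[lab] = kmf
    if events.sum() == 0:
        return KMComparison(fitters=fitters, statistic=float("nan"), p=float("nan"), evaluable=False)
    mask = groups == labels[1]
    res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
    return KMComparison(
        fitters=fitters,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        evaluable=bool(np.isfinite(res.p_value)),
    )


def cox_univariate(times, events, covariate) -> CoxResult:
    """Univariate Cox PH fit of a binary covariate (Efron ties, Wald CI).

    Monotone likelihood — all events concentrated in one covariate level —
    is detected up front and flagged instead of letting the fit diverge.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=bool).astype(int),
            "x": np.asarray(covariate).astype(float),
        }
    )
    levels = df["x"].unique()
    if len(levels) != 2:
        return CoxResult(math.nan, math.nan, math.nan, math.nan, ok=False,
                         message=f"covariate has {len(levels)} level(s), need 2")
    if df["event"].sum() == 0:
        return CoxResult(math.nan, math.nan, math.nan, math.nan, ok=False,
                         message="no events")
    events_per_level = df.groupby("x")["event"].sum()
    if (events_per_level == 0).any():
        lvl = events_per_level.idxmin()
        return CoxResult(math.inf if lvl == 0 else 0.0, math.nan, math.nan, math.nan,
                         ok=False, message=f"monotone likelihood: no events at level {lvl}")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    ci = cph.confidence_intervals_
    return CoxResult(
        hr=hr,
        ci_low=float(np.exp(ci.iloc[0, 0])),
        ci_high=float(np.exp(ci.iloc[0, 1])),
        p=float(cph.summary["p"].iloc[0]),
    )


def cutoff_scan(
    cohort: pd.DataFrame,
    step: float = 50.0,
    min_group: int = 5,
) -> list[CutoffScanRow]:
    """Log-rank p for DSS and MFS at every cut-off step, 2·step, …

    The ladder runs up to the maximum observed density (floor(max/step)
    rungs). A row is evaluable when both groups have at least ``min_group``
    patients and both log-rank tests are defined.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    density = cohort["density_per_mm2"].to_numpy(dtype=float)
    n_steps = int(math.floor(density.max() / step))
    rows: list[CutoffScanRow] = []
    for k in range(1, n_steps + 1):
        cutoff = k * step
        high = density >= cutoff
        n_high = int(high.sum())
        n_low = len(cohort) - n_high
        if n_low < min_group or n_high < min_group:
            rows.append(CutoffScanRow(cutoff, n_low, n_high, math.nan, math.nan, False))
            continue
        ps = {}
        ok = True
        for ep in ("dss", "mfs"):
            res = km_logrank(cohort[f"{ep}_months"], cohort[f"{ep}_event"], high)
            ps[ep] = res.p
            ok = ok and res.evaluable
        rows.append(CutoffScanRow(cutoff, n_low, n_high, ps["dss"], ps["mfs"], ok))
    return rows


def scan_to_frame(rows: Sequence[CutoffScanRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def select_cutoff(rows: Sequence[CutoffScanRow], alpha: float = 0.05) -> float | None:
    """The balanced significant cut-off, or None.

    Among evaluable rows with p < alpha on both endpoints, pick the one
    minimizing |n_low - n_high|; ties go to the smallest cut-off. The
    result is invariant to row order.
    """
    qualifying = [
        r for r in rows
        if r.evaluable and r.p_dss < alpha and r.p_mfs < alpha
    ]
    if not qualifying:
        return None
    best = min(qualifying, key=lambda r: (abs(r.n_low - r.n_high), r.cutoff))
    return best.cutoff


def necrosis_grade_to_pct(grade) -> float:
    """Map a necrosis grade I-IV to a representative percentage.

    Grades III-IV correspond to >= 90% necrosis (good response); I-II to
    < 90%.
    """
    mapping = {
        "I": 30.0, "II": 70.0, "III": 95.0, "IV": 100.0,
        1: 30.0, 2: 70.0, 3: 95.0, 4: 100.0,
    }
    try:
        return mapping[grade]
    except KeyError:
        raise ValueError(f"unknown necrosis grade {grade!r}") from None


def crosstab_necrosis(
    cohort: pd.DataFrame,
    cutoff: float,
    necrosis_threshold: float = 90.0,
) -> CrosstabResult:
    """Cross-tabulate density group against necrosis response."""
    necrosis = cohort["necrosis_rate_pct"].to_numpy(dtype=float)
    if np.isnan(necrosis).any():
        raise ValueError("necrosis_rate_pct required for every patient")
    high = stratify(cohort, cutoff)
    good = necrosis >= necrosis_threshold
    n_low_good = int((~high & good).sum())
    n_high_good = int((high & good).sum())
    n_low_poor = int((~high & ~good).sum())
    n_high_poor = int((high & ~good).sum())
    n_poor = n_low_poor + n_high_poor
    discordance = n_low_poor / n_poor if n_poor else 0.0
    return CrosstabResult(
        n_low_good=n_low_good,
        n_high_good=n_high_good,
        n_low_poor=n_low_poor,
        n_high_poor=n_high_poor,
        discordance_fraction=discordance,
    )


def compare_distributions(densities_a, densities_b) -> float:
    """Two-sided Mann–Whitney rank-sum p between two density samples.

    Exact enumeration when both samples have at most 10 observations and
    no ties; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(densities_a, dtype=float)
    b = np.asarray(densities_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(a) <= 10 and len(b) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
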