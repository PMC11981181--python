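"""Cohort-level statistics: trait-group assignment and descriptive tests.

Participants are assigned to the high or low autistic-trait group by
comparing their SRS-2 T-score against the sex-specific screening cutoff
used for Japanese five-year-olds (boys 53.5, girls 52.5). Group
comparisons use the Welch (unequal-variance) two-sample t-test, whose
Satterthwaite degrees of freedom match the published cohort table, and a
Pearson chi-square test without continuity correction for the sex ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sex-specific SRS-2 screening cutoffs (T-score). Scores strictly above
#: the cutoff are classified as high autistic trait.
SRS2_CUTOFFS: dict[str, float] = {"M": 53.5, "F": 52.5}


class CohortError(ValueError):
    """Invalid cohort data or test inputs."""


def assign_group(sex: str, srs2: float) -> str:
    """Classify a participant as ``"high"`` or ``"low"`` autistic trait.

    Parameters
    ----------
    sex:
        ``"M"`` or ``"F"``.
    srs2:
        SRS-2 total T-score (nonnegative).

    Returns
    -------
    ``"high"`` iff ``srs2`` strictly exceeds the sex-specific cutoff.
    Half-point cutoffs make ties impossible for integer scores.
    """
    if sex not in SRS2_CUTOFFS:
        raise CohortError(f"unknown sex code {sex!r}; expected 'M' or 'F'")
    if srs2 < 0:
        raise CohortError(f"SRS-2 score must be nonnegative, got {srs2}")
    return "high" if srs2 > SRS2_CUTOFFS[sex] else "low"


def welch_t_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch two-sample t statistic and Satterthwaite df from summaries.

    ``t = (m1 - m2) / sqrt(sd1^2/n1 + sd2^2/n2)`` with

    ``df = (se1^2 + se2^2)^2 / (se1^4/(n1-1) + se2^4/(n2-1))``

    where ``se_k^2 = sd_k^2 / n_k``. Returns ``(t, df)`` with the raw
    (fractional) df; round to the nearest integer for table-style display.
    """
    if n1 < 2 or n2 < 2:
        raise CohortError(f"need n >= 2 per group, got n1={n1}, n2={n2}")
    if sd1 <= 0 or sd2 <= 0:
        raise CohortError(f"standard deviations must be > 0, got {sd1}, {sd2}")
    se1sq = sd1 * sd1 / n1
    se2sq = sd2 * sd2 / n2
    t = (m1 - m2) / math.sqrt(se1sq + se2sq)
    df = (se1sq + se2sq) ** 2 / (se1sq**2 / (n1 - 1) + se2sq**2 / (n2 - 1))
    return t, df


def pearson_chi2(a: int, b: int, c: int, d: int) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) for a 2x2 table.

    Table layout ``[[a, b], [c, d]]``; returns ``(chi2, df)`` with df = 1.
    Closed form ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise CohortError(f"counts must be nonnegative, got {counts}")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise CohortError(f"zero margin in 2x2 table {counts}")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return chi2, 1


@dataclass(frozen=True)
class GroupComparison:
    """One row of a cohort characteristics table."""

    high_mean: float
    high_sd: float
    low_mean: float
    low_sd: float
    t: float
    df: float


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Descriptive statistics and group tests for a cohort table.

    Expects columns ``participant_id, sex, age_years, srs2_score, group``.
    Returns a JSON-serializable dict with per-group n, age and SRS-2
    comparisons (Welch t), and the sex-ratio chi-square.
    """
    required = {"sex", "age_years", "srs2_score", "group"}
    missing = required - set(cohort.columns)
    if missing:
        raise CohortError(f"cohort table missing columns: {sorted(missing)}")
    hi = cohort[cohort["group"] == "high"]
    lo = cohort[cohort["group"] == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise CohortError("need at least 2 participants per group for summaries")

    out: dict = {"n_high": int(len(hi)), "n_low": int(len(lo))}
    for name, col in (("age", "age_years"), ("srs2", "srs2_score")):
        m1, s1 = float(hi[col].mean()), float(hi[col].std(ddof=1))
        m2, s2 = float(lo[col].mean()), float(lo[col].std(ddof=1))
        t, df = welch_t_summary(m1, s1, len(hi), m2, s2, len(lo))
        out[name] = {
            "high_mean": m1, "high_sd": s1, "low_mean": m2, "low_sd": s2,
            "t": t, "df": df, "df_rounded": int(np.rint(df)),
        }
    a = int((hi["sex"] == "M").sum())
    b = int((hi["sex"] == "F").sum())
    c = int((lo["sex"] == "M").sum())
    d = int((lo["sex"] == "F").sum())
    chi2, df_chi = pearson_chi2(a, b, c, d)
    out["sex_ratio"] = {
        "high_male": a, "high_female": b, "low_male": c, "low_female": d,
        "chi2": chi2, "df": df_chi,
    }
    return out
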