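"""Test-retest reliability: intraclass correlation, SEM and study sizing.

Relative reliability is the intraclass correlation of the two-way random
effects model, consistency form, single measures — ICC(C,1) in
McGraw-Wong terms.  From the two-way ANOVA mean squares of an
n-subjects x k-sessions matrix,

    ICC(C,1) = (MS_rows - MS_error) / (MS_rows + (k - 1) MS_error),

with the standard F-based 95% confidence interval of the consistency
form.  Absolute reliability is the standard error of measurement,
SEM = SD * sqrt(1 - ICC), where SD is taken across subjects over each
subject's mean of the compared measurements.  ICC >= 0.75 is read as
excellent reliability, 0.40-0.74 fair-to-high, below 0.40 poor; negative
estimates are reported as computed but classified poor.

Study sizing follows the Walter-Eliasziw-Donner procedure for testing
H0: rho = rho0 against H1: rho = rho1 with k observations per subject,
in both the ln-transform approximation and the exact F-power variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "IntraclassCorrelation",
    "ICCResults",
    "SampleSizeSpec",
    "classify_icc",
    "sem_from_icc",
    "classification_summary",
    "reliability_sample_size",
]

ICC_EXCELLENT = 0.75
ICC_FAIR = 0.40


def classify_icc(icc: float) -> str:
    """Classify an ICC estimate into excellent / fair_to_high / poor."""
    if icc > 1.0:
        raise ValueError(f"ICC cannot exceed 1, got {icc}")
    if icc >= ICC_EXCELLENT:
        return "excellent"
    if icc >= ICC_FAIR:
        return "fair_to_high"
    return "poor"


def sem_from_icc(sd: float, icc: float) -> float:
    """Standard error of measurement, SD * sqrt(1 - ICC)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    return float(sd * math.sqrt(1.0 - icc))


@dataclass
class ICCResults:
    """Reliability estimates for one subjects x sessions outcome matrix."""

    icc: float
    ci95: tuple[float, float]
    sem: float
    sd_used: float
    n_subjects: int
    k_sessions: int
    ms_rows: float
    ms_error: float
    model: str = "two-way random, consistency, single measures"

    @property
    def classification(self) -> str:
        return classify_icc(self.icc)

    def summary(self) -> str:
        lo, hi = self.ci95
        return "\n".join(
            [
                f"Intraclass correlation ({self.model})",
                f"  subjects x sessions : {self.n_subjects} x {self.k_sessions}",
                f"  ICC   : {self.icc:.4f}  [95% CI {lo:.4f}, {hi:.4f}]",
                f"  SEM   : {self.sem:.4g}  (SD used: {self.sd_used:.4g})",
                f"  class : {self.classification}",
            ]
        )


class IntraclassCorrelation:
    """ICC model on a complete subjects-by-sessions outcome matrix.

    ``form='single'`` (default) estimates ICC(C,1); ``form='average'``
    estimates ICC(C,k), the reliability of the k-session mean.
    """

    def __init__(self, data: np.ndarray, *, form: str = "single") -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D subjects x sessions matrix")
        n, k = data.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 sessions")
        if not np.isfinite(data).all():
            raise ValueError("matrix is incomplete (non-finite entries)")
        if form not in ("single", "average"):
            raise ValueError(f"unknown ICC form {form!r}")
        self.data = data
        self.form = form

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        subject: str = "participant_id",
        session: str = "session",
        value: str = "range_value",
        form: str = "single",
    ) -> "IntraclassCorrelation":
        wide = df.pivot_table(index=subject, columns=session, values=value)
        if wide.isna().any().any():
            raise ValueError("incomplete subject x session grid")
        return cls(wide.to_numpy(), form=form)

    def _mean_squares(self) -> tuple[float, float, float]:
        y = self.data
        n, k = y.shape
        grand = y.mean()
        ss_rows = k * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_cols = n * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_rows - ss_cols
        ms_rows = ss_rows / (n - 1)
        ms_cols = ss_cols / (k - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        return ms_rows, ms_cols, ms_err

    def fit(self, confidence: float = 0.95) -> ICCResults:
        y = self.data
        n, k = y.shape
        ms_rows, _ms_cols, ms_err = self._mean_squares()
        denom_single = ms_rows + (k - 1) * ms_err
        if denom_single == 0.0:
            raise ValueError("zero total variance; ICC undefined")
        if ms_err == 0.0 and ms_rows == 0.0:
            raise ValueError("zero total variance; ICC undefined")

        alpha = 1.0 - confidence
        df1, df2 = n - 1, (n - 1) * (k - 1)
        if ms_err == 0.0:
            icc_s, ci = 1.0, (1.0, 1.0)
        else:
            fobs = ms_rows / ms_err
            fl = fobs / _stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = fobs * _stats.f.ppf(1 - alpha / 2, df2, df1)
            # analytically <= 1; clip floating-point excess
            icc_s = min((ms_rows - ms_err) / denom_single, 1.0)
            ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        if self.form == "average":
            # Spearman-Brown step-up of the single-measures quantities
            def up(r: float) -> float:
                return k * r / (1 + (k - 1) * r) if r > -1 else -1.0

            icc, ci = up(icc_s), (up(ci[0]), up(ci[1]))
        else:
            icc = icc_s

        # SD across subjects of each subject's session-mean outcome
        sd_used = float(y.mean(axis=1).std(ddof=1))
        sem = sem_from_icc(sd_used, min(icc, 1.0))
        return ICCResults(
            icc=float(icc),
            ci95=(float(ci[0]), float(ci[1])),
            sem=sem,
            sd_used=sd_used,
            n_subjects=n,
            k_sessions=k,
            ms_rows=float(ms_rows),
            ms_error=float(ms_err),
            model=f"two-way random, consistency, {'single' if self.form == 'single' else 'average'} measures",
        )


def _pct_half_up(x: float) -> float:
    """Percentage rounded half-up to one decimal (1/45 -> 2.2, 7/45 -> 15.6)."""
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classification_summary(classes: Iterable[str]) -> pd.DataFrame:
    """Count and percentage per class over a case grid.

    Accepts class labels directly or results objects with a
    ``classification`` attribute.
    """
    labels = [
        c if isinstance(c, str) else c.classification for c in classes
    ]
    if not labels:
        raise ValueError("empty classification input")
    total = len(labels)
    order = ["excellent", "fair_to_high", "fair_to_good", "poor"]
    present = [lab for lab in order if lab in labels]
    # keep any unexpected labels too, after the known ones
    present += [lab for lab in dict.fromkeys(labels) if lab not in present]
    rows = []
    for lab in present:
        count = labels.count(lab)
        rows.append(
            {
                "class": lab,
                "count": count,
                "percent": _pct_half_up(100.0 * count / total),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SampleSizeSpec:
    """Design parameters of a reliability study sizing computation."""

    alpha: float = 0.05
    beta: float = 0.20
    k_observations: int = 3
    rho0: float = 0.4
    rho1: float = 0.7
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if not (0 <= self.rho0 < self.rho1 < 1):
            raise ValueError("need 0 <= rho0 < rho1 < 1")
        if self.k_observations < 2:
            raise ValueError("need at least 2 observations per subject")


def _wed_ratio(spec: SampleSizeSpec) -> float:
    k = spec.k_observations
    c0 = 1 + k * spec.rho0 / (1 - spec.rho0)
    c1 = 1 + k * spec.rho1 / (1 - spec.rho1)
    return c0 / c1


def reliability_sample_size(spec: SampleSizeSpec, *, method: str = "exact") -> int:
    """Subjects needed to show rho > rho0 when rho = rho1 (Walter-Eliasziw-Donner).

    ``method='approx'`` uses the ln-transform normal approximation

        n = 1 + 2 k (z_a + z_b)^2 / ((k - 1) (ln C0)^2),

    rounded up; ``method='exact'`` searches for the smallest n whose
    F-test of H0: rho = rho0 attains power 1 - beta at rho = rho1.
    """
    ratio = _wed_ratio(spec)
    a = spec.alpha / 2 if spec.two_sided else spec.alpha
    if method == "approx":
        za = _stats.norm.ppf(1 - a)
        zb = _stats.norm.ppf(1 - spec.beta)
        k = spec.k_observations
        n = 1 + 2 * k * (za + zb) ** 2 / ((k - 1) * math.log(ratio) ** 2)
        return int(math.ceil(n))
    if method == "exact":
        k = spec.k_observations
        for n in range(2, 10_000):
            df1, df2 = n - 1, n * (k - 1)
            fcrit = _stats.f.ppf(1 - a, df1, df2)
            power = _stats.f.sf(fcrit * ratio, df1, df2)
            if power >= 1 - spec.beta:
                return n
        raise RuntimeError("sample-size search did not converge")
    raise ValueError(f"unknown method {method!r}")
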