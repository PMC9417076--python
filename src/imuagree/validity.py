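"""Concurrent-validity statistics for a test device against a criterion device.

Two complementary views of agreement:

* the **Linear Fit Method (LFM)** regresses the test waveform on the
  criterion waveform by ordinary least squares.  A perfect instrument
  gives slope alpha1 = 1, intercept alpha0 = 0 and r^2 = 1; r^2 >= 0.75
  is read as excellent waveform validity, 0.40-0.74 as fair-to-good and
  below 0.40 as poor.
* **Bland-Altman analysis** of scalar range outcomes: the mean and spread
  of the per-participant differences (criterion minus test), with limits
  of agreement mean +/- 1.96 SD and a t-based 95% CI of the mean
  difference.

Both are exposed as small model objects whose ``fit()`` returns a results
object with a ``summary()`` table, plus per-case helpers used by the
pipeline layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .cycles import MovementCycle

__all__ = [
    "LinearFit",
    "LinearFitResults",
    "BlandAltman",
    "BlandAltmanResults",
    "classify_r2",
    "lfm_by_participant",
]

#: Classification bands on r^2 (closed on the left, open on the right).
R2_EXCELLENT = 0.75
R2_FAIR = 0.40


def classify_r2(r2: float) -> str:
    """Classify a squared correlation into excellent / fair_to_good / poor."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must lie in [0, 1], got {r2}")
    if r2 >= R2_EXCELLENT:
        return "excellent"
    if r2 >= R2_FAIR:
        return "fair_to_good"
    return "poor"


@dataclass
class LinearFitResults:
    """OLS waveform-agreement parameters for one test/criterion pair."""

    alpha1: float
    alpha0: float
    r2: float
    n_points: int

    @property
    def classification(self) -> str:
        return classify_r2(self.r2)

    def summary(self) -> str:
        lines = [
            "Linear Fit Method (test ~ criterion, OLS)",
            f"  n points : {self.n_points}",
            f"  alpha1   : {self.alpha1:.6g}   (identity: 1)",
            f"  alpha0   : {self.alpha0:.6g}   (identity: 0)",
            f"  r^2      : {self.r2:.6g}   (identity: 1)",
            f"  class    : {self.classification}",
        ]
        return "\n".join(lines)


class LinearFit:
    """Linear Fit Method model: OLS of the test waveform on the criterion.

    Parameters
    ----------
    test, criterion
        Equal-length waveforms (>= 3 samples).  Typically the
        concatenation of a participant's retained time-normalized cycles.
    """

    def __init__(self, test: np.ndarray, criterion: np.ndarray) -> None:
        test = np.asarray(test, dtype=float).ravel()
        criterion = np.asarray(criterion, dtype=float).ravel()
        if test.shape != criterion.shape:
            raise ValueError("test and criterion waveforms differ in length")
        if len(test) < 3:
            raise ValueError("need at least 3 samples")
        if np.ptp(criterion) == 0.0:
            raise ValueError("criterion waveform is constant; fit undefined")
        self.test = test
        self.criterion = criterion

    @classmethod
    def from_cycles(
        cls, test_cycles: Sequence[MovementCycle], criterion_cycles: Sequence[MovementCycle]
    ) -> "LinearFit":
        """Build from paired cycle lists, pairing by cycle index.

        Devices segment with their own thigh stream, so cycle counts can
        differ by edge effects; the pairing truncates to the shorter list.
        """
        k = min(len(test_cycles), len(criterion_cycles))
        if k == 0:
            raise ValueError("no paired cycles")
        t = np.concatenate([c.values for c in test_cycles[:k]])
        c = np.concatenate([c.values for c in criterion_cycles[:k]])
        return cls(t, c)

    def fit(self) -> LinearFitResults:
        res = _stats.linregress(self.criterion, self.test)
        return LinearFitResults(
            alpha1=float(res.slope),
            alpha0=float(res.intercept),
            r2=float(res.rvalue**2),
            n_points=len(self.test),
        )


@dataclass
class BlandAltmanResults:
    """Agreement of paired scalar outcomes via differences criterion - test."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci95_mean_diff: tuple[float, float]
    n: int
    means: np.ndarray
    diffs: np.ndarray

    def summary(self) -> str:
        lo, hi = self.ci95_mean_diff
        return "\n".join(
            [
                "Bland-Altman agreement (criterion - test)",
                f"  n pairs          : {self.n}",
                f"  mean difference  : {self.mean_diff:.6g}  [95% CI {lo:.6g}, {hi:.6g}]",
                f"  SD of differences: {self.sd_diff:.6g}",
                f"  limits of agreement: [{self.loa_lower:.6g}, {self.loa_upper:.6g}]",
            ]
        )

    def plot(self, ax=None):
        """Scatter of differences against pairwise means with LoA lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.means, self.diffs, s=18, alpha=0.8)
        ax.axhline(self.mean_diff, color="k", lw=1.2)
        for y in (self.loa_lower, self.loa_upper):
            ax.axhline(y, color="k", lw=1.0, ls="--")
        ax.set_xlabel("pairwise mean")
        ax.set_ylabel("difference (criterion - test)")
        return ax


class BlandAltman:
    """Bland-Altman agreement model on paired outcome values."""

    def __init__(self, test: np.ndarray, criterion: np.ndarray) -> None:
        test = np.asarray(test, dtype=float).ravel()
        criterion = np.asarray(criterion, dtype=float).ravel()
        if test.shape != criterion.shape:
            raise ValueError("paired vectors differ in length")
        if len(test) < 2:
            raise ValueError("need at least 2 pairs")
        self.test = test
        self.criterion = criterion

    def fit(self, loa_factor: float = 1.96, confidence: float = 0.95) -> BlandAltmanResults:
        diffs = self.criterion - self.test
        n = len(diffs)
        mean = float(diffs.mean())
        sd = float(diffs.std(ddof=1))
        se = sd / np.sqrt(n)
        tcrit = float(_stats.t.ppf(0.5 + confidence / 2, df=n - 1))
        return BlandAltmanResults(
            mean_diff=mean,
            sd_diff=sd,
            loa_lower=mean - loa_factor * sd,
            loa_upper=mean + loa_factor * sd,
            ci95_mean_diff=(mean - tcrit * se, mean + tcrit * se),
            n=n,
            means=(self.test + self.criterion) / 2.0,
            diffs=diffs,
        )


def lfm_by_participant(
    pairs: Iterable[tuple[str, Sequence[MovementCycle], Sequence[MovementCycle]]],
    *,
    mode: str = "concatenated",
) -> pd.DataFrame:
    """Fit the LFM per participant and tabulate alpha1 / alpha0 / r^2.

    ``pairs`` yields (participant_id, test_cycles, criterion_cycles).
    ``mode='concatenated'`` fits on all retained cycles strung together;
    ``mode='mean_cycle'`` fits on the participant's cycle-ensemble mean.
    """
    rows = []
    for pid, tcyc, ccyc in pairs:
        if mode == "concatenated":
            model = LinearFit.from_cycles(tcyc, ccyc)
        elif mode == "mean_cycle":
            k = min(len(tcyc), len(ccyc))
            if k == 0:
                raise ValueError("no paired cycles")
            t = np.mean([c.values for c in tcyc[:k]], axis=0)
            c = np.mean([c.values for c in ccyc[:k]], axis=0)
            model = LinearFit(t, c)
        else:
            raise ValueError(f"unknown LFM mode {mode!r}")
        res = model.fit()
        rows.append(
            {
                "participant_id": pid,
                "alpha1": res.alpha1,
                "alpha0": res.alpha0,
                "r2": res.r2,
                "n_points": res.n_points,
            }
        )
    return pd.DataFrame(rows)
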