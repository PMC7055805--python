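"""The g-distinct statistic: equivalence-class histograms and risk curves.

Patients sharing an identical quasi-identifier tuple under a policy form an
*equivalence class* (bin). A patient is *g-distinct* when their tuple is
shared by at most g−1 others, i.e. their class has size ≤ g; 1-distinct
patients are unique. With |bin(i)| the number of classes of exact size i,
the cumulative count of patients at risk at threshold g is

    h(g) = Σ_{i=1..g} i · |bin(i)|

and h(g)/N is the at-risk population fraction. h is non-decreasing and
reaches N at the largest class size (every patient is counted exactly once
through their own class), which makes h(g)/N a proper cumulative curve —
the object plotted as "g-distinct versus percentage of population".

All counts are exact integers; fractions are formed only at the point of
reporting, so thresholds like "smallest g covering 95% of patients" are
resolved by integer comparison (h(g)·1 ≥ p·N within one ulp), not by
accumulating floating-point error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .policies import KEY_COLUMNS, PolicySpec, QuasiIdentifierView, apply_policy, get_policy


@dataclass(frozen=True)
class ClassSizeHistogram:
    """Histogram of equivalence-class sizes.

    ``counts`` maps class size i (≥1) to the number of classes |bin(i)| of
    exactly that size; ``n_total`` is the number of patients N. Invariant:
    Σ i·counts[i] == n_total (each patient lies in exactly one class).
    """

    counts: dict[int, int] = field(default_factory=dict)
    n_total: int = 0

    def __post_init__(self) -> None:
        if any(i < 1 or c < 1 for i, c in self.counts.items()):
            raise ValueError("class sizes and bin counts must be strictly positive")
        total = sum(i * c for i, c in self.counts.items())
        if total != self.n_total:
            raise ValueError(f"patients not conserved: Σ i·|bin(i)| = {total} != {self.n_total}")

    @property
    def max_class_size(self) -> int:
        return max(self.counts, default=0)

    def to_frame(self) -> pd.DataFrame:
        """Export as columns class_size, num_bins, num_patients."""
        sizes = sorted(self.counts)
        return pd.DataFrame(
            {
                "class_size": sizes,
                "num_bins": [self.counts[i] for i in sizes],
                "num_patients": [i * self.counts[i] for i in sizes],
            }
        )


def compute_bins(view: QuasiIdentifierView | pd.DataFrame) -> ClassSizeHistogram:
    """Bin patients by exact key equality and histogram the class sizes.

    Accepts a :class:`QuasiIdentifierView` or its key frame. An empty view
    yields an empty histogram with ``n_total`` 0.
    """
    keys = view.keys if isinstance(view, QuasiIdentifierView) else view
    if len(keys) == 0:
        return ClassSizeHistogram()
    class_sizes = keys.groupby(list(KEY_COLUMNS), sort=False).size()
    hist = class_sizes.value_counts()
    return ClassSizeHistogram(
        counts={int(i): int(c) for i, c in hist.items()}, n_total=int(len(keys))
    )


def h_of_g(hist: ClassSizeHistogram, g: int) -> int:
    """h(g) = Σ_{i=1..g} i·|bin(i)| — patients in classes of size ≤ g."""
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    return sum(i * c for i, c in hist.counts.items() if i <= g)


@dataclass(frozen=True)
class RiskCurve:
    """Cumulative risk curve: (g, h(g), h(g)/N) for g = 1..max class size.

    ``h`` holds exact patient counts; ``fraction`` is h/N rendered as
    float. h is non-decreasing and ends at N, so fractions end at exactly
    1.0.
    """

    g: np.ndarray
    h: np.ndarray
    n_total: int

    @property
    def fraction(self) -> np.ndarray:
        return self.h / self.n_total

    def to_frame(self, log_spaced: bool = False, points_per_decade: int = 20) -> pd.DataFrame:
        """Export as columns g, h_g, fraction.

        With ``log_spaced`` the grid is thinned to roughly
        ``points_per_decade`` log-spaced g values (always keeping the first
        and last), which keeps exports small when the largest class holds
        thousands of patients.
        """
        idx = np.arange(len(self.g))
        if log_spaced and len(self.g) > 2:
            n_pts = max(2, int(points_per_decade * math.log10(self.g[-1]) + 1))
            grid = np.unique(
                np.round(np.logspace(0, math.log10(self.g[-1]), n_pts)).astype(int)
            )
            idx = np.searchsorted(self.g, grid)
            idx = np.unique(np.clip(idx, 0, len(self.g) - 1))
        return pd.DataFrame(
            {"g": self.g[idx], "h_g": self.h[idx], "fraction": self.fraction[idx]}
        )


def risk_curve(hist: ClassSizeHistogram) -> RiskCurve:
    """Materialize h(g) for every g from 1 to the largest class size."""
    if hist.n_total == 0:
        raise ValueError(
            "risk curve undefined for an empty histogram; check upstream filters"
        )
    gmax = hist.max_class_size
    per_size = np.zeros(gmax + 1, dtype=np.int64)
    for i, c in hist.counts.items():
        per_size[i] = i * c
    h = np.cumsum(per_size)[1:]
    return RiskCurve(g=np.arange(1, gmax + 1), h=h, n_total=hist.n_total)


def unique_fraction(hist: ClassSizeHistogram) -> float:
    """h(1)/N — the 1-distinct (uniquely identifiable) population share."""
    if hist.n_total == 0:
        raise ValueError("unique fraction undefined for an empty histogram")
    return h_of_g(hist, 1) / hist.n_total


def g_for_fraction(curve: RiskCurve, p: float) -> int:
    """Smallest g whose at-risk fraction h(g)/N reaches p ∈ (0, 1].

    Resolved on exact counts: the first g with h(g) ≥ p·N (p·N rounded up
    within one ulp to absorb float representation of p). p = 1 returns the
    maximum class size.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    threshold = int(math.ceil(p * curve.n_total - 1e-9))
    idx = int(np.searchsorted(curve.h, threshold, side="left"))
    return int(curve.g[idx])


class GDistinctAnalyzer(BaseEstimator):
    """Estimator computing the g-distinct risk profile under one policy.

    Parameters
    ----------
    policy : PolicySpec or str, default "limited"
        Generalization policy applied to the encoded records before
        binning.
    reference_date : str, optional
        ISO date for age top-coding policies.

    Attributes
    ----------
    view_ : QuasiIdentifierView
        The policy view the histogram was computed from.
    histogram_ : ClassSizeHistogram
        Equivalence-class size histogram.
    curve_ : RiskCurve
        h(g) for g = 1..max class size.
    n_total_ : int
        Patients entering the binning (complete keys).
    unique_fraction_ : float
        1-distinct share h(1)/N.

    Examples
    --------
    >>> est = GDistinctAnalyzer(policy="safe_harbor").fit(encoded)  # doctest: +SKIP
    >>> est.unique_fraction_, est.h(10)  # doctest: +SKIP
    """

    def __init__(self, policy: PolicySpec | str = "limited", reference_date: str | None = None):
        self.policy = policy
        self.reference_date = reference_date

    def fit(self, X: pd.DataFrame, y=None) -> "GDistinctAnalyzer":
        """Bin encoded records ``X`` under the policy and build the curve."""
        self.policy_ = get_policy(self.policy)
        self.view_ = apply_policy(X, self.policy_, reference_date=self.reference_date)
        self.histogram_ = compute_bins(self.view_)
        self.n_total_ = self.histogram_.n_total
        self.curve_ = risk_curve(self.histogram_)
        self.unique_fraction_ = unique_fraction(self.histogram_)
        return self

    def h(self, g: int) -> int:
        """Patients in classes of size ≤ g (h(g) of the fitted histogram)."""
        return h_of_g(self.histogram_, g)

    def fraction_at(self, g: int) -> float:
        """At-risk fraction h(g)/N of the fitted histogram."""
        return self.h(g) / self.n_total_

    def g_for_fraction(self, p: float) -> int:
        """Smallest g whose at-risk fraction reaches p."""
        return g_for_fraction(self.curve_, p)
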