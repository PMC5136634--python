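"""Frame-rate stability statistics and the Group 1-4 taxonomy.

Given a parameter x rate x recording table, each parameter is taken through
a nonparametric repeated-measures pipeline: an omnibus Friedman test across
rates (recordings as blocks), then, when the omnibus test is significant,
pairwise Wilcoxon signed-rank tests for every unordered rate pair at a
Bonferroni-corrected level (each rate takes part in n_rates - 1 pairwise
comparisons, hence alpha / (n_rates - 1); for 15 rates and family alpha
0.05 this is 0.05/14 = 0.0036).  Consecutive rates with no significant pair
among them are merged into stable intervals, and the interval structure maps
to a stability group:

    Group 1 — one interval spans every rate (rate independent);
    Group 2 — the final interval reaches the top rate and spans >= 2 rates
              (stable from some rate upward);
    Group 3 — some strictly interior interval spans >= 4 rates (stable in a
              band, changing below and above);
    Group 4 — none of the above (stable for at most a few rates).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .parameters import PARAMETER_NAMES

__all__ = [
    "RateSweepTable",
    "StabilityInterval",
    "ParameterStability",
    "StabilityReport",
    "corrected_alpha",
    "normality_check",
    "friedman_across_rates",
    "pairwise_wilcoxon",
    "merge_stable_intervals",
    "classify_group",
    "build_report",
]


@dataclass
class RateSweepTable:
    """parameter x rate x recording value array for a sensitivity experiment."""

    values: np.ndarray  # (n_params, n_rates, n_recordings); NaN = sentinel
    rates: list[float]
    recording_ids: list[str]
    parameter_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.parameter_names), len(self.rates), len(self.recording_ids))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if list(self.rates) != sorted(self.rates):
            raise ValueError("rates must be ascending")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, parameter_names: list[str] | None = None
    ) -> "RateSweepTable":
        """Build from a tidy table with recording, fps and parameter columns."""
        names = parameter_names or [c for c in PARAMETER_NAMES if c in df.columns]
        rates = sorted(df["fps"].unique())
        recs = sorted(df["recording"].unique())
        values = np.full((len(names), len(rates), len(recs)), np.nan)
        pivoted = df.set_index(["recording", "fps"])
        for pi, name in enumerate(names):
            for ri, rate in enumerate(rates):
                for ki, rec in enumerate(recs):
                    try:
                        values[pi, ri, ki] = pivoted.loc[(rec, rate), name]
                    except KeyError:
                        pass
        return cls(values=values, rates=[float(r) for r in rates],
                   recording_ids=list(recs), parameter_names=list(names))

    def matrix(self, parameter: str) -> np.ndarray:
        """(n_recordings, n_rates) block matrix for one parameter."""
        pi = self.parameter_names.index(parameter)
        return self.values[pi].T.copy()


def corrected_alpha(alpha_family: float = 0.05, n_rates: int = 15) -> float:
    """Bonferroni-corrected pairwise level: each rate enters n_rates - 1 tests."""
    return alpha_family / (n_rates - 1)


def normality_check(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk and Lilliefors p-values for one sample (n >= 4).

    A constant sample is reported as non-normal by convention (p = 0).
    """
    sample = np.asarray(sample, dtype=float)
    sample = sample[np.isfinite(sample)]
    if sample.size < 4:
        raise ValueError("normality check needs n >= 4")
    if np.ptp(sample) == 0:
        warnings.warn("constant sample reported as non-normal by convention",
                      stacklevel=2)
        return 0.0, 0.0
    p_sw = float(stats.shapiro(sample).pvalue)
    _, p_lf = lilliefors(sample, dist="norm")
    return p_sw, float(p_lf)


def _complete_blocks(block_matrix: np.ndarray) -> np.ndarray:
    """Drop recordings (rows) containing sentinels, listwise."""
    keep = np.all(np.isfinite(block_matrix), axis=1)
    return block_matrix[keep]


def friedman_across_rates(table: RateSweepTable, parameter: str) -> float:
    """Friedman omnibus p-value across rates (recordings as blocks)."""
    m = _complete_blocks(table.matrix(parameter))
    if m.shape[0] < 2:
        raise ValueError("fewer than 2 complete recordings (blocks)")
    if m.shape[1] < 3:
        raise ValueError("Friedman test needs at least 3 rates")
    if np.all(m == m[:, [0]]):
        return 1.0  # identical values at every rate: statistic 0
    _, p = stats.friedmanchisquare(*m.T)
    return float(p)


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    d = x - y
    d = d[d != 0]  # common discard convention for zero differences
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    except ValueError:
        res = stats.wilcoxon(d, zero_method="wilcox", method="approx")
    return float(res.pvalue)


def pairwise_wilcoxon(
    table: RateSweepTable, parameter: str, alpha_family: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Wilcoxon signed-rank tests over rates for one parameter.

    Returns (sig, pvals): symmetric boolean significance matrix at the
    Bonferroni-corrected level alpha_family / (n_rates - 1), and the p-value
    matrix (diagonal 1).  Rate pairs with all-zero paired differences are
    non-significant by convention.
    """
    m = _complete_blocks(table.matrix(parameter))
    n_rates = len(table.rates)
    if m.shape[0] < 2:
        raise ValueError("fewer than 2 complete recordings (blocks)")
    alpha = corrected_alpha(alpha_family, n_rates)
    pvals = np.ones((n_rates, n_rates))
    for i in range(n_rates):
        for j in range(i + 1, n_rates):
            p = _wilcoxon_p(m[:, i], m[:, j])
            pvals[i, j] = pvals[j, i] = p
    sig = pvals < alpha
    np.fill_diagonal(sig, False)
    return sig, pvals


@dataclass
class StabilityInterval:
    """A maximal run of consecutive rates with no significant pair inside."""

    lo: int           # index of first rate in the run
    hi: int           # index of last rate (inclusive)
    gray: bool = False
    value_range: tuple[float, float] | None = None  # (min, max) of rate means

    @property
    def span(self) -> int:
        return self.hi - self.lo + 1


def merge_stable_intervals(pairwise_sig: np.ndarray) -> list[StabilityInterval]:
    """Greedy left-to-right merge of rates into maximal stable runs.

    A run grows while the next rate has no significant pair with any rate
    already in the run.  A run is additionally marked gray when it has no
    significant pair with either neighboring run while the neighbors differ
    significantly from each other.
    """
    sig = np.asarray(pairwise_sig, dtype=bool)
    n = sig.shape[0]
    if sig.shape != (n, n) or not np.array_equal(sig, sig.T):
        raise ValueError("pairwise_sig must be a symmetric square matrix")
    runs: list[list[int]] = [[0]]
    for r in range(1, n):
        if any(sig[r, member] for member in runs[-1]):
            runs.append([r])
        else:
            runs[-1].append(r)
    intervals = [StabilityInterval(lo=run[0], hi=run[-1]) for run in runs]

    def blocks_differ(a: StabilityInterval, b: StabilityInterval) -> bool:
        return bool(
            sig[a.lo : a.hi + 1, b.lo : b.hi + 1].any()
        )

    for k in range(1, len(intervals) - 1):
        left, mid, right = intervals[k - 1], intervals[k], intervals[k + 1]
        if (
            not blocks_differ(mid, left)
            and not blocks_differ(mid, right)
            and blocks_differ(left, right)
        ):
            mid.gray = True
    return intervals


def classify_group(intervals: list[StabilityInterval], n_rates: int = 15) -> int:
    """Map a stable-interval partition to stability group 1-4."""
    if not intervals:
        raise ValueError("no intervals")
    if intervals[0].lo != 0 or intervals[-1].hi != n_rates - 1:
        raise ValueError("intervals must cover all rates")
    if len(intervals) == 1:
        return 1
    final = intervals[-1]
    if final.hi == n_rates - 1 and final.span >= 2:
        return 2
    for iv in intervals:
        if iv.lo > 0 and iv.hi < n_rates - 1 and iv.span >= 4:
            return 3
    return 4


@dataclass
class ParameterStability:
    """Stability record for one parameter over the rate sweep."""

    parameter: str
    friedman_p: float
    pairwise_sig: np.ndarray
    pairwise_p: np.ndarray
    intervals: list[StabilityInterval]
    group: int
    n_excluded_recordings: int = 0


@dataclass
class StabilityReport:
    """Per-parameter stability analysis of a full rate sweep."""

    rates: list[float]
    parameters: dict[str, ParameterStability] = field(default_factory=dict)

    def groups(self) -> dict[str, int]:
        return {name: ps.group for name, ps in self.parameters.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, ps in self.parameters.items():
            ivs = "; ".join(
                f"{self.rates[iv.lo]:g}-{self.rates[iv.hi]:g}"
                + (" (gray)" if iv.gray else "")
                for iv in ps.intervals
            )
            ranges = "; ".join(
                f"[{iv.value_range[0]:.4g}, {iv.value_range[1]:.4g}]"
                if iv.value_range else "-"
                for iv in ps.intervals
            )
            rows.append(
                {"parameter": name, "group": ps.group, "friedman_p": ps.friedman_p,
                 "intervals": ivs, "value_ranges": ranges,
                 "n_excluded_recordings": ps.n_excluded_recordings}
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rates": self.rates,
            "parameters": {
                name: {
                    "group": ps.group,
                    "friedman_p": ps.friedman_p,
                    "intervals": [
                        {"lo_fps": self.rates[iv.lo], "hi_fps": self.rates[iv.hi],
                         "gray": iv.gray, "value_range": iv.value_range}
                        for iv in ps.intervals
                    ],
                    "pairwise_p": ps.pairwise_p.tolist(),
                    "n_excluded_recordings": ps.n_excluded_recordings,
                }
                for name, ps in self.parameters.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def build_report(
    table: RateSweepTable,
    alpha_family: float = 0.05,
    friedman_gate: float = 0.05,
) -> StabilityReport:
    """Run the full stability pipeline on a rate sweep table.

    Parameters whose Friedman omnibus test is not significant skip pairwise
    testing (all-false significance matrix, one full-span interval, Group 1).
    Deterministic given the table.
    """
    if table.values.size == 0:
        raise ValueError("empty table")
    n_rates = len(table.rates)
    report = StabilityReport(rates=list(table.rates))
    for name in table.parameter_names:
        m = table.matrix(name)
        n_excluded = int(m.shape[0] - _complete_blocks(m).shape[0])
        friedman_p = friedman_across_rates(table, name)
        if friedman_p < friedman_gate:
            sig, pvals = pairwise_wilcoxon(table, name, alpha_family)
        else:
            sig = np.zeros((n_rates, n_rates), dtype=bool)
            pvals = np.ones((n_rates, n_rates))
        intervals = merge_stable_intervals(sig)
        rate_means = np.nanmean(table.matrix(name), axis=0)
        for iv in intervals:
            seg = rate_means[iv.lo : iv.hi + 1]
            iv.value_range = (float(np.min(seg)), float(np.max(seg)))
        group = classify_group(intervals, n_rates)
        report.parameters[name] = ParameterStability(
            parameter=name, friedman_p=friedman_p, pairwise_sig=sig,
            pairwise_p=pvals, intervals=intervals, group=group,
            n_excluded_recordings=n_excluded,
        )
    return report
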