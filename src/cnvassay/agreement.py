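"""Agreement statistics between two sets of copy-number calls.

Cross-tabulation of integer predictions (concordance matrix and rates),
replicate reproducibility, Bland-Altman analysis of continuous estimates,
and a Pearson chi-square comparison of predicted-copy-number distributions
with adjacent-category pooling for sparse classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceMatrix",
    "ConcordanceRates",
    "AgreementSummary",
    "Chi2Result",
    "concordance_matrix",
    "concordance_rates",
    "replicate_agreement",
    "bland_altman",
    "distribution_chi2",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Cross-tabulation of two callers' integer predictions.

    ``counts[i, j]`` is the number of samples called i by method A (rows)
    and j by method B (columns).  Orientation is recorded in the labels,
    never positional: "B higher" always means above the diagonal.
    """

    counts: np.ndarray
    method_a: str = "A"
    method_b: str = "B"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (c < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def k_max(self) -> int:
        return self.counts.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        labels = np.arange(self.counts.shape[0])
        df = pd.DataFrame(self.counts, index=labels, columns=labels)
        df.index.name = self.method_a
        df.columns.name = self.method_b
        return df


class ConcordanceRates(NamedTuple):
    frac_same: float
    frac_b_higher: float
    frac_b_lower: float


class Chi2Result(NamedTuple):
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class AgreementSummary:
    """Summary of agreement between two paired sets of calls.

    Fields not computed by a given analysis are ``None`` (e.g. Bland-Altman
    on continuous values fills the difference statistics but not the integer
    concordance fractions).
    """

    n: int
    frac_same: float | None = None
    frac_b_higher: float | None = None
    frac_b_lower: float | None = None
    mean_diff: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    frac_abs_diff_lt_1: float | None = None
    pearson_r: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _merge_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame, columns) -> pd.DataFrame:
    for name, df in (("A", calls_a), ("B", calls_b)):
        missing = ({"sample_id"} | set(columns)) - set(df.columns)
        if missing:
            raise ValueError(f"calls {name} missing columns: {sorted(missing)}")
    merged = calls_a.merge(calls_b, on="sample_id", suffixes=("_a", "_b"))
    dropped = len(calls_a) + len(calls_b) - 2 * len(merged)
    if dropped:
        logger.warning("dropped %d unpaired call(s) while merging on sample_id", dropped)
    if merged.empty:
        raise ValueError("no samples shared between the two call sets")
    return merged


def concordance_matrix(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    method_a: str = "A",
    method_b: str = "B",
    k_max: int | None = None,
) -> ConcordanceMatrix:
    """Cross-tabulate integer predictions of two callers over shared samples.

    Samples missing from either set are dropped (and counted in a warning).
    ``k_max`` defaults to the largest predicted value observed.
    """
    merged = _merge_calls(calls_a, calls_b, ["predicted_cn"])
    pa = merged["predicted_cn_a"].to_numpy(dtype=int)
    pb = merged["predicted_cn_b"].to_numpy(dtype=int)
    if k_max is None:
        k_max = int(max(pa.max(), pb.max()))
    if pa.max() > k_max or pb.max() > k_max:
        raise ValueError("predictions exceed k_max")
    counts = np.zeros((k_max + 1, k_max + 1), dtype=int)
    np.add.at(counts, (pa, pb), 1)
    return ConcordanceMatrix(counts, method_a=method_a, method_b=method_b)


def concordance_rates(matrix: ConcordanceMatrix) -> ConcordanceRates:
    """Diagonal, above-diagonal (B higher) and below-diagonal (B lower) fractions.

    Fractions are exact over the integer cell counts; rounding to whole
    percents belongs to the reporting layer.
    """
    n = matrix.n_total
    if n == 0:
        raise ValueError("empty concordance matrix")
    c = matrix.counts
    same = int(np.trace(c))
    b_higher = int(np.triu(c, k=1).sum())
    b_lower = int(np.tril(c, k=-1).sum())
    return ConcordanceRates(same / n, b_higher / n, b_lower / n)


def bland_altman(values_a, values_b) -> AgreementSummary:
    """Bland-Altman agreement of paired continuous copy-number estimates.

    Differences are B - A; limits of agreement are mean +/- 1.96 SD; the
    reported fraction counts pairs with |difference| strictly below 1 copy.
    Also reports the Pearson correlation of the paired values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values must be 1-D and paired")
    n = len(a)
    if n < 2:
        raise ValueError("Bland-Altman requires n >= 2 pairs")
    diff = b - a
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(a) > 0 and np.ptp(b) > 0:
        r = float(stats.pearsonr(a, b)[0])
    else:
        r = None
    return AgreementSummary(
        n=n,
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        frac_abs_diff_lt_1=float((np.abs(diff) < 1.0).mean()),
        pearson_r=r,
    )


def replicate_agreement(calls_run1: pd.DataFrame, calls_run2: pd.DataFrame) -> AgreementSummary:
    """Reproducibility of a caller across two runs of the same samples.

    Pairs runs by ``sample_id`` and reports the integer-concordance fractions
    (run 2 playing "method B") together with the Bland-Altman statistics and
    Pearson correlation of the continuous estimates.
    """
    merged = _merge_calls(calls_run1, calls_run2, ["predicted_cn", "continuous_cn"])
    p1 = merged["predicted_cn_a"].to_numpy(dtype=int)
    p2 = merged["predicted_cn_b"].to_numpy(dtype=int)
    ba = bland_altman(merged["continuous_cn_a"], merged["continuous_cn_b"])
    n = len(merged)
    return AgreementSummary(
        n=n,
        frac_same=float((p1 == p2).mean()),
        frac_b_higher=float((p2 > p1).mean()),
        frac_b_lower=float((p2 < p1).mean()),
        mean_diff=ba.mean_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        frac_abs_diff_lt_1=ba.frac_abs_diff_lt_1,
        pearson_r=ba.pearson_r,
    )


def distribution_chi2(predicted_a, predicted_b, min_expected: float = 5.0) -> Chi2Result:
    """Pearson chi-square comparing two predicted-copy-number distributions.

    Builds the 2 x K table of call frequencies over the union of observed
    integer categories, pools adjacent categories from the tails inward until
    every expected count is at least ``min_expected``, then computes the
    uncorrected Pearson chi-square with df = K_pooled - 1.  Raises if fewer
    than two categories survive pooling.
    """
    a = np.asarray(predicted_a, dtype=int)
    b = np.asarray(predicted_b, dtype=int)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both call sets must be non-empty")
    cats = np.array(sorted(set(a.tolist()) | set(b.tolist())))
    table = np.vstack(
        [[(a == c).sum() for c in cats], [(b == c).sum() for c in cats]]
    ).astype(float)

    while True:
        k = table.shape[1]
        row_tot = table.sum(axis=1)
        col_tot = table.sum(axis=0)
        expected = np.outer(row_tot, col_tot) / table.sum()
        if expected.min() >= min_expected:
            break
        if k <= 2:
            raise ValueError(
                "fewer than 2 categories with adequate expected counts after pooling"
            )
        # pool the sparser tail column into its neighbour (tie -> low tail)
        if col_tot[0] <= col_tot[-1]:
            table[:, 1] += table[:, 0]
            table = table[:, 1:]
        else:
            table[:, -2] += table[:, -1]
            table = table[:, :-1]

    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(float(chi2), int(df), float(p))
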