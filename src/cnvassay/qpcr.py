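"""qPCR copy-number calling: standard curves, ddCt and the input-amount bias.

The relative-quantification chain is

    dCt_i   = mean Ct(target) - mean Ct(reference)          per sample i
    ddCt_i  = dCt_i - dCt_cal                               cohort calibration
    CN_i    = modal_cn * 2 ** (-ddCt_i)

anchored so the cohort median continuous copy number equals the population's
modal copy number.  The base-2 exponent deliberately reproduces the standard
calling assumption that both assays amplify at 100% efficiency; when target
and reference efficiencies actually differ, dCt drifts with the amount of
input DNA and the called copy number inflates or deflates accordingly —
``predict_dct_drift`` quantifies that bias analytically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurveFit",
    "DctDrift",
    "CorrelationResult",
    "fit_standard_curve",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "delta_ct_table",
    "continuous_cn_qpcr",
    "predict_dct_drift",
    "input_cn_correlation",
    "call_qpcr",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of Ct against log10(input DNA) for one assay.

    ``efficiency = 10**(-1/slope) - 1`` holds exactly; ``slope`` is in
    cycles per decade of input and is negative for any amplifying assay.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float


class DctDrift(NamedTuple):
    """Analytical input-amount bias for a target/reference efficiency pair."""

    dct_per_decade: float  # change of dCt per tenfold input increase, cycles
    cn_factor_per_decade: float  # multiplicative CN error per decade under base-2 calling


class CorrelationResult(NamedTuple):
    pearson_r: float
    p_value: float
    n: int
    degenerate: bool


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a dilution-curve slope: E = 10**(-1/m) - 1.

    A slope of -3.32193 cycles/decade corresponds to perfect doubling
    (E = 1.0).  Raises for non-negative slopes (no amplification).
    """
    if not slope < 0:
        raise ValueError(f"dilution-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def slope_from_efficiency(efficiency: float) -> float:
    """Inverse of :func:`efficiency_from_slope`: m = -1 / log10(1 + E)."""
    if not efficiency > 0:
        raise ValueError(f"efficiency must be > 0, got {efficiency}")
    return -1.0 / math.log10(1.0 + efficiency)


def fit_standard_curve(dilution_series) -> StandardCurveFit:
    """Fit Ct on log10(input) by ordinary least squares and derive efficiency.

    Parameters
    ----------
    dilution_series : DataFrame or sequence
        Either a DataFrame with columns ``log10_input`` and ``ct`` or a
        sequence of ``(log10_input, ct)`` pairs.  At least three distinct
        dilution points are required.
    """
    if isinstance(dilution_series, pd.DataFrame):
        x = dilution_series["log10_input"].to_numpy(dtype=float)
        y = dilution_series["ct"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(dilution_series), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("dilution series must be (log10_input, ct) pairs")
        x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("standard curve requires >= 3 distinct dilution points")
    fit = stats.linregress(x, y)
    if not fit.slope < 0:
        raise ValueError(
            f"fitted slope {fit.slope:.4f} is not negative; Ct must fall with input"
        )
    return StandardCurveFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=efficiency_from_slope(float(fit.slope)),
    )


def delta_ct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample dCt = mean(target Ct) - mean(reference Ct) over usable replicates.

    Replicates with either Ct missing are dropped and counted; samples with
    no usable replicate are excluded with a warning and listed in the result's
    ``attrs["excluded"]``.  Returns columns ``sample_id``, ``delta_ct``,
    ``n_replicates_used`` and ``input_mass`` (if present).
    """
    required = {"sample_id", "ct_target", "ct_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    usable = ct_table.dropna(subset=["ct_target", "ct_reference"])
    grouped = usable.groupby("sample_id", sort=False)
    out = pd.DataFrame(
        {
            "sample_id": list(grouped.groups),
            "delta_ct": (grouped["ct_target"].mean() - grouped["ct_reference"].mean()).to_numpy(),
            "n_replicates_used": grouped.size().to_numpy(),
        }
    )
    if "input_mass" in ct_table.columns:
        out["input_mass"] = grouped["input_mass"].first().to_numpy()
    excluded = sorted(set(ct_table["sample_id"]) - set(out["sample_id"]))
    if excluded:
        logger.warning(
            "NO_USABLE_REPLICATES: excluded %d sample(s) with no complete Ct pair: %s",
            len(excluded),
            ", ".join(map(str, excluded[:10])),
        )
    out.attrs["excluded"] = excluded
    return out


def continuous_cn_qpcr(
    records: pd.DataFrame, modal_cn: int, efficiency: float = 1.0
) -> pd.DataFrame:
    """Continuous copy numbers from dCt records, anchored at the cohort median.

    ``CN_i = modal_cn * r_i / median(r)`` with ``r_i = (1+efficiency)**(-dCt_i)``,
    so the cohort median continuous CN equals ``modal_cn`` exactly.  The
    default ``efficiency=1.0`` is the conventional 100%-efficiency (base-2)
    calling rule; pass the measured common efficiency for an
    efficiency-corrected contrast.
    """
    if len(records) < 3:
        raise ValueError("cohort calibration requires >= 3 dCt records")
    if not efficiency > 0:
        raise ValueError("efficiency must be > 0")
    if modal_cn < 1:
        raise ValueError("modal_cn must be >= 1")
    raw = (1.0 + efficiency) ** (-records["delta_ct"].to_numpy(dtype=float))
    out = records.loc[:, [c for c in records.columns if c != "delta_ct"]].copy()
    out["continuous_cn"] = modal_cn * raw / np.median(raw)
    return out


def predict_dct_drift(e_target: float, e_reference: float) -> DctDrift:
    """Analytical dCt drift per decade of input DNA for unequal efficiencies.

    The standard-curve slope of an assay is ``m = -1/log10(1+E)``; dCt changes
    by ``m_target - m_reference`` cycles per tenfold input increase.  A more
    efficient target has the shallower slope, so its dCt rises with input and
    base-2 calling deflates the copy number (``cn_factor_per_decade < 1``);
    a more efficient *reference* inflates it.
    """
    if not (e_target > 0 and e_reference > 0):
        raise ValueError("efficiencies must be > 0")
    drift = slope_from_efficiency(e_target) - slope_from_efficiency(e_reference)
    return DctDrift(dct_per_decade=drift, cn_factor_per_decade=2.0 ** (-drift))


def input_cn_correlation(input_mass, continuous_cn) -> CorrelationResult:
    """Pearson correlation of called copy number against input DNA amount.

    Constant copy-number vectors are reported as ``r = 0, p = 1`` with the
    ``degenerate`` flag set (batch pipelines survive constant-call cohorts);
    constant input masses are an input error.
    """
    x = np.asarray(input_mass, dtype=float)
    y = np.asarray(continuous_cn, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("input_mass and continuous_cn must be 1-D and paired")
    n = len(x)
    if n < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("input masses are all equal; correlation undefined")
    if np.ptp(y) == 0:
        return CorrelationResult(0.0, 1.0, n, True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, False)


def call_qpcr(
    ct_table: pd.DataFrame,
    modal_cn: int,
    sigma0: float = 0.1,
    cv: float = 0.05,
    k_max: int = 10,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """Full qPCR arm: Ct table -> dCt -> continuous CN -> ML integer calls.

    Returns the calls schema: ``sample_id, continuous_cn, predicted_cn,
    confidence, method``.
    """
    from .prt import ml_assign_integer  # shared ML engine

    records = delta_ct_table(ct_table)
    cont = continuous_cn_qpcr(records, modal_cn, efficiency=efficiency)
    calls = ml_assign_integer(cont, sigma0=sigma0, cv=cv, k_max=k_max)
    calls["method"] = "qpcr"
    return calls
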