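"""PRT copy-number calling and the shared maximum-likelihood integer engine.

A paralog ratio test amplifies a copy-variable locus and a fixed-copy paralog
with one primer pair, so the per-sample peak-area ratio (target/paralog)
estimates ``copy_number / reference_copies`` free of efficiency mismatch.
Ratios are anchored to the population's modal copy number, then converted to
integer calls by the same maximum-likelihood engine the qPCR arm uses:
each candidate integer k is scored by a Gaussian likelihood centred on k with
an affine scale ``sigma(k) = sigma0 + cv * k`` (multiplicative assay noise
spreads more at higher copy numbers), and the call's confidence is its
normalized likelihood.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["peak_ratios", "continuous_cn_prt", "ml_assign_integer", "call_prt"]

logger = logging.getLogger(__name__)


def peak_ratios(peak_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean of per-replicate target/paralog peak-area ratios.

    Replicates with zero (or negative) paralog area are dropped and counted;
    samples left with no usable replicate are excluded with a warning and
    listed in ``attrs["excluded"]``.
    """
    required = {"sample_id", "area_target", "area_paralog"}
    missing = required - set(peak_table.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if (peak_table[["area_target", "area_paralog"]] < 0).any().any():
        raise ValueError("peak areas must be >= 0")
    usable = peak_table[peak_table["area_paralog"] > 0].copy()
    usable["ratio"] = usable["area_target"] / usable["area_paralog"]
    grouped = usable.groupby("sample_id", sort=False)
    out = pd.DataFrame(
        {
            "sample_id": list(grouped.groups),
            "ratio": grouped["ratio"].mean().to_numpy(),
            "n_replicates_used": grouped.size().to_numpy(),
        }
    )
    excluded = sorted(set(peak_table["sample_id"]) - set(out["sample_id"]))
    if excluded:
        logger.warning(
            "ZERO_PARALOG_AREA: excluded %d sample(s) with no usable replicate: %s",
            len(excluded),
            ", ".join(map(str, excluded[:10])),
        )
    out.attrs["excluded"] = excluded
    return out


def continuous_cn_prt(
    records: pd.DataFrame, modal_cn: int, reference_copies: int
) -> pd.DataFrame:
    """Continuous copy numbers from peak ratios, anchored at the cohort median.

    The calibration factor ``c = median(ratio) / (modal_cn / reference_copies)``
    absorbs run-level scale (injection, labelling, digestion completeness);
    ``CN_i = reference_copies * ratio_i / c``, so the cohort median continuous
    CN equals ``modal_cn`` exactly.
    """
    if len(records) < 3:
        raise ValueError("cohort calibration requires >= 3 ratio records")
    if modal_cn < 1 or reference_copies < 1:
        raise ValueError("modal_cn and reference_copies must be >= 1")
    ratios = records["ratio"].to_numpy(dtype=float)
    if (ratios < 0).any():
        raise ValueError("ratios must be >= 0")
    c = np.median(ratios) / (modal_cn / reference_copies)
    if not c > 0:
        raise ValueError("cohort median ratio must be > 0 for calibration")
    out = records.loc[:, [c_ for c_ in records.columns if c_ != "ratio"]].copy()
    out["continuous_cn"] = reference_copies * ratios / c
    return out


def ml_assign_integer(
    values,
    sigma0: float = 0.1,
    cv: float = 0.05,
    k_max: int = 10,
) -> pd.DataFrame:
    """Maximum-likelihood integer copy numbers from continuous estimates.

    Each value v is scored against candidates k = 0..k_max with the Gaussian
    density N(v; k, sigma(k)), sigma(k) = sigma0 + cv*k.  The call is the
    argmax (ties broken toward the smaller k); confidence is the call's
    density divided by the sum over all candidates, so candidate posteriors
    sum to 1 per sample.  With cv = 0 this reduces exactly to
    nearest-integer rounding with half-points assigned downward; with cv > 0
    the decision boundaries shift below the midpoints (a larger sigma at
    k+1 pulls the boundary toward k).

    Parameters
    ----------
    values : DataFrame with a ``continuous_cn`` column, or 1-D array-like.
    sigma0 : float
        Baseline SD of the continuous estimate around its integer, copies.
    cv : float
        Increment of that SD per copy (multiplicative noise component).
    k_max : int
        Largest candidate copy number (>= 2).

    Returns
    -------
    DataFrame with ``continuous_cn``, ``predicted_cn``, ``confidence`` (and
    any columns of the input carried through).  Non-finite values are
    excluded with a warning.
    """
    if not sigma0 > 0:
        raise ValueError("sigma0 must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")

    if isinstance(values, pd.DataFrame):
        if "continuous_cn" not in values.columns:
            raise ValueError("DataFrame input must have a 'continuous_cn' column")
        frame = values.copy()
    else:
        frame = pd.DataFrame({"continuous_cn": np.asarray(values, dtype=float)})

    v = frame["continuous_cn"].to_numpy(dtype=float)
    finite = np.isfinite(v)
    if not finite.all():
        bad = frame.loc[~finite, "sample_id"] if "sample_id" in frame else (~finite).nonzero()[0]
        logger.warning("NON_FINITE_CN: excluded %d sample(s): %s", (~finite).sum(), list(bad)[:10])
        frame = frame.loc[finite].reset_index(drop=True)
        v = v[finite]

    k = np.arange(k_max + 1, dtype=float)
    sigma = sigma0 + cv * k
    # log N(v; k, sigma(k)) for every sample x candidate
    z = (v[:, None] - k[None, :]) / sigma[None, :]
    log_dens = -0.5 * z**2 - np.log(sigma)[None, :] - 0.5 * np.log(2.0 * np.pi)
    predicted = np.argmax(log_dens, axis=1)  # first max -> smaller k on ties
    confidence = np.exp(
        log_dens[np.arange(len(v)), predicted] - logsumexp(log_dens, axis=1)
    )
    frame["predicted_cn"] = predicted.astype(int)
    frame["confidence"] = confidence
    return frame


def call_prt(
    peak_table: pd.DataFrame,
    modal_cn: int,
    reference_copies: int,
    sigma0: float = 0.1,
    cv: float = 0.05,
    k_max: int = 10,
) -> pd.DataFrame:
    """Full PRT arm: peak table -> ratios -> continuous CN -> ML integer calls.

    Returns the calls schema: ``sample_id, continuous_cn, predicted_cn,
    confidence, method``.
    """
    records = peak_ratios(peak_table)
    cont = continuous_cn_prt(records, modal_cn, reference_copies)
    calls = ml_assign_integer(cont, sigma0=sigma0, cv=cv, k_max=k_max)
    calls["method"] = "prt"
    return calls
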