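"""Spike-in-calibrated scaling and length/depth-normalized expression.

The calibration fits, per sample, a through-origin least-squares line of
spike-in count against known amount; the slope ratio to a designated
reference sample is the per-sample scale factor.  Expression is then
RPKM/FPKM computed against the calibrated factor instead of each sample's
own raw depth, so between-sample comparisons are anchored to the spike-ins
(total-RNA decay over the time course does not masquerade as stability
change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    pass


@dataclass
class ScaleFactors:
    """Per-sample multiplicative factors, equal to 1 for the reference."""

    factors: pd.Series
    reference_sample: str
    slopes: pd.Series  # raw through-origin slopes (count per known amount)

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


def fit_spikein_calibration(
    spikeins: pd.DataFrame,
    reference_sample: str | None = None,
    method: str = "linear",
) -> ScaleFactors:
    """Fit per-sample spike-in calibration factors.

    Parameters
    ----------
    spikeins : table with a ``known_amount`` column (attomoles) and one
        count column per sample; index = spike-in ids.
    reference_sample : sample whose factor is fixed at 1 (default: first
        count column).
    method : ``"linear"`` (through-origin OLS on the linear scale,
        slope = sum(x*y)/sum(x^2)) or ``"loglog"`` (through-origin on log
        scale with unit slope, i.e. geometric-mean count/amount ratio).
    """
    if "known_amount" not in spikeins.columns:
        raise CalibrationError("spike-in table must carry a 'known_amount' column")
    x = spikeins["known_amount"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise CalibrationError("need >= 3 distinct spike-in amounts")
    samples = [c for c in spikeins.columns if c != "known_amount"]
    if not samples:
        raise CalibrationError("spike-in table has no sample columns")
    reference_sample = reference_sample or samples[0]
    if reference_sample not in samples:
        raise CalibrationError(f"reference sample {reference_sample!r} not in table")

    slopes = {}
    for s in samples:
        y = spikeins[s].to_numpy(dtype=float)
        if (y < 0).any():
            raise CalibrationError(f"sample {s!r}: negative spike-in counts")
        if np.count_nonzero(y) < 3:
            raise CalibrationError(f"sample {s!r}: fewer than 3 spike-ins with count > 0")
        if method == "linear":
            slopes[s] = float(np.sum(x * y) / np.sum(x * x))
        elif method == "loglog":
            pos = y > 0
            slopes[s] = float(np.exp(np.mean(np.log(y[pos]) - np.log(x[pos]))))
        else:
            raise ValueError(f"unknown calibration method {method!r}")
        if slopes[s] <= 0:
            raise CalibrationError(f"sample {s!r}: non-positive calibration slope")
    slopes = pd.Series(slopes, name="slope")
    factors = slopes / slopes[reference_sample]
    factors.name = "factor"
    return ScaleFactors(factors=factors, reference_sample=reference_sample, slopes=slopes)


def normalize_expression(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    factors: ScaleFactors,
    depth_millions: float | None = None,
    units: str = "RPKM",
) -> pd.DataFrame:
    """Length- and calibration-normalized expression.

    ``value = count / (factor * length_kb * depth_millions)`` — the factor
    is applied exactly once; the depth divisor is a single run-wide constant
    (by default the reference sample's raw depth in millions), so the
    spike-in factor alone carries all between-sample scaling.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        warnings.warn(f"dropping {len(missing)} gene(s) without length: {list(missing[:5])}")
        counts = counts.drop(index=missing)
    lengths_kb = gene_lengths.loc[counts.index].to_numpy(dtype=float) / 1e3
    if (lengths_kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    absent = [s for s in counts.columns if s not in factors.factors.index]
    if absent:
        raise CalibrationError(f"no calibration factor for sample(s) {absent}")
    if depth_millions is None:
        depth_millions = float(counts[factors.reference_sample].sum()) / 1e6
    if depth_millions <= 0:
        raise ValueError("depth must be positive")
    out = counts.div(factors.factors[counts.columns], axis=1).div(lengths_kb, axis=0) / depth_millions
    out.attrs["units"] = units
    return out


def expressed_filter(
    table: pd.DataFrame,
    threshold: float = 1.0,
    samples: list[str] | None = None,
) -> pd.Index:
    """Genes whose mean normalized value across ``samples`` is strictly
    greater than ``threshold`` (``samples`` defaults to all columns; pass
    the t=0/control columns of the relevant condition)."""
    if table.empty:
        return table.index[:0]
    sub = table if samples is None else table[samples]
    return table.index[sub.mean(axis=1) > threshold]


def compute_tpm(tag_counts: pd.DataFrame) -> pd.DataFrame:
    """Tags-per-million per column; each column sums to 1e6."""
    totals = tag_counts.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-depth sample(s): {list(zero)}")
    return tag_counts * 1e6 / totals
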