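"""First-order mRNA decay fitting from transcription shut-off time courses.

After actinomycin D stalls transcription, dC/dt = -K_decay * C, so
ln(C_t / C_0) = -K_decay * t and the half-life is t1/2 = ln 2 / K_decay.
The estimator is a through-origin least-squares regression of
ln(C_t / C_0) on t — the intercept is pinned at 0 because ln(C_0/C_0) = 0
by construction — with replicate values entering as separate observations
and C_0 taken as the mean of the t = 0 replicates.

The module is organised as a model/results pair: build an
:class:`ExponentialDecayModel` from a normalized expression matrix and a
design table, call :meth:`~ExponentialDecayModel.fit`, and read per-gene
estimates and diagnostics off the returned :class:`DecayResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

_LN2 = math.log(2.0)

STATUS_OK = "ok"
STATUS_INCREASING = "increasing"
STATUS_INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class DecayFit:
    """Per-gene decay estimate.

    ``k_decay`` is the first-order decay constant (per hour; the ``A`` of
    the relative-expression fit ``y = exp(-A x)``); ``t_half = ln2/k`` when
    ``k > 0`` and NaN otherwise, with ``status`` explaining why.
    """

    gene_id: str
    k_decay: float
    t_half: float
    n_points: int
    rss: float
    status: str


def fit_decay(
    time: np.ndarray,
    value: np.ndarray,
    gene_id: str = "",
    replicate_mean: bool = False,
) -> DecayFit:
    """Fit K_decay and t1/2 for one gene.

    Parameters
    ----------
    time, value : observation vectors (hours, normalized abundance); the
        t = 0 observations define C_0 (their mean).  Zero values are
        dropped (no pseudocount); genes without a positive C_0 or with
        fewer than two usable timepoints are flagged ``insufficient``.
    replicate_mean : average replicates within each timepoint before the
        regression instead of pooling them as separate observations.
    """
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    if time.shape != value.shape:
        raise ValueError("time and value must have equal length")
    if np.any(value < 0):
        raise ValueError("abundance values must be >= 0")
    if replicate_mean:
        tp = np.unique(time)
        value = np.array([value[time == u].mean() for u in tp])
        time = tp

    at0 = time == 0
    if not at0.any():
        return DecayFit(gene_id, math.nan, math.nan, 0, math.nan, STATUS_INSUFFICIENT)
    c0 = float(value[at0].mean())
    if c0 <= 0:
        return DecayFit(gene_id, math.nan, math.nan, 0, math.nan, STATUS_INSUFFICIENT)

    usable = value > 0
    # distinct timepoints with signal, t=0 included, must number >= 2
    if len(np.unique(time[usable])) < 2 or not usable[at0].any():
        return DecayFit(gene_id, math.nan, math.nan, int(usable.sum()), math.nan, STATUS_INSUFFICIENT)

    t = time[usable]
    y = np.log(value[usable] / c0)
    # through-origin OLS: slope = sum(t*y)/sum(t^2); K = -slope
    denom = float(np.sum(t * t))
    k = -float(np.sum(t * y)) / denom
    rss = float(np.sum((y + k * t) ** 2))
    if k <= 0:
        return DecayFit(gene_id, k, math.nan, len(t), rss, STATUS_INCREASING)
    return DecayFit(gene_id, k, _LN2 / k, len(t), rss, STATUS_OK)


def relative_decay_curve(time, value, gene_id: str = "") -> DecayFit:
    """Exponential fit ``y = exp(-A x)`` to relative expression values.

    The RT-qPCR-style variant of :func:`fit_decay`: values are relative to
    t = 0 (so the series should be ~1 there) and the same through-origin
    estimator applies with A = K_decay.
    """
    value = np.asarray(value, dtype=float)
    time = np.asarray(time, dtype=float)
    at0 = time == 0
    if at0.any() and value[at0].mean() > 0 and not np.isclose(value[at0].mean(), 1.0, rtol=0.05):
        import warnings

        warnings.warn(f"{gene_id or 'series'}: t=0 relative value not ~1; fitting anyway")
    return fit_decay(time, value, gene_id=gene_id)


class ExponentialDecayModel:
    """Per-gene exponential decay model over a normalized expression matrix.

    Parameters
    ----------
    values : genes x samples normalized expression (spike-in calibrated).
    design : one row per sample with at least a ``time`` column (hours);
        indexed by sample name.  All samples handed to one model belong to
        one genotype/condition.
    """

    def __init__(self, values: pd.DataFrame, design: pd.DataFrame):
        missing = [s for s in values.columns if s not in design.index]
        if missing:
            raise ValueError(f"design rows missing for sample(s) {missing}")
        if "time" not in design.columns:
            raise ValueError("design must carry a 'time' column")
        self.values = values
        self.design = design.loc[values.columns]
        self.times = self.design["time"].to_numpy(dtype=float)
        if not (self.times == 0).any():
            raise ValueError("design must include t=0 samples")

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        design: pd.DataFrame,
        genotype: str | None = None,
    ) -> "ExponentialDecayModel":
        """Build a model from a full-experiment matrix, optionally
        restricted to one genotype (``design`` then needs a ``genotype``
        column)."""
        if genotype is not None:
            keep = design.index[design["genotype"] == genotype]
            values = values[[s for s in values.columns if s in set(keep)]]
            design = design.loc[keep]
        return cls(values, design)

    def fit(self, replicate_mean: bool = False) -> "DecayResults":
        fits = [
            fit_decay(self.times, row, gene_id=gid, replicate_mean=replicate_mean)
            for gid, row in zip(self.values.index, self.values.to_numpy(dtype=float))
        ]
        return DecayResults(self, fits)


class DecayResults:
    """Estimates, diagnostics and summary for a fitted decay model."""

    def __init__(self, model: ExponentialDecayModel, fits: list[DecayFit]):
        self.model = model
        self.fits = {f.gene_id: f for f in fits}
        self.frame = pd.DataFrame(
            {
                "k_decay": [f.k_decay for f in fits],
                "t_half": [f.t_half for f in fits],
                "n_points": [f.n_points for f in fits],
                "rss": [f.rss for f in fits],
                "status": [f.status for f in fits],
            },
            index=pd.Index([f.gene_id for f in fits], name="gene_id"),
        )

    @property
    def k_decay(self) -> pd.Series:
        return self.frame["k_decay"]

    @property
    def t_half(self) -> pd.Series:
        return self.frame["t_half"]

    @property
    def status(self) -> pd.Series:
        return self.frame["status"]

    def ok(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] == STATUS_OK]

    def summary(self) -> str:
        ok = self.ok()
        n = len(self.frame)
        lines = [
            "Exponential decay model (through-origin fit of ln(Ct/C0) on t)",
            "=" * 62,
            f"genes fitted:        {n}",
            f"status ok:           {len(ok)}",
            f"status increasing:   {int((self.status == STATUS_INCREASING).sum())}",
            f"status insufficient: {int((self.status == STATUS_INSUFFICIENT).sum())}",
        ]
        if len(ok):
            lines += [
                f"median K_decay [1/h]: {ok['k_decay'].median():.4f}",
                f"median t1/2 [h]:      {ok['t_half'].median():.3f}",
                f"t1/2 IQR [h]:         {ok['t_half'].quantile(0.25):.3f}"
                f" - {ok['t_half'].quantile(0.75):.3f}",
            ]
        return "\n".join(lines)


def halflife_table(
    results_wt: DecayResults,
    results_mut: DecayResults,
    expressed: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-gene half-life table for two genotypes with log2 fold change.

    Genes with status ``ok`` in both genotypes get
    ``log2fc = log2(t_half_mut / t_half_WT)``; anything else is flagged in
    the ``status`` column and left NaN.
    """
    genes = results_wt.frame.index.intersection(results_mut.frame.index)
    if expressed is not None:
        genes = genes.intersection(expressed)
    wt = results_wt.frame.loc[genes]
    mut = results_mut.frame.loc[genes]
    both_ok = (wt["status"] == STATUS_OK) & (mut["status"] == STATUS_OK)
    log2fc = pd.Series(np.nan, index=genes)
    log2fc[both_ok] = np.log2(mut.loc[both_ok, "t_half"] / wt.loc[both_ok, "t_half"])
    status = pd.Series("not-ok", index=genes)
    status[both_ok] = STATUS_OK
    return pd.DataFrame(
        {
            "t_half_WT": wt["t_half"],
            "t_half_mut": mut["t_half"],
            "log2fc_halflife": log2fc,
            "status": status,
        }
    )
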