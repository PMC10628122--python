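"""DNA fragmentation index (DFI) computation and prediction-error reporting.

The DFI of a sperm cell is the share of its fluorescence signal attributable
to single-stranded DNA::

    DFI = 100 * A_ss / (A_ss + A_ds)   [percent]

where the "area" ``A`` of a channel is, by default, its integrated intensity
(sum of pixel values of the denoised or generated patch); a pixel-count
interpretation (number of pixels above a threshold) is available as an
alternative.  Prediction quality against ground truth is summarized per donor
with MAE and MAPE::

    MAE  = (1/N) * sum_i |y_i - x_i|
    MAPE = (1/N) * sum_i |y_i - x_i| / y_i

computed on the 0-1 fractional DFI scale by convention, so an MAE of 0.02
corresponds to two DFI percentage points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DFIResult",
    "DfiSeries",
    "EvalReport",
    "compute_dfi",
    "mae",
    "mape",
    "evaluate_per_donor",
    "aggregate_report",
    "compare_models",
]


@dataclass(frozen=True)
class DFIResult:
    cell_id: object
    area_ds: float
    area_ss: float
    dfi: float  # percent; NaN when both areas are zero

    @property
    def defined(self) -> bool:
        return not np.isnan(self.dfi)


def compute_dfi(
    ds_patch: np.ndarray,
    ss_patch: np.ndarray,
    area_mode: str = "intensity_sum",
    threshold: float = 0.0,
    cell_id: object = None,
) -> DFIResult:
    """Per-cell DFI from a dsDNA/ssDNA patch pair.

    With both areas zero the DFI is undefined and returned as NaN; such cells
    are flagged and excluded from downstream error metrics.
    """
    ds = np.asarray(ds_patch, dtype=float)
    ss = np.asarray(ss_patch, dtype=float)
    if ds.shape != ss.shape:
        raise ValueError(f"patch shapes differ: {ds.shape} vs {ss.shape}")
    if ds.min() < 0 or ss.min() < 0:
        raise ValueError("patch intensities must be >= 0")
    if area_mode == "intensity_sum":
        a_ds, a_ss = float(ds.sum()), float(ss.sum())
    elif area_mode == "pixel_count":
        a_ds, a_ss = float((ds > threshold).sum()), float((ss > threshold).sum())
    else:
        raise ValueError(f"unknown area_mode {area_mode!r}")
    denom = a_ss + a_ds
    if denom == 0:
        logger.warning("cell %s has zero area in both channels; DFI undefined", cell_id)
        return DFIResult(cell_id, a_ds, a_ss, float("nan"))
    return DFIResult(cell_id, a_ds, a_ss, 100.0 * a_ss / denom)


@dataclass(frozen=True)
class DfiSeries:
    """Paired ground-truth (``y``) and predicted (``x``) per-cell DFI values
    in percent for one donor."""

    y: np.ndarray
    x: np.ndarray
    donor_id: object = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("y and x must be 1-D arrays of equal length")
        if y.size < 1:
            raise ValueError("series must contain at least one cell")
        if (y < 0).any() or (y > 100).any() or (x < 0).any() or (x > 100).any():
            raise ValueError("DFI values must lie in [0, 100]")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x", x)


def _fractional(v: np.ndarray, scale: str) -> np.ndarray:
    if scale == "fraction":
        return v / 100.0
    if scale == "percent":
        return v
    raise ValueError(f"unknown scale {scale!r}")


def mae(series: DfiSeries, scale: str = "fraction") -> float:
    """Mean absolute DFI error, by default on the 0-1 fractional scale."""
    y = _fractional(series.y, scale)
    x = _fractional(series.x, scale)
    return float(np.mean(np.abs(y - x)))


def mape(series: DfiSeries) -> float:
    """Mean absolute percentage error, as a fraction (0.22 = 22 %).

    Cells with zero ground-truth DFI cannot be normalized and are excluded
    (logged); an all-zero ground truth is an error.
    """
    keep = series.y > 0
    n_excl = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all ground-truth DFI values are zero; MAPE undefined")
    if n_excl:
        logger.info("MAPE: excluded %d cell(s) with zero ground-truth DFI", n_excl)
    y, x = series.y[keep], series.x[keep]
    return float(np.mean(np.abs(y - x) / y))


def evaluate_per_donor(
    truth: pd.DataFrame,
    pred: pd.DataFrame,
    on: tuple[str, ...] = ("donor", "frame", "cell"),
) -> pd.DataFrame:
    """Join per-cell truth and prediction tables (columns ``true_dfi`` /
    ``pred_dfi`` in percent) and return per-donor MAE and MAPE."""
    merged = truth.merge(pred, on=list(on), how="inner", validate="one_to_one")
    if merged.empty:
        raise ValueError("truth and prediction tables share no cells")
    rows = []
    for donor, grp in merged.groupby("donor", sort=True):
        grp = grp[np.isfinite(grp["pred_dfi"])]
        series = DfiSeries(grp["true_dfi"].to_numpy(), grp["pred_dfi"].to_numpy(), donor)
        rows.append(dict(donor=donor, n=len(grp), mae=mae(series), mape=mape(series)))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EvalReport:
    """Per-donor error table plus aggregates, mirroring the usual
    per-donor-rows / Mean / S.D. report layout."""

    per_donor: pd.DataFrame  # columns: donor, mae, mape (and optionally n)
    test_donors: tuple = ()
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    train_mean: dict = field(default_factory=dict)
    train_sd: dict = field(default_factory=dict)
    test_values: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Report table: test donors first, then training donors, then Mean
        and S.D. rows over all donors."""
        df = self.per_donor.copy()
        df["__is_test"] = df["donor"].isin(self.test_donors)
        df = df.sort_values(["__is_test", "donor"], ascending=[False, True]).drop(
            columns="__is_test"
        )
        metrics = [c for c in df.columns if c != "donor" and np.issubdtype(df[c].dtype, np.number)]
        extra = [
            {"donor": "Mean", **{m: self.mean.get(m, np.nan) for m in metrics}},
            {"donor": "S.D.", **{m: self.sd.get(m, np.nan) for m in metrics}},
        ]
        return pd.concat([df, pd.DataFrame(extra)], ignore_index=True)[["donor", *metrics]]


def aggregate_report(per_donor: pd.DataFrame, test_donors=()) -> EvalReport:
    """Aggregate per-donor metric values.

    ``per_donor`` needs a ``donor`` column plus one column per metric (for
    example ``mae``/``mape``).  Reports the mean and sample (n-1) standard
    deviation across all donors, and the same restricted to training donors
    (those not in ``test_donors``); with a single donor the SD is undefined
    and reported as NaN.
    """
    df = pd.DataFrame(per_donor)
    if "donor" not in df.columns or len(df) < 1:
        raise ValueError("per_donor must have a 'donor' column and at least one row")
    if df["donor"].duplicated().any():
        raise ValueError("duplicate donor IDs in per-donor table")
    test_donors = tuple(test_donors)
    metrics = [c for c in df.columns if c != "donor" and np.issubdtype(df[c].dtype, np.number)]
    metrics = [m for m in metrics if m != "n"]

    def _agg(frame: pd.DataFrame):
        m = {k: float(frame[k].mean()) for k in metrics}
        s = {
            k: (float(frame[k].std(ddof=1)) if len(frame) > 1 else float("nan"))
            for k in metrics
        }
        return m, s

    mean, sd = _agg(df)
    train = df[~df["donor"].isin(test_donors)]
    train_mean, train_sd = _agg(train) if len(train) else ({}, {})
    test_values = df[df["donor"].isin(test_donors)] if test_donors else None
    return EvalReport(
        per_donor=df,
        test_donors=test_donors,
        mean=mean,
        sd=sd,
        train_mean=train_mean,
        train_sd=train_sd,
        test_values=test_values,
    )


def compare_models(col_a, col_b) -> dict:
    """Compare two models' donor-aligned per-donor metric values.

    Reports both a two-tailed paired t-test and a Wilcoxon signed-rank test
    (exact for small n); neither is privileged, since which test produced a
    given published p-value is often unstated.
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("columns must be 1-D and donor-aligned")
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.allclose(a, b):
        t_stat, t_p = 0.0, 1.0
    else:
        t_stat, t_p = stats.ttest_rel(a, b)
    try:
        w_stat, w_p = stats.wilcoxon(a, b, mode="exact")
    except ValueError:  # all differences zero
        w_stat, w_p = 0.0, 1.0
    return dict(
        n=int(a.size),
        t_stat=float(t_stat),
        t_pvalue=float(t_p),
        wilcoxon_stat=float(w_stat),
        wilcoxon_pvalue=float(w_p),
    )
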