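"""Growth-curve fitting and stress-phenotype scoring.

Fitness proxy: the growth rate ``r`` (divisions/hour) from a least-squares
fit of the logistic model ``N(t) = K / (1 + ((K - n0)/n0) exp(-r t))`` to
plate-reader absorbance series; relative fitness is the difference in ``r``
between a focal sample and the mean of its same-plate reference replicates.

Endpoint assays score each sample x compound well as
``B = A_24h - A_10m``; differences below a noise threshold ``A_thresh``
(fixed default 0.097, or derived as the 99th percentile of 10-minute
pairwise absolute differences) are treated as no change.  The normalized
stress fold change ``G = (A_X,evo / A_X,anc) / (A_ctrl,evo / A_ctrl,anc)``
cancels evolved carrying-capacity shifts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "logistic",
    "fit_logistic",
    "relative_fitness",
    "curve_auc",
    "biolog_score",
    "noise_threshold",
    "select_concentration_well",
    "call_tolerance",
    "stress_fold_change",
    "DEFAULT_A_THRESH",
]

DEFAULT_A_THRESH = 0.097


@dataclass
class GrowthCurve:
    """Absorbance time series for one well."""

    times: np.ndarray
    readings: np.ndarray
    sample_id: str = ""
    plate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.times.shape != self.readings.shape:
            raise ValueError("times and readings must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.readings)):
            raise ValueError("readings must be finite")


def logistic(t, r, K, n0):
    """Logistic growth: K / (1 + ((K - n0)/n0) * exp(-r t))."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - n0) / n0) * np.exp(-r * t))


@dataclass
class LogisticFit:
    r: float
    K: float
    n0: float
    residual_sse: float
    converged: bool
    non_growth: bool = False
    n_starts_tried: int = 0

    def __post_init__(self) -> None:
        if not self.non_growth and self.converged:
            if not (self.K > self.n0 > 0):
                raise ValueError("logistic fit requires K > n0 > 0")


def fit_logistic(
    curve: GrowthCurve,
    blank: float = 0.0,
    noise_floor: float = 0.02,
) -> LogisticFit:
    """Multi-start nonlinear least-squares logistic fit.

    ``blank`` (e.g. a media-only reading) is subtracted before fitting.
    Wells whose dynamic range is below ``noise_floor`` are flagged as
    non-growing with ``r`` undefined rather than fitted to noise.
    """
    y = curve.readings - blank
    t = curve.times
    if t.size < 10:
        raise ValueError("need >= 10 time points spanning lag through saturation")
    if float(y.max() - y.min()) < noise_floor:
        return LogisticFit(
            r=float("nan"), K=float("nan"), n0=float("nan"),
            residual_sse=float(np.sum((y - y.mean()) ** 2)),
            converged=False, non_growth=True,
        )
    k0 = float(max(y.max(), 1e-6))
    n00 = float(np.clip(y[0], 1e-6, 0.9 * k0))
    span = t[-1] - t[0]
    best = None
    tried = 0
    for r0 in (0.1, 0.3, 0.5, 1.0, 2.0, 5.0 / span):
        tried += 1
        try:
            popt, _ = curve_fit(
                logistic, t, y, p0=(r0, k0, n00),
                bounds=([1e-8, 1e-8, 1e-10], [np.inf, np.inf, np.inf]),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((logistic(t, *popt) - y) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return LogisticFit(
            r=float("nan"), K=float("nan"), n0=float("nan"),
            residual_sse=float("nan"), converged=False, n_starts_tried=tried,
        )
    (r, K, n0), sse = best
    if not K > n0:
        # saturating fit degenerated; treat as non-converged
        return LogisticFit(
            r=float("nan"), K=float("nan"), n0=float("nan"),
            residual_sse=sse, converged=False, n_starts_tried=tried,
        )
    return LogisticFit(
        r=float(r), K=float(K), n0=float(n0), residual_sse=sse,
        converged=True, n_starts_tried=tried,
    )


def relative_fitness(r_focal: float, r_reference_mean: float) -> float:
    """Growth-rate difference between a focal sample and its reference mean."""
    return r_focal - r_reference_mean


def curve_auc(curve: GrowthCurve, baseline: float | None = None) -> float:
    """Trapezoidal area under the curve above the baseline.

    The baseline defaults to the initial reading; pass an explicit value
    (e.g. a blank-well reading) to override.
    """
    if baseline is None:
        baseline = float(curve.readings[0])
    return float(np.trapezoid(curve.readings - baseline, curve.times))


def biolog_score(plate: pd.DataFrame) -> pd.DataFrame:
    """Endpoint growth score B = A_24h - A_10m per (sample, compound, well).

    Input is long format with columns sample_id, compound, well, time_label
    in {"10m", "24h"}, od600.
    """
    wide = plate.pivot_table(
        index=["sample_id", "compound", "well"],
        columns="time_label",
        values="od600",
        aggfunc="mean",
    )
    missing = {"10m", "24h"} - set(wide.columns)
    if missing:
        raise ValueError(f"plate data missing time labels: {sorted(missing)}")
    out = wide.reset_index()
    out["B"] = out["24h"] - out["10m"]
    return out[["sample_id", "compound", "well", "10m", "24h", "B"]]


def noise_threshold(plate: pd.DataFrame, quantile: float = 0.99) -> float:
    """Noise threshold: quantile of |A_i - A_j| over all 10-minute sample pairs.

    Pairs are formed within each (compound, well) and pooled across wells
    before taking the quantile.
    """
    t10 = plate[plate["time_label"] == "10m"]
    diffs: list[float] = []
    for _, grp in t10.groupby(["compound", "well"]):
        vals = grp["od600"].to_numpy()
        for a, b in itertools.combinations(vals, 2):
            diffs.append(abs(a - b))
    if not diffs:
        raise ValueError("no 10-minute sample pairs found")
    return float(np.quantile(diffs, quantile))


def select_concentration_well(
    scores: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.Series:
    """Per compound, pick the well maximizing the variance of matched
    evolved-minus-ancestor score differences across sample pairs.

    ``scores`` is the output of :func:`biolog_score`; ``pairs`` lists
    (evolved_sample_id, ancestor_sample_id) matches.  Ties pick the lowest
    well index (logged).
    """
    indexed = scores.set_index(["sample_id", "compound", "well"])["B"]
    choices = {}
    for compound, grp in scores.groupby("compound"):
        wells = sorted(grp["well"].unique())
        variances = []
        for well in wells:
            deltas = []
            for evo, anc in pairs:
                try:
                    deltas.append(
                        indexed.loc[(evo, compound, well)]
                        - indexed.loc[(anc, compound, well)]
                    )
                except KeyError:
                    continue
            variances.append(np.var(deltas) if len(deltas) > 1 else -np.inf)
        variances = np.asarray(variances, dtype=float)
        best = int(np.argmax(variances))
        if np.sum(variances == variances[best]) > 1:
            logger.warning(
                "compound %s: tied well variances; choosing lowest well index", compound
            )
        choices[compound] = wells[best]
    return pd.Series(choices, name="well").rename_axis("compound")


def call_tolerance(
    B_evolved: float, B_ancestor: float, A_thresh: float = DEFAULT_A_THRESH
) -> str:
    """Tolerance call: 'gained' if evolved exceeds ancestor by more than
    A_thresh, 'lost' for the symmetric case, else 'none' (strict inequality)."""
    if A_thresh <= 0:
        raise ValueError("A_thresh must be positive")
    if B_evolved - B_ancestor > A_thresh:
        return "gained"
    if B_ancestor - B_evolved > A_thresh:
        return "lost"
    return "none"


def stress_fold_change(
    A_X_evolved: float,
    A_X_ancestor: float,
    A_ctrl_evolved: float,
    A_ctrl_ancestor: float,
) -> float:
    """Normalized fold change G = (A_X,E / A_X,A) / (A_ctrl,E / A_ctrl,A).

    G > 1 means the evolved sample improved in condition X beyond any change
    in its unstressed carrying capacity.
    """
    readings = {
        "A_X_evolved": A_X_evolved,
        "A_X_ancestor": A_X_ancestor,
        "A_ctrl_evolved": A_ctrl_evolved,
        "A_ctrl_ancestor": A_ctrl_ancestor,
    }
    bad = [k for k, v in readings.items() if not v > 0]
    if bad:
        raise ValueError(f"non-positive absorbance reading(s): {bad}")
    return (A_X_evolved / A_X_ancestor) / (A_ctrl_evolved / A_ctrl_ancestor)
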