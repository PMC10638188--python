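"""Model-measurement agreement metrics.

RMSE and MAPE on the time-resolved 0.5 Hz traces, Bland-Altman limits of
agreement, an uncorrected pointwise paired t statistic across subjects (the
random-field-corrected inference used for formal significance maps is out of
scope; outputs are labelled uncorrected), and the day-to-day RMSE of
last-60-s segment means between two trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "rmse", "mape", "bland_altman", "pointwise_paired_t",
    "day_to_day_rmse", "agreement_report", "AgreementReport",
    "time_normalize",
]

#: Nodes with measured MR_ae below this (W) are excluded from MAPE with a
#: warning; they should not occur after preprocessing (MR_ae >= MR_rest).
MAPE_FLOOR = 50.0


def _aligned(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be equal-length and aligned")
    return a, b


def rmse(y_meas, y_mod) -> float:
    """Root mean squared error, W."""
    a, b = _aligned(y_meas, y_mod)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mape(y_meas, y_mod) -> float:
    """Mean absolute percentage error, %, with measurement as reference.

    Nodes where the measured rate falls below 50 W (possible only on raw or
    heavily noise-corrupted input; preprocessing guarantees MR_ae at or
    above MR_rest) are excluded with a warning rather than inflating the
    statistic; an all-excluded input is an error.
    """
    a, b = _aligned(y_meas, y_mod)
    keep = a >= MAPE_FLOOR
    if not keep.any():
        raise ValueError("no measured values at or above the MAPE floor")
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} nodes with measured MR_ae "
            f"below {MAPE_FLOOR:.0f} W from MAPE", stacklevel=2)
    return float(100.0 * np.mean(np.abs(a[keep] - b[keep]) / a[keep]))


def bland_altman(y_meas, y_mod):
    """Mean difference, 95% limits of agreement and fraction within.

    Differences are measured minus modeled, so model underprediction gives a
    positive mean difference. Limits are mean ± 1.96 SD of the differences.
    """
    a, b = _aligned(y_meas, y_mod)
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    frac = float(np.mean((d >= lo) & (d <= hi)))
    return {"mean_diff": mean, "loa_low": lo, "loa_high": hi,
            "fraction_within": frac}


def time_normalize(y, n_out: int) -> np.ndarray:
    """Linearly time-warp a trace to ``n_out`` nodes (for aligning
    open-ended final periods of different durations across subjects)."""
    y = np.asarray(y, dtype=float)
    x_old = np.linspace(0.0, 1.0, y.size)
    x_new = np.linspace(0.0, 1.0, n_out)
    return np.interp(x_new, x_old, y)


def pointwise_paired_t(measured, modeled, alpha: float = 0.05):
    """Node-wise paired t statistic across subjects, uncorrected.

    ``measured`` and ``modeled`` are (n_subjects, n_nodes) arrays of MR_ae
    already normalized by each subject's MR_ae_max and time-aligned
    (open-ended periods rescaled to a common length). Returns the t trace,
    the naive two-tailed critical value at ``alpha`` (no random-field
    correction) and the supra-threshold clusters as (start, end) node index
    pairs (end exclusive).
    """
    meas = np.atleast_2d(np.asarray(measured, dtype=float))
    mod = np.atleast_2d(np.asarray(modeled, dtype=float))
    if meas.shape != mod.shape:
        raise ValueError("groups must share shape (n_subjects, n_nodes)")
    n = meas.shape[0]
    if n < 3:
        raise ValueError("need at least three subjects")
    d = meas - mod
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0.0,
                     np.where(mean == 0.0, 0.0, np.inf * np.sign(mean)), t)
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    above = np.abs(t) > crit
    clusters = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            clusters.append((i, j))
            i = j
        else:
            i += 1
    return {"t": t, "critical": crit, "clusters": clusters,
            "corrected": False}


def day_to_day_rmse(trial_a, trial_b, n_segments: int = 6,
                    window: float = 60.0) -> float:
    """RMSE between two trials of the last-``window``-s mean of the first
    ``n_segments`` (submaximal) exercise periods.

    Segment boundaries come from each trial; both must share at least
    ``n_segments`` closed segments. The mean of each period is taken over
    its final 60 s (31 nodes at 0.5 Hz).
    """
    means = []
    for trial in (trial_a, trial_b):
        if trial.y is None:
            raise ValueError("both trials need measured output")
        edges = [trial.t[0], *trial.segment_boundaries, trial.t[-1]]
        segs = [(a, b) for a, b in zip(edges[:-1], edges[1:])]
        if len(segs) < n_segments:
            raise ValueError(
                f"trial has {len(segs)} segments, need {n_segments}")
        seg_means = []
        for a, b in segs[:n_segments]:
            m = (trial.t >= b - window - 1e-9) & (trial.t <= b + 1e-9) \
                & (trial.t >= a - 1e-9)
            seg_means.append(float(trial.y[m].mean()))
        means.append(np.array(seg_means))
    return float(np.sqrt(np.mean((means[0] - means[1]) ** 2)))


@dataclass
class AgreementReport:
    rmse_W: float
    mape_percent: float
    bland_altman: dict
    day_to_day_rmse_W: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(y_meas, y_mod, trial_pair=None) -> AgreementReport:
    """Bundle the scalar agreement metrics for one trial (and optionally the
    day-to-day RMSE for a pair of trials)."""
    d2d = None
    if trial_pair is not None:
        d2d = day_to_day_rmse(*trial_pair)
    return AgreementReport(
        rmse_W=rmse(y_meas, y_mod),
        mape_percent=mape(y_meas, y_mod),
        bland_altman=bland_altman(y_meas, y_mod),
        day_to_day_rmse_W=d2d,
    )
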