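"""ERFE biomarker statistics: baseline changes, correlation, ROC/Youden.

The early-biomarker logic: the change of circulating ERFE from its pre-dose
baseline at 4 h post-rHuEPO (before the circadian evening peak) reflects the
immediate induction of ERFE and is used to predict the hemoglobin response
over the following week. A *hyporesponder* is a subject whose HGB rises by
less than 1 g/dL from baseline within one week of dosing.

ROC analysis is implemented explicitly (trapezoidal AUC over all thresholds,
Youden ``J = max(sensitivity + specificity - 1)``, cutoff reported as the
midpoint between adjacent distinct scores) so tie handling and cutoff
conventions are under the package's control; linear regression and its
p-value come from :func:`scipy.stats.linregress`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTable

__all__ = [
    "delta_erfe",
    "relative_delta",
    "correlate",
    "CorrelationResult",
    "roc",
    "RocResult",
    "is_hyporesponder",
    "biomarker_table",
]

HYPORESPONDER_DHGB = 1.0  # g/dL within one week


def delta_erfe(
    times: Sequence[float],
    values: Sequence[float],
    at: float = 4.0,
    baseline_time: float = 0.0,
) -> float:
    """Change of ERFE from baseline at ``at`` hours (linear interp off-grid).

    Requires a baseline sample at ``baseline_time``; the post-dose value is
    linearly interpolated when ``at`` is not a sampled time (only within the
    sampled range).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    order = np.argsort(t)
    t, v = t[order], v[order]
    base = np.nonzero(np.isclose(t, baseline_time, atol=1e-9))[0]
    if base.size == 0:
        raise ValueError(f"no baseline sample at t={baseline_time}")
    if at < t.min() - 1e-9 or at > t.max() + 1e-9:
        raise ValueError(f"offset {at} h outside the sampled range [{t.min()}, {t.max()}]")
    return float(np.interp(at, t, v) - v[base[0]])


def relative_delta(delta: float, baseline: float) -> float:
    """Relative change from baseline in percent: 100 * delta / baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 100.0 * delta / baseline


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Least-squares linear association: Pearson R, two-sided p for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlate needs paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return CorrelationResult(
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(x.size),
    )


@dataclass(frozen=True)
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    cutoff: float
    j_index: float
    positive_low: bool


def roc(scores: Sequence[float], labels: Sequence[bool], positive_low: bool = False) -> RocResult:
    """ROC curve, trapezoidal AUC and Youden-optimal cutoff.

    ``labels`` are the positive-class flags (e.g. hyporesponder). By default
    high scores indicate the positive class; ``positive_low=True`` flips the
    orientation (low ERFE induction predicts hyporesponsiveness) while still
    reporting the cutoff on the original score scale.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if s.size != lab.size or s.size == 0:
        raise ValueError("scores and labels must be non-empty and aligned")
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present for ROC analysis")
    work = -s if positive_low else s

    n_pos = int(lab.sum())
    n_neg = int(s.size - n_pos)
    distinct = np.unique(work)
    # candidate thresholds: below all scores, midpoints, above all scores
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
    # sentinel thresholds strictly outside the score range at any magnitude
    cand = np.concatenate(
        [[np.nextafter(distinct[0], -np.inf)], mids, [np.nextafter(distinct[-1], np.inf)]]
    )

    sens = np.array([np.sum(work[lab] >= c) / n_pos for c in cand])
    spec = np.array([np.sum(work[~lab] < c) / n_neg for c in cand])

    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # step curve: within tied FPR, rising TPR
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best = int(np.argmax(j))
    cutoff_work = float(cand[best])
    cutoff = -cutoff_work if positive_low else cutoff_work
    return RocResult(
        auc=auc,
        thresholds=-cand[::-1] if positive_low else cand,
        sensitivity=sens[::-1].copy() if positive_low else sens,
        specificity=spec[::-1].copy() if positive_low else spec,
        cutoff=cutoff,
        j_index=float(j[best]),
        positive_low=positive_low,
    )


def is_hyporesponder(delta_hgb: float, threshold: float = HYPORESPONDER_DHGB) -> bool:
    """Hyporesponder rule: HGB increase below ``threshold`` g/dL in 1 week."""
    return bool(delta_hgb < threshold)


def biomarker_table(
    events: EventTable,
    dose_time: float,
    hgb_window_h: float = 168.0,
    erfe_offsets: tuple[float, float] = (4.0, 10.0),
) -> pd.DataFrame:
    """Per-subject biomarker records from an observation dataset.

    For every subject with an ERFE baseline at ``dose_time``: baseline ERFE,
    the ERFE change at each requested post-dose offset, its relative change
    (percent of baseline), the HGB change from the sample at ``dose_time`` to
    the sample at ``dose_time + hgb_window_h`` (nearest sampled times used,
    flagged if off-nominal), and the hyporesponder flag.

    Default windows per disease model: 96 h (day 4) for CKD and 144 h
    (day 6) for CIA are the response windows used in the correlation
    analysis; the 168 h default here is the 1-week hyporesponder rule.
    """
    rows = []
    for subject in events.subjects:
        erfe = events.observations(subject=subject, analyte="ERFE")
        hgb = events.observations(subject=subject, analyte="HGB")
        if erfe.empty or hgb.empty:
            continue
        t_e = erfe["time_h"].to_numpy(dtype=float) - dose_time
        v_e = erfe["dv"].to_numpy(dtype=float)
        base = v_e[np.isclose(t_e, 0.0)]
        if base.size == 0:
            raise ValueError(f"subject {subject}: no ERFE baseline at dose time")
        record: dict = {"subject": subject, "erfe_baseline": float(base[0])}
        for off in erfe_offsets:
            d = delta_erfe(t_e, v_e, at=off)
            record[f"delta_erfe_{off:g}h"] = d
            record[f"rel_delta_erfe_{off:g}h"] = relative_delta(d, float(base[0]))
        t_h = hgb["time_h"].to_numpy(dtype=float) - dose_time
        v_h = hgb["dv"].to_numpy(dtype=float)
        i0 = int(np.argmin(np.abs(t_h)))
        i1 = int(np.argmin(np.abs(t_h - hgb_window_h)))
        d_hgb = float(v_h[i1] - v_h[i0])
        record["delta_hgb"] = d_hgb
        record["hgb_window_actual_h"] = float(t_h[i1] - t_h[i0])
        record["hyporesponder"] = is_hyporesponder(d_hgb)
        rows.append(record)
    return pd.DataFrame(rows)
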