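"""Virtual rats and complete in-silico study datasets.

The published estimates fixed interindividual variability to zero, so the
virtual-cohort generator is the package's own statistical layer: it draws
per-subject parameters log-normally around the table values (CV = 0
reproduces the population values exactly) and produces long-format datasets
under the two study designs, with proportional residual error matching the
estimation likelihood (``y = yhat * (1 + eps)``, ``eps ~ N(0, sigma_a^2)``,
independent across observations).

Study designs (all times on the simulation clock, phase-locked to the 24-h
circadian rhythm):

``ckd_study``
    saline n=5 / 450 IU/kg n=6 / 1350 IU/kg n=6, rHuEPO t.i.w. for 2 weeks
    at 0, 48, 96, 168, 216, 264 h; ERFE sampled 0,1,2,4,6,8,10,12,24 h after
    the first injection; hematology on days 0,4,10,15,20,25,30,34.
``cia_study``
    carboplatin 60 mg/kg at t=24 h, then a single rHuEPO dose (0/450/1350
    IU/kg, n=9 each) at t=192 h (one week post-carboplatin); ERFE sampled at
    the same offsets after the rHuEPO dose; hematology on days
    -8..24 relative to the rHuEPO dose (clock starts at the earliest
    hematology sample so all event times are nonnegative).
``hyporesponder_study``
    single-arm 1350 IU/kg variant of the CIA design with a dense first week
    of hematology, used with :func:`make_hyporesponder_cohort`.

Negative simulated observations (possible under proportional Gaussian error
at small predictions) are truncated at 0 and flagged in a ``trunc`` column —
deterministic given the seed, never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import predict
from .events import EventTable
from .params import ParameterSet, load_parameters

__all__ = [
    "SyntheticSubject",
    "DESIGNS",
    "get_design",
    "make_cohort",
    "make_dataset",
    "make_hyporesponder_cohort",
]

_ERFE_OFFSETS = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0)

DESIGNS: Mapping[str, dict] = {
    "ckd_study": {
        "model": "ckd",
        "arms": (("saline", 0.0, 5), ("epo450", 450.0, 6), ("epo1350", 1350.0, 6)),
        "epo_dose_times": (0.0, 48.0, 96.0, 168.0, 216.0, 264.0),
        "carb_dose": None,
        "first_epo_time": 0.0,
        "erfe_times": tuple(0.0 + off for off in _ERFE_OFFSETS),
        "hema_times": tuple(24.0 * d for d in (0, 4, 10, 15, 20, 25, 30, 34)),
    },
    "cia_study": {
        "model": "cia",
        "arms": (("saline", 0.0, 9), ("epo450", 450.0, 9), ("epo1350", 1350.0, 9)),
        "epo_dose_times": (192.0,),
        "carb_dose": (24.0, 60.0),
        "first_epo_time": 192.0,
        "erfe_times": tuple(192.0 + off for off in _ERFE_OFFSETS),
        "hema_times": tuple(
            192.0 + 24.0 * d
            for d in (-8, -6, -4, -2, 0, 3, 6, 9, 12, 13, 14, 16, 17, 18, 20, 21, 24)
        ),
    },
    "hyporesponder_study": {
        "model": "cia",
        "arms": (("epo1350", 1350.0, None),),  # n = cohort size
        "epo_dose_times": (192.0,),
        "carb_dose": (24.0, 60.0),
        "first_epo_time": 192.0,
        "erfe_times": tuple(192.0 + off for off in _ERFE_OFFSETS),
        "hema_times": tuple(192.0 + 24.0 * d for d in (-1, 0, 3, 6, 7)),
    },
}


def get_design(name: str) -> dict:
    try:
        return DESIGNS[name]
    except KeyError:
        raise ValueError(f"unknown design {name!r}; one of {sorted(DESIGNS)}") from None


@dataclass(frozen=True)
class SyntheticSubject:
    """One virtual rat: parameters plus optional induction-scaling phenotype."""

    sid: str
    params: ParameterSet
    p3_scale: float = 1.0
    severity: float | None = None

    @property
    def true_hyporesponder(self) -> bool | None:
        """Generative phenotype label (severity >= 0.5), if severity is set."""
        return None if self.severity is None else bool(self.severity >= 0.5)


def make_cohort(
    model: str,
    n: int,
    cv: Mapping[str, float] | None = None,
    seed: int = 0,
    base: ParameterSet | None = None,
) -> list[SyntheticSubject]:
    """Draw ``n`` virtual subjects around the table values for ``model``.

    ``cv`` maps parameter names to between-subject coefficients of variation;
    draws are log-normal with log-SD ``sqrt(ln(1 + cv^2))`` so CV=0 (or an
    absent entry) reproduces the population value exactly. Deterministic
    given ``seed``.
    """
    if base is None:
        base = load_parameters("table1" if model == "ckd" else "table2")
    cv = dict(cv or {})
    for name, c in cv.items():
        if c < 0:
            raise ValueError(f"CV for {name} must be >= 0")
        if name not in base:
            raise ValueError(f"unknown parameter {name!r} in CV map")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        overrides = {}
        for name, c in cv.items():
            z = rng.standard_normal()
            if c > 0:
                sd_log = np.sqrt(np.log1p(c**2))
                overrides[name] = base[name] * np.exp(sd_log * z)
        cohort.append(SyntheticSubject(sid=f"{model}{i + 1:03d}", params=base.replace(**overrides)))
    return cohort


def make_dataset(
    cohort: Sequence[SyntheticSubject],
    design: str | Mapping,
    seed: int = 0,
    pk_config: Mapping | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> EventTable:
    """Simulate a full study dataset for ``cohort`` under a named design.

    Subjects are assigned to arms in order; arm sizes must sum to the cohort
    size (an arm with ``n=None`` absorbs the whole cohort). Observations are
    the noiseless model predictions with per-analyte proportional error from
    each subject's own sigma parameters; sigma=0 is impossible by parameter
    validation, but the noiseless predictions are recoverable by setting
    ``dv`` aside and re-running :func:`erfesim.engine.predict`.
    """
    if isinstance(design, str):
        design = get_design(design)
    arms = []
    total = 0
    for label, dose, n in design["arms"]:
        n = len(cohort) if n is None else int(n)
        arms.append((label, float(dose), n))
        total += n
    if total != len(cohort):
        raise ValueError(f"cohort size {len(cohort)} != design total {total}")

    records = []
    assignment = []  # (subject, arm_label, epo_dose)
    i = 0
    for label, dose, n in arms:
        for _ in range(n):
            assignment.append((cohort[i], label, dose))
            i += 1

    for subj, label, dose in assignment:
        sid = subj.sid
        if design["carb_dose"] is not None:
            t_c, amt_c = design["carb_dose"]
            records.append(
                dict(subject=sid, arm=label, time_h=t_c, evid=1, drug="carboplatin", amt=amt_c)
            )
        if dose > 0:
            for t_d in design["epo_dose_times"]:
                records.append(
                    dict(subject=sid, arm=label, time_h=t_d, evid=1, drug="rHuEPO", amt=dose)
                )
        for t in design["erfe_times"]:
            records.append(
                dict(subject=sid, arm=label, time_h=t, evid=0, analyte="ERFE", dv=0.0, mdv=0)
            )
        for t in design["hema_times"]:
            for analyte in ("RBC", "HGB"):
                records.append(
                    dict(subject=sid, arm=label, time_h=t, evid=0, analyte=analyte, dv=0.0, mdv=0)
                )
    table = EventTable.from_records(records)

    params_by_subject = {s.sid: s.params for s in cohort}
    p3_by_subject = {s.sid: s.p3_scale for s in cohort}
    preds = predict(
        table, params_by_subject, design["model"], pk_config=pk_config,
        rtol=rtol, atol=atol, p3_scale_by_subject=p3_by_subject,
    )
    df = table.df
    obs_mask = df["evid"] == 0
    yhat = preds[obs_mask].to_numpy(dtype=float)
    sigma = np.array(
        [
            params_by_subject[s].sigma_frac(a)
            for s, a in zip(df.loc[obs_mask, "subject"], df.loc[obs_mask, "analyte"])
        ]
    )
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(yhat.size)
    y = yhat * (1.0 + sigma * eps)
    trunc = y < 0.0
    y = np.where(trunc, 0.0, y)
    df.loc[obs_mask, "dv"] = y
    df["trunc"] = 0
    df.loc[obs_mask, "trunc"] = trunc.astype(int)
    return EventTable(df)


# severity -> parameter mapping for the hyporesponder phenotype spectrum.
# A benign subject (severity 0) has an expanded inducible erythroblast pool,
# high rHuEPO potency, mild myelosuppression and an active direct EPO effect;
# a severe subject (severity 1) has the full published kill effect, a depleted
# pool, low potency and a lost EPO effect.
_RESPONDER_K_EPO = 1.2e-3  # direct EPO proliferation stimulation, benign end


def make_hyporesponder_cohort(
    n: int,
    seed: int = 0,
    severities: Sequence[float] | None = None,
    base: ParameterSet | None = None,
    responder_k_epo: float = _RESPONDER_K_EPO,
) -> list[SyntheticSubject]:
    """CIA cohort spanning responder -> hyporesponder phenotypes.

    ``severities`` in [0, 1] (drawn U(0,1) when omitted) scale the
    carboplatin kill, the ERFE potency (EC50), the inducible precursor mass
    and the direct EPO effect; the generative ground-truth label is
    severity >= 0.5 (recorded on each subject).
    """
    if base is None:
        base = load_parameters("table2")
    rng = np.random.default_rng(seed)
    if severities is None:
        severities = rng.uniform(0.0, 1.0, size=n)
    severities = np.asarray(severities, dtype=float)
    if severities.size != n or ((severities < 0) | (severities > 1)).any():
        raise ValueError("severities must be n values in [0, 1]")
    cohort = []
    for i, s in enumerate(severities):
        params = base.replace(
            k_carb=base.k_carb * (0.05 + 0.95 * s),
            ec50=base.ec50 * (0.5 + 4.5 * s),
            k_epo=responder_k_epo * (1.0 - s),
        )
        cohort.append(
            SyntheticSubject(
                sid=f"hypo{i + 1:03d}",
                params=params,
                p3_scale=float(2.0 - 1.8 * s),
                severity=float(s),
            )
        )
    return cohort
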