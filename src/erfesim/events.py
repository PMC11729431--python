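"""Long-format dose/observation event tables.

The on-disk dialect is a NONMEM-like CSV with columns

``subject,arm,time_h,evid,drug,amt,analyte,dv,mdv``

where ``evid=1`` marks a dose row (``drug`` in {rHuEPO, carboplatin},
``amt`` in IU/kg or mg/kg, ``analyte``/``dv`` empty) and ``evid=0`` an
observation row (``analyte`` in {ERFE, RBC, HGB}, ``dv`` the measured value,
``amt`` empty). ``mdv=1`` flags a missing observation: the row is retained
but excluded from fitting. Extra columns (e.g. a truncation flag written by
the synthetic-data generator) are preserved through round trips.

Row order is normalized to (subject, time, dose-before-observation at ties).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["EventTable", "EventTableError", "read_event_table", "write_event_table"]

COLUMNS = ["subject", "arm", "time_h", "evid", "drug", "amt", "analyte", "dv", "mdv"]
DRUGS = ("rHuEPO", "carboplatin", "none")
ANALYTES = ("ERFE", "RBC", "HGB")


class EventTableError(ValueError):
    """Malformed or invariant-violating event data."""


def _fail(line, msg):
    prefix = f"line {line}: " if line is not None else ""
    raise EventTableError(prefix + msg)


class EventTable:
    """Validated long-format table of doses and observations.

    Thin wrapper around a :class:`pandas.DataFrame` (attribute ``df``) that
    enforces the dialect invariants and provides schedule extraction helpers
    used by the simulation engine and the estimator.
    """

    def __init__(self, df: pd.DataFrame, _lines: Sequence[int] | None = None):
        df = df.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise EventTableError(f"missing columns: {missing}")
        df["subject"] = df["subject"].astype(str)
        df["arm"] = df["arm"].astype(str)
        for col in ("time_h", "amt", "dv"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("evid", "mdv"):
            df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
        df["drug"] = df["drug"].fillna("none").replace("", "none")
        df["analyte"] = df["analyte"].fillna("").astype(str)
        self._validate(df, _lines)
        order = np.lexsort((-df["evid"].to_numpy(), df["time_h"].to_numpy()))
        # stable per-subject ordering: sort by subject first, then time, dose first
        df = (
            df.iloc[order]
            .sort_values("subject", kind="stable")
            .reset_index(drop=True)
        )
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame, lines: Sequence[int] | None) -> None:
        for i, row in df.iterrows():
            line = lines[i] if lines is not None else None
            t = row["time_h"]
            if pd.isna(t):
                _fail(line, "time_h is not a number")
            if t < 0:
                _fail(line, f"negative time {t}")
            if row["evid"] == 1:
                if row["drug"] not in ("rHuEPO", "carboplatin"):
                    _fail(line, f"dose row with drug {row['drug']!r}")
                if pd.isna(row["amt"]) or row["amt"] <= 0:
                    _fail(line, f"dose row needs amount > 0, got {row['amt']}")
                if not pd.isna(row["dv"]):
                    _fail(line, "dose row must not carry an observation value")
            elif row["evid"] == 0:
                if row["analyte"] not in ANALYTES:
                    _fail(line, f"observation row with analyte {row['analyte']!r}")
                if not pd.isna(row["amt"]):
                    _fail(line, "observation row must not carry a dose amount")
                if row["mdv"] == 1:
                    continue  # missing observation: dv may be empty
                if pd.isna(row["dv"]):
                    _fail(line, "non-missing observation without a value (set mdv=1?)")
                if row["dv"] < 0:
                    _fail(line, f"negative observation value {row['dv']}")
            else:
                _fail(line, f"evid must be 0 or 1, got {row['evid']}")

    # -- convenience --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        a, b = self.df[COLUMNS], other.df[COLUMNS]
        if len(a) != len(b):
            return False
        return bool(
            a.fillna("<na>").reset_index(drop=True).eq(b.fillna("<na>").reset_index(drop=True)).all().all()
        )

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject"]))

    def subset(self, subject: str) -> "EventTable":
        return EventTable(self.df[self.df["subject"] == subject])

    def doses(self, subject: str | None = None, drug: str | None = None) -> pd.DataFrame:
        d = self.df[self.df["evid"] == 1]
        if subject is not None:
            d = d[d["subject"] == subject]
        if drug is not None:
            d = d[d["drug"] == drug]
        return d

    def observations(
        self, subject: str | None = None, analyte: str | None = None, include_missing: bool = False
    ) -> pd.DataFrame:
        d = self.df[self.df["evid"] == 0]
        if not include_missing:
            d = d[d["mdv"] == 0]
        if subject is not None:
            d = d[d["subject"] == subject]
        if analyte is not None:
            d = d[d["analyte"] == analyte]
        return d

    def dose_schedule(self, subject: str) -> tuple[tuple, tuple]:
        """((epo_time, epo_amt), ...), ((carb_time, carb_amt), ...) for one subject."""
        d = self.doses(subject)
        epo = tuple(
            (float(r.time_h), float(r.amt)) for r in d[d["drug"] == "rHuEPO"].itertuples()
        )
        carb = tuple(
            (float(r.time_h), float(r.amt)) for r in d[d["drug"] == "carboplatin"].itertuples()
        )
        return epo, carb

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "EventTable":
        rows = []
        for rec in records:
            row = {c: rec.get(c, np.nan) for c in COLUMNS}
            row.setdefault("subject", "1")
            for key in rec:
                if key not in COLUMNS:
                    row[key] = rec[key]
            rows.append(row)
        df = pd.DataFrame(rows)
        df["arm"] = df.get("arm", pd.Series(dtype=object)).fillna("")
        return cls(df)

    def write(self, path: str | Path) -> None:
        write_event_table(self, path)


def read_event_table(path: str | Path) -> EventTable:
    """Read and validate an event CSV; parse errors name the offending line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject": str, "arm": str, "drug": str, "analyte": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise EventTableError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"{path}: header missing columns {missing}")
    for col in ("time_h", "amt", "dv", "evid", "mdv"):
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise EventTableError(f"{path}: line {line}: non-numeric value in column {col!r}")
        df[col] = coerced
    lines = [int(i) + 2 for i in df.index]
    return EventTable(df, _lines=lines)


def write_event_table(events: EventTable, path: str | Path) -> None:
    events.df.to_csv(path, index=False)
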