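"""Crash-record data model: CSV ingest, validation, splitting, descriptive statistics.

The unit of analysis is a single crash with a four-level injury-severity
outcome (``NI`` no injury, ``MI`` minor injury, ``SI`` severe injury,
``FI`` fatal injury), a period label (typically the calendar year), a
rider-group label (``helmet`` / ``non-helmet``), and binary indicator
covariates.  Outcomes are kept as categorical labels in a fixed canonical
order rather than integers so that nothing downstream can accidentally
treat the scale as ordinal: the model estimated on these data is an
unordered (multinomial) logit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical severity levels, fixed order: no / minor / severe / fatal injury.
SEVERITY_LEVELS: tuple[str, ...] = ("NI", "MI", "SI", "FI")

_META_COLUMNS = ("outcome", "period", "group")


class CrashRecord(NamedTuple):
    """One crash: outcome label, 0/1 covariates, period and rider-group labels."""

    outcome: str
    covariates: dict[str, int]
    period: str
    group: str


@dataclass
class CrashDataset:
    """A validated collection of crash records.

    Wraps a :class:`pandas.DataFrame` with columns ``outcome``, ``period``,
    ``group`` plus one 0/1 column per indicator variable.  ``provenance``
    records where the rows came from (source file, generator seed, ...).
    ``rejections`` holds rows that failed validation on ingest.
    """

    df: pd.DataFrame
    variables: list[str]
    provenance: str = ""
    rejections: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns: {missing}")
        for var in self.variables:
            if var not in self.df.columns:
                raise ValueError(f"declared variable {var!r} has no column")
            vals = set(pd.unique(self.df[var]))
            if not vals <= {0, 1}:
                raise ValueError(f"indicator {var!r} has non-binary values {vals - {0, 1}}")
        bad = set(self.df["outcome"]) - set(SEVERITY_LEVELS)
        if bad:
            raise ValueError(f"unknown outcome labels {bad}; expected {SEVERITY_LEVELS}")
        if len(self.df) == 0:
            raise ValueError("dataset has no records")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def outcomes(self) -> pd.Series:
        return self.df["outcome"]

    def covariates(self) -> pd.DataFrame:
        """The indicator block (one 0/1 column per variable)."""
        return self.df[self.variables]

    def records(self) -> Iterator[CrashRecord]:
        for _, row in self.df.iterrows():
            yield CrashRecord(
                outcome=row["outcome"],
                covariates={v: int(row[v]) for v in self.variables},
                period=str(row["period"]),
                group=str(row["group"]),
            )


#: Identity coding for files written by :func:`write_crash_table`.
DEFAULT_CODING: dict = {
    "outcome_column": "outcome",
    "outcome_levels": list(SEVERITY_LEVELS),
    "period_column": "period",
    "group_column": "group",
    "indicators": None,  # None -> every remaining column
}


def load_coding(path: str | Path) -> dict:
    """Read a coding configuration (JSON or YAML) mapping file columns to roles."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _outcome_mapper(outcome_levels) -> Mapping[object, str]:
    """Normalise the outcome coding to a raw-value -> canonical-label mapping."""
    if isinstance(outcome_levels, Mapping):
        bad = set(outcome_levels.values()) - set(SEVERITY_LEVELS)
        if bad:
            raise ValueError(f"outcome_levels maps to unknown levels {bad}")
        return dict(outcome_levels)
    levels = list(outcome_levels)
    if len(levels) != len(SEVERITY_LEVELS):
        raise ValueError(
            "outcome_levels as a list must give the raw values for "
            f"{SEVERITY_LEVELS} in that order"
        )
    return dict(zip(levels, SEVERITY_LEVELS))


def read_crash_table(path: str | Path, coding: Mapping | None = None) -> CrashDataset:
    """Read a crash CSV into a validated :class:`CrashDataset`.

    Rows with an unmappable outcome, a non-binary indicator value, or a
    missing period/group label are rejected — never coerced — and collected
    into ``dataset.rejections`` with a ``reason`` column.

    Parameters
    ----------
    path:
        CSV file, comma-separated, UTF-8, header row required.
    coding:
        Mapping with keys ``outcome_column``, ``outcome_levels`` (list of the
        four raw values in NI/MI/SI/FI order, or a raw->label mapping),
        ``period_column``, ``group_column``, ``indicators`` (list of column
        names, or None for "all remaining columns").
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    coding = {**DEFAULT_CODING, **(coding or {})}
    raw = pd.read_csv(path)
    if len(raw) == 0:
        raise ValueError(f"{path}: file has no data rows")

    for key in ("outcome_column", "period_column", "group_column"):
        col = coding[key]
        if col not in raw.columns:
            raise ValueError(f"{path}: mapped column {col!r} ({key}) not found")
    indicators = coding["indicators"]
    if indicators is None:
        reserved = {coding["outcome_column"], coding["period_column"], coding["group_column"]}
        indicators = [c for c in raw.columns if c not in reserved]
    for col in indicators:
        if col not in raw.columns:
            raise ValueError(f"{path}: mapped indicator column {col!r} not found")

    mapper = _outcome_mapper(coding["outcome_levels"])
    reasons = pd.Series("", index=raw.index)

    outcome = raw[coding["outcome_column"]].map(mapper)
    reasons[outcome.isna()] = "unmappable outcome"
    for col in indicators:
        vals = pd.to_numeric(raw[col], errors="coerce")
        ok = vals.isin([0, 1])
        reasons[(reasons == "") & ~ok] = f"non-binary indicator {col!r}"
    for key, what in (("period_column", "period"), ("group_column", "group")):
        missing = raw[coding[key]].isna()
        reasons[(reasons == "") & missing] = f"missing {what}"

    rejected_mask = reasons != ""
    rejections = raw[rejected_mask].copy()
    rejections["reason"] = reasons[rejected_mask]

    kept = raw[~rejected_mask]
    if len(kept) == 0:
        raise ValueError(f"{path}: no valid rows after validation")
    df = pd.DataFrame(
        {
            "outcome": outcome[~rejected_mask],
            "period": kept[coding["period_column"]].astype(str),
            "group": kept[coding["group_column"]].astype(str),
        }
    )
    for col in indicators:
        df[col] = pd.to_numeric(kept[col]).astype(int)
    return CrashDataset(
        df=df,
        variables=list(indicators),
        provenance=f"read_crash_table({path})",
        rejections=rejections.reset_index(drop=True),
    )


def write_crash_table(ds: CrashDataset, path: str | Path) -> None:
    """Write the dataset in the canonical CSV dialect ``read_crash_table`` accepts."""
    cols = list(_META_COLUMNS) + ds.variables
    ds.df[cols].to_csv(path, index=False)


def split_dataset(ds: CrashDataset, by: str = "period") -> dict:
    """Partition a dataset by ``period``, ``group`` or ``both``.

    Every record lands in exactly one part; part sizes sum to ``ds.n_obs``.
    Empty combinations are simply absent from the returned mapping.
    """
    if by == "period":
        keys = ds.df["period"]
    elif by == "group":
        keys = ds.df["group"]
    elif by == "both":
        keys = list(zip(ds.df["group"], ds.df["period"]))
    else:
        raise ValueError(f"by must be 'period', 'group' or 'both', got {by!r}")
    out = {}
    grouped = ds.df.groupby(pd.Series(keys, index=ds.df.index), sort=True)
    for label, part in grouped:
        out[label] = CrashDataset(
            df=part.reset_index(drop=True),
            variables=list(ds.variables),
            provenance=f"{ds.provenance} | split by={by} label={label}",
        )
    return out


def descriptive_stats(ds: CrashDataset) -> pd.DataFrame:
    """Mean and population standard deviation of every indicator.

    For a 0/1 indicator with proportion-of-ones p the population SD is
    sqrt(p(1-p)); the N (not N-1) denominator is deliberate so the value is
    an exact function of the reported mean.
    """
    p = ds.covariates().mean(axis=0)
    sd = np.sqrt(p * (1.0 - p))
    return pd.DataFrame({"variable": ds.variables, "mean": p.values, "sd": sd.values})
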