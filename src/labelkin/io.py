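"""CSV readers/writers with schema validation, plus the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .celldynamics import CountSeries
from .labelmodel import COMPARTMENTS, EnrichmentSeries

__all__ = [
    "ValidationError",
    "read_enrichment",
    "read_counts",
    "read_qpcr",
    "read_groups",
    "read_trec",
    "enrichment_series",
    "count_series",
    "RunManifest",
]


class ValidationError(ValueError):
    """Input table violates the expected schema; lists offending rows."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _offending(df: pd.DataFrame, mask) -> list[int]:
    return [int(i) for i in df.index[mask]]


def read_enrichment(path) -> pd.DataFrame:
    """Read and validate an enrichment table.

    Columns: individual, compartment, time_days, enrichment,
    scaled_flag. Rejects unknown compartments, negative values,
    duplicated or non-monotone time stamps (per individual and
    compartment), reporting row numbers.
    """
    df = pd.read_csv(path)
    _require_columns(
        df, ["individual", "compartment", "time_days", "enrichment",
             "scaled_flag"], path,
    )
    if df.empty:
        return df
    bad = ~df["compartment"].isin(COMPARTMENTS)
    if bad.any():
        raise ValidationError(
            f"{path}: unknown compartment(s) at rows {_offending(df, bad)}"
        )
    neg = (df["enrichment"] < 0) | (df["time_days"] < 0)
    if neg.any():
        raise ValidationError(f"{path}: negative values at rows {_offending(df, neg)}")
    dup = df.duplicated(subset=["individual", "compartment", "time_days"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicated (individual, compartment, time) at rows "
            f"{_offending(df, dup)}"
        )
    for (ind, comp), grp in df.groupby(["individual", "compartment"]):
        if np.any(np.diff(grp["time_days"].to_numpy()) <= 0):
            raise ValidationError(
                f"{path}: non-monotone times for {ind}/{comp} at rows "
                f"{list(grp.index)}"
            )
    return df


def read_counts(path) -> pd.DataFrame:
    """Read and validate a counts table (long format).

    Columns: individual, time_days, leukocytes_per_ml, subset, and
    subset_count_per_ml and/or fraction. A missing fraction is derived
    from subset count / leukocytes at the same draw.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["individual", "time_days", "leukocytes_per_ml",
                          "subset"], path)
    if "fraction" not in df.columns and "subset_count_per_ml" not in df.columns:
        raise ValidationError(
            f"{path}: need subset_count_per_ml and/or fraction column"
        )
    if df.empty:
        return df
    if "fraction" not in df.columns:
        df["fraction"] = df["subset_count_per_ml"] / df["leukocytes_per_ml"]
    else:
        derived = df["subset_count_per_ml"] / df["leukocytes_per_ml"] \
            if "subset_count_per_ml" in df.columns else np.nan
        df["fraction"] = df["fraction"].fillna(pd.Series(derived, index=df.index))
    bad = (df["leukocytes_per_ml"] <= 0) | (df["time_days"] < 0)
    if bad.any():
        raise ValidationError(f"{path}: invalid values at rows {_offending(df, bad)}")
    frac_bad = (df["fraction"] < 0) | (df["fraction"] > 1)
    if frac_bad.any():
        raise ValidationError(
            f"{path}: fractions outside [0, 1] at rows {_offending(df, frac_bad)}"
        )
    dup = df.duplicated(subset=["individual", "subset", "time_days"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicated (individual, subset, time) at rows "
            f"{_offending(df, dup)}"
        )
    return df


def read_qpcr(path) -> pd.DataFrame:
    """qPCR table: individual, subset, target (signal|coding|albumin),
    ct_mean, control_flag."""
    df = pd.read_csv(path)
    _require_columns(df, ["individual", "subset", "target", "ct_mean",
                          "control_flag"], path)
    if df.empty:
        return df
    bad = ~df["target"].isin({"signal", "coding", "albumin"})
    if bad.any():
        raise ValidationError(f"{path}: unknown target(s) at rows {_offending(df, bad)}")
    ct_bad = (df["ct_mean"] <= 0) | (df["ct_mean"] >= 45)
    if ct_bad.any():
        raise ValidationError(
            f"{path}: Ct outside (0, 45) at rows {_offending(df, ct_bad)}"
        )
    return df


def read_groups(path) -> pd.DataFrame:
    """Cohort membership: individual, group, tau (labeling end, days)."""
    df = pd.read_csv(path)
    _require_columns(df, ["individual", "group", "tau"], path)
    return df


def read_trec(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["individual", "subset", "trec_copies",
                          "cell_equivalents"], path)
    return df


def enrichment_series(df: pd.DataFrame, individual: str,
                      compartment: str) -> EnrichmentSeries:
    """Extract one (individual, compartment) series from a validated table."""
    sel = df[(df["individual"] == individual) & (df["compartment"] == compartment)]
    if sel.empty:
        raise ValidationError(f"no {compartment!r} data for {individual!r}")
    sel = sel.sort_values("time_days")
    return EnrichmentSeries(
        individual=individual,
        compartment=compartment,
        times=sel["time_days"].to_numpy(dtype=float),
        values=sel["enrichment"].to_numpy(dtype=float),
        scaled=bool(sel["scaled_flag"].iloc[0]),
    )


def count_series(df: pd.DataFrame, individual: str) -> CountSeries:
    """Build a CountSeries (leukocytes + per-subset fractions) for one
    individual from the long-format counts table."""
    sel = df[df["individual"] == individual]
    if sel.empty:
        raise ValidationError(f"no count data for {individual!r}")
    wide = sel.pivot_table(index="time_days", columns="subset",
                           values="fraction", aggfunc="first")
    leuk = sel.groupby("time_days")["leukocytes_per_ml"].first()
    times = wide.index.to_numpy(dtype=float)
    return CountSeries(
        individual=individual,
        times=times,
        leukocytes=leuk.loc[wide.index].to_numpy(dtype=float),
        fractions={s: wide[s].to_numpy(dtype=float) for s in wide.columns},
    )


@dataclass
class RunManifest:
    """Provenance of one pipeline run; written even on partial failure."""

    command: str
    seed: int | None = None
    config_hash: str | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: dict[str, str] = field(default_factory=dict)
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    @staticmethod
    def hash_config(obj) -> str:
        return hashlib.sha256(
            json.dumps(obj, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
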