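"""Growth-rate computation from OD750 measurements.

The per-day exponential growth rate between two corrected (blank-subtracted)
optical-density readings is μ = (ln OD₂ − ln OD₁) / (t₂ − t₁). Blank
subtraction happens at ingest; non-positive corrected ODs are clamped to a
small floor and flagged rather than silently dropped, since plate blanks
occasionally exceed dilute samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

log = logging.getLogger("subtelo")

OD_FLOOR = 1e-6


@dataclass
class GrowthMeasurement:
    sample_id: str
    treatment: str
    od_1: float  # corrected OD750 at t_1
    od_2: float
    t_1: float  # days
    t_2: float
    replicate: int = 0
    flags: list[str] = field(default_factory=list)


def growth_rate(m: GrowthMeasurement) -> float:
    """Per-day growth rate μ = (ln OD₂ − ln OD₁)/(t₂ − t₁)."""
    if m.t_2 <= m.t_1:
        raise ValueError(f"t_2 must exceed t_1 for {m.sample_id}")
    if m.od_1 <= 0 or m.od_2 <= 0:
        raise ValueError(f"non-positive corrected OD for {m.sample_id}; log undefined")
    return (math.log(m.od_2) - math.log(m.od_1)) / (m.t_2 - m.t_1)


def summarize_growth(measurements: Sequence[GrowthMeasurement]) -> pd.DataFrame:
    """Mean μ ± standard error (SD/√n) per treatment group.

    Single-replicate groups get a missing SE and a flag.
    """
    if not measurements:
        raise ValueError("no measurements")
    rows = [
        {"treatment": m.treatment, "mu": growth_rate(m)} for m in measurements
    ]
    df = pd.DataFrame(rows)
    out = []
    for trt, grp in df.groupby("treatment", sort=True):
        n = len(grp)
        mean = grp["mu"].mean()
        se: Optional[float] = None
        flag = ""
        if n > 1:
            se = grp["mu"].std(ddof=1) / math.sqrt(n)
        else:
            flag = "single_replicate"
            log.warning("treatment %r has a single replicate; SE undefined", trt)
        out.append({"treatment": trt, "n": n, "mean_mu": mean, "se": se, "flag": flag})
    return pd.DataFrame(out).set_index("treatment")


def read_od_table(path: str | Path) -> list[GrowthMeasurement]:
    """Read a long-format OD table into paired first/last-day measurements.

    Expected TSV columns: sample, treatment, replicate, day, od, blank.
    For every (sample, treatment, replicate) series the earliest and latest
    day form the measurement pair; corrected OD = od − blank, clamped to a
    positive floor (flagged) when the blank exceeds the sample.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "treatment", "replicate", "day", "od", "blank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"OD table missing columns: {sorted(missing)}")
    out: list[GrowthMeasurement] = []
    for (sample, trt, rep), grp in df.groupby(
        ["sample", "treatment", "replicate"], sort=True
    ):
        grp = grp.sort_values("day")
        first, last = grp.iloc[0], grp.iloc[-1]
        if first["day"] == last["day"]:
            raise ValueError(f"series {sample}/{trt}/rep{rep} has a single time point")
        flags = []
        ods = []
        for row in (first, last):
            corrected = row["od"] - row["blank"]
            if corrected <= 0:
                flags.append(f"clamped_day_{row['day']}")
                corrected = OD_FLOOR
            ods.append(corrected)
        out.append(
            GrowthMeasurement(
                sample_id=str(sample),
                treatment=str(trt),
                od_1=ods[0],
                od_2=ods[1],
                t_1=float(first["day"]),
                t_2=float(last["day"]),
                replicate=int(rep),
                flags=flags,
            )
        )
    return out
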