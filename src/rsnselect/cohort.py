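"""Cohort descriptive statistics for a tinnitus patient table.

A bundled reference table (``data/tinnitus_cohort.tsv``) holds the 13-patient
chronic-tinnitus cohort used throughout: per patient sex, age, affected ear,
tinnitus duration (possibly only a lower bound, written ">x"), best-matched
tinnitus frequency, THI and TQ severity scores, and in-scanner loudness
rating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PatientRecord:
    id: str
    sex: str
    age_years: float
    ear: str
    duration_years: float
    frequency_hz: float
    thi: int
    tq: int
    loudness_0_10: float
    duration_is_lower_bound: bool = False

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be M or F")
        if not 0 <= self.thi <= 100:
            raise ValueError("THI must lie in [0, 100]")
        if self.tq < 0:
            raise ValueError("TQ must be >= 0")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")


@dataclass
class CohortSummary:
    n: int
    mean_age: float
    sd_age: float
    mean_duration: float
    sd_duration: float
    mean_freq: float
    sd_freq: float
    sd_freq_as_printed: int        # sample SD truncated to integer
    thi_range: tuple
    tq_range: tuple
    freq_range: tuple
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def text_block(self) -> str:
        return (
            f"n = {self.n} patients\n"
            f"age: mean {self.mean_age:.1f} y (SD {self.sd_age:.1f})\n"
            f"tinnitus duration: mean {self.mean_duration:.1f} y"
            f" (SD {self.sd_duration:.1f})\n"
            f"tinnitus frequency: mean {self.mean_freq:.0f} Hz"
            f" (SD {self.sd_freq:.1f}; as printed {self.sd_freq_as_printed}),"
            f" range {self.freq_range[0]:.0f}-{self.freq_range[1]:.0f} Hz\n"
            f"THI range {self.thi_range[0]}-{self.thi_range[1]},"
            f" TQ range {self.tq_range[0]}-{self.tq_range[1]}\n"
        )


def _parse_duration(value):
    s = str(value).strip()
    if s.startswith(">"):
        return float(s[1:]), True
    return float(s), False


def load_records(path=None) -> list:
    """Read patient records from a TSV (default: the bundled cohort)."""
    if path is None:
        with resources.files("rsnselect.data").joinpath(
                "tinnitus_cohort.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(Path(path), sep="\t")
    records = []
    for _, r in df.iterrows():
        dur, lb = _parse_duration(r["duration_years"])
        records.append(PatientRecord(
            id=str(r["id"]), sex=str(r["sex"]), age_years=float(r["age_years"]),
            ear=str(r["ear"]), duration_years=dur,
            frequency_hz=float(r["frequency_hz"]), thi=int(r["thi"]),
            tq=int(r["tq"]), loudness_0_10=float(r["loudness_0_10"]),
            duration_is_lower_bound=lb))
    return records


def summarize(records) -> CohortSummary:
    """Means, sample SDs (n-1 denominator) and ranges of the cohort columns;
    lower-bound durations (">x") enter as x."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    age = np.array([r.age_years for r in records], dtype=float)
    dur = np.array([r.duration_years for r in records], dtype=float)
    freq = np.array([r.frequency_hz for r in records], dtype=float)
    thi = np.array([r.thi for r in records])
    tq = np.array([r.tq for r in records])
    sd_freq = freq.std(ddof=1)
    return CohortSummary(
        n=len(records),
        mean_age=float(age.mean()), sd_age=float(age.std(ddof=1)),
        mean_duration=float(dur.mean()), sd_duration=float(dur.std(ddof=1)),
        mean_freq=float(freq.mean()), sd_freq=float(sd_freq),
        sd_freq_as_printed=int(sd_freq),
        thi_range=(int(thi.min()), int(thi.max())),
        tq_range=(int(tq.min()), int(tq.max())),
        freq_range=(float(freq.min()), float(freq.max())),
        provenance={
            "lower_bound_durations_coerced": sorted(
                r.id for r in records if r.duration_is_lower_bound),
            "sd_convention": "sample (n-1); as-printed frequency SD is the "
                             "sample SD truncated to integer",
        },
    )
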