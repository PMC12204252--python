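"""Core data containers for the biosignature pipeline.

The pipeline's unit of analysis is a baseline-corrected time-frequency
representation (TFR): a ``T x F`` grid of oscillatory power in decibels for
one subject x region-of-interest (ROI) x stimulus condition. A cohort is a
collection of such matrices plus a per-subject covariate / phenotype /
outcome table.

Conditions are (site, intensity) pairs with site in {affected, unaffected}
and intensity in {low, high}; this harmonizes the back/hand stimulation of a
low-back-pain protocol with the abdomen/forearm stimulation of a
pancreatitis protocol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Stimulation sites and intensities in harmonized (cross-cohort) coding.
SITES = ("affected", "unaffected")
INTENSITIES = ("low", "high")

#: The four stimulus conditions modeled jointly.
DEFAULT_CONDITIONS = tuple(
    (site, intensity) for site in SITES for intensity in INTENSITIES
)

#: Source-localized regions of interest.
ROIS = ("mOFC-left", "mOFC-right", "dlPFC-left", "dlPFC-right")

Condition = tuple[str, str]


def condition_key(condition: Condition) -> str:
    """Canonical string key, e.g. ``('affected', 'high') -> 'affected_high'``."""
    site, intensity = condition
    if site not in SITES or intensity not in INTENSITIES:
        raise ValueError(f"unknown condition {condition!r}")
    return f"{site}_{intensity}"


def parse_condition(key: str) -> Condition:
    site, intensity = key.split("_")
    if site not in SITES or intensity not in INTENSITIES:
        raise ValueError(f"unknown condition key {key!r}")
    return site, intensity


@dataclass(frozen=True)
class TimeFreqGrid:
    """Analysis grid: post-stimulus time bins x integer frequencies.

    Parameters
    ----------
    times : ndarray, shape (T,)
        Bin centers in seconds, strictly increasing. The default spans the
        0 to 0.7 s post-stimulus analysis window with T = 27 points
        (~27 ms spacing); the -0.3 to 0 s pre-stimulus segment is used for
        baseline correction upstream and is not part of the analysis grid.
    freqs : ndarray, shape (F,)
        Frequencies in Hz, strictly increasing; default 1..45 Hz.
    """

    times: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        for name, arr in (("times", self.times), ("freqs", self.freqs)):
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError(f"{name} must be a 1-D array with >= 2 points")
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def default(cls, n_times: int = 27, t_max: float = 0.7,
                f_min: int = 1, f_max: int = 45) -> "TimeFreqGrid":
        return cls(times=np.linspace(0.0, t_max, n_times),
                   freqs=np.arange(f_min, f_max + 1, dtype=float))

    @property
    def shape(self) -> tuple[int, int]:
        return self.times.size, self.freqs.size

    @property
    def n_cells(self) -> int:
        return self.times.size * self.freqs.size

    def __eq__(self, other) -> bool:
        return (isinstance(other, TimeFreqGrid)
                and np.array_equal(self.times, other.times)
                and np.array_equal(self.freqs, other.freqs))

    def __hash__(self):
        return hash((self.times.tobytes(), self.freqs.tobytes()))


@dataclass
class TFRMatrix:
    """Baseline-corrected dB power for one subject x ROI x condition."""

    grid: TimeFreqGrid
    values: np.ndarray  # (T, F) dB
    subject: str = ""
    roi: str = ""
    condition: Condition | None = None
    n_trials: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFR values must be finite")


@dataclass
class SubjectRecord:
    """One participant: covariates, labels and their TFR set.

    ``tfrs`` maps ``(roi, condition_key)`` to a ``TFRMatrix``.
    """

    subject: str
    age: float
    sex: int  # 0 = female, 1 = male
    pain_intensity: float
    phenotype: str
    cohort: str = "clbp"
    tfrs: dict[tuple[str, str], TFRMatrix] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def tfr(self, roi: str, condition: Condition) -> TFRMatrix:
        key = (roi, condition_key(condition))
        if key not in self.tfrs:
            raise KeyError(
                f"subject {self.subject}: no TFR for ROI {roi!r}, "
                f"condition {condition_key(condition)!r}")
        return self.tfrs[key]


@dataclass
class CohortDataset:
    """A cohort of subjects plus a tabular covariate/phenotype/outcome view."""

    grid: TimeFreqGrid
    subjects: list[SubjectRecord]
    name: str = "cohort"

    def __post_init__(self):
        ids = [s.subject for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in cohort")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def rois(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            for roi, _ in s.tfrs:
                seen.setdefault(roi, None)
        return list(seen)

    @property
    def conditions(self) -> list[Condition]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            for _, ck in s.tfrs:
                seen.setdefault(ck, None)
        return [parse_condition(k) for k in seen]

    def covariate_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = dict(subject=s.subject, age=s.age, sex=s.sex,
                       pain_intensity=s.pain_intensity, phenotype=s.phenotype,
                       cohort=s.cohort)
            row.update(s.extra)
            rows.append(row)
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    # Persistence: one HDF5 array per subject x ROI x condition, and a CSV
    # covariate table next to it.
    # ------------------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        h5_path = directory / "cohort.h5"
        with h5py.File(h5_path, "w") as f:
            f.attrs["name"] = self.name
            f.create_dataset("grid/times", data=self.grid.times)
            f.create_dataset("grid/freqs", data=self.grid.freqs)
            for s in self.subjects:
                grp = f.create_group(f"subjects/{s.subject}")
                for (roi, ck), tfr in s.tfrs.items():
                    d = grp.create_dataset(f"{roi}/{ck}", data=tfr.values)
                    d.attrs["n_trials"] = tfr.n_trials
        self.covariate_table().to_csv(directory / "subjects.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CohortDataset":
        directory = Path(directory)
        table = pd.read_csv(directory / "subjects.csv")
        core_cols = {"subject", "age", "sex", "pain_intensity", "phenotype",
                     "cohort"}
        subjects: list[SubjectRecord] = []
        with h5py.File(directory / "cohort.h5", "r") as f:
            grid = TimeFreqGrid(times=f["grid/times"][:], freqs=f["grid/freqs"][:])
            for _, row in table.iterrows():
                sid = str(row["subject"])
                extra = {k: row[k] for k in table.columns if k not in core_cols}
                rec = SubjectRecord(
                    subject=sid, age=float(row["age"]), sex=int(row["sex"]),
                    pain_intensity=float(row["pain_intensity"]),
                    phenotype=str(row["phenotype"]), cohort=str(row["cohort"]),
                    extra=extra)
                sgrp = f[f"subjects/{sid}"]
                for roi in sgrp:
                    for ck in sgrp[roi]:
                        d = sgrp[roi][ck]
                        rec.tfrs[(roi, ck)] = TFRMatrix(
                            grid=grid, values=d[:], subject=sid, roi=roi,
                            condition=parse_condition(ck),
                            n_trials=int(d.attrs.get("n_trials", 1)))
                subjects.append(rec)
            name = str(f.attrs.get("name", "cohort"))
        return cls(grid=grid, subjects=subjects, name=name)


def asdict_shallow(obj) -> dict:
    """Shallow dataclass -> dict (no recursion into arrays)."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
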