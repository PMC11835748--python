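"""Cohort I/O, scene masks and ROI time-series preprocessing.

Input conventions
-----------------
* ROI time series: one CSV/TSV per subject, header row of region ids, one row
  per fMRI volume.  A cohort manifest (YAML) maps subject id -> file path and
  group label.
* Facial data: the OpenFace CSV dialect with per-frame ``AU.._r`` intensity
  columns plus ``success``/``confidence`` bookkeeping columns.
* Scene annotations: CSV with columns ``onset_s``, ``duration_s``, ``valence``,
  ``description`` giving movie periods in absolute movie seconds.

The preprocessing applied here is the last step of a standard naturalistic
fMRI pipeline: trim the lead-in/lead-out volumes during which the movie was
not playing (defaults: first 10 and last 35 volumes), then demean and scale
each subject x region trace to unit standard deviation.  Spatial
preprocessing, filtering and confound regression are assumed to have happened
upstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortSeries",
    "SceneTable",
    "EpochMask",
    "DataIOError",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_manifest",
    "preprocess_series",
    "read_scene_table",
    "scenes_to_mask",
    "read_openface_csv",
]

#: Default repetition time of the study's EPI sequence, in seconds.
DEFAULT_TR = 0.81

#: Volumes dropped before / after the movie per the acquisition protocol.
DEFAULT_TRIM_START = 10
DEFAULT_TRIM_END = 35

#: The 16 emotion-relevant action units retained for analysis.  AU45 (blink)
#: is parsed when present but never enters the analysis pipeline.
ANALYSIS_AUS = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26",
)
EXCLUDED_AUS = ("AU45",)


class DataIOError(ValueError):
    """Raised for malformed cohort inputs (parse errors, label mismatches...)."""


@dataclasses.dataclass
class CohortSeries:
    """Multi-subject ROI time series.

    Attributes
    ----------
    data : ndarray, shape (n_subjects, n_volumes, n_regions)
        Real-valued fMRI signal; all subjects share the volume count and the
        region set/order.
    tr_seconds : float
        Repetition time between volumes.
    subject_ids, region_ids : list of str
        Ordered unique identifiers.
    group_labels : list of str
        One of ``{"A", "B"}`` per subject (A = melancholic, B =
        non-melancholic in the study's usage).
    """

    data: np.ndarray
    tr_seconds: float
    subject_ids: list[str]
    region_ids: list[str]
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataIOError("data must be (subjects, volumes, regions)")
        n_subj = self.data.shape[0]
        if not (len(self.subject_ids) == len(self.group_labels) == n_subj):
            raise DataIOError("subject_ids/group_labels length mismatch")
        if len(set(self.subject_ids)) != n_subj:
            raise DataIOError("subject ids must be unique")
        if self.data.shape[2] != len(self.region_ids):
            raise DataIOError("region_ids length mismatch")
        if self.tr_seconds <= 0:
            raise DataIOError("tr_seconds must be positive")
        bad = set(self.group_labels) - {"A", "B"}
        if bad:
            raise DataIOError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def n_regions(self) -> int:
        return self.data.shape[2]

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.group_labels) == group)


@dataclasses.dataclass
class SceneTable:
    """Movie scene annotations (onset/duration in movie seconds)."""

    frame: pd.DataFrame  # columns onset_s, duration_s, valence, description

    def __post_init__(self) -> None:
        required = {"onset_s", "duration_s"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataIOError(f"scene table missing columns: {sorted(missing)}")
        df = self.frame.sort_values("onset_s").reset_index(drop=True)
        if (df["duration_s"] <= 0).any():
            raise DataIOError("scene durations must be positive")
        if (df["onset_s"] < 0).any():
            raise DataIOError("scene onsets must be non-negative")
        ends = df["onset_s"] + df["duration_s"]
        if (df["onset_s"].values[1:] < ends.values[:-1]).any():
            raise DataIOError("scene intervals overlap after sorting by onset")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, valence: str) -> "SceneTable":
        """Subset to scenes with the given valence tag (e.g. 'positive')."""
        if "valence" not in self.frame.columns:
            raise DataIOError("scene table has no valence column")
        return SceneTable(self.frame[self.frame["valence"] == valence].copy())


@dataclasses.dataclass
class EpochMask:
    """Boolean per retained volume; True marks volumes inside scene epochs."""

    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 1:
            raise DataIOError("mask must be 1-D")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_true(self) -> int:
        return int(self.values.sum())


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    for col in non_numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise DataIOError(
                f"non-numeric cell in {path.name}: row {row}, column '{col}' "
                f"(value {df[col].iloc[row]!r})"
            )
        df[col] = coerced
    if df.isna().any().any():
        col = df.columns[df.isna().any().values][0]
        row = int(df.index[df[col].isna()][0])
        raise DataIOError(f"missing value in {path.name}: row {row}, column '{col}'")
    return df


def read_roi_timeseries(
    paths: Mapping[str, str | Path],
    labels: Mapping[str, str],
    tr_seconds: float = DEFAULT_TR,
) -> CohortSeries:
    """Read per-subject ROI tables into a :class:`CohortSeries`.

    Parameters
    ----------
    paths : mapping subject id -> file path
    labels : mapping subject id -> group label ("A" or "B")

    Region columns are harmonised to the first subject's ordering; a subject
    whose region set differs is rejected.
    """
    if not paths:
        raise DataIOError("no subject files given")
    missing = set(paths) - set(labels)
    if missing:
        raise DataIOError(f"missing group label for subjects: {sorted(missing)}")

    subject_ids = list(paths)
    region_ids: list[str] | None = None
    mats = []
    for sid in subject_ids:
        df = _read_table(paths[sid])
        if region_ids is None:
            region_ids = list(df.columns)
        else:
            if set(df.columns) != set(region_ids):
                raise DataIOError(
                    f"subject {sid}: region set differs from cohort "
                    f"({sorted(set(df.columns) ^ set(region_ids))})"
                )
            df = df[region_ids]
        mats.append(df.to_numpy(dtype=float))
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise DataIOError(f"subjects differ in volume count: {sorted(shapes)}")
    return CohortSeries(
        data=np.stack(mats),
        tr_seconds=tr_seconds,
        subject_ids=subject_ids,
        region_ids=list(region_ids or []),
        group_labels=[labels[s] for s in subject_ids],
    )


def write_roi_timeseries(cohort: CohortSeries, out_dir: str | Path) -> Path:
    """Write one CSV per subject plus a YAML manifest; returns manifest path.

    Values round-trip bit-identically through :func:`read_roi_timeseries`
    (full repr precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tr_seconds": float(cohort.tr_seconds), "subjects": {}}
    for i, sid in enumerate(cohort.subject_ids):
        fname = f"{sid}.csv"
        pd.DataFrame(cohort.data[i], columns=cohort.region_ids).to_csv(
            out_dir / fname, index=False, float_format="%.17g"
        )
        manifest["subjects"][str(sid)] = {
            "file": fname,
            "group": str(cohort.group_labels[i]),
        }
    mpath = out_dir / "cohort.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return mpath


def read_manifest(manifest_path: str | Path) -> CohortSeries:
    """Read a cohort via its YAML manifest (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    subjects = manifest["subjects"]
    paths = {sid: base / entry["file"] for sid, entry in subjects.items()}
    labels = {sid: entry["group"] for sid, entry in subjects.items()}
    return read_roi_timeseries(
        paths, labels, tr_seconds=float(manifest.get("tr_seconds", DEFAULT_TR))
    )


def preprocess_series(
    raw: CohortSeries,
    trim_start: int = DEFAULT_TRIM_START,
    trim_end: int = DEFAULT_TRIM_END,
) -> CohortSeries:
    """Trim lead-in/lead-out volumes, then z-score each subject x region trace.

    Demeaning and scaling are per trace over the retained volumes (the
    HMM-toolbox convention).  Raises on a constant trace, which cannot be
    scaled.
    """
    if trim_start < 0 or trim_end < 0:
        raise DataIOError("trim counts must be non-negative")
    T = raw.n_volumes
    if T <= trim_start + trim_end:
        raise DataIOError(
            f"cannot trim {trim_start}+{trim_end} volumes from series of length {T}"
        )
    data = raw.data[:, trim_start : T - trim_end if trim_end else T, :]
    sd = data.std(axis=1, ddof=0)
    if np.any(sd == 0):
        s, r = map(int, np.argwhere(sd == 0)[0])
        raise DataIOError(
            f"degenerate (constant) signal for subject "
            f"{raw.subject_ids[s]!r}, region {raw.region_ids[r]!r}"
        )
    data = (data - data.mean(axis=1, keepdims=True)) / sd[:, None, :]
    return CohortSeries(
        data=data,
        tr_seconds=raw.tr_seconds,
        subject_ids=list(raw.subject_ids),
        region_ids=list(raw.region_ids),
        group_labels=list(raw.group_labels),
    )


def read_scene_table(path: str | Path) -> SceneTable:
    return SceneTable(pd.read_csv(path))


def scenes_to_mask(
    scenes: SceneTable,
    tr_seconds: float,
    n_volumes: int,
    trim_start: int = DEFAULT_TRIM_START,
    movie_length_s: float | None = None,
) -> EpochMask:
    """Build a boolean volume mask from scene annotations.

    Post-trim volume ``v`` is True iff its acquisition onset
    ``(v + trim_start) * tr_seconds`` (absolute movie time; the movie starts
    at volume ``trim_start``) falls in some half-open interval
    ``[onset, onset + duration)``.  Half-open intervals mean a boundary
    instant belongs to the later scene, so adjacent scenes never double-count
    a volume.
    """
    if tr_seconds <= 0:
        raise DataIOError("tr_seconds must be positive")
    if movie_length_s is None:
        movie_length_s = (n_volumes + trim_start) * tr_seconds
    onsets = scenes.frame["onset_s"].to_numpy(dtype=float) if len(scenes) else np.empty(0)
    durations = scenes.frame["duration_s"].to_numpy(dtype=float) if len(scenes) else np.empty(0)
    if len(scenes) and np.any(onsets + durations > movie_length_s + 1e-9):
        bad = int(np.argmax(onsets + durations > movie_length_s + 1e-9))
        raise DataIOError(
            f"scene {bad} (onset {onsets[bad]} s, duration {durations[bad]} s) "
            f"extends beyond the movie end ({movie_length_s:.2f} s)"
        )
    t = (np.arange(n_volumes) + trim_start) * tr_seconds
    mask = np.zeros(n_volumes, dtype=bool)
    for onset, dur in zip(onsets, durations):
        mask |= (t >= onset) & (t < onset + dur)
    return EpochMask(values=mask, tr_seconds=tr_seconds)


def read_openface_csv(path: str | Path) -> pd.DataFrame:
    """Read one subject's OpenFace AU-intensity CSV.

    Returns a frame indexed like the input with one column per analysis AU
    (the 16 emotion-relevant AUs) plus, when present, an ``AU45`` column kept
    only for completeness (blinks are excluded from all analyses downstream).
    Frames with ``success == 0`` are set to NaN (missing), never zero.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    missing = [au for au in ANALYSIS_AUS if f"{au}_r" not in df.columns]
    if missing:
        raise DataIOError(f"OpenFace file {Path(path).name} missing AU columns: {missing}")
    cols = [f"{au}_r" for au in ANALYSIS_AUS]
    out = df[cols].copy()
    out.columns = list(ANALYSIS_AUS)
    if "AU45_r" in df.columns:
        out["AU45"] = df["AU45_r"]
    if "success" in df.columns:
        failed = df["success"].to_numpy() == 0
        out.loc[failed, :] = np.nan
    out.attrs["excluded_aus"] = list(EXCLUDED_AUS)
    out.attrs["analysis_aus"] = list(ANALYSIS_AUS)
    return out
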