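"""On-disk formats: subject CSV, per-subject time-series TSVs, NIfTI images."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import RegionTimeSeries, SubjectRecord

SUBJECT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "waist_cm",
    "hip_cm",
    "bmi",
    "wmh_total_mm3",
    "wmh_deep_mm3",
    "wmh_peri_mm3",
]

# full double precision so downstream stages reproduce in-memory results exactly
FLOAT_FORMAT = "%.17g"


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "age": s.age,
            "sex": s.sex,
            "waist_cm": s.waist,
            "hip_cm": s.hip,
            "bmi": s.bmi,
            "wmh_total_mm3": s.wmh_total,
            "wmh_deep_mm3": s.wmh_deep,
            "wmh_peri_mm3": s.wmh_peri,
        }
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def write_subjects(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    frame = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS) - {"bmi"} - set(frame.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        bmi = getattr(row, "bmi", None)
        out.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                age=float(row.age),
                sex=str(row.sex),
                waist=float(row.waist_cm),
                hip=float(row.hip_cm),
                wmh_total=float(row.wmh_total_mm3),
                wmh_deep=float(row.wmh_deep_mm3),
                wmh_peri=float(row.wmh_peri_mm3),
                bmi=None if bmi is None or pd.isna(bmi) else float(bmi),
            )
        )
    return out


def write_timeseries(ts: RegionTimeSeries, path: str | Path) -> None:
    """T rows x R columns, tab-separated, header = region ids."""
    frame = pd.DataFrame(ts.data, columns=[str(r) for r in ts.region_ids])
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_timeseries(path: str | Path, subject_id: str = "") -> RegionTimeSeries:
    frame = pd.read_csv(path, sep="\t")
    region_ids = [int(c) for c in frame.columns]
    return RegionTimeSeries(
        subject_id=subject_id or Path(path).stem.replace("_ts", ""),
        data=frame.to_numpy(dtype=float),
        region_ids=region_ids,
    )


def write_timeseries_bundle(
    series: Sequence[RegionTimeSeries], out_dir: str | Path
) -> Path:
    """One TSV per subject plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in series:
        name = f"{ts.subject_id}_ts.tsv"
        write_timeseries(ts, out_dir / name)
        rows.append(
            {
                "subject_id": ts.subject_id,
                "path": name,
                "n_timepoints": ts.n_timepoints,
                "n_regions": ts.n_regions,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_timeseries_bundle(manifest: str | Path) -> list[RegionTimeSeries]:
    manifest = Path(manifest)
    frame = pd.read_csv(manifest, sep="\t")
    return [
        read_timeseries(manifest.parent / row.path, subject_id=str(row.subject_id))
        for row in frame.itertuples(index=False)
    ]


def write_nifti(data: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data), affine=np.eye(4))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_graph(weights: np.ndarray, region_ids: Sequence[int],
                path: str | Path) -> None:
    """Square CSV with region ids as both header and index."""
    labels = [str(r) for r in region_ids]
    pd.DataFrame(weights, index=labels, columns=labels).to_csv(
        path, float_format=FLOAT_FORMAT
    )
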