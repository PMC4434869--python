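"""Tables, images and metadata sidecars.

All tables are comma-separated UTF-8 CSV with '.' decimals; images are
multi-page TIFF (one page per channel) with a JSON sidecar recording the
channel order, seed and config hash so a re-run is byte-reproducible and
self-describing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .records import CellRecord, CtcemtError, PatientRecord


class SchemaError(CtcemtError):
    pass


CELL_COLUMNS = [
    "sample_id",
    "cell_id",
    "area",
    "ctcf_keratin",
    "ctcf_vimentin",
    "ctcf_cd45",
    "ctcf_dapi",
    "mean_keratin",
    "mean_vimentin",
    "mean_cd45",
    "mean_dapi",
    "is_dapi_positive",
    "is_cd45_negative",
    "is_ctc",
]

PATIENT_COLUMNS = [
    "patient_id",
    "er_status",
    "pr_status",
    "her2_status",
    "triple_negative",
    "os_months",
    "os_event",
]

CTC_VALUE_COLUMNS = ["patient_id", "ctc_index", "keratin"]

BEAD_COLUMNS = ["pmt_voltage", "nominal_level", "replicate", "measured"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def cells_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "cell_id": r.cell_id, "area": r.area}
        for m, v in r.ctcf.items():
            row[f"ctcf_{m}"] = v
            row[f"mean_{m}"] = v / r.area
        row["is_dapi_positive"] = r.is_dapi_positive
        row["is_cd45_negative"] = r.is_cd45_negative
        row["is_ctc"] = r.is_ctc
        rows.append(row)
    df = pd.DataFrame(rows)
    ordered = [c for c in CELL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in CELL_COLUMNS]
    return df[ordered + extra]


def frame_to_cells(df: pd.DataFrame) -> list[CellRecord]:
    _check_columns(df, ["sample_id", "cell_id", "area"], "cell table")
    markers = [c.removeprefix("ctcf_") for c in df.columns if c.startswith("ctcf_")]
    if not markers:
        raise SchemaError("cell table: no ctcf_* columns")
    records = []
    for _, row in df.iterrows():
        flags = {}
        for col in ("is_dapi_positive", "is_cd45_negative"):
            flags[col] = None if col not in df.columns or pd.isna(row[col]) else bool(row[col])
        records.append(
            CellRecord(
                cell_id=str(row["cell_id"]),
                sample_id=str(row["sample_id"]),
                area=float(row["area"]),
                ctcf={m: float(row[f"ctcf_{m}"]) for m in markers},
                is_dapi_positive=flags["is_dapi_positive"],
                is_cd45_negative=flags["is_cd45_negative"],
            )
        )
    return records


def write_cells_csv(records: list[CellRecord], path: str | Path) -> None:
    cells_to_frame(records).to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> list[CellRecord]:
    return frame_to_cells(pd.read_csv(path))


def read_beads_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["pmt_voltage", "nominal_level", "measured"], "bead series")
    return df


def patients_to_frames(
    patients: list[PatientRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical table (one row per patient) + long per-CTC keratin table."""
    clinical = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "er_status": p.er_status,
                "pr_status": p.pr_status,
                "her2_status": p.her2_status,
                "triple_negative": p.triple_negative,
                "os_months": p.os_months,
                "os_event": p.os_event,
            }
            for p in patients
        ]
    )
    ctcs = pd.DataFrame(
        [
            {"patient_id": p.patient_id, "ctc_index": i, "keratin": v}
            for p in patients
            for i, v in enumerate(p.ctc_keratin_values)
        ]
    )
    return clinical, ctcs


def frames_to_patients(
    clinical: pd.DataFrame, ctcs: pd.DataFrame
) -> list[PatientRecord]:
    _check_columns(clinical, PATIENT_COLUMNS, "patient table")
    _check_columns(ctcs, ["patient_id", "keratin"], "CTC keratin table")
    grouped = ctcs.groupby("patient_id")["keratin"].apply(list)
    patients = []
    for _, row in clinical.iterrows():
        pid = str(row["patient_id"])
        if pid not in grouped.index:
            raise SchemaError(f"patient {pid}: no CTC keratin values")
        patients.append(
            PatientRecord(
                patient_id=pid,
                ctc_keratin_values=[float(v) for v in grouped[pid]],
                er_status=str(row["er_status"]),
                pr_status=str(row["pr_status"]),
                her2_status=str(row["her2_status"]),
                triple_negative=bool(row["triple_negative"]),
                os_months=float(row["os_months"]),
                os_event=bool(row["os_event"]),
            )
        )
    return patients


def write_patients_csv(
    patients: list[PatientRecord], clinical_path: str | Path, ctc_path: str | Path
) -> None:
    clinical, ctcs = patients_to_frames(patients)
    clinical.to_csv(clinical_path, index=False)
    ctcs.to_csv(ctc_path, index=False)


def read_patients_csv(
    clinical_path: str | Path, ctc_path: str | Path
) -> list[PatientRecord]:
    return frames_to_patients(pd.read_csv(clinical_path), pd.read_csv(ctc_path))


# ---------------------------------------------------------------------------
# Images and sidecars
# ---------------------------------------------------------------------------


def config_hash(config) -> str:
    if is_dataclass(config) and not isinstance(config, type):
        payload = asdict(config)
    else:
        payload = config
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_sidecar(path: str | Path, **metadata) -> None:
    """JSON metadata sidecar at ``<path>.meta.json`` (no timestamps: re-runs
    must be byte-identical)."""
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(metadata, sort_keys=True, indent=1, default=str))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(str(path) + ".meta.json").read_text())


def write_image_tiff(
    image: np.ndarray,
    path: str | Path,
    channel_names: tuple[str, ...],
    **metadata,
) -> None:
    """Multi-page 16-bit TIFF, one page per channel, channel order in sidecar."""
    data = np.round(image).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    write_sidecar(path, channel_names=list(channel_names), **metadata)


def read_image_tiff(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    image = tifffile.imread(path).astype(float)
    meta = read_sidecar(path)
    return image, tuple(meta["channel_names"])
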