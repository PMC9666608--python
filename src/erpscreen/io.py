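"""Optional ingestion of real multichannel EEG from EDF files.

Requires the ``edf`` extra (MNE).  Each requested channel of each file
becomes one :class:`~erpscreen.synthetic.ERPRecord`, joined to a subject
metadata table carrying the class label and demographics.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import ERPRecord

__all__ = ["read_edf_records"]


def read_edf_records(
    edf_path: str | Path,
    subject_meta: dict,
    modality: str,
    channel_map: dict[str, str] | None = None,
) -> list[ERPRecord]:
    """Read one EDF file into per-electrode records.

    ``channel_map`` maps EDF channel labels to electrode names (Fz, Cz,
    Pz); unmapped channels are skipped.  ``subject_meta`` must provide
    subject_id, group_label, gender and first_child.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF ingestion requires MNE; install the 'edf' extra"
        ) from exc
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    channel_map = channel_map or {ch: ch for ch in raw.ch_names}
    records = []
    for ch_name, electrode in channel_map.items():
        if ch_name not in raw.ch_names:
            continue
        data = raw.get_data(picks=[ch_name])[0] * 1e6  # volts -> microvolts
        records.append(
            ERPRecord(
                subject_id=subject_meta["subject_id"],
                group_label=subject_meta["group_label"],
                modality=modality,
                electrode=electrode,
                sampling_rate=float(raw.info["sfreq"]),
                signal=data,
                gender=subject_meta.get("gender", "F"),
                first_child=bool(subject_meta.get("first_child", False)),
            )
        )
    return records


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Subject metadata CSV: subject_id, group, gender, first_child."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "gender", "first_child"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns {sorted(missing)}")
    return df
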