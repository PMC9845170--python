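"""Reading and writing signal containers, event tables and calibration tables.

Raw sessions live in HDF5 containers with one ``samples`` dataset and the
attributes ``sample_rate_hz``, ``start_time_utc``, ``acquisition_range_mv``
and ``label``. Samples may be stored either as float64 millivolts or as
raw digitiser codes (integer dtype); codes are converted on read as
``mv = code * acquisition_range_mv / 2**16``, matching a 16-bit digitiser
spanning the acquisition range.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .records import SignalRecord

__all__ = [
    "SignalFormatError",
    "CalibrationSample",
    "read_signal",
    "write_signal",
    "read_wav",
    "read_calibration_table",
    "write_calibration_table",
    "EVENT_TABLE_COLUMNS",
    "read_event_table",
    "write_event_table",
]

DIGITIZER_BITS = 16


class SignalFormatError(ValueError):
    """Raised when a signal container is missing required metadata."""


_REQUIRED_ATTRS = ("sample_rate_hz", "start_time_utc")


def read_signal(path: str | Path) -> SignalRecord:
    """Read a session container written by :func:`write_signal`.

    Integer-coded datasets are converted to millivolts using the stored
    acquisition range; float datasets are taken to already be in mV.
    """
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if "samples" not in fh:
            raise SignalFormatError(f"{path}: missing 'samples' dataset")
        dset = fh["samples"]
        for attr in _REQUIRED_ATTRS:
            if attr not in dset.attrs:
                raise SignalFormatError(f"{path}: missing attribute '{attr}'")
        rng = float(dset.attrs.get("acquisition_range_mv", 5000.0))
        raw = dset[...]
        if np.issubdtype(raw.dtype, np.integer):
            samples = raw.astype(np.float64) * (rng / 2**DIGITIZER_BITS)
        else:
            samples = raw.astype(np.float64)
        start = datetime.fromisoformat(str(dset.attrs["start_time_utc"]))
        return SignalRecord(
            samples=samples,
            sample_rate=float(dset.attrs["sample_rate_hz"]),
            start_time=start,
            label=str(dset.attrs.get("label", "")),
            acquisition_range_mv=rng,
        )


def write_signal(
    record: SignalRecord,
    path: str | Path,
    *,
    overwrite: bool = False,
    as_codes: bool = False,
) -> Path:
    """Write a :class:`SignalRecord` to an HDF5 container.

    With ``as_codes=True`` samples are quantised to 16-bit digitiser codes
    over the acquisition range (the instrument's native representation);
    the round trip is then bit exact for code-aligned data.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    if as_codes:
        scale = record.acquisition_range_mv / 2**DIGITIZER_BITS
        data = np.round(record.samples / scale).astype(np.int32)
    else:
        data = record.samples
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("samples", data=data)
        dset.attrs["sample_rate_hz"] = float(record.sample_rate)
        dset.attrs["start_time_utc"] = record.start_time.astimezone(
            timezone.utc
        ).isoformat()
        dset.attrs["acquisition_range_mv"] = float(record.acquisition_range_mv)
        dset.attrs["label"] = record.label
    return path


def read_wav(
    path: str | Path,
    start_time: datetime,
    *,
    acquisition_range_mv: float = 5000.0,
    label: str = "",
) -> SignalRecord:
    """Import a mono WAV file as a signal record.

    The sample rate comes from the WAV header; amplitudes are rescaled so
    that the dtype's full scale maps onto the declared acquisition range,
    centred at half range (audio is signed, the detector voltage is not).
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise SignalFormatError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        full = float(np.iinfo(data.dtype).max)
        frac = data.astype(np.float64) / full
    else:
        frac = np.clip(data.astype(np.float64), -1.0, 1.0)
    samples = (frac + 1.0) * (acquisition_range_mv / 2.0)
    return SignalRecord(
        samples=samples,
        sample_rate=float(rate),
        start_time=start_time,
        label=label,
        acquisition_range_mv=acquisition_range_mv,
    )


@dataclass(frozen=True)
class CalibrationSample:
    """One weighed specimen: optical cross section plus wet and dry mass."""

    group: str
    sigma: float  # body extinction cross section, mm²
    mass_wet: float  # mg
    mass_dry: float  # mg

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (0 < self.mass_dry <= self.mass_wet):
            raise ValueError(
                f"need 0 < mass_dry <= mass_wet, got dry={self.mass_dry}, "
                f"wet={self.mass_wet}"
            )


_CAL_COLUMNS = ["group", "sigma_mm2", "mass_wet_mg", "mass_dry_mg"]


def read_calibration_table(path: str | Path) -> list[CalibrationSample]:
    """Read a calibration CSV with columns group,sigma_mm2,mass_wet_mg,mass_dry_mg.

    Every row is validated (positive cross section and masses, dry mass not
    exceeding wet mass); a failing row raises with its 1-based row number.
    """
    df = pd.read_csv(path)
    missing = set(_CAL_COLUMNS) - set(df.columns)
    if missing:
        raise SignalFormatError(f"calibration table missing columns: {sorted(missing)}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            samples.append(
                CalibrationSample(
                    group=str(row.group),
                    sigma=float(row.sigma_mm2),
                    mass_wet=float(row.mass_wet_mg),
                    mass_dry=float(row.mass_dry_mg),
                )
            )
        except ValueError as exc:
            raise ValueError(f"calibration table row {i}: {exc}") from exc
    return samples


def write_calibration_table(
    samples: list[CalibrationSample], path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(s.group, s.sigma, s.mass_wet, s.mass_dry) for s in samples],
        columns=_CAL_COLUMNS,
    ).to_csv(path, index=False)
    return path


#: Fixed event-table schema shared by all pipeline stages.
EVENT_TABLE_COLUMNS = [
    "event_id",
    "start_time_utc",
    "transit_time_s",
    "i0_mv",
    "ib_mv",
    "sigma_b_mm2",
    "wingbeat_hz",
    "kurtosis",
    "mass_wet_mg",
    "mass_dry_mg",
    "is_insect",
]


def write_event_table(events: pd.DataFrame, path: str | Path) -> Path:
    """Write an event table CSV with the fixed column order."""
    path = Path(path)
    df = events.copy()
    for col in EVENT_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[EVENT_TABLE_COLUMNS].to_csv(path, index=False)
    return path


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SignalFormatError(f"event table missing columns: {sorted(missing)}")
    df["start_time_utc"] = pd.to_datetime(df["start_time_utc"], utc=True)
    df["is_insect"] = df["is_insect"].astype(bool)
    return df
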