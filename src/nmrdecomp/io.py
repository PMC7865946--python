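"""Reading and writing NMR data: FIDs, 1D spectra, spectrograms/tensors and
property tables.

Supported on-disk formats are a minimal JCAMP-DX dialect (AFFN ``(XY..XY)``
tables, uncompressed) for FIDs and spectra, delimited text (CSV/TSV) for
spectra and property tables, and HDF5 for spectrograms and spectro-tensors.
Vendor formats (Bruker/Varian/JEOL directories) are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FID",
    "Spectrum1D",
    "PropertyTable",
    "ParseError",
    "read_fid",
    "write_fid",
    "read_spectrum",
    "write_spectrum",
    "read_property_table",
    "write_property_table",
    "write_spectrogram",
    "read_spectrogram",
    "write_tensor",
    "read_tensor",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line/cell."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class FID:
    """Complex time-domain NMR signal with acquisition metadata.

    Parameters
    ----------
    signal : complex ndarray
        The free-induction decay s(t_k) sampled at t_k = k * dwell_time.
    dwell_time : float
        Seconds per point; must be positive.
    spectrometer_freq : float, optional
        Observe frequency in MHz; enables Hz -> ppm conversion.
    reference_offset : float
        Reference frequency offset in Hz (default 0).
    label : str
        Free-text sample label.
    """

    signal: np.ndarray
    dwell_time: float
    spectrometer_freq: Optional[float] = None
    reference_offset: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=complex)
        if self.signal.ndim != 1 or self.signal.size < 2:
            raise ValueError("FID signal must be 1-D with at least 2 points")
        if not self.dwell_time > 0:
            raise ValueError(f"dwell_time must be > 0, got {self.dwell_time}")

    @property
    def n_points(self) -> int:
        return self.signal.size

    @property
    def times(self) -> np.ndarray:
        """Acquisition time axis in seconds."""
        return np.arange(self.n_points) * self.dwell_time

    @property
    def nyquist(self) -> float:
        """Largest representable |frequency| in Hz, 1/(2*dwell_time)."""
        return 0.5 / self.dwell_time


@dataclass
class Spectrum1D:
    """A 1-D spectrum: monotone frequency axis plus real intensities."""

    frequencies: np.ndarray
    intensities: np.ndarray
    axis_unit: str = "Hz"
    label: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.size == 0:
            raise ValueError("spectrum must contain at least one point")
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequencies and intensities must have equal length")
        d = np.diff(self.frequencies)
        if self.frequencies.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("frequency axis must be strictly monotone")
        if self.axis_unit not in ("Hz", "ppm"):
            raise ValueError(f"axis_unit must be 'Hz' or 'ppm', got {self.axis_unit!r}")

    def to_ppm(self, spectrometer_freq: float, reference_offset: float = 0.0) -> "Spectrum1D":
        """Convert a Hz axis to ppm: ppm = (f - offset) / spectrometer_freq[MHz]."""
        if self.axis_unit == "ppm":
            return self
        ppm = (self.frequencies - reference_offset) / spectrometer_freq
        return Spectrum1D(ppm, self.intensities.copy(), axis_unit="ppm", label=self.label)


@dataclass
class PropertyTable:
    """Sample x property matrix (e.g. Tg/Tm/Td in deg C, or scaled peak intensities)."""

    sample_ids: list
    property_names: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.property_names)):
            raise ValueError("values shape must be (n_samples, n_properties)")
        if np.isnan(self.values).any():
            rows = [self.sample_ids[i] for i in np.unique(np.where(np.isnan(self.values))[0])]
            raise ValueError(f"missing values in rows: {rows}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.property_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.property_names.index(name)]


# --------------------------------------------------------------------------
# FID readers / writers
# --------------------------------------------------------------------------

def _infer_format(path: str, explicit: Optional[str], kinds: Sequence[str]) -> str:
    if explicit is not None:
        if explicit not in kinds:
            raise ValueError(f"unknown format {explicit!r}; expected one of {kinds}")
        return explicit
    ext = os.path.splitext(path)[1].lower()
    if ext in (".jdx", ".dx", ".jcamp"):
        return "jcamp"
    return "text" if "text" in kinds else "csv"


def read_fid(path: str, format: Optional[str] = None, dwell_time: Optional[float] = None) -> FID:
    """Read an FID from a JCAMP-DX or delimited-text file.

    Text files hold 3 columns (time, real, imag) or 2 columns (real, imag);
    for 2-column files ``dwell_time`` must be given here or in a
    ``# dwell_time = <sec>`` header line.  A time column, when present, must
    agree with the dwell time to 1e-9 s.
    """
    fmt = _infer_format(path, format, ("jcamp", "text"))
    if fmt == "jcamp":
        return _read_fid_jcamp(path)
    return _read_fid_text(path, dwell_time)


def _read_fid_text(path: str, dwell_time: Optional[float]) -> FID:
    rows: list[tuple[float, ...]] = []
    header_dwell = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip().lower() in ("dwell_time", "dwell time"):
                        header_dwell = float(val)
                continue
            tokens = [t for t in line.replace(",", " ").split() if t]
            try:
                vals = tuple(float(t) for t in tokens)
            except ValueError:
                raise ParseError(f"{path}: non-numeric token at line {lineno}: {line!r}")
            if len(vals) not in (2, 3):
                raise ParseError(
                    f"{path}: expected 2 or 3 columns at line {lineno}, got {len(vals)}"
                )
            rows.append(vals)
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least 2 data rows, found {len(rows)}")
    ncols = {len(r) for r in rows}
    if len(ncols) > 1:
        raise ParseError(f"{path}: inconsistent column counts {sorted(ncols)}")
    arr = np.array(rows, dtype=float)
    dt = dwell_time if dwell_time is not None else header_dwell
    if arr.shape[1] == 3:
        times, re_part, im_part = arr.T
        steps = np.diff(times)
        inferred = float(steps[0])
        if not np.allclose(steps, inferred, atol=1e-12, rtol=1e-6):
            raise ParseError(f"{path}: time column is not uniformly spaced")
        if dt is None:
            dt = inferred
        elif abs(inferred - dt) > 1e-9:
            raise ParseError(
                f"{path}: time column spacing {inferred} conflicts with dwell_time {dt}"
            )
    else:
        re_part, im_part = arr.T
        if dt is None:
            raise ValueError(
                f"{path}: dwell_time required for 2-column FID text (argument or header)"
            )
    return FID(re_part + 1j * im_part, dwell_time=float(dt))


# minimal JCAMP-DX dialect: uncompressed AFFN (XY..XY) tables, one PAGE per
# complex component for FIDs.

def write_fid(fid: FID, path: str, format: str = "jcamp") -> None:
    if format == "text":
        with open(path, "w") as fh:
            fh.write(f"# dwell_time = {float(fid.dwell_time)!r}\n")
            for t, z in zip(fid.times, fid.signal):
                fh.write(f"{float(t)!r},{float(z.real)!r},{float(z.imag)!r}\n")
        return
    if format != "jcamp":
        raise ValueError(f"unknown FID format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"##TITLE= {fid.label}\n")
        fh.write("##JCAMP-DX= 6.00\n")
        fh.write("##DATA TYPE= NMR FID\n")
        fh.write(f"##NPOINTS= {fid.n_points}\n")
        fh.write(f"##.DWELL TIME= {float(fid.dwell_time)!r}\n")
        if fid.spectrometer_freq is not None:
            fh.write(f"##.OBSERVE FREQUENCY= {float(fid.spectrometer_freq)!r}\n")
        fh.write(f"##$REFERENCE OFFSET= {float(fid.reference_offset)!r}\n")
        for name, comp in (("REAL", fid.signal.real), ("IMAG", fid.signal.imag)):
            fh.write(f"##PAGE= COMPONENT={name}\n")
            fh.write("##DATA TABLE= (XY..XY)\n")
            for t, y in zip(fid.times, comp):
                fh.write(f"{float(t)!r}, {float(y)!r}\n")
        fh.write("##END=\n")


def _parse_jcamp_records(path: str) -> tuple[dict, list[tuple[str, np.ndarray]]]:
    """Return (header fields, list of (page name, Nx2 XY array))."""
    fields: dict[str, str] = {}
    pages: list[tuple[str, list]] = []
    current: Optional[list] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                val = val.strip()
                if key == "PAGE":
                    pages.append((val, []))
                    current = pages[-1][1]
                elif key == "DATA TABLE" or key == "XYDATA" or key == "XYPOINTS":
                    if key != "PAGE" and not pages:
                        pages.append((val, []))
                        current = pages[-1][1]
                elif key == "END":
                    current = None
                else:
                    fields[key] = val
                    current = None if key not in ("DATA TABLE",) else current
                continue
            if current is None:
                # bare numeric line outside any table
                raise ParseError(f"{path}: unexpected data at line {lineno}: {line!r}")
            tokens = [t for t in line.replace(",", " ").split() if t]
            try:
                vals = [float(t) for t in tokens]
            except ValueError:
                raise ParseError(f"{path}: non-numeric token at line {lineno}: {line!r}")
            if len(vals) % 2:
                raise ParseError(f"{path}: odd token count in (XY..XY) table at line {lineno}")
            current.extend(zip(vals[::2], vals[1::2]))
    return fields, [(name, np.array(tab, dtype=float)) for name, tab in pages]


def _read_fid_jcamp(path: str) -> FID:
    fields, pages = _parse_jcamp_records(path)
    real = imag = None
    for name, tab in pages:
        up = name.upper()
        if "REAL" in up:
            real = tab
        elif "IMAG" in up:
            imag = tab
    if real is None:
        raise ParseError(f"{path}: no REAL component page found")
    if imag is None:
        imag = np.column_stack([real[:, 0], np.zeros(len(real))])
    if len(real) != len(imag):
        raise ParseError(f"{path}: REAL/IMAG page lengths differ")
    dwell = fields.get(".DWELL TIME")
    if dwell is None:
        steps = np.diff(real[:, 0])
        if len(steps) == 0:
            raise ParseError(f"{path}: cannot infer dwell time")
        dwell = steps[0]
    sfreq = fields.get(".OBSERVE FREQUENCY")
    offset = fields.get("$REFERENCE OFFSET", "0.0")
    return FID(
        real[:, 1] + 1j * imag[:, 1],
        dwell_time=float(dwell),
        spectrometer_freq=float(sfreq) if sfreq is not None else None,
        reference_offset=float(offset),
        label=fields.get("TITLE", ""),
    )


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum1D, path: str, format: Optional[str] = None) -> None:
    """Write a spectrum as CSV (``frequency,intensity``) or JCAMP-DX."""
    fmt = _infer_format(path, format, ("jcamp", "csv"))
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write("frequency,intensity\n")
            for f, y in zip(spectrum.frequencies, spectrum.intensities):
                fh.write(f"{float(f)!r},{float(y)!r}\n")
        return
    with open(path, "w") as fh:
        fh.write(f"##TITLE= {spectrum.label}\n")
        fh.write("##JCAMP-DX= 6.00\n")
        fh.write("##DATA TYPE= NMR SPECTRUM\n")
        fh.write(f"##XUNITS= {spectrum.axis_unit.upper()}\n")
        fh.write(f"##NPOINTS= {spectrum.frequencies.size}\n")
        fh.write("##XYPOINTS= (XY..XY)\n")
        for f, y in zip(spectrum.frequencies, spectrum.intensities):
            fh.write(f"{float(f)!r}, {float(y)!r}\n")
        fh.write("##END=\n")


def read_spectrum(path: str, format: Optional[str] = None) -> Spectrum1D:
    fmt = _infer_format(path, format, ("jcamp", "csv"))
    if fmt == "jcamp":
        fields, pages = _parse_jcamp_records(path)
        if not pages:
            raise ParseError(f"{path}: no XY data table found")
        tab = pages[0][1]
        unit = fields.get("XUNITS", "HZ")
        unit = "ppm" if unit.lower().startswith("ppm") else "Hz"
        return Spectrum1D(tab[:, 0], tab[:, 1], axis_unit=unit, label=fields.get("TITLE", ""))
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns (frequency,intensity)")
    return Spectrum1D(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


# --------------------------------------------------------------------------
# property tables
# --------------------------------------------------------------------------

def read_property_table(path: str, sep: Optional[str] = None) -> PropertyTable:
    """Read a delimited sample x property table (first column = sample id)."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    ids = [str(i) for i in df.index]
    dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample ids: {sorted(set(dup))}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing cell at row {bad[0]!r}, column {col!r}"
            )
        values[:, j] = coerced.to_numpy(float)
    return PropertyTable(ids, [str(c) for c in df.columns], values)


def write_property_table(table: PropertyTable, path: str) -> None:
    table.to_frame().to_csv(path, index_label="sample_id")


# --------------------------------------------------------------------------
# spectrogram / tensor HDF5 containers
# --------------------------------------------------------------------------

def write_spectrogram(spectrogram, path: str) -> None:
    """Persist a Spectrogram to HDF5 (datasets: magnitude/time_axis/frequency_axis)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("magnitude", data=spectrogram.magnitude)
        h5.create_dataset("time_axis", data=spectrogram.frame_times)
        h5.create_dataset("frequency_axis", data=spectrogram.frequencies)
        h5.attrs["window"] = spectrogram.window
        h5.attrs["segment_length"] = spectrogram.segment_length
        h5.attrs["hop"] = spectrogram.hop
        h5.attrs["two_sided"] = spectrogram.two_sided
        h5.attrs["source_label"] = spectrogram.source_label


def read_spectrogram(path: str):
    from .spectro import Spectrogram

    with h5py.File(path, "r") as h5:
        return Spectrogram(
            magnitude=h5["magnitude"][()],
            frame_times=h5["time_axis"][()],
            frequencies=h5["frequency_axis"][()],
            window=str(h5.attrs["window"]),
            segment_length=int(h5.attrs["segment_length"]),
            hop=int(h5.attrs["hop"]),
            two_sided=bool(h5.attrs["two_sided"]),
            source_label=str(h5.attrs["source_label"]),
        )


def write_tensor(tensor, path: str) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("magnitude", data=tensor.magnitude)
        h5.create_dataset("time_axis", data=tensor.frame_times)
        h5.create_dataset("frequency_axis", data=tensor.frequencies)
        h5.create_dataset(
            "sample_ids", data=np.array([str(s) for s in tensor.sample_ids], dtype="S")
        )


def read_tensor(path: str):
    from .spectro import SpectroTensor

    with h5py.File(path, "r") as h5:
        return SpectroTensor(
            magnitude=h5["magnitude"][()],
            sample_ids=[s.decode() for s in h5["sample_ids"][()]],
            frame_times=h5["time_axis"][()],
            frequencies=h5["frequency_axis"][()],
        )
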