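"""EDF input/output and epoch segmentation.

Clinical scalp EEG is exchanged in the 16-bit European Data Format (EDF).
This module reads EDF files into physical units (microvolts), writes plain
EDF (no EDF+ annotations), and cuts continuous recordings into fixed-length
labeled :class:`EEGEpoch` segments.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: 10-20 system labels of the standard 19-electrode clinical montage.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

#: Physical range (µV) used when writing synthetic EDF; covers 100-200 µV
#: discharges with ample headroom.
PHYS_RANGE_UV = 1000.0

_DIG_MAX = 32767
_DIG_MIN = -32768


class EDFFormatError(ValueError):
    """Raised when an EDF file is malformed or truncated."""


@dataclass
class EEGEpoch:
    """One fixed-length multi-channel EEG segment in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered electrode labels (10-20 system for the default montage).
    label : str
        ``"normal"`` or ``"epileptiform"``.
    subtype : list of str
        Zero or more discharge subtype names (an epoch may carry several).
    epoch_id : str
        Opaque unique identifier.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    label: str = "normal"
    subtype: list[str] = field(default_factory=list)
    epoch_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} "
                "channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, signals: np.ndarray, fs: float,
              channel_names: list[str],
              phys_range: float = PHYS_RANGE_UV) -> None:
    """Write a plain EDF file with one data record per second.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Physical signal in µV. Samples outside ``±phys_range`` are clipped.
    fs : float
        Sampling rate; ``fs`` must be an integer so each 1 s record holds a
        whole number of samples.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samp = signals.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9 or fs_int <= 0:
        raise ValueError("write_edf requires an integer sampling rate")
    n_records = n_samp // fs_int
    if n_records * fs_int != n_samp:
        raise ValueError("signal length must be a whole number of seconds")

    # physical -> 16-bit digital
    scale = (_DIG_MAX - _DIG_MIN) / (2 * phys_range)
    digital = np.clip(
        np.round((signals + phys_range) * scale) + _DIG_MIN,
        _DIG_MIN, _DIG_MAX,
    ).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(Path(path), "wb") as fh:
        fh.write(_pad("0", 8))                      # version
        fh.write(_pad("X X X X", 80))               # patient id (anonymous)
        fh.write(_pad("Startdate X X X X", 80))     # recording id
        fh.write(_pad("01.01.00", 8))               # start date
        fh.write(_pad("00.00.00", 8))               # start time
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))                      # reserved (plain EDF)
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))                      # record duration (s)
        fh.write(_pad(str(n_ch), 4))
        for name in channel_names:
            fh.write(_pad(name, 16))
        for _ in range(n_ch):
            fh.write(_pad("AgAgCl electrode", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for _ in range(n_ch):
            fh.write(_pad(f"{-phys_range:g}", 8))
        for _ in range(n_ch):
            fh.write(_pad(f"{phys_range:g}", 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_DIG_MIN), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_DIG_MAX), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))                  # prefiltering
        for _ in range(n_ch):
            fh.write(_pad(str(fs_int), 8))          # samples per record
        for _ in range(n_ch):
            fh.write(_pad("", 32))                  # reserved
        for rec in range(n_records):
            chunk = digital[:, rec * fs_int:(rec + 1) * fs_int]
            fh.write(chunk.tobytes())


def read_edf(path: str | Path) -> list[tuple[str, np.ndarray, float]]:
    """Read an EDF/EDF+ file, returning ``(channel_name, signal_µV, fs)``.

    Annotation channels are ignored; all EEG channels must share one
    sampling rate. Channel order is preserved.
    """
    path = Path(path)
    _validate_edf_header(path)
    import mne  # heavy import kept local

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [i for i, name in enumerate(raw.ch_names)
             if "annotation" not in name.lower()]
    fs = float(raw.info["sfreq"])
    data_v = raw.get_data(picks=picks)
    out = []
    for row, idx in zip(data_v, picks):
        out.append((raw.ch_names[idx], row * 1e6, fs))  # V -> µV
    return out


def _validate_edf_header(path: Path) -> None:
    """Cheap structural validation so truncated files fail cleanly."""
    try:
        with open(path, "rb") as fh:
            header = fh.read(256)
            if len(header) < 256:
                raise EDFFormatError(f"{path}: truncated EDF header")
            try:
                n_records = int(header[236:244].decode("ascii").strip())
                n_ch = int(header[252:256].decode("ascii").strip())
                header_bytes = int(header[184:192].decode("ascii").strip())
            except (UnicodeDecodeError, ValueError) as exc:
                raise EDFFormatError(f"{path}: malformed EDF header") from exc
            sig_header = fh.read(header_bytes - 256)
            if len(sig_header) < header_bytes - 256:
                raise EDFFormatError(f"{path}: truncated signal headers")
            # samples-per-record fields start after 216 bytes per channel
            off = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
            spr = []
            for k in range(n_ch):
                fld = sig_header[off + 8 * k: off + 8 * (k + 1)]
                try:
                    spr.append(int(fld.decode("ascii").strip()))
                except (UnicodeDecodeError, ValueError) as exc:
                    raise EDFFormatError(
                        f"{path}: malformed samples-per-record field"
                    ) from exc
            expect = header_bytes + n_records * sum(spr) * 2
            actual = path.stat().st_size
            if actual < expect:
                raise EDFFormatError(
                    f"{path}: file holds {actual} bytes, header promises "
                    f"{expect}"
                )
    except OSError as exc:
        raise EDFFormatError(f"cannot read {path}: {exc}") from exc


def read_edf_epoch(path: str | Path, label: str = "normal",
                   subtype: list[str] | None = None,
                   epoch_id: str = "") -> EEGEpoch:
    """Read a single-epoch EDF file straight into an :class:`EEGEpoch`."""
    rows = read_edf(path)
    if not rows:
        raise EDFFormatError(f"{path}: no signal channels")
    fs_set = {fs for _, _, fs in rows}
    if len(fs_set) != 1:
        raise EDFFormatError(f"{path}: mixed sampling rates {sorted(fs_set)}")
    names = [name for name, _, _ in rows]
    data = np.vstack([sig for _, sig, _ in rows])
    return EEGEpoch(data=data, fs=fs_set.pop(), channel_names=names,
                    label=label, subtype=list(subtype or []),
                    epoch_id=epoch_id or Path(path).stem)


def segment_epochs(signals: np.ndarray, fs: float, epoch_seconds: float,
                   channel_names: list[str] | None = None,
                   id_prefix: str = "epoch") -> list[EEGEpoch]:
    """Cut a continuous multi-channel recording into non-overlapping epochs.

    Epochs are half-open sample windows ``[k*N, (k+1)*N)``; a trailing
    partial window is discarded.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_per = epoch_seconds * fs
    if n_per <= 0 or abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_seconds * fs must be a positive integer")
    n_per = int(round(n_per))
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(signals.shape[0])]
    n_epochs = signals.shape[1] // n_per
    if n_epochs == 0:
        logger.warning(
            "recording of %d samples shorter than one %d-sample epoch",
            signals.shape[1], n_per,
        )
        return []
    return [
        EEGEpoch(
            data=signals[:, k * n_per:(k + 1) * n_per].copy(),
            fs=fs,
            channel_names=list(channel_names),
            epoch_id=f"{id_prefix}_{k:05d}",
        )
        for k in range(n_epochs)
    ]
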