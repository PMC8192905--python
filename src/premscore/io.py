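"""Domain containers and file I/O for signals and hypnograms.

Two signal dialects are supported:

* **EDF** (European Data Format), the interchange format of sleep labs.  A
  minimal single-channel reader/writer is implemented here; samples are
  stored as 16-bit integers with physical scaling, so the EDF round trip is
  exact only up to that quantisation.
* **raw dialect** — little-endian float32 samples in a ``.raw`` file plus a
  JSON sidecar ``<file>.json`` with keys ``fs_hz``, ``unit``, ``subject_id``
  and ``channel``.  This round-trips bit-exactly and represents arbitrary
  (non-integer) sampling rates such as the 992.06 Hz used by typical rodent
  acquisition hardware.

Hypnograms are CSV files with header ``epoch_index,label`` (0-based indices,
one row per 10-s epoch).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DataError, FormatError
from .stages import Stage

__all__ = [
    "Recording",
    "Hypnogram",
    "DatasetSplit",
    "read_recording",
    "write_recording",
    "read_hypnogram",
    "write_hypnogram",
    "reduce_to_standard_stages",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Recording:
    """A uniformly sampled single-channel EEG signal.

    Parameters
    ----------
    samples : ndarray
        Signal in microvolt.
    fs : float
        Sampling rate in Hz, constant over the recording.
    subject_id, channel : str
        Free-text metadata.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    channel: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise DataError("Recording.samples must be one-dimensional")
        if not np.isfinite(self.samples).all():
            raise DataError("Recording contains non-finite samples")
        if not (self.fs > 0):
            raise FormatError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def n_epochs(self, epoch_len_s: float = 10.0) -> int:
        """Number of whole epochs; a trailing partial epoch is dropped."""
        return int(math.floor(len(self.samples) / (epoch_len_s * self.fs) + 1e-9))


@dataclass
class Hypnogram:
    """Ordered per-epoch stage labels aligned to a recording.

    ``labels`` is stored as an integer array of :class:`~premscore.stages.Stage`
    codes.  Epoch ``k`` covers samples ``[k*epoch_len_s*fs, (k+1)*epoch_len_s*fs)``
    of the aligned recording (0-based, half-open).
    """

    labels: np.ndarray
    epoch_len_s: float = 10.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise DataError("Hypnogram.labels must be one-dimensional")
        if not (self.epoch_len_s > 0):
            raise ConfigError("epoch_len_s must be positive")
        bad = ~np.isin(self.labels, [int(s) for s in Stage])
        if bad.any():
            raise DataError(f"invalid stage codes: {np.unique(self.labels[bad])}")

    def __len__(self) -> int:
        return len(self.labels)

    def stages(self) -> list[Stage]:
        return [Stage(c) for c in self.labels]

    def counts(self) -> dict[Stage, int]:
        return {s: int(np.sum(self.labels == int(s))) for s in Stage}


@dataclass
class DatasetSplit:
    """Assignment of whole subjects to one of train/validation/test."""

    role: str
    subject_ids: set = field(default_factory=set)

    ROLES = ("train", "validation", "test")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ConfigError(f"role must be one of {self.ROLES}, got {self.role!r}")
        self.subject_ids = set(self.subject_ids)


def check_disjoint(splits: list[DatasetSplit]) -> None:
    """Raise unless the subject sets of all splits are pairwise disjoint."""
    seen: dict[str, str] = {}
    for sp in splits:
        for sid in sp.subject_ids:
            if sid in seen:
                raise ConfigError(
                    f"subject {sid!r} assigned to both {seen[sid]!r} and {sp.role!r}"
                )
            seen[sid] = sp.role


# ---------------------------------------------------------------------------
# raw float32 dialect


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _write_raw(path: Path, rec: Recording) -> None:
    rec.samples.astype("<f4").tofile(path)
    meta = {
        "fs_hz": float(rec.fs),
        "unit": "uV",
        "subject_id": rec.subject_id,
        "channel": rec.channel,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _read_raw(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"raw dialect sidecar not found: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        fs = float(meta["fs_hz"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"invalid sidecar {sidecar}: {exc}") from exc
    if not (fs > 0):
        raise FormatError(f"sampling rate must be positive, got {fs}")
    samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    return Recording(
        samples=samples,
        fs=fs,
        subject_id=str(meta.get("subject_id", "")),
        channel=str(meta.get("channel", "EEG")),
    )


# ---------------------------------------------------------------------------
# minimal single-channel EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def _edf_number(value: float, width: int) -> bytes:
    """Format a float into a fixed-width ASCII EDF field."""
    for prec in range(width - 1, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width and "e" not in s and "E" not in s:
            return s.ljust(width).encode("ascii")
    raise FormatError(f"cannot represent {value} in {width} characters")


def _record_geometry(fs: float) -> tuple[float, int]:
    """Pick a data-record duration so that fs * duration is an integer.

    EDF stores the rate as (samples per record) / (record duration); rates
    like 992.06 Hz need records longer than 1 s (992.06 = 49603/50).
    """
    frac = Fraction(fs).limit_denominator(10_000)
    duration = frac.denominator
    n_per_record = frac.numerator
    # prefer ~1 s records when the rate is integral
    if duration == 1 and n_per_record > 100_000:
        raise FormatError(f"sampling rate {fs} too high for EDF records")
    if abs(n_per_record / duration - fs) > 1e-6 * fs:
        raise FormatError(f"sampling rate {fs} is not representable in EDF")
    return float(duration), n_per_record


def _write_edf(path: Path, rec: Recording) -> None:
    duration, n_per_record = _record_geometry(rec.fs)
    x = rec.samples
    n_records = max(1, math.ceil(len(x) / n_per_record))
    pad = n_records * n_per_record - len(x)
    if pad:
        # EDF has no partial records; repeat the final sample
        x = np.concatenate([x, np.full(pad, x[-1] if len(x) else 0.0)])

    pmin, pmax = float(x.min(initial=0.0)), float(x.max(initial=0.0))
    if pmax <= pmin:
        pmin, pmax = pmin - 1.0, pmax + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((x - pmin) * scale + dmin).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(rec.subject_id[:80], 80),
            _edf_field("premscore", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * 2, 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_number(duration, 8),
            _edf_field(1, 4),
            # per-signal header (one signal)
            _edf_field(rec.channel[:16], 16),
            _edf_field("", 80),
            _edf_field("uV", 8),
            _edf_number(pmin, 8),
            _edf_number(pmax, 8),
            _edf_field(dmin, 8),
            _edf_field(dmax, 8),
            _edf_field("", 80),
            _edf_field(n_per_record, 8),
            _edf_field("", 32),
        ]
    )
    assert len(header) == 512
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def _read_edf(path: Path) -> Recording:
    blob = path.read_bytes()
    if len(blob) < 256:
        raise FormatError(f"{path}: not an EDF file (header truncated)")
    try:
        n_signals = int(blob[252:256])
        n_records = int(blob[236:244])
        duration = float(blob[244:252])
        subject_id = blob[8:88].decode("ascii").strip()
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: malformed EDF header: {exc}") from exc
    if n_signals < 1:
        raise FormatError(f"{path}: EDF declares {n_signals} signals")
    if len(blob) < 256 + 256 * n_signals:
        raise FormatError(f"{path}: EDF signal headers truncated")

    # signal headers are field-major: all labels, all transducers, ...
    widths = {"label": 16, "transducer": 80, "dim": 8, "pmin": 8, "pmax": 8,
              "dmin": 8, "dmax": 8, "prefilter": 80, "n_per_record": 8,
              "reserved": 32}
    offsets, acc = {}, 0
    for name, w in widths.items():
        offsets[name] = acc
        acc += w

    def sig_field(name: str, k: int) -> str:
        base = 256 + offsets[name] * n_signals + widths[name] * k
        return blob[base : base + widths[name]].decode("ascii", "replace").strip()

    # only the first signal is returned (the package is single-channel)
    label = sig_field("label", 0)
    try:
        pmin = float(sig_field("pmin", 0))
        pmax = float(sig_field("pmax", 0))
        dmin = int(sig_field("dmin", 0))
        dmax = int(sig_field("dmax", 0))
        n_per_record = int(sig_field("n_per_record", 0))
        record_len = sum(int(sig_field("n_per_record", k)) for k in range(n_signals))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF signal header: {exc}") from exc
    if duration <= 0 or n_per_record <= 0:
        raise FormatError(f"{path}: non-positive record duration or sample count")
    fs = n_per_record / duration
    if dmax == dmin:
        raise FormatError(f"{path}: degenerate digital range")

    data_offset = 256 + 256 * n_signals
    digital = np.frombuffer(blob, dtype="<i2", offset=data_offset)
    if n_records < 0:  # -1 means "unknown" in the standard
        n_records = len(digital) // record_len
    records = digital[: n_records * record_len].reshape(n_records, record_len)
    sig = records[:, :n_per_record].reshape(-1).astype(np.float64)
    physical = (sig - dmin) * (pmax - pmin) / (dmax - dmin) + pmin
    return Recording(samples=physical, fs=fs, subject_id=subject_id, channel=label)


# ---------------------------------------------------------------------------
# public signal API


def write_recording(path, rec: Recording) -> Path:
    """Write a recording; format chosen by suffix (``.edf`` vs raw dialect)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".edf":
        _write_edf(path, rec)
    else:
        _write_raw(path, rec)
    return path


def read_recording(path) -> Recording:
    """Read an EDF or raw-dialect recording (dispatch on suffix)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return _read_raw(path)


# ---------------------------------------------------------------------------
# hypnogram CSV


def write_hypnogram(path, hyp: Hypnogram) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(len(hyp)),
            "label": [Stage(c).name for c in hyp.labels],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_hypnogram(path, n_epochs: int | None = None, epoch_len_s: float = 10.0) -> Hypnogram:
    """Read a hypnogram CSV (``epoch_index,label``).

    Rows may appear in any order; indices must be exactly 0..n-1 with no
    duplicates.  If ``n_epochs`` is given, the row count must match.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"label": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse hypnogram {path}: {exc}") from exc
    if not {"epoch_index", "label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns epoch_index,label")
    idx = df["epoch_index"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise DataError(f"{path}: duplicate epoch_index values")
    df = df.sort_values("epoch_index")
    if not np.array_equal(df["epoch_index"].to_numpy(), np.arange(len(df))):
        raise DataError(f"{path}: epoch_index values are not 0..{len(df) - 1}")
    if n_epochs is not None and len(df) != n_epochs:
        raise AlignmentError(
            f"{path}: {len(df)} epochs in file, {n_epochs} expected"
        )
    labels = [int(Stage.from_token(t)) for t in df["label"]]
    return Hypnogram(labels=np.asarray(labels), epoch_len_s=epoch_len_s)


# ---------------------------------------------------------------------------
# 3-class reduction


def reduce_to_standard_stages(hyp: Hypnogram) -> tuple[Hypnogram, np.ndarray]:
    """Reduce a 5-class hypnogram to Wake/NREM/REM.

    Pre-REM epochs are reinterpreted as NREM; artifact epochs are removed.
    Returns the reduced hypnogram and the original epoch positions that
    survive, so window bookkeeping can follow the removal.
    """
    labels = hyp.labels.copy()
    labels[labels == int(Stage.PREREM)] = int(Stage.NREM)
    kept = np.flatnonzero(labels != int(Stage.ARTIFACT))
    return Hypnogram(labels=labels[kept], epoch_len_s=hyp.epoch_len_s), kept
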