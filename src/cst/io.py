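"""Raw EEG input/output, filtering, epoch segmentation and split construction.

The classification unit throughout the toolkit is the *epoch*: a fixed-length
window cut from a continuous multichannel recording.  A recording enters as an
:class:`EEGRecord` (channels x samples, microvolts), is optionally filtered,
and is segmented into an :class:`EpochSet` whose array is laid out
``[n_epochs, n_times, n_channels]`` — each row of an epoch is the vector of
channel amplitudes at one time frame.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .exceptions import (
    DataError,
    FormatError,
    ParameterError,
    UnsupportedRateError,
)

__all__ = [
    "EEGRecord",
    "SegmentationSpec",
    "EpochSet",
    "read_edf",
    "write_edf",
    "read_csv_record",
    "bandpass_filter",
    "highpass_filter",
    "segment",
    "annotation_overlap_labeler",
    "split_holdout",
    "kfold",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class EEGRecord:
    """One continuous multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (C, n_samples)
        Signal in microvolts, one row per electrode channel.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    subject_id : str
    annotations : list of (onset_s, duration_s, label)
        Event annotations; onsets/durations in seconds from recording start.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    subject_id: str = ""
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError("EEGRecord.data must be 2-D [channels, samples]")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        if self.data.shape[0] < 1:
            raise DataError("need at least one channel")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError("channel_names length must match channel count")
        for onset, dur, _label in self.annotations:
            if onset < 0 or onset + dur > self.duration + 1e-9:
                raise DataError(
                    f"annotation ({onset}, {dur}) outside [0, {self.duration:.3f}]"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class SegmentationSpec:
    """Epoch geometry: ``window_s * fs`` samples per epoch, ``channels`` wide."""

    window_s: float
    fs: float
    channels: int

    def __post_init__(self):
        n = self.window_s * self.fs
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"window_s*fs must be a positive integer, got {n!r}"
            )

    @property
    def n_times(self) -> int:
        return int(round(self.window_s * self.fs))


@dataclass
class EpochSet:
    """Segmented, labelled epochs ready for modelling.

    ``epochs`` has shape ``[N, T, C]`` (epoch, time frame, channel);
    ``labels`` are integer class indices; ``group_ids`` carry the originating
    subject/record so grouped (leakage-safe) splitting is possible.
    """

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    class_names: Sequence[str]
    group_ids: Sequence[str]

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.group_ids = list(self.group_ids)
        if self.epochs.ndim != 3:
            raise DataError("epochs must be [N, T, C]")
        n = self.epochs.shape[0]
        if self.labels.shape != (n,) or len(self.group_ids) != n:
            raise DataError("labels and group_ids must have one entry per epoch")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise DataError("labels must lie in [0, n_classes)")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            self.epochs[idx],
            self.labels[idx],
            self.fs,
            list(self.class_names),
            [self.group_ids[i] for i in idx],
        )

    # -- portable container: .npz arrays + JSON sidecar ---------------------
    def save(self, path) -> Path:
        """Write epochs to ``<path>.npz`` plus a ``<path>.json`` sidecar."""
        path = Path(path)
        base = path.with_suffix("") if path.suffix == ".npz" else path
        np.savez(base.with_suffix(".npz"), epochs=self.epochs, labels=self.labels)
        sidecar = {
            "fs": self.fs,
            "class_names": list(self.class_names),
            "group_ids": list(self.group_ids),
        }
        base.with_suffix(".json").write_text(json.dumps(sidecar))
        return base.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "EpochSet":
        path = Path(path)
        base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
        try:
            with np.load(base.with_suffix(".npz")) as z:
                epochs, labels = z["epochs"], z["labels"]
            sidecar = json.loads(base.with_suffix(".json").read_text())
        except (OSError, KeyError, json.JSONDecodeError) as e:
            raise FormatError(f"cannot load EpochSet from {path}: {e}") from e
        return cls(epochs, labels, sidecar["fs"], sidecar["class_names"],
                   sidecar["group_ids"])


# ---------------------------------------------------------------------------
# EDF reading (via MNE) and a minimal EDF+ writer
# ---------------------------------------------------------------------------

def _edf_header_rates(path: Path):
    """Parse just enough of an EDF header to detect mixed per-channel rates."""
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_sig = int(header[252:256].decode("ascii").strip())
            dur = float(header[244:252].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as e:
            raise FormatError(f"{path}: unreadable EDF header") from e
        if n_sig < 1 or dur <= 0:
            raise FormatError(f"{path}: implausible EDF header fields")
        sig_hdr = f.read(256 * n_sig)
        if len(sig_hdr) < 256 * n_sig:
            raise FormatError(f"{path}: truncated EDF signal headers")
    labels = [sig_hdr[16 * i:16 * (i + 1)].decode("ascii", "replace").strip()
              for i in range(n_sig)]
    off = n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    nsamp = []
    for i in range(n_sig):
        raw = sig_hdr[off + 8 * i: off + 8 * (i + 1)]
        try:
            nsamp.append(int(raw.decode("ascii").strip()))
        except (UnicodeDecodeError, ValueError) as e:
            raise FormatError(f"{path}: bad samples-per-record field") from e
    rates = {ns / dur for lab, ns in zip(labels, nsamp)
             if lab != "EDF Annotations"}
    return rates


def read_edf(path) -> EEGRecord:
    """Read an EDF/EDF+ file into an :class:`EEGRecord` (data in microvolts).

    Raises
    ------
    FormatError
        If the file cannot be parsed as EDF.
    UnsupportedRateError
        If signal channels carry different sampling rates.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    rates = _edf_header_rates(path)
    if len(rates) > 1:
        raise UnsupportedRateError(
            f"{path}: mixed per-channel sampling rates {sorted(rates)}"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as e:  # mne raises many concrete types here
        raise FormatError(f"{path}: not a readable EDF file ({e})") from e
    data_uv = raw.get_data() * 1e6  # MNE returns SI volts
    annotations = [
        (float(on), float(du), str(desc))
        for on, du, desc in zip(raw.annotations.onset,
                                raw.annotations.duration,
                                raw.annotations.description)
    ]
    return EEGRecord(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=path.stem,
        annotations=annotations,
    )


def _ascii_field(value, width) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecord, path) -> Path:
    """Write an :class:`EEGRecord` as a minimal EDF+C file.

    Intended for fixture generation and data export; requires an integer
    sampling rate and pads the signal with zeros to a whole number of 1 s
    data records.  Annotations are stored in an ``EDF Annotations`` channel.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(math.ceil(rec.n_samples / fs))
    data = np.zeros((rec.n_channels, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    # digital <-> physical scaling, one symmetric range per channel
    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    dig_max = 32767

    tals = []
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for onset, dur, label in rec.annotations:
            if r == min(int(onset), n_rec - 1):
                tal += f"+{onset:g}\x15{dur:g}\x14{label}\x14\x00".encode("utf-8")
        tals.append(tal)
    ann_nsamp = max(16, (max(len(t) for t in tals) + 1) // 2 + 1)

    ns = rec.n_channels + 1
    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(rec.subject_id or "X", 80),
        _ascii_field("Startdate 01-JAN-2000", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(256 * (ns + 1), 8),
        _ascii_field("EDF+C", 44),
        _ascii_field(n_rec, 8),
        _ascii_field(1, 8),
        _ascii_field(ns, 4),
    ])
    labels = [_ascii_field(n, 16) for n in rec.channel_names]
    labels.append(_ascii_field("EDF Annotations", 16))
    fields = [
        labels,
        [_ascii_field("", 80)] * ns,
        [_ascii_field("uV", 8)] * rec.n_channels + [_ascii_field("", 8)],
        [_ascii_field(f"{-m:.6g}"[:8], 8) for m in phys_max] + [_ascii_field(-1, 8)],
        [_ascii_field(f"{m:.6g}"[:8], 8) for m in phys_max] + [_ascii_field(1, 8)],
        [_ascii_field(-dig_max, 8)] * ns,
        [_ascii_field(dig_max, 8)] * ns,
        [_ascii_field("", 80)] * ns,
        [_ascii_field(fs, 8)] * rec.n_channels + [_ascii_field(ann_nsamp, 8)],
        [_ascii_field("", 32)] * ns,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        for r in range(n_rec):
            for c in range(rec.n_channels):
                chunk = data[c, r * fs:(r + 1) * fs]
                dig = np.round(chunk / phys_max[c] * dig_max).astype("<i2")
                f.write(dig.tobytes())
            raw = tals[r].ljust(2 * ann_nsamp, b"\x00")
            f.write(raw[: 2 * ann_nsamp])
    return path


def read_csv_record(path, fs: Optional[float] = None) -> EEGRecord:
    """Read a generic CSV recording: one channel per column, header row.

    The sampling rate comes either from ``fs`` or from a ``<path>.json``
    sidecar with an ``fs`` key (the sidecar wins if both are given).
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs", fs)
    if fs is None:
        raise ParameterError(f"{path}: sampling rate not given and no sidecar")
    df = pd.read_csv(path)
    return EEGRecord(df.to_numpy().T, float(fs), list(df.columns),
                     subject_id=path.stem)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

_FILTER_ORDER = 4  # zero-phase Butterworth applied forward-backward


def _sos_filter(rec: EEGRecord, sos) -> EEGRecord:
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecord(out, rec.fs, list(rec.channel_names), rec.subject_id,
                     list(rec.annotations))


def bandpass_filter(rec: EEGRecord, lo: float, hi: float) -> EEGRecord:
    """Zero-phase order-4 Butterworth band-pass between ``lo`` and ``hi`` Hz.

    The default preprocessing band for scalp EEG is 0.1-70 Hz, wide enough to
    keep delta through gamma while removing drift and high-frequency noise.
    """
    nyq = rec.fs / 2
    if not (0 < lo < hi):
        raise ParameterError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ParameterError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(_FILTER_ORDER, [lo, hi], btype="bandpass", fs=rec.fs,
                     output="sos")
    return _sos_filter(rec, sos)


def highpass_filter(rec: EEGRecord, cutoff: float) -> EEGRecord:
    """Zero-phase order-4 Butterworth high-pass (drift/DC removal)."""
    nyq = rec.fs / 2
    if not 0 < cutoff:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if cutoff >= nyq:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(_FILTER_ORDER, cutoff, btype="highpass", fs=rec.fs,
                     output="sos")
    return _sos_filter(rec, sos)


def filter_frequency_response(kind: str, freqs, fs: float, *args):
    """|H(f)|^2-equivalent amplitude response of the filters above.

    Because the filters run forward-backward the effective amplitude response
    is the squared Butterworth magnitude.  Used as the analytic oracle when
    validating filter behaviour.
    """
    if kind == "bandpass":
        sos = sps.butter(_FILTER_ORDER, list(args), btype="bandpass", fs=fs,
                         output="sos")
    elif kind == "highpass":
        sos = sps.butter(_FILTER_ORDER, args[0], btype="highpass", fs=fs,
                         output="sos")
    else:
        raise ParameterError(f"unknown filter kind {kind!r}")
    _w, h = sps.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=fs)
    return np.abs(h) ** 2


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def annotation_overlap_labeler(positive_label: str = "seizure",
                               threshold: float = 0.5) -> Callable:
    """Build a window labeller from record annotations.

    A window is labelled positive (1) when annotated intervals carrying
    ``positive_label`` cover at least ``threshold`` of the window, else 0.
    """
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")

    def label_fn(rec: EEGRecord, t0: float, t1: float) -> int:
        covered = 0.0
        for onset, dur, lab in rec.annotations:
            if lab != positive_label:
                continue
            covered += max(0.0, min(t1, onset + dur) - max(t0, onset))
        return int(covered >= threshold * (t1 - t0) - 1e-12)

    return label_fn


def segment(rec: EEGRecord, spec: SegmentationSpec,
            label_fn: Optional[Callable] = None,
            class_names: Optional[Sequence[str]] = None) -> EpochSet:
    """Cut a recording into consecutive non-overlapping fixed-length epochs.

    Produces ``floor(duration / window_s)`` epochs of shape ``[T, C]`` with
    ``T = window_s * fs``; a trailing partial window is dropped.  ``label_fn``
    maps ``(record, t_start, t_end)`` to an integer class label; without one,
    every epoch is labelled 0.  A record shorter than one window yields an
    empty (zero-epoch) set.
    """
    if abs(spec.fs - rec.fs) > 1e-9:
        raise ParameterError(
            f"spec.fs={spec.fs} does not match record fs={rec.fs}"
        )
    if spec.channels != rec.n_channels:
        raise ParameterError(
            f"spec.channels={spec.channels} != record channels={rec.n_channels}"
        )
    T = spec.n_times
    n = rec.n_samples // T
    epochs = np.empty((n, T, rec.n_channels))
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        epochs[i] = rec.data[:, i * T:(i + 1) * T].T
        if label_fn is None:
            labels[i] = 0
        else:
            labels[i] = label_fn(rec, i * spec.window_s, (i + 1) * spec.window_s)
    if class_names is None:
        n_classes = int(labels.max()) + 1 if n else 1
        class_names = [f"class{i}" for i in range(max(n_classes, 1))]
    return EpochSet(epochs, labels, rec.fs, list(class_names),
                    [rec.subject_id] * n)


def concatenate_epochs(sets: Sequence[EpochSet]) -> EpochSet:
    """Stack EpochSets from several records (same geometry and classes)."""
    sets = [s for s in sets if len(s)]
    if not sets:
        raise DataError("no non-empty EpochSets to concatenate")
    ref = sets[0]
    for s in sets[1:]:
        if s.epochs.shape[1:] != ref.epochs.shape[1:] or s.fs != ref.fs:
            raise DataError("EpochSets have incompatible geometry")
    return EpochSet(
        np.concatenate([s.epochs for s in sets]),
        np.concatenate([s.labels for s in sets]),
        ref.fs,
        list(ref.class_names),
        [g for s in sets for g in s.group_ids],
    )


# ---------------------------------------------------------------------------
# Splits and folds
# ---------------------------------------------------------------------------

def _stratified_indices(labels: np.ndarray, train_frac: float, rng):
    """Largest-remainder stratified allocation.

    The per-class training counts are ``floor(frac * n_c)`` plus one extra
    for the classes with the largest fractional remainders until the overall
    total reaches ``round(frac * N)``; remainder ties break by class order.
    """
    n_total = len(labels)
    target = int(round(train_frac * n_total))
    classes = np.unique(labels)
    floors, rema = {}, {}
    for c in classes:
        n_c = int((labels == c).sum())
        exact = train_frac * n_c
        floors[c] = int(math.floor(exact))
        rema[c] = exact - floors[c]
    deficit = target - sum(floors.values())
    order = sorted(classes, key=lambda c: (-rema[c], c))
    take = dict(floors)
    for c in order[:max(deficit, 0)]:
        take[c] += 1
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        train_idx.extend(idx[: take[c]])
        test_idx.extend(idx[take[c]:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(
        np.array(test_idx, dtype=int))


def split_holdout(es: EpochSet, train_frac: float, seed: int):
    """Stratified random holdout split, reproducible under ``seed``.

    Returns ``(train, test)`` EpochSets that are disjoint and exhaustive with
    per-class proportions preserved by largest-remainder rounding.
    """
    if not 0 < train_frac < 1:
        raise ParameterError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    tr, te = _stratified_indices(es.labels, train_frac, rng)
    return es.subset(tr), es.subset(te)


def kfold(es: EpochSet, k: int, seed: int = 0, grouped: bool = False):
    """K-fold partition of epoch indices; grouped mode keeps each
    ``group_id`` (subject/record) inside a single fold to prevent leakage.

    Returns a list of ``(train_idx, test_idx)`` arrays whose test sets
    partition ``range(N)``.
    """
    from sklearn.model_selection import GroupKFold, KFold

    n = len(es)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if grouped:
        groups = np.asarray(es.group_ids)
        n_groups = len(np.unique(groups))
        if k > n_groups:
            raise ParameterError(f"k={k} exceeds number of groups {n_groups}")
        splitter = GroupKFold(n_splits=k)
        return [(tr, te) for tr, te in splitter.split(np.zeros(n), groups=groups)]
    if k > n:
        raise ParameterError(f"k={k} exceeds number of epochs {n}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n))]
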