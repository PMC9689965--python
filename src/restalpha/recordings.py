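"""Recording container plus EDF and fixture I/O.

A :class:`Recording` is one subject/run of multi-channel EEG: data in
microvolts, channels in the canonical montage order, and event annotations
stored in *samples* (seconds drift at odd sampling rates; samples do not).

EDF reading goes through :mod:`mne` and understands the PhysioNet motor
movement/imagery dialect (dotted channel labels, ``T0/T1/T2`` event codes,
run numbering that decides which task a ``T1``/``T2`` maps to).  Writing uses
a small self-contained EDF+C writer (16-bit samples, one-second records, a
TAL annotation track) sufficient for round-trip tests and fixture export.
"""

from __future__ import annotations

import json
import re
import warnings
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CHANNELS_64, canonical_order, normalize_label

FIXTURE_VERSION = 1

RUN_STATE = {1: "eyes_open", 2: "eyes_closed"}
# PhysioNet run numbering: 4, 8, 12 are imagined left/right-hand runs;
# 6, 10, 14 imagined hands/feet runs (3,7,11 / 5,9,13 are executed movement).
HAND_RUNS = {3, 4, 7, 8, 11, 12}
HANDS_FEET_RUNS = {5, 6, 9, 10, 13, 14}


class FixtureError(RuntimeError):
    """Raised when a fixture file is truncated, corrupt, or version-mismatched."""


@dataclass(frozen=True)
class Annotation:
    """One event: onset and duration in samples, plus a task label."""

    onset: int
    duration: int
    label: str


@dataclass
class Recording:
    subject_id: str
    run_id: str
    state: str  # eyes_open | eyes_closed | mi_run
    sample_rate: float
    channel_labels: tuple[str, ...]
    data: np.ndarray  # (channels, samples), microvolts
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.state not in ("eyes_open", "eyes_closed", "mi_run"):
            raise ValueError(f"unknown recording state {self.state!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channel rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN/Inf")
        for ann in self.annotations:
            if not 0 <= ann.onset < self.n_samples:
                raise ValueError(f"annotation onset {ann.onset} outside data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


def _decode_task_labels(descriptions, run_number: int | None):
    """Map PhysioNet T0/T1/T2 codes to task names; pass other labels through."""
    out = []
    for desc in descriptions:
        code = desc.strip()
        if code == "T0":
            out.append("rest")
        elif code in ("T1", "T2") and run_number is not None:
            if run_number in HAND_RUNS:
                out.append("left_hand" if code == "T1" else "right_hand")
            elif run_number in HANDS_FEET_RUNS:
                out.append("both_hands" if code == "T1" else "feet")
            else:
                out.append(code)
        else:
            out.append(code)
    return out


def read_edf(path, strict_montage: bool = True) -> Recording:
    """Read an EDF(+) file into a :class:`Recording`.

    Channel labels are normalized and the data rows reordered into the
    canonical montage order.  With ``strict_montage`` (default) a file whose
    channel set is not the canonical 64 raises, naming the offending labels.
    PhysioNet-style filenames (``S001R04.edf``) determine the run state and
    the ``T1``/``T2`` task mapping.
    """
    import mne

    path = str(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise IOError(f"cannot parse EDF file {path}: {exc}") from exc

    data_uv = raw.get_data() * 1e6  # mne loads volts
    labels = [normalize_label(name) for name in raw.ch_names]

    if strict_montage:
        order = canonical_order(labels)  # raises with missing/extra names
        data_uv = data_uv[order]
        labels = list(CHANNELS_64)

    m = re.search(r"S(\d+)R(\d+)", path.replace("\\", "/").split("/")[-1])
    subject_id = f"S{int(m.group(1)):03d}" if m else path.split("/")[-1]
    run_number = int(m.group(2)) if m else None
    state = RUN_STATE.get(run_number, "mi_run") if run_number is not None else "mi_run"

    fs = float(raw.info["sfreq"])
    tasks = _decode_task_labels(raw.annotations.description, run_number)
    annotations = [
        Annotation(
            onset=int(round(onset * fs)),
            duration=int(round(dur * fs)),
            label=label,
        )
        for onset, dur, label in zip(raw.annotations.onset, raw.annotations.duration, tasks)
        if int(round(onset * fs)) < data_uv.shape[1]
    ]
    return Recording(
        subject_id=subject_id,
        run_id=f"R{run_number:02d}" if run_number is not None else "R??",
        state=state,
        sample_rate=fs,
        channel_labels=tuple(labels),
        data=data_uv,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# minimal EDF+C writer


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(recording: Recording, path) -> None:
    """Write a Recording as EDF+C with a TAL annotation track.

    Samples are quantized to 16 bits over a symmetric physical range covering
    the data, one data record per second.  The recording length must be a
    whole number of seconds and the sampling rate an integer (both true for
    everything this package generates).
    """
    fs = recording.sample_rate
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records, rem = divmod(recording.n_samples, fs)
    if rem:
        raise ValueError("EDF writer requires a whole number of 1-s records")

    amax = float(np.abs(recording.data).max())
    phys = max(np.ceil(amax), 1.0)
    # EDF affine mapping: phys = (dig - digmin) * slope + physmin
    slope = 2 * phys / 65535.0
    digital = np.clip(
        np.round((recording.data + phys) / slope) - 32768, -32768, 32767
    ).astype("<i2")

    ns = recording.n_channels + 1  # + annotation track
    ann_samples = 32  # 64 bytes of TAL space per record

    header = b""
    header += _pad("0", 8)
    header += _pad(f"X X X {recording.subject_id}", 80)
    header += _pad(f"Startdate 01-JAN-2000 X X {recording.run_id}", 80)
    header += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("EDF+C", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration, seconds
    header += _pad(str(ns), 4)

    labels = [f"EEG {ch}" for ch in recording.channel_labels] + ["EDF Annotations"]
    header += b"".join(_pad(lb, 16) for lb in labels)
    header += b"".join(_pad("", 80) for _ in range(ns))  # transducer
    header += b"".join(_pad("uV", 8) for _ in recording.channel_labels) + _pad("", 8)
    header += b"".join(_pad(f"{-phys:g}", 8) for _ in recording.channel_labels) + _pad("-1", 8)
    header += b"".join(_pad(f"{phys:g}", 8) for _ in recording.channel_labels) + _pad("1", 8)
    header += b"".join(_pad("-32768", 8) for _ in range(ns))
    header += b"".join(_pad("32767", 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_pad(str(fs), 8) for _ in recording.channel_labels)
    header += _pad(str(ann_samples), 8)
    header += b"".join(_pad("", 32) for _ in range(ns))

    # annotations bucketed into their record, onsets printed in seconds
    by_record: dict[int, list[Annotation]] = {}
    for ann in recording.annotations:
        by_record.setdefault(int(ann.onset // fs), []).append(ann)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            fh.write(digital[:, rec * fs : (rec + 1) * fs].tobytes(order="C"))
            tals = [f"+{rec}\x14\x14".encode("ascii")]
            for ann in by_record.get(rec, []):
                onset_s = ann.onset / fs
                dur_s = ann.duration / fs
                tals.append(
                    f"+{onset_s:.6g}\x15{dur_s:.6g}\x14{ann.label}\x14".encode("ascii")
                )
            tal = b"\x00".join(tals) + b"\x00"
            if len(tal) > 2 * ann_samples:
                raise ValueError("too many annotations in one 1-s record")
            fh.write(tal.ljust(2 * ann_samples, b"\x00"))


def edf_quantization_step(recording: Recording) -> float:
    """Worst-case amplitude error of one EDF round trip of ``recording``."""
    phys = max(np.ceil(float(np.abs(recording.data).max())), 1.0)
    return 2 * phys / 65535.0


# ---------------------------------------------------------------------------
# internal fixture format: a zip (numpy .npz) with a JSON header entry


def write_fixture(recording: Recording, path) -> None:
    header = {
        "fixture_version": FIXTURE_VERSION,
        "subject_id": recording.subject_id,
        "run_id": recording.run_id,
        "state": recording.state,
        "sample_rate": recording.sample_rate,
        "channel_labels": list(recording.channel_labels),
        "annotations": [
            [a.onset, a.duration, a.label] for a in recording.annotations
        ],
    }
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header).encode("utf-8"), dtype=np.uint8),
        data=recording.data,
    )


def read_fixture(path) -> Recording:
    try:
        with np.load(path) as npz:
            header = json.loads(npz["header"].tobytes().decode("utf-8"))
            data = npz["data"]
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
        raise FixtureError(f"corrupt or truncated fixture {path}: {exc}") from exc
    version = header.get("fixture_version")
    if version != FIXTURE_VERSION:
        raise FixtureError(
            f"fixture version mismatch: file has {version}, reader supports {FIXTURE_VERSION}"
        )
    return Recording(
        subject_id=header["subject_id"],
        run_id=header["run_id"],
        state=header["state"],
        sample_rate=header["sample_rate"],
        channel_labels=tuple(header["channel_labels"]),
        data=data,
        annotations=[Annotation(int(o), int(d), lb) for o, d, lb in header["annotations"]],
    )
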