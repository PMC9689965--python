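"""Common average reference, Butterworth band filtering, segmentation.

The band layout partitions 4-50 Hz into the four classical EEG rhythms;
band powers computed after these filters therefore sum (approximately) to
the broadband 4-50 Hz power, which is what the relative-power feature
normalizes by.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, sosfiltfilt

from .recordings import Recording

log = logging.getLogger(__name__)

MI_CLASSES = ("left_hand", "right_hand", "both_hands", "feet")

#: Epoch length for resting runs, in samples (9.375 s at 160 Hz).
EPOCH_LEN = 1500

#: Default single-trial window for motor-imagery runs: 4 s at 160 Hz.
MI_WINDOW = 640

DEFAULT_FILTER_ORDER = 4


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")

    def validate(self, sample_rate: float) -> None:
        if self.high >= sample_rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz >= Nyquist "
                f"({sample_rate / 2} Hz)"
            )


#: The four analysis rhythms; they partition the 4-50 Hz range.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)
BAND_NAMES = tuple(b.name for b in BANDS)

#: Band used for motor-imagery classification (mu + beta).
MI_BAND = BandDefinition("mu_beta", 8.0, 30.0)


@dataclass
class EpochSet:
    """Consecutive fixed-length resting epochs: (n_epochs, channels, samples)."""

    subject_id: str
    state: str
    epochs: np.ndarray
    sample_rate: float
    channel_labels: tuple[str, ...]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class TrialSet:
    """Labeled MI trials: trials (n, channels, samples), labels length n."""

    subject_id: str
    trials: np.ndarray
    labels: np.ndarray  # array of strings from MI_CLASSES
    sample_rate: float
    channel_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n, channels, samples)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("one label per trial required")
        unknown = set(np.unique(self.labels)) - set(MI_CLASSES)
        if unknown:
            raise ValueError(f"unknown MI class labels {sorted(unknown)!r}")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def apply_car(recording: Recording) -> Recording:
    """Common average reference: subtract the instantaneous channel mean."""
    if recording.n_channels < 2:
        raise ValueError("CAR needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.copy_with(data=data)


def bandpass_array(
    data: np.ndarray,
    sample_rate: float,
    band: BandDefinition,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    band.validate(sample_rate)
    sos = butter(order, [band.low, band.high], btype="bandpass", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, data, axis=-1)


def bandpass(obj, band: BandDefinition, order: int = DEFAULT_FILTER_ORDER):
    """Band-pass a Recording, EpochSet, TrialSet, or plain array (last axis)."""
    if isinstance(obj, Recording):
        return obj.copy_with(data=bandpass_array(obj.data, obj.sample_rate, band, order))
    if isinstance(obj, EpochSet):
        return EpochSet(
            obj.subject_id,
            obj.state,
            bandpass_array(obj.epochs, obj.sample_rate, band, order),
            obj.sample_rate,
            obj.channel_labels,
        )
    if isinstance(obj, TrialSet):
        return TrialSet(
            obj.subject_id,
            bandpass_array(obj.trials, obj.sample_rate, band, order),
            obj.labels,
            obj.sample_rate,
            obj.channel_labels,
        )
    raise TypeError(f"cannot band-pass object of type {type(obj).__name__}")


def epoch_rest(recording: Recording, epoch_len: int = EPOCH_LEN) -> EpochSet:
    """Cut a resting recording into consecutive non-overlapping epochs.

    Epochs start at sample 0; the trailing remainder shorter than one epoch
    is discarded (a one-minute 160 Hz run of 9600 samples yields 6 epochs).
    """
    n = recording.n_samples
    if n < epoch_len:
        raise ValueError(
            f"recording of {n} samples shorter than one {epoch_len}-sample epoch"
        )
    n_epochs = n // epoch_len
    epochs = (
        recording.data[:, : n_epochs * epoch_len]
        .reshape(recording.n_channels, n_epochs, epoch_len)
        .transpose(1, 0, 2)
        .copy()
    )
    return EpochSet(
        recording.subject_id,
        recording.state,
        epochs,
        recording.sample_rate,
        tuple(recording.channel_labels),
    )


def extract_mi_trials(recording: Recording, window: int = MI_WINDOW) -> TrialSet:
    """Cut one trial of ``window`` samples from each non-rest annotation.

    Trials whose window would run past the end of the record are dropped with
    a warning, as are annotations the 4-class task set does not cover.
    """
    trials, labels = [], []
    n_rest = 0
    for ann in recording.annotations:
        if ann.label == "rest" or ann.label == "T0":
            n_rest += 1
            continue
        if ann.label not in MI_CLASSES:
            warnings.warn(f"skipping annotation with unknown task {ann.label!r}")
            continue
        if ann.onset + window > recording.n_samples:
            warnings.warn(
                f"dropping trial at sample {ann.onset}: window of {window} samples "
                f"extends past the end of {recording.subject_id}/{recording.run_id}"
            )
            continue
        trials.append(recording.data[:, ann.onset : ann.onset + window])
        labels.append(ann.label)
    if not trials:
        warnings.warn(
            f"{recording.subject_id}/{recording.run_id}: no task annotations, "
            "returning an empty trial set"
        )
        trials_arr = np.empty((0, recording.n_channels, window))
    else:
        trials_arr = np.stack(trials)
    return TrialSet(
        recording.subject_id,
        trials_arr,
        np.asarray(labels, dtype=object),
        recording.sample_rate,
        tuple(recording.channel_labels),
    )


def merge_trial_sets(trial_sets: list[TrialSet]) -> TrialSet:
    """Concatenate trial sets from several runs of one subject."""
    if not trial_sets:
        raise ValueError("no trial sets to merge")
    first = trial_sets[0]
    return TrialSet(
        first.subject_id,
        np.concatenate([ts.trials for ts in trial_sets]),
        np.concatenate([ts.labels for ts in trial_sets]),
        first.sample_rate,
        first.channel_labels,
    )
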