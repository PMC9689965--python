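"""Canonical 64-channel 10-10 montage used throughout the pipeline.

The channel set and order match the BCI2000 64-electrode layout used by the
PhysioNet motor movement/imagery recordings.  On-disk EDF labels in that
dataset carry trailing dots and inconsistent case (``"C3.."``, ``"FC3."``,
``"AFz."``); :func:`normalize_label` maps them onto the canonical names.
"""

from __future__ import annotations

# Frontocentral / central / centroparietal rows first (the sensorimotor strip),
# then the outer rows — this fixed order is the canonical in-memory order.
CHANNELS_64: tuple[str, ...] = (
    "Fc5", "Fc3", "Fc1", "Fcz", "Fc2", "Fc4", "Fc6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "Cp5", "Cp3", "Cp1", "Cpz", "Cp2", "Cp4", "Cp6",
    "Fp1", "Fpz", "Fp2",
    "Af7", "Af3", "Afz", "Af4", "Af8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "Ft7", "Ft8",
    "T7", "T8", "T9", "T10",
    "Tp7", "Tp8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "Po7", "Po3", "Poz", "Po4", "Po8",
    "O1", "Oz", "O2", "Iz",
)

#: Channels over the motor cortex used for the focused association analysis.
MOTOR_CORTEX: tuple[str, ...] = (
    "Fz", "Fc3", "Fc4", "C3", "C4", "C5", "C6",
    "Cp3", "Cp4", "Cp5", "Cp6", "Cpz",
)

#: Posterior channels that carry the extra eyes-closed alpha rhythm.
POSTERIOR: tuple[str, ...] = (
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "Po7", "Po3", "Poz", "Po4", "Po8",
    "O1", "Oz", "O2", "Iz",
)

_CANONICAL = {name.upper(): name for name in CHANNELS_64}


def normalize_label(label: str) -> str:
    """Map a raw EDF channel label onto its canonical montage name.

    Strips the PhysioNet trailing-dot padding and normalizes case
    (``"FC3."`` -> ``"Fc3"``, ``"C3.."`` -> ``"C3"``).  Labels outside the
    montage are returned dot-stripped and capitalized, so callers can report
    them by name.
    """
    stripped = label.strip().strip(".")
    if stripped.upper().startswith("EEG ") or stripped.upper().startswith("EEG-"):
        stripped = stripped[4:].strip()
    return _CANONICAL.get(stripped.upper(), stripped.capitalize())


def canonical_order(labels: list[str]) -> list[int]:
    """Indices that reorder ``labels`` (already normalized) canonically.

    Raises ``ValueError`` naming missing/unknown channels when ``labels`` is
    not exactly the canonical 64-channel set.
    """
    normalized = [normalize_label(lb) for lb in labels]
    missing = [ch for ch in CHANNELS_64 if ch not in normalized]
    extra = [ch for ch in normalized if ch not in CHANNELS_64]
    if missing or extra:
        raise ValueError(
            f"channel set does not match the canonical 64-channel montage; "
            f"missing={missing!r} unexpected={extra!r}"
        )
    pos = {ch: i for i, ch in enumerate(normalized)}
    return [pos[ch] for ch in CHANNELS_64]
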