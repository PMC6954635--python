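"""Electrode montages of the two consumer EEG headsets and their canonical union.

The 5-electrode headset (dry electrodes) and the 14-electrode headset
(saline electrodes) share AF3, AF4, P7 and P8.  Downstream processing pads
every recording to the 15-channel union so that a single network
architecture serves both devices; missing electrodes become zero-filled
placeholder channels.
"""

from __future__ import annotations

#: 5-electrode headset montage (plus one reference electrode, not recorded).
INSIGHT_5: tuple[str, ...] = ("AF3", "AF4", "P7", "P8", "Pz")

#: 14-electrode headset montage, in the vendor's channel order.
EPOC_14: tuple[str, ...] = (
    "AF3", "AF4", "F7", "F3", "FC5", "T7", "P7",
    "O1", "O2", "P8", "T8", "FC6", "F4", "F8",
)

#: Canonical 15-channel union, fixed ordering used for harmonized signals.
CANONICAL_15: tuple[str, ...] = (
    "AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6",
    "O1", "O2", "P7", "P8", "Pz", "T7", "T8",
)

#: Headset identifier (electrode count) -> montage.
HEADSET_CHANNELS: dict[int, tuple[str, ...]] = {5: INSIGHT_5, 14: EPOC_14}

#: Default EEG sampling rate of both headsets, Hz.
EEG_SAMPLING_RATE: float = 128.0


def headset_for_labels(labels) -> int:
    """Identify the headset from a set of electrode labels (case-insensitive).

    Returns 5 or 14.  Raises ``ValueError`` if the label set matches neither
    montage.
    """
    norm = {str(c).strip().lower() for c in labels}
    for headset, chans in HEADSET_CHANNELS.items():
        if norm == {c.lower() for c in chans}:
            return headset
    raise ValueError(
        f"electrode labels {sorted(norm)} match neither the 5-electrode nor "
        f"the 14-electrode headset"
    )
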