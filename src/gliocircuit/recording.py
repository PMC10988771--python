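"""In-memory containers for intraoperative ECoG data.

An :class:`EcogRecording` is the unit every preprocessing stage consumes and
returns: a channels x samples voltage array (microvolts) with its sampling
rate, a channel table mapping each channel to an electrode strip, trial
markers in sample units, and a provenance trail of applied steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError

CONDITIONS = ("rest", "easy", "hard")

#: seconds trimmed from (start, end) of each trial, by condition, to absorb
#: manual-marker reaction-time error; hard trials additionally lose the
#: initial easy phase of the switch task.
TRIM_SECONDS = {"rest": (2.0, 2.0), "easy": (1.0, 1.0), "hard": (1.0 + 3.0, 1.0)}


def make_channel_table(channel_ids, strip_ids, index_in_strip=None) -> pd.DataFrame:
    """Build the canonical channel table (channel_id, strip_id, index_in_strip)."""
    df = pd.DataFrame({"channel_id": list(channel_ids), "strip_id": list(strip_ids)})
    if index_in_strip is None:
        df["index_in_strip"] = df.groupby("strip_id").cumcount()
    else:
        df["index_in_strip"] = list(index_in_strip)
    if df["channel_id"].duplicated().any():
        raise FormatError("duplicate channel ids")
    return df


def make_marker_table(trial_ids, conditions, onsets, offsets) -> pd.DataFrame:
    """Build and validate the marker table (sample units), sorted by onset."""
    df = pd.DataFrame(
        {
            "trial_id": list(trial_ids),
            "condition": list(conditions),
            "onset": np.asarray(onsets, dtype=np.int64),
            "offset": np.asarray(offsets, dtype=np.int64),
        }
    )
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"unknown condition label(s): {sorted(bad)}")
    if (df["onset"] >= df["offset"]).any():
        raise RangeError("marker onset must precede offset")
    return df.sort_values("onset", kind="stable").reset_index(drop=True)


@dataclass
class EcogRecording:
    """Multichannel ECoG voltages with channel/strip layout and trial markers.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : DataFrame
        Columns ``channel_id``, ``strip_id``, ``index_in_strip``.
    markers : DataFrame
        Columns ``trial_id``, ``condition``, ``onset``, ``offset`` (samples,
        half-open interval [onset, offset)), sorted by onset.
    provenance : list of str
        Names of processing steps applied so far, in order.
    """

    data: np.ndarray
    fs: float
    channels: pd.DataFrame
    markers: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise FormatError(
                f"channel table has {len(self.channels)} rows for {self.data.shape[0]} channels"
            )
        if len(self.markers) and int(self.markers["offset"].max()) > self.n_samples:
            raise RangeError("marker offset beyond end of recording")
        if len(self.markers) and int(self.markers["onset"].min()) < 0:
            raise RangeError("negative marker onset")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_ids(self) -> list:
        return list(self.channels["channel_id"])

    def with_(self, **kwargs) -> "EcogRecording":
        """Copy with replaced fields; appends ``step`` to provenance if given."""
        step = kwargs.pop("step", None)
        out = replace(self, **kwargs)
        if step is not None:
            out.provenance = list(self.provenance) + [step]
        return out


@dataclass
class SegmentedPower:
    """Instantaneous band power cut into trimmed, condition-labelled trials.

    ``trials`` preserves recorded order; ``data[i]`` is the (n_channels,
    n_samples_i) power block of trial i.  Power is in microvolt-squared units.
    """

    channel_ids: list
    trials: pd.DataFrame  # trial_id, condition, n_samples
    data: list  # list of (n_channels, n_i) arrays, parallel to trials rows
    band: tuple
    band_name: str
    fs: float

    def __post_init__(self) -> None:
        if len(self.data) != len(self.trials):
            raise FormatError("one power block per trial row required")
        for block, n in zip(self.data, self.trials["n_samples"]):
            if block.shape != (len(self.channel_ids), int(n)):
                raise FormatError("power block shape disagrees with trial table")
            if np.any(block < 0):
                raise ValueError("instantaneous power must be non-negative")

    @property
    def conditions(self) -> list:
        return sorted(set(self.trials["condition"]))

    def condition_blocks(self, condition: str) -> list:
        """Power blocks of all trials of one condition, in recorded order."""
        idx = np.flatnonzero((self.trials["condition"] == condition).to_numpy())
        return [self.data[i] for i in idx]
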