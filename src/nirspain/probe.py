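"""Probe geometry, channel definitions, events, and behavioral tables.

A *channel* is one emitter-detector pair; the default study layout has
8 emitters and 28 detectors at 3 cm separation yielding 45 channels, each
mapped to an anatomical label.  Channel ordering is canonical throughout the
package: channels are sorted by (emitter id, detector id) and every matrix
(activation, connectivity) indexes channels in that order.

Time is expressed in seconds from recording start; events and session phases
are half-open intervals ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Recognised anatomical labels for the region map.
REGION_LABELS = (
    "aPFC",
    "DLPFC",
    "PMC",
    "SMA",
    "M1",
    "S1",
    "V1",
    "STG",
    "TPJ",
    "IPL",
    "other",
)

GROUPS = ("TMB", "VRB")

SESSION_PHASES = ("rest_pre", "breathing", "tqst", "rest_post")

#: Thermode ramp floor and ceiling (degC) of the thermal QST paradigm.
TQST_BASELINE_C = 30.0
TQST_CEILING_C = 50.0


class FormatError(ValueError):
    """A recording or table violates the container format or an invariant."""


@dataclass(frozen=True)
class ProbeLayout:
    """Optode montage: emitter-detector pairs, wavelengths, region labels.

    Parameters
    ----------
    channels
        Ordered (emitter id, detector id) pairs; must be sorted by
        (emitter, detector).  Channel ids are 1-based positions in this list.
    wavelengths
        Wavelengths in nm; defaults to the 690/830 nm pair.
    nominal_separation
        Emitter-detector distance in mm.
    region_map
        Mapping channel id -> anatomical label; must cover every channel
        exactly once.
    """

    emitters: tuple[int, ...]
    detectors: tuple[int, ...]
    channels: tuple[tuple[int, int], ...]
    wavelengths: tuple[float, ...] = (690.0, 830.0)
    nominal_separation: float = 30.0
    region_map: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.channels) != sorted(self.channels):
            raise FormatError("channels must be sorted by (emitter, detector)")
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("duplicate emitter-detector pair in channels")
        for e, d in self.channels:
            if e not in self.emitters:
                raise FormatError(f"channel references unknown emitter {e}")
            if d not in self.detectors:
                raise FormatError(f"channel references unknown detector {d}")
        ids = set(self.channel_ids)
        mapped = set(self.region_map)
        if mapped != ids:
            missing = sorted(ids - mapped)
            extra = sorted(mapped - ids)
            raise FormatError(
                f"region_map must cover every channel exactly once "
                f"(missing {missing}, extra {extra})"
            )
        bad = {r for r in self.region_map.values() if r not in REGION_LABELS}
        if bad:
            raise FormatError(
                f"unknown region labels {sorted(bad)}; valid: {REGION_LABELS}"
            )
        if len(self.wavelengths) < 2:
            raise FormatError("at least two wavelengths required")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        """1-based channel ids in canonical order."""
        return tuple(range(1, len(self.channels) + 1))

    def separation_cm(self) -> float:
        return self.nominal_separation / 10.0


def default_layout() -> ProbeLayout:
    """The packaged 45-channel, 8-emitter/28-detector study layout."""
    ref = resources.files("nirspain").joinpath("data/default_layout.yaml")
    data = yaml.safe_load(ref.read_text())
    pairs = tuple((int(e), int(d)) for e, d in data["pairs"])
    return ProbeLayout(
        emitters=tuple(sorted({e for e, _ in pairs})),
        detectors=tuple(sorted({d for _, d in pairs})),
        channels=pairs,
        wavelengths=tuple(float(w) for w in data["wavelengths_nm"]),
        nominal_separation=float(data["nominal_separation_mm"]),
        region_map={int(k): str(v) for k, v in data["region_map"].items()},
    )


def region_channels(layout: ProbeLayout, region: str) -> list[int]:
    """Channel ids mapped to ``region`` (possibly empty for a valid label).

    Raises
    ------
    KeyError
        If ``region`` is not a recognised anatomical label.
    """
    if region not in REGION_LABELS:
        raise KeyError(
            f"unknown region {region!r}; valid labels: {', '.join(REGION_LABELS)}"
        )
    return [ch for ch in layout.channel_ids if layout.region_map[ch] == region]


@dataclass
class EventDesign:
    """Stimulus events: onsets and durations in seconds plus condition labels."""

    onsets: np.ndarray
    durations: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.onsets) == len(self.durations) == len(self.labels)):
            raise FormatError("onsets, durations and labels must be equal length")
        for cond in set(self.labels):
            mask = [lab == cond for lab in self.labels]
            if np.any(np.diff(self.onsets[mask]) <= 0):
                raise FormatError(
                    f"onsets must be strictly increasing within condition "
                    f"{cond!r}"
                )
        if np.any(self.durations <= 0):
            raise FormatError("durations must be positive")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def end_time(self) -> float:
        if not len(self.onsets):
            return 0.0
        return float(np.max(self.onsets + self.durations))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets, "duration_s": self.durations, "label": self.labels}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventDesign":
        return cls(
            onsets=df["onset_s"].to_numpy(float),
            durations=df["duration_s"].to_numpy(float),
            labels=[str(x) for x in df["label"]],
        )


@dataclass
class RawIntensityRecording:
    """Two-wavelength raw intensity time series for one subject and session.

    ``intensities`` has shape (n_channels, n_wavelengths, n_times) and holds
    strictly positive detector counts (positivity is required by the log
    transform to optical density).  ``phases`` maps session phase labels to
    half-open (start_s, stop_s) windows.
    """

    layout: ProbeLayout
    sampling_rate: float
    intensities: np.ndarray
    events: EventDesign
    subject: str
    group: str
    visit: int
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        n_ch, n_wl, _ = self._check_shape()
        if n_ch != self.layout.n_channels:
            raise FormatError(
                f"intensities have {n_ch} channels but layout defines "
                f"{self.layout.n_channels}"
            )
        if n_wl != len(self.layout.wavelengths):
            raise FormatError(
                f"intensities have {n_wl} wavelengths but layout defines "
                f"{len(self.layout.wavelengths)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("intensities contain non-finite values")
        if np.any(self.intensities <= 0):
            ch, wl, t = np.argwhere(self.intensities <= 0)[0]
            raise FormatError(
                f"non-positive intensity at channel {ch + 1}, wavelength index "
                f"{wl}, sample {t} (log transform requires positive counts)"
            )
        if self.group not in GROUPS:
            raise FormatError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.visit not in (1, 2):
            raise FormatError(f"visit must be 1 or 2, got {self.visit!r}")
        if len(self.events.onsets) and self.events.end_time() > self.duration + 1e-9:
            raise FormatError(
                f"events extend to {self.events.end_time():.2f} s beyond the "
                f"recording duration {self.duration:.2f} s"
            )
        for name, (start, stop) in self.phases.items():
            if not 0 <= start < stop <= self.duration + 1e-9:
                raise FormatError(
                    f"phase {name!r} window ({start}, {stop}) outside recording"
                )

    def _check_shape(self) -> tuple[int, int, int]:
        if self.intensities.ndim != 3:
            raise FormatError(
                "intensities must be (channels, wavelengths, time), got "
                f"shape {self.intensities.shape}"
            )
        return self.intensities.shape

    @property
    def n_times(self) -> int:
        return self.intensities.shape[2]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.sampling_rate

    def phase_slice(self, phase: str) -> slice:
        """Sample slice for a named session phase (half-open window)."""
        if phase not in self.phases:
            raise KeyError(
                f"phase {phase!r} not in recording (has {sorted(self.phases)})"
            )
        start, stop = self.phases[phase]
        i0 = int(np.ceil(start * self.sampling_rate - 1e-9))
        i1 = int(np.ceil(stop * self.sampling_rate - 1e-9))
        return slice(i0, min(i1, self.n_times))


BEHAVIOR_COLUMNS = ("subject", "group", "visit", "mean_threshold_c")


@dataclass
class BehavioralTable:
    """Per subject x visit behavioral outcomes, keyed like the recordings.

    The response of the brain-behavior analysis is ``mean_threshold_c``, the
    average thermal pain threshold over the 20 tQST trials, bounded by the
    thermode ramp floor (30 degC) and ceiling (50 degC).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"behavioral table missing columns {missing}")
        if df.duplicated(subset=["subject", "visit"]).any():
            raise FormatError("behavioral table has duplicate subject x visit rows")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group labels {sorted(bad_group)}")
        thr = df["mean_threshold_c"].to_numpy(float)
        if np.any(thr < TQST_BASELINE_C) or np.any(thr > TQST_CEILING_C):
            raise FormatError(
                f"mean_threshold_c outside the thermode range "
                f"[{TQST_BASELINE_C}, {TQST_CEILING_C}] degC"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehavioralTable":
        return cls(pd.read_csv(path))


def make_layout(
    n_emitters: int,
    n_detectors: int,
    channels: Sequence[tuple[int, int]],
    region_map: Mapping[int, str] | None = None,
    wavelengths: Sequence[float] = (690.0, 830.0),
    nominal_separation: float = 30.0,
) -> ProbeLayout:
    """Convenience constructor; unlabeled channels default to ``other``."""
    pairs = tuple(sorted((int(e), int(d)) for e, d in channels))
    rmap = dict(region_map or {})
    for ch in range(1, len(pairs) + 1):
        rmap.setdefault(ch, "other")
    return ProbeLayout(
        emitters=tuple(range(1, n_emitters + 1)),
        detectors=tuple(range(1, n_detectors + 1)),
        channels=pairs,
        wavelengths=tuple(wavelengths),
        nominal_separation=nominal_separation,
        region_map=rmap,
    )
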