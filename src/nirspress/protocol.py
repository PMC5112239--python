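"""Probe geometry, channel roles and the pseudo-randomized stimulus protocol.

The probe array is an 18-channel multi-distance continuous-wave layout over
the supplementary motor area (SMA, channels 1-6) and the primary
somatosensory cortex (S1, channels 7-18).  Channels 2 and 10 are
short-separation channels (~11 mm source-detector distance) that sample only
the superficial scalp compartment; they feed the short-separation regression
and are excluded from cortical statistics.  All long channels have
separations between 25 and 45 mm.

The stimulus protocol is a 5 min rest baseline followed by 45 trials (three
conditions - painful pressure ``PAPain``, non-painful pressure ``PAnP`` and
tactile ``Brush`` - applied 15 times each) of 5 s duration with a 15 s
inter-stimulus interval, in a pseudo-randomized order with no more than two
equal consecutive trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CONDITIONS = ("PAPain", "PAnP", "Brush")

#: Default short-channel -> long-channel correction routing.
DEFAULT_SSR_MAP = {
    2: (1, 3, 4, 5, 6),
    10: (7, 8, 9, 11, 12, 13, 14, 15, 16, 17, 18),
}

SAMPLING_RATE = 7.81  # Hz


@dataclass(frozen=True)
class Channel:
    id: int  # 1-based, as in all reports
    source: int
    detector: int
    separation_mm: float
    roi: str  # "SMA" or "S1"
    hemisphere: str  # "left" / "right" / "midline"
    is_short: bool = False


@dataclass(frozen=True)
class ProbeLayout:
    """Channel table plus the SSR routing and acquisition constants."""

    channels: tuple[Channel, ...]
    ssr_map: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SSR_MAP.items()}
    )
    wavelengths: tuple[float, float] = (760.0, 850.0)
    sampling_rate: float = SAMPLING_RATE

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ----------------------------------------------------------
    @property
    def channel_ids(self) -> list[int]:
        return [c.id for c in self.channels]

    @property
    def short_channel_ids(self) -> list[int]:
        return [c.id for c in self.channels if c.is_short]

    @property
    def long_channel_ids(self) -> list[int]:
        return [c.id for c in self.channels if not c.is_short]

    def channel(self, channel_id: int) -> Channel:
        for c in self.channels:
            if c.id == channel_id:
                return c
        raise KeyError(f"no channel with id {channel_id}")

    def index(self, channel_id: int) -> int:
        """Row index of a 1-based channel id in data arrays."""
        return self.channel_ids.index(channel_id)

    def separation_cm(self, channel_id: int) -> float:
        return self.channel(channel_id).separation_mm / 10.0

    def short_for(self, long_id: int) -> int:
        for short, longs in self.ssr_map.items():
            if long_id in longs:
                return short
        raise KeyError(f"channel {long_id} has no short-separation channel assigned")

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        ids = self.channel_ids
        if len(set(ids)) != len(ids):
            raise ValueError("channel ids must be unique")
        shorts = self.short_channel_ids
        for c in self.channels:
            if c.is_short and not (8.0 <= c.separation_mm <= 15.0):
                raise ValueError(
                    f"short channel {c.id} separation {c.separation_mm} mm not ~11 mm"
                )
            if not c.is_short and not (25.0 <= c.separation_mm <= 45.0):
                raise ValueError(
                    f"long channel {c.id} separation {c.separation_mm} mm outside 25-45 mm"
                )
        covered: list[int] = []
        for short, longs in self.ssr_map.items():
            if short not in shorts:
                raise ValueError(f"ssr_map key {short} is not a short channel")
            covered.extend(longs)
        longs_all = self.long_channel_ids
        if sorted(covered) != sorted(longs_all):
            raise ValueError("ssr_map must cover every long channel exactly once")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "wavelengths": list(self.wavelengths),
            "sampling_rate": self.sampling_rate,
            "ssr_map": {str(k): list(v) for k, v in self.ssr_map.items()},
            "channels": [
                {
                    "id": c.id,
                    "source": c.source,
                    "detector": c.detector,
                    "separation_mm": c.separation_mm,
                    "roi": c.roi,
                    "hemisphere": c.hemisphere,
                    "is_short": c.is_short,
                }
                for c in self.channels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeLayout":
        return cls(
            channels=tuple(Channel(**c) for c in d["channels"]),
            ssr_map={int(k): tuple(v) for k, v in d["ssr_map"].items()},
            wavelengths=tuple(d.get("wavelengths", (760.0, 850.0))),
            sampling_rate=float(d.get("sampling_rate", SAMPLING_RATE)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProbeLayout":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# Hemisphere defaults: the source study reports ROI membership per channel
# (1-6 SMA, 7-18 S1) but not a left/right assignment; this split is a
# configurable convention, not a claim about the original montage.
_HEMI = {
    1: "left", 2: "midline", 3: "left", 4: "right", 5: "right", 6: "right",
    7: "left", 8: "left", 9: "left", 10: "midline", 11: "left", 12: "left",
    13: "left", 14: "right", 15: "right", 16: "right", 17: "right", 18: "right",
}

# Long separations spread over the reported 25-45 mm range (exact per-channel
# optode coordinates are not published); shorts fixed at 11 mm.
_SEP_MM = {
    1: 30.0, 2: 11.0, 3: 30.0, 4: 30.0, 5: 35.0, 6: 35.0,
    7: 30.0, 8: 30.0, 9: 35.0, 10: 11.0, 11: 30.0, 12: 30.0,
    13: 35.0, 14: 30.0, 15: 30.0, 16: 35.0, 17: 35.0, 18: 30.0,
}


def build_default_layout() -> ProbeLayout:
    """The 18-channel default montage (8 sources x 8 detectors).

    Channels 1-6 cover the SMA, 7-18 the S1; channels 2 and 10 are the
    short-separation channels of the two regions.
    """
    channels = []
    for cid in range(1, 19):
        roi = "SMA" if cid <= 6 else "S1"
        src = (cid - 1) % 8 + 1           # 8 sources
        det = (cid * 3) % 8 + 1           # 8 detectors
        channels.append(
            Channel(
                id=cid,
                source=src,
                detector=det,
                separation_mm=_SEP_MM[cid],
                roi=roi,
                hemisphere=_HEMI[cid],
                is_short=cid in (2, 10),
            )
        )
    return ProbeLayout(channels=tuple(channels))


@dataclass(frozen=True)
class StimulusProtocol:
    """Event timing of the block-design experiment."""

    baseline_s: float = 300.0
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 15
    stimulus_s: float = 5.0
    isi_s: float = 15.0
    max_consecutive_repeats: int = 2
    sequence: tuple[str, ...] = ()

    @property
    def trial_period_s(self) -> float:
        return self.stimulus_s + self.isi_s

    @property
    def n_trials(self) -> int:
        return len(self.conditions) * self.trials_per_condition

    @property
    def total_duration_s(self) -> float:
        return self.baseline_s + self.n_trials * self.trial_period_s

    def onsets(self) -> np.ndarray:
        """Onset time (s) of trial k = baseline + k * (stimulus + ISI)."""
        return self.baseline_s + np.arange(self.n_trials) * self.trial_period_s

    def events(self) -> pd.DataFrame:
        if len(self.sequence) != self.n_trials:
            raise ValueError("protocol has no complete stimulus sequence")
        return pd.DataFrame(
            {
                "onset_s": self.onsets(),
                "duration_s": self.stimulus_s,
                "condition": list(self.sequence),
            }
        )

    def with_sequence(self, sequence) -> "StimulusProtocol":
        return replace(self, sequence=tuple(sequence))

    def to_dict(self) -> dict:
        return {
            "baseline_s": self.baseline_s,
            "conditions": list(self.conditions),
            "trials_per_condition": self.trials_per_condition,
            "stimulus_s": self.stimulus_s,
            "isi_s": self.isi_s,
            "max_consecutive_repeats": self.max_consecutive_repeats,
            "sequence": list(self.sequence),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        d = dict(d)
        d["conditions"] = tuple(d.get("conditions", CONDITIONS))
        d["sequence"] = tuple(d.get("sequence", ()))
        return cls(**d)


def _run_lengths_ok(seq: np.ndarray, max_run: int) -> bool:
    run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run > max_run:
            return False
    return True


def generate_stimulus_sequence(
    protocol: StimulusProtocol | None = None,
    seed: int | None = None,
    *,
    max_attempts: int = 100_000,
) -> StimulusProtocol:
    """Draw a pseudo-random trial sequence satisfying the run-length constraint.

    Rejection sampling over uniform shuffles: every valid sequence is equally
    likely.  Deterministic for a fixed seed.  Raises ``ValueError`` if the
    constraint is unsatisfiable or no valid shuffle is found.
    """
    proto = protocol or StimulusProtocol()
    if proto.trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    if proto.max_consecutive_repeats < 1:
        raise ValueError("max_consecutive_repeats must be >= 1 (constraint unsatisfiable)")
    # Feasibility: the most frequent label must be interleavable.
    n_other = (len(proto.conditions) - 1) * proto.trials_per_condition
    if proto.trials_per_condition > proto.max_consecutive_repeats * (n_other + 1):
        raise ValueError("run-length constraint unsatisfiable for these counts")

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(proto.conditions)), proto.trials_per_condition)
    for _ in range(max_attempts):
        perm = rng.permutation(labels)
        if _run_lengths_ok(perm, proto.max_consecutive_repeats):
            seq = tuple(proto.conditions[i] for i in perm)
            return proto.with_sequence(seq)
    raise ValueError("no valid sequence found (constraint too tight?)")


def validate_sequence(
    sequence, protocol: StimulusProtocol | None = None
) -> tuple[bool, list[str]]:
    """Check condition counts and the maximum-run constraint.

    Returns ``(ok, violations)`` where each violation names the index or the
    condition concerned.
    """
    proto = protocol or StimulusProtocol()
    seq = list(sequence)
    violations: list[str] = []
    if not seq:
        raise ValueError("sequence is empty")
    for cond in proto.conditions:
        n = seq.count(cond)
        if n != proto.trials_per_condition:
            violations.append(
                f"count violation: {cond} occurs {n} times, "
                f"expected {proto.trials_per_condition}"
            )
    unknown = sorted(set(seq) - set(proto.conditions))
    for lbl in unknown:
        violations.append(f"unknown condition label: {lbl}")
    run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run == proto.max_consecutive_repeats + 1:
            violations.append(f"run violation at index {i}: >{proto.max_consecutive_repeats} "
                              f"consecutive {seq[i]!r}")
    return (not violations, violations)


def write_events_tsv(protocol: StimulusProtocol, path: str | Path) -> None:
    protocol.events().to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"events file {path} is empty")
    return df
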