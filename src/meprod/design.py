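"""Plex layout: channel roles, conditions, and design file round-trip.

A booster-channel pulsed-SILAC/TMT plex contains three kinds of channels:

``sample``
    A pulse-labeled biological sample, annotated with a condition label and a
    replicate number.
``booster``
    A fully heavy-labeled digest spiked in at a molar ratio relative to the
    per-sample peptide amount (typically 2.0, i.e. 200%). It lifts the summed
    heavy precursor signal above the MS1 detection limit and serves as the
    reference every sample is quantified against.
``noise``
    A non-SILAC-labeled digest. Any heavy-peptide reporter signal in it is
    co-isolation interference, which is subtracted per peptide from all other
    channels.

A valid design has exactly one booster, exactly one noise channel, and at
least two sample channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import DesignError

ROLE_SAMPLE = "sample"
ROLE_BOOSTER = "booster"
ROLE_NOISE = "noise"
ROLES = (ROLE_SAMPLE, ROLE_BOOSTER, ROLE_NOISE)

#: Reporter tag labels of a 16-channel TMTpro-style plex, in mass order.
#: Presets and fixtures draw channel ids from this list.
TMT_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
)

DEFAULT_BOOSTER_MOLAR_RATIO = 2.0


@dataclass(frozen=True)
class ChannelSpec:
    """One TMT channel and its role in the plex."""

    channel_id: str
    role: str
    condition: str | None = None
    replicate: int | None = None
    booster_molar_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DesignError(
                f"channel {self.channel_id!r}: unknown role {self.role!r}; "
                f"expected one of {ROLES}"
            )
        if self.role == ROLE_SAMPLE:
            if not self.condition:
                raise DesignError(
                    f"sample channel {self.channel_id!r} requires a condition label"
                )
            if self.replicate is None or int(self.replicate) < 1:
                raise DesignError(
                    f"sample channel {self.channel_id!r} requires a positive "
                    f"replicate number (got {self.replicate!r})"
                )
            if self.booster_molar_ratio is not None:
                raise DesignError(
                    f"sample channel {self.channel_id!r} must not set "
                    f"booster_molar_ratio"
                )
        elif self.role == ROLE_BOOSTER:
            if self.condition is not None or self.replicate is not None:
                raise DesignError(
                    f"booster channel {self.channel_id!r} must not carry "
                    f"condition/replicate labels"
                )
            if self.booster_molar_ratio is None:
                object.__setattr__(
                    self, "booster_molar_ratio", DEFAULT_BOOSTER_MOLAR_RATIO
                )
            if not self.booster_molar_ratio > 0:
                raise DesignError(
                    f"booster channel {self.channel_id!r}: booster_molar_ratio "
                    f"must be > 0 (got {self.booster_molar_ratio!r})"
                )
        else:  # noise
            if (
                self.condition is not None
                or self.replicate is not None
                or self.booster_molar_ratio is not None
            ):
                raise DesignError(
                    f"noise channel {self.channel_id!r} must not carry "
                    f"condition/replicate/booster attributes"
                )


@dataclass(frozen=True)
class PlexDesign:
    """Validated channel layout of one multiplexed run."""

    plex_id: str
    channels: tuple[ChannelSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DesignError(f"duplicate channel ids in plex {self.plex_id!r}: {dupes}")
        for role in (ROLE_BOOSTER, ROLE_NOISE):
            n = sum(c.role == role for c in self.channels)
            if n == 0:
                raise DesignError(f"plex {self.plex_id!r} has no {role} channel")
            if n > 1:
                raise DesignError(
                    f"plex {self.plex_id!r} has {n} {role} channels; exactly one required"
                )
        if sum(c.role == ROLE_SAMPLE for c in self.channels) < 2:
            raise DesignError(
                f"plex {self.plex_id!r} needs at least two sample channels"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def booster(self) -> ChannelSpec:
        return next(c for c in self.channels if c.role == ROLE_BOOSTER)

    @property
    def noise(self) -> ChannelSpec:
        return next(c for c in self.channels if c.role == ROLE_NOISE)

    @property
    def sample_channels(self) -> tuple[ChannelSpec, ...]:
        return tuple(c for c in self.channels if c.role == ROLE_SAMPLE)

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(c.channel_id for c in self.channels)

    @property
    def conditions(self) -> tuple[str, ...]:
        """Condition labels in first-appearance order."""
        seen: list[str] = []
        for c in self.sample_channels:
            if c.condition not in seen:
                seen.append(c.condition)  # type: ignore[arg-type]
        return tuple(seen)

    def channels_for(self, condition: str) -> tuple[ChannelSpec, ...]:
        return tuple(c for c in self.sample_channels if c.condition == condition)

    # -- (de)serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        channels = []
        for c in self.channels:
            entry: dict = {"id": c.channel_id, "role": c.role}
            if c.condition is not None:
                entry["condition"] = c.condition
            if c.replicate is not None:
                entry["replicate"] = int(c.replicate)
            if c.booster_molar_ratio is not None:
                entry["booster_molar_ratio"] = float(c.booster_molar_ratio)
            channels.append(entry)
        return {"plex_id": self.plex_id, "channels": channels}

    @classmethod
    def from_dict(cls, data: dict) -> "PlexDesign":
        if not isinstance(data, dict) or "plex_id" not in data or "channels" not in data:
            raise DesignError(
                "design must be a mapping with keys 'plex_id' and 'channels'"
            )
        channels = []
        for entry in data["channels"]:
            if not isinstance(entry, dict) or "id" not in entry or "role" not in entry:
                raise DesignError(
                    f"each channel entry needs 'id' and 'role' keys (got {entry!r})"
                )
            rep = entry.get("replicate")
            channels.append(
                ChannelSpec(
                    channel_id=str(entry["id"]),
                    role=str(entry["role"]).lower(),
                    condition=entry.get("condition"),
                    replicate=int(rep) if rep is not None else None,
                    booster_molar_ratio=entry.get("booster_molar_ratio"),
                )
            )
        return cls(plex_id=str(data["plex_id"]), channels=tuple(channels))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )


def load_plex_design(path: str | Path) -> PlexDesign:
    """Load and validate a plex design from a YAML (or JSON) config file.

    The schema is ``{plex_id, channels: [{id, role, condition, replicate,
    booster_molar_ratio}]}``; JSON parses as a YAML subset.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise DesignError(f"cannot parse design file {path}: {exc}") from exc
    return PlexDesign.from_dict(data)
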