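"""Channel geometry for the 18-channel prefrontal fNIRS sensor.

The default layout mirrors a continuous-wave prefrontal sensor with four
sources and twelve detectors yielding 16 long source-detector separation
(SDS) channels at 2.5 cm and 2 short SDS channels at 1.0 cm.  Channels
3-6 (left) and 11-14 (right) are averaged into the left/right long-SDS
middle-frontal regions; channels 17 and 18 are the left/right short-SDS
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

LONG_SEPARATION_CM = 2.5
SHORT_SEPARATION_CM = 1.0

#: region name -> member channel ids in the default layout
DEFAULT_REGIONS: dict[str, tuple[int, ...]] = {
    "left_long": (3, 4, 5, 6),
    "right_long": (11, 12, 13, 14),
    "left_short": (17,),
    "right_short": (18,),
}


@dataclass(frozen=True)
class Channel:
    """One source-detector pair."""

    channel_id: int
    source: int
    detector: int
    separation_cm: float
    sds_class: str  # "long" | "short"
    hemisphere: str  # "left" | "right"
    region_member: bool

    def __post_init__(self) -> None:
        if self.sds_class not in ("long", "short"):
            raise ValueError(f"sds_class must be long|short, got {self.sds_class!r}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left|right, got {self.hemisphere!r}")


@dataclass
class ChannelMap:
    """Mapping channel id -> geometry, with region bookkeeping."""

    channels: dict[int, Channel]
    regions: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __iter__(self) -> Iterator[Channel]:
        return iter(self.channels.values())

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, channel_id: int) -> Channel:
        return self.channels[channel_id]

    @property
    def channel_ids(self) -> list[int]:
        return sorted(self.channels)

    def ids_by_class(self, sds_class: str) -> list[int]:
        return [c.channel_id for c in self if c.sds_class == sds_class]

    def region_of(self, channel_id: int) -> str | None:
        for name, members in self.regions.items():
            if channel_id in members:
                return name
        return None

    @staticmethod
    def region_sds(region: str) -> str:
        return "long" if region.endswith("long") else "short"

    @staticmethod
    def region_hemisphere(region: str) -> str:
        return region.split("_", 1)[0]

    def validate_default_layout(self) -> None:
        n_long = len(self.ids_by_class("long"))
        n_short = len(self.ids_by_class("short"))
        if (n_long, n_short) != (16, 2):
            raise ValueError(
                f"default layout requires 16 long + 2 short channels, got {n_long}+{n_short}"
            )

    def to_records(self) -> list[dict]:
        return [
            {
                "channel_id": c.channel_id,
                "source": c.source,
                "detector": c.detector,
                "separation_cm": c.separation_cm,
                "sds_class": c.sds_class,
                "hemisphere": c.hemisphere,
                "region_member": c.region_member,
            }
            for c in self
        ]

    @classmethod
    def from_records(cls, records: list[dict], regions: dict | None = None) -> "ChannelMap":
        channels = {
            int(r["channel_id"]): Channel(
                channel_id=int(r["channel_id"]),
                source=int(r["source"]),
                detector=int(r["detector"]),
                separation_cm=float(r["separation_cm"]),
                sds_class=str(r["sds_class"]),
                hemisphere=str(r["hemisphere"]),
                region_member=bool(r["region_member"]),
            )
            for r in records
        }
        regs = {k: tuple(v) for k, v in regions.items()} if regions else dict(DEFAULT_REGIONS)
        return cls(channels=channels, regions=regs)


def default_channel_map() -> ChannelMap:
    """The 16-long + 2-short prefrontal layout.

    Long channels 1-8 sit over the left hemisphere, 9-16 over the right;
    short channels 17 (left) and 18 (right) hang off the middle sources.
    """
    region_ids = {cid for members in DEFAULT_REGIONS.values() for cid in members}
    channels: dict[int, Channel] = {}
    for cid in range(1, 17):
        hemi = "left" if cid <= 8 else "right"
        source = (cid - 1) // 4 + 1  # sources 1-4, four detectors each
        detector = cid
        channels[cid] = Channel(
            channel_id=cid,
            source=source,
            detector=detector,
            separation_cm=LONG_SEPARATION_CM,
            sds_class="long",
            hemisphere=hemi,
            region_member=cid in region_ids,
        )
    channels[17] = Channel(17, 2, 11, SHORT_SEPARATION_CM, "short", "left", True)
    channels[18] = Channel(18, 3, 12, SHORT_SEPARATION_CM, "short", "right", True)
    cmap = ChannelMap(channels=channels)
    cmap.validate_default_layout()
    return cmap
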