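"""Genomic intervals with explicit coordinate conventions.

Internally everything is 0-based half-open (BED convention). 1-based inclusive
coordinates (the convention of junction-read tables and human-readable region
strings like ``chr3:34721183-34721192``) appear only at I/O boundaries, through
the explicit ``from_1based`` / ``to_1based`` converters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from hoplandscape.errors import ConfigurationError

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ConfigurationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def contains_position(self, position_1based: int, chrom: str | None = None) -> bool:
        """Whether a 1-based position lies inside the interval."""
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start < position_1based <= self.end

    @classmethod
    def from_1based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from a 1-based inclusive pair (lossless: start-1, end)."""
        return cls(chrom, start - 1, end)

    def to_1based(self) -> tuple[str, int, int]:
        """Return (chrom, start, end) as 1-based inclusive (lossless inverse)."""
        return self.chrom, self.start + 1, self.end

    @classmethod
    def from_string(cls, region: str) -> "GenomicInterval":
        """Parse a 1-based inclusive region string like ``chr3:100-200``."""
        m = _REGION_RE.match(region)
        if m is None:
            raise ConfigurationError(f"cannot parse region string {region!r}")
        chrom, start, end = m.group(1), m.group(2), m.group(3)
        return cls.from_1based(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        chrom, start, end = self.to_1based()
        return f"{chrom}:{start}-{end}"
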