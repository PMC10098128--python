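"""Partition schemes: named site subsets over an alignment.

Coordinates are 0-based half-open internally; the RAxML and NEXUS charset
file dialects use 1-based inclusive coordinates, converted exactly once at
the file boundary.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Partition", "PartitionScheme", "parse_partition_file", "PartitionError"]


class PartitionError(ValueError):
    """Invalid partition definition (overlap, coverage gap, bad name)."""


@dataclass
class Partition:
    """A named union of half-open site ranges."""

    name: str
    ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.name:
            raise PartitionError("empty partition name")
        for start, stop in self.ranges:
            if not (0 <= start < stop):
                raise PartitionError(f"bad range ({start}, {stop}) in {self.name!r}")
        self.ranges = sorted(self.ranges)

    @property
    def n_sites(self) -> int:
        return sum(stop - start for start, stop in self.ranges)

    def indices(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(start, stop, dtype=np.intp) for start, stop in self.ranges]
        )


@dataclass
class PartitionScheme:
    partitions: list[Partition] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.partitions]
        if len(set(names)) != len(names):
            raise PartitionError("duplicate partition names")
        covered: set[int] = set()
        for p in self.partitions:
            idx = set(p.indices().tolist())
            if covered & idx:
                raise PartitionError(f"partition {p.name!r} overlaps an earlier one")
            covered |= idx

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.partitions]

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    @property
    def n_sites(self) -> int:
        return sum(p.n_sites for p in self.partitions)

    def __getitem__(self, name: str) -> Partition:
        for p in self.partitions:
            if p.name == name:
                return p
        raise KeyError(name)

    def validate_coverage(self, total_sites: int, strict: bool = True) -> None:
        """Check the scheme against a declared alignment length.

        With ``strict`` the union must cover exactly ``[0, total_sites)``.
        """
        covered = np.zeros(total_sites, dtype=bool)
        for p in self.partitions:
            idx = p.indices()
            if idx.size and idx[-1] >= total_sites:
                raise PartitionError(
                    f"partition {p.name!r} extends past {total_sites} sites"
                )
            covered[idx] = True
        if strict and not covered.all():
            gap = int(np.flatnonzero(~covered)[0])
            raise PartitionError(f"coverage gap at site {gap} (0-based)")

    def to_raxml(self) -> str:
        lines = []
        for p in self.partitions:
            spans = ", ".join(f"{a + 1}-{b}" for a, b in p.ranges)
            lines.append(f"DNA, {p.name} = {spans}")
        return "\n".join(lines) + "\n"

    def to_nexus_charsets(self) -> str:
        lines = ["#NEXUS", "begin sets;"]
        for p in self.partitions:
            spans = " ".join(f"{a + 1}-{b}" for a, b in p.ranges)
            lines.append(f"    charset {p.name} = {spans};")
        lines.append("end;")
        return "\n".join(lines) + "\n"


_RAXML_RE = re.compile(r"^\s*DNA\s*,\s*(\S+)\s*=\s*(.+)$", re.IGNORECASE)
_CHARSET_RE = re.compile(r"charset\s+(\S+)\s*=\s*([^;]+);", re.IGNORECASE)
_SPAN_RE = re.compile(r"^(\d+)\s*-\s*(\d+)$|^(\d+)$")


def _parse_spans(text: str, name: str) -> list[tuple[int, int]]:
    ranges = []
    for chunk in re.split(r"[,\s]+", text.strip()):
        if not chunk:
            continue
        m = _SPAN_RE.match(chunk)
        if not m:
            raise PartitionError(f"bad range {chunk!r} in partition {name!r}")
        if m.group(3) is not None:
            a = b = int(m.group(3))
        else:
            a, b = int(m.group(1)), int(m.group(2))
        if a < 1 or b < a:
            raise PartitionError(f"bad 1-based range {chunk!r} in {name!r}")
        ranges.append((a - 1, b))  # 1-based inclusive -> 0-based half-open
    if not ranges:
        raise PartitionError(f"no ranges for partition {name!r}")
    return ranges


def parse_partition_file(
    text: str,
    dialect: str = "raxml",
    total_sites: int | None = None,
    strict: bool = False,
) -> PartitionScheme:
    """Parse a RAxML-style or NEXUS-charset partition definition.

    File coordinates are 1-based inclusive and converted to internal
    0-based half-open ranges.  When ``total_sites`` is given, coverage is
    validated (gaps are errors only in ``strict`` mode; overlaps always).
    """
    parts: list[Partition] = []
    if dialect == "raxml":
        for line in text.splitlines():
            if not line.strip() or line.strip().startswith("#"):
                continue
            m = _RAXML_RE.match(line)
            if not m:
                raise PartitionError(f"unparseable RAxML partition line: {line!r}")
            name, spans = m.group(1), m.group(2)
            parts.append(Partition(name, _parse_spans(spans, name)))
    elif dialect == "nexus_charsets":
        for m in _CHARSET_RE.finditer(text):
            name, spans = m.group(1), m.group(2)
            parts.append(Partition(name, _parse_spans(spans, name)))
        if not parts:
            raise PartitionError("no charset statements found")
    else:
        raise ValueError(f"unknown partition dialect: {dialect!r}")
    scheme = PartitionScheme(parts)
    if total_sites is not None:
        scheme.validate_coverage(total_sites, strict=strict)
    return scheme
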