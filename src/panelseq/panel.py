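"""Amplicon panel representation and BED I/O.

The panel is the on-target universe of the assay: a set of PCR amplicons
covering hotspot regions of cancer genes.  BED coordinates are kept 0-based
half-open throughout; conversion to 1-based variant coordinates happens only
at the VCF boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator


class PanelError(ValueError):
    """Malformed or inconsistent panel definition."""


@dataclass(frozen=True)
class Amplicon:
    """One targeted interval of the panel (0-based, half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    gene: str = "NA"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"amplicon {self.id!r}: start must be < end "
                f"(got {self.start} >= {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership test for a 1-based position (VCF convention)."""
        return chrom == self.chrom and self.start < pos <= self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Overlap test against a 0-based half-open interval."""
        return chrom == self.chrom and start < self.end and self.start < end


@dataclass
class Panel:
    """Ordered collection of amplicons with unique ids."""

    amplicons: list[Amplicon] = field(default_factory=list)
    name: str = "panel"

    def __post_init__(self) -> None:
        ids = [a.id for a in self.amplicons]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate amplicon ids: {dupes}")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    @property
    def genes(self) -> list[str]:
        """Genes in panel order, deduplicated."""
        seen: dict[str, None] = {}
        for a in self.amplicons:
            seen.setdefault(a.gene)
        return list(seen)

    def amplicons_for_gene(self, gene: str) -> list[Amplicon]:
        return [a for a in self.amplicons if a.gene == gene]

    def covering(self, chrom: str, pos: int) -> Amplicon | None:
        """First amplicon containing the 1-based position, if any."""
        for a in self.amplicons:
            if a.contains(chrom, pos):
                return a
        return None

    def covers_interval(self, chrom: str, start: int, end: int) -> bool:
        return any(a.overlaps(chrom, start, end) for a in self.amplicons)


def read_panel_bed(path: str | Path, name: str | None = None) -> Panel:
    """Read a BED file of target regions into a :class:`Panel`.

    Requires >= 3 tab-separated columns per data line; an optional 4th column
    becomes the gene name (otherwise ``"NA"``).  BED's 0-based half-open
    coordinates are preserved unchanged.  Lines starting with ``track``,
    ``browser`` or ``#`` are skipped.
    """
    path = Path(path)
    amplicons: list[Amplicon] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene = fields[3] if len(fields) >= 4 and fields[3] else "NA"
            amp_id = fields[3] if len(fields) >= 4 and fields[3] else f"amp{lineno}"
            # ids must be unique even when the gene repeats across amplicons
            amp_id = f"{amp_id}_{chrom}_{start}"
            try:
                amplicons.append(
                    Amplicon(id=amp_id, chrom=chrom, start=start, end=end, gene=gene)
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    return Panel(amplicons=amplicons, name=name or path.stem)


def write_panel_bed(panel: Panel, path: str | Path) -> None:
    """Write the panel as 4-column BED (chrom, start, end, gene)."""
    with open(path, "w") as fh:
        for a in panel.amplicons:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.gene}\n")
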