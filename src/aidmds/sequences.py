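"""Strand-specific reference sequences and region annotations.

A transcribed amplicon is represented by its two strands: the
non-transcribed (sense) strand NTS and the transcribed (template) strand
TS, each stored 5'->3'.  Coordinates throughout the package are 1-based
duplex coordinates running along the NTS from ``coord_offset``; a
position on the TS is reported at the coordinate of the base it pairs
with, so region annotations (FW1/CDR1/...) apply to both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


#: Region map of the IGHV3-23*01 amplicon in duplex coordinates
#: (inclusive intervals).  The scaffold bubble is the preformed 12-bp
#: DNA-RNA heteroduplex where elongation starts.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "scaffold_bubble": (16, 27),
    "FW1": (38, 65),
    "CDR1": (66, 106),
    "FW2": (107, 146),
    "CDR2": (147, 177),
    "FW3": (178, 203),
}


@dataclass
class ReferencePair:
    """NTS/TS reference sequences plus coordinate and region annotations.

    Parameters
    ----------
    name:
        Label for the amplicon.
    nts_seq:
        Non-transcribed (sense) strand, 5'->3'.
    coord_offset:
        Duplex coordinate of the first NTS base (1-based numbering).
    regions:
        ``{name: (start, end)}`` inclusive intervals in duplex coordinates.
        Regions may not overlap, except ``scaffold_bubble``.
    """

    name: str
    nts_seq: str
    coord_offset: int = 1
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nts_seq = self.nts_seq.upper()
        self.ts_seq = revcomp(self.nts_seq)
        lo, hi = self.coord_offset, self.coord_offset + len(self.nts_seq) - 1
        spans: list[tuple[int, int]] = []
        for rname, (start, end) in self.regions.items():
            if not (lo <= start <= end <= hi):
                raise ValueError(
                    f"region {rname!r} [{start},{end}] outside reference span [{lo},{hi}]"
                )
            if rname != "scaffold_bubble":
                for s2, e2 in spans:
                    if start <= e2 and s2 <= end:
                        raise ValueError(f"region {rname!r} overlaps another region")
                spans.append((start, end))

    def __len__(self) -> int:
        return len(self.nts_seq)

    def strand_seq(self, strand: str) -> str:
        if strand == "NTS":
            return self.nts_seq
        if strand == "TS":
            return self.ts_seq
        raise ValueError(f"unknown strand {strand!r}")

    def duplex_coord(self, strand: str, local_pos: int) -> int:
        """Map a 1-based position on a strand (read 5'->3') to duplex coordinates."""
        if not 1 <= local_pos <= len(self):
            raise ValueError(f"position {local_pos} outside reference of length {len(self)}")
        if strand == "NTS":
            return self.coord_offset + local_pos - 1
        if strand == "TS":
            return self.coord_offset + len(self) - local_pos
        raise ValueError(f"unknown strand {strand!r}")

    def local_pos(self, strand: str, coord: int) -> int:
        """Inverse of :meth:`duplex_coord`."""
        if strand == "NTS":
            pos = coord - self.coord_offset + 1
        elif strand == "TS":
            pos = self.coord_offset + len(self) - coord
        else:
            raise ValueError(f"unknown strand {strand!r}")
        if not 1 <= pos <= len(self):
            raise ValueError(f"coordinate {coord} outside reference span")
        return pos

    def c_positions(self, strand: str) -> list[int]:
        """1-based local positions of C on a strand."""
        seq = self.strand_seq(strand)
        return [i + 1 for i, b in enumerate(seq) if b == "C"]

    def region_of(self, coord: int) -> str:
        """Region name for a duplex coordinate; 'unassigned' if in none.

        The scaffold bubble may overlap named regions; non-bubble regions
        take precedence so a coordinate always has a single label.
        """
        bubble = None
        for rname, (start, end) in self.regions.items():
            if start <= coord <= end:
                if rname == "scaffold_bubble":
                    bubble = rname
                else:
                    return rname
        return bubble or "unassigned"

    # ---- I/O -------------------------------------------------------

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.nts_seq), id=f"{self.name}|NTS", description=f"offset={self.coord_offset}"),
            SeqRecord(Seq(self.ts_seq), id=f"{self.name}|TS", description=f"offset={self.coord_offset}"),
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path, regions: dict[str, tuple[int, int]] | None = None) -> "ReferencePair":
        records = list(SeqIO.parse(path, "fasta"))
        nts = next((r for r in records if r.id.endswith("|NTS")), records[0])
        offset = 1
        for token in nts.description.split():
            if token.startswith("offset="):
                offset = int(token.split("=", 1)[1])
        name = nts.id.split("|")[0]
        return cls(name=name, nts_seq=str(nts.seq), coord_offset=offset,
                   regions=dict(regions) if regions else {})
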