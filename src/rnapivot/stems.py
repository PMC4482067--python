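"""Stem catalogs: the rigid-stem / pivot / final-loop tripartition of a helix.

A pivoting helix is described by three parts: a short rigid stem proximal to
the candidate pivot (the superposition frame), the path of residues running
from that stem out toward the terminal loop, and a designated tip residue in
the final loop whose displacement quantifies the motion.  Catalogs of such
definitions are plain TSV inputs, one row per helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["StemDefinition", "read_stem_catalog", "write_stem_catalog"]


@dataclass
class StemDefinition:
    """Rigid stem, helix path and tip residue of one candidate pivot helix.

    Residue numbers are author numbers by default, or reference (E. coli)
    numbers when ``numbering="reference"``.  Ranges are inclusive on both
    ends.
    """

    helix_id: str
    chain: str
    stem_ranges: list[tuple[int, int]]
    path_ranges: list[tuple[int, int]]
    tip_residue: int | None = None
    numbering: str = "author"
    species: str = ""

    def __post_init__(self) -> None:
        stem = set(self.stem_residues())
        path = set(self.helix_path())
        overlap = stem & path
        if overlap:
            raise ValueError(
                f"{self.helix_id}: stem and helix path overlap at {sorted(overlap)[:5]}")
        if self.tip_residue is None and self.path_ranges:
            self.tip_residue = self.helix_path()[-1]

    def stem_residues(self) -> list[int]:
        return _expand(self.stem_ranges)

    def helix_path(self) -> list[int]:
        return _expand(self.path_ranges)


def _expand(ranges: list[tuple[int, int]]) -> list[int]:
    out: list[int] = []
    for start, end in ranges:
        step = 1 if end >= start else -1
        out.extend(range(start, end + step, step))
    return out


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    ranges = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, _, hi = part.partition("-")
            ranges.append((int(lo), int(hi)))
        else:
            ranges.append((int(part), int(part)))
    return ranges


def _format_ranges(ranges: list[tuple[int, int]]) -> str:
    return ",".join(f"{lo}-{hi}" for lo, hi in ranges)


def read_stem_catalog(path: str | Path, numbering: str = "author") -> list[StemDefinition]:
    """Read a stem catalog TSV with columns
    ``helix_id  chain  stem_ranges  path_ranges  tip_residue``."""
    stems: list[StemDefinition] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen and parts[0] == "helix_id":
                header_seen = True
                continue
            helix_id, chain, stem_txt, path_txt, tip_txt = parts[:5]
            stems.append(StemDefinition(
                helix_id=helix_id,
                chain=chain,
                stem_ranges=_parse_ranges(stem_txt),
                path_ranges=_parse_ranges(path_txt),
                tip_residue=int(tip_txt) if tip_txt not in ("", "NA") else None,
                numbering=numbering,
            ))
    return stems


def write_stem_catalog(stems: list[StemDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("helix_id\tchain\tstem_ranges\tpath_ranges\ttip_residue\n")
        for s in stems:
            fh.write(
                f"{s.helix_id}\t{s.chain}\t{_format_ranges(s.stem_ranges)}\t"
                f"{_format_ranges(s.path_ranges)}\t{s.tip_residue}\n")
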