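"""Genepop format reader/writer (2- and 3-digit allele dialects).

Layout handled::

    title line
    LOCUS1
    LOCUS2          # or all loci comma-separated on one line
    POP
    ind1 , 101103 000000 ...
    ...

``000000`` / ``0000`` (and any all-zero code) denote a missing genotype.
Multiple POP sections are concatenated; individual labels must be unique.
"""

from __future__ import annotations

import re

from .genetics import Genotype, GenotypeError, GenotypeTable


class GenepopParseError(GenotypeError):
    def __init__(self, msg: str, line_no: int | None = None):
        if line_no is not None:
            msg = f"line {line_no}: {msg}"
        super().__init__(msg)


def _decode_entry(entry: str, line_no: int) -> tuple[Genotype | None, int]:
    """Decode one genotype code, returning (genotype-or-None, digits per allele)."""
    if not entry.isdigit():
        raise GenepopParseError(f"non-numeric genotype code {entry!r}", line_no)
    if len(entry) == 4:
        w = 2
    elif len(entry) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"genotype code {entry!r} must be 4 (2-digit) or 6 (3-digit) characters", line_no
        )
    a1, a2 = int(entry[:w]), int(entry[w:])
    if a1 == 0 or a2 == 0:
        return None, w
    return (min(a1, a2), max(a1, a2)), w


def read_genepop(path) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be Genepop")
    # locus names: lines 2.. until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if not chunk:
            raise GenepopParseError("blank line in locus header", i + 1)
        parts = [p.strip() for p in chunk.split(",") if p.strip()]
        for p in parts:
            if re.search(r"\s", p):
                raise GenepopParseError(f"malformed locus name {p!r}", i + 1)
            loci.append(p)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP line found")
    if not loci:
        raise GenepopParseError("no loci declared before first POP")

    data: dict[str, dict[str, Genotype | None]] = {}
    width: int | None = None
    for j in range(i, len(lines)):
        line = lines[j].strip()
        if not line:
            continue
        if line.lower() == "pop":
            continue
        if "," not in line:
            raise GenepopParseError("individual line lacks ',' separator", j + 1)
        label, rest = line.split(",", 1)
        label = label.strip()
        entries = rest.split()
        if len(entries) != len(loci):
            raise GenepopParseError(
                f"individual {label!r}: {len(entries)} genotypes for {len(loci)} loci", j + 1
            )
        if label in data:
            raise GenepopParseError(f"duplicate individual label {label!r}", j + 1)
        gts: dict[str, Genotype | None] = {}
        for loc, entry in zip(loci, entries):
            gt, w = _decode_entry(entry, j + 1)
            if width is None:
                width = w
            elif w != width:
                raise GenepopParseError(
                    f"mixed allele widths ({w} vs {width} digits)", j + 1
                )
            gts[loc] = gt
        data[label] = gts
    if not data:
        raise GenepopParseError("no individuals found")
    return GenotypeTable(data, loci)


def write_genepop(table: GenotypeTable, path, title: str = "meles export", digits: int = 3) -> None:
    """Write a :class:`GenotypeTable` as a single-POP Genepop file."""
    if digits not in (2, 3):
        raise GenotypeError("digits must be 2 or 3")
    fmt = f"{{:0{digits}d}}"
    limit = 10**digits
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in table.loci:
            fh.write(loc + "\n")
        fh.write("POP\n")
        for ind in table.individuals:
            codes = []
            for loc in table.loci:
                gt = table.get(ind, loc)
                if gt is None:
                    codes.append(fmt.format(0) * 2)
                else:
                    if gt[0] >= limit or gt[1] >= limit:
                        raise GenotypeError(
                            f"allele {max(gt)} at {loc} does not fit {digits}-digit coding"
                        )
                    codes.append(fmt.format(gt[0]) + fmt.format(gt[1]))
            fh.write(f"{ind} , " + " ".join(codes) + "\n")
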