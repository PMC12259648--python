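"""IMGT unique numbering for immunoglobulin variable domains.

The IMGT scheme assigns every variable-domain residue a fixed position in
1-128, with CDR1 = 27-38, CDR2 = 56-65 and CDR3 = 105-117.  Positions that a
particular germline gene does not encode are gaps; CDR3 loops longer than 13
residues receive decimal insertion codes at the loop apex (111.1, 111.2, ...
on the ascending side and 112.1, 112.2, ... on the descending side, where
112.1 sorts *closest to* 112).

This module provides germline-allele containers, propagation of IMGT numbers
from gapped germline references onto rearranged sequences, the CDR3
insertion scheme, allele comparison at the protein level, and the
``E38_H_S`` substitution-string grammar used throughout the package.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ImgtPosition",
    "GermlineAllele",
    "NumberedResidue",
    "NumberedDomain",
    "Substitution",
    "GermlineFormatError",
    "UnsupportedIndelError",
    "REGION_BOUNDS",
    "region_of",
    "read_germline_set",
    "write_germline_set",
    "number_v_domain",
    "number_cdr3",
    "compare_alleles",
    "parse_substitution",
    "format_substitution",
]

_DNA = set("ACGT")
_GAPS = set(".-")

#: Framework/CDR boundaries on the universal numbering (both chains).
REGION_BOUNDS = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),
}

#: Longest CDR3 accepted by the insertion scheme (13 base positions plus up
#: to 13 insertions on either side of the apex).
MAX_CDR3_LEN = 40


class GermlineFormatError(ValueError):
    """A germline record violates the expected format."""


class UnsupportedIndelError(ValueError):
    """The query cannot be aligned to the germline without indels."""


@functools.total_ordering
@dataclass(frozen=True)
class ImgtPosition:
    """A position in the IMGT unique numbering.

    ``insertion`` is the decimal index of a CDR3 apex insertion and is only
    meaningful at positions 111 and 112.  The total order places 111.x
    insertions in ascending index order after 111, and 112.x insertions in
    *descending* index order before 112::

        110 < 111 < 111.1 < 111.2 < ... < 112.2 < 112.1 < 112 < 113
    """

    number: int
    insertion: int | None = None
    chain: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 1 <= self.number <= 128:
            raise ValueError(f"IMGT position out of range: {self.number}")
        if self.insertion is not None:
            if self.number not in (111, 112):
                raise ValueError(
                    f"insertions are only defined at 111/112, got {self.number}.{self.insertion}"
                )
            if self.insertion < 1:
                raise ValueError("insertion index must be a positive integer")
        if self.chain is not None and self.chain not in ("H", "L"):
            raise ValueError(f"chain must be 'H' or 'L', got {self.chain!r}")

    @property
    def sort_key(self) -> tuple[int, int]:
        ins = self.insertion or 0
        # 112-side insertions count down toward 112 itself.
        return (self.number, -ins if self.number == 112 else ins)

    def __lt__(self, other: "ImgtPosition") -> bool:
        if not isinstance(other, ImgtPosition):
            return NotImplemented
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        if self.insertion is not None:
            return f"{self.number}.{self.insertion}"
        return str(self.number)

    @classmethod
    def parse(cls, text: str, chain: str | None = None) -> "ImgtPosition":
        m = re.fullmatch(r"(\d+)(?:\.(\d+))?", text)
        if m is None:
            raise ValueError(f"not an IMGT position: {text!r}")
        number = int(m.group(1))
        insertion = int(m.group(2)) if m.group(2) else None
        return cls(number, insertion, chain)

    @property
    def region(self) -> str:
        return region_of(self)


def region_of(pos: ImgtPosition) -> str:
    """Region label (FR1..FR4) of an IMGT position; pure function of position."""
    for name, (lo, hi) in REGION_BOUNDS.items():
        if lo <= pos.number <= hi:
            return name
    raise ValueError(f"position {pos} outside variable domain")


_NAME_RE = re.compile(r"^(?P<gene>[A-Za-z0-9/.-]+)\*(?P<allele>\d+)$")


@dataclass(frozen=True)
class GermlineAllele:
    """One germline V, D or J allele.

    ``gapped_seq_nt`` (V alleles) is the sequence aligned to IMGT codon
    positions with '.' at gap codons; stripping gaps recovers ``seq_nt``.
    The gapped region covers IMGT codons 1-104; any trailing ungapped bases
    are the allele's contribution to CDR3.
    """

    name: str
    locus: str
    segment: str
    seq_nt: str
    gapped_seq_nt: str | None = None

    def __post_init__(self) -> None:
        if self.locus not in ("IGH", "IGK", "IGL"):
            raise GermlineFormatError(f"unknown locus {self.locus!r}")
        if self.segment not in ("V", "D", "J"):
            raise GermlineFormatError(f"unknown segment {self.segment!r}")
        if _NAME_RE.match(self.name) is None:
            raise GermlineFormatError(
                f"allele name {self.name!r} does not parse as GENE*NN"
            )
        if set(self.seq_nt) - _DNA:
            bad = sorted(set(self.seq_nt) - _DNA)
            raise GermlineFormatError(f"non-DNA characters in {self.name}: {bad}")
        if self.gapped_seq_nt is not None:
            norm = self.gapped_seq_nt.replace("-", ".")
            object.__setattr__(self, "gapped_seq_nt", norm)
            if set(norm) - _DNA - {"."}:
                bad = sorted(set(norm) - _DNA - {"."})
                raise GermlineFormatError(
                    f"non-DNA characters in gapped {self.name}: {bad}"
                )
            if norm.replace(".", "") != self.seq_nt:
                raise GermlineFormatError(
                    f"{self.name}: gapped sequence does not degap to seq_nt"
                )
            if len(norm) % 3 != 0:
                raise GermlineFormatError(
                    f"{self.name}: gapped length {len(norm)} not a multiple of 3"
                )

    @property
    def gene(self) -> str:
        return _NAME_RE.match(self.name).group("gene")

    @property
    def allele_number(self) -> str:
        return _NAME_RE.match(self.name).group("allele")

    @property
    def chain(self) -> str:
        return "H" if self.locus == "IGH" else "L"

    def position_map(self) -> list[tuple[ImgtPosition, str]]:
        """(IMGT position, codon) for every non-gap codon of a gapped V allele.

        Codons 1-104 are read off the gapped alignment; trailing CDR3 codons
        continue sequentially from 105.
        """
        if self.segment != "V" or self.gapped_seq_nt is None:
            raise ValueError(f"{self.name}: position_map requires a gapped V allele")
        out: list[tuple[ImgtPosition, str]] = []
        codons = [
            self.gapped_seq_nt[i : i + 3] for i in range(0, len(self.gapped_seq_nt), 3)
        ]
        for i, codon in enumerate(codons, start=1):
            if codon == "...":
                continue
            if "." in codon:
                raise GermlineFormatError(
                    f"{self.name}: partial gap codon {codon!r} at IMGT {i}"
                )
            if i > 128:
                raise GermlineFormatError(f"{self.name}: gapped codons extend past 128")
            out.append((ImgtPosition(i, chain=self.chain), codon))
        return out


@dataclass(frozen=True)
class NumberedResidue:
    position: ImgtPosition
    aa: str
    codon: str

    @property
    def region(self) -> str:
        return region_of(self.position)


@dataclass
class NumberedDomain:
    """A variable-domain (or partial) sequence with IMGT-numbered residues."""

    chain: str
    residues: list[NumberedResidue]

    def __post_init__(self) -> None:
        positions = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("residue positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence_aa(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def sequence_nt(self) -> str:
        return "".join(r.codon for r in self.residues)

    def at(self, position: ImgtPosition) -> NumberedResidue:
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(f"no residue at IMGT {position}")

    def region_residues(self, region: str) -> list[NumberedResidue]:
        return [r for r in self.residues if r.region == region]


_SUB_RE = re.compile(r"^([A-Z])(\d+(?:\.\d+)?)_(H|L)_([A-Z])$")
_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Substitution:
    """An amino-acid substitution such as ``N40_H_T`` (Asn40 -> Thr, heavy)."""

    from_aa: str
    position: ImgtPosition
    to_aa: str

    def __post_init__(self) -> None:
        for aa in (self.from_aa, self.to_aa):
            if aa not in _AA_LETTERS:
                raise ValueError(f"not an amino-acid letter: {aa!r}")
        if self.from_aa == self.to_aa:
            raise ValueError(
                f"substitution must change the residue ({self.from_aa}{self.position})"
            )
        if self.position.chain is None:
            raise ValueError("substitution position must carry a chain")

    @property
    def chain(self) -> str:
        return self.position.chain

    def reverted(self) -> "Substitution":
        return Substitution(self.to_aa, self.position, self.from_aa)

    def __str__(self) -> str:
        return format_substitution(self)


def parse_substitution(text: str) -> Substitution:
    """Parse a substitution string like ``V29_L_I`` or ``D111.3_H_E``."""
    m = _SUB_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed substitution string: {text!r}")
    from_aa, pos_txt, chain, to_aa = m.groups()
    position = ImgtPosition.parse(pos_txt, chain=chain)
    return Substitution(from_aa, position, to_aa)


def format_substitution(s: Substitution) -> str:
    return f"{s.from_aa}{s.position}_{s.chain}_{s.to_aa}"


# ---------------------------------------------------------------------------
# Germline set I/O  (FASTA, header convention ``>NAME|LOCUS|SEGMENT``)
# ---------------------------------------------------------------------------


def read_germline_set(path: str | Path) -> list[GermlineAllele]:
    """Read a germline allele set from FASTA.

    Headers follow ``>NAME|LOCUS|SEGMENT``.  V records are expected to carry
    IMGT-gapped sequences ('.' or '-' at gap codons); D/J records are
    ungapped.  Duplicate allele names are rejected.
    """
    alleles: list[GermlineAllele] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise GermlineFormatError(
                f"header {rec.id!r} does not follow NAME|LOCUS|SEGMENT"
            )
        name, locus, segment = parts
        if name in seen:
            raise GermlineFormatError(f"duplicate allele name {name!r}")
        seen.add(name)
        raw = str(rec.seq).upper()
        seq = raw.replace(".", "").replace("-", "")
        gapped = raw.replace("-", ".") if segment == "V" else None
        alleles.append(
            GermlineAllele(
                name=name, locus=locus, segment=segment, seq_nt=seq, gapped_seq_nt=gapped
            )
        )
    return alleles


def write_germline_set(alleles: Iterable[GermlineAllele], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alleles:
            seq = a.gapped_seq_nt if a.gapped_seq_nt is not None else a.seq_nt
            fh.write(f">{a.name}|{a.locus}|{a.segment}\n{seq}\n")


# ---------------------------------------------------------------------------
# Numbering
# ---------------------------------------------------------------------------


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def number_v_domain(
    seq_nt: str,
    v_allele: GermlineAllele,
    chain: str,
    max_mismatch_frac: float = 0.2,
) -> NumberedDomain:
    """Propagate IMGT numbers from a gapped germline V allele onto a query.

    The query is assumed to start at germline codon 1 and to align without
    indels (this lineage has none); each query codon inherits the position
    of the germline codon it aligns to, and germline gap positions are
    skipped.  A mismatch fraction above ``max_mismatch_frac`` is taken as
    evidence of an indel or a wrong allele and raises
    :class:`UnsupportedIndelError` rather than silently renumbering.
    """
    pmap = v_allele.position_map()
    germ_nt = v_allele.seq_nt
    n = min(len(seq_nt), len(germ_nt))
    if n < 60:
        raise UnsupportedIndelError("query too short to anchor on germline V")
    mismatches = sum(1 for a, b in zip(seq_nt[:n], germ_nt[:n]) if a != b)
    if mismatches / n > max_mismatch_frac:
        raise UnsupportedIndelError(
            f"{mismatches}/{n} mismatches against {v_allele.name}; "
            "indel or wrong allele (indels are not supported)"
        )
    residues = []
    offset = 0
    for pos, _germ_codon in pmap:
        if offset + 3 > len(seq_nt):
            break
        codon = seq_nt[offset : offset + 3]
        residues.append(NumberedResidue(pos, _translate(codon), codon))
        offset += 3
    return NumberedDomain(chain=chain, residues=residues)


def number_cdr3(cdr3_aa: str | Sequence[str]) -> list[ImgtPosition]:
    """IMGT positions for a CDR3 of the given length.

    Length 13 maps onto 105..117 directly.  Longer loops insert decimal
    positions at the apex, alternating sides starting with 112.1, then
    111.1, 112.2, 111.2, ... which after sorting yields
    105..111, 111.1..111.k, 112.m..112.1, 112..117.  Shorter loops drop
    apex positions starting from the 112 side.
    """
    length = len(cdr3_aa)
    if not 1 <= length <= MAX_CDR3_LEN:
        raise ValueError(f"CDR3 length {length} outside 1..{MAX_CDR3_LEN}")
    base = [ImgtPosition(n) for n in range(105, 118)]
    if length == 13:
        return base
    if length < 13:
        # Remove apex positions alternating from the 112 side inward.
        removal: list[int] = []
        lo, hi = 111, 112
        while len(removal) < 13 - length:
            removal.append(hi)
            if len(removal) < 13 - length:
                removal.append(lo)
            hi += 1
            lo -= 1
        keep = [p for p in base if p.number not in removal]
        return keep
    # Insertions alternate starting on the 112 side: 112.1, 111.1, 112.2, ...
    n_ins = length - 13
    ins: list[ImgtPosition] = []
    for k in range(n_ins):
        side = 112 if k % 2 == 0 else 111
        index = k // 2 + 1
        ins.append(ImgtPosition(side, index))
    return sorted(base + ins)


def compare_alleles(
    a: GermlineAllele, b: GermlineAllele
) -> list[tuple[ImgtPosition, str, str, str]]:
    """Positions at which two gapped V alleles of the same gene differ.

    Returns ``(position, aa_in_a, aa_in_b, region)`` for every IMGT position
    whose translated residues differ.  Positions present in only one allele
    are reported with '-' for the missing side.
    """
    if a.segment != "V" or b.segment != "V":
        raise ValueError("compare_alleles requires V alleles")
    if a.locus != b.locus:
        raise ValueError(f"locus mismatch: {a.locus} vs {b.locus}")
    if a.gene != b.gene:
        raise ValueError(f"gene mismatch: {a.gene} vs {b.gene}")
    map_a = {pos: _translate(codon) for pos, codon in a.position_map()}
    map_b = {pos: _translate(codon) for pos, codon in b.position_map()}
    diffs = []
    for pos in sorted(set(map_a) | set(map_b)):
        aa_a = map_a.get(pos, "-")
        aa_b = map_b.get(pos, "-")
        if aa_a != aa_b:
            diffs.append((pos, aa_a, aa_b, region_of(pos)))
    return diffs
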