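"""Germline assignment, junction base classification and UCA inference.

A rearranged antibody sequence is aligned gap-free to germline V and J
alleles (anchored at the read 5' and 3' ends respectively; this lineage
carries no indels) and the junction window in between is searched for
exact runs of D-gene sequence.  Every read base is then labeled V, D, J or
N (non-templated).  The unmutated common ancestor (UCA) is built under the
standard assumption that non-templated junction bases are unmutated:
templated positions revert to the germline base, N positions are copied
from the observed read.  Substitutions between the mature sequence and the
UCA are reported in IMGT coordinates.

Boundary bases are assigned conservatively: beyond a core region the V and
J blocks extend only while the read matches the germline exactly, so a
somatic mutation immediately adjacent to a trimmed junction end is
absorbed into the N region (and, by the UCA assumption, never reported).
This asymmetry is inherent to junction analysis and is asserted, not
hidden, in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .imgt import (
    GermlineAllele,
    ImgtPosition,
    NumberedDomain,
    NumberedResidue,
    Substitution,
    number_cdr3,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Rearrangement",
    "SegmentAlignment",
    "JunctionAnnotation",
    "UCAResult",
    "NoAssignmentError",
    "align_v",
    "align_j",
    "find_d",
    "classify_bases",
    "build_uca",
    "codon_template_coverage",
    "infer_uca",
    "j_anchor_offset",
    "airr_table",
]

MIN_LENGTH = {"H": 250, "L": 230}


class NoAssignmentError(ValueError):
    """No germline allele aligns acceptably to the read."""


@dataclass(frozen=True)
class Rearrangement:
    """A rearranged variable-region nucleotide sequence, V through J, in frame."""

    id: str
    chain: str
    seq_nt: str

    def __post_init__(self) -> None:
        if self.chain not in ("H", "L"):
            raise ValueError(f"chain must be H or L, got {self.chain!r}")
        if set(self.seq_nt) - set("ACGT"):
            raise ValueError("rearrangement must be plain DNA")
        if len(self.seq_nt) < MIN_LENGTH[self.chain]:
            raise ValueError(
                f"{self.id}: length {len(self.seq_nt)} below the "
                f"{MIN_LENGTH[self.chain]} nt sanity floor for chain {self.chain}"
            )
        aa = str(Seq(self.seq_nt[: len(self.seq_nt) // 3 * 3]).translate())
        if "*" in aa:
            raise ValueError(f"{self.id}: stop codon in reading frame")


@dataclass
class SegmentAlignment:
    """A gap-free alignment of one germline segment onto the read.

    Coordinates are 0-based half-open; the read and germline intervals have
    equal length (no indels).  ``ties`` lists co-optimal allele names
    (including the chosen one) when assignment was ambiguous.
    """

    allele: GermlineAllele
    read_start: int
    read_end: int
    germline_start: int
    germline_end: int
    mismatch_positions: list[int] = field(default_factory=list)
    ties: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.read_end <= self.read_start or self.germline_end <= self.germline_start:
            raise ValueError("alignment intervals must be non-empty")
        if self.read_end - self.read_start != self.germline_end - self.germline_start:
            raise ValueError("read and germline intervals must have equal length")

    @property
    def allele_name(self) -> str:
        return self.allele.name


@dataclass
class JunctionAnnotation:
    """Per-base origin labels (V/D/J/N) for a rearrangement."""

    labels: list[str]
    d_candidates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.labels) - set("VDJN"):
            raise ValueError("labels must be V, D, J or N")

    def count(self, label: str) -> int:
        return self.labels.count(label)

    def blocks(self) -> list[tuple[str, int, int]]:
        """Maximal runs of one label as (label, start, end)."""
        out = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                out.append((self.labels[start], start, i))
                start = i
        return out


def _candidates(alleles, segment: str, chain: str) -> list[GermlineAllele]:
    loci = ("IGH",) if chain == "H" else ("IGK", "IGL")
    return sorted(
        (a for a in alleles if a.segment == segment and a.locus in loci),
        key=lambda a: a.name,
    )


def align_v(
    r: Rearrangement,
    v_alleles,
    core_reserve: int = 15,
    max_mismatch_frac: float = 0.2,
) -> SegmentAlignment:
    """Assign and align the V allele, anchored at the read 5' end.

    The allele minimizing mismatches over the junction-distal core (the
    germline minus ``core_reserve`` 3'-terminal bases, which may be trimmed)
    is selected; co-optimal alleles are reported as ties and the
    lexicographically smallest name is used.  Beyond the core the V block
    extends only while read and germline match exactly.
    """
    cands = _candidates(v_alleles, "V", r.chain)
    if not cands:
        raise NoAssignmentError(f"no V alleles for chain {r.chain}")
    scored = []
    for a in cands:
        n = min(len(r.seq_nt), len(a.seq_nt))
        core = n - core_reserve
        if core < 50:
            continue
        mm = sum(1 for i in range(core) if r.seq_nt[i] != a.seq_nt[i])
        scored.append((mm, core, a))
    if not scored:
        raise NoAssignmentError("no V allele long enough to anchor the read")
    best_mm = min(s[0] for s in scored)
    ties = [s for s in scored if s[0] == best_mm]
    mm, core, allele = ties[0]
    if mm / core > max_mismatch_frac:
        raise NoAssignmentError(
            f"best V allele {allele.name} mismatch fraction {mm / core:.2f} > "
            f"{max_mismatch_frac}"
        )
    n = min(len(r.seq_nt), len(allele.seq_nt))
    end = core
    while end < n and r.seq_nt[end] == allele.seq_nt[end]:
        end += 1
    mismatch_positions = [i for i in range(end) if r.seq_nt[i] != allele.seq_nt[i]]
    if len(ties) > 1:
        logger.warning(
            "%s: co-optimal V alleles %s; choosing %s",
            r.id,
            [t[2].name for t in ties],
            allele.name,
        )
    return SegmentAlignment(
        allele=allele,
        read_start=0,
        read_end=end,
        germline_start=0,
        germline_end=end,
        mismatch_positions=mismatch_positions,
        ties=[t[2].name for t in ties],
    )


def align_j(
    r: Rearrangement,
    j_alleles,
    core_reserve: int = 15,
    max_mismatch_frac: float = 0.2,
) -> SegmentAlignment:
    """Assign and align the J allele, anchored at the read 3' end.

    The 5' end of J may be exonuclease-trimmed; ``germline_start`` reports
    how many germline bases are absent from the read.
    """
    cands = _candidates(j_alleles, "J", r.chain)
    if not cands:
        raise NoAssignmentError(f"no J alleles for chain {r.chain}")
    read = r.seq_nt
    scored = []
    for a in cands:
        n = min(len(read), len(a.seq_nt))
        core = n - core_reserve
        if core < 12:
            continue
        mm = sum(1 for k in range(core) if read[-1 - k] != a.seq_nt[-1 - k])
        scored.append((mm, core, a))
    if not scored:
        raise NoAssignmentError("no usable J allele")
    best_mm = min(s[0] for s in scored)
    ties = [s for s in scored if s[0] == best_mm]
    mm, core, allele = ties[0]
    if mm / core > max_mismatch_frac:
        raise NoAssignmentError(
            f"best J allele {allele.name} mismatch fraction {mm / core:.2f} > "
            f"{max_mismatch_frac}"
        )
    n = min(len(read), len(allele.seq_nt))
    extent = core
    while extent < n and read[-1 - extent] == allele.seq_nt[-1 - extent]:
        extent += 1
    read_start = len(read) - extent
    germ_start = len(allele.seq_nt) - extent
    mismatch_positions = [
        read_start + i
        for i in range(extent)
        if read[read_start + i] != allele.seq_nt[germ_start + i]
    ]
    return SegmentAlignment(
        allele=allele,
        read_start=read_start,
        read_end=len(read),
        germline_start=germ_start,
        germline_end=len(allele.seq_nt),
        mismatch_positions=mismatch_positions,
        ties=[t[2].name for t in ties],
    )


def _longest_common_run(window: str, germ: str) -> tuple[int, int, int]:
    """(run length, window offset, germline offset) of the longest exact run."""
    best = (0, 0, 0)
    nw, ng = len(window), len(germ)
    for i in range(nw):
        for j in range(ng):
            k = 0
            while i + k < nw and j + k < ng and window[i + k] == germ[j + k]:
                k += 1
            if k > best[0]:
                best = (k, i, j)
    return best


def find_d(
    r: Rearrangement,
    v_aln: SegmentAlignment,
    j_aln: SegmentAlignment,
    d_alleles,
    min_len: int = 5,
) -> list[SegmentAlignment]:
    """Exact-run D search in the junction window between V end and J start.

    All alleles achieving the maximal run length >= ``min_len`` are
    returned (ties are real and must be reported); an empty list means no
    D could be assigned, which is the expected outcome for light chains.
    """
    window = r.seq_nt[v_aln.read_end : j_aln.read_start]
    if not window:
        return []
    cands = _candidates(d_alleles, "D", r.chain)
    hits = []
    for a in cands:
        run, wi, gi = _longest_common_run(window, a.seq_nt)
        if run >= min_len:
            hits.append((run, a, wi, gi))
    if not hits:
        return []
    best_run = max(h[0] for h in hits)
    out = []
    for run, a, wi, gi in hits:
        if run != best_run:
            continue
        start = v_aln.read_end + wi
        out.append(
            SegmentAlignment(
                allele=a,
                read_start=start,
                read_end=start + run,
                germline_start=gi,
                germline_end=gi + run,
            )
        )
    return sorted(out, key=lambda s: s.allele_name)


def classify_bases(
    r: Rearrangement,
    v_aln: SegmentAlignment,
    d_alns: list[SegmentAlignment],
    j_aln: SegmentAlignment,
) -> JunctionAnnotation:
    """Label every read base V, D, J or N.

    Overlapping segment claims are resolved by precedence V > J > D with a
    logged warning; anything not claimed by a segment is N.
    """
    labels = ["N"] * len(r.seq_nt)

    def claim(start: int, end: int, label: str) -> None:
        for i in range(start, end):
            if labels[i] != "N":
                logger.warning(
                    "%s: base %d claimed by %s and %s; keeping %s",
                    r.id,
                    i,
                    labels[i],
                    label,
                    labels[i],
                )
                continue
            labels[i] = label

    claim(v_aln.read_start, v_aln.read_end, "V")
    claim(j_aln.read_start, j_aln.read_end, "J")
    if d_alns:
        claim(d_alns[0].read_start, d_alns[0].read_end, "D")
    return JunctionAnnotation(
        labels=labels, d_candidates=[d.allele_name for d in d_alns]
    )


def j_anchor_offset(j_allele: GermlineAllele) -> int:
    """Germline nt offset of the FR4-initiating J anchor (J-TRP / J-PHE).

    Located by scanning the three frames for the conserved W-G-x-G (heavy)
    or F-G-x-G (light) motif.
    """
    target = "W" if j_allele.locus == "IGH" else "F"
    for frame in range(3):
        aa = str(Seq(j_allele.seq_nt[frame:]).translate())
        for i in range(len(aa) - 3):
            if aa[i] == target and aa[i + 1] == "G" and aa[i + 3] == "G":
                return frame + 3 * i
    raise ValueError(f"{j_allele.name}: no {target}-G-x-G anchor motif found")


@dataclass
class UCAResult:
    """The inferred unmutated common ancestor of one rearrangement."""

    uca_nt: str
    mature_domain: NumberedDomain
    uca_domain: NumberedDomain
    substitutions: list[Substitution]
    codon_coverage: dict[ImgtPosition, int]
    cdr3_start: int
    fr4_start: int

    @property
    def cdr3_length(self) -> int:
        return (self.fr4_start - self.cdr3_start) // 3


def _numbered(
    seq_nt: str,
    chain: str,
    v_allele: GermlineAllele,
    cdr3_start: int,
    fr4_start: int,
) -> NumberedDomain:
    pmap = v_allele.position_map()
    residues = []
    offset = 0
    for pos, _ in pmap:
        if pos.number > 104 or offset + 3 > cdr3_start:
            break
        codon = seq_nt[offset : offset + 3]
        residues.append(
            NumberedResidue(
                ImgtPosition(pos.number, pos.insertion, chain),
                str(Seq(codon).translate()),
                codon,
            )
        )
        offset += 3
    cdr3_nt = seq_nt[cdr3_start:fr4_start]
    positions = number_cdr3("X" * (len(cdr3_nt) // 3))
    for k, pos in enumerate(positions):
        codon = cdr3_nt[3 * k : 3 * k + 3]
        residues.append(
            NumberedResidue(
                ImgtPosition(pos.number, pos.insertion, chain),
                str(Seq(codon).translate()),
                codon,
            )
        )
    number = 118
    for off in range(fr4_start, len(seq_nt) - 2, 3):
        codon = seq_nt[off : off + 3]
        residues.append(
            NumberedResidue(
                ImgtPosition(number, chain=chain), str(Seq(codon).translate()), codon
            )
        )
        number += 1
    return NumberedDomain(chain=chain, residues=residues)


def build_uca(
    r: Rearrangement,
    annotation: JunctionAnnotation,
    v_aln: SegmentAlignment,
    d_alns: list[SegmentAlignment],
    j_aln: SegmentAlignment,
) -> UCAResult:
    """Build the most likely UCA and the mature-vs-UCA substitution list.

    Templated positions are reverted to the germline base; non-templated
    (N) positions are assumed unmutated and copied from the observed read.
    """
    uca = list(r.seq_nt)
    for i in range(v_aln.read_start, v_aln.read_end):
        uca[i] = v_aln.allele.seq_nt[v_aln.germline_start + (i - v_aln.read_start)]
    for i in range(j_aln.read_start, j_aln.read_end):
        uca[i] = j_aln.allele.seq_nt[j_aln.germline_start + (i - j_aln.read_start)]
    if d_alns:
        d = d_alns[0]
        for i in range(d.read_start, d.read_end):
            if annotation.labels[i] == "D":
                uca[i] = d.allele.seq_nt[d.germline_start + (i - d.read_start)]
    uca_nt = "".join(uca)

    # CDR3 spans from the end of IMGT codon 104 to the J FR4 anchor.
    v_codons_104 = sum(
        1 for pos, _ in v_aln.allele.position_map() if pos.number <= 104
    )
    cdr3_start = 3 * v_codons_104
    anchor = j_anchor_offset(j_aln.allele)
    fr4_start = j_aln.read_start + (anchor - j_aln.germline_start)
    if fr4_start <= cdr3_start or fr4_start % 3 != 0:
        raise ValueError(
            f"{r.id}: junction out of frame (CDR3 {cdr3_start}..{fr4_start})"
        )
    mature_dom = _numbered(r.seq_nt, r.chain, v_aln.allele, cdr3_start, fr4_start)
    uca_dom = _numbered(uca_nt, r.chain, v_aln.allele, cdr3_start, fr4_start)

    subs = []
    for m_res, u_res in zip(mature_dom.residues, uca_dom.residues):
        if m_res.aa != u_res.aa:
            subs.append(Substitution(u_res.aa, m_res.position, m_res.aa))

    cdr3_positions = [
        res.position for res in mature_dom.residues if res.region == "CDR3"
    ]
    coverage = codon_template_coverage(annotation, cdr3_positions, cdr3_start)
    return UCAResult(
        uca_nt=uca_nt,
        mature_domain=mature_dom,
        uca_domain=uca_dom,
        substitutions=subs,
        codon_coverage=coverage,
        cdr3_start=cdr3_start,
        fr4_start=fr4_start,
    )


def codon_template_coverage(
    annotation: JunctionAnnotation,
    cdr3_positions: list[ImgtPosition],
    cdr3_start: int,
) -> dict[ImgtPosition, int]:
    """Per-CDR3-codon count (0-3) of germline-templated bases.

    Residues with count 0 are encoded entirely by non-templated junction
    bases.
    """
    out = {}
    for k, pos in enumerate(cdr3_positions):
        start = cdr3_start + 3 * k
        out[pos] = sum(
            1 for i in range(start, start + 3) if annotation.labels[i] != "N"
        )
    return out


@dataclass
class LineageInference:
    """Bundle of everything inferred for one rearrangement."""

    rearrangement: Rearrangement
    v: SegmentAlignment
    d: list[SegmentAlignment]
    j: SegmentAlignment
    annotation: JunctionAnnotation
    uca: UCAResult


def infer_uca(r: Rearrangement, germline_set, min_d_len: int = 5) -> LineageInference:
    """Full inference for one rearrangement: align, classify, build the UCA."""
    v_aln = align_v(r, germline_set)
    j_aln = align_j(r, germline_set)
    d_alns = find_d(r, v_aln, j_aln, germline_set, min_len=min_d_len) if r.chain == "H" else []
    annotation = classify_bases(r, v_aln, d_alns, j_aln)
    uca = build_uca(r, annotation, v_aln, d_alns, j_aln)
    return LineageInference(r, v_aln, d_alns, j_aln, annotation, uca)


def airr_table(results: list[LineageInference]) -> pd.DataFrame:
    """AIRR-rearrangement-style summary with UCA custom columns."""
    rows = []
    for res in results:
        junction_nt = res.rearrangement.seq_nt[
            res.uca.cdr3_start - 3 : res.uca.fr4_start + 3
        ]
        rows.append(
            {
                "sequence_id": res.rearrangement.id,
                "sequence": res.rearrangement.seq_nt,
                "v_call": ",".join(res.v.ties) if len(res.v.ties) > 1 else res.v.allele_name,
                "d_call": ",".join(res.annotation.d_candidates),
                "j_call": ",".join(res.j.ties) if len(res.j.ties) > 1 else res.j.allele_name,
                "junction": junction_nt,
                "junction_aa": str(Seq(junction_nt).translate()),
                "uca_sequence": res.uca.uca_nt,
                "substitutions": ",".join(str(s) for s in res.uca.substitutions),
            }
        )
    return pd.DataFrame(rows)


def json_report(res: LineageInference) -> str:
    """Per-sequence JSON report of the inference."""
    payload = {
        "sequence_id": res.rearrangement.id,
        "chain": res.rearrangement.chain,
        "v_call": res.v.allele_name,
        "v_ties": res.v.ties,
        "d_candidates": res.annotation.d_candidates,
        "j_call": res.j.allele_name,
        "n_bases": res.annotation.count("N"),
        "cdr3_length": res.uca.cdr3_length,
        "substitutions": [str(s) for s in res.uca.substitutions],
        "codon_coverage": {
            str(pos): cnt for pos, cnt in res.uca.codon_coverage.items()
        },
        "uca_sequence": res.uca.uca_nt,
    }
    return json.dumps(payload, indent=2)
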