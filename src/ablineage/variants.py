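"""Reversion-variant panel enumeration and site-directed mutagenesis primers.

The experimental panel walks back the somatic substitutions of a mature
antibody toward its UCA (singles, cumulative heavy combinations, the light
chain block, and the full reversion) and additionally swaps the
allele-unique residues of the heavy chain V gene.  Mutagenesis uses fully
overlapping complementary primer pairs centred on the mutated codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

from .imgt import NumberedDomain, Substitution, parse_substitution

__all__ = [
    "VariantSpec",
    "PrimerPair",
    "PrimerValidation",
    "PrimerDesignError",
    "enumerate_panel",
    "apply_substitutions",
    "design_primers",
    "validate_primer_pair",
]


class PrimerDesignError(ValueError):
    """Primer design is impossible with the requested geometry."""


# Codon preference per amino acid, ordered by human codon usage; used to
# break ties among equally small nucleotide edits.
CODON_PREFERENCE: dict[str, list[str]] = {
    "A": ["GCC", "GCT", "GCA", "GCG"],
    "C": ["TGC", "TGT"],
    "D": ["GAC", "GAT"],
    "E": ["GAG", "GAA"],
    "F": ["TTC", "TTT"],
    "G": ["GGC", "GGA", "GGG", "GGT"],
    "H": ["CAC", "CAT"],
    "I": ["ATC", "ATT", "ATA"],
    "K": ["AAG", "AAA"],
    "L": ["CTG", "CTC", "TTG", "CTT", "CTA", "TTA"],
    "M": ["ATG"],
    "N": ["AAC", "AAT"],
    "P": ["CCC", "CCT", "CCA", "CCG"],
    "Q": ["CAG", "CAA"],
    "R": ["CGG", "AGA", "AGG", "CGC", "CGA", "CGT"],
    "S": ["AGC", "TCC", "TCT", "AGT", "TCA", "TCG"],
    "T": ["ACC", "ACA", "ACT", "ACG"],
    "V": ["GTG", "GTC", "GTT", "GTA"],
    "W": ["TGG"],
    "Y": ["TAC", "TAT"],
}


def _as_subs(items: Iterable[Substitution | str]) -> list[Substitution]:
    out = []
    for item in items:
        out.append(item if isinstance(item, Substitution) else parse_substitution(item))
    return out


def _sub_sort_key(s: Substitution):
    return (s.chain, s.position.sort_key)


def _canonical_name(subs: Sequence[Substitution], all_lineage: frozenset) -> str:
    if not subs:
        return "212579"
    if frozenset(subs) == all_lineage and all_lineage:
        return "UCA"
    heavy = sorted([s for s in subs if s.chain == "H"], key=_sub_sort_key)
    light = sorted([s for s in subs if s.chain == "L"], key=_sub_sort_key)
    return ",".join(str(s) for s in heavy + light)


@dataclass(frozen=True)
class VariantSpec:
    """A named antibody variant: a background plus a substitution set."""

    name: str
    background: str  # "mature" or "UCA"
    substitutions: frozenset[Substitution]

    def __post_init__(self) -> None:
        if self.background not in ("mature", "UCA"):
            raise ValueError(f"unknown background {self.background!r}")
        positions = [(s.chain, s.position) for s in self.substitutions]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one substitution per position")


def enumerate_panel(
    heavy_subs: Iterable[Substitution | str],
    light_subs: Iterable[Substitution | str],
    allele_swaps: Iterable[Substitution | str] = (),
) -> list[VariantSpec]:
    """Enumerate the reversion/allele-swap variant panel.

    The panel consists of the parental antibody; each heavy-chain reversion
    alone; cumulative heavy combinations in position order; the light-chain
    reversions as a single block, alone and combined with each heavy
    reversion of the penultimate cumulative step; the full reversion (UCA);
    and each allele swap alone plus all swaps together.  For the six
    lineage substitutions and two allele swaps of antibody 212579 this
    yields the published 13-member panel.  Enumeration is deterministic and
    independent of input ordering.
    """
    heavy = sorted(_as_subs(heavy_subs), key=_sub_sort_key)
    light = sorted(_as_subs(light_subs), key=_sub_sort_key)
    swaps = sorted(_as_subs(allele_swaps), key=_sub_sort_key)
    all_lineage = frozenset(heavy + light)

    sets: list[frozenset[Substitution]] = [frozenset()]
    for h in heavy:
        sets.append(frozenset([h]))
    for k in range(2, len(heavy) + 1):
        sets.append(frozenset(heavy[:k]))
    if light:
        block = frozenset(light)
        sets.append(block)
        for h in heavy[: max(len(heavy) - 1, 0)]:
            sets.append(block | {h})
        sets.append(all_lineage)
    for a in swaps:
        sets.append(frozenset([a]))
    if len(swaps) >= 2:
        sets.append(frozenset(swaps))

    seen: set[frozenset[Substitution]] = set()
    panel: list[VariantSpec] = []
    for s in sets:
        if s in seen:
            continue
        seen.add(s)
        panel.append(
            VariantSpec(
                name=_canonical_name(sorted(s, key=_sub_sort_key), all_lineage),
                background="mature",
                substitutions=s,
            )
        )
    return panel


def _choose_codon(current: str, target_aa: str) -> str:
    """Codon for ``target_aa`` with minimal nucleotide edits from ``current``.

    Ties are broken by a fixed human-usage preference order, then
    alphabetically.
    """
    candidates = CODON_PREFERENCE[target_aa]
    ranked = sorted(
        candidates,
        key=lambda c: (
            sum(1 for a, b in zip(c, current) if a != b),
            candidates.index(c),
            c,
        ),
    )
    return ranked[0]


def apply_substitutions(
    gene_nt: str,
    numbered: NumberedDomain,
    subs: Iterable[Substitution | str],
    codon_policy=_choose_codon,
) -> str:
    """Apply amino-acid substitutions to a nucleotide gene.

    ``numbered`` maps IMGT positions onto consecutive codons starting at
    the 5' end of ``gene_nt``.  Each targeted codon is replaced by the
    policy's choice (default: minimal nucleotide edit, ties by a fixed
    preference table); all other positions are untouched.
    """
    subs = _as_subs(subs)
    seq = list(gene_nt)
    index_of = {r.position: i for i, r in enumerate(numbered.residues)}
    for s in subs:
        if s.position not in index_of:
            raise KeyError(f"position {s.position} not present in numbered domain")
        i = index_of[s.position]
        offset = 3 * i
        codon = gene_nt[offset : offset + 3]
        observed = str(Seq(codon).translate())
        if observed != s.from_aa:
            raise ValueError(
                f"substitution {s} inconsistent with template: codon {codon} at "
                f"IMGT {s.position} encodes {observed}, expected {s.from_aa}"
            )
        seq[offset : offset + 3] = codon_policy(codon, s.to_aa)
    return "".join(seq)


@dataclass(frozen=True)
class PrimerPair:
    """An overlapping complementary primer pair for one substitution."""

    forward: str
    reverse: str
    substitution: Substitution
    overlap_len: int

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if set(p) - set("ACGT"):
                raise ValueError("primers must be plain DNA")


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _anchored_overlap(forward: str, rc_reverse: str, max_shift: int = 3) -> int:
    """Longest 5'-anchored common run between forward and revcomp(reverse).

    A shift of up to ``max_shift`` nt between the two windows is allowed
    (published pairs differ in window placement by a few bases).
    """
    best = 0
    for shift in range(-max_shift, max_shift + 1):
        run = 0
        for i in range(len(forward)):
            j = i + shift
            if j < 0 or j >= len(rc_reverse):
                break
            if forward[i] != rc_reverse[j]:
                break
            run += 1
        best = max(best, run)
    return best


def design_primers(
    template_nt: str,
    numbered: NumberedDomain,
    sub: Substitution | str,
    flank: int = 14,
    rev_extra: int = 0,
) -> PrimerPair:
    """Design an overlapping complementary mutagenesis primer pair.

    The forward primer spans ``flank`` nt on each side of the mutated codon
    (mutant codon included); the reverse primer is the reverse complement
    of the same window extended 3' by ``rev_extra`` (0-3) nt, so the
    reverse complement of the reverse primer carries the forward primer as
    a prefix.
    """
    if isinstance(sub, str):
        sub = parse_substitution(sub)
    if not 0 <= rev_extra <= 3:
        raise PrimerDesignError("rev_extra must be within 0..3")
    index_of = {r.position: i for i, r in enumerate(numbered.residues)}
    if sub.position not in index_of:
        raise PrimerDesignError(f"position {sub.position} not in numbered domain")
    offset = 3 * index_of[sub.position]
    start = offset - flank
    end = offset + 3 + flank + rev_extra
    if start < 0 or end > len(template_nt):
        raise PrimerDesignError(
            f"codon at {sub.position} too close to template end for flank {flank}"
        )
    mutant = apply_substitutions(template_nt, numbered, [sub])
    window = mutant[start:end]
    forward = window[: 2 * flank + 3]
    reverse = _revcomp(window)
    return PrimerPair(
        forward=forward,
        reverse=reverse,
        substitution=sub,
        overlap_len=len(forward),
    )


@dataclass
class PrimerValidation:
    """Per-check validation report for a primer pair.

    Check values are True/False, or None when the check needs a template
    that was not supplied.
    """

    complementarity: bool
    overlap_len: int
    template_match: bool | None
    translated_effect: bool | None
    est_tm_forward_C: float
    details: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        checks = [self.complementarity, self.template_match, self.translated_effect]
        return all(c for c in checks if c is not None)


def _best_template_offset(primer: str, template: str) -> tuple[int, list[int]]:
    """Offset in template minimizing mismatches to the primer; returns
    (offset, mismatch positions relative to primer)."""
    best = (len(primer) + 1, -1, [])
    for off in range(len(template) - len(primer) + 1):
        mm = [i for i in range(len(primer)) if primer[i] != template[off + i]]
        if len(mm) < best[0]:
            best = (len(mm), off, mm)
    return best[1], best[2]


def validate_primer_pair(
    pair: PrimerPair, template_nt: str | None = None
) -> PrimerValidation:
    """Validate a mutagenesis primer pair.

    Checks: (a) mutual complementarity of forward and reverse over at least
    the reported overlap; (b) each primer matches the template except at
    the intended codon (template required); (c) applying the forward primer
    to the template produces exactly the target substitution (template
    required); (d) an informational nearest-neighbour Tm estimate.
    """
    rc_rev = _revcomp(pair.reverse)
    overlap = _anchored_overlap(pair.forward, rc_rev)
    complementarity = overlap >= pair.overlap_len
    est_tm = float(MeltingTemp.Tm_NN(Seq(pair.forward)))
    details: dict = {"observed_overlap": overlap}

    template_match: bool | None = None
    translated_effect: bool | None = None
    if template_nt is not None:
        off_f, mm_f = _best_template_offset(pair.forward, template_nt)
        off_r, mm_r = _best_template_offset(rc_rev, template_nt)
        details["forward_offset"] = off_f
        details["forward_mismatches"] = mm_f
        details["reverse_mismatches"] = mm_r

        def confined(mm: list[int], off: int) -> bool:
            if not mm:
                return True
            lo, hi = min(mm) + off, max(mm) + off
            return hi - lo < 3 and lo // 3 == hi // 3

        template_match = (
            len(mm_f) <= 3
            and len(mm_r) <= 3
            and off_f >= 0
            and off_r >= 0
            and confined(mm_f, off_f)
            and confined(mm_r, off_r)
        )
        if template_match and mm_f:
            codon_idx = (min(mm_f) + off_f) // 3
            old = template_nt[3 * codon_idx : 3 * codon_idx + 3]
            mutated = (
                template_nt[: off_f] + pair.forward + template_nt[off_f + len(pair.forward) :]
            )
            new = mutated[3 * codon_idx : 3 * codon_idx + 3]
            translated_effect = (
                str(Seq(old).translate()) == pair.substitution.from_aa
                and str(Seq(new).translate()) == pair.substitution.to_aa
            )
        elif template_match:
            translated_effect = False  # no edit at all
        else:
            translated_effect = False
    return PrimerValidation(
        complementarity=complementarity,
        overlap_len=overlap,
        template_match=template_match,
        translated_effect=translated_effect,
        est_tm_forward_C=est_tm,
        details=details,
    )
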