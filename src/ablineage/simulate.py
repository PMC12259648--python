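"""Synthetic-data generators: germline fixtures, V(D)J rearrangements, traces.

Everything the pipeline consumes can be generated here with a fixed seed:

* a fixture germline set — one synthetic heavy V gene with four alleles
  mirroring the allele structure of IGHV3-48 (two CDR differences at
  positions 38/62, one FR3 difference at 96, one synonymous variant),
  plus D, J and kappa V/J alleles;
* simulated V(D)J rearrangements with exonuclease trimming, non-templated
  (N) additions and point somatic hypermutation, each paired with a
  complete ground-truth record; and
* instrument traces (sensorgram concentration series, melt-curve
  triplicates, taylorgram triplicates at two temperatures) matching the
  study designs.

Generators are pure functions of (seed, config): outputs are byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq

from . import biophys, kinetics
from .imgt import GermlineAllele, write_germline_set
from .uca import Rearrangement

__all__ = [
    "ScenarioConfig",
    "RearrangementGroundTruth",
    "make_fixture_germline_set",
    "simulate_rearrangement",
    "simulate_instrument_suite",
]

_AA_CODONS = {
    "A": ["GCC", "GCT", "GCA", "GCG"],
    "D": ["GAC", "GAT"],
    "E": ["GAG", "GAA"],
    "G": ["GGC", "GGA", "GGG", "GGT"],
    "I": ["ATC", "ATT"],
    "K": ["AAG", "AAA"],
    "L": ["CTG", "CTC"],
    "N": ["AAC", "AAT"],
    "P": ["CCC", "CCT"],
    "Q": ["CAG", "CAA"],
    "R": ["CGG", "AGA"],
    "S": ["AGC", "TCC", "TCT"],
    "T": ["ACC", "ACA"],
    "V": ["GTG", "GTC"],
    "Y": ["TAC", "TAT"],
    "F": ["TTC", "TTT"],
    "H": ["CAC", "CAT"],
    "M": ["ATG"],
    "W": ["TGG"],
    "C": ["TGC", "TGT"],
}

# Amino acids drawn for framework filler; W/C/F excluded so that conserved
# anchors and the J W-G-x-G / F-G-x-G motifs stay unique.
_FILLER_AAS = "ADEGIKLNPQRSTVYHM"

HEAVY_V_GAPS = (10, 31, 32, 73)
LIGHT_V_GAPS = (10, 81, 82)
HEAVY_J_FR4 = "TGGGGCCAAGGCACCCTGGTCACCGTCTCCTCA"  # WGQGTLVTVSS
LIGHT_J_FR4 = "TTCGGCGGAGGGACCAAGGTGGAGATCAAA"  # FGGGTKVEIK


def _codon(rng: np.random.Generator, aa: str) -> str:
    opts = _AA_CODONS[aa]
    return opts[int(rng.integers(len(opts)))]


def _random_codons(rng: np.random.Generator, n: int, exclude: str = "WCF") -> str:
    aas = [a for a in _FILLER_AAS if a not in exclude]
    return "".join(_codon(rng, aas[int(rng.integers(len(aas)))]) for _ in range(n))


def _build_v_gene(
    rng: np.random.Generator,
    gaps: tuple[int, ...],
    fixed_aa: dict[int, str],
    tail_aa: str,
) -> tuple[str, dict[int, str]]:
    """Gapped V sequence (codons 1..104 plus an ungapped CDR3 tail).

    Returns the gapped nucleotide string and the per-position codon map so
    allele variants can swap individual codons.
    """
    codons: dict[int, str] = {}
    for pos in range(1, 105):
        if pos in gaps:
            continue
        if pos in fixed_aa:
            codons[pos] = _codon(rng, fixed_aa[pos])
        else:
            aa = _FILLER_AAS[int(rng.integers(len(_FILLER_AAS)))]
            codons[pos] = _codon(rng, aa)
    tail = "".join(_codon(rng, aa) for aa in tail_aa)
    gapped = "".join(
        codons[p] if p in codons else "..." for p in range(1, 105)
    ) + tail
    return gapped, codons


def _with_codon(gapped: str, position: int, codon: str) -> str:
    offset = 3 * (position - 1)
    return gapped[:offset] + codon + gapped[offset + 3 :]


def make_fixture_germline_set(seed: int = 0) -> list[GermlineAllele]:
    """Deterministic synthetic germline set.

    The heavy V gene carries four alleles: *01 (S38/S62/G96 baseline),
    *02 (D96, framework 3), *03 (E38/G62, the CDR-variant allele) and *04
    (a synonymous nucleotide variant of *01).  Comparing the *03-like and
    *01-like alleles at the protein level therefore yields differences at
    exactly positions 38 and 62.
    """
    rng = np.random.default_rng(seed)
    fixed = {23: "C", 41: "W", 104: "C", 38: "S", 62: "S", 96: "G"}
    hv_gapped, hv_codons = _build_v_gene(rng, HEAVY_V_GAPS, fixed, tail_aa="AR")

    hv01 = hv_gapped
    hv02 = _with_codon(hv_gapped, 96, "GAC")  # G96D, FR3
    hv03 = _with_codon(_with_codon(hv_gapped, 38, "GAG"), 62, "GGA")  # S38E, S62G
    # synonymous variant of *01 at position 50
    syn_pos = 50
    old = hv_codons[syn_pos]
    aa50 = str(Seq(old).translate())
    alt = next(c for c in _AA_CODONS[aa50] if c != old) if len(_AA_CODONS[aa50]) > 1 else old
    hv04 = _with_codon(hv_gapped, syn_pos, alt)

    lv_fixed = {23: "C", 41: "W", 104: "C"}
    # kappa V genes contribute most of the short light CDR3
    lv_gapped, _ = _build_v_gene(rng, LIGHT_V_GAPS, lv_fixed, tail_aa="QQYGSSP")

    def v(name, locus, gapped):
        return GermlineAllele(
            name=name,
            locus=locus,
            segment="V",
            seq_nt=gapped.replace(".", ""),
            gapped_seq_nt=gapped,
        )

    d_lengths = {"SYNHD2-2*01": 20, "SYNHD3-3*01": 23, "SYNHD6-6*01": 16}
    d_alleles = [
        GermlineAllele(
            name=name,
            locus="IGH",
            segment="D",
            seq_nt="".join("ACGT"[int(rng.integers(4))] for _ in range(length)),
        )
        for name, length in d_lengths.items()
    ]
    hj = _random_codons(rng, 4) + HEAVY_J_FR4
    lj = _random_codons(rng, 2) + LIGHT_J_FR4
    return [
        v("SYNHV3-7*01", "IGH", hv01),
        v("SYNHV3-7*02", "IGH", hv02),
        v("SYNHV3-7*03", "IGH", hv03),
        v("SYNHV3-7*04", "IGH", hv04),
        *d_alleles,
        GermlineAllele(name="SYNHJ4-1*01", locus="IGH", segment="J", seq_nt=hj),
        v("SYNKV2-5*01", "IGK", lv_gapped),
        GermlineAllele(name="SYNKJ1-1*01", locus="IGK", segment="J", seq_nt=lj),
    ]


def write_fixture_germline_fasta(path: str | Path, seed: int = 0) -> None:
    write_germline_set(make_fixture_germline_set(seed), path)


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic scenario; serializable to/from YAML."""

    seed: int = 0
    chain: str = "H"
    shm_rate: float = 0.02
    trim_geom_p: float = 0.35
    max_v_trim: int = 6
    max_d_trim: int = 4
    max_j_trim: int = 12
    n_geom_p: float = 0.25
    max_n_len: int = 12
    min_cdr3_len: int = 8
    max_cdr3_len: int = 24
    v_allele: str | None = None
    d_allele: str | None = None
    j_allele: str | None = None
    planted_positions: tuple[int, ...] = ()
    forced_n1_len: int | None = None
    forced_n2_len: int | None = None
    # instrument design (study defaults)
    conc_series_nM: tuple[float, ...] = (0.0, 1.875, 3.75, 7.5, 15.0, 30.0, 60.0)
    t_assoc_s: float = 120.0
    t_dissoc_s: float = 1360.0
    spr_noise_RU: float = 0.5
    spr_ka: float = 4.4e5
    spr_kd: float = 1.4e-4
    spr_rmax: float = 100.0
    melt_tm_C: float = 67.8
    melt_dH_kJ_mol: float = 400.0
    melt_noise_frac: float = 0.002
    rh25_nm: float = 6.52
    rh37_nm: float = 5.54
    taylor_noise: float = 0.005

    def __post_init__(self) -> None:
        for rate in (self.shm_rate, self.trim_geom_p, self.n_geom_p):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("conc_series_nM", "planted_positions"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RearrangementGroundTruth:
    """Everything the simulator decided, for use as an inference oracle."""

    chain: str
    v_name: str
    d_name: str | None
    j_name: str
    v_trim_3p: int
    d_trim_5p: int
    d_trim_3p: int
    j_trim_5p: int
    n1: str
    n2: str
    labels: list[str]
    mutations: list[dict]  # {pos, from, to, templated}
    seq_nt: str
    unmutated_nt: str

    def reconstruct(self, germline_by_name: dict[str, GermlineAllele]) -> str:
        """Re-assemble the emitted sequence from components; must equal seq_nt."""
        v = germline_by_name[self.v_name].seq_nt
        j = germline_by_name[self.j_name].seq_nt
        parts = [v[: len(v) - self.v_trim_3p], self.n1]
        if self.d_name is not None:
            d = germline_by_name[self.d_name].seq_nt
            parts.append(d[self.d_trim_5p : len(d) - self.d_trim_3p])
            parts.append(self.n2)
        parts.append(j[self.j_trim_5p :])
        seq = list("".join(parts))
        for m in self.mutations:
            if seq[m["pos"]] != m["from"]:
                raise AssertionError("ground truth inconsistent with components")
            seq[m["pos"]] = m["to"]
        return "".join(seq)


def _geom(rng: np.random.Generator, p: float, cap: int) -> int:
    return min(int(rng.geometric(p)) - 1, cap)


_BASES = "ACGT"


def simulate_rearrangement(
    germline_set: list[GermlineAllele],
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    seq_id: str = "sim",
) -> tuple[Rearrangement, RearrangementGroundTruth]:
    """Simulate one V(D)J rearrangement with ground truth.

    Heavy chains assemble V (3'-trimmed) + N1 + D (both ends trimmed) + N2 +
    J (5'-trimmed); light chains V + N + J.  Junction parameters are
    resampled until the J frame is preserved and the product is stop-free;
    point mutations are then applied at ``shm_rate`` per base (plus any
    explicitly planted coding mutations at templated V positions).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chain = config.chain
    loci = ("IGH",) if chain == "H" else ("IGK", "IGL")
    by_name = {a.name: a for a in germline_set}

    def pick(segment, preset):
        if preset is not None:
            return by_name[preset]
        opts = sorted(
            (a for a in germline_set if a.segment == segment and a.locus in loci),
            key=lambda a: a.name,
        )
        return opts[int(rng.integers(len(opts)))]

    v = pick("V", config.v_allele)
    j = pick("J", config.j_allele)
    d = pick("D", config.d_allele) if chain == "H" else None

    from .uca import j_anchor_offset

    anchor = j_anchor_offset(j)
    n104 = 3 * sum(1 for pos, _ in v.position_map() if pos.number <= 104)

    for _attempt in range(300):
        v_trim = _geom(rng, config.trim_geom_p, config.max_v_trim)
        j_trim = _geom(rng, config.trim_geom_p, min(config.max_j_trim, anchor))
        n1_len = (
            config.forced_n1_len
            if config.forced_n1_len is not None
            else _geom(rng, config.n_geom_p, config.max_n_len)
        )
        n1 = "".join(_BASES[int(rng.integers(4))] for _ in range(n1_len))
        if chain == "H":
            d_t5 = _geom(rng, config.trim_geom_p, config.max_d_trim)
            d_t3 = _geom(rng, config.trim_geom_p, config.max_d_trim)
            d_part = d.seq_nt[d_t5 : len(d.seq_nt) - d_t3]
            n2_len = (
                config.forced_n2_len
                if config.forced_n2_len is not None
                else _geom(rng, config.n_geom_p, config.max_n_len)
            )
            n2 = "".join(_BASES[int(rng.integers(4))] for _ in range(n2_len))
        else:
            d_t5 = d_t3 = 0
            d_part, n2 = "", ""
        v_part = v.seq_nt[: len(v.seq_nt) - v_trim]
        j_part = j.seq_nt[j_trim:]
        fr4_start = len(v_part) + len(n1) + len(d_part) + len(n2) + (anchor - j_trim)
        if fr4_start % 3 != 0 or fr4_start <= n104:
            continue
        cdr3_len = (fr4_start - n104) // 3
        if not config.min_cdr3_len <= cdr3_len <= config.max_cdr3_len:
            continue
        unmutated = v_part + n1 + d_part + n2 + j_part
        if len(unmutated) % 3 != 0:
            continue
        if "*" in str(Seq(unmutated).translate()):
            continue
        labels = (
            ["V"] * len(v_part)
            + ["N"] * len(n1)
            + ["D"] * len(d_part)
            + ["N"] * len(n2)
            + ["J"] * len(j_part)
        )
        mutated = _apply_mutations(unmutated, labels, v, config, rng)
        if mutated is None:
            continue
        seq, mutations = mutated
        gt = RearrangementGroundTruth(
            chain=chain,
            v_name=v.name,
            d_name=d.name if d is not None else None,
            j_name=j.name,
            v_trim_3p=v_trim,
            d_trim_5p=d_t5,
            d_trim_3p=d_t3,
            j_trim_5p=j_trim,
            n1=n1,
            n2=n2,
            labels=labels,
            mutations=mutations,
            seq_nt=seq,
            unmutated_nt=unmutated,
        )
        return Rearrangement(id=seq_id, chain=chain, seq_nt=seq), gt
    raise RuntimeError("could not sample an in-frame junction within the retry cap")


def _apply_mutations(unmutated, labels, v_allele, config, rng):
    """Planted coding mutations plus uniform per-base SHM; None if a stop
    codon cannot be avoided."""
    seq = list(unmutated)
    mutations: list[dict] = []

    # planted non-synonymous mutations at given IMGT positions (V core)
    pmap = v_allele.position_map()
    pos_to_codon_index = {
        pos.number: idx for idx, (pos, _) in enumerate(pmap) if pos.number <= 104
    }
    for number in config.planted_positions:
        idx = pos_to_codon_index[number]
        offset = 3 * idx
        codon = "".join(seq[offset : offset + 3])
        old_aa = str(Seq(codon).translate())
        done = False
        for within in range(3):
            for base in _BASES:
                if base == codon[within]:
                    continue
                new = codon[:within] + base + codon[within + 1 :]
                aa = str(Seq(new).translate())
                if aa not in ("*", old_aa):
                    mutations.append(
                        {
                            "pos": offset + within,
                            "from": codon[within],
                            "to": base,
                            "templated": True,
                        }
                    )
                    seq[offset + within] = base
                    done = True
                    break
            if done:
                break
        if not done:
            return None

    if config.shm_rate > 0:
        planted = {m["pos"] for m in mutations}
        for _retry in range(20):
            trial = list(seq)
            trial_muts = []
            hits = np.nonzero(rng.random(len(trial)) < config.shm_rate)[0]
            for pos in hits:
                pos = int(pos)
                if pos in planted:
                    continue
                old = trial[pos]
                new = [b for b in _BASES if b != old][int(rng.integers(3))]
                trial[pos] = new
                trial_muts.append(
                    {
                        "pos": pos,
                        "from": old,
                        "to": new,
                        "templated": labels[pos] != "N",
                    }
                )
            if "*" not in str(Seq("".join(trial)).translate()):
                return "".join(trial), mutations + sorted(
                    trial_muts, key=lambda m: m["pos"]
                )
        return None
    if "*" in str(Seq("".join(seq)).translate()):
        return None
    return "".join(seq), mutations


def simulate_instrument_suite(
    config: ScenarioConfig, outdir: str | Path | None = None
) -> dict:
    """Generate the full instrument-trace suite for one scenario.

    Returns sensorgrams (one per concentration, including the 0 nM blank),
    three melt-curve replicates and triplicate taylorgrams at 25 and 37
    degC; optionally writes CSVs plus a ground-truth JSON.
    """
    seed = config.seed
    sensorgrams = kinetics.simulate_sensorgram(
        config.spr_ka,
        config.spr_kd,
        config.spr_rmax,
        [c * 1e-9 for c in config.conc_series_nM],
        t_assoc_s=config.t_assoc_s,
        t_dissoc_s=config.t_dissoc_s,
        noise_sd=config.spr_noise_RU,
        seed=seed,
    )
    melts = [
        biophys.simulate_melt_curve(
            config.melt_tm_C,
            config.melt_dH_kJ_mol,
            noise_frac=config.melt_noise_frac,
            seed=seed * 1000 + rep,
            replicate=rep,
        )
        for rep in range(3)
    ]
    taylors = {25.0: [], 37.0: []}
    for temp, rh in ((25.0, config.rh25_nm), (37.0, config.rh37_nm)):
        for rep in range(3):
            taylors[temp].append(
                biophys.simulate_taylorgram(
                    rh,
                    temperature_C=temp,
                    noise_sd=config.taylor_noise,
                    seed=seed * 1000 + int(temp) * 10 + rep,
                    replicate=rep,
                )
            )
    truth = {
        "spr": {"ka": config.spr_ka, "kd": config.spr_kd, "rmax": config.spr_rmax},
        "melt": {"tm_C": config.melt_tm_C, "dH_kJ_mol": config.melt_dH_kJ_mol},
        "taylor": {"rh25_nm": config.rh25_nm, "rh37_nm": config.rh37_nm},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kinetics.write_sensorgram_csv(sensorgrams, outdir / "sensorgrams.csv")
        biophys.write_melt_csv(melts, outdir / "melt_curves.csv")
        for temp, series in taylors.items():
            for tg in series:
                biophys.write_taylorgram_csv(
                    tg, outdir / f"taylorgram_{int(temp)}C_rep{tg.replicate}.csv"
                )
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
        config.to_yaml(outdir / "scenario.yaml")
    return {
        "sensorgrams": sensorgrams,
        "melt_curves": melts,
        "taylorgrams": taylors,
        "truth": truth,
    }
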