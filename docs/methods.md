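# Methods

This note documents the models, conventions and numerical choices behind
`ablineage`, and what the synthetic-data generators do and do not emulate.

## IMGT numbering and the CDR3 insertion scheme

Variable-domain residues are numbered on the IMGT unique scheme
(FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117,
FR4 118–128). Numbering is propagated from IMGT-gapped germline V
references by gap-free alignment rather than recomputed ab initio: each
query codon inherits the position of the germline codon it aligns to and
germline gap positions are skipped. This is appropriate because the
numbering is germline-anchored and the lineage analysed here carries no
indels; inputs whose mismatch fraction exceeds 0.2 raise an explicit
unsupported-indel error instead of being silently renumbered.

CDR3 loops of length L ≠ 13 are handled at the loop apex. For L > 13,
decimal insertions are added alternating sides starting at 112.1
(112.1, 111.1, 112.2, 111.2, …), which sorts as
105…111, 111.1…111.k, 112.m…112.1, 112…117; a 19-residue loop therefore
carries 111.1–111.3 and 112.3–112.1. For L < 13 apex positions are removed
starting from the 112 side (112, 111, 113, 110, …). The insertion grammar
accepts loops up to L = 40. Gap characters '.' and '-' are both accepted
on input and normalised to '.'; germline FASTA headers follow
`>NAME|LOCUS|SEGMENT`.

Substitutions are written `<from><position>_<chain>_<to>`, e.g. `N40_H_T`
(heavy-chain Asn40 → Thr) or `D111.3_H_E`; parsing and formatting are
exact inverses.

## UCA inference

A rearranged sequence is assigned to germline segments as follows:

* **V**: gap-free alignment anchored at the read 5′ end. Allele selection
  minimises mismatches over a junction-distal core (the germline minus a
  15 nt 3′ reserve, which may have been exonuclease-trimmed); co-optimal
  alleles are reported as ties and the lexicographically smallest name is
  used for UCA construction. Beyond the core the V block extends only
  while read and germline match exactly.
* **J**: the mirror image, anchored at the read 3′ end, allowing 5′
  trimming; the reported `germline_start` is the number of germline bases
  absent from the read.
* **D** (heavy only): exact-substring search of all D alleles over the
  window between the V end and the J start; the longest exact run of at
  least 5 nt wins and *all* alleles achieving the maximal run are
  reported — allele ties are real observations, not errors. No run ≥ 5
  yields an empty D assignment (the normal light-chain outcome).

Every base not claimed by a segment is non-templated (N); P-nucleotides
are not modelled separately, matching the two-way templated/non-templated
accounting used for this lineage. The UCA reverts templated positions to
the germline base and copies N positions from the observed read — the
standard assumption that non-templated junction bases are unmutated.
Substitutions are the translated differences between the mature and UCA
domains in IMGT coordinates, and a per-CDR3-codon count of templated bases
(0–3) identifies residues encoded entirely by junction additions.

Two consequences of the exact-extension boundary rule are asserted openly
in the test suite rather than hidden: (i) a somatic mutation immediately
adjacent to a trimmed junction end stops the extension, is absorbed into
the N region and is therefore never reported — the inference-side
manifestation of the UCA assumption; (ii) a junction base that happens to
continue the germline is indistinguishable from less trimming and may be
labelled templated, but since such bases match the germline exactly the
UCA is unaffected. Recovery of planted substitutions is therefore exact
whenever all planted mutations fall inside the inferred V/J blocks and
the V/J allele assignment is unambiguous; simulation tests verify this
over ≥200 rearrangements at hypermutation rates of 0–5%, and separately
verify that N-labelled bases are bitwise identical between input and UCA.

## Variant panel and mutagenesis primers

The panel generalises the experimental design: the parental antibody;
each heavy-chain reversion alone; cumulative heavy combinations in
position order; the light-chain reversions as a single block (they were
built and tested as one unit), alone and combined with each heavy
reversion of the penultimate cumulative step; the full reversion (UCA);
and each allele swap alone plus all swaps together. For the six lineage
substitutions and two allele swaps of 212579 this reproduces the
13-member published panel; enumeration is deterministic and independent
of input ordering.

Codon edits use a "minimal nucleotide edit" policy with ties broken by a
fixed human-codon-usage preference table (so Thr ACC → Asn gives AAC, as
in the published T40_H_N primer, and Glu GAG → Ser gives the uniquely
minimal TCG, as in the published E38_H_S primer). The true policy behind
the codon-optimised expression genes is not published; the preference
table is seeded so the printed primers validate.

Primers follow the fully overlapping complementary design: the forward
primer spans a configurable flank (default 14 nt) on each side of the
mutated codon, and the reverse primer is the reverse complement of the
same window, optionally extended 3′ by up to 3 nt. Splitting each
published primer row at its midpoint yields exact reverse-complement
pairs, which is the representation stored here. Validation checks
(a) mutual complementarity over the reported overlap, (b) template match
outside the intended codon, (c) that applying the forward primer to the
template produces exactly the target substitution, and (d) reports a
nearest-neighbour Tm estimate (informational only; no Tm criterion is
enforced).

## Binding kinetics

Sensorgrams follow the 1:1 Langmuir model: during association
R(t) = R_eq (1 − e^{−(k_a C + k_d) t}) with
R_eq = R_max C / (C + K_D), and during dissociation
R(t) = R(t_assoc) e^{−k_d (t − t_assoc)}; K_D ≡ k_d / k_a and is stored as
exactly that quotient. Fitting is a *global* nonlinear least squares
sharing (k_a, k_d, R_max) across the whole concentration series — the
standard practice for this model — with the 0 M blank subtracted when
present (a per-curve-R_max mode exists behind a flag). Optimisation runs
in log-parameter space from a fixed 3×3 grid of (k_a, k_d) starts
(k_a ∈ {10³, 10⁵, 10⁷} M⁻¹s⁻¹, k_d ∈ {10⁻⁵, 10⁻³, 10⁻¹} s⁻¹) for
deterministic convergence; mass-transport limitation is not modelled.
Because parameters are fitted on the log scale, the linearised covariance
directly gives fractional errors; k_d (or k_a) is flagged as poorly
constrained when its approximate 95% interval exceeds ±50% of the
estimate. Note that with the study's concentration series the dissociation
rate remains surprisingly well constrained even at k_d ≪ 1/t_dissoc — the
equilibrium levels carry k_d information through K_D — so the flag fires
only when the signal is genuinely uninformative.

The default simulated design mirrors the experiment: 0 nM plus a twofold
series 1.875–60 nM, 120 s association, 1360 s dissociation, 1 Hz
sampling, 0.5 RU additive Gaussian noise, and parental-like parameters
(k_a = 4.4×10⁵ M⁻¹s⁻¹, k_d = 1.4×10⁻⁴ s⁻¹, R_max = 100 RU). Reported
fold changes round half-away-from-zero, to one decimal below 10 and to
the nearest integer above. Summary tables always recompute k_d/k_a and
flag rows whose stated K_D disagrees by more than 5% — one published row
(ka 26×10⁵ with kd 1.4×10⁻⁴ against KD 0.56 nM) is internally
inconsistent and is flagged, not corrected.

## Thermostability

Melt curves are simulated as a two-state van't Hoff transition,
f_u(T) = 1 / (1 + exp(ΔH/R (1/T − 1/T_m))), mixing linear native and
unfolded baselines per fluorescence channel over a 25–95 °C ramp
(0.1 °C grid, the sampling a 1 °C/min ramp produces); default
ΔH = 400 kJ/mol and 0.2% multiplicative noise. T_m is extracted from the
first derivative of the F350/F330 ratio: an 11-point moving-polynomial
(order 2) derivative, then a second, temperature-scaled smoothing pass
(default 7 °C window) so the peak position is set by the transition
rather than point noise, and finally a quadratic fit over ±1.5 °C around
the grid maximum. A single smoothing pass at the 11-point scale proved
too jittery to meet the 0.2 °C triplicate-recovery target at realistic
noise, hence the second pass; with the default baselines the
derivative-peak T_m carries a small systematic offset (< 0.05 °C) from
the thermodynamic midpoint because the 330 nm channel also changes
through the transition. Curves without an interior derivative maximum or
without a detectable transition raise an extraction error. Replicate
summaries use the sample SD (n−1).

## Hydrodynamic radius

Taylorgrams are Gaussian elution profiles; a single Gaussian plus
constant baseline is fitted first, giving the residence time t_R and
temporal variance σ². The Taylor–Aris relation D = r_c² t_R / (24 σ²)
(default capillary radius 37.5 µm — instrument constants are explicit
configuration, not hidden defaults) and Stokes–Einstein
R_h = k_B T / (6πηD) convert to a radius; default viscosities are
aqueous (8.9×10⁻⁴ Pa·s at 25 °C, 6.92×10⁻⁴ at 37 °C). Because an 80/20
mixture of IgG-like species leaves only a ~0.2% single-Gaussian residual,
dual-species detection is noise-aware rather than fixed-threshold: the
fit residual RMS is compared with the high-frequency noise estimated
from its first differences, and structured misfit (ratio > 1.5, and
above a 0.05%-of-amplitude floor) triggers a two-Gaussian fit (shared
t_R) and sets the dispersity flag; the dominant-amplitude species is
reported. The radius itself is temperature-invariant by construction,
which the tests use as a physics identity.

## Exact Mann–Whitney test

U counts pairs where an observation of the first group exceeds one of the
second, with half credit for ties. The two-sided p doubles the smaller
tail of the exact permutation distribution, capped at 1. The distribution
is computed by an integer dynamic programme over doubled midranks, which
is exactly equivalent to enumerating all C(n_a+n_b, n_a) labelings
(verified against brute-force enumeration in the tests) while remaining
fast up to the supported group sizes (≤12 each). On the published
25 °C hydrodynamic-radius groups this gives U = 33 and p = 8/792 ≈ 0.0101,
which does *not* reproduce the published p = 0.015 (the published test
variant — normal approximation, continuity correction or different
grouping — is unstated); the report carries both values and a discrepancy
flag rather than matching the printed number.

## Synthetic-data generators

All generators are pure functions of (seed, config) and byte-reproducible.

* **Germline fixture set**: one synthetic heavy V gene with four alleles
  mirroring a CDR-variant allele family — a baseline, an FR3 variant
  (position 96), a CDR variant differing at exactly positions 38 and 62,
  and a synonymous nucleotide variant — plus three D alleles, a heavy J
  (four filler codons + the canonical WGQGTLVTVSS FR4), and kappa V/J
  (the V contributing a realistic 7-codon CDR3 tail, the J ending in
  FGGGTKVEIK). Gap architecture (positions 10, 31, 32, 73 heavy; 10, 81,
  82 light) is fabricated-but-plausible; runs against real alleles
  require an external IMGT/OGRDB germline download.
* **Rearrangements**: V(3′-trim) + N1 + D(both-end trim) + N2 + J(5′-trim)
  for heavy, V + N + J for light; geometric-like trim and N-length
  distributions capped at 12 nt; junction parameters resampled until the
  J frame is preserved, the CDR3 length is in range and the product is
  stop-free. Somatic hypermutation is uniform per base (no hotspot bias —
  inference never uses mutability; a pluggable mutability hook exists),
  with optional explicitly planted coding mutations at chosen IMGT
  positions. The ground-truth record reconstructs the emitted sequence
  exactly, which is asserted for every simulation.
* **Instrument suite**: the sensorgram series, three melt replicates and
  triplicate taylorgrams at 25/37 °C under the study designs, with CSV
  writers and a ground-truth JSON.

What the generators deliberately do not emulate: repertoire-scale
diversity, clonal expansion, SHM hotspot bias, instrument drift or
baseline artefacts, and proprietary export formats. Passing the recovery
tests therefore demonstrates correctness of the estimators under the
stated noise models, not robustness to every artefact of real traces.

## Problem sizes

The default test and acceptance runs use ~200 simulated rearrangements
(two chains × three hypermutation rates), 20 seeds for the SPR recovery
experiment, triplicate melt curves and 4–5 taylorgram round trips —
sizes chosen to make the recovery statistics stable at a few percent
while keeping a full run in tens of seconds on one CPU.

## Known limitations

Indel-containing rearrangements are rejected, not repaired. Junction
boundary ambiguity is intrinsic: mutations within a few bases of a
trimmed segment end are unrecoverable by any method under the UCA
assumption, and allele assignment can be ambiguous when hypermutation
hits allele-differentiating positions (the same positions 38/62 that
motivate the allele-swap variants). The Mann–Whitney implementation is
exact-only by design and refuses group sizes beyond 12. The kinetics
module fits a plain 1:1 model; avidity and mass-transport effects are out
of scope.
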