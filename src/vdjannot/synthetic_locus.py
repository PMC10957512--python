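"""Synthetic IG/TR loci with fully specified ground truth.

This module generates miniature heavy-chain-style loci (V cluster, then D,
then J, separated by random intergenic sequence) in which every implanted
gene is built from a synthetic germline reference allele plus motif
instances drawn from the training sets of synthetic PWM models:

* every V gets an ATG-initiated, stop-free L-PART1 / GT-intron-AG /
  L-PART2 leader, a V-REGION copied from a reference allele, and a
  heptamer + 23 nt spacer + nonamer RSS;
* every D gets a nonamer + 12 + heptamer RSS upstream and a
  heptamer + 12 + nonamer RSS downstream;
* every J gets a nonamer + 23 + heptamer RSS upstream, a J-motif at the
  configured offset from its 3' end, and a trailing GT donor splice.

The motif models are *synthetic*: they are seeded from the field-canonical
consensus motifs (CACAGTG heptamer, ACAAAAACC nonamer, and their reverse
complements on the 5' side of D and J genes) with a small set of
deterministic single-base variants, not from any curated species PWM set.
Intact implants therefore satisfy every functionality hallmark by
construction, and a menu of minimal engineered defects exercises each
classification criterion individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np

from .io_model import (
    Assembly,
    Interval,
    LocusConfig,
    ReferenceAllele,
    ReferenceSet,
)
from .motifs import PWM, build_pwm, matches_consensus
from .sequence import STOP_CODONS, has_stop

_MOTIF_SEED = 20240214  # fixed: the synthetic motif models are constants

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

L_PART1_LENGTH = 46
L_PART2_LENGTH = 11
J_MOTIF_SAMPLE = "TGGGGG"  # matches the default TKGGGG pattern


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _variants(
    rng: np.random.Generator, master: str, n: int, n_subs: int, fixed: set[int]
) -> list[str]:
    out = []
    for _ in range(n):
        seq = list(master)
        positions = [i for i in range(len(master)) if i not in fixed]
        for pos in rng.choice(positions, size=n_subs, replace=False):
            choices = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = str(rng.choice(choices))
        out.append("".join(seq))
    return out


def _spliced_leader_ok(l1: str, l2: str) -> bool:
    spliced = l1 + l2
    return spliced.startswith("ATG") and not has_stop(spliced)


def default_motif_training() -> dict[str, tuple[list[str], Optional[str]]]:
    """Deterministic training sets: name -> (sequences, consensus or None).

    RSS training sets hold five consensus copies plus three single-base
    variants; the variants pass the resulting PWM threshold by construction
    (the threshold is the minimum training log-likelihood) while violating
    the strict consensus, which is exactly the distinction the
    consensus-break defects exploit.
    """
    rng = np.random.default_rng(_MOTIF_SEED)
    sets: dict[str, tuple[list[str], Optional[str]]] = {}

    def rss(name: str, consensus: str) -> None:
        seqs = [consensus] * 5 + _variants(rng, consensus, 3, 1, fixed=set())
        sets[name] = (seqs, consensus)

    rss("V-HEPTAMER", "CACAGTG")
    rss("V-NONAMER", "ACAAAAACC")
    rss("D-5-NONAMER", "GGTTTTTGT")
    rss("D-5-HEPTAMER", "CACTGTG")
    rss("D-3-HEPTAMER", "CACAGTG")
    rss("D-3-NONAMER", "ACAAAAACC")
    rss("J-NONAMER", "GGTTTTTGT")
    rss("J-HEPTAMER", "CACTGTG")

    # leader parts: ATG-initiated L-PART1, and an L-PART2 such that every
    # training combination splices to a stop-free in-frame leader
    while True:
        l2_master = _random_seq(rng, L_PART2_LENGTH)
        l1_master = "ATG" + "".join(
            rng.choice(_NON_STOP_CODONS)
            for _ in range((L_PART1_LENGTH - 3) // 3)
        )
        l1_master += _random_seq(rng, L_PART1_LENGTH - len(l1_master))
        l2_seqs = [l2_master] + _variants(rng, l2_master, 3, 2, fixed=set())
        l1_seqs = [l1_master] + _variants(
            rng, l1_master, 5, 4, fixed={0, 1, 2}
        )
        if all(
            _spliced_leader_ok(l1, l2) for l1 in l1_seqs for l2 in l2_seqs
        ):
            break
    sets["L-PART1"] = (l1_seqs, None)
    sets["L-PART2"] = (l2_seqs, None)
    return sets


def make_default_pwms(pseudocount: float = 0.1) -> dict[str, PWM]:
    """PWMs built from the default training sets (threshold = min training
    log-likelihood, strict consensus on RSS motifs)."""
    pwms = {}
    for name, (seqs, consensus) in default_motif_training().items():
        pwms[name] = build_pwm(seqs, pseudocount=pseudocount, consensus=consensus, name=name)
    return pwms


# ---------------------------------------------------------------------------
# synthetic germline reference set

V_CODONS = 108  # IMGT-gapped codon scaffold length
_GAPPED_CODONS = (59, 60)  # 0-based codon indices gapped in most alleles


def _make_v_master(rng: np.random.Generator) -> list[str]:
    codons = [str(rng.choice(_NON_STOP_CODONS)) for _ in range(V_CODONS)]
    codons[0] = "CAG"
    codons[22] = "TGT"  # first conserved cysteine, IMGT 23
    codons[40] = "TGG"  # conserved tryptophan, IMGT 41
    codons[103] = "TGT"  # second conserved cysteine, IMGT 104
    return codons


def _mutate_v(
    rng: np.random.Generator, codons: list[str], n_codons: int
) -> list[str]:
    protected = {0, 22, 40, 103}
    out = list(codons)
    targets = rng.choice(
        [i for i in range(V_CODONS) if i not in protected],
        size=n_codons,
        replace=False,
    )
    for i in targets:
        choices = [c for c in _NON_STOP_CODONS if c != out[i]]
        out[i] = str(rng.choice(choices))
    return out


def _make_j_sequence(rng: np.random.Generator, length: int, offset: int) -> str:
    """Random J-REGION with the J-motif at *offset* from the 3' end and no
    stop codon at or downstream of the motif in the motif's frame."""
    while True:
        seq = list(_random_seq(rng, length))
        ms = length - offset
        seq[ms : ms + len(J_MOTIF_SAMPLE)] = list(J_MOTIF_SAMPLE)
        s = "".join(seq)
        if not any(
            s[p : p + 3] in STOP_CODONS for p in range(ms, length - 2, 3)
        ):
            return s


def make_reference_set(
    seed: int = 0,
    n_v: int = 12,
    n_d: int = 6,
    n_j: int = 6,
    config: Optional[LocusConfig] = None,
) -> ReferenceSet:
    """Synthetic germline reference set with IMGT-gapped V alleles.

    V alleles share a 108-codon gapped scaffold with conserved Cys23/Trp41/
    Cys104; most carry a two-codon gap (missing codons 60-61), the last two
    are full length, exercising gap-pattern transfer. D alleles are short
    random segments (the first is the 8 nt minimum); J alleles embed the
    J-motif at the configured offset.
    """
    config = config or LocusConfig()
    rng = np.random.default_rng(seed)
    master = _make_v_master(rng)
    alleles: list[ReferenceAllele] = []
    for i in range(n_v):
        codons = _mutate_v(rng, master, n_codons=7)
        gap_codons = _GAPPED_CODONS if i < n_v - 2 else ()
        gapped = "".join(
            "..." if j in gap_codons else codons[j] for j in range(V_CODONS)
        )
        ungapped = gapped.replace(".", "")
        alleles.append(
            ReferenceAllele(f"IGHV1-{i + 1}*01", "V", ungapped, gapped)
        )

    d_lengths = [8, 12, 14, 16, 18, 21]
    for i in range(n_d):
        length = d_lengths[i % len(d_lengths)]
        alleles.append(
            ReferenceAllele(f"IGHD1-{i + 1}*01", "D", _random_seq(rng, length))
        )

    j_lengths = [54, 57, 60]
    for i in range(n_j):
        length = j_lengths[i % len(j_lengths)]
        seq = _make_j_sequence(rng, length, config.j.j_motif_offset)
        alleles.append(ReferenceAllele(f"IGHJ{i + 1}*01", "J", seq))
    return ReferenceSet(alleles, species="synthetic")


def v_codon_index(allele: ReferenceAllele, imgt_position: int) -> int:
    """Ungapped index of the first base of the codon at *imgt_position*."""
    if allele.gapped_sequence is None:
        return 3 * (imgt_position - 1)
    col = 3 * (imgt_position - 1)
    return sum(1 for ch in allele.gapped_sequence[:col] if ch not in ".-")


def diverge_reference_set(
    refset: ReferenceSet, rate: float, seed: int = 0
) -> ReferenceSet:
    """Random per-base substitution of every allele (gapped sequences edited
    consistently), emulating a cross-species reference set."""
    rng = np.random.default_rng(seed)
    alleles = []
    for allele in refset:
        seq = list(allele.sequence)
        for i in range(len(seq)):
            if rng.random() < rate:
                seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
        new_seq = "".join(seq)
        gapped = None
        if allele.gapped_sequence is not None:
            out, k = [], 0
            for ch in allele.gapped_sequence:
                if ch in ".-":
                    out.append(ch)
                else:
                    out.append(new_seq[k])
                    k += 1
            gapped = "".join(out)
        alleles.append(replace(allele, sequence=new_seq, gapped_sequence=gapped))
    return ReferenceSet(alleles, species=refset.species + "-diverged")


# ---------------------------------------------------------------------------
# locus generation


@dataclass
class TruthRecord:
    """Ground truth for one implanted gene."""

    implant_id: str
    gene_type: str
    allele: str
    features: dict[str, Interval]
    functionality: str  # intended classification
    defect: Optional[str] = None
    notes: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.features.values())

    @property
    def end(self) -> int:
        return max(e for _, e in self.features.values())


IntergenicSampler = Union[int, Callable[[np.random.Generator], int], None]


class _Builder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0

    def add(self, seq: str) -> Interval:
        start = self.length
        self.parts.append(seq)
        self.length += len(seq)
        return (start, self.length)

    def sequence(self) -> str:
        return "".join(self.parts)


def _pick_consensus_instance(training: list[str], consensus: Optional[str]) -> str:
    if consensus is None:
        return training[0]
    for seq in training:
        if matches_consensus(seq, consensus):
            return seq
    raise ValueError("no consensus-matching training sequence")


def generate_locus(
    refset: ReferenceSet,
    pwms: Optional[dict[str, PWM]] = None,
    config: Optional[LocusConfig] = None,
    n_v: int = 10,
    n_d: int = 5,
    n_j: int = 5,
    intergenic: IntergenicSampler = None,
    seed: int = 0,
    max_length: Optional[int] = None,
    decoy_motifs: bool = False,
) -> tuple[Assembly, list[TruthRecord]]:
    """Build a locus of intact implants with a ground-truth table.

    Genes appear in locus order (V cluster, D cluster, J cluster) separated
    by intergenic sequence drawn i.i.d. uniform over ACGT; *intergenic* may
    be a constant, a callable of the generator, or None for the default
    uniform 2000-6000 nt. ``decoy_motifs`` salts intergenic stretches with
    lone heptamers to stress false-positive behaviour. Fully reproducible
    from *seed*.
    """
    config = config or LocusConfig()
    rng = np.random.default_rng(seed)
    training = default_motif_training()
    del pwms  # geometry comes from config; instances from the training sets

    if intergenic is None:
        sample_gap = lambda: int(rng.integers(2000, 6001))  # noqa: E731
    elif callable(intergenic):
        sample_gap = lambda: int(intergenic(rng))  # noqa: E731
    else:
        sample_gap = lambda: int(intergenic)  # noqa: E731

    def intergenic_seq() -> str:
        length = sample_gap()
        seq = _random_seq(rng, length)
        if decoy_motifs and length >= 60:
            pos = int(rng.integers(20, length - 30))
            seq = seq[:pos] + "CACAGTG" + seq[pos + 7 :]
        return seq

    def motif(name: str) -> str:
        seqs, consensus = training[name]
        if consensus is not None:
            return _pick_consensus_instance(seqs, consensus)
        return str(seqs[int(rng.integers(len(seqs)))])

    builder = _Builder()
    truths: list[TruthRecord] = []

    v_alleles = refset.by_type("V") if n_v else []
    d_alleles = refset.by_type("D") if n_d else []
    j_alleles = refset.by_type("J") if n_j else []
    for n, alleles, gene_type in (
        (n_v, v_alleles, "V"),
        (n_d, d_alleles, "D"),
        (n_j, j_alleles, "J"),
    ):
        if n and not alleles:
            raise ValueError(f"reference set has no {gene_type} alleles")

    for i in range(n_v):
        builder.add(intergenic_seq())
        allele = v_alleles[int(rng.integers(len(v_alleles)))]
        feats: dict[str, Interval] = {}
        # leader: pick a training pair whose splice is stop-free (guaranteed)
        l1 = str(training["L-PART1"][0][int(rng.integers(len(training["L-PART1"][0])))])
        l2 = str(training["L-PART2"][0][int(rng.integers(len(training["L-PART2"][0])))])
        feats["l_part1"] = builder.add(l1)
        intron_len = int(rng.integers(80, 151))
        intron = "GT" + _random_seq(rng, intron_len - 4) + "AG"
        feats["v_intron"] = builder.add(intron)
        feats["l_part2"] = builder.add(l2)
        feats["v_region"] = builder.add(allele.sequence)
        feats["v_heptamer"] = builder.add(motif("V-HEPTAMER"))
        feats["v_spacer"] = builder.add(_random_seq(rng, config.v.spacer_length))
        feats["v_nonamer"] = builder.add(motif("V-NONAMER"))
        truths.append(
            TruthRecord(f"V{i + 1:02d}", "V", allele.name, feats, "Functional")
        )

    for i in range(n_d):
        builder.add(intergenic_seq())
        allele = d_alleles[int(rng.integers(len(d_alleles)))]
        feats = {}
        feats["d_5_nonamer"] = builder.add(motif("D-5-NONAMER"))
        feats["d_5_spacer"] = builder.add(_random_seq(rng, config.d.spacer_5_length))
        feats["d_5_heptamer"] = builder.add(motif("D-5-HEPTAMER"))
        feats["d_region"] = builder.add(allele.sequence)
        feats["d_3_heptamer"] = builder.add(motif("D-3-HEPTAMER"))
        feats["d_3_spacer"] = builder.add(_random_seq(rng, config.d.spacer_3_length))
        feats["d_3_nonamer"] = builder.add(motif("D-3-NONAMER"))
        truths.append(
            TruthRecord(f"D{i + 1:02d}", "D", allele.name, feats, "Functional")
        )

    for i in range(n_j):
        builder.add(intergenic_seq())
        allele = j_alleles[int(rng.integers(len(j_alleles)))]
        feats = {}
        feats["j_nonamer"] = builder.add(motif("J-NONAMER"))
        feats["j_spacer"] = builder.add(_random_seq(rng, config.j.spacer_length))
        feats["j_heptamer"] = builder.add(motif("J-HEPTAMER"))
        feats["j_region"] = builder.add(allele.sequence)
        ms = feats["j_region"][1] - config.j.j_motif_offset
        feats["j_motif"] = (ms, ms + len(J_MOTIF_SAMPLE))
        feats["j_donor"] = builder.add("GT")
        truths.append(
            TruthRecord(f"J{i + 1:02d}", "J", allele.name, feats, "Functional")
        )

    builder.add(intergenic_seq())
    if max_length is not None and builder.length > max_length:
        raise ValueError(
            f"requested gene counts do not fit in {max_length} nt "
            f"(locus is {builder.length} nt)"
        )
    assembly = Assembly(f"synthetic_locus_seed{seed}", builder.sequence())
    return assembly, truths


# ---------------------------------------------------------------------------
# engineered defects

DEFECT_APPLICABILITY: dict[str, frozenset[str]] = {
    "rss_heptamer_break": frozenset("VDJ"),
    "rss_nonamer_break": frozenset("VDJ"),
    "leader_stop": frozenset("V"),
    "leader_frameshift": frozenset("V"),
    "cys104_loss": frozenset("V"),
    "early_stop": frozenset("V"),
    "post104_stop": frozenset("V"),
    "missing_donor_GT": frozenset("V"),
    "j_motif_shift": frozenset("J"),
    "splice_loss": frozenset("J"),
}

#: classification dictated by the functionality criteria for each defect
DEFECT_EXPECTATION: dict[str, str] = {
    "rss_heptamer_break": "ORF",
    "rss_nonamer_break": "ORF",
    "leader_stop": "ORF",
    "leader_frameshift": "ORF",
    "cys104_loss": "ORF",
    "early_stop": "pseudogene",
    "post104_stop": "Functional",
    "missing_donor_GT": "ORF",
    "j_motif_shift": "ORF",
    "splice_loss": "ORF",
}

_DEFECT_MOTIF_FEATURE = {
    ("rss_heptamer_break", "V"): ("v_heptamer", "V-HEPTAMER"),
    ("rss_heptamer_break", "D"): ("d_3_heptamer", "D-3-HEPTAMER"),
    ("rss_heptamer_break", "J"): ("j_heptamer", "J-HEPTAMER"),
    ("rss_nonamer_break", "V"): ("v_nonamer", "V-NONAMER"),
    ("rss_nonamer_break", "D"): ("d_3_nonamer", "D-3-NONAMER"),
    ("rss_nonamer_break", "J"): ("j_nonamer", "J-NONAMER"),
}


def _splice(seq: str, interval: Interval, replacement: str) -> str:
    return seq[: interval[0]] + replacement + seq[interval[1] :]


def implant_defect(
    assembly: Assembly,
    truth: TruthRecord,
    defect: str,
    refset: ReferenceSet,
    seed: int = 0,
) -> tuple[Assembly, TruthRecord]:
    """Apply one minimal engineered defect to an implanted gene.

    Edits change at most 3 nt, except the frameshift defect (a 1 nt
    deletion). The returned truth record carries the classification the
    functionality criteria dictate for the defect. Coordinates of *other*
    truth records are invalidated by the frameshift defect; defect studies
    therefore use one gene per locus for that case.
    """
    if defect not in DEFECT_APPLICABILITY:
        raise ValueError(f"unknown defect {defect!r}")
    if truth.gene_type not in DEFECT_APPLICABILITY[defect]:
        raise ValueError(
            f"defect {defect!r} is not applicable to a {truth.gene_type} gene"
        )
    rng = np.random.default_rng(seed)
    seq = assembly.sequence
    training = default_motif_training()
    new_truth = replace(
        truth,
        defect=defect,
        functionality=DEFECT_EXPECTATION[defect],
        features=dict(truth.features),
        notes=list(truth.notes),
    )

    if defect in ("rss_heptamer_break", "rss_nonamer_break"):
        feature, motif_name = _DEFECT_MOTIF_FEATURE[(defect, truth.gene_type)]
        seqs, consensus = training[motif_name]
        variants = [s for s in seqs if not matches_consensus(s, consensus)]
        replacement = str(variants[int(rng.integers(len(variants)))])
        seq = _splice(seq, truth.features[feature], replacement)
    elif defect == "leader_stop":
        start = truth.features["l_part1"][0] + 12  # codon 5 of L-PART1
        seq = _splice(seq, (start, start + 3), "TAA")
    elif defect == "leader_frameshift":
        pos = truth.features["l_part1"][0] + 10
        seq = seq[:pos] + seq[pos + 1 :]
        shifted = {}
        for name, (s, e) in new_truth.features.items():
            shifted[name] = (s - 1 if s > pos else s, e - 1 if e > pos else e)
        new_truth.features = shifted
    elif defect in ("cys104_loss", "early_stop", "post104_stop"):
        allele = refset[truth.allele]
        imgt = {"cys104_loss": 104, "early_stop": 50, "post104_stop": 106}[defect]
        start = truth.features["v_region"][0] + v_codon_index(allele, imgt)
        replacement = {"cys104_loss": "AGT"}.get(defect, "TAA")
        seq = _splice(seq, (start, start + 3), replacement)
    elif defect == "missing_donor_GT":
        pos = truth.features["v_intron"][0]
        seq = _splice(seq, (pos, pos + 2), "GC")
    elif defect == "j_motif_shift":
        ms, _ = truth.features["j_motif"]
        # knock the motif out of every tolerated in-frame window; the C
        # substitutions leave codons TGC/GCG, so no stop is introduced
        seq = _splice(seq, (ms + 2, ms + 3), "C")
        seq = _splice(seq, (ms + 4, ms + 5), "C")
        del new_truth.features["j_motif"]
    elif defect == "splice_loss":
        donor = truth.features["j_donor"]
        seq = _splice(seq, donor, "GC")
        del new_truth.features["j_donor"]

    return Assembly(assembly.name, seq, assembly.sense), new_truth
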