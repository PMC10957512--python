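"""D and J gene annotation.

D genes carry a recombination signal sequence on *both* sides
(nonamer-spacer-heptamer upstream, heptamer-spacer-nonamer downstream, both
heptamers abutting the D-REGION). Because a D-REGION can be as short as
8 nt and offers no reading frame of its own before rearrangement, the RSS
criterion is the only check: a D candidate is kept only when all four
motifs pass their PWM thresholds, is Functional when they also match the
canonical consensus (if one is defined), and is otherwise an ORF. D genes
are never classified as pseudogenes here.

J genes carry a 5' RSS (nonamer-spacer-heptamer, heptamer end = J-REGION
start), a conserved J-motif (the [W/F]-G-X-G core, matched as an IUPAC
nucleotide pattern) at a configured offset from the J-REGION 3' end, and a
GT donor splice immediately after the J-REGION. A J candidate is taken
forward when at least one of nonamer/heptamer passes threshold; it is
Functional when both pass (and match consensus if defined), the J-motif is
found at the expected position, and the donor splice is present. In-frame
stop codons *before* the J-motif do not block functionality (they may be
excised during junction formation) but are noted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .io_model import (
    Assembly,
    Feature,
    Functionality,
    GeneAnnotation,
    Interval,
    LocusConfig,
)
from .motifs import PWM, MotifHit, find_best_motif_pair, matches_consensus
from .sequence import STOP_CODONS


@dataclass
class DCall:
    d_region: Interval
    nonamer_5: MotifHit
    heptamer_5: MotifHit
    spacer_5: int
    heptamer_3: MotifHit
    nonamer_3: MotifHit
    spacer_3: int

    @property
    def motifs(self) -> tuple[MotifHit, ...]:
        return (self.nonamer_5, self.heptamer_5, self.heptamer_3, self.nonamer_3)

    @property
    def joint_log_likelihood(self) -> float:
        return sum(m.log_likelihood for m in self.motifs)


@dataclass
class JCall:
    j_region: Interval
    nonamer: MotifHit
    heptamer: MotifHit
    spacer: int
    j_motif: Optional[Interval] = None
    donor_splice: Optional[int] = None
    stop_before_motif: bool = False
    stop_after_motif: bool = False

    @property
    def joint_log_likelihood(self) -> float:
        return self.nonamer.log_likelihood + self.heptamer.log_likelihood


def locate_d_rss_pair(
    assembly: Assembly,
    candidate,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
) -> Optional[DCall]:
    """Find both D RSSs and adjust the D-REGION to abut the two heptamers.

    Heptamer ends (5') and starts (3') are searched within
    ``+- d_end_adjust_max`` of the match boundaries; returns None when
    either end has no geometric placement or the adjusted region is empty.
    """
    seq = assembly.sequence
    dstart, dend = candidate.interval
    cfg = config.d
    h5_len = len(pwms["D-5-HEPTAMER"])
    n5_len = len(pwms["D-5-NONAMER"])

    # upstream: nonamer + spacer + heptamer, heptamer end near dstart
    up_lo = dstart - cfg.d_end_adjust_max - h5_len - cfg.spacer_5_length - n5_len
    up_hi = dstart + cfg.d_end_adjust_max - h5_len - cfg.spacer_5_length - n5_len + 1
    up = find_best_motif_pair(
        seq,
        pwms["D-5-NONAMER"],
        pwms["D-5-HEPTAMER"],
        spacer=cfg.spacer_5_length,
        tolerance=cfg.spacer_tolerance,
        window=(up_lo, up_hi),
    )
    if up is None:
        return None
    nonamer_5, heptamer_5, spacer_5 = up

    # downstream: heptamer + spacer + nonamer, heptamer start near dend
    down = find_best_motif_pair(
        seq,
        pwms["D-3-HEPTAMER"],
        pwms["D-3-NONAMER"],
        spacer=cfg.spacer_3_length,
        tolerance=cfg.spacer_tolerance,
        window=(dend - cfg.d_end_adjust_max, dend + cfg.d_end_adjust_max + 1),
    )
    if down is None:
        return None
    heptamer_3, nonamer_3, spacer_3 = down

    new_start = heptamer_5.position + len(pwms["D-5-HEPTAMER"])
    new_end = heptamer_3.position
    if new_end <= new_start:
        return None
    return DCall(
        d_region=(new_start, new_end),
        nonamer_5=nonamer_5,
        heptamer_5=heptamer_5,
        spacer_5=spacer_5,
        heptamer_3=heptamer_3,
        nonamer_3=nonamer_3,
        spacer_3=spacer_3,
    )


def classify_d(dcall: DCall) -> Optional[tuple[Functionality, list[str]]]:
    """D classification; returns None when the candidate is to be dropped
    (any of the four motifs below its PWM threshold)."""
    if not all(m.passes_threshold for m in dcall.motifs):
        return None
    notes: list[str] = []
    consensus_ok = all(m.matches_consensus is not False for m in dcall.motifs)
    if consensus_ok:
        return Functionality.FUNCTIONAL, notes
    notes.append("RSS motif does not match canonical consensus")
    return Functionality.ORF, notes


def locate_j_rss(
    assembly: Assembly,
    candidate,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
) -> Optional[JCall]:
    """Find the J 5' RSS (nonamer-spacer-heptamer) with the heptamer end
    within ``+- j_end_adjust_max`` of the match start; the J-REGION start is
    adjusted to the heptamer end. The candidate is retained only when at
    least one of nonamer/heptamer passes its PWM threshold."""
    seq = assembly.sequence
    jstart, jend = candidate.interval
    cfg = config.j
    h_len = len(pwms["J-HEPTAMER"])
    n_len = len(pwms["J-NONAMER"])
    lo = jstart - cfg.j_end_adjust_max - h_len - cfg.spacer_length - n_len
    hi = jstart + cfg.j_end_adjust_max - h_len - cfg.spacer_length - n_len + 1
    pair = find_best_motif_pair(
        seq,
        pwms["J-NONAMER"],
        pwms["J-HEPTAMER"],
        spacer=cfg.spacer_length,
        tolerance=cfg.spacer_tolerance,
        window=(lo, hi),
    )
    if pair is None:
        return None
    nonamer, heptamer, spacer = pair
    if not (nonamer.passes_threshold or heptamer.passes_threshold):
        return None
    new_start = heptamer.position + h_len
    if new_start >= jend:
        return None
    return JCall(
        j_region=(new_start, jend),
        nonamer=nonamer,
        heptamer=heptamer,
        spacer=spacer,
    )


def _frame_anchor(jstart: int, jend: int, offset: int) -> int:
    """First in-frame position of the J-REGION, anchoring the reading frame
    so that the expected J-motif start (jend - offset) falls on a codon
    boundary."""
    return jstart + (jend - offset - jstart) % 3


def locate_j_motif_and_splice(
    assembly: Assembly, jcall: JCall, config: LocusConfig
) -> JCall:
    """Locate the J-motif and donor splice, and partition in-frame stops.

    The motif pattern is matched at in-frame shifts within
    ``j_motif_offset +- j_motif_tolerance`` of the J-REGION 3' end (closest
    shift wins); the donor splice is the GT dinucleotide immediately after
    the J-REGION end. Absence of either is recorded, not an error.
    """
    seq = assembly.sequence
    jstart, jend = jcall.j_region
    cfg = config.j
    pattern = cfg.j_motif_pattern

    motif: Optional[Interval] = None
    shifts = sorted(
        range(-cfg.j_motif_tolerance, cfg.j_motif_tolerance + 1),
        key=lambda s: (abs(s), s),
    )
    for shift in shifts:
        if shift % 3 != 0:  # keep the motif in the frame implied by the 3' end
            continue
        pos = jend - cfg.j_motif_offset + shift
        if pos < jstart or pos + len(pattern) > jend:
            continue
        if matches_consensus(seq[pos : pos + len(pattern)], pattern):
            motif = (pos, pos + len(pattern))
            break

    donor: Optional[int] = None
    if jend + 2 <= len(seq) and seq[jend : jend + 2] == "GT":
        donor = jend

    # in-frame stops, partitioned at the (found or expected) motif start
    boundary = motif[0] if motif is not None else jend - cfg.j_motif_offset
    frame_start = _frame_anchor(jstart, jend, cfg.j_motif_offset)
    stop_before = stop_after = False
    for p in range(frame_start, jend - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            if p < boundary:
                stop_before = True
            else:
                stop_after = True

    jcall.j_motif = motif
    jcall.donor_splice = donor
    jcall.stop_before_motif = stop_before
    jcall.stop_after_motif = stop_after
    return jcall


def classify_j(jcall: JCall) -> tuple[Functionality, list[str]]:
    """J classification per the criteria in the module docstring."""
    notes: list[str] = []
    rss_ok = (
        jcall.nonamer.passes_threshold
        and jcall.heptamer.passes_threshold
        and jcall.nonamer.matches_consensus is not False
        and jcall.heptamer.matches_consensus is not False
    )
    if not (jcall.nonamer.passes_threshold and jcall.heptamer.passes_threshold):
        notes.append("RSS motif below PWM threshold")
    elif not rss_ok:
        notes.append("RSS motif does not match canonical consensus")
    if jcall.j_motif is None:
        notes.append("J-motif not found at expected position")
    if jcall.donor_splice is None:
        notes.append("donor splice (GT) not found after J-REGION")
    if jcall.stop_before_motif:
        notes.append("STOP-CODON before J-motif")

    if (
        rss_ok
        and jcall.j_motif is not None
        and jcall.donor_splice is not None
        and not jcall.stop_after_motif
    ):
        return Functionality.FUNCTIONAL, notes
    if jcall.stop_after_motif:
        notes.append("STOP-CODON after J-motif")
        return Functionality.PSEUDOGENE, notes
    return Functionality.ORF, notes


# ---------------------------------------------------------------------------
# candidate-level drivers


def annotate_d(
    assembly: Assembly,
    candidate,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
) -> Optional[GeneAnnotation]:
    """Full D annotation of one extended candidate; None = dropped."""
    dcall = locate_d_rss_pair(assembly, candidate, pwms, config)
    if dcall is None:
        return None
    classified = classify_d(dcall)
    if classified is None:
        return None
    functionality, class_notes = classified

    seq = assembly.sequence
    n5_len = len(pwms["D-5-NONAMER"])
    h5_len = len(pwms["D-5-HEPTAMER"])
    h3_len = len(pwms["D-3-HEPTAMER"])
    n3_len = len(pwms["D-3-NONAMER"])

    def feat(interval: Interval) -> Feature:
        return Feature(interval, seq[interval[0] : interval[1]])

    n5 = (dcall.nonamer_5.position, dcall.nonamer_5.position + n5_len)
    h5 = (dcall.heptamer_5.position, dcall.heptamer_5.position + h5_len)
    h3 = (dcall.heptamer_3.position, dcall.heptamer_3.position + h3_len)
    n3 = (dcall.nonamer_3.position, dcall.nonamer_3.position + n3_len)
    features = {
        "d_5_nonamer": feat(n5),
        "d_5_spacer": feat((n5[1], h5[0])),
        "d_5_heptamer": feat(h5),
        "d_region": feat(dcall.d_region),
        "d_3_heptamer": feat(h3),
        "d_3_spacer": feat((h3[1], n3[0])),
        "d_3_nonamer": feat(n3),
    }
    return GeneAnnotation(
        assembly_name=assembly.name,
        assembly_length=len(assembly),
        gene_type="D",
        sense=assembly.sense,
        features=features,
        allele=candidate.allele,
        percent_identity=candidate.percent_identity,
        functionality=functionality,
        joint_log_likelihood=dcall.joint_log_likelihood,
        notes=list(candidate.notes) + class_notes,
    )


def annotate_j(
    assembly: Assembly,
    candidate,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
) -> Optional[GeneAnnotation]:
    """Full J annotation of one extended candidate; None = dropped."""
    jcall = locate_j_rss(assembly, candidate, pwms, config)
    if jcall is None:
        return None
    jcall = locate_j_motif_and_splice(assembly, jcall, config)
    functionality, class_notes = classify_j(jcall)

    seq = assembly.sequence
    n_len = len(pwms["J-NONAMER"])
    h_len = len(pwms["J-HEPTAMER"])

    def feat(interval: Interval) -> Feature:
        return Feature(interval, seq[interval[0] : interval[1]])

    nona = (jcall.nonamer.position, jcall.nonamer.position + n_len)
    hept = (jcall.heptamer.position, jcall.heptamer.position + h_len)
    features = {
        "j_nonamer": feat(nona),
        "j_spacer": feat((nona[1], hept[0])),
        "j_heptamer": feat(hept),
        "j_region": feat(jcall.j_region),
    }
    joint_ll = jcall.joint_log_likelihood
    if jcall.j_motif is not None:
        features["j_motif"] = feat(jcall.j_motif)
    if jcall.donor_splice is not None:
        features["j_donor"] = feat((jcall.donor_splice, jcall.donor_splice + 2))

    return GeneAnnotation(
        assembly_name=assembly.name,
        assembly_length=len(assembly),
        gene_type="J",
        sense=assembly.sense,
        features=features,
        allele=candidate.allele,
        percent_identity=candidate.percent_identity,
        functionality=functionality,
        joint_log_likelihood=joint_ll,
        notes=list(candidate.notes) + class_notes,
    )
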