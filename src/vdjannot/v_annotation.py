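"""V gene annotation: 3' RSS location, 5' leader location, IMGT position
mapping, and functionality classification.

A V gene is Functional when every sequence hallmark is intact: its RSS
heptamer and nonamer pass their PWM thresholds (and match the canonical
consensus when one is defined); an L-PART1/L-PART2 leader is found whose
parts pass their PWM thresholds and splice to a stop-free coding sequence
in frame with the V-REGION; the V-REGION is in frame with the conserved
cysteines present at IMGT positions 23 and 104; and no stop codon occurs
before position 104. Stop codons strictly after position 104 do not block
functionality (their nucleotides may be excised during junction formation)
but are noted. A V gene failing any hallmark is an ORF if its V-REGION is
stop-free, otherwise a pseudogene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from Bio import Align

from .io_model import (
    Assembly,
    Feature,
    Functionality,
    GeneAnnotation,
    Interval,
    LocusConfig,
    ReferenceSet,
)
from .motifs import PWM, MotifHit, find_best_motif_pair
from .sequence import has_stop, translate

#: joint-likelihood contribution of a missing motif group (large negative
#: sentinel standing in for -inf so comparisons stay well defined)
MISSING_MOTIF_LL = -1.0e6


@dataclass
class VRss:
    heptamer: MotifHit
    nonamer: MotifHit
    spacer_used: int

    @property
    def joint_log_likelihood(self) -> float:
        return self.heptamer.log_likelihood + self.nonamer.log_likelihood

    @property
    def passes(self) -> bool:
        return self.heptamer.passes_threshold and self.nonamer.passes_threshold

    @property
    def consensus_ok(self) -> bool:
        # None (no consensus defined) does not count against the motif
        return (
            self.heptamer.matches_consensus is not False
            and self.nonamer.matches_consensus is not False
        )


@dataclass
class LeaderCall:
    l_part1: Interval
    l_part2: Interval
    intron: Interval
    donor_present: bool
    acceptor_present: bool
    spliced_leader: str
    peptide: str
    in_frame_with_v: bool
    l1_hit: MotifHit
    l2_hit: MotifHit

    @property
    def joint_log_likelihood(self) -> float:
        return self.l1_hit.log_likelihood + self.l2_hit.log_likelihood

    @property
    def passes(self) -> bool:
        return self.l1_hit.passes_threshold and self.l2_hit.passes_threshold

    @property
    def stop_free(self) -> bool:
        return not has_stop(self.spliced_leader)


@dataclass
class VRegionCheck:
    in_frame: bool
    cys23_present: bool
    cys104_present: bool
    stop_before_cys104: bool
    stop_after_cys104: bool
    gapped_allele: str
    imgt_mode: bool = True  # False => ungapped fallback transfer
    notes: list[str] = field(default_factory=list)

    @property
    def stop_free(self) -> bool:
        return not (self.stop_before_cys104 or self.stop_after_cys104)


def locate_v_rss(
    assembly: Assembly,
    candidate,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
) -> tuple[Optional[VRss], int, list[str]]:
    """Search for heptamer + spacer + nonamer near the candidate 3' end.

    Heptamer start positions range over
    ``[end - v_end_adjust_max, end + rss_search_window)``; the V-REGION end
    is adjusted to the heptamer start (the heptamer abuts the V-REGION).
    The RSS is reported absent — with the end left unchanged and a note —
    when no placement fits or when both motifs score below threshold.
    """
    vend = candidate.interval[1]
    cfg = config.v
    window = (vend - cfg.v_end_adjust_max, vend + cfg.rss_search_window)
    notes: list[str] = []
    scan_lo = max(window[0], 0)
    scan_hi = min(window[1] + len(pwms["V-HEPTAMER"]), len(assembly))
    if "N" in assembly.sequence[scan_lo:scan_hi]:
        notes.append("ambiguous (N) bases in V RSS search window")
    pair = find_best_motif_pair(
        assembly.sequence,
        pwms["V-HEPTAMER"],
        pwms["V-NONAMER"],
        spacer=cfg.spacer_length,
        tolerance=cfg.spacer_tolerance,
        window=window,
    )
    if pair is None:
        notes.append("V RSS not found (no placement fits)")
        return None, vend, notes
    heptamer, nonamer, spacer = pair
    if not heptamer.passes_threshold and not nonamer.passes_threshold:
        notes.append("V RSS not found (best placement below PWM thresholds)")
        return None, vend, notes
    return VRss(heptamer, nonamer, spacer), heptamer.position, notes


MIN_INTRON = 4  # donor GT + acceptor AG, back to back


def locate_leader(
    assembly: Assembly,
    candidate,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
) -> Optional[LeaderCall]:
    """Joint search for L-PART1 and L-PART2 upstream of the V-REGION.

    L-PART2 is the window of ``l_part2_length`` nt ending at the V-REGION
    start, admissible only when preceded by the AG acceptor dinucleotide.
    L-PART1 candidates are PWM-length windows within ``leader_search_window``
    upstream whose next two bases are the GT donor. Placements whose spliced
    leader starts with ATG, is stop-free, and is in frame with the V-REGION
    are preferred; joint PWM log-likelihood ranks within a tier.
    """
    seq = assembly.sequence
    vstart = candidate.interval[0]
    cfg = config.v
    l2_len = cfg.l_part2_length
    l1_pwm, l2_pwm = pwms["L-PART1"], pwms["L-PART2"]
    l1_len = len(l1_pwm)

    l2_start = vstart - l2_len
    if l2_start - 2 < 0:
        return None
    if seq[l2_start - 2 : l2_start] != "AG":
        return None
    l2_seq = seq[l2_start:vstart]
    from .motifs import score_pwm

    l2_hit = score_pwm(l2_pwm, l2_seq, position=l2_start)

    search_lo = max(0, vstart - cfg.leader_search_window)
    last_l1_start = l2_start - 2 - MIN_INTRON - l1_len + 2  # GT..AG overlap-free
    best = None
    best_key = None
    for s in range(search_lo, last_l1_start + 1):
        donor = seq[s + l1_len : s + l1_len + 2]
        if donor != "GT":
            continue
        l1_seq = seq[s : s + l1_len]
        l1_hit = score_pwm(l1_pwm, l1_seq, position=s)
        spliced = l1_seq + l2_seq
        in_frame = (l1_len + l2_len) % 3 == 0
        good = spliced.startswith("ATG") and not has_stop(spliced) and in_frame
        key = (good, l1_hit.log_likelihood + l2_hit.log_likelihood, -s)
        if best_key is None or key > best_key:
            best_key = key
            best = (s, l1_hit, spliced, in_frame)
    if best is None:
        return None
    s, l1_hit, spliced, in_frame = best
    return LeaderCall(
        l_part1=(s, s + l1_len),
        l_part2=(l2_start, vstart),
        intron=(s + l1_len, l2_start),
        donor_present=True,
        acceptor_present=True,
        spliced_leader=spliced,
        peptide=translate(spliced),
        in_frame_with_v=in_frame,
        l1_hit=l1_hit,
        l2_hit=l2_hit,
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def map_to_imgt_positions(
    v_seq: str, refset: ReferenceSet, matched_allele: str
) -> VRegionCheck:
    """Transfer IMGT positions onto *v_seq* via the matched allele.

    The reference gap pattern defines which alignment column each ungapped
    reference base occupies (IMGT position = column // 3 + 1); a global
    alignment of *v_seq* to the ungapped reference carries those columns
    onto *v_seq*. Codons at positions 23 and 104 are checked for cysteine
    (TGT/TGC) and stop codons are partitioned relative to position 104; a
    stop at 104 itself counts as "before" (it destroys the cysteine).
    """
    allele = refset[matched_allele]
    notes: list[str] = []
    imgt_mode = allele.gapped_sequence is not None
    gapped = allele.gapped_sequence if imgt_mode else allele.sequence
    if not imgt_mode:
        notes.append(
            f"no IMGT-gapped reference for {matched_allele}; cysteine positions "
            "transferred through ungapped alignment (lower confidence)"
        )

    # column of each ungapped reference base
    ref_cols = [i for i, ch in enumerate(gapped) if ch not in ".-"]
    col_to_ref = {col: i for i, col in enumerate(ref_cols)}

    aligner = _make_aligner()
    alignment = aligner.align(allele.sequence, v_seq)[0]
    ref_to_v: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for off in range(t1 - t0):
            ref_to_v[t0 + off] = q0 + off

    def codon_at(position: int) -> Optional[str]:
        cols = range(3 * (position - 1), 3 * position)
        bases = []
        for col in cols:
            if col >= len(gapped) or gapped[col] in ".-":
                return None
            v_idx = ref_to_v.get(col_to_ref[col])
            if v_idx is None:
                return None
            bases.append(v_seq[v_idx])
        return "".join(bases)

    def imgt_position_of_v_index(v_idx: int) -> Optional[int]:
        # nearest mapped reference base at or left of v_idx
        ref_idx = None
        for r, v in ref_to_v.items():
            if v <= v_idx and (ref_idx is None or v > ref_to_v[ref_idx]):
                ref_idx = r
        if ref_idx is None:
            return None
        return ref_cols[ref_idx] // 3 + 1

    cys23 = codon_at(23)
    cys104 = codon_at(104)

    stop_before = stop_after = False
    for k in range(len(v_seq) // 3):
        codon = v_seq[3 * k : 3 * k + 3]
        if codon in ("TAA", "TAG", "TGA"):
            pos = imgt_position_of_v_index(3 * k)
            if pos is None or pos <= 104:
                stop_before = True
            else:
                stop_after = True

    return VRegionCheck(
        in_frame=(len(v_seq) - len(allele.sequence)) % 3 == 0,
        cys23_present=cys23 in ("TGT", "TGC"),
        cys104_present=cys104 in ("TGT", "TGC"),
        stop_before_cys104=stop_before,
        stop_after_cys104=stop_after,
        gapped_allele=matched_allele,
        imgt_mode=imgt_mode,
        notes=notes,
    )


def classify_v(
    leader: Optional[LeaderCall],
    rss: Optional[VRss],
    vcheck: VRegionCheck,
) -> tuple[Functionality, list[str]]:
    """Apply the V functionality criteria (see module docstring)."""
    notes: list[str] = []
    rss_ok = rss is not None and rss.passes and rss.consensus_ok
    leader_ok = (
        leader is not None
        and leader.passes
        and leader.stop_free
        and leader.in_frame_with_v
    )
    v_ok = (
        vcheck.in_frame
        and vcheck.cys23_present
        and vcheck.cys104_present
        and not vcheck.stop_before_cys104
    )

    if rss is None:
        notes.append("RSS not located")
    elif not rss.passes:
        notes.append("RSS motif below PWM threshold")
    elif not rss.consensus_ok:
        notes.append("RSS motif does not match canonical consensus")
    if leader is None:
        notes.append("leader not located")
    elif not leader.passes:
        notes.append("leader part below PWM threshold")
    elif not leader.stop_free:
        notes.append("STOP-CODON in spliced leader")
    elif not leader.in_frame_with_v:
        notes.append("leader not in frame with V-REGION")
    if not vcheck.in_frame:
        notes.append("V-REGION frameshifted relative to reference")
    if not vcheck.cys23_present:
        notes.append("first conserved cysteine (IMGT 23) absent")
    if not vcheck.cys104_present:
        notes.append("second conserved cysteine (IMGT 104) absent")
    if vcheck.stop_before_cys104:
        notes.append("STOP-CODON before second cysteine (IMGT 104)")
    if vcheck.stop_after_cys104:
        notes.append("STOP-CODON after IMGT position 104")

    if rss_ok and leader_ok and v_ok:
        return Functionality.FUNCTIONAL, notes
    if vcheck.stop_free:
        return Functionality.ORF, notes
    return Functionality.PSEUDOGENE, notes


def annotate_v(
    assembly: Assembly,
    candidate,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
    refset: ReferenceSet,
) -> GeneAnnotation:
    """Full V annotation of one extended candidate."""
    seq = assembly.sequence
    start, _ = candidate.interval
    rss, vend, rss_notes = locate_v_rss(assembly, candidate, pwms, config)
    leader = locate_leader(assembly, candidate, pwms, config)
    v_seq = seq[start:vend]
    vcheck = map_to_imgt_positions(v_seq, refset, candidate.allele)
    functionality, class_notes = classify_v(leader, rss, vcheck)

    features: dict[str, Feature] = {
        "v_region": Feature((start, vend), v_seq),
    }
    joint_ll = 0.0
    if rss is not None:
        hlen, nlen = len(pwms["V-HEPTAMER"]), len(pwms["V-NONAMER"])
        hept = (rss.heptamer.position, rss.heptamer.position + hlen)
        nona = (rss.nonamer.position, rss.nonamer.position + nlen)
        features["v_heptamer"] = Feature(hept, seq[hept[0] : hept[1]])
        features["v_spacer"] = Feature((hept[1], nona[0]), seq[hept[1] : nona[0]])
        features["v_nonamer"] = Feature(nona, seq[nona[0] : nona[1]])
        joint_ll += rss.joint_log_likelihood
    else:
        joint_ll += MISSING_MOTIF_LL
    if leader is not None:
        features["l_part1"] = Feature(
            leader.l_part1, seq[leader.l_part1[0] : leader.l_part1[1]]
        )
        features["v_intron"] = Feature(
            leader.intron, seq[leader.intron[0] : leader.intron[1]]
        )
        features["l_part2"] = Feature(
            leader.l_part2, seq[leader.l_part2[0] : leader.l_part2[1]]
        )
        joint_ll += leader.joint_log_likelihood
    else:
        joint_ll += MISSING_MOTIF_LL

    notes = list(candidate.notes) + rss_notes + vcheck.notes + class_notes
    return GeneAnnotation(
        assembly_name=assembly.name,
        assembly_length=len(assembly),
        gene_type="V",
        sense=assembly.sense,
        features=features,
        allele=candidate.allele,
        percent_identity=candidate.percent_identity,
        functionality=functionality,
        joint_log_likelihood=joint_ll,
        notes=notes,
    )
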