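"""V gene RSS/leader location, IMGT position transfer, and functionality
classification."""

import itertools

import pytest

from vdjannot.io_model import Assembly, Functionality, ReferenceAllele, ReferenceSet
from vdjannot.motifs import MotifHit
from vdjannot.similarity_search import Candidate, RawHit
from vdjannot.synthetic_locus import generate_locus, make_reference_set, v_codon_index
from vdjannot.v_annotation import (
    LeaderCall,
    VRegionCheck,
    VRss,
    annotate_v,
    classify_v,
    locate_leader,
    locate_v_rss,
    map_to_imgt_positions,
)


def _candidate(interval, allele="IGHV1-1*01", gene_type="V"):
    hit = RawHit(allele, gene_type, interval, (0, interval[1] - interval[0]), 100.0, 1e-40, interval[1] - interval[0])
    return Candidate(
        gene_type=gene_type,
        interval=interval,
        allele=allele,
        evalue=1e-40,
        match_fraction=1.0,
        percent_identity=100.0,
        hit=hit,
    )


@pytest.fixture(scope="module")
def v_locus(refset, pwms, config):
    asm, truths = generate_locus(
        refset,
        pwms,
        config,
        n_v=1,
        n_d=0,
        n_j=0,
        seed=21,
        intergenic=lambda rng: int(rng.integers(700, 1100)),
    )
    return asm, truths[0]


class TestLocateVRss:
    def test_planted_rss_found_at_region_end(self, v_locus, pwms, config):
        asm, truth = v_locus
        cand = _candidate(truth.features["v_region"], truth.allele)
        rss, vend, notes = locate_v_rss(asm, cand, pwms, config)
        assert rss is not None
        assert rss.heptamer.position == truth.features["v_heptamer"][0]
        assert rss.nonamer.position == truth.features["v_nonamer"][0]
        assert vend == truth.features["v_region"][1]

    def test_overshooting_end_pulled_back(self, v_locus, pwms, config):
        asm, truth = v_locus
        s, e = truth.features["v_region"]
        rss, vend, _ = locate_v_rss(asm, _candidate((s, e + 3), truth.allele), pwms, config)
        assert rss is not None
        assert vend == e  # pulled back 3 nt to the heptamer start

    def test_all_n_window_reports_absent_with_note(self, pwms, config):
        asm = Assembly("n", "ACGT" * 25 + "N" * 80)
        rss, vend, notes = locate_v_rss(asm, _candidate((0, 100)), pwms, config)
        assert rss is None
        assert vend == 100
        assert any("N" in n or "threshold" in n for n in notes)


class TestLocateLeader:
    def test_planted_leader_recovered_exactly(self, v_locus, pwms, config):
        asm, truth = v_locus
        cand = _candidate(truth.features["v_region"], truth.allele)
        leader = locate_leader(asm, cand, pwms, config)
        assert leader is not None
        assert leader.l_part1 == truth.features["l_part1"]
        assert leader.l_part2 == truth.features["l_part2"]
        assert leader.intron == truth.features["v_intron"]
        assert leader.in_frame_with_v
        assert leader.stop_free
        assert leader.spliced_leader.startswith("ATG")

    def test_no_acceptor_gives_none(self, v_locus, pwms, config):
        asm, truth = v_locus
        l2_start = truth.features["l_part2"][0]
        seq = list(asm.sequence)
        seq[l2_start - 2 : l2_start] = ["C", "C"]  # destroy the AG acceptor
        broken = Assembly(asm.name, "".join(seq))
        cand = _candidate(truth.features["v_region"], truth.allele)
        assert locate_leader(broken, cand, pwms, config) is None

    def test_stop_free_placement_preferred_over_likelihood(
        self, v_locus, pwms, config, training
    ):
        """A stop-free in-frame spliced leader wins even when a stop-carrying
        placement scores at least as well under the PWMs."""
        asm, truth = v_locus
        seq = list(asm.sequence)
        # put a stop into the planted L-PART1
        s = truth.features["l_part1"][0]
        seq[s + 12 : s + 15] = list("TAA")
        # plant a clean training L-PART1 + GT donor further upstream
        clean = training["L-PART1"][0][0]
        alt = s - 100
        seq[alt : alt + len(clean)] = list(clean)
        seq[alt + len(clean) : alt + len(clean) + 2] = list("GT")
        modified = Assembly(asm.name, "".join(seq))
        cand = _candidate(truth.features["v_region"], truth.allele)
        leader = locate_leader(modified, cand, pwms, config)
        assert leader is not None
        assert leader.l_part1[0] == alt
        assert leader.stop_free


class TestImgtMapping:
    def test_identity_transfer(self, refset):
        allele = refset.by_type("V")[0]
        check = map_to_imgt_positions(allele.sequence, refset, allele.name)
        assert check.in_frame
        assert check.cys23_present and check.cys104_present
        assert not check.stop_before_cys104 and not check.stop_after_cys104
        assert check.imgt_mode

    def test_stop_at_104_counts_as_before(self, refset):
        allele = refset.by_type("V")[0]
        idx = v_codon_index(allele, 104)
        v_seq = allele.sequence[:idx] + "TGA" + allele.sequence[idx + 3 :]
        check = map_to_imgt_positions(v_seq, refset, allele.name)
        assert not check.cys104_present
        assert check.stop_before_cys104
        assert not check.stop_after_cys104

    def test_in_frame_deletion_still_resolves_positions(self, refset):
        allele = refset.by_type("V")[0]
        # remove one codon in FR2 (IMGT ~ position 45), upstream of Cys104
        idx = v_codon_index(allele, 45)
        v_seq = allele.sequence[:idx] + allele.sequence[idx + 3 :]
        check = map_to_imgt_positions(v_seq, refset, allele.name)
        assert check.in_frame
        assert check.cys23_present and check.cys104_present

    def test_ungapped_fallback_flagged(self, refset):
        # an allele without a gapped sequence: positions transfer through the
        # ungapped alignment and a lower-confidence note is recorded
        full = [a for a in refset.by_type("V") if "." not in a.gapped_sequence][0]
        bare = ReferenceAllele(full.name, "V", full.sequence)
        alt = ReferenceSet([bare])
        check = map_to_imgt_positions(full.sequence, alt, full.name)
        assert not check.imgt_mode
        assert check.cys23_present and check.cys104_present
        assert any("lower confidence" in n for n in check.notes)


def _rss_stub(passes=True, consensus_ok=True):
    ll = -1.0 if passes else -50.0
    cons = True if consensus_ok else False
    return VRss(MotifHit(0, ll, passes, cons), MotifHit(30, ll, passes, cons), 23)


def _leader_stub(passes=True, stop_free=True):
    spliced = "ATG" + ("GCT" * 18 if stop_free else "TAA" + "GCT" * 17)
    ll = -1.0 if passes else -80.0
    return LeaderCall(
        l_part1=(0, 46),
        l_part2=(100, 111),
        intron=(46, 100),
        donor_present=True,
        acceptor_present=True,
        spliced_leader=spliced,
        peptide="",
        in_frame_with_v=True,
        l1_hit=MotifHit(0, ll, passes, None),
        l2_hit=MotifHit(100, ll, passes, None),
    )


def _vcheck_stub(cys=True, stop_before=False, stop_after=False):
    return VRegionCheck(
        in_frame=True,
        cys23_present=cys,
        cys104_present=cys,
        stop_before_cys104=stop_before,
        stop_after_cys104=stop_after,
        gapped_allele="x",
    )


class TestClassifyV:
    def test_all_hallmarks_functional(self):
        func, _ = classify_v(_leader_stub(), _rss_stub(), _vcheck_stub())
        assert func == Functionality.FUNCTIONAL

    def test_rss_below_threshold_stop_free_is_orf(self):
        func, _ = classify_v(_leader_stub(), _rss_stub(passes=False), _vcheck_stub())
        assert func == Functionality.ORF

    def test_early_stop_is_pseudogene(self):
        func, _ = classify_v(
            _leader_stub(), _rss_stub(), _vcheck_stub(stop_before=True)
        )
        assert func == Functionality.PSEUDOGENE

    def test_stop_after_104_still_functional_with_note(self):
        func, notes = classify_v(
            _leader_stub(), _rss_stub(), _vcheck_stub(stop_after=True)
        )
        assert func == Functionality.FUNCTIONAL
        assert any("after IMGT position 104" in n for n in notes)

    def test_missing_leader_is_orf(self):
        func, _ = classify_v(None, _rss_stub(), _vcheck_stub())
        assert func == Functionality.ORF

    def test_monotone_in_every_check(self):
        """Turning any single failing check into a pass never demotes the
        functionality class."""
        rank = {
            Functionality.PSEUDOGENE: 0,
            Functionality.ORF: 1,
            Functionality.FUNCTIONAL: 2,
        }

        def outcome(bits):
            rss_pass, rss_cons, lead_pass, lead_stopfree, cys, nostop = bits
            func, _ = classify_v(
                _leader_stub(passes=lead_pass, stop_free=lead_stopfree),
                _rss_stub(passes=rss_pass, consensus_ok=rss_cons),
                _vcheck_stub(cys=cys, stop_before=not nostop),
            )
            return rank[func]

        for bits in itertools.product([False, True], repeat=6):
            base = outcome(bits)
            for i, b in enumerate(bits):
                if not b:
                    flipped = bits[:i] + (True,) + bits[i + 1 :]
                    assert outcome(flipped) >= base, (bits, i)


class TestAnnotateV:
    def test_intact_implant_fully_annotated(self, v_locus, pwms, config, refset):
        asm, truth = v_locus
        ann = annotate_v(
            asm, _candidate(truth.features["v_region"], truth.allele), pwms, config, refset
        )
        assert str(ann.functionality) == "Functional"
        for key, interval in truth.features.items():
            assert ann.features[key].interval == interval
        # feature order invariant on the working sense
        order = ["l_part1", "l_part2", "v_region", "v_heptamer", "v_spacer", "v_nonamer"]
        starts = [ann.features[k].interval[0] for k in order]
        assert starts == sorted(starts)
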