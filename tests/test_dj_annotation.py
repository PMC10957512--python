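"""D and J RSS location, J-motif/donor-splice detection, and
classification."""

import numpy as np
import pytest

from vdjannot.dj_annotation import (
    DCall,
    JCall,
    annotate_d,
    annotate_j,
    classify_d,
    classify_j,
    locate_d_rss_pair,
    locate_j_motif_and_splice,
    locate_j_rss,
)
from vdjannot.io_model import Assembly, Functionality
from vdjannot.motifs import MotifHit, matches_consensus
from vdjannot.similarity_search import Candidate, RawHit
from vdjannot.synthetic_locus import generate_locus


def _candidate(interval, allele, gene_type):
    hit = RawHit(
        allele,
        gene_type,
        interval,
        (0, interval[1] - interval[0]),
        100.0,
        1e-10,
        interval[1] - interval[0],
    )
    return Candidate(
        gene_type=gene_type,
        interval=interval,
        allele=allele,
        evalue=1e-10,
        match_fraction=1.0,
        percent_identity=100.0,
        hit=hit,
    )


@pytest.fixture(scope="module")
def d_locus(refset, pwms, config):
    asm, truths = generate_locus(
        refset, pwms, config, n_v=0, n_d=2, n_j=0, seed=31,
        intergenic=lambda rng: int(rng.integers(500, 900)),
    )
    return asm, truths


@pytest.fixture(scope="module")
def j_locus(refset, pwms, config):
    asm, truths = generate_locus(
        refset, pwms, config, n_v=0, n_d=0, n_j=2, seed=32,
        intergenic=lambda rng: int(rng.integers(500, 900)),
    )
    return asm, truths


class TestLocateDRss:
    def test_planted_rss_pair_recovered_exactly(self, d_locus, pwms, config):
        asm, truths = d_locus
        for truth in truths:
            cand = _candidate(truth.features["d_region"], truth.allele, "D")
            dcall = locate_d_rss_pair(asm, cand, pwms, config)
            assert dcall is not None
            assert dcall.d_region == truth.features["d_region"]
            assert dcall.heptamer_5.position == truth.features["d_5_heptamer"][0]
            assert dcall.nonamer_3.position == truth.features["d_3_nonamer"][0]

    def test_minimum_length_d_recovered(self, refset, pwms, config):
        # the 8 nt D allele, flanked by intact RSSs
        asm, truths = generate_locus(
            refset, pwms, config, n_v=0, n_d=8, n_j=0, seed=33,
            intergenic=lambda rng: int(rng.integers(400, 700)),
        )
        short = [t for t in truths if t.features["d_region"][1] - t.features["d_region"][0] == 8]
        assert short, "expected at least one 8 nt implant"
        for truth in short:
            cand = _candidate(truth.features["d_region"], truth.allele, "D")
            dcall = locate_d_rss_pair(asm, cand, pwms, config)
            assert dcall is not None and dcall.d_region == truth.features["d_region"]

    def test_deleted_upstream_rss_drops_candidate(self, d_locus, pwms, config):
        asm, truths = d_locus
        truth = truths[0]
        rng = np.random.default_rng(0)
        seq = list(asm.sequence)
        s, e = truth.features["d_5_nonamer"][0], truth.features["d_5_heptamer"][1]
        seq[s:e] = rng.choice(list("ACGT"), size=e - s)
        broken = Assembly(asm.name, "".join(seq))
        cand = _candidate(truth.features["d_region"], truth.allele, "D")
        assert annotate_d(broken, cand, pwms, config) is None

    def test_heptamer_adjacency_invariant(self, d_locus, pwms, config):
        asm, truths = d_locus
        for truth in truths:
            ann = annotate_d(
                asm, _candidate(truth.features["d_region"], truth.allele, "D"), pwms, config
            )
            assert ann.features["d_5_heptamer"].interval[1] == ann.features["d_region"].interval[0]
            assert ann.features["d_region"].interval[1] == ann.features["d_3_heptamer"].interval[0]


def _dcall_stub(passes=(True,) * 4, consensus=(True,) * 4):
    def hit(i):
        return MotifHit(i * 20, -1.0 if passes[i] else -60.0, passes[i], consensus[i])

    return DCall(
        d_region=(30, 45),
        nonamer_5=hit(0),
        heptamer_5=hit(1),
        spacer_5=12,
        heptamer_3=hit(2),
        nonamer_3=hit(3),
        spacer_3=12,
    )


class TestClassifyD:
    def test_all_pass_and_match_consensus_functional(self):
        func, _ = classify_d(_dcall_stub())
        assert func == Functionality.FUNCTIONAL

    def test_consensus_violation_is_orf(self):
        func, _ = classify_d(_dcall_stub(consensus=(True, False, True, True)))
        assert func == Functionality.ORF

    def test_no_consensus_defined_functional(self):
        func, _ = classify_d(_dcall_stub(consensus=(None,) * 4))
        assert func == Functionality.FUNCTIONAL

    def test_threshold_failure_drops_candidate(self):
        assert classify_d(_dcall_stub(passes=(True, False, True, True))) is None


class TestLocateJRss:
    def test_planted_rss_recovered(self, j_locus, pwms, config):
        asm, truths = j_locus
        for truth in truths:
            cand = _candidate(truth.features["j_region"], truth.allele, "J")
            jcall = locate_j_rss(asm, cand, pwms, config)
            assert jcall is not None
            assert jcall.j_region == truth.features["j_region"]
            assert jcall.heptamer.position == truth.features["j_heptamer"][0]

    def test_single_degraded_motif_still_retained(self, j_locus, pwms, config):
        asm, truths = j_locus
        truth = truths[0]
        rng = np.random.default_rng(1)
        seq = list(asm.sequence)
        s, e = truth.features["j_heptamer"]
        seq[s:e] = rng.choice(list("ACGT"), size=e - s)
        asm2 = Assembly(asm.name, "".join(seq))
        cand = _candidate(truth.features["j_region"], truth.allele, "J")
        jcall = locate_j_rss(asm2, cand, pwms, config)
        assert jcall is not None  # nonamer still passes

    def test_both_degraded_dropped(self, j_locus, pwms, config):
        asm, truths = j_locus
        truth = truths[0]
        rng = np.random.default_rng(2)
        seq = list(asm.sequence)
        for key in ("j_heptamer", "j_nonamer"):
            s, e = truth.features[key]
            seq[s:e] = rng.choice(list("ACGT"), size=e - s)
        asm2 = Assembly(asm.name, "".join(seq))
        cand = _candidate(truth.features["j_region"], truth.allele, "J")
        assert locate_j_rss(asm2, cand, pwms, config) is None


class TestJMotifAndSplice:
    def _jcall(self, j_region):
        return JCall(
            j_region=j_region,
            nonamer=MotifHit(0, -1.0, True, True),
            heptamer=MotifHit(30, -1.0, True, True),
            spacer=23,
        )

    def test_planted_motif_and_donor_found(self, j_locus, config):
        asm, truths = j_locus
        for truth in truths:
            jcall = locate_j_motif_and_splice(
                asm, self._jcall(truth.features["j_region"]), config
            )
            assert jcall.j_motif == truth.features["j_motif"]
            assert jcall.donor_splice == truth.features["j_donor"][0]

    def test_destroyed_motif_not_found(self, j_locus, config):
        asm, truths = j_locus
        truth = truths[0]
        seq = list(asm.sequence)
        ms = truth.features["j_motif"][0]
        seq[ms + 2] = "C"
        seq[ms + 4] = "C"
        asm2 = Assembly(asm.name, "".join(seq))
        jcall = locate_j_motif_and_splice(
            asm2, self._jcall(truth.features["j_region"]), config
        )
        assert jcall.j_motif is None

    def test_mutated_donor_not_found(self, j_locus, config):
        asm, truths = j_locus
        truth = truths[0]
        seq = list(asm.sequence)
        seq[truth.features["j_donor"][0] + 1] = "C"  # GT -> GC
        asm2 = Assembly(asm.name, "".join(seq))
        jcall = locate_j_motif_and_splice(
            asm2, self._jcall(truth.features["j_region"]), config
        )
        assert jcall.donor_splice is None

    def test_agrees_with_exhaustive_scan_fuzz(self, config):
        """Independent pattern scan restricted to the tolerance window, 200
        random J-REGIONs with the motif planted at varying offsets."""
        rng = np.random.default_rng(7)
        pattern = config.j.j_motif_pattern
        offset, tol = config.j.j_motif_offset, config.j.j_motif_tolerance
        for _ in range(200):
            jlen = int(rng.integers(45, 70))
            seq = "".join(rng.choice(list("ACGT"), size=jlen + 40))
            jstart, jend = 20, 20 + jlen
            true_off = int(rng.integers(offset - 6, offset + 7))
            ms = jend - true_off
            seq = seq[:ms] + "TGGGGG" + seq[ms + 6 :]
            asm = Assembly("f", seq + "GT")
            jcall = locate_j_motif_and_splice(
                asm, self._jcall((jstart, jend)), config
            )
            # oracle: try in-frame shifts by increasing |shift|
            expected = None
            for shift in sorted(range(-tol, tol + 1), key=lambda s: (abs(s), s)):
                if shift % 3 != 0:
                    continue
                pos = jend - offset + shift
                if pos < jstart or pos + len(pattern) > jend:
                    continue
                if matches_consensus(seq[pos : pos + len(pattern)], pattern):
                    expected = (pos, pos + len(pattern))
                    break
            assert jcall.j_motif == expected


class TestClassifyJ:
    def _jcall(self, motif=(40, 46), donor=60, passes=True, consensus=True,
               stop_before=False, stop_after=False):
        return JCall(
            j_region=(10, 60),
            nonamer=MotifHit(0, -1.0, passes, consensus),
            heptamer=MotifHit(30, -1.0, passes, consensus),
            spacer=23,
            j_motif=motif,
            donor_splice=donor,
            stop_before_motif=stop_before,
            stop_after_motif=stop_after,
        )

    def test_all_present_functional(self):
        func, _ = classify_j(self._jcall())
        assert func == Functionality.FUNCTIONAL

    def test_missing_motif_no_stops_orf(self):
        func, _ = classify_j(self._jcall(motif=None))
        assert func == Functionality.ORF

    def test_stop_before_motif_functional_with_note(self):
        func, notes = classify_j(self._jcall(stop_before=True))
        assert func == Functionality.FUNCTIONAL
        assert any("before J-motif" in n for n in notes)

    def test_stop_after_motif_pseudogene(self):
        func, _ = classify_j(self._jcall(stop_after=True))
        assert func == Functionality.PSEUDOGENE

    def test_consensus_violation_orf(self):
        func, _ = classify_j(self._jcall(consensus=False))
        assert func == Functionality.ORF


class TestAnnotateJ:
    def test_intact_implant_fully_annotated(self, j_locus, pwms, config):
        asm, truths = j_locus
        for truth in truths:
            ann = annotate_j(
                asm, _candidate(truth.features["j_region"], truth.allele, "J"), pwms, config
            )
            assert str(ann.functionality) == "Functional"
            for key, interval in truth.features.items():
                assert ann.features[key].interval == interval
            assert ann.features["j_heptamer"].interval[1] == ann.features["j_region"].interval[0]
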