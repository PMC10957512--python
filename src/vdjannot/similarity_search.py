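"""Candidate discovery by similarity to germline reference alleles.

Two interchangeable backends produce :class:`RawHit` records:

* ``external`` shells out to NCBI ``blastn`` (alleles compiled into a BLAST
  database, the assembly used as query) with the gene-type-specific
  parameters: word size 11 for V, 7 for D and J; gap open 5, gap extend 5,
  mismatch penalty -1; e-value cutoff 10 for V and J and 100 for D to widen
  the short-sequence search.
* ``internal`` is an ungapped seed-and-extend aligner honouring the same
  word sizes and match/mismatch scores, with a Karlin-Altschul-style
  e-value surrogate (only its ordering matters downstream; absolute values
  are approximate). Any exact full-length occurrence of a reference allele
  is always reported with 100% identity.

Overlapping raw hits are consolidated into one best candidate per locus
position, preferring matches covering a larger fraction of their allele,
then lower e-value, then longer alignments, with the allele name as the
final deterministic tie-break. Best matches are then extended to cover the
full length of their allele.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from .io_model import Assembly, Interval, ReferenceSet, write_fasta

# Karlin-Altschul-style constants for the +1/-1 internal scoring scheme.
_LAMBDA = 1.28
_LN_K = math.log(0.46)
_XDROP = 16
_SEED_CHAIN_GAP = 60


@dataclass(frozen=True)
class RawHit:
    """One similarity match between an allele and the working sequence."""

    allele: str
    gene_type: str
    a_interval: Interval  # assembly, 0-based half-open, working sense
    q_interval: Interval  # allele, 0-based half-open
    percent_identity: float
    evalue: float
    length: int  # aligned length

    def __post_init__(self) -> None:
        if self.a_interval[1] <= self.a_interval[0]:
            raise ValueError("empty assembly interval")
        if self.q_interval[1] <= self.q_interval[0]:
            raise ValueError("empty allele interval")


@dataclass
class Candidate:
    """The best hit at one locus position, extended to full allele length."""

    gene_type: str
    interval: Interval
    allele: str
    evalue: float
    match_fraction: float
    percent_identity: float
    hit: RawHit
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GeneTypeParams:
    word_size: int
    evalue_cutoff: float
    gap_open: int = 5
    gap_extend: int = 5
    penalty: int = -1
    reward: int = 1


@dataclass(frozen=True)
class SearchParams:
    """Per-gene-type search parameters; defaults follow the V/D/J scheme
    described in the module docstring."""

    v: GeneTypeParams = GeneTypeParams(word_size=11, evalue_cutoff=10.0)
    d: GeneTypeParams = GeneTypeParams(word_size=7, evalue_cutoff=100.0)
    j: GeneTypeParams = GeneTypeParams(word_size=7, evalue_cutoff=10.0)

    def for_type(self, gene_type: str) -> GeneTypeParams:
        return {"V": self.v, "D": self.d, "J": self.j}[gene_type]


# ---------------------------------------------------------------------------
# internal backend


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _extend_xdrop(seq: str, allele: str, a0: int, a1: int, q0: int, q1: int):
    """Extend the ungapped core [q0,q1) (allele) / [a0,a1) (assembly)
    outward on the shared diagonal with X-drop termination; returns the
    best-scoring endpoints and the score/matches across them."""

    def span_score(astart, aend, qstart):
        score = 0
        for off in range(aend - astart):
            score += 1 if seq[astart + off] == allele[qstart + off] else -1
        return score

    core = span_score(a0, a1, q0)

    # extend right
    best, run, best_off = core, core, 0
    off = 0
    while a1 + off < len(seq) and q1 + off < len(allele):
        run += 1 if seq[a1 + off] == allele[q1 + off] else -1
        off += 1
        if run > best:
            best, best_off = run, off
        if run < best - _XDROP:
            break
    a1, q1 = a1 + best_off, q1 + best_off
    core = best

    # extend left
    best, run, best_off = core, core, 0
    off = 0
    while a0 - off > 0 and q0 - off > 0:
        off += 1
        run += 1 if seq[a0 - off] == allele[q0 - off] else -1
        if run > best:
            best, best_off = run, off
        if run < best - _XDROP:
            break
    a0, q0 = a0 - best_off, q0 - best_off
    score = best
    length = a1 - a0
    matches = (length + score) // 2
    return a0, a1, q0, q1, score, matches


def _surrogate_evalue(score: int, allele_len: int, assembly_len: int) -> float:
    bits = (_LAMBDA * score - _LN_K) / math.log(2)
    return allele_len * assembly_len * 2.0 ** (-bits)


def _search_internal(
    assembly: Assembly, alleles, params: GeneTypeParams, gene_type: str
) -> list[RawHit]:
    seq = assembly.sequence
    index = _kmer_index(seq, params.word_size)
    hits: dict[tuple, tuple[int, RawHit]] = {}
    k = params.word_size
    for allele in alleles:
        aseq = allele.sequence
        diagonals: dict[int, list[int]] = {}
        for qpos in range(len(aseq) - k + 1):
            for apos in index.get(aseq[qpos : qpos + k], ()):
                diagonals.setdefault(apos - qpos, []).append(qpos)
        for diag, qlist in diagonals.items():
            qlist.sort()
            clusters = [[qlist[0], qlist[0]]]
            for q in qlist[1:]:
                if q - clusters[-1][1] > _SEED_CHAIN_GAP:
                    clusters.append([q, q])
                else:
                    clusters[-1][1] = q
            for qlo, qhi in clusters:
                a0, a1, q0, q1, score, matches = _extend_xdrop(
                    seq, aseq, qlo + diag, qhi + k + diag, qlo, qhi + k
                )
                evalue = _surrogate_evalue(score, len(aseq), len(seq))
                if evalue > params.evalue_cutoff:
                    continue
                length = a1 - a0
                key = (allele.name, a0, a1)
                hit = RawHit(
                    allele.name,
                    gene_type,
                    (a0, a1),
                    (q0, q1),
                    100.0 * matches / length,
                    evalue,
                    length,
                )
                prev = hits.get(key)
                if prev is None or score > prev[0]:
                    hits[key] = (score, hit)
    return sorted(
        (h for _, h in hits.values()),
        key=lambda h: (h.a_interval, h.allele, h.q_interval),
    )


# ---------------------------------------------------------------------------
# external backend (NCBI BLAST+)


def parse_blast_tabular(
    text: str, refset: ReferenceSet, keep_types: Optional[set[str]] = None
) -> list[RawHit]:
    """Parse BLAST outfmt-6 lines (query = assembly, subject = allele).

    Minus-orientation hits (sstart > send) are skipped: each search runs on
    a single working sense and hits are never mixed across senses.
    """
    hits = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        (_, subject, pident, length, _, _, qstart, qend, sstart, send, evalue, _) = (
            fields[:12]
        )
        sstart, send = int(sstart), int(send)
        if sstart > send:
            continue
        allele = refset[subject]
        if keep_types is not None and allele.gene_type not in keep_types:
            continue
        hits.append(
            RawHit(
                subject,
                allele.gene_type,
                (int(qstart) - 1, int(qend)),
                (sstart - 1, send),
                float(pident),
                float(evalue),
                int(length),
            )
        )
    return hits


def _search_external(
    assembly: Assembly, alleles, params: GeneTypeParams, gene_type: str, refset
) -> list[RawHit]:
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError(
            "BLAST+ (blastn/makeblastdb) not found on PATH; "
            "use backend='internal' instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db_fasta = tmp / "db.fasta"
        write_fasta(
            [Assembly(a.name, a.sequence) for a in alleles], db_fasta
        )
        query_fasta = tmp / "query.fasta"
        write_fasta([assembly], query_fasta)
        subprocess.run(
            ["makeblastdb", "-in", str(db_fasta), "-dbtype", "nucl"],
            check=True,
            capture_output=True,
        )
        result = subprocess.run(
            [
                "blastn",
                "-task",
                "blastn",
                "-query",
                str(query_fasta),
                "-db",
                str(db_fasta),
                "-word_size",
                str(params.word_size),
                "-gapopen",
                str(params.gap_open),
                "-gapextend",
                str(params.gap_extend),
                "-penalty",
                str(params.penalty),
                "-reward",
                str(params.reward),
                "-evalue",
                str(params.evalue_cutoff),
                "-outfmt",
                "6",
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    hits = parse_blast_tabular(result.stdout, refset, keep_types={gene_type})
    return sorted(hits, key=lambda h: (h.a_interval, h.allele, h.q_interval))


# ---------------------------------------------------------------------------
# public operations


def run_similarity_search(
    assembly: Assembly,
    refset: ReferenceSet,
    params: Optional[SearchParams] = None,
    backend: str = "internal",
    gene_types: Optional[Iterable[str]] = None,
) -> list[RawHit]:
    """Find raw similarity hits on the working sense of *assembly*."""
    params = params or SearchParams()
    gene_types = list(gene_types) if gene_types is not None else sorted(
        refset.gene_types
    )
    hits: list[RawHit] = []
    for gene_type in gene_types:
        alleles = refset.by_type(gene_type)
        if not alleles:
            raise ValueError(f"reference set has no {gene_type} alleles")
        type_params = params.for_type(gene_type)
        if backend == "internal":
            hits.extend(_search_internal(assembly, alleles, type_params, gene_type))
        elif backend == "external":
            hits.extend(
                _search_external(assembly, alleles, type_params, gene_type, refset)
            )
        else:
            raise ValueError(f"unknown backend {backend!r}")
    return hits


def _hit_sort_key(hit: RawHit, refset: ReferenceSet):
    fraction = (hit.q_interval[1] - hit.q_interval[0]) / len(refset[hit.allele])
    return (-round(fraction, 2), hit.evalue, -hit.length, hit.allele)


def consolidate_hits(hits: list[RawHit], refset: ReferenceSet) -> list[Candidate]:
    """Group transitively overlapping hits and keep the best hit per group.

    The winner maximises the ordered key (match fraction rounded to two
    decimals, -evalue, aligned length, lexicographically earliest allele
    name), i.e. longer-coverage matches win and e-value breaks ties.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: h.a_interval)
    groups: list[list[RawHit]] = [[ordered[0]]]
    group_end = ordered[0].a_interval[1]
    for hit in ordered[1:]:
        if hit.a_interval[0] < group_end:
            groups[-1].append(hit)
            group_end = max(group_end, hit.a_interval[1])
        else:
            groups.append([hit])
            group_end = hit.a_interval[1]

    candidates = []
    for group in groups:
        best = min(group, key=lambda h: _hit_sort_key(h, refset))
        fraction = (best.q_interval[1] - best.q_interval[0]) / len(
            refset[best.allele]
        )
        candidates.append(
            Candidate(
                gene_type=best.gene_type,
                interval=best.a_interval,
                allele=best.allele,
                evalue=best.evalue,
                match_fraction=fraction,
                percent_identity=best.percent_identity,
                hit=best,
            )
        )
    return candidates


def extend_candidate(
    candidate: Candidate, assembly: Assembly, refset: ReferenceSet
) -> Candidate:
    """Grow the candidate interval so it spans allele positions 0..len,
    using the hit's allele-interval offsets (ungapped extension), clamped
    at assembly edges with a truncation note."""
    allele = refset[candidate.allele]
    hit = candidate.hit
    start = hit.a_interval[0] - hit.q_interval[0]
    end = hit.a_interval[1] + (len(allele) - hit.q_interval[1])
    notes = list(candidate.notes)
    if start < 0:
        notes.append("5' truncated")
        start = 0
    if end > len(assembly):
        notes.append("3' truncated")
        end = len(assembly)
    return replace(candidate, interval=(start, end), notes=notes)
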