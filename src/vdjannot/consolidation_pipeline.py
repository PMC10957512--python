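"""Orchestration of a full annotation run and final overlap resolution.

Per sense, the pipeline runs: similarity search -> consolidation of raw
hits -> extension to full allele length -> per-gene-type annotation and
classification. Senses are then merged on input coordinates and
overlapping annotations resolved: every Functional annotation is retained
(mutual overlaps noted), any non-functional annotation overlapping a
Functional one is discarded, and among mutually overlapping non-functional
annotations only the one with the highest joint motif log-likelihood
survives. Overlap rules are applied uniformly across gene types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .dj_annotation import annotate_d, annotate_j
from .io_model import (
    Assembly,
    GeneAnnotation,
    LocusConfig,
    ReferenceSet,
    check_required_motifs,
    read_assembly,
    read_motif_params,
    read_reference_set,
    write_annotation_report,
    write_gff3,
)
from .motifs import PWM
from .similarity_search import (
    SearchParams,
    consolidate_hits,
    extend_candidate,
    run_similarity_search,
)
from .v_annotation import annotate_v


@dataclass
class RunConfig:
    """Everything one annotation run needs."""

    assembly_path: object
    motif_dir: object
    ref_paths: dict[str, object]  # gene type -> FASTA path
    gapped_v_path: Optional[object] = None
    senses: tuple[str, ...] = ("+",)
    gene_types: Optional[tuple[str, ...]] = None  # default: those with refs
    backend: str = "internal"
    out_csv: Optional[object] = None
    out_gff: Optional[object] = None
    search_params: SearchParams = field(default_factory=SearchParams)

    def __post_init__(self) -> None:
        if not self.senses:
            raise ValueError("at least one sense must be annotated")
        if self.gene_types is not None and not self.gene_types:
            raise ValueError("at least one gene type must be searched")


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def resolve_overlaps(annotations: list[GeneAnnotation]) -> list[GeneAnnotation]:
    """Apply the consolidation rules on input-coordinate intervals.

    Ties among non-functional annotations with equal joint likelihood break
    toward the longer annotation, then the leftmost, then the allele name.
    """
    # remove exact duplicates first: two candidates can relocate onto the
    # same motif geometry and then describe the same gene
    unique: dict[tuple, GeneAnnotation] = {}
    for ann in annotations:
        key = (
            ann.gene_type,
            ann.sense,
            tuple(sorted((k, f.interval) for k, f in ann.features.items())),
        )
        prev = unique.get(key)
        if prev is None or (
            ann.functionality,
            ann.percent_identity,
            prev.allele,
        ) > (prev.functionality, prev.percent_identity, ann.allele):
            unique[key] = ann
    annotations = list(unique.values())

    functional = [
        a for a in annotations if str(a.functionality) == "Functional"
    ]
    non_functional = [
        a for a in annotations if str(a.functionality) != "Functional"
    ]

    for ann in functional:
        others = [
            b
            for b in functional
            if b is not ann and _overlaps(ann.input_interval(), b.input_interval())
        ]
        for other in others:
            note = f"overlaps functional annotation {other.allele}"
            if note not in ann.notes:
                ann.notes.append(note)

    survivors = list(functional)
    remaining = [
        a
        for a in non_functional
        if not any(
            _overlaps(a.input_interval(), f.input_interval()) for f in functional
        )
    ]

    # transitive overlap groups among the remaining non-functional annotations
    remaining.sort(key=lambda a: a.input_interval())
    groups: list[list[GeneAnnotation]] = []
    group_end = None
    for ann in remaining:
        start, end = ann.input_interval()
        if group_end is not None and start < group_end:
            groups[-1].append(ann)
            group_end = max(group_end, end)
        else:
            groups.append([ann])
            group_end = end
    for group in groups:
        # ties break toward the longer annotation, then the allele name,
        # then a strand-symmetric position (distance to the nearer assembly
        # edge), so resolution commutes with reverse complementation
        def rank(a: GeneAnnotation):
            s, e = a.input_interval()
            return (
                -a.joint_log_likelihood,
                -(e - s),
                a.allele,
                min(s, a.assembly_length - e),
            )

        survivors.append(min(group, key=rank))

    survivors.sort(key=lambda a: (a.input_interval(), a.gene_type, a.allele))
    return survivors


def annotate_working_sense(
    assembly: Assembly,
    refset: ReferenceSet,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
    gene_types: Iterable[str],
    backend: str = "internal",
    params: Optional[SearchParams] = None,
) -> list[GeneAnnotation]:
    """Annotate one working-sense sequence (no overlap resolution)."""
    params = params or SearchParams()
    annotations: list[GeneAnnotation] = []
    for gene_type in gene_types:
        hits = run_similarity_search(
            assembly, refset, params, backend=backend, gene_types=[gene_type]
        )
        candidates = consolidate_hits(hits, refset)
        for candidate in candidates:
            candidate = extend_candidate(candidate, assembly, refset)
            if gene_type == "V":
                ann = annotate_v(assembly, candidate, pwms, config, refset)
            elif gene_type == "D":
                ann = annotate_d(assembly, candidate, pwms, config)
            else:
                ann = annotate_j(assembly, candidate, pwms, config)
            if ann is not None:
                annotations.append(ann)
    return annotations


def annotate(
    assembly: Assembly,
    refset: ReferenceSet,
    pwms: Mapping[str, PWM],
    config: LocusConfig,
    gene_types: Optional[Iterable[str]] = None,
    senses: Iterable[str] = ("+",),
    backend: str = "internal",
    params: Optional[SearchParams] = None,
) -> list[GeneAnnotation]:
    """Annotate an assembly in one or both senses and resolve overlaps."""
    gene_types = (
        sorted(refset.gene_types) if gene_types is None else list(gene_types)
    )
    check_required_motifs(pwms, gene_types)
    annotations: list[GeneAnnotation] = []
    for sense in senses:
        working = assembly if sense == "+" else assembly.reverse_complemented()
        annotations.extend(
            annotate_working_sense(
                working, refset, pwms, config, gene_types, backend, params
            )
        )
    return resolve_overlaps(annotations)


def annotate_assembly(run: RunConfig) -> tuple[list[GeneAnnotation], list[Path]]:
    """File-to-file driver: read inputs, annotate every assembly record,
    write the CSV (and optional GFF3) report."""
    assemblies = read_assembly(run.assembly_path)
    refset = read_reference_set(run.ref_paths, gapped_v_path=run.gapped_v_path)
    pwms, config = read_motif_params(run.motif_dir)
    gene_types = (
        list(run.gene_types)
        if run.gene_types is not None
        else sorted(refset.gene_types)
    )

    all_annotations: list[GeneAnnotation] = []
    for assembly in assemblies:
        all_annotations.extend(
            annotate(
                assembly,
                refset,
                pwms,
                config,
                gene_types=gene_types,
                senses=run.senses,
                backend=run.backend,
                params=run.search_params,
            )
        )

    written: list[Path] = []
    if run.out_csv is not None:
        write_annotation_report(all_annotations, assemblies[0], run.out_csv)
        written.append(Path(run.out_csv))
    if run.out_gff is not None:
        write_gff3(all_annotations, assemblies[0], run.out_gff)
        written.append(Path(run.out_gff))
    return all_annotations, written
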