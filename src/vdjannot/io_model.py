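"""Core domain types and file I/O: assemblies, germline reference sets,
motif parameter directories, and the CSV/GFF3 annotation report.

Conventions
-----------
* Internal coordinates are 0-based half-open intervals on the working-sense
  sequence (the sequence after optional reverse complementation).
* Reported coordinates are 1-based inclusive on the *input* (forward)
  sequence, with a sense column; extracting a reported range from the input
  and reverse-complementing when sense is "-" reproduces the reported
  feature sequence.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml
from Bio import SeqIO

from .motifs import PWM
from .sequence import clean_nucleotides, reverse_complement

Interval = tuple[int, int]

GENE_TYPES = ("V", "D", "J")

#: Fixed, documented report schema: one (start, end, seq) column triple per key.
FEATURE_KEYS = (
    "l_part1",
    "v_intron",
    "l_part2",
    "v_region",
    "v_heptamer",
    "v_spacer",
    "v_nonamer",
    "d_5_nonamer",
    "d_5_spacer",
    "d_5_heptamer",
    "d_region",
    "d_3_heptamer",
    "d_3_spacer",
    "d_3_nonamer",
    "j_nonamer",
    "j_spacer",
    "j_heptamer",
    "j_region",
    "j_motif",
    "j_donor",
)

REPORT_COLUMNS = (
    "assembly",
    "gene_type",
    "functionality",
    "start",
    "end",
    "sense",
    "allele",
    "percent_identity",
    "joint_log_likelihood",
    "notes",
) + tuple(f"{k}_{suffix}" for k in FEATURE_KEYS for suffix in ("start", "end", "seq"))


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass(frozen=True)
class Assembly:
    """A named nucleotide sequence with sense bookkeeping.

    ``sense`` records whether ``sequence`` has been reverse-complemented
    relative to the input record ("+" means as-read, "-" means working on
    the reverse complement).
    """

    name: str
    sequence: str
    sense: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"assembly {self.name!r} has an empty sequence")
        if self.sense not in ("+", "-"):
            raise ValueError(f"sense must be '+' or '-', got {self.sense!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complemented(self) -> "Assembly":
        return Assembly(
            self.name,
            reverse_complement(self.sequence),
            "-" if self.sense == "+" else "+",
        )


@dataclass(frozen=True)
class ReferenceAllele:
    """One germline allele from a reference set (e.g. IGHV1-2*02)."""

    name: str
    gene_type: str
    sequence: str
    gapped_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"gene_type must be one of {GENE_TYPES}")
        if self.gapped_sequence is not None:
            ungapped = self.gapped_sequence.replace(".", "").replace("-", "")
            if ungapped != self.sequence:
                raise FormatError(
                    f"gapped sequence of {self.name} does not match its "
                    "ungapped sequence after gap removal"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceSet:
    """Germline alleles keyed by name; at least one per searched gene type."""

    def __init__(self, alleles: Iterable[ReferenceAllele], species: str = ""):
        self.species = species
        self._alleles: dict[str, ReferenceAllele] = {}
        for allele in alleles:
            if allele.name in self._alleles:
                raise FormatError(f"duplicate allele name {allele.name!r}")
            self._alleles[allele.name] = allele

    def __len__(self) -> int:
        return len(self._alleles)

    def __iter__(self):
        return iter(self._alleles.values())

    def __contains__(self, name: str) -> bool:
        return name in self._alleles

    def __getitem__(self, name: str) -> ReferenceAllele:
        return self._alleles[name]

    def by_type(self, gene_type: str) -> list[ReferenceAllele]:
        return [a for a in self._alleles.values() if a.gene_type == gene_type]

    @property
    def gene_types(self) -> set[str]:
        return {a.gene_type for a in self._alleles.values()}


@functools.total_ordering
class Functionality(enum.Enum):
    """IMGT-style functionality classes, ordered by consolidation preference
    (Functional > ORF > pseudogene)."""

    FUNCTIONAL = "Functional"
    ORF = "ORF"
    PSEUDOGENE = "pseudogene"

    def __lt__(self, other: "Functionality") -> bool:
        order = [
            Functionality.PSEUDOGENE,
            Functionality.ORF,
            Functionality.FUNCTIONAL,
        ]
        return order.index(self) < order.index(other)

    def __str__(self) -> str:
        return self.value


@dataclass
class VMotifConfig:
    spacer_length: int = 23
    spacer_tolerance: int = 0
    rss_search_window: int = 40
    v_end_adjust_max: int = 10
    leader_search_window: int = 500
    l_part2_length: int = 11


@dataclass
class DMotifConfig:
    spacer_5_length: int = 12
    spacer_3_length: int = 12
    spacer_tolerance: int = 0
    # boundary uncertainty of a short-D similarity match is of the order of
    # a motif length, so the RSS relocation window spans one minimal spacer
    d_end_adjust_max: int = 12


@dataclass
class JMotifConfig:
    spacer_length: int = 23
    spacer_tolerance: int = 0
    j_end_adjust_max: int = 5
    j_motif_pattern: str = "TKGGGG"
    j_motif_offset: int = 31
    j_motif_tolerance: int = 3


@dataclass
class LocusConfig:
    """Per-locus motif geometry: spacer lengths, search windows, J-motif."""

    locus: str = "IGH"
    v: VMotifConfig = field(default_factory=VMotifConfig)
    d: DMotifConfig = field(default_factory=DMotifConfig)
    j: JMotifConfig = field(default_factory=JMotifConfig)

    def __post_init__(self) -> None:
        for spacer in (
            self.v.spacer_length,
            self.d.spacer_5_length,
            self.d.spacer_3_length,
            self.j.spacer_length,
        ):
            if spacer not in (12, 23):
                raise ValueError(f"RSS spacer length must be 12 or 23, got {spacer}")
        for window in (
            self.v.rss_search_window,
            self.v.leader_search_window,
            self.v.l_part2_length,
        ):
            if window <= 0:
                raise ValueError("search windows must be positive")

    @classmethod
    def from_dict(cls, data: Mapping) -> "LocusConfig":
        cfg = cls(locus=data.get("locus", "IGH"))
        for section, target in (("v", cfg.v), ("d", cfg.d), ("j", cfg.j)):
            for key, value in (data.get(section) or {}).items():
                if not hasattr(target, key):
                    raise FormatError(f"unknown config key {section}.{key}")
                setattr(target, key, value)
        return cls(locus=cfg.locus, v=cfg.v, d=cfg.d, j=cfg.j)

    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "v": vars(self.v).copy(),
            "d": vars(self.d).copy(),
            "j": vars(self.j).copy(),
        }


@dataclass
class Feature:
    """One annotated feature: working-sense interval plus its sequence."""

    interval: Interval
    sequence: str


@dataclass
class GeneAnnotation:
    """One annotated gene with every located feature.

    Features are keyed by the names in :data:`FEATURE_KEYS`; intervals are
    0-based half-open working-sense coordinates.
    """

    assembly_name: str
    assembly_length: int
    gene_type: str
    sense: str
    features: dict[str, Feature]
    allele: str
    percent_identity: float
    functionality: Functionality
    joint_log_likelihood: float
    notes: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        """Working-sense span start over all features."""
        return min(f.interval[0] for f in self.features.values())

    @property
    def end(self) -> int:
        return max(f.interval[1] for f in self.features.values())

    def input_interval(self, interval: Optional[Interval] = None) -> Interval:
        """Map a working-sense interval to 0-based half-open input coordinates."""
        s, e = interval if interval is not None else (self.start, self.end)
        if self.sense == "+":
            return (s, e)
        return (self.assembly_length - e, self.assembly_length - s)

    def validate(self) -> None:
        for name, feat in self.features.items():
            s, e = feat.interval
            if not (0 <= s < e <= self.assembly_length):
                raise ValueError(
                    f"feature {name} interval {feat.interval} outside assembly"
                )


# ---------------------------------------------------------------------------
# readers


def read_assembly(path) -> list[Assembly]:
    """Read a FASTA file into a list of forward-sense assemblies.

    Sequences are uppercased, U is mapped to T, and non-ACGT ambiguity codes
    collapse to N; characters outside the IUPAC set raise
    :class:`FormatError` naming the record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    assemblies = []
    for rec in records:
        try:
            seq = clean_nucleotides(str(rec.seq), context=f"record {rec.id!r}")
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
        assemblies.append(Assembly(rec.id, seq))
    return assemblies


def read_reference_set(
    paths: Mapping[str, object],
    gapped_v_path=None,
    species: str = "",
) -> ReferenceSet:
    """Read per-gene-type FASTA files into a :class:`ReferenceSet`.

    *paths* maps gene type ("V"/"D"/"J") to a FASTA path. The optional
    IMGT-gap-aligned V file must contain the same allele names as the V
    file, with sequences identical after gap removal.
    """
    alleles: list[ReferenceAllele] = []
    seen: set[str] = set()
    for gene_type, path in paths.items():
        if gene_type not in GENE_TYPES:
            raise ValueError(f"unknown gene type {gene_type!r}")
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate allele name {rec.id!r}")
            seen.add(rec.id)
            seq = clean_nucleotides(str(rec.seq), context=f"allele {rec.id!r}")
            alleles.append(ReferenceAllele(rec.id, gene_type, seq))

    refset = ReferenceSet(alleles, species=species)
    if gapped_v_path is not None:
        gapped = {}
        for rec in SeqIO.parse(str(gapped_v_path), "fasta"):
            gapped[rec.id] = str(rec.seq).upper().replace("U", "T")
        for name, gseq in gapped.items():
            if name not in refset:
                raise FormatError(
                    f"gapped allele {name!r} has no ungapped counterpart"
                )
            allele = refset[name]
            # ReferenceAllele.__post_init__ verifies the gap-removal identity
            refset._alleles[name] = replace(allele, gapped_sequence=gseq)
    return refset


def read_pwm_file(path, name: Optional[str] = None) -> PWM:
    """Read one motif matrix file.

    Dialect: optional ``# threshold:`` / ``# consensus:`` header lines, then
    one whitespace-separated probability row per position (columns A C G T).
    """
    path = Path(path)
    threshold = None
    consensus = None
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("threshold:"):
                threshold = float(body.split(":", 1)[1])
            elif body.lower().startswith("consensus:"):
                consensus = body.split(":", 1)[1].strip().upper()
            continue
        values = line.split()
        if len(values) != 4:
            raise FormatError(
                f"{path.name}: expected 4 probabilities per row, got {len(values)}"
            )
        rows.append([float(v) for v in values])
    if not rows:
        raise FormatError(f"{path.name}: no matrix rows found")
    for i, row in enumerate(rows):
        if abs(sum(row) - 1.0) > 1e-6:
            raise FormatError(
                f"{path.name}: probabilities at position {i} sum to "
                f"{sum(row):.6f}, not 1"
            )
    return PWM(
        name=name or path.stem,
        matrix=rows,
        threshold=threshold if threshold is not None else float("-inf"),
        consensus=consensus,
    )


def write_pwm_file(pwm: PWM, path) -> None:
    # full-precision floats so a write/read cycle reproduces scores exactly
    lines = [f"# threshold: {pwm.threshold!r}"]
    if pwm.consensus:
        lines.append(f"# consensus: {pwm.consensus}")
    for row in pwm.matrix:
        lines.append(" ".join(repr(float(p)) for p in row))
    Path(path).write_text("\n".join(lines) + "\n")


#: motifs a gene-type search needs, by file stem
REQUIRED_MOTIFS = {
    "V": ("V-HEPTAMER", "V-NONAMER", "L-PART1", "L-PART2"),
    "D": ("D-5-NONAMER", "D-5-HEPTAMER", "D-3-HEPTAMER", "D-3-NONAMER"),
    "J": ("J-NONAMER", "J-HEPTAMER"),
}


def read_motif_params(directory) -> tuple[dict[str, PWM], LocusConfig]:
    """Read a motif parameter directory: ``*.pwm`` matrices + ``config.yaml``."""
    directory = Path(directory)
    pwms = {}
    for path in sorted(directory.glob("*.pwm")):
        pwms[path.stem] = read_pwm_file(path)
    config_path = directory / "config.yaml"
    if config_path.exists():
        config = LocusConfig.from_dict(yaml.safe_load(config_path.read_text()) or {})
    else:
        config = LocusConfig()
    return pwms, config


def check_required_motifs(pwms: Mapping[str, PWM], gene_types: Iterable[str]) -> None:
    for gene_type in gene_types:
        missing = [m for m in REQUIRED_MOTIFS[gene_type] if m not in pwms]
        if missing:
            raise FormatError(
                f"motif directory lacks {', '.join(missing)} required for "
                f"{gene_type} gene search"
            )


def write_motif_params(pwms: Mapping[str, PWM], config: LocusConfig, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, pwm in pwms.items():
        write_pwm_file(pwm, directory / f"{name}.pwm")
    (directory / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))


# ---------------------------------------------------------------------------
# report writers


def _to_report_coords(ann: GeneAnnotation, interval: Interval) -> tuple[int, int]:
    """0-based half-open working coords -> 1-based inclusive input coords."""
    s, e = ann.input_interval(interval)
    return s + 1, e


def annotations_to_frame(annotations: list[GeneAnnotation]) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        row: dict[str, object] = {
            "assembly": ann.assembly_name,
            "gene_type": ann.gene_type,
            "functionality": str(ann.functionality),
            "sense": ann.sense,
            "allele": ann.allele,
            "percent_identity": round(ann.percent_identity, 2),
            "joint_log_likelihood": round(ann.joint_log_likelihood, 4),
            "notes": "; ".join(ann.notes),
        }
        row["start"], row["end"] = _to_report_coords(ann, (ann.start, ann.end))
        for key in FEATURE_KEYS:
            feat = ann.features.get(key)
            if feat is None:
                row[f"{key}_start"] = row[f"{key}_end"] = None
                row[f"{key}_seq"] = None
            else:
                start, end = _to_report_coords(ann, feat.interval)
                row[f"{key}_start"], row[f"{key}_end"] = start, end
                row[f"{key}_seq"] = feat.sequence
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    return frame


def write_annotation_report(
    annotations: list[GeneAnnotation], assembly: Assembly, path
) -> None:
    """Write the CSV report: one row per gene, fixed column set, 1-based
    inclusive input coordinates with a sense column."""
    for ann in annotations:
        ann.validate()
    frame = annotations_to_frame(annotations)
    frame.to_csv(path, index=False)


def write_gff3(annotations: list[GeneAnnotation], assembly: Assembly, path) -> None:
    """Optional GFF3 mirror of the CSV features (1-based inclusive, strand)."""
    lines = ["##gff-version 3", f"##sequence-region {assembly.name} 1 {len(assembly)}"]
    for i, ann in enumerate(sorted(annotations, key=lambda a: a.input_interval())):
        gid = f"gene{i:04d}"
        start, end = _to_report_coords(ann, (ann.start, ann.end))
        attrs = (
            f"ID={gid};Name={ann.allele};gene_type={ann.gene_type};"
            f"functionality={ann.functionality}"
        )
        lines.append(
            "\t".join(
                [
                    assembly.name,
                    "vdjannot",
                    f"{ann.gene_type}_gene",
                    str(start),
                    str(end),
                    ".",
                    ann.sense,
                    ".",
                    attrs,
                ]
            )
        )
        for key in FEATURE_KEYS:
            feat = ann.features.get(key)
            if feat is None:
                continue
            fstart, fend = _to_report_coords(ann, feat.interval)
            lines.append(
                "\t".join(
                    [
                        assembly.name,
                        "vdjannot",
                        key,
                        str(fstart),
                        str(fend),
                        ".",
                        ann.sense,
                        ".",
                        f"ID={gid}.{key};Parent={gid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(assemblies: Iterable[Assembly], path) -> None:
    with open(path, "w") as handle:
        for asm in assemblies:
            handle.write(f">{asm.name}\n")
            for i in range(0, len(asm.sequence), 80):
                handle.write(asm.sequence[i : i + 80] + "\n")
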