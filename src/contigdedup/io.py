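"""Readers and writers for the external formats the pipeline consumes.

Formats: FASTA (contigs, reference genes), BLAST tabular output format 6
(12 columns), CD-HIT ``.clstr`` cluster membership, read counts as either
a two-column TSV or a SAM/BAM alignment file, and gene-to-GO-slim
annotation TSVs.  Parsing contracts are strict: malformed input raises
:class:`FormatError` with file/line context rather than silently skipping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigRecord:
    """One assembled sequence with its parsed assembler ID structure.

    ``subcomponent_key`` groups putative isoforms emitted together by the
    assembler (Trinity components/subcomponents); contigs whose IDs carry
    no recognizable isoform suffix form singleton subcomponents.
    """

    contig_id: str
    sequence: str
    subcomponent_key: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")


@dataclass(frozen=True)
class BlastHit:
    """One HSP row of BLAST tabular (outfmt 6) output.

    Coordinates are 1-based inclusive and carried for completeness only;
    downstream selection uses the bit score alone.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.q_start > self.q_end:
            raise ValueError("query coordinates must ascend in outfmt6")


@dataclass
class ClusterSet:
    """Cluster membership with optional marked representatives.

    ``clusters`` is a list of ``(member_ids, representative_id)`` pairs;
    the representative may be None when the source file marks none, in
    which case consumers fall back to the longest member.
    """

    clusters: list[tuple[list[str], Optional[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members, rep in self.clusters:
            for m in members:
                if m in seen:
                    raise ValueError(f"member {m!r} appears in more than one cluster")
                seen.add(m)
            if rep is not None and rep not in members:
                raise ValueError(f"representative {rep!r} is not a member of its cluster")

    def member_ids(self) -> set[str]:
        return {m for members, _ in self.clusters for m in members}


@dataclass
class CountTable:
    """Per-feature read counts plus the library's total mapped reads.

    ``total_mapped`` is the mapped-read total of the library (the RPKM
    denominator) and may exceed the sum over listed features when reads
    mapped to features outside the table.
    """

    feature_counts: dict[str, int]
    total_mapped: int

    def __post_init__(self) -> None:
        for fid, c in self.feature_counts.items():
            if c < 0:
                raise ValueError(f"negative count for feature {fid!r}")
        if self.total_mapped < 0:
            raise ValueError("total_mapped must be >= 0")


@dataclass
class GoAnnotationMap:
    """Mapping from gene ID to its set of GO slim term IDs."""

    gene_to_terms: dict[str, set[str]]

    def term_universe(self) -> set[str]:
        return {t for terms in self.gene_to_terms.values() for t in terms}


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def read_fasta(path: PathLike, parse_ids: bool = True) -> list[ContigRecord]:
    """Read a FASTA file into :class:`ContigRecord` objects, order preserved.

    The record ID is the first whitespace-delimited token of the header.
    Duplicate IDs and empty sequences are hard errors.  When ``parse_ids``
    is true, the assembler subcomponent key is parsed from each ID.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA ID {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        key = parse_trinity_id(rec.id) if parse_ids else None
        records.append(ContigRecord(rec.id, seq, subcomponent_key=key))
    return records


def write_fasta(records: Iterable[ContigRecord], path: PathLike, width: int = 70) -> None:
    """Write contig records to FASTA (fixed line width, ID-only headers)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# --------------------------------------------------------------------------
# Assembler IDs
# --------------------------------------------------------------------------

# Classic Trinity comp<i>_c<j>_seq<k> and newer TRINITY_DN<i>_c<j>_g<k>_i<l>.
_CLASSIC_RE = re.compile(r"^(comp\d+_c\d+)_seq\d+$")
_MODERN_RE = re.compile(r"^(TRINITY_DN\d+_c\d+_g\d+)_i\d+$")


def parse_trinity_id(contig_id: str) -> str:
    """Return the subcomponent key of an assembler-style contig ID.

    Strips the trailing isoform token (``_seqN`` in the classic
    ``comp<i>_c<j>_seq<k>`` scheme, ``_iN`` in the newer
    ``TRINITY_DN<i>_c<j>_g<k>_i<l>`` scheme).  IDs matching neither
    scheme are returned whole, i.e. they form singleton subcomponents.
    """
    if not contig_id:
        raise ValueError("contig_id must be non-empty")
    for pattern in (_CLASSIC_RE, _MODERN_RE):
        m = pattern.match(contig_id)
        if m:
            return m.group(1)
    return contig_id


# --------------------------------------------------------------------------
# BLAST tabular
# --------------------------------------------------------------------------

_OUTFMT6_COLS = 12


def parse_blast_tab(path: PathLike) -> list[BlastHit]:
    """Parse 12-column BLAST tabular (``-outfmt 6``) output.

    One :class:`BlastHit` per line; multiple HSPs per query-subject pair
    are retained (aggregation happens downstream in best-hit assignment).
    Comment lines starting with ``#`` (outfmt 7 headers) are skipped.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_OUTFMT6_COLS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: PathLike) -> None:
    """Write hits back out as 12-column outfmt6 lines."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# CD-HIT .clstr
# --------------------------------------------------------------------------

_CLSTR_MEMBER_RE = re.compile(r">(\S+?)\.\.\.")


def parse_clstr(path: PathLike) -> ClusterSet:
    """Parse a CD-HIT ``.clstr`` file.

    ``>Cluster N`` lines open clusters; member lines carry ``>id...``
    with the representative marked by a trailing ``*``.  A member line
    before any cluster header is a hard error.  Clusters with no marked
    representative get ``None`` (downstream falls back to the longest
    member).
    """
    clusters: list[tuple[list[str], Optional[str]]] = []
    members: Optional[list[str]] = None
    rep: Optional[str] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                if members is not None:
                    clusters.append((members, rep))
                members, rep = [], None
                continue
            if members is None:
                raise FormatError(f"{path}:{lineno}: member line before any '>Cluster' header")
            m = _CLSTR_MEMBER_RE.search(line)
            if not m:
                raise FormatError(f"{path}:{lineno}: cannot parse member line {line!r}")
            member_id = m.group(1)
            members.append(member_id)
            if line.rstrip().endswith("*"):
                rep = member_id
    if members is not None:
        clusters.append((members, rep))
    return ClusterSet(clusters)


def write_clstr(clusters: ClusterSet, lengths: Mapping[str, int], path: PathLike) -> None:
    """Write a ClusterSet in CD-HIT ``.clstr`` dialect (for fixtures)."""
    with open(path, "w") as fh:
        for i, (members, rep) in enumerate(clusters.clusters):
            fh.write(f">Cluster {i}\n")
            for j, m in enumerate(members):
                mark = "*" if m == rep else "at 100.00%"
                fh.write(f"{j}\t{lengths[m]}nt, >{m}... {mark}\n")


# --------------------------------------------------------------------------
# Counts
# --------------------------------------------------------------------------


def load_counts(
    path: PathLike,
    feature_ids: Optional[Sequence[str]] = None,
    total_mapped: Optional[int] = None,
) -> CountTable:
    """Load per-feature read counts from a 2-column TSV or a SAM/BAM file.

    TSV input: one ``feature_id<TAB>count`` pair per line; ``total_mapped``
    defaults to the sum of counts unless overridden.

    SAM/BAM input: a feature's count is the number of mapped, primary,
    non-supplementary alignment records on it (each mate of a pair counts
    once); ``total_mapped`` is the number of such records in the whole
    file.  Records on references outside ``feature_ids`` still count
    toward ``total_mapped`` and are reported as a warning tally.
    """
    p = Path(path)
    if p.suffix.lower() in {".sam", ".bam"}:
        return _load_counts_sam(p, feature_ids)
    return _load_counts_tsv(p, feature_ids, total_mapped)


def _load_counts_tsv(
    path: Path, feature_ids: Optional[Sequence[str]], total_mapped: Optional[int]
) -> CountTable:
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            fid, raw = fields
            if lineno == 1 and not raw.lstrip("-").isdigit():
                continue  # header row
            try:
                counts[fid] = int(raw)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count {raw!r}") from exc
    if feature_ids is not None:
        for fid in feature_ids:
            counts.setdefault(fid, 0)
    total = total_mapped if total_mapped is not None else sum(counts.values())
    return CountTable(counts, total)


def _load_counts_sam(path: Path, feature_ids: Optional[Sequence[str]]) -> CountTable:
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    wanted = set(feature_ids) if feature_ids is not None else None
    counts: dict[str, int] = {}
    if wanted is not None:
        counts = {fid: 0 for fid in wanted}
    total = 0
    unknown = 0
    with pysam.AlignmentFile(str(path), mode) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            total += 1
            ref = rec.reference_name
            if wanted is not None and ref not in wanted:
                unknown += 1
                continue
            counts[ref] = counts.get(ref, 0) + 1
    if unknown:
        logger.warning(
            "%s: %d mapped records on references outside the feature set "
            "(counted toward total_mapped only)",
            path,
            unknown,
        )
    return CountTable(counts, total)


def write_counts(table: CountTable, path: PathLike) -> None:
    """Write a count table as header + 2-column TSV plus a total line."""
    with open(path, "w") as fh:
        fh.write("feature_id\tcount\n")
        for fid in sorted(table.feature_counts):
            fh.write(f"{fid}\t{table.feature_counts[fid]}\n")


# --------------------------------------------------------------------------
# GO annotations
# --------------------------------------------------------------------------


def read_go_annotations(path: PathLike) -> GoAnnotationMap:
    """Read a 2-column TSV of (gene_id, GO term) pairs, de-duplicating."""
    gene_to_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            gene, term = fields
            if lineno == 1 and gene == "gene_id":
                continue  # header row
            gene_to_terms.setdefault(gene, set()).add(term)
    return GoAnnotationMap(gene_to_terms)


def write_go_annotations(go_map: GoAnnotationMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene in sorted(go_map.gene_to_terms):
            for term in sorted(go_map.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
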