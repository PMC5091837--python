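"""Per-family concatenated "repeat genome" references.

A repeat genome is built by concatenating the genomic sequence of every
annotated instance of one repeat family into a single reference, with
instances separated by a short run of ``N`` (default ``NNNNN``) so that
reads cannot align across instance boundaries.  A segments table maps
offsets in the concatenated sequence back to their genomic source, and a
named consensus sequence (e.g. the 120-nt mouse minor-satellite consensus)
can be appended manually as an extra segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

from Bio.Seq import Seq

from .annotation import RepeatInstance

#: 120-nt mouse minor-satellite consensus appended manually to the
#: minor-satellite repeat genome (the assembly is depleted of centromeric
#: sequence, so annotated instances alone under-represent this family).
MINOR_SATELLITE_CONSENSUS = (
    "TTGTAGAACAGTGTATATCAATGAGTTACAATGAGAAACATGGAAAATGATAAAAACCAC"
    "ACTGTAGAACATATTAGATGAGTGAGTTACACTGAAAAACACATTCGTTGGAAACGGGAT"
)

_VALID = set("ACGTN")

SourceType = Union[RepeatInstance, str]


@dataclass(frozen=True)
class Segment:
    """Half-open offset interval of the repeat genome and its source.

    ``source`` is the originating :class:`RepeatInstance`, or a plain
    string naming a manually added consensus.  ``reverse_complemented``
    records whether the stored sequence is the reverse complement of the
    genomic plus strand.
    """

    offset_start: int
    offset_end: int
    source: SourceType
    reverse_complemented: bool = False

    def __len__(self) -> int:
        return self.offset_end - self.offset_start


@dataclass
class RepeatGenome:
    """One concatenated reference for one repeat family."""

    family: str
    sequence: str
    spacer_len: int = 5
    segments: list[Segment] = field(default_factory=list)
    strand_policy: str = "reverse_complement_minus"

    def __len__(self) -> int:
        return len(self.sequence)

    def segment_sequence(self, i: int) -> str:
        seg = self.segments[i]
        return self.sequence[seg.offset_start:seg.offset_end]


@dataclass(frozen=True)
class MappedOffset:
    """Result of mapping a repeat-genome offset back to its source."""

    kind: str                       # "segment" or "spacer"
    segment_index: int | None = None
    source: SourceType | None = None
    within_source: int | None = None   # 0-based position along the stored segment
    chrom: str | None = None
    genomic_position: int | None = None  # 0-based plus-strand genomic coordinate


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return str(Seq(seq).reverse_complement())


def _chrom_sequence(genome: Mapping[str, object], chrom: str) -> str:
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    return seq if isinstance(seq, str) else str(seq)


def _validate_alphabet(seq: str, what: str) -> None:
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")


def build_repeat_genome(
    genome: Mapping[str, object],
    instances: Sequence[RepeatInstance],
    spacer: str = "NNNNN",
    strand_policy: str = "reverse_complement_minus",
    max_read_length: int | None = None,
) -> RepeatGenome:
    """Concatenate one family's instances into a repeat genome.

    Parameters
    ----------
    genome
        Mapping from chromosome name to sequence (plain strings or any
        object whose ``str()`` is the sequence, e.g. a pyfaidx record).
    instances
        All instances of a single family, in the order to concatenate.
    spacer
        Inserted between consecutive segments; ``"NNNNN"`` by default so
        any read crossing a boundary accrues at least five mismatches.
    strand_policy
        ``"reverse_complement_minus"`` stores minus-strand instances in
        repeat-consensus orientation; ``"as_plus"`` stores the literal
        plus-strand genomic sequence for every instance.
    max_read_length
        If given and larger than the spacer, a warning is emitted: a
        spacer shorter than the read length cannot by itself guarantee
        that boundary-crossing reads fail to align.
    """
    if not instances:
        raise ValueError("empty family: no instances to concatenate")
    if strand_policy not in ("reverse_complement_minus", "as_plus"):
        raise ValueError(f"unknown strand policy: {strand_policy!r}")
    if set(spacer) != {"N"} and spacer != "":
        raise ValueError("spacer must consist of N characters")
    families = {inst.family for inst in instances}
    if len(families) != 1:
        raise ValueError(f"instances span multiple families: {sorted(families)}")
    if max_read_length is not None and len(spacer) < max_read_length:
        warnings.warn(
            f"spacer length {len(spacer)} < max read length {max_read_length}: "
            "reads may align across instance boundaries",
            stacklevel=2,
        )
    family = next(iter(families))
    chrom_cache: dict[str, str] = {}
    parts: list[str] = []
    segments: list[Segment] = []
    offset = 0
    for inst in instances:
        if inst.chrom not in chrom_cache:
            chrom_cache[inst.chrom] = _chrom_sequence(genome, inst.chrom)
        chrom_seq = chrom_cache[inst.chrom]
        if inst.end > len(chrom_seq):
            raise ValueError(
                f"instance {inst.chrom}:{inst.start}-{inst.end} exceeds "
                f"chromosome length {len(chrom_seq)}"
            )
        sub = chrom_seq[inst.start:inst.end].upper()
        _validate_alphabet(sub, f"instance {inst.chrom}:{inst.start}-{inst.end}")
        rc = inst.strand == "-" and strand_policy == "reverse_complement_minus"
        if rc:
            sub = reverse_complement(sub)
        if segments:
            parts.append(spacer)
            offset += len(spacer)
        segments.append(Segment(offset, offset + len(sub), inst, rc))
        parts.append(sub)
        offset += len(sub)
    return RepeatGenome(
        family=family,
        sequence="".join(parts),
        spacer_len=len(spacer),
        segments=segments,
        strand_policy=strand_policy,
    )


def add_consensus(rg: RepeatGenome, name: str, seq: str) -> RepeatGenome:
    """Return a new repeat genome with a named consensus segment appended.

    The consensus goes after one spacer (or forms the whole sequence if
    the repeat genome is empty), mirroring the manual addition of the
    minor-satellite consensus to its repeat genome.
    """
    if not seq:
        raise ValueError("consensus sequence must be non-empty")
    seq = seq.upper()
    _validate_alphabet(seq, f"consensus {name!r}")
    if rg.sequence:
        spacer = "N" * rg.spacer_len
        offset = len(rg.sequence) + rg.spacer_len
        new_seq = rg.sequence + spacer + seq
    else:
        offset = 0
        new_seq = seq
    new_segments = list(rg.segments) + [Segment(offset, offset + len(seq), name)]
    return replace(rg, sequence=new_seq, segments=new_segments)


def map_offset(rg: RepeatGenome, offset: int) -> MappedOffset:
    """Map a repeat-genome offset back to its source (inverse of construction).

    Offsets inside a segment resolve to the source instance (with the
    plus-strand genomic coordinate) or consensus name; offsets inside a
    spacer return ``kind="spacer"``.
    """
    if not (0 <= offset < len(rg.sequence)):
        raise IndexError(
            f"offset {offset} out of range for repeat genome of length {len(rg.sequence)}"
        )
    for i, seg in enumerate(rg.segments):
        if offset < seg.offset_start:
            return MappedOffset(kind="spacer")
        if offset < seg.offset_end:
            within = offset - seg.offset_start
            if isinstance(seg.source, RepeatInstance):
                inst = seg.source
                if seg.reverse_complemented:
                    gpos = inst.end - 1 - within
                else:
                    gpos = inst.start + within
                return MappedOffset(
                    kind="segment", segment_index=i, source=inst,
                    within_source=within, chrom=inst.chrom, genomic_position=gpos,
                )
            return MappedOffset(
                kind="segment", segment_index=i, source=seg.source,
                within_source=within,
            )
    return MappedOffset(kind="spacer")


def write_repeat_genome_fasta(rg: RepeatGenome, path: str | Path) -> Path:
    """Write the repeat genome as FASTA (60-column) plus a segments sidecar.

    The FASTA holds one record named after the family; the sidecar
    ``<path>.segments.tsv`` tabulates each segment's offsets and source so
    alignments against the reference can be interpreted.  Returns the
    sidecar path.
    """
    if not rg.sequence:
        raise ValueError(f"empty family {rg.family!r}: refusing to write")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{rg.family}\n")
        for i in range(0, len(rg.sequence), 60):
            fh.write(rg.sequence[i:i + 60] + "\n")
    sidecar = path.with_name(path.name + ".segments.tsv")
    with open(sidecar, "w") as fh:
        fh.write(f"#family={rg.family}\tspacer_len={rg.spacer_len}"
                 f"\tstrand_policy={rg.strand_policy}\n")
        fh.write("offset_start\toffset_end\tsource_type\tchrom\tstart\tend"
                 "\tstrand\tname\treverse_complemented\n")
        for seg in rg.segments:
            if isinstance(seg.source, RepeatInstance):
                inst = seg.source
                row = [seg.offset_start, seg.offset_end, "instance", inst.chrom,
                       inst.start, inst.end, inst.strand, inst.family,
                       int(seg.reverse_complemented)]
            else:
                row = [seg.offset_start, seg.offset_end, "consensus", ".",
                       ".", ".", ".", seg.source, 0]
            fh.write("\t".join(map(str, row)) + "\n")
    return sidecar


def read_repeat_genome_fasta(path: str | Path) -> RepeatGenome:
    """Re-read a repeat genome written by :func:`write_repeat_genome_fasta`."""
    path = Path(path)
    family = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if family is not None:
                    raise ValueError("repeat genome FASTA must hold one record")
                family = line[1:].split()[0]
            elif line:
                chunks.append(line)
    if family is None:
        raise ValueError("no FASTA record found")
    sequence = "".join(chunks)
    sidecar = path.with_name(path.name + ".segments.tsv")
    spacer_len, strand_policy, segments = 5, "reverse_complement_minus", []
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = fh.readline().lstrip("#").strip().split("\t")
            kv = dict(item.split("=", 1) for item in meta)
            spacer_len = int(kv.get("spacer_len", 5))
            strand_policy = kv.get("strand_policy", strand_policy)
            fh.readline()  # column header
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if f[2] == "instance":
                    src: SourceType = RepeatInstance(
                        chrom=f[3], start=int(f[4]), end=int(f[5]),
                        strand=f[6], family=f[7],
                    )
                else:
                    src = f[7]
                segments.append(
                    Segment(int(f[0]), int(f[1]), src, bool(int(f[8])))
                )
    return RepeatGenome(
        family=family, sequence=sequence, spacer_len=spacer_len,
        segments=segments, strand_policy=strand_policy,
    )
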