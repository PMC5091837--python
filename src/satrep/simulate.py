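"""Synthetic data with known ground truth for every pipeline stage.

Generators emulate the study's inputs at desk scale: a toy genome with
embedded repeat-family instances and exactly matching annotation,
ChIP/input read libraries with a specified per-family enrichment factor,
single-nucleus images with a known number of bright spots of known radii,
and long-format Ct tables with specified fold changes and Gaussian Ct
noise.  Every generator is driven by :func:`numpy.random.default_rng`
with an explicit seed, so outputs are byte-stable for a given (spec,
seed) pair.

Enrichment is modelled as region-weight multiplication: ChIP read start
positions falling entirely within an instance of family *f* carry weight
``e_f`` relative to background, input reads are uniform.  With repeat
families occupying a small fraction of the genome (the default), the
ChIP/input hit-fraction ratio converges to ``e_f``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .annotation import RepeatCatalog, RepeatInstance
from .repeat_genome import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PackingError(RuntimeError):
    """Requested spot placements could not be packed into the nucleus."""


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class FamilySpec:
    """One repeat family in the toy genome."""

    n_instances: int = 4
    length_range: tuple[int, int] = (140, 160)


@dataclass(frozen=True)
class GenomeSpec:
    """Toy genome layout: repeat instances embedded in random background.

    The defaults keep the repeat fraction of the genome below ~1% so that
    ChIP/input hit-fraction ratios estimate the generative enrichment
    factor essentially without attenuation.
    """

    families: Mapping[str, FamilySpec] = field(
        default_factory=lambda: {
            "major_sat": FamilySpec(4, (140, 160)),
            "minor_sat": FamilySpec(4, (110, 130)),
        }
    )
    background_len: int = 11000      # nt between consecutive instances
    divergence: float = 0.05         # per-base substitution rate vs consensus
    minus_strand_prob: float = 0.3
    chrom: str = "chrT"


@dataclass(frozen=True)
class ReadSpec:
    """ChIP/input library simulation settings."""

    n_reads: int = 100_000
    read_length: int = 36
    error_rate: float = 0.002
    enrichment: Mapping[str, float] = field(
        default_factory=lambda: {"major_sat": 1.2, "minor_sat": 1.9}
    )


@dataclass(frozen=True)
class ImageSpec:
    """Single-nucleus image simulation settings."""

    n_cells: int = 200
    mean_spots: float = 12.0
    radius_choices: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0)
    noise_sd: float = 0.0
    shape: tuple[int, int] = (192, 192)
    background: float = 50.0
    spot_intensity: float = 200.0


@dataclass(frozen=True)
class QpcrSpec:
    """Ct-table simulation settings."""

    folds: Mapping[str, float] = field(default_factory=lambda: {"MG132": 10.0})
    noise_sd: float = 0.1
    n_replicates: int = 6
    target: str = "major_sat"
    reference: str = "spike"
    vehicle: str = "DMSO"
    efficiency: float = 2.0


@dataclass(frozen=True)
class SimulationSpec:
    """Bundle of all generator settings plus the master seed."""

    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    reads: ReadSpec = field(default_factory=ReadSpec)
    images: ImageSpec = field(default_factory=ImageSpec)
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)


# ---------------------------------------------------------------------------
# toy genome

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hit):
        idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(idx + rng.integers(1, 4, size=len(hit))) % 4]
    return out


def make_toy_genome(
    spec: GenomeSpec = GenomeSpec(), seed: int | np.random.Generator = 0
) -> tuple[dict[str, str], RepeatCatalog, dict[str, str]]:
    """Generate a toy genome with embedded repeat instances.

    Each family gets a random consensus; instances are copies of it with
    ``divergence`` per-base substitutions, embedded (minus-strand copies
    reverse-complemented) between stretches of random background.  Returns
    ``(genome, catalog, consensus_by_family)``; annotation coordinates
    match the embedded positions exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    consensus: dict[str, str] = {}
    placements: list[tuple[str, np.ndarray]] = []
    for fam in spec.families:
        fspec = spec.families[fam]
        lo, hi = fspec.length_range
        cons = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        consensus[fam] = cons.tobytes().decode()
        for _ in range(fspec.n_instances):
            placements.append((fam, _mutate(rng, cons, spec.divergence)))
    order = rng.permutation(len(placements))
    parts = [_random_seq(rng, spec.background_len)]
    pos = spec.background_len
    instances: list[RepeatInstance] = []
    for j in order:
        fam, inst_seq = placements[j]
        strand = "-" if rng.random() < spec.minus_strand_prob else "+"
        embedded = inst_seq.tobytes().decode()
        if strand == "-":
            embedded = reverse_complement(embedded)
        parts.append(np.frombuffer(embedded.encode(), dtype=np.uint8))
        instances.append(RepeatInstance(
            chrom=spec.chrom, start=pos, end=pos + len(embedded),
            strand=strand, family=fam,
            repclass="Satellite" if "sat" in fam else "Unknown",
        ))
        pos += len(embedded)
        parts.append(_random_seq(rng, spec.background_len))
        pos += spec.background_len
    genome = {spec.chrom: np.concatenate(parts).tobytes().decode()}
    catalog = RepeatCatalog(instances=instances, genome_build="toy")
    return genome, catalog, consensus


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# reads

@lru_cache(maxsize=8)
def _read_ids(lib: str, n: int) -> tuple[str, ...]:
    return tuple(f"{lib}_{i:06d}" for i in range(n))


@dataclass
class ReadSimulation:
    """Simulated ChIP/input libraries plus per-read ground truth."""

    chip: list[tuple[str, str]] | None
    input: list[tuple[str, str]] | None
    truth: pd.DataFrame           # library, read_id, chrom, start, end, family, strand
    n_reads: int


def _start_annotation(
    genome: Mapping[str, str], catalog: RepeatCatalog, read_length: int
) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Valid start positions across chromosomes with family labels.

    A start is attributed to a family iff the whole read lies inside one
    of that family's instances; all other starts are background ("").
    """
    chroms, starts_chrom, starts_pos, labels = [], [], [], []
    fam_index: list[str] = []
    for ci, (chrom, seq) in enumerate(genome.items()):
        n_valid = len(seq) - read_length + 1
        if n_valid <= 0:
            raise ValueError("read length exceeds chromosome length")
        chroms.append(chrom)
        lab = np.full(n_valid, -1, dtype=np.int32)
        for inst in catalog:
            if inst.chrom != chrom:
                continue
            lo, hi = inst.start, inst.end - read_length  # inclusive start range
            if hi < lo:
                continue
            if inst.family not in fam_index:
                fam_index.append(inst.family)
            lab[lo:hi + 1] = fam_index.index(inst.family)
        starts_chrom.append(np.full(n_valid, ci, dtype=np.int32))
        starts_pos.append(np.arange(n_valid, dtype=np.int64))
        labels.append(lab)
    return (chroms, np.concatenate(starts_chrom), np.concatenate(starts_pos),
            fam_index), np.concatenate(labels)  # type: ignore[return-value]


def simulate_reads(
    genome: Mapping[str, str],
    catalog: RepeatCatalog,
    spec: ReadSpec = ReadSpec(),
    seed: int | np.random.Generator = 0,
    with_sequences: bool = True,
) -> ReadSimulation:
    """Simulate one ChIP and one input library with known per-read origin.

    Input read starts are uniform over all valid positions; ChIP starts
    re-weight positions inside family-*f* instances by ``e_f`` and
    renormalise.  Substitution errors are i.i.d. at ``error_rate``; each
    read is taken from a uniformly random strand.  With
    ``with_sequences=False`` only the truth table is produced (origin
    sampling is identical), which is much faster for estimator studies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = spec.read_length
    min_inst = min((len(i) for i in catalog), default=k)
    if k > min_inst:
        raise ValueError("read length exceeds the shortest repeat instance")
    (chroms, start_chrom, start_pos, fam_index), labels = _start_annotation(
        genome, catalog, k
    )
    n_valid = len(start_pos)
    weights = np.ones(n_valid, dtype=float)
    for fam, e in spec.enrichment.items():
        if e <= 0:
            raise ValueError(f"enrichment factor for {fam!r} must be > 0")
        if fam in fam_index:
            weights[labels == fam_index.index(fam)] = e
    records: list[pd.DataFrame] = []
    libs: dict[str, list[tuple[str, str]] | None] = {}
    encoded = {c: np.frombuffer(genome[c].encode(), dtype=np.uint8) for c in chroms}
    for lib in ("input", "chip"):
        if lib == "input":
            idx = rng.integers(0, n_valid, size=spec.n_reads)
        else:
            p = weights / weights.sum()
            idx = rng.choice(n_valid, size=spec.n_reads, p=p)
        strands = np.where(rng.random(spec.n_reads) < 0.5, "+", "-")
        lab = labels[idx]
        fam_lookup = np.array([""] + fam_index, dtype=object)
        df = pd.DataFrame({
            "library": lib,
            "read_id": _read_ids(lib, spec.n_reads),
            "chrom": np.array(chroms, dtype=object)[start_chrom[idx]],
            "start": start_pos[idx],
            "end": start_pos[idx] + k,
            "family": fam_lookup[lab + 1],
            "strand": strands,
        })
        records.append(df)
        if not with_sequences:
            libs[lib] = None
            continue
        # vectorised sequence extraction + substitution errors
        reads: list[tuple[str, str]] = []
        mat = np.empty((spec.n_reads, k), dtype=np.uint8)
        for ci, chrom in enumerate(chroms):
            sel = np.nonzero(start_chrom[idx] == ci)[0]
            if len(sel) == 0:
                continue
            mat[sel] = encoded[chrom][start_pos[idx[sel], None] + np.arange(k)]
        err = rng.random((spec.n_reads, k)) < spec.error_rate
        if err.any():
            base_idx = np.searchsorted(_BASES, mat[err])
            mat[err] = _BASES[(base_idx + rng.integers(1, 4, size=err.sum())) % 4]
        for i in range(spec.n_reads):
            s = mat[i].tobytes().decode()
            if strands[i] == "-":
                s = reverse_complement(s)
            reads.append((f"{lib}_{i:06d}", s))
        libs[lib] = reads
    truth = pd.concat(records, ignore_index=True)
    return ReadSimulation(
        chip=libs["chip"], input=libs["input"], truth=truth, n_reads=spec.n_reads
    )


def truth_hit_counts(sim: ReadSimulation, family: str, library: str):
    """(hits, total) a perfect within-instance aligner would report."""
    sub = sim.truth[sim.truth["library"] == library]
    return int((sub["family"] == family).sum()), sim.n_reads


def write_fastq(
    reads: Sequence[tuple[str, str]], path: str | Path, sidecar: dict | None = None
) -> None:
    """Write reads as FASTQ (constant quality); optional JSON sidecar with
    the generating spec and seed."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    if sidecar is not None:
        with open(path.with_name(path.name + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# nucleus images

def simulate_nucleus_image(
    n_spots: int,
    radii: Sequence[float] | float,
    spec: ImageSpec = ImageSpec(),
    seed: int | np.random.Generator = 0,
    min_separation: float | None = None,
    max_tries: int = 400,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one nucleus: elliptical mask, background + noise, bright disks.

    ``radii`` is one radius per spot (scalar = same for all).  Spot
    centres are rejection-sampled so each disk lies well inside the
    nuclear mask and centres are separated by at least
    ``r_i + r_j + 6`` px by default, keeping the thresholded components
    disjoint after smoothing.  Returns ``(image, mask, truth)`` with the
    truth table listing each spot's centre and radius.  Raises
    :class:`PackingError` when placement fails after bounded retries.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(radii):
        radii = [float(radii)] * n_spots
    radii = [float(r) for r in radii]
    if len(radii) != n_spots:
        raise ValueError("need one radius per spot")
    nr, nc = spec.shape
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    ay, ax = 0.42 * nr, 0.42 * nc
    rows, cols = np.mgrid[0:nr, 0:nc]
    mask = ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0
    image = np.full(spec.shape, 10.0)
    image[mask] = spec.background
    centres: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        placed = False
        for _ in range(max_tries):
            yy = rng.uniform(cy - ay, cy + ay)
            xx = rng.uniform(cx - ax, cx + ax)
            # disk fully inside the ellipse with a 2-px margin
            margin = (r + 2.0)
            if ((yy - cy) / (ay - margin)) ** 2 + ((xx - cx) / (ax - margin)) ** 2 > 1:
                continue
            ok = True
            for (py, px), pr in zip(centres, radii[:len(centres)]):
                sep = min_separation if min_separation is not None else r + pr + 6.0
                if math.hypot(yy - py, xx - px) < sep:
                    ok = False
                    break
            if ok:
                centres.append((yy, xx))
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place spot {i + 1}/{n_spots} after {max_tries} tries"
            )
    for (yy, xx), r in zip(centres, radii):
        rr, cc = draw_disk((yy, xx), r, shape=spec.shape)
        image[rr, cc] = spec.spot_intensity
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    truth = pd.DataFrame(
        {"row": [c[0] for c in centres], "col": [c[1] for c in centres],
         "radius": radii}
    )
    return image, mask, truth


# ---------------------------------------------------------------------------
# qPCR

def simulate_ct_table(
    spec: QpcrSpec = QpcrSpec(),
    seed: int | np.random.Generator = 0,
    base_reference_ct: float = 20.0,
    base_target_ct: float = 26.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a long-format Ct table with known fold changes.

    Reference Ct is Normal(``base_reference_ct``, sd) in every condition;
    the target's vehicle Ct is Normal(``base_target_ct``, sd); in each
    treated condition the target Ct is shifted down by
    ``log_efficiency(fold)`` cycles.  Returns the table and the truth
    mapping condition -> fold (vehicle = 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for cond, fold in spec.folds.items():
        if fold <= 0:
            raise ValueError(f"fold for {cond!r} must be > 0")
    rows = []
    truth = {spec.vehicle: 1.0, **{c: float(f) for c, f in spec.folds.items()}}
    for cond in truth:
        shift = math.log(truth[cond], spec.efficiency)
        for rep in range(1, spec.n_replicates + 1):
            noise = rng.normal(0.0, spec.noise_sd, size=2) if spec.noise_sd > 0 \
                else np.zeros(2)
            rows.append((f"s_{cond}_{rep}", cond, spec.target, rep,
                         base_target_ct - shift + noise[0]))
            rows.append((f"s_{cond}_{rep}", cond, spec.reference, rep,
                         base_reference_ct + noise[1]))
    df = pd.DataFrame(rows, columns=["sample", "condition", "target",
                                     "replicate", "ct"])
    return df, truth
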