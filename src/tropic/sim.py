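"""Truth-bearing synthetic tumour-normal cohorts.

The generator reproduces an in-silico benchmark design for anchored-IRR
detection: a reference genome carrying short tandem repeats, a subset
expanded beyond the read length in tumours at a configurable carrier
frequency, paired-end reads with a substitution error model (wgsim-style),
optional copy-number amplification of repeat-containing regions, coverage
downsampling, and an oracle aligner that replaces an external short-read
aligner.  The oracle's mapping-quality model encodes exactly the property
the detector relies on: reads whose sequence is near-pure repeat multi-map
(MAPQ 0), everything else maps uniquely to its true position (MAPQ 60).
Every stage is deterministic given (config, seed).

Coordinates of tumour-genome reads are mapped back to reference coordinates
before alignment records are emitted, mirroring alignment of all samples to
one reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .alignments import ReadAlignments
from .motifs import decode, detect_irr, encode, periodic_read_mask, repeat_purity

__all__ = [
    "SimulationConfig",
    "RepeatSpec",
    "SimulatedGenome",
    "ReadSet",
    "CohortSim",
    "random_reference",
    "genome_from_fasta",
    "expand_reference",
    "simulate_reads",
    "oracle_align",
    "simulate_amplification",
    "merge_reads",
    "simulate_cohort",
    "downsample",
    "write_fasta",
    "write_fastq",
]

_CHUNK = 32768


@dataclasses.dataclass
class SimulationConfig:
    """Full parameterization of a simulated cohort (seed is mandatory)."""

    seed: int
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.02
    fragment_mean: float = 500.0
    fragment_sd: float = 50.0
    carrier_frequency: float = 0.3
    n_pairs: int = 20

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        if not 0 <= self.carrier_frequency <= 1:
            raise ValueError("carrier_frequency must lie in [0, 1]")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")


@dataclasses.dataclass
class RepeatSpec:
    """One tandem repeat to place in the reference.

    ``expanded_copies`` marks the locus as a designated somatic expansion
    target; None means the repeat stays at its reference length everywhere.
    """

    motif: str
    ref_copies: int
    expanded_copies: int | None = None
    position: int | None = None


@dataclasses.dataclass
class SimulatedGenome:
    """Named sequences (uint8 codes) plus the locus truth table.

    ``truth`` columns: chrom, start, end (this genome's coordinates), motif,
    ref_copies, sim_copies, copy_number.  ``ref_lengths``/``coord_maps``
    translate this genome's coordinates back to the reference it was derived
    from (identity for the reference itself).
    """

    sequences: dict[str, np.ndarray]
    truth: pd.DataFrame
    ref_lengths: dict[str, int] | None = None
    coord_maps: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self):
        if self.ref_lengths is None:
            self.ref_lengths = {c: len(s) for c, s in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def to_ref(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Map this genome's coordinates onto reference coordinates."""
        if not self.coord_maps or chrom not in self.coord_maps:
            return positions
        starts, offsets = self.coord_maps[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        return positions + offsets[idx]

    def sequence(self, chrom: str) -> str:
        return decode(self.sequences[chrom])


def random_reference(
    length: int,
    repeats: list[RepeatSpec],
    seed: int,
    chrom: str = "chr1",
) -> SimulatedGenome:
    """Random background sequence with tandem repeats placed along it.

    Unpositioned repeats are spaced evenly; positions are starts of the
    repeat tract in the final coordinate system (background bases are
    consumed left to right between tracts).
    """
    rng = np.random.default_rng(seed)
    background = rng.integers(0, 4, size=length, dtype=np.uint8)
    n = len(repeats)
    auto = np.linspace(length / (n + 1), n * length / (n + 1), n).astype(int)
    placed = sorted(
        (r.position if r.position is not None else int(auto[i]), i, r)
        for i, r in enumerate(repeats)
    )
    parts = []
    rows = []
    consumed = 0
    shift = 0
    for bg_pos, _, spec in placed:
        if bg_pos < consumed:
            raise ValueError("repeat positions overlap")
        parts.append(background[consumed:bg_pos])
        tract = np.tile(encode(spec.motif.upper()), spec.ref_copies)
        start = bg_pos + shift
        parts.append(tract)
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + tract.size,
                "motif": spec.motif.upper(),
                "ref_copies": spec.ref_copies,
                "sim_copies": spec.ref_copies,
                "copy_number": 2,
                "expanded_copies": spec.expanded_copies,
            }
        )
        shift += tract.size
        consumed = bg_pos
    parts.append(background[consumed:])
    seq = np.concatenate(parts)
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "motif", "ref_copies", "sim_copies",
                 "copy_number", "expanded_copies"],
    )
    return SimulatedGenome(sequences={chrom: seq}, truth=truth)


def genome_from_fasta(path, truth: pd.DataFrame | None = None) -> SimulatedGenome:
    """Load a genome from FASTA (truth table optional, e.g. from TSV)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    seqs = {name: encode(str(fa[name])) for name in fa.keys()}
    if truth is None:
        truth = pd.DataFrame(
            columns=["chrom", "start", "end", "motif", "ref_copies",
                     "sim_copies", "copy_number", "expanded_copies"]
        )
    return SimulatedGenome(sequences=seqs, truth=truth)


def expand_reference(
    genome: SimulatedGenome, targets: dict[int, int]
) -> SimulatedGenome:
    """Rewrite repeat tracts to target copy counts (keyed by truth row index).

    Each targeted tract is replaced by perfect copies of its motif; all
    downstream coordinates (sequence and truth) shift consistently, and a
    coordinate map back to the input genome's reference frame is recorded.
    The existing tract must actually be tandem copies of the motif (purity
    >= 0.9).
    """
    truth = genome.truth.copy()
    for idx, copies in targets.items():
        if copies < 1:
            raise ValueError("target copy count must be >= 1")
        if idx not in truth.index:
            raise KeyError(f"no truth locus with index {idx}")
    intervals = truth.sort_values(["chrom", "start"])
    prev_end = {}
    for _, row in intervals.iterrows():
        if row["chrom"] in prev_end and row["start"] < prev_end[row["chrom"]]:
            raise ValueError("overlapping truth loci")
        prev_end[row["chrom"]] = row["end"]

    new_seqs = {}
    maps = {}
    new_truth = truth.copy()
    for chrom, seq in genome.sequences.items():
        rows = truth[truth["chrom"] == chrom].sort_values("start")
        parts = []
        seg_starts = [0]
        seg_offsets = [0]
        cursor = 0          # position in old sequence
        shift = 0           # new coordinate minus old, past the cursor
        for idx, row in rows.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if idx not in targets:
                new_truth.loc[idx, ["start", "end"]] = [start + shift, end + shift]
                continue
            motif = str(row["motif"])
            if repeat_purity(decode(seq[start:end]), motif) < 0.9:
                raise ValueError(
                    f"reference content at truth locus {idx} does not match motif {motif}"
                )
            new_tract = np.tile(encode(motif), targets[idx])
            parts.append(seq[cursor:start])
            parts.append(new_tract)
            new_start = start + shift
            new_end = new_start + new_tract.size
            # the rewritten tract maps back onto the old tract start
            seg_starts.append(new_start)
            seg_offsets.append(start - new_start)
            shift += new_tract.size - (end - start)
            seg_starts.append(new_end)
            seg_offsets.append(-shift)
            new_truth.loc[idx, ["start", "end", "sim_copies"]] = [
                new_start, new_end, targets[idx],
            ]
            cursor = end
        parts.append(seq[cursor:])
        new_seqs[chrom] = np.concatenate(parts) if len(parts) > 1 else seq.copy()
        maps[chrom] = (np.asarray(seg_starts), np.asarray(seg_offsets))
    return SimulatedGenome(
        sequences=new_seqs,
        truth=new_truth,
        ref_lengths=dict(genome.ref_lengths),
        coord_maps=maps,
    )


@dataclasses.dataclass
class ReadSet:
    """Paired reads with truth origins.

    ``seq1``/``seq2`` hold the *sequenced* bases (mate 2 is read off the
    reverse strand of the fragment's right end).  ``start1``/``start2`` are
    leftmost genome coordinates of each mate in the source genome's frame.
    """

    references: dict[str, int]
    read_length: int
    chrom: np.ndarray         # reference index per pair
    start1: np.ndarray
    start2: np.ndarray
    seq1: np.ndarray
    seq2: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.chrom)

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(
            dict(self.references), self.read_length,
            self.chrom[mask], self.start1[mask], self.start2[mask],
            self.seq1[mask], self.seq2[mask],
        )


def _apply_errors(seqs: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate <= 0:
        return seqs
    mask = rng.random(seqs.shape) < error_rate
    shift = rng.integers(1, 4, size=seqs.shape, dtype=np.uint8)
    out = seqs.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def simulate_reads(
    genome: SimulatedGenome,
    config: SimulationConfig,
    rng=None,
    n_pairs: int | None = None,
    coverage: float | None = None,
) -> ReadSet:
    """wgsim-style paired reads at the configured coverage.

    Pair count = round(coverage x genome length / (2 x read length));
    fragment starts are uniform, lengths normal(mean, sd) clipped to
    [read_length, chromosome length]; mates are read from opposite strands
    of the fragment ends; substitutions are independent per base.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rl = config.read_length
    names = list(genome.sequences)
    lengths = np.array([len(genome.sequences[c]) for c in names], dtype=np.int64)
    if (lengths < rl).any():
        raise ValueError("chromosome shorter than the read length")
    cov = config.coverage if coverage is None else coverage
    total = int(lengths.sum())
    n = int(round(cov * total / (2 * rl))) if n_pairs is None else n_pairs
    chrom = (
        rng.choice(len(names), size=n, p=lengths / total)
        if len(names) > 1
        else np.zeros(n, dtype=np.int64)
    )
    chrom_len = lengths[chrom]
    flen = np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=n))
    flen = np.clip(flen, rl, chrom_len).astype(np.int64)
    start1 = (rng.random(n) * (chrom_len - flen + 1)).astype(np.int64)
    start2 = start1 + flen - rl
    seq1 = np.empty((n, rl), dtype=np.uint8)
    seq2 = np.empty((n, rl), dtype=np.uint8)
    offs = np.arange(rl)
    for cid, cname in enumerate(names):
        sel = np.flatnonzero(chrom == cid)
        arr = genome.sequences[cname]
        for lo in range(0, sel.size, _CHUNK):
            block = sel[lo : lo + _CHUNK]
            seq1[block] = arr[start1[block, None] + offs]
            # mate 2 sequenced from the reverse strand: complement and reverse
            fwd = arr[start2[block, None] + offs]
            seq2[block] = (3 - fwd)[:, ::-1]
    seq1 = _apply_errors(seq1, config.error_rate, rng)
    seq2 = _apply_errors(seq2, config.error_rate, rng)
    return ReadSet(
        references={c: int(l) for c, l in zip(names, lengths)},
        read_length=rl,
        chrom=chrom, start1=start1, start2=start2, seq1=seq1, seq2=seq2,
    )


def merge_reads(*readsets: ReadSet) -> ReadSet:
    first = readsets[0]
    for rs in readsets[1:]:
        if rs.references != first.references or rs.read_length != first.read_length:
            raise ValueError("read sets must share references and read length")
    return ReadSet(
        dict(first.references), first.read_length,
        np.concatenate([r.chrom for r in readsets]),
        np.concatenate([r.start1 for r in readsets]),
        np.concatenate([r.start2 for r in readsets]),
        np.vstack([r.seq1 for r in readsets]),
        np.vstack([r.seq2 for r in readsets]),
    )


def _irr_mapq(seqs: np.ndarray, min_purity: float) -> np.ndarray:
    """MAPQ 0 for in-repeat reads, 60 otherwise (vectorized screen first)."""
    mapq = np.full(len(seqs), 60, dtype=np.int16)
    for i in np.flatnonzero(periodic_read_mask(seqs, min_purity)):
        if detect_irr(decode(seqs[i]), min_purity=min_purity)[0]:
            mapq[i] = 0
    return mapq


def oracle_align(
    reads: ReadSet, genome: SimulatedGenome, min_purity: float = 0.9
) -> ReadAlignments:
    """Model aligner: every read is placed at its truth position.

    Reads classified as in-repeat reads receive MAPQ 0 (a perfect repeat
    read is placeable anywhere in the tract), all others MAPQ 60.  Tumour
    coordinates are translated back to the reference frame so cohorts share
    one coordinate system.
    """
    names = list(reads.references)
    mapq1 = _irr_mapq(reads.seq1, min_purity)
    mapq2 = _irr_mapq(reads.seq2, min_purity)
    pos1 = reads.start1.copy()
    pos2 = reads.start2.copy()
    for cid, cname in enumerate(names):
        sel = reads.chrom == cid
        pos1[sel] = genome.to_ref(cname, pos1[sel])
        pos2[sel] = genome.to_ref(cname, pos2[sel])
    ref_lengths = genome.ref_lengths or reads.references
    # store genome-forward-strand sequence for the reverse mate, SAM-style
    seq2_fwd = (3 - reads.seq2)[:, ::-1]
    return ReadAlignments(
        references={c: int(ref_lengths[c]) for c in names},
        read_length=reads.read_length,
        chrom1=reads.chrom.copy(), pos1=pos1, mapq1=mapq1, seq1=reads.seq1.copy(),
        chrom2=reads.chrom.copy(), pos2=pos2, mapq2=mapq2, seq2=np.ascontiguousarray(seq2_fwd),
        rev1=np.zeros(reads.n_pairs, dtype=bool),
        rev2=np.ones(reads.n_pairs, dtype=bool),
    )


def simulate_amplification(
    genome: SimulatedGenome,
    truth_indices: list[int],
    copy_number: int,
    config: SimulationConfig,
    rng,
    flank: int = 1000,
) -> ReadSet:
    """Extra reads emulating copy-number amplification of repeat regions.

    Reads are drawn from each region plus ``flank`` bp at a rate that brings
    the expected regional coverage to base x copy_number / 2 (diploid
    baseline: copy number 2 adds nothing).
    """
    if not isinstance(copy_number, (int, np.integer)) or copy_number < 2:
        raise ValueError("copy_number must be an integer >= 2")
    rl = config.read_length
    pieces = []
    for idx in truth_indices:
        row = genome.truth.loc[idx]
        chrom = row["chrom"]
        chrom_len = len(genome.sequences[chrom])
        lo = max(0, int(row["start"]) - flank)
        hi = min(chrom_len, int(row["end"]) + flank)
        if copy_number == 2:
            continue
        sub = SimulatedGenome(
            sequences={chrom: genome.sequences[chrom][lo:hi]},
            truth=genome.truth.iloc[0:0],
        )
        extra_cov = config.coverage * (copy_number - 2) / 2
        # fragment starts are confined to the sub-reference, which concentrates
        # coverage in its interior; rate against the start span keeps the
        # interior depth at base x copy_number / 2
        span = max(1.0, (hi - lo) - config.fragment_mean + rl)
        n_extra = int(round(extra_cov * span / (2 * rl)))
        rs = simulate_reads(sub, config, rng=rng, n_pairs=n_extra)
        rs.start1 += lo
        rs.start2 += lo
        rs.references = {c: len(genome.sequences[c]) for c in genome.sequences}
        rs.chrom = np.full(rs.n_pairs, list(genome.sequences).index(chrom), dtype=np.int64)
        pieces.append(rs)
    if not pieces:
        return ReadSet(
            {c: len(s) for c, s in genome.sequences.items()}, rl,
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty((0, rl), dtype=np.uint8), np.empty((0, rl), dtype=np.uint8),
        )
    return merge_reads(*pieces)


@dataclasses.dataclass
class CohortSim:
    """A simulated cohort: alignments, sample manifest, and the truth."""

    genome: SimulatedGenome
    alignments: dict[str, ReadAlignments]
    samples: pd.DataFrame            # index sample_id: role, pair_id, read_length
    truth_pairs: pd.DataFrame        # pair_id x designated locus: carrier, copy_number


def simulate_cohort(
    genome: SimulatedGenome,
    config: SimulationConfig,
    amplification: dict[str, tuple[int, int]] | None = None,
) -> CohortSim:
    """Simulate ``n_pairs`` tumour-normal pairs from a designed reference.

    Expansion targets are the truth loci with non-null ``expanded_copies``;
    each tumour carries each expansion independently with probability
    ``carrier_frequency``.  ``amplification`` optionally maps a pair_id to
    (truth locus index, copy number) for tumour-side regional amplification.
    All randomness descends from ``config.seed``.
    """
    if config.n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    designated = genome.truth.index[genome.truth["expanded_copies"].notna()].tolist()
    if not designated:
        raise ValueError("no designated expansion loci in the truth table")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_pairs * 2 + 1)
    carrier_rng = np.random.default_rng(children[0])
    carriers = carrier_rng.random((config.n_pairs, len(designated))) < config.carrier_frequency

    alignments: dict[str, ReadAlignments] = {}
    sample_rows = []
    truth_rows = []
    for i in range(config.n_pairs):
        pair_id = f"P{i:02d}"
        normal_rng = np.random.default_rng(children[1 + 2 * i])
        tumour_rng = np.random.default_rng(children[2 + 2 * i])

        normal_reads = simulate_reads(genome, config, rng=normal_rng)
        alignments[pair_id + "N"] = oracle_align(normal_reads, genome)
        sample_rows.append((pair_id + "N", "normal", pair_id))

        targets = {
            idx: int(genome.truth.loc[idx, "expanded_copies"])
            for j, idx in enumerate(designated)
            if carriers[i, j]
        }
        tumour_genome = expand_reference(genome, targets) if targets else genome
        tumour_reads = simulate_reads(tumour_genome, config, rng=tumour_rng)
        cn_map = {}
        if amplification and pair_id in amplification:
            idx, cn = amplification[pair_id]
            extra = simulate_amplification(
                tumour_genome, [idx], cn, config, rng=tumour_rng
            )
            tumour_reads = merge_reads(tumour_reads, extra)
            cn_map[idx] = cn
        alignments[pair_id + "T"] = oracle_align(tumour_reads, tumour_genome)
        sample_rows.append((pair_id + "T", "tumour", pair_id))

        for j, idx in enumerate(designated):
            truth_rows.append(
                {
                    "pair_id": pair_id,
                    "locus_index": idx,
                    "carrier": bool(carriers[i, j]),
                    "copy_number": cn_map.get(idx, 2),
                }
            )
        for idx, cn in cn_map.items():
            if idx not in designated:
                truth_rows.append(
                    {"pair_id": pair_id, "locus_index": idx,
                     "carrier": False, "copy_number": cn}
                )
    samples = pd.DataFrame(
        [
            {"sample_id": sid, "role": role, "pair_id": pid,
             "read_length": config.read_length}
            for sid, role, pid in sample_rows
        ]
    ).set_index("sample_id")
    return CohortSim(
        genome=genome,
        alignments=alignments,
        samples=samples,
        truth_pairs=pd.DataFrame(truth_rows),
    )


def downsample(obj, fraction: float, seed: int):
    """Keep each read pair independently with probability ``fraction``.

    Mates stay together; the subset is deterministic in ``seed``.  Works on
    :class:`ReadSet` and :class:`~tropic.alignments.ReadAlignments`.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = obj.n_pairs
    mask = np.random.default_rng(seed).random(n) < fraction
    return obj.subset(mask)


def write_fasta(genome: SimulatedGenome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            text = decode(seq)
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def write_fastq(reads: ReadSet, path1, path2) -> None:
    qual = "I" * reads.read_length
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i in range(reads.n_pairs):
            f1.write(f"@pair{i}/1\n{decode(reads.seq1[i])}\n+\n{qual}\n")
            f2.write(f"@pair{i}/2\n{decode(reads.seq2[i])}\n+\n{qual}\n")
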