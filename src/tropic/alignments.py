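"""Paired-alignment containers.

Two interchangeable sources feed the scanner and the depth calculator: a
coordinate-sorted BAM/SAM on disk (via pysam) and :class:`ReadAlignments`, a
compact in-memory struct-of-arrays used for simulated cohorts.  Both expose
the same information: per-pair positions, mapping qualities, and read
sequences (stored on the forward genome strand, as in SAM).
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pysam

from .motifs import decode, encode

__all__ = ["ReadAlignments", "open_alignments"]

_NON_AUTOSOMES = {"X", "Y", "M", "MT"}


def is_autosome(name: str) -> bool:
    return name.removeprefix("chr").upper() not in _NON_AUTOSOMES


@dataclasses.dataclass
class ReadAlignments:
    """Aligned read pairs for one sample, column-oriented.

    ``seq1``/``seq2`` are uint8 code matrices (reads x read_length) on the
    forward genome strand; ``rev1``/``rev2`` record which mate was sequenced
    from the reverse strand.  All pairs are primary alignments.
    """

    references: dict[str, int]                 # name -> length
    read_length: int
    chrom1: np.ndarray                         # index into reference names
    pos1: np.ndarray
    mapq1: np.ndarray
    seq1: np.ndarray
    chrom2: np.ndarray
    pos2: np.ndarray
    mapq2: np.ndarray
    seq2: np.ndarray
    rev1: np.ndarray | None = None
    rev2: np.ndarray | None = None

    def __post_init__(self):
        n = self.n_pairs
        if self.rev1 is None:
            self.rev1 = np.zeros(n, dtype=bool)
        if self.rev2 is None:
            self.rev2 = np.ones(n, dtype=bool)
        self._starts_cache: dict[str, np.ndarray] = {}

    @property
    def n_pairs(self) -> int:
        return len(self.pos1)

    @property
    def reference_names(self) -> list[str]:
        return list(self.references)

    # ---- depth ----------------------------------------------------------

    def _starts(self, chrom: str) -> np.ndarray:
        """Sorted start positions of all mates mapped to ``chrom``."""
        cached = self._starts_cache.get(chrom)
        if cached is not None:
            return cached
        names = self.reference_names
        if chrom not in self.references:
            raise KeyError(f"chromosome {chrom!r} absent from alignments")
        cid = names.index(chrom)
        starts = np.concatenate(
            [self.pos1[self.chrom1 == cid], self.pos2[self.chrom2 == cid]]
        )
        starts.sort()
        self._starts_cache[chrom] = starts
        return starts

    def coverage(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base aligned coverage over [start, end), pileup semantics."""
        if end <= start:
            raise ValueError("empty window")
        L = self.read_length
        starts = self._starts(chrom)
        lo = np.searchsorted(starts, start - L, side="left")
        hi = np.searchsorted(starts, end, side="left")
        s = starts[lo:hi]
        overlap = np.minimum(end, s + L) - np.maximum(start, s)
        total = int(overlap[overlap > 0].sum())
        return total / (end - start)

    def aligned_bases(self, chrom_names=None) -> int:
        if chrom_names is None:
            chrom_names = self.reference_names
        wanted = {self.reference_names.index(c) for c in chrom_names}
        n = 0
        for cid in wanted:
            n += int(np.count_nonzero(self.chrom1 == cid))
            n += int(np.count_nonzero(self.chrom2 == cid))
        return n * self.read_length

    # ---- subsetting -----------------------------------------------------

    def subset(self, mask: np.ndarray) -> "ReadAlignments":
        """New container keeping pairs where ``mask`` is True (mates together)."""
        return ReadAlignments(
            references=dict(self.references),
            read_length=self.read_length,
            chrom1=self.chrom1[mask], pos1=self.pos1[mask],
            mapq1=self.mapq1[mask], seq1=self.seq1[mask],
            chrom2=self.chrom2[mask], pos2=self.pos2[mask],
            mapq2=self.mapq2[mask], seq2=self.seq2[mask],
            rev1=self.rev1[mask], rev2=self.rev2[mask],
        )

    # ---- BAM bridge -----------------------------------------------------

    def to_bam(self, path: str | os.PathLike) -> str:
        """Write a coordinate-sorted, indexed BAM."""
        path = str(path)
        names = self.reference_names
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": self.references[n]} for n in names],
        }
        tmp = path + ".unsorted.bam"
        L = self.read_length
        cigar = [(0, L)]
        with pysam.AlignmentFile(tmp, "wb", header=header) as out:
            for i in range(self.n_pairs):
                for mate in (0, 1):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"p{i}"
                    this_c, this_p, this_q, this_s, this_r = (
                        (self.chrom1, self.pos1, self.mapq1, self.seq1, self.rev1)
                        if mate == 0
                        else (self.chrom2, self.pos2, self.mapq2, self.seq2, self.rev2)
                    )
                    other_c, other_p, other_r = (
                        (self.chrom2, self.pos2, self.rev2)
                        if mate == 0
                        else (self.chrom1, self.pos1, self.rev1)
                    )
                    a.reference_id = int(this_c[i])
                    a.reference_start = int(this_p[i])
                    a.mapping_quality = int(this_q[i])
                    a.query_sequence = decode(this_s[i])
                    a.cigartuples = cigar
                    a.next_reference_id = int(other_c[i])
                    a.next_reference_start = int(other_p[i])
                    a.is_paired = True
                    a.is_proper_pair = True
                    a.is_read1 = mate == 0
                    a.is_read2 = mate == 1
                    a.is_reverse = bool(this_r[i])
                    a.mate_is_reverse = bool(other_r[i])
                    tlen = int(max(other_p[i], this_p[i]) + L - min(other_p[i], this_p[i]))
                    a.template_length = tlen if this_p[i] <= other_p[i] else -tlen
                    out.write(a)
        pysam.sort("-o", path, tmp)
        os.unlink(tmp)
        pysam.index(path)
        return path

    @classmethod
    def from_bam(cls, path: str | os.PathLike) -> "ReadAlignments":
        """Load all primary paired records from a coordinate-sorted BAM/SAM.

        Raises ``ValueError`` on unsorted input or unpaired primary reads.
        """
        path = str(path)
        mode = "r" if path.endswith(".sam") else "rb"
        with pysam.AlignmentFile(path, mode) as af:
            so = (af.header.to_dict().get("HD") or {}).get("SO")
            if so != "coordinate":
                raise ValueError(f"{path}: input must be coordinate-sorted (SO={so})")
            references = dict(zip(af.references, af.lengths))
            name_to_id = {n: i for i, n in enumerate(af.references)}
            pending: dict[str, tuple] = {}
            pairs = []
            last = (-1, -1)
            for rec in af:
                if rec.is_secondary or rec.is_supplementary or rec.is_unmapped or rec.is_duplicate:
                    continue
                key = (rec.reference_id, rec.reference_start)
                if key < last:
                    raise ValueError(f"{path}: records out of coordinate order")
                last = key
                entry = (
                    name_to_id[rec.reference_name],
                    rec.reference_start,
                    rec.mapping_quality,
                    rec.query_sequence,
                    rec.is_reverse,
                    rec.is_read2,
                )
                mate = pending.pop(rec.query_name, None)
                if mate is None:
                    pending[rec.query_name] = entry
                else:
                    first, second = (mate, entry) if not mate[5] else (entry, mate)
                    pairs.append((first, second))
            if pending:
                some = sorted(pending)[:3]
                raise ValueError(f"{path}: unpaired primary reads (e.g. {some})")
        if not pairs:
            raise ValueError(f"{path}: no aligned read pairs")
        lengths = {len(p[0][3]) for p in pairs} | {len(p[1][3]) for p in pairs}
        if len(lengths) != 1:
            raise ValueError(f"{path}: mixed read lengths {sorted(lengths)} unsupported")
        L = lengths.pop()
        n = len(pairs)
        out = cls(
            references=references,
            read_length=L,
            chrom1=np.fromiter((p[0][0] for p in pairs), dtype=np.int32, count=n),
            pos1=np.fromiter((p[0][1] for p in pairs), dtype=np.int64, count=n),
            mapq1=np.fromiter((p[0][2] for p in pairs), dtype=np.int16, count=n),
            seq1=np.vstack([encode(p[0][3]) for p in pairs]),
            chrom2=np.fromiter((p[1][0] for p in pairs), dtype=np.int32, count=n),
            pos2=np.fromiter((p[1][1] for p in pairs), dtype=np.int64, count=n),
            mapq2=np.fromiter((p[1][2] for p in pairs), dtype=np.int16, count=n),
            seq2=np.vstack([encode(p[1][3]) for p in pairs]),
            rev1=np.fromiter((p[0][4] for p in pairs), dtype=bool, count=n),
            rev2=np.fromiter((p[1][4] for p in pairs), dtype=bool, count=n),
        )
        return out


def open_alignments(source) -> ReadAlignments:
    """Accept a ReadAlignments object or a BAM/SAM path."""
    if isinstance(source, ReadAlignments):
        return source
    if isinstance(source, (str, Path)):
        return ReadAlignments.from_bam(source)
    raise TypeError(f"unsupported alignment source: {type(source)!r}")
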