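"""Local read-depth normalization.

Chromosomal amplification inflates anchored-IRR counts the same way it
inflates every other read near a locus, and so mimics a repeat expansion
after global depth normalization.  Dividing the raw count by the mean
aligned coverage in a window around the locus cancels that inflation: a
truly expanded repeat keeps its tumour-vs-normal excess, an amplified one
flattens out.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .alignments import open_alignments
from .motifs import TandemRepeatLocus

__all__ = ["LocusDepth", "local_depth", "local_normalize", "cohort_local_depths"]


@dataclasses.dataclass(frozen=True)
class LocusDepth:
    """Mean per-base coverage around one locus for one sample."""

    locus: TandemRepeatLocus
    sample_id: str
    window: tuple[int, int]
    local_depth: float


def local_depth(source, locus: TandemRepeatLocus, flank: int = 250,
                sample_id: str = "") -> LocusDepth:
    """Mean aligned coverage over the locus plus ``flank`` bp on each side.

    The window is [start - flank, end + flank) clipped to the chromosome;
    with the default flank of 250 bp it adds a 500-bp region around the
    repeat's start and stop positions.  Coverage counts every aligned
    primary read regardless of MAPQ (amplification inflates low-MAPQ
    in-repeat mates too).
    """
    aln = open_alignments(source)
    if locus.chrom not in aln.references:
        raise KeyError(f"chromosome {locus.chrom!r} absent from alignments")
    chrom_len = aln.references[locus.chrom]
    lo = max(0, locus.start - flank)
    hi = min(chrom_len, locus.end + flank)
    depth = aln.coverage(locus.chrom, lo, hi)
    return LocusDepth(locus, sample_id, (lo, hi), depth)


def local_normalize(raw_air, depth: float) -> float:
    """Raw anchored-IRR count divided by local depth.

    A zero or negative depth leaves the value undefined; callers must flag
    the locus rather than coerce it to zero, so this raises.
    """
    if depth <= 0 or math.isnan(depth):
        raise ValueError("local depth is zero/undefined; locus must be flagged")
    return float(raw_air) / depth


def cohort_local_depths(
    sources: dict[str, object],
    loci: list[TandemRepeatLocus],
    flank: int = 250,
) -> pd.DataFrame:
    """Local depth for every (locus, sample); rows locus_id, columns sample_id.

    Missing chromosomes yield NaN (flagged downstream), never silent zeros.
    """
    table = pd.DataFrame(
        np.nan, index=[l.locus_id for l in loci], columns=list(sources)
    )
    for sid, src in sources.items():
        aln = open_alignments(src)
        for locus in loci:
            try:
                table.loc[locus.locus_id, sid] = local_depth(
                    aln, locus, flank=flank, sample_id=sid
                ).local_depth
            except KeyError:
                pass
    return table
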