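"""Anchored in-repeat-read profiling.

A read pair votes for a nearby repeat expansion when one mate maps
confidently (the *anchor*, MAPQ >= 50 by default) while the other mate is an
in-repeat read: it maps nowhere specific (MAPQ <= 40) and its sequence is
near-pure tandem copies of one motif.  Per-sample event lists are clustered
into candidate tandem-repeat loci, and raw per-locus counts are normalized to
a common global sequencing depth (Anchored IRR values, "AIR").
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .alignments import ReadAlignments, is_autosome, open_alignments
from .motifs import Motif, TandemRepeatLocus, decode, detect_irr, periodic_read_mask

__all__ = [
    "AnchoredIrrEvent",
    "SampleProfile",
    "scan_alignments",
    "cluster_events",
    "global_normalize",
]


@dataclasses.dataclass(frozen=True)
class AnchoredIrrEvent:
    """One anchored in-repeat read pair, positioned at the anchor mate."""

    sample_id: str
    chrom: str
    anchor_pos: int
    anchor_mapq: int
    motif: Motif


@dataclasses.dataclass
class SampleProfile:
    """A sample's anchored-IRR events plus its global depth summary."""

    sample_id: str
    role: str                       # "tumour" | "normal"
    pair_id: str
    read_length: int
    global_depth: float
    events: list[AnchoredIrrEvent]

    def __post_init__(self):
        if self.role not in ("tumour", "normal"):
            raise ValueError(f"role must be tumour|normal: {self.role!r}")
        if self.global_depth <= 0:
            raise ValueError("global_depth must be positive")


def scan_alignments(
    source,
    sample_id: str,
    role: str = "tumour",
    pair_id: str = "",
    min_anchor_mapq: int = 50,
    max_irr_mapq: int = 40,
    min_purity: float = 0.9,
) -> SampleProfile:
    """Collect anchored IRR events from one sample's paired alignments.

    ``source`` is a coordinate-sorted BAM/SAM path or a
    :class:`~tropic.alignments.ReadAlignments`.  One event is emitted per
    pair in which exactly one mate has MAPQ <= ``max_irr_mapq`` and passes
    the in-repeat-read classifier while the other has MAPQ >=
    ``min_anchor_mapq``.  Global depth is total aligned autosomal bases over
    autosomal genome length (all references if none look autosomal).
    """
    aln = open_alignments(source)
    names = aln.reference_names
    autosomes = [n for n in names if is_autosome(n)] or names
    genome_len = sum(aln.references[n] for n in autosomes)
    depth = aln.aligned_bases(autosomes) / genome_len
    if depth <= 0:
        raise ValueError(f"{sample_id}: no aligned bases, cannot estimate depth")

    anchor1 = (aln.mapq1 >= min_anchor_mapq) & (aln.mapq2 <= max_irr_mapq)
    anchor2 = (aln.mapq2 >= min_anchor_mapq) & (aln.mapq1 <= max_irr_mapq)

    events: list[AnchoredIrrEvent] = []
    for anchor_is_1 in (True, False):
        cand = np.flatnonzero(anchor1 if anchor_is_1 else anchor2)
        if cand.size == 0:
            continue
        irr_seqs = (aln.seq2 if anchor_is_1 else aln.seq1)[cand]
        # cheap periodicity screen first, full classification after
        screened = cand[periodic_read_mask(irr_seqs, min_purity)]
        for i in screened:
            seq = decode((aln.seq2 if anchor_is_1 else aln.seq1)[i])
            is_irr, motif = detect_irr(seq, min_purity=min_purity)
            if not is_irr:
                continue
            if anchor_is_1:
                chrom, pos, mapq = names[aln.chrom1[i]], aln.pos1[i], aln.mapq1[i]
            else:
                chrom, pos, mapq = names[aln.chrom2[i]], aln.pos2[i], aln.mapq2[i]
            events.append(
                AnchoredIrrEvent(sample_id, chrom, int(pos), int(mapq), motif)
            )
    events.sort(key=lambda e: (e.chrom, e.anchor_pos, e.motif.sequence))
    return SampleProfile(
        sample_id=sample_id,
        role=role,
        pair_id=pair_id or sample_id,
        read_length=aln.read_length,
        global_depth=depth,
        events=events,
    )


def cluster_events(
    profiles: list[SampleProfile],
    merge_distance: int = 500,
) -> tuple[list[TandemRepeatLocus], pd.DataFrame]:
    """Merge same-motif events within ``merge_distance`` into candidate loci.

    Events sharing chromosome and canonical motif are single-linkage merged
    when consecutive anchor positions are within ``merge_distance``.  Each
    cluster becomes a locus spanning [min anchor, max anchor + read_length).

    Returns the locus catalogue and a raw-count table (rows: locus_id,
    columns: every profiled sample, absent counts filled with 0).
    """
    read_length = max((p.read_length for p in profiles), default=100)
    by_key: dict[tuple[str, Motif], list[tuple[int, str]]] = {}
    for prof in profiles:
        for ev in prof.events:
            by_key.setdefault((ev.chrom, ev.motif), []).append(
                (ev.anchor_pos, prof.sample_id)
            )
    sample_ids = [p.sample_id for p in profiles]
    loci: list[TandemRepeatLocus] = []
    rows: list[dict] = []
    for (chrom, motif), items in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].sequence)
    ):
        items.sort()
        cluster: list[tuple[int, str]] = []
        for item in items:
            if cluster and item[0] - cluster[-1][0] > merge_distance:
                loci.append(_finish_cluster(chrom, motif, cluster, read_length, rows))
                cluster = []
            cluster.append(item)
        if cluster:
            loci.append(_finish_cluster(chrom, motif, cluster, read_length, rows))
    counts = pd.DataFrame(
        0, index=[loc.locus_id for loc in loci], columns=sample_ids, dtype=int
    )
    for row in rows:
        counts.loc[row["locus_id"], row["sample_id"]] = row["count"]
    loci.sort(key=lambda l: (l.chrom, l.start, l.motif.sequence))
    counts = counts.loc[[l.locus_id for l in loci]]
    return loci, counts


def _finish_cluster(chrom, motif, cluster, read_length, rows) -> TandemRepeatLocus:
    positions = [p for p, _ in cluster]
    locus = TandemRepeatLocus(chrom, min(positions), max(positions) + read_length, motif)
    per_sample: dict[str, int] = {}
    for _, sid in cluster:
        per_sample[sid] = per_sample.get(sid, 0) + 1
    for sid, n in per_sample.items():
        rows.append({"locus_id": locus.locus_id, "sample_id": sid, "count": n})
    return locus


def global_normalize(raw_count, global_depth, target_depth: float = 40.0):
    """Scale a raw anchored-IRR count to a common global depth.

    AIR = raw x target_depth / global_depth.  The target depth cancels in
    every case-control comparison; it only sets the absolute scale.
    """
    depth = np.asarray(global_depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("global_depth must be positive")
    air = np.asarray(raw_count, dtype=float) * target_depth / depth
    return float(air) if air.ndim == 0 else air
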