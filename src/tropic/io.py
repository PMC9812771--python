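"""Tabular file formats used across the pipeline surface.

Everything is TSV with 0-based half-open coordinates; profiles carry their
sample metadata in leading ``#key=value`` comment lines so a profile file is
self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .motifs import Motif, TandemRepeatLocus
from .profiling import AnchoredIrrEvent, SampleProfile

LOCI_COLUMNS = ["chrom", "start", "end", "motif"]


def write_loci(loci: list[TandemRepeatLocus], path) -> None:
    pd.DataFrame(
        [
            {"chrom": l.chrom, "start": l.start, "end": l.end, "motif": str(l.motif)}
            for l in loci
        ],
        columns=LOCI_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_loci(path) -> list[TandemRepeatLocus]:
    df = pd.read_csv(path, sep="\t")
    return [
        TandemRepeatLocus(str(r.chrom), int(r.start), int(r.end), Motif(str(r.motif)))
        for r in df.itertuples()
    ]


def write_profile(profile: SampleProfile, path) -> None:
    with open(path, "w") as fh:
        for key in ("sample_id", "role", "pair_id", "read_length"):
            fh.write(f"#{key}={getattr(profile, key)}\n")
        fh.write(f"#global_depth={profile.global_depth!r}\n")
        fh.write("chrom\tanchor_pos\tanchor_mapq\tmotif\n")
        for ev in profile.events:
            fh.write(f"{ev.chrom}\t{ev.anchor_pos}\t{ev.anchor_mapq}\t{ev.motif}\n")


def read_profile(path) -> SampleProfile:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
        else:
            body_start = i
            break
    header = lines[body_start].rstrip("\n").split("\t")
    events = []
    for line in lines[body_start + 1 :]:
        if not line.strip():
            continue
        rec = dict(zip(header, line.rstrip("\n").split("\t")))
        events.append(
            AnchoredIrrEvent(
                sample_id=meta["sample_id"],
                chrom=rec["chrom"],
                anchor_pos=int(rec["anchor_pos"]),
                anchor_mapq=int(rec["anchor_mapq"]),
                motif=Motif(rec["motif"]),
            )
        )
    return SampleProfile(
        sample_id=meta["sample_id"],
        role=meta["role"],
        pair_id=meta["pair_id"],
        read_length=int(meta["read_length"]),
        global_depth=float(meta["global_depth"]),
        events=events,
    )


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("sample_id")


def write_counts(raw: pd.DataFrame, air: pd.DataFrame, path) -> None:
    long = (
        raw.rename_axis("locus_id")
        .reset_index()
        .melt(id_vars="locus_id", var_name="sample_id", value_name="raw")
    )
    long["air"] = (
        air.rename_axis("locus_id")
        .reset_index()
        .melt(id_vars="locus_id", var_name="sample_id", value_name="air")["air"]
    )
    long.to_csv(path, sep="\t", index=False)


def read_counts(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t")
    raw = long.pivot(index="locus_id", columns="sample_id", values="raw")
    air = long.pivot(index="locus_id", columns="sample_id", values="air")
    return raw, air


def file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
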