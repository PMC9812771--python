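"""End-to-end orchestration: scan -> cluster -> test -> refilter -> call.

One run is one cohort (one cancer type): a manifest of tumour-normal pairs,
one configuration, one output directory.  Configuration comes only from the
manifest/config objects, results only from files; reruns with the same
inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    CohortMatrix,
    TropicConfig,
    build_matrix,
    call_expansions,
    local_depth_refilter,
    prioritize,
)
from .depthnorm import cohort_local_depths
from .io import file_md5, write_counts, write_json, write_loci, write_samples
from .motifs import TandemRepeatLocus
from .popfreq import PopFreqConfig
from .profiling import cluster_events, scan_alignments

__all__ = ["RunManifest", "AnalysisResult", "load_manifest", "analyze_cohort", "run_pipeline"]

MANIFEST_COLUMNS = ["sample_id", "path", "role", "pair_id", "read_length"]


@dataclasses.dataclass
class RunManifest:
    """Sample table plus full configuration for one cohort run."""

    samples: pd.DataFrame            # index sample_id: path, role, pair_id, read_length
    tropic: TropicConfig = dataclasses.field(default_factory=TropicConfig)
    pop: PopFreqConfig = dataclasses.field(default_factory=PopFreqConfig)
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        """Enumerate every manifest problem before any computation."""
        errors = []
        df = self.samples
        for col in ("path", "role", "pair_id"):
            if col not in df.columns:
                errors.append(f"manifest missing column {col!r}")
        if not errors:
            bad_roles = df.index[~df["role"].isin(["tumour", "normal"])].tolist()
            for sid in bad_roles:
                errors.append(f"{sid}: role must be tumour|normal")
            tum = df[df["role"] == "tumour"]
            nor = df[df["role"] == "normal"]
            for pid, grp in df.groupby("pair_id"):
                roles = sorted(grp["role"])
                if roles != ["normal", "tumour"]:
                    errors.append(f"pair {pid!r}: needs one tumour and one normal, has {roles}")
            if len(tum) < 2:
                errors.append("cohort must contain at least 2 tumour-normal pairs")
            if check_paths:
                for sid, row in df.iterrows():
                    if not Path(str(row["path"])).exists():
                        errors.append(f"{sid}: path {row['path']} does not exist")
        if errors:
            raise ValueError("invalid manifest:\n  " + "\n  ".join(errors))


def load_manifest(path, tropic: TropicConfig | None = None,
                  pop: PopFreqConfig | None = None, seed: int = 0) -> RunManifest:
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    return RunManifest(
        samples=df,
        tropic=tropic or TropicConfig(),
        pop=pop or PopFreqConfig(),
        seed=seed,
    )


@dataclasses.dataclass
class AnalysisResult:
    matrix: CohortMatrix
    results: pd.DataFrame
    calls: pd.DataFrame
    local_depths: pd.DataFrame
    loci: list[TandemRepeatLocus]


def analyze_cohort(
    sources: dict[str, object],
    samples: pd.DataFrame,
    config: TropicConfig | None = None,
) -> AnalysisResult:
    """Run the full cascade over in-memory or on-disk alignments.

    ``sources`` maps sample_id to a BAM path or ReadAlignments;``samples``
    carries role and pair_id per sample_id.  Local depths are computed only
    for the loci that reach the refilter.
    """
    config = config or TropicConfig()
    profiles = [
        scan_alignments(
            sources[sid],
            sample_id=sid,
            role=row["role"],
            pair_id=row["pair_id"],
            min_anchor_mapq=config.min_anchor_mapq,
            max_irr_mapq=config.max_irr_mapq,
            min_purity=config.min_purity,
        )
        for sid, row in samples.iterrows()
    ]
    loci, counts = cluster_events(profiles, merge_distance=config.merge_distance)
    matrix = build_matrix(loci, counts, profiles, target_depth=config.target_depth)
    results = prioritize(matrix, config)

    cand_ids = results.index[results["status"] == "somatic_rre"]
    cand_loci = [l for l in loci if l.locus_id in set(cand_ids)]
    local_depths = cohort_local_depths(sources, cand_loci, flank=config.flank)
    matrix.local_depth = local_depths
    results = local_depth_refilter(results, matrix, local_depths, config)

    final = results.index[results["status"] == "rre"]
    calls = (
        pd.concat(
            [call_expansions(matrix, lid, config.aiq_threshold) for lid in final],
            ignore_index=True,
        )
        if len(final)
        else pd.DataFrame(
            columns=["pair_id", "locus_id", "tumour_air", "normal_air", "aiq", "called"]
        )
    )
    return AnalysisResult(
        matrix=matrix, results=results, calls=calls,
        local_depths=local_depths, loci=loci,
    )


def run_pipeline(manifest: RunManifest, outdir) -> dict[str, str]:
    """Execute a manifest and write the result bundle.

    Outputs: loci.tsv, samples.tsv, counts.tsv, results.tsv, calls.tsv,
    local_depth.tsv and run_metadata.json (config echo, seed, input
    checksums) -- enough to reproduce the run byte for byte.
    """
    manifest.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sources = {sid: str(row["path"]) for sid, row in manifest.samples.iterrows()}
    res = analyze_cohort(sources, manifest.samples, manifest.tropic)

    paths = {name: str(outdir / f"{name}.tsv") for name in
             ("loci", "samples", "counts", "results", "calls", "local_depth")}
    write_loci(res.loci, paths["loci"])
    write_samples(res.matrix.samples, paths["samples"])
    write_counts(res.matrix.raw, res.matrix.air, paths["counts"])
    res.results.rename_axis("locus_id").reset_index().to_csv(
        paths["results"], sep="\t", index=False
    )
    res.calls.to_csv(paths["calls"], sep="\t", index=False)
    res.local_depths.rename_axis("locus_id").reset_index().to_csv(
        paths["local_depth"], sep="\t", index=False
    )
    meta = {
        "version": __version__,
        "seed": manifest.seed,
        "tropic_config": {
            k: (sorted(v) if isinstance(v, frozenset) else v)
            for k, v in dataclasses.asdict(manifest.tropic).items()
        },
        "popfreq_config": dataclasses.asdict(manifest.pop),
        "inputs": {
            sid: {"path": str(row["path"]), "md5": file_md5(str(row["path"]))}
            for sid, row in manifest.samples.iterrows()
        },
    }
    meta_path = str(outdir / "run_metadata.json")
    write_json(meta, meta_path)
    paths["run_metadata"] = meta_path
    return paths
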