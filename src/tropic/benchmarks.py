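"""Reduced-scale in-silico benchmarks for the discovery pipeline.

Each function builds a synthetic study with :mod:`tropic.sim`, runs the
pipeline, and returns the measured quantities.  The designs are fixed study
conditions (documented in docs/methods.md), sized so a laptop CPU runs each
benchmark in minutes:

* ``run_standard_fixture`` -- parameter recovery: 20 tumour-normal pairs,
  10 tandem repeats of which 3 are somatically expanded to 2.5x read length
  at 30% carrier frequency, 30x coverage.
* ``copy_number_sweep`` -- a germline-long repeat amplified from 2 to 10
  copies on a 1-Mb chromosome: global AIR inflates with copy number, locally
  normalized AIR stays flat.
* ``amplification_refilter`` -- a cohort whose tumours carry both an 8-copy
  amplification of a germline-long repeat (a copy-number artefact) and a
  true somatic expansion; the local-depth refilter must remove the former
  and keep the latter.
* ``downsampling_benchmark`` -- marginal expansions (just past read length,
  on a germline-long background) across replicate loci; the median
  BH-corrected p is significant at 30x and lost at 10x.
* ``population_calibration`` -- the 99th-percentile population-calling rule
  flags ~1% of samples drawn from the reference distribution itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import TropicConfig, aiq, theoretical_air_cap
from .depthnorm import local_depth
from .motifs import TandemRepeatLocus, canonical_motif
from .pipeline import analyze_cohort
from .popfreq import PopFreqConfig, population_frequency
from .profiling import global_normalize, scan_alignments
from .sim import (
    RepeatSpec,
    SimulationConfig,
    downsample,
    merge_reads,
    oracle_align,
    random_reference,
    simulate_amplification,
    simulate_cohort,
    simulate_reads,
)

__all__ = [
    "STANDARD_FIXTURE_SEED",
    "standard_reference",
    "run_standard_fixture",
    "copy_number_sweep",
    "amplification_refilter",
    "downsampling_benchmark",
    "population_calibration",
]

# Fixture seed chosen from the truth table alone: the exact tie-structure
# rank-sum bound C(20,k)/C(40,k) exceeds 0.05 for k < 5 carriers, so the
# fixture requires >= 5 carriers at every designated locus; seed 5 is the
# first satisfying that under the 30% binomial carrier draw.
STANDARD_FIXTURE_SEED = 5

_STANDARD_REPEATS = [
    RepeatSpec("GAAA", 12, 63),   # expanded to 252 bp
    RepeatSpec("AAAT", 12, None),
    RepeatSpec("AT", 24, 126),    # expanded to 252 bp
    RepeatSpec("AC", 24, None),
    RepeatSpec("AGG", 16, None),
    RepeatSpec("AGC", 16, 84),    # expanded to 252 bp
    RepeatSpec("AATG", 12, None),
    RepeatSpec("CCG", 16, None),
    RepeatSpec("AAG", 16, None),
    RepeatSpec("ATCC", 12, None),
]


def simulation_cap(config: SimulationConfig) -> float:
    """The AIR-cap value consistent with the simulator's fragment geometry."""
    return theoretical_air_cap(config.read_length, config.fragment_mean)


def standard_reference(seed: int = 11):
    """120-kb reference with ten tandem repeats (three designated expansions)."""
    return random_reference(120_000, _STANDARD_REPEATS, seed=seed)


def _match_results_to_truth(results: pd.DataFrame, truth: pd.DataFrame) -> dict[int, list[str]]:
    """Map designated truth loci to overlapping same-motif result rows."""
    matches: dict[int, list[str]] = {}
    for idx, row in truth[truth["expanded_copies"].notna()].iterrows():
        want = canonical_motif(row["motif"]).sequence
        hit = results[
            (results["chrom"] == row["chrom"])
            & (results["motif"] == want)
            & (results["start"] < int(row["end"]) + 1000)
            & (results["end"] > int(row["start"]) - 1000)
        ]
        matches[idx] = list(hit.index)
    return matches


def run_standard_fixture(seed: int = STANDARD_FIXTURE_SEED) -> dict:
    """Parameter-recovery benchmark: full cascade on the standard fixture."""
    genome = standard_reference()
    config = SimulationConfig(
        seed=seed, read_length=100, coverage=30.0, carrier_frequency=0.3, n_pairs=20
    )
    cohort = simulate_cohort(genome, config)
    tconfig = TropicConfig(air_cap=simulation_cap(config))
    analysis = analyze_cohort(cohort.alignments, cohort.samples, tconfig)
    results = analysis.results

    matches = _match_results_to_truth(results, genome.truth)
    recovered = {
        idx: ids
        for idx, ids in matches.items()
        if any(results.loc[i, "status"] == "rre" for i in ids)
    }
    truth_ids = {i for ids in matches.values() for i in ids}
    false_pos = [
        i for i in results.index
        if results.loc[i, "status"] == "rre" and i not in truth_ids
    ]
    # per-pair AIQ call sensitivity on truth carriers
    n_carrier = n_called = 0
    calls = analysis.calls
    for idx, ids in matches.items():
        rre_ids = [i for i in ids if results.loc[i, "status"] == "rre"]
        tp = cohort.truth_pairs
        carriers = tp.loc[(tp["locus_index"] == idx) & tp["carrier"], "pair_id"]
        for pid in carriers:
            n_carrier += 1
            hit = calls[
                calls["locus_id"].isin(rre_ids)
                & (calls["pair_id"] == pid)
                & calls["called"]
            ]
            n_called += int(len(hit) > 0)
    qvals = {
        idx: float(results.loc[ids, "q"].min()) if ids else float("nan")
        for idx, ids in matches.items()
    }
    return {
        "genome": genome,
        "cohort": cohort,
        "analysis": analysis,
        "matches": matches,
        "n_truth": int(genome.truth["expanded_copies"].notna().sum()),
        "n_recovered": len(recovered),
        "false_positives": false_pos,
        "truth_q": qvals,
        "call_sensitivity": (n_called / n_carrier) if n_carrier else float("nan"),
    }


def copy_number_sweep(
    seed: int,
    length: int = 1_000_000,
    copy_numbers: tuple[int, ...] = tuple(range(2, 11)),
) -> pd.DataFrame:
    """Amplify a germline-long repeat from 2 to 10 copies on one chromosome.

    The chromosome carries a 400-bp germline GAAA tract (locus 0, longer than
    the read length in every genome: a copy-number false-positive source)
    and a somatically expanded 252-bp AGC tract (locus 1).  As in the
    benchmark's design, one base read set is shared by all copy numbers and
    per-copy-number amplification reads are added on top.  Returns per-CN
    raw counts, globally and locally normalized AIR at the amplified locus.
    """
    ss = np.random.SeedSequence(seed).spawn(2 + len(copy_numbers))
    genome = random_reference(
        length,
        [RepeatSpec("GAAA", 100, None), RepeatSpec("AGC", 16, 84)],
        seed=int(ss[0].generate_state(1)[0] % (2**31)),
    )
    config = SimulationConfig(seed=seed, read_length=100, coverage=30.0, n_pairs=2)
    base = simulate_reads(genome, config, rng=np.random.default_rng(ss[1]))
    base_aln = oracle_align(base, genome)
    locus = TandemRepeatLocus(
        "chr1", int(genome.truth.loc[0, "start"]), int(genome.truth.loc[0, "end"]),
        canonical_motif("GAAA"),
    )
    rows = []
    for cn, child in zip(copy_numbers, ss[2:]):
        extra = simulate_amplification(
            genome, [0], cn, config, rng=np.random.default_rng(child)
        )
        if extra.n_pairs:
            aln = oracle_align(merge_reads(base, extra), genome)
        else:
            aln = base_aln
        prof = scan_alignments(aln, f"cn{cn}", role="tumour", pair_id=f"cn{cn}")
        raw = sum(
            1 for e in prof.events
            if e.motif == locus.motif and abs(e.anchor_pos - locus.start) < 1500
        )
        ld = local_depth(aln, locus).local_depth
        rows.append(
            {
                "copy_number": cn,
                "raw": raw,
                "global_air": global_normalize(raw, prof.global_depth),
                "local_depth": ld,
                "local_air": raw / ld,
            }
        )
    return pd.DataFrame(rows)


def amplification_refilter(seed: int, length: int = 120_000, n_pairs: int = 9) -> dict:
    """Cohort where every tumour has an 8-copy amplification artefact plus a
    true expansion; returns the final status of both loci."""
    genome = random_reference(
        length,
        [RepeatSpec("GAAA", 30, None), RepeatSpec("AGC", 16, 84)],
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
    )
    config = SimulationConfig(
        seed=seed, read_length=100, coverage=30.0, carrier_frequency=1.0, n_pairs=n_pairs
    )
    amplification = {f"P{i:02d}": (0, 8) for i in range(n_pairs)}
    cohort = simulate_cohort(genome, config, amplification=amplification)
    tconfig = TropicConfig(air_cap=simulation_cap(config))
    analysis = analyze_cohort(cohort.alignments, cohort.samples, tconfig)
    results = analysis.results

    def status_of(truth_idx: int) -> str:
        row = genome.truth.loc[truth_idx]
        want = canonical_motif(row["motif"]).sequence
        hit = results[
            (results["motif"] == want)
            & (results["start"] < int(row["end"]) + 1000)
            & (results["end"] > int(row["start"]) - 1000)
        ]
        return str(hit["status"].iloc[0]) if len(hit) else "absent"

    return {
        "analysis": analysis,
        "amplified_status": status_of(0),
        "expanded_status": status_of(1),
    }


def downsampling_benchmark(
    seed: int, n_loci: int = 49, n_pairs: int = 20, fraction: float = 1 / 3
) -> dict:
    """Marginal expansions under coverage loss.

    Each of ``n_loci`` replicate repeats is germline-long (112 bp GAAA, so
    normals carry background anchored IRRs) and somatically expanded to
    140 bp in half the tumours.  The same cohort is analysed at full 30x
    coverage and after binomial pair downsampling to 10x; the summary
    statistic is the median BH-corrected p over the designated loci (absent
    loci count as q = 1).
    """
    genome = random_reference(
        4000 * n_loci,
        [RepeatSpec("GAAA", 28, 35) for _ in range(n_loci)],
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
    )
    config = SimulationConfig(
        seed=seed, read_length=100, coverage=30.0, carrier_frequency=0.5,
        n_pairs=n_pairs,
    )
    cohort = simulate_cohort(genome, config)
    tconfig = TropicConfig(air_cap=simulation_cap(config))

    def median_q(alignments) -> float:
        analysis = analyze_cohort(alignments, cohort.samples, tconfig)
        matches = _match_results_to_truth(analysis.results, genome.truth)
        qs = []
        for ids in matches.values():
            qs.append(
                float(analysis.results.loc[ids, "q"].min()) if ids else 1.0
            )
        return float(np.median(qs))

    q30 = median_q(cohort.alignments)
    ds_seeds = np.random.SeedSequence(seed + 1).generate_state(len(cohort.alignments))
    downsampled = {
        sid: downsample(aln, fraction, int(s % (2**31)))
        for (sid, aln), s in zip(cohort.alignments.items(), ds_seeds)
    }
    q10 = median_q(downsampled)
    return {"median_q_30x": q30, "median_q_10x": q10}


def population_calibration(
    seed: int, n_population: int = 10_000, n_reference: int = 50_000
) -> float:
    """Fraction of population samples called expanded when the population is
    drawn from the reference-normal AIR distribution itself (expect ~1%)."""
    rng = np.random.default_rng(seed)
    reference = rng.lognormal(mean=-0.5, sigma=1.0, size=n_reference)
    population = rng.lognormal(mean=-0.5, sigma=1.0, size=n_population)
    return population_frequency(population, reference, PopFreqConfig())
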