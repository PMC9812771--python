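"""The TROPIC prioritization cascade.

Case-control discovery of recurrent repeat expansions from a loci x samples
table of anchored-IRR values: structural filters (chromosome set, value cap),
a one-sided Wilcoxon rank-sum test per locus with Benjamini-Hochberg FDR,
per-pair calling through the Anchored IRR quotient
AIQ = (tumour - normal) / (normal + 1), and a second-pass refilter on locally
depth-normalized values that strips copy-number artefacts.

All threshold comparisons are strict (>, <), so boundary values (AIQ exactly
2.5, a cap fraction of exactly 10%) fall on the conservative side.
"""

from __future__ import annotations

import dataclasses
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import TandemRepeatLocus
from .profiling import SampleProfile, global_normalize

__all__ = [
    "TropicConfig",
    "CohortMatrix",
    "build_matrix",
    "cap_filter",
    "rank_sum_test",
    "bh_fdr",
    "aiq",
    "aiq_frequency",
    "call_expansions",
    "prioritize",
    "local_depth_refilter",
    "theoretical_air_cap",
]

ALLOWED_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


@dataclasses.dataclass
class TropicConfig:
    """Every threshold of the cascade, defaults as printed for the method."""

    min_anchor_mapq: int = 50
    max_irr_mapq: int = 40
    min_purity: float = 0.9
    target_depth: float = 40.0
    air_cap: float = 40.0
    air_cap_fraction: float = 0.10
    fdr_candidate: float = 0.10
    fdr_somatic: float = 0.05
    aiq_threshold: float = 2.5
    frequency_threshold: float = 0.05
    merge_distance: int = 500
    flank: int = 250
    allowed_chromosomes: frozenset = ALLOWED_CHROMOSOMES

    def __post_init__(self):
        if self.fdr_somatic > self.fdr_candidate:
            raise ValueError("fdr_somatic must be <= fdr_candidate")
        for name in ("air_cap", "air_cap_fraction", "fdr_candidate", "fdr_somatic",
                     "aiq_threshold", "frequency_threshold", "merge_distance", "flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def theoretical_air_cap(read_length: int, fragment_mean: float,
                        target_depth: float = 40.0) -> float:
    """Theoretical maximum of the normalized AIR statistic for a geometry.

    For a repeat much longer than a fragment, anchored pairs arise from
    fragments with one mate fully inside the tract and the other fully
    outside; their start positions occupy (fragment - 2 x read_length) bp per
    flank and orientation, giving at most
    (fragment - 2 x read_length) / read_length x target_depth after global
    normalization.  Values above this are artefacts and are what the cap
    filter removes; the printed default cap of 40 corresponds to a ~300 bp
    fragment at 100-bp reads.
    """
    width = fragment_mean - 2 * read_length
    if width <= 0:
        raise ValueError("fragment_mean must exceed twice the read length")
    return width / read_length * target_depth


@dataclasses.dataclass
class CohortMatrix:
    """Loci x samples anchored-IRR values with tumour/normal pairing."""

    loci: list[TandemRepeatLocus]
    raw: pd.DataFrame                       # loci x samples, integer counts
    air: pd.DataFrame                       # globally normalized values
    samples: pd.DataFrame                   # index sample_id: role, pair_id, global_depth
    local_depth: pd.DataFrame | None = None

    def __post_init__(self):
        roles = self.samples["role"]
        tum = self.samples[roles == "tumour"]
        nor = self.samples[roles == "normal"]
        if sorted(tum["pair_id"]) != sorted(set(tum["pair_id"])) or set(
            tum["pair_id"]
        ) != set(nor["pair_id"]) or len(nor) != len(tum):
            raise ValueError("every tumour must have exactly one paired normal")

    @property
    def pairs(self) -> list[tuple[str, str, str]]:
        """(pair_id, tumour sample_id, normal sample_id), sorted by pair_id."""
        roles = self.samples["role"]
        t = {r["pair_id"]: sid for sid, r in self.samples[roles == "tumour"].iterrows()}
        n = {r["pair_id"]: sid for sid, r in self.samples[roles == "normal"].iterrows()}
        return [(p, t[p], n[p]) for p in sorted(t)]

    def locus(self, locus_id: str) -> TandemRepeatLocus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)


def build_matrix(
    loci: list[TandemRepeatLocus],
    counts: pd.DataFrame,
    profiles: list[SampleProfile],
    target_depth: float = 40.0,
) -> CohortMatrix:
    """Assemble the cohort matrix from clustered counts and sample profiles."""
    samples = pd.DataFrame(
        {
            "role": [p.role for p in profiles],
            "pair_id": [p.pair_id for p in profiles],
            "global_depth": [p.global_depth for p in profiles],
            "read_length": [p.read_length for p in profiles],
        },
        index=[p.sample_id for p in profiles],
    )
    depths = samples.loc[counts.columns, "global_depth"].to_numpy()
    air = counts.astype(float) * target_depth / depths
    return CohortMatrix(loci=loci, raw=counts, air=air, samples=samples)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def rank_sum_test(tumour_values, normal_values, alternative: str = "greater") -> float:
    """One-sided Wilcoxon rank-sum p-value, P(rank sum >= observed).

    Exact (full enumeration of group assignments, ties handled through
    midranks) when both groups have <= 12 values; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(tumour_values, dtype=float)
    y = np.asarray(normal_values, dtype=float)
    if alternative != "greater":
        x, y = y, x
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    if x.size <= 12 and y.size <= 12:
        return _exact_rank_sum(x, y)
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def _exact_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Exact null distribution of the rank sum by subset-sum counting.

    Midranks are doubled to integers; dp[c, s] counts size-c subsets of the
    pooled doubled ranks with sum s, enumerating all C(N, nx) group
    assignments implicitly.
    """
    nx = x.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    r2 = np.rint(2 * ranks).astype(np.int64)
    w_obs = int(np.rint(ranks[:nx].sum() * 2))
    total = int(r2.sum())
    dp = np.zeros((nx + 1, total + 1))
    dp[0, 0] = 1.0
    for v in r2:
        for c in range(nx, 0, -1):
            dp[c, v:] += dp[c - 1, : total + 1 - v]
    count_ge = dp[nx, w_obs:].sum()
    return float(count_ge / comb(len(r2), nx))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def aiq(tumour_air, normal_air):
    """Anchored IRR quotient: (tumour - normal) / (normal + 1)."""
    t = np.asarray(tumour_air, dtype=float)
    n = np.asarray(normal_air, dtype=float)
    if np.any(t < 0) or np.any(n < 0):
        raise ValueError("anchored-IRR values must be non-negative")
    q = (t - n) / (n + 1.0)
    return float(q) if q.ndim == 0 else q


def aiq_frequency(values: pd.Series, matrix: CohortMatrix, threshold: float = 2.5) -> float:
    """Fraction of tumour-normal pairs with AIQ strictly above ``threshold``."""
    pairs = matrix.pairs
    called = sum(
        1 for _, t, n in pairs if aiq(values[t], values[n]) > threshold
    )
    return called / len(pairs)


def call_expansions(matrix: CohortMatrix, locus_id: str, threshold: float = 2.5) -> pd.DataFrame:
    """Per-pair expansion calls at one locus (called iff AIQ > threshold)."""
    values = matrix.air.loc[locus_id]
    rows = []
    for pair_id, t, n in matrix.pairs:
        q = aiq(values[t], values[n])
        rows.append(
            {
                "pair_id": pair_id,
                "locus_id": locus_id,
                "tumour_air": float(values[t]),
                "normal_air": float(values[n]),
                "aiq": q,
                "called": bool(q > threshold),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


def cap_filter(air: pd.DataFrame, cap: float = 40.0, max_fraction: float = 0.10):
    """Remove loci where the share of values above ``cap`` exceeds ``max_fraction``.

    Returns a boolean Series (True = removed).  Exactly ``max_fraction`` is
    kept: the removal inequality is strict.
    """
    if air.empty:
        raise ValueError("empty matrix")
    frac = (air > cap).mean(axis=1)
    return frac > max_fraction


def _chrom_allowed(chrom: str, allowed) -> bool:
    return chrom.removeprefix("chr").upper() in allowed


def prioritize(matrix: CohortMatrix, config: TropicConfig | None = None) -> pd.DataFrame:
    """Run the cascade on globally normalized values.

    Order: chromosome filter -> cap filter -> per-locus one-sided rank-sum
    test (tumours vs normals) -> BH FDR over surviving loci -> AIQ-frequency
    filter.  Terminal statuses: removed_chrom, removed_cap, not_significant,
    candidate (q < fdr_candidate), somatic_rre (q < fdr_somatic and AIQ
    frequency > frequency_threshold).
    """
    config = config or TropicConfig()
    if len(matrix.pairs) < 2:
        raise ValueError("cohort must contain at least 2 tumour-normal pairs")
    loci = {loc.locus_id: loc for loc in matrix.loci}
    res = pd.DataFrame(
        {
            "chrom": [loci[i].chrom for i in matrix.air.index],
            "start": [loci[i].start for i in matrix.air.index],
            "end": [loci[i].end for i in matrix.air.index],
            "motif": [str(loci[i].motif) for i in matrix.air.index],
            "p": np.nan,
            "q": np.nan,
            "aiq_frequency": np.nan,
            "status": "not_significant",
            "reason": "",
        },
        index=matrix.air.index.copy(),
    )
    if res.empty:
        return res

    bad_chrom = ~res["chrom"].map(
        lambda c: _chrom_allowed(c, config.allowed_chromosomes)
    )
    res.loc[bad_chrom, ["status", "reason"]] = [
        "removed_chrom",
        "chromosome outside 1-22,X,Y",
    ]
    surviving = res.index[~bad_chrom]
    if len(surviving) == 0:
        return res

    capped = cap_filter(
        matrix.air.loc[surviving], config.air_cap, config.air_cap_fraction
    )
    removed_cap = capped.index[capped]
    res.loc[removed_cap, ["status", "reason"]] = [
        "removed_cap",
        f">{config.air_cap_fraction:.0%} of values above cap {config.air_cap:g}",
    ]
    surviving = [i for i in surviving if i not in set(removed_cap)]
    if not surviving:
        return res

    t_cols = [t for _, t, _ in matrix.pairs]
    n_cols = [n for _, _, n in matrix.pairs]
    pvals = [
        rank_sum_test(matrix.air.loc[i, t_cols], matrix.air.loc[i, n_cols])
        for i in surviving
    ]
    qvals = bh_fdr(pvals)
    res.loc[surviving, "p"] = pvals
    res.loc[surviving, "q"] = qvals
    for i in surviving:
        res.loc[i, "aiq_frequency"] = aiq_frequency(
            matrix.air.loc[i], matrix, config.aiq_threshold
        )
    for i in surviving:
        q = res.loc[i, "q"]
        freq = res.loc[i, "aiq_frequency"]
        if q < config.fdr_somatic and freq > config.frequency_threshold:
            res.loc[i, ["status", "reason"]] = [
                "somatic_rre",
                f"q={q:.3g} < {config.fdr_somatic}, AIQ frequency {freq:.3g}",
            ]
        elif q < config.fdr_candidate:
            res.loc[i, ["status", "reason"]] = [
                "candidate",
                f"q={q:.3g} < {config.fdr_candidate}",
            ]
        else:
            res.loc[i, ["status", "reason"]] = [
                "not_significant",
                f"q={q:.3g} >= {config.fdr_candidate}",
            ]
    return res


def local_depth_refilter(
    results: pd.DataFrame,
    matrix: CohortMatrix,
    local_depths: pd.DataFrame,
    config: TropicConfig | None = None,
) -> pd.DataFrame:
    """Second-pass filter of somatic candidates on locally normalized values.

    For each somatic_rre locus, raw counts are divided by per-sample local
    depth and rescaled by the locus's median local depth (so magnitudes stay
    comparable to raw counts); the rank-sum test, BH adjustment (across the
    refiltered loci) and the AIQ-frequency filter are then recomputed.  Loci
    that still satisfy q < fdr_somatic and frequency > threshold graduate to
    status ``rre``; the rest become ``removed_local_depth``.  A locus with an
    undefined (zero/missing) local depth in any sample is excluded with its
    own reason, never silently zeroed.
    """
    config = config or TropicConfig()
    res = results.copy()
    res["p_local"] = np.nan
    res["q_local"] = np.nan
    res["aiq_frequency_local"] = np.nan
    cands = [i for i in res.index if res.loc[i, "status"] == "somatic_rre"]
    if not cands:
        return res

    t_cols = [t for _, t, _ in matrix.pairs]
    n_cols = [n for _, _, n in matrix.pairs]
    testable = []
    local_values = {}
    for i in cands:
        if i not in local_depths.index:
            res.loc[i, ["status", "reason"]] = [
                "removed_local_depth",
                "no local depth available",
            ]
            continue
        depths = local_depths.loc[i, matrix.air.columns].astype(float)
        if depths.isna().any() or (depths <= 0).any():
            bad = depths.index[depths.isna() | (depths <= 0)].tolist()
            res.loc[i, ["status", "reason"]] = [
                "removed_local_depth",
                f"undefined local depth in {','.join(map(str, bad[:4]))}",
            ]
            continue
        scale = float(depths.median())
        local_values[i] = matrix.raw.loc[i].astype(float) / depths * scale
        testable.append(i)
    if not testable:
        return res

    pvals = [
        rank_sum_test(local_values[i][t_cols], local_values[i][n_cols])
        for i in testable
    ]
    qvals = bh_fdr(pvals)
    for i, p, q in zip(testable, pvals, qvals):
        freq = aiq_frequency(local_values[i], matrix, config.aiq_threshold)
        res.loc[i, ["p_local", "q_local", "aiq_frequency_local"]] = [p, q, freq]
        if q < config.fdr_somatic and freq > config.frequency_threshold:
            res.loc[i, ["status", "reason"]] = [
                "rre",
                f"retained after local-depth refilter (q_local={q:.3g})",
            ]
        else:
            res.loc[i, ["status", "reason"]] = [
                "removed_local_depth",
                f"signal lost under local normalization (q_local={q:.3g}, "
                f"AIQ frequency {freq:.3g})",
            ]
    return res
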