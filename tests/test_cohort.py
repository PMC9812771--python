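"""The prioritization cascade: filters, tests, AIQ calling, refilter."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from tropic.cohort import (
    CohortMatrix,
    TropicConfig,
    aiq,
    bh_fdr,
    build_matrix,
    call_expansions,
    cap_filter,
    local_depth_refilter,
    prioritize,
    rank_sum_test,
    theoretical_air_cap,
)
from tropic.motifs import Motif, TandemRepeatLocus
from tropic.profiling import SampleProfile


def brute_rank_sum_p(x, y):
    """Oracle: enumerate every assignment of pooled values to the two groups."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        total += 1
        count += ranks[list(idx)].sum() >= obs - 1e-12
    return count / total


def brute_bh(p):
    """Oracle: literal step-up definition q_i = min_{j>=rank(i)} p_(j) n/j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestRankSum:
    def test_exact_examples(self):
        assert rank_sum_test([5, 6, 7], [0, 1, 2]) == pytest.approx(0.05)
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) >= 0.5
        assert rank_sum_test([0, 0, 0], [0, 0, 0]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])
        with pytest.raises(ValueError):
            rank_sum_test([1, 2], [])

    def test_exact_path_matches_enumeration_with_ties(self, rng):
        for _ in range(30):
            nx, ny = rng.integers(1, 7, size=2)
            x = rng.integers(0, 4, nx).astype(float)
            y = rng.integers(0, 4, ny).astype(float)
            assert rank_sum_test(x, y) == pytest.approx(brute_rank_sum_p(x, y), abs=1e-12)

    def test_asymptotic_path_close_to_tie_free_exact(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(0.8, 1.0, 13)  # sizes > 12 force the asymptotic branch
        y = rng.normal(0.0, 1.0, 13)
        p_asym = rank_sum_test(x, y)
        p_exact = mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
        assert p_asym == pytest.approx(p_exact, rel=0.25)


class TestBhFdr:
    def test_examples(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert bh_fdr([0.01, 0.5]) == pytest.approx([0.02, 0.5])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_matches_step_up_oracle(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 30)))
            assert bh_fdr(p) == pytest.approx(brute_bh(p), abs=1e-12)


class TestAiq:
    @pytest.mark.parametrize("t, n, expected", [(7, 1, 3.0), (4, 4, 0.0), (5, 0, 5.0)])
    def test_formula(self, t, n, expected):
        assert aiq(t, n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            aiq(-1, 0)


class TestCapFilter:
    def make_air(self, n_high, n_total=20, high=45.0, low=1.0):
        values = [high] * n_high + [low] * (n_total - n_high)
        return pd.DataFrame([values], index=["L1"])

    def test_fraction_boundary_is_strict(self):
        assert cap_filter(self.make_air(3)).loc["L1"]          # 15% > 10% removed
        assert not cap_filter(self.make_air(1)).loc["L1"]      # 5% kept
        assert not cap_filter(self.make_air(2)).loc["L1"]      # exactly 10% kept

    def test_cap_boundary_is_strict(self):
        air = pd.DataFrame([[40.0] * 20], index=["L1"])        # at cap, not above
        assert not cap_filter(air).loc["L1"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cap_filter(pd.DataFrame())


def _matrix(loci_values, n_pairs=4, chroms=None):
    """Build a CohortMatrix from {locus_name: (tumour_values, normal_values)}."""
    sample_ids = [f"P{i}T" for i in range(n_pairs)] + [f"P{i}N" for i in range(n_pairs)]
    samples = pd.DataFrame(
        {
            "role": ["tumour"] * n_pairs + ["normal"] * n_pairs,
            "pair_id": [f"P{i}" for i in range(n_pairs)] * 2,
            "global_depth": 40.0,
            "read_length": 100,
        },
        index=sample_ids,
    )
    loci = []
    rows = {}
    for j, (name, (tvals, nvals)) in enumerate(loci_values.items()):
        chrom = (chroms or {}).get(name, "chr1")
        locus = TandemRepeatLocus(chrom, 1000 + 10_000 * j, 1500 + 10_000 * j, Motif("AAAG"))
        loci.append(locus)
        rows[locus.locus_id] = list(tvals) + list(nvals)
    raw = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    profiles = [
        SampleProfile(s, r["role"], r["pair_id"], 100, 40.0, [])
        for s, r in samples.iterrows()
    ]
    return build_matrix(loci, raw, profiles)


class TestCallExpansions:
    def test_strict_threshold(self):
        m = _matrix({"L": ([7, 7, 7, 0], [1, 1, 1, 4])})
        calls = call_expansions(m, m.loci[0].locus_id)
        by_pair = calls.set_index("pair_id")
        assert by_pair.loc["P0", "aiq"] == 3.0 and by_pair.loc["P0", "called"]
        assert not by_pair.loc["P3", "called"]          # aiq = -0.8

    def test_aiq_exactly_at_threshold_not_called(self):
        m = _matrix({"L": ([6, 0, 0, 0], [1, 0, 0, 0])})
        calls = call_expansions(m, m.loci[0].locus_id).set_index("pair_id")
        assert calls.loc["P0", "aiq"] == 2.5
        assert not calls.loc["P0", "called"]


class TestPrioritize:
    def test_cascade_statuses(self):
        m = _matrix(
            {
                "signal": ([30, 30, 30, 30], [1, 1, 1, 1]),
                "null": ([1, 2, 1, 2], [2, 1, 2, 1]),
                "mito": ([30, 30, 30, 30], [0, 0, 0, 0]),
                "capped": ([45, 45, 45, 45], [45, 45, 45, 0]),
            },
            chroms={"mito": "chrM"},
        )
        res = prioritize(m, TropicConfig())
        statuses = res["status"]
        assert (res["chrom"] == "chrM").sum() == 1
        assert statuses[res["chrom"] == "chrM"].iloc[0] == "removed_chrom"
        assert (statuses == "removed_cap").sum() == 1
        assert (statuses == "somatic_rre").sum() == 1
        sig = res[(statuses == "somatic_rre")]
        assert sig["q"].iloc[0] < 0.05 and sig["aiq_frequency"].iloc[0] > 0.05

    def test_all_zero_locus_is_not_a_candidate(self):
        m = _matrix({"z": ([0, 0, 0, 0], [0, 0, 0, 0]), "s": ([9, 9, 9, 9], [0, 0, 0, 0])})
        res = prioritize(m)
        zero_row = res[res["p"] >= 0.5]
        assert len(zero_row) == 1
        assert zero_row["status"].iloc[0] == "not_significant"

    def test_single_pair_cohort_rejected(self):
        with pytest.raises(ValueError):
            prioritize(_matrix({"L": ([1], [0])}, n_pairs=1))

    def test_locus_order_stability(self, rng):
        values = {
            f"L{k}": (rng.integers(0, 20, 4).tolist(), rng.integers(0, 20, 4).tolist())
            for k in range(6)
        }
        base = prioritize(_matrix(values))
        shuffled_names = list(values)
        rng.shuffle(shuffled_names)
        perm = prioritize(_matrix({k: values[k] for k in shuffled_names}))
        # identical locus -> status mapping regardless of input order
        joint = base["status"].sort_index()
        assert joint.equals(perm["status"].sort_index())

    def test_null_cohort_fdr_control(self, rng):
        """Matched tumour/normal distributions yield (almost) no discoveries."""
        n_discoveries = 0
        for _ in range(5):
            values = {
                f"L{k}": (rng.poisson(5, 8).tolist(), rng.poisson(5, 8).tolist())
                for k in range(20)
            }
            res = prioritize(_matrix(values, n_pairs=8))
            n_discoveries += int((res["q"] < 0.05).sum())
        # BH bounds the false-discovery rate, not the count; out of 100 null
        # loci essentially none should pass
        assert n_discoveries <= 2


class TestLocalDepthRefilter:
    def _depths(self, m, values):
        return pd.DataFrame(
            {s: [values[s]] for s in m.air.columns}, index=[m.loci[0].locus_id]
        )

    def test_amplification_artifact_removed(self):
        # tumours: raw 32 at local depth 120 (8 copies); normals: raw 8 at 30
        m = _matrix({"amp": ([32, 32, 32, 32], [8, 8, 8, 8])})
        res = prioritize(m)
        assert res["status"].iloc[0] == "somatic_rre"
        depths = self._depths(m, {s: 120.0 if s.endswith("T") else 30.0 for s in m.air.columns})
        final = local_depth_refilter(res, m, depths)
        assert final["status"].iloc[0] == "removed_local_depth"

    def test_true_expansion_retained(self):
        m = _matrix({"exp": ([30, 30, 30, 30], [0, 0, 0, 0])})
        res = prioritize(m)
        depths = self._depths(m, {s: 30.0 for s in m.air.columns})
        final = local_depth_refilter(res, m, depths)
        assert final["status"].iloc[0] == "rre"
        assert final["q_local"].iloc[0] < 0.05

    def test_zero_depth_window_flags_locus(self):
        m = _matrix({"exp": ([30, 30, 30, 30], [0, 0, 0, 0])})
        res = prioritize(m)
        values = {s: 30.0 for s in m.air.columns}
        values["P2N"] = 0.0
        final = local_depth_refilter(res, m, self._depths(m, values))
        assert final["status"].iloc[0] == "removed_local_depth"
        assert "undefined local depth" in final["reason"].iloc[0]


def test_theoretical_cap_geometry():
    assert theoretical_air_cap(100, 500, 40.0) == pytest.approx(120.0)
    # the printed cap of 40 corresponds to a 300-bp fragment at 100-bp reads
    assert theoretical_air_cap(100, 300, 40.0) == pytest.approx(40.0)
    with pytest.raises(ValueError):
        theoretical_air_cap(100, 150)


def test_parameter_recovery_on_standard_fixture(standard_fixture):
    """Sensitivity >= 90% and no false discoveries on the 20-pair fixture."""
    fx = standard_fixture
    assert fx["n_recovered"] == fx["n_truth"] == 3
    assert fx["false_positives"] == []
    assert fx["call_sensitivity"] >= 0.9
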