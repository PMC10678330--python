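"""Significance filtering, pairwise LD, expansion and locus chaining."""

import itertools

import numpy as np
import pandas as pd
import pytest

from postgwas import (
    cluster_loci,
    compute_ld_r2,
    expand_ld_snps,
    assemble_snp_list,
    select_significant_snps,
)
from postgwas.exceptions import (
    MissingVariantError,
    MonomorphicVariantError,
    ValidationError,
)

from conftest import make_panel, pearson_r2


def summary(pvalues, chrom=None, pos=None):
    n = len(pvalues)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(n)],
            "chrom": chrom or ["1"] * n,
            "pos": pos or [1000 * (i + 1) for i in range(n)],
            "pvalue": pvalues,
        }
    )


class TestSelectSignificant:
    def test_strict_threshold(self):
        out = select_significant_snps(summary([1e-9, 1e-8, 0.5]))
        assert list(out["variant_id"]) == ["rs1"]  # 1e-8 itself excluded

    def test_empty_and_boundary(self):
        assert len(select_significant_snps(summary([]))) == 0
        assert len(select_significant_snps(summary([0.0, 0.0]))) == 2

    def test_order_preserved(self):
        out = select_significant_snps(summary([1e-10, 0.5, 1e-12]))
        assert list(out["variant_id"]) == ["rs1", "rs3"]

    @pytest.mark.parametrize("bad", [-0.1, 1.5, np.nan])
    def test_malformed_pvalue_names_row(self, bad):
        with pytest.raises(ValidationError, match="rs2"):
            select_significant_snps(summary([0.5, bad, 0.1]))

    def test_bad_threshold(self):
        with pytest.raises(ValidationError):
            select_significant_snps(summary([0.5]), threshold=0.0)


class TestComputeLdR2:
    def test_identical_vectors(self):
        panel = make_panel(np.array([[0, 0], [1, 1], [2, 2]]))
        assert compute_ld_r2(panel, "rs1", "rs2") == pytest.approx(1.0)

    def test_hand_example(self):
        x = [0, 0, 1, 1, 2, 2]
        y = [0, 1, 0, 2, 1, 2]
        panel = make_panel(np.array([x, y]).T)
        assert compute_ld_r2(panel, "rs1", "rs2") == pytest.approx(0.25)
        assert pearson_r2(x, y) == pytest.approx(0.25)

    def test_anticorrelation(self):
        x = np.array([0, 1, 2, 1, 0, 2])
        panel = make_panel(np.array([x, 2 - x]).T)
        assert compute_ld_r2(panel, "rs1", "rs2") == pytest.approx(1.0)

    def test_symmetry_range_against_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            d = rng.integers(0, 3, size=(12, 2))
            if d[:, 0].var() == 0 or d[:, 1].var() == 0:
                continue
            panel = make_panel(d)
            ab = compute_ld_r2(panel, "rs1", "rs2")
            ba = compute_ld_r2(panel, "rs2", "rs1")
            assert ab == pytest.approx(ba)
            assert 0.0 <= ab <= 1.0
            assert ab == pytest.approx(pearson_r2(d[:, 0], d[:, 1]), rel=1e-12)

    def test_monomorphic_and_missing(self):
        panel = make_panel(np.array([[1, 0], [1, 1], [1, 2]]))
        with pytest.raises(MonomorphicVariantError):
            compute_ld_r2(panel, "rs1", "rs2")
        with pytest.raises(MissingVariantError):
            compute_ld_r2(panel, "rs1", "rs99")


def brute_force_expansion(significant, panel, window_bp, r2_min):
    """Exhaustive pair enumeration oracle."""
    rows = []
    var = panel.variants.set_index("variant_id")
    for q in significant["variant_id"]:
        for p in panel.variant_ids:
            if p == q or var.loc[p, "chrom"] != var.loc[q, "chrom"]:
                continue
            dist = abs(int(var.loc[p, "pos"]) - int(var.loc[q, "pos"]))
            if not 0 < dist <= window_bp:
                continue
            x, y = panel.dosage_vector(q), panel.dosage_vector(p)
            if np.var(y) == 0:
                continue
            if pearson_r2(x, y) > r2_min:
                rows.append((q, p))
    return sorted(rows)


class TestExpandLd:
    def _random_panel(self, rng, n_snps=10):
        while True:
            d = rng.integers(0, 3, size=(25, n_snps))
            if all(d[:, j].var() > 0 for j in range(n_snps)):
                break
        # two chromosomes, irregular spacing so the window rule bites
        chroms = ["1"] * (n_snps // 2) + ["2"] * (n_snps - n_snps // 2)
        pos = list(
            itertools.chain(
                np.cumsum(rng.integers(1, 2000, size=n_snps // 2)),
                np.cumsum(rng.integers(1, 2000, size=n_snps - n_snps // 2)),
            )
        )
        return make_panel(d, positions=[int(p) for p in pos], chroms=chroms)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for trial in range(25):
            panel = self._random_panel(rng)
            sig = panel.variants.iloc[:3].copy()
            sig["pvalue"] = 1e-12
            window, r2_min = 3000, 0.3
            out = expand_ld_snps(sig, panel, window, r2_min)
            got = sorted(zip(out["query_id"], out["partner_id"]))
            assert got == brute_force_expansion(sig, panel, window, r2_min)

    def test_window_rule(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2]])
        panel = make_panel(d, positions=[1, 600_002])
        sig = panel.variants.iloc[:1].copy()
        sig["pvalue"] = 0.0
        assert len(expand_ld_snps(sig, panel, 500_000, 0.9)) == 0
        assert len(expand_ld_snps(sig, panel, 700_000, 0.9)) == 1

    def test_r2_threshold_strict(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2]])
        panel = make_panel(d)  # r2 exactly 1.0
        sig = panel.variants.iloc[:1].copy()
        sig["pvalue"] = 0.0
        assert len(expand_ld_snps(sig, panel, 500_000, r2_min=1.0)) == 0
        assert len(expand_ld_snps(sig, panel, 500_000, r2_min=0.99)) == 1

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        panel = self._random_panel(rng, n_snps=12)
        sig = panel.variants.iloc[:4].copy()
        sig["pvalue"] = 1e-12

        def pairs(window, r2m):
            out = expand_ld_snps(sig, panel, window, r2m)
            return set(zip(out["query_id"], out["partner_id"]))

        assert pairs(2000, 0.5) <= pairs(2000, 0.2)
        assert pairs(1000, 0.2) <= pairs(4000, 0.2)

    def test_missing_query_lists_ids(self):
        panel = make_panel(np.array([[0, 1], [1, 0], [2, 2]]))
        sig = pd.DataFrame(
            {"variant_id": ["rsX"], "chrom": ["1"], "pos": [5], "pvalue": [0.0]}
        )
        with pytest.raises(MissingVariantError, match="rsX"):
            expand_ld_snps(sig, panel, 500_000, 0.9)


class TestAssemble:
    def test_dedup_prefers_significant(self):
        panel = make_panel(np.array([[0, 1, 2], [1, 0, 1], [2, 2, 0]]))
        sig = panel.variants.iloc[[0]].copy()
        sig["pvalue"] = 1e-10
        exp = pd.DataFrame(
            {
                "query_id": ["rs1", "rs1"],
                "partner_id": ["rs2", "rs1"],
                "r2": [0.95, 1.0],
                "distance_bp": [1000, 0],
            }
        )
        out = assemble_snp_list(sig, exp, panel)
        assert list(out["variant_id"]) == ["rs1", "rs2"]
        assert out.loc[out["variant_id"] == "rs1", "provenance"].item() == "significant"

    def test_disjoint_union_count(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(10, 7))
        panel = make_panel(d)
        sig = panel.variants.iloc[:3].copy()
        sig["pvalue"] = 1e-9
        exp = pd.DataFrame(
            {
                "query_id": ["rs1"] * 4,
                "partner_id": ["rs4", "rs5", "rs6", "rs7"],
                "r2": [0.95] * 4,
                "distance_bp": [1, 2, 3, 4],
            }
        )
        out = assemble_snp_list(sig, exp, panel)
        assert len(out) == 7
        assert list(out["pos"]) == sorted(out["pos"])


def brute_force_loci(positions, max_gap):
    """Single-linkage chaining oracle on one chromosome."""
    groups, current = [], [0]
    for i in range(1, len(positions)):
        if positions[i] - positions[i - 1] < max_gap:
            current.append(i)
        else:
            groups.append(current)
            current = [i]
    groups.append(current)
    return groups


class TestClusterLoci:
    def test_spec_example(self):
        snps = summary([0.1] * 3, pos=[1_000_000, 1_400_000, 2_100_000])
        loci = cluster_loci(snps)
        assert [l.member_ids for l in loci] == [("rs1", "rs2"), ("rs3",)]
        assert (loci[0].start, loci[0].end) == (1_000_000, 1_400_000)

    def test_single_snp(self):
        loci = cluster_loci(summary([0.5], pos=[42]))
        assert len(loci) == 1 and loci[0].start == loci[0].end == 42

    def test_chaining_below_gap(self):
        pos = [1 + 499_999 * i for i in range(10)]
        loci = cluster_loci(summary([0.5] * 10, pos=pos))
        assert len(loci) == 1 and loci[0].size == 10

    def test_gap_exactly_at_threshold_splits(self):
        loci = cluster_loci(summary([0.5] * 2, pos=[1, 500_001]))
        assert len(loci) == 2

    def test_partition_against_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            pos = np.sort(rng.choice(np.arange(1, 5_000_000), size=n, replace=False))
            snps = summary([0.5] * n, pos=[int(p) for p in pos])
            max_gap = int(rng.integers(10_000, 1_000_000))
            loci = cluster_loci(snps, max_gap)
            expected = brute_force_loci(list(pos), max_gap)
            assert [len(g) for g in expected] == [l.size for l in loci]
            assert sum(l.size for l in loci) == n
            members = [m for l in loci for m in l.member_ids]
            assert len(set(members)) == n

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            cluster_loci(summary([]))
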