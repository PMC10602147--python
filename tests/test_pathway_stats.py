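"""Gene contrasts, the combined pathway Z statistic and the paired-t dropout."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tmzkit import pathway_stats as ps
from tmzkit.pathway_stats import GeneContrast

from conftest import make_count_matrix


class TestGeneZstat:
    def test_worked_example(self):
        c = ps.gene_zstat([-2, -1, 0], [1, 0, -1])
        assert c.x == pytest.approx(-1.0)
        assert c.s == pytest.approx(math.sqrt(2 / 3), abs=1e-12)
        assert c.z == pytest.approx(-1.2247, abs=1e-4)

    def test_identical_arms(self):
        c = ps.gene_zstat([0.3, -0.2, 1.0], [0.3, -0.2, 1.0])
        assert c.x == 0.0 and c.z == 0.0

    def test_linear_in_shift(self):
        base = np.array([0.1, -0.4, 0.7, 0.2])
        z1 = ps.gene_zstat(base + 1.0, base).z
        z3 = ps.gene_zstat(base + 3.0, base).z
        assert z3 == pytest.approx(3 * z1)

    def test_degenerate_variance_flagged(self):
        c = ps.gene_zstat([1.0, 1.0], [1.0, 1.0])
        assert c.s == 0.0 and math.isnan(c.z)

    def test_needs_two_per_arm(self):
        with pytest.raises(ValueError):
            ps.gene_zstat([1.0], [0.0, 1.0])


class TestPathwayZ:
    def test_single_gene_equals_gene_z(self):
        c = ps.gene_zstat([-2, -1, 0], [1, 0, -1], gene_id="g")
        r = ps.pathway_zstat([c], pathway="P")
        assert r.z == pytest.approx(c.z) and r.n_genes == 1

    def test_two_identical_genes(self):
        c = GeneContrast("g", x=-1.0, s=math.sqrt(2 / 3), z=None, n_tmz=3,
                         n_dmso=3)
        r = ps.pathway_zstat([c, c])
        assert r.z == pytest.approx(-math.sqrt(3), abs=1e-12)
        assert r.z == pytest.approx(-1.7321, abs=1e-4)

    def test_order_and_partition_invariance(self):
        rng = np.random.default_rng(1)
        cs = [GeneContrast(f"g{i}", x=rng.normal(), s=rng.uniform(0.1, 2),
                           z=0.0, n_tmz=3, n_dmso=3) for i in range(8)]
        direct = ps.pathway_zstat(cs).z
        shuffled = ps.pathway_zstat(cs[::-1]).z
        # merging subset sums reproduces the same statistic
        x = sum(c.x for c in cs[:3]) + sum(c.x for c in cs[3:])
        s2 = sum(c.s ** 2 for c in cs[:3]) + sum(c.s ** 2 for c in cs[3:])
        assert direct == pytest.approx(shuffled, abs=1e-14)
        assert direct == pytest.approx(x / math.sqrt(s2), abs=1e-14)

    def test_zero_effect_tiny_s_gene_is_neutral_in_limit(self):
        cs = [GeneContrast("a", x=-2.0, s=1.0, z=-2.0, n_tmz=3, n_dmso=3)]
        base = ps.pathway_zstat(cs).z
        with_tiny = ps.pathway_zstat(
            cs + [GeneContrast("b", x=0.0, s=1e-9, z=0.0, n_tmz=3, n_dmso=3)]).z
        assert with_tiny == pytest.approx(base, abs=1e-12)

    def test_degenerate_genes_excluded_and_counted(self):
        cs = [GeneContrast("a", x=-1.0, s=0.5, z=-2.0, n_tmz=3, n_dmso=3),
              GeneContrast("b", x=5.0, s=0.0, z=float("nan"), n_tmz=2,
                           n_dmso=2)]
        r = ps.pathway_zstat(cs)
        assert r.n_genes == 1 and r.n_excluded == 1
        assert r.z == pytest.approx(-2.0)

    def test_all_degenerate_rejected(self):
        c = GeneContrast("b", x=5.0, s=0.0, z=float("nan"), n_tmz=2, n_dmso=2)
        with pytest.raises(ValueError, match="S_g > 0"):
            ps.pathway_zstat([c], pathway="P")


class TestPairedT:
    def test_worked_example_closed_form_df2(self):
        t, p, degen = ps.paired_t_dropout(
            np.array([-1.0, -2.0, -3.0]), np.zeros(3))
        assert not degen
        assert t == pytest.approx(-3.4641, abs=1e-4)
        # closed-form t CDF for df=2: P(T<=t) = 1/2 + t/(2*sqrt(2+t^2))
        closed = 2 * (0.5 + t / (2 * math.sqrt(2 + t * t)))
        assert p == pytest.approx(closed, abs=1e-10)
        assert p == pytest.approx(0.0742, abs=2e-4)
        assert -math.log10(p) == pytest.approx(1.1295, abs=2e-3)

    def test_no_change_is_degenerate_zero(self):
        t, p, degen = ps.paired_t_dropout(np.ones(4), np.ones(4))
        assert t == 0.0 and p == 1.0 and degen

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(-5, 5, allow_nan=False),
        st.floats(-5, 5, allow_nan=False)), min_size=3, max_size=10))
    def test_matches_textbook_computation(self, pairs):
        pd20 = np.array([a for a, _ in pairs])
        pd0 = np.array([b for _, b in pairs])
        d = pd20 - pd0
        if np.allclose(d.var(ddof=1), 0):
            return
        t, p, degen = ps.paired_t_dropout(pd20, pd0)
        n = len(d)
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        p_ref = 2 * stats.t.sf(abs(t_ref), df=n - 1)
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)


class TestPathwayPairedT:
    def _matrix(self, toy_design, pd20_scale=1.0, shuffle=False, jitter=5.0):
        guide_ids = list(toy_design.guides["guide_id"])
        n = len(guide_ids)
        cols, meta = {}, {}
        for rep in (1, 2):
            base = 100 + np.arange(n, dtype=float)
            cols[f"PD0_TMZ_R{rep}"] = base
            # per-guide jitter so paired differences are not constant
            cols[f"PD20_TMZ_R{rep}"] = base * pd20_scale + jitter * np.sin(
                np.arange(n) + rep)
            meta[f"PD0_TMZ_R{rep}"] = ("PD0", "TMZ", "WT", rep)
            meta[f"PD20_TMZ_R{rep}"] = ("PD20", "TMZ", "WT", rep)
        cm = make_count_matrix(cols, guide_ids, meta)
        if shuffle:
            perm = np.random.default_rng(5).permutation(n)
            cm = make_count_matrix(
                {c: cm.counts[c].to_numpy()[perm] for c in cm.counts.columns},
                [guide_ids[i] for i in perm], meta)
        return cm

    def test_identity_counts_give_null(self, toy_design):
        cm = self._matrix(toy_design, jitter=0.0)
        res = ps.pathway_paired_t(cm, toy_design, toy_design.pathway_map)
        for r in res:
            assert r.t_stat == 0.0 and r.neg_log10_p == 0.0
            assert r.log2_fc_pooled == pytest.approx(0.0)

    def test_guide_order_irrelevant(self, toy_design):
        a = ps.pathway_paired_t(self._matrix(toy_design, 0.5),
                                toy_design, toy_design.pathway_map)
        b = ps.pathway_paired_t(self._matrix(toy_design, 0.5, shuffle=True),
                                toy_design, toy_design.pathway_map)
        for ra, rb in zip(a, b):
            assert ra.pathway == rb.pathway
            assert ra.t_stat == pytest.approx(rb.t_stat, rel=1e-12)
            assert ra.log2_fc_pooled == pytest.approx(rb.log2_fc_pooled)


class TestRadarSummary:
    def _zres(self, pathway, p):
        z = stats.norm.isf(p / 2)
        return ps.PathwayZResult(pathway=pathway, z=z, p_two_sided=p,
                                 n_genes=3)

    def test_neg_log10_transform(self):
        df = ps.radar_summary({"U373": [self._zres("HR", 0.01)]})
        assert df["neg_log10_p"].iloc[0] == pytest.approx(2.0)

    def test_missing_pathway_is_explicit_na(self):
        df = ps.radar_summary({
            "U373": [self._zres("HR", 0.01)],
            "U87": [self._zres("HR", 0.5), self._zres("FA", 0.2)]})
        assert len(df) == 4  # 2 cell lines x 2 pathways
        row = df[(df["cell_line"] == "U373") & (df["pathway"] == "FA")]
        assert math.isnan(row["neg_log10_p"].iloc[0])

    def test_row_count_is_product(self):
        res = {f"line{i}": [self._zres(p, 0.3) for p in ("a", "b", "c")]
               for i in range(3)}
        assert len(ps.radar_summary(res)) == 9
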