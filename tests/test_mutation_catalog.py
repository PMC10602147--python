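"""Filter cascade semantics, 96-context classification and arm comparisons."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmzkit import mutation_catalog as mc, synthetic_data as sd
from tmzkit.io_formats import VariantRecord
from tmzkit.sbs import CONTEXTS_96, SUB_CLASSES, classify_snv


def snv(maf=0.4, depth_t=50, depth_n=50, alt_reads=20, known=False,
        exome=True, ref="C", alt="A", context="ACG", clone="c1"):
    return VariantRecord("chr1", 100, ref, alt, maf, depth_t, depth_n,
                         alt_reads, context, known, exome, clone)


def indel(length, insertion=False):
    ref, alt = ("A", "A" + "T" * length) if insertion else ("A" + "T" * length, "A")
    return VariantRecord("chr1", 100, ref, alt, 0.4, 50, 50, 20, "NNN")


class TestFilterBoundaries:
    @pytest.mark.parametrize("record,kept", [
        (indel(10), True),           # "greater than 10 bp" removed: 10 stays
        (indel(11), False),
        (indel(11, insertion=True), False),
        (snv(maf=0.10), True),       # MAF >= 10%
        (snv(maf=0.09), False),
        (snv(depth_t=10, depth_n=10), True),   # coverage >= 10x, both samples
        (snv(depth_t=9), False),
        (snv(depth_n=9), False),
        (snv(alt_reads=3), True),    # >= 3 supporting reads
        (snv(alt_reads=2), False),
        (snv(known=True), False),    # known-polymorphism subtraction
        (snv(exome=False), False),   # exome-interval mask
    ])
    def test_inclusive_boundaries(self, record, kept):
        kept_records, audit = mc.filter_variants([record])
        assert (len(kept_records) == 1) is kept
        assert audit.n_input == 1
        assert audit.n_kept + audit.total_removed() == 1

    def test_first_failing_rule_attribution(self):
        r = snv(maf=0.05, depth_t=5, alt_reads=1, known=True)
        _, audit = mc.filter_variants([r])
        assert audit.removed["maf"] == 1
        assert audit.total_removed() == 1

    def test_empty_input(self):
        kept, audit = mc.filter_variants([])
        assert kept == [] and audit.n_input == 0 and audit.total_removed() == 0


def _random_records(rng, n):
    out = []
    for i in range(n):
        if rng.random() < 0.3:
            out.append(indel(int(rng.integers(1, 20))))
        else:
            out.append(snv(
                maf=float(rng.uniform(0, 0.5)),
                depth_t=int(rng.integers(0, 40)),
                depth_n=int(rng.integers(0, 40)),
                alt_reads=int(rng.integers(0, 10)),
                known=bool(rng.random() < 0.2),
                exome=bool(rng.random() < 0.8)))
    return out


class TestFilterProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(0, 60))
    def test_audit_sums_and_idempotence(self, seed, n):
        records = _random_records(np.random.default_rng(seed), n)
        kept, audit = mc.filter_variants(records)
        assert audit.n_input == n
        assert audit.n_kept + audit.total_removed() == n
        again, audit2 = mc.filter_variants(kept)
        assert again == kept and audit2.total_removed() == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_tightening_never_keeps_more(self, seed):
        rng = np.random.default_rng(seed)
        records = _random_records(rng, 50)
        base = mc.FilterConfig()
        n_base = len(mc.filter_variants(records, base)[0])
        for tighter in (
            dataclasses.replace(base, max_indel_len=base.max_indel_len - 1),
            dataclasses.replace(base, min_maf=base.min_maf + 0.05),
            dataclasses.replace(base, min_depth=base.min_depth + 5),
            dataclasses.replace(base, min_alt_reads=base.min_alt_reads + 2),
        ):
            assert len(mc.filter_variants(records, tighter)[0]) <= n_base


class TestClassify:
    def test_purine_strand_normalised(self):
        assert classify_snv("G", "A", "TGA") == ("C>T", "T[C>T]A")

    def test_pyrimidine_passthrough(self):
        assert classify_snv("C", "A", "ACG") == ("C>A", "A[C>A]G")

    def test_strand_symmetry(self):
        from tmzkit.sbs import revcomp
        rng = np.random.default_rng(3)
        bases = "ACGT"
        for _ in range(50):
            ref = bases[rng.integers(4)]
            alt = rng.permutation([b for b in bases if b != ref])[0]
            ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
            fwd = classify_snv(ref, alt, ctx)
            rev = classify_snv(revcomp(ref), revcomp(alt), revcomp(ctx))
            assert fwd == rev

    def test_exactly_96_reachable_labels(self):
        labels = set()
        for ref in "ACGT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for five in "ACGT":
                    for three in "ACGT":
                        _, lab = classify_snv(ref, alt, five + ref + three)
                        labels.add(lab)
        assert labels == set(CONTEXTS_96)
        per_class = {c: sum(1 for l in labels if l[2:5] == c)
                     for c in SUB_CLASSES}
        assert set(per_class.values()) == {16}

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError, match="ambiguous|invalid"):
            classify_snv("N", "A", "ANA")


class TestBuildCatalogs:
    def test_three_identical_snvs(self):
        recs = [snv(ref="C", alt="T", context="ACG")] * 3
        cat = mc.build_catalogs({"c1": recs}, {"c1": ("WT", "TMZ")})[0]
        assert cat.class_counts["C>T"] == 3 and cat.total_snv == 3
        assert cat.context_counts[CONTEXTS_96.index("A[C>T]G")] == 3

    def test_indel_not_counted(self):
        recs = [snv(), indel(2)]
        cat = mc.build_catalogs({"c1": recs}, {"c1": ("WT", "TMZ")})[0]
        assert cat.total_snv == 1

    def test_zero_snv_clone_valid(self):
        cat = mc.build_catalogs({"c1": []}, {"c1": ("WT", "DMSO")})[0]
        assert cat.total_snv == 0
        assert sum(cat.class_counts.values()) == 0

    def test_count_conservation_invariants(self, toy_signatures):
        p = sd.CatalogSimParams(
            signature_matrix=toy_signatures, arms=[("WT", "TMZ", 5)],
            activities={("WT", "TMZ"): [200, 50, 10, 0, 0]}, seed=6)
        cats, _ = sd.simulate_catalogs(p)
        for c in cats:
            assert sum(c.class_counts.values()) == c.total_snv
            assert c.context_counts.sum() == c.total_snv
            per_class = c.context_counts.reshape(6, 16).sum(axis=1)
            assert list(per_class) == [c.class_counts[k] for k in SUB_CLASSES]


class TestCompareArms:
    def _catalog(self, clone, genotype, treatment, total):
        ctx = np.zeros(96, dtype=int)
        ctx[0] = total
        return mc.CloneCatalog(clone, genotype, treatment, ctx)

    def test_induced_difference_of_means(self):
        cats = [self._catalog(f"t{i}", "WT", "TMZ", v)
                for i, v in enumerate([10, 12, 14])]
        cats += [self._catalog(f"d{i}", "WT", "DMSO", v)
                 for i, v in enumerate([4, 6, 5])]
        res = [r for r in mc.compare_arms(cats) if r.which == "total"][0]
        assert res.induced == pytest.approx(7.0)
        assert res.induced == res.mean_tmz - res.mean_dmso

    def test_identical_arms_degenerate(self):
        cats = [self._catalog(f"t{i}", "WT", "TMZ", 5) for i in range(3)]
        cats += [self._catalog(f"d{i}", "WT", "DMSO", 5) for i in range(3)]
        res = [r for r in mc.compare_arms(cats) if r.which == "total"][0]
        assert res.induced == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_pattern_labels(self):
        cats = [self._catalog("t", "WT", "TMZ", 5),
                self._catalog("t2", "WT", "TMZ", 6),
                self._catalog("d", "WT", "DMSO", 1),
                self._catalog("d2", "WT", "DMSO", 2)]
        res = mc.compare_arms(cats)
        labels = {r.which: r.pattern for r in res}
        assert labels["C>T"] == "I" and labels["C>A"] == "II"
        assert labels["total"] == ""

    def test_generator_oracle_recovery(self, toy_signatures):
        act_tmz = np.array([400.0, 100.0, 0, 0, 0])
        act_dmso = np.array([0.0, 100.0, 0, 0, 0])
        p = sd.CatalogSimParams(
            signature_matrix=toy_signatures,
            arms=[("WT", "TMZ", 6), ("WT", "DMSO", 6)],
            activities={("WT", "TMZ"): act_tmz, ("WT", "DMSO"): act_dmso},
            seed=7)
        cats, _ = sd.simulate_catalogs(p)
        res = [r for r in mc.compare_arms(cats) if r.which == "total"][0]
        se = np.sqrt(500.0 / 6 + 100.0 / 6)  # Poisson SE of the two means
        assert abs(res.induced - 400.0) < 3 * se
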