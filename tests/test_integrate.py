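import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonaltraj.exprdyn import presence_filter
from clonaltraj.integrate import (
    AssociationRecord,
    associate_pairs,
    genotype_expression_association,
    immune_intersection,
    map_loci_to_genes,
    mirna_target_concordance,
    select_candidates,
)
from clonaltraj.io import ExpressionMatrix, GeneAnnotation, GenotypeMatrix, SampleSheet


def _geno(positions, dosages=None, sheet=None):
    sheet = sheet or SampleSheet.default()
    if dosages is None:
        dosages = np.zeros((len(positions), len(sheet)))
        dosages[:, 0] = 1  # polymorphic
    loci = pd.DataFrame(
        {
            "locus_id": [f"chr1:{p}:A:G" for p in positions],
            "chrom": "chr1",
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(loci, np.asarray(dosages, float), sheet)


class TestMapLociToGenes:
    ANN = [
        GeneAnnotation("gA", "chr1", 100, 200),
        GeneAnnotation("gB", "chr1", 150, 250),
    ]

    def test_containment_is_half_open(self):
        # 1-based positions 101..200 fall in the 0-based interval [100, 200)
        pairs, unmapped = map_loci_to_genes(_geno([151, 201, 101, 100]), [self.ANN[0]])
        mapped = {p.locus_id for p in pairs}
        assert mapped == {"chr1:151:A:G", "chr1:101:A:G"}
        assert unmapped == 2

    def test_overlapping_genes_give_two_pairs(self):
        pairs, _ = map_loci_to_genes(_geno([180]), self.ANN)
        assert {(p.locus_id, p.gene_id) for p in pairs} == {
            ("chr1:180:A:G", "gA"),
            ("chr1:180:A:G", "gB"),
        }


class TestAssociation:
    DOSE = np.array([0, 0, 0, 1, 0, 0, 1, 1, 0, 1, 1, 0, 2, 1, 1], float)

    def test_perfect_linear_fit_is_degenerate_with_unit_slope(self):
        rec = genotype_expression_association(
            self.DOSE, 1.0 + self.DOSE, log_transform=False
        )
        assert rec.degenerate
        assert rec.slope == pytest.approx(1.0)
        assert rec.p_value < 1e-300

    def test_matches_independent_least_squares_oracle(self):
        """Six-point hand example against scipy.stats.linregress."""
        d = np.array([0, 0, 1, 1, 2, 2], float)
        y = np.array([3.0, 3.4, 4.1, 4.4, 5.2, 4.9])
        rec = genotype_expression_association(d, y, log_transform=False)
        lr = stats.linregress(d, y)
        assert rec.slope == pytest.approx(lr.slope, abs=1e-10)
        assert rec.p_value == pytest.approx(lr.pvalue, abs=1e-10)
        assert rec.f_stat == pytest.approx(lr.rvalue**2 / (1 - lr.rvalue**2) * 4, abs=1e-8)

    def test_missing_genotypes_dropped(self):
        d = self.DOSE.copy()
        d[:3] = np.nan
        rec = genotype_expression_association(d, np.arange(15.0), log_transform=False)
        assert rec.n_used == 12

    def test_monomorphic_locus_skipped(self):
        assert genotype_expression_association(np.zeros(15), np.arange(15.0)) is None

    def test_constant_expression_has_no_signal(self):
        rec = genotype_expression_association(self.DOSE, np.full(15, 8.0))
        assert rec.p_value == 1.0 and rec.slope == 0.0

    def test_permutation_null_is_uniform(self):
        """P values of permuted expression are uniform (KS test)."""
        rng = np.random.default_rng(17)
        y = rng.normal(5, 1, 15)
        ps = []
        for _ in range(1000):
            rec = genotype_expression_association(
                self.DOSE, rng.permutation(y), log_transform=False
            )
            ps.append(rec.p_value)
        frac = np.mean(np.array(ps) < 0.01)
        assert 0.005 <= frac <= 0.02 or frac == 0.0  # small-n binomial wobble
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSelectCandidates:
    def _rec(self, locus, gene, p):
        return AssociationRecord(locus, gene, 1.0, 10.0, p, 15)

    def test_two_loci_one_gene_deduplicated(self):
        records = [self._rec("l1", "gX", 0.001), self._rec("l2", "gX", 0.002)]
        loci, genes = select_candidates(records, 0.01)
        assert loci == ["l1", "l2"] and genes == ["gX"]

    def test_alpha_zero_selects_nothing(self):
        loci, genes = select_candidates([self._rec("l", "g", 1e-10)], 0.0)
        assert loci == [] and genes == []

    def test_gene_list_never_longer_than_locus_list(self):
        rng = np.random.default_rng(4)
        records = [
            self._rec(f"l{i}", f"g{rng.integers(5)}", rng.uniform())
            for i in range(50)
        ]
        loci, genes = select_candidates(records, 0.5)
        assert len(genes) <= len(loci)


class TestImmuneIntersection:
    def test_basic_overlap_sorted(self):
        assert immune_intersection({"B", "A"}, {"B", "C", "A"}) == ["A", "B"]

    def test_disjoint_sets_empty(self):
        assert immune_intersection({"A"}, {"B"}) == []

    def test_commutative(self):
        a, b = {"x", "y", "z"}, {"y", "q"}
        assert immune_intersection(a, b) == immune_intersection(b, a)


class TestMirTargetConcordance:
    def _mat(self, rows, ids, kind):
        sheet = SampleSheet.default()
        return ExpressionMatrix(
            pd.DataFrame(np.asarray(rows, float), index=ids,
                         columns=list(sheet.sample_ids)),
            sheet, kind,
        )

    UP = np.repeat([1.0, 2, 3, 4, 5], 3)
    DOWN = np.repeat([5.0, 4, 3, 2, 1], 3)
    FLAT = np.full(15, 3.0)

    def test_same_mode_requires_equal_trends(self):
        mirna = self._mat([self.UP], ["m1"], "mirna")
        genes = self._mat([self.UP, self.DOWN, self.FLAT], ["gU", "gD", "gF"], "gene")
        pairs = [("m1", "gU"), ("m1", "gD"), ("m1", "gF")]
        out, _ = mirna_target_concordance(mirna, genes, pairs, mode="same")
        assert [p.concordant for p in out] == [True, False, False]

    def test_inverse_mode_requires_opposite_trends(self):
        mirna = self._mat([self.UP], ["m1"], "mirna")
        genes = self._mat([self.UP, self.DOWN], ["gU", "gD"], "gene")
        out, _ = mirna_target_concordance(
            mirna, genes, [("m1", "gU"), ("m1", "gD")], mode="inverse"
        )
        assert [p.concordant for p in out] == [False, True]

    def test_absent_members_skipped_with_reason(self):
        mirna = self._mat([self.UP], ["m1"], "mirna")
        genes = self._mat([self.UP], ["gU"], "gene")
        out, skipped = mirna_target_concordance(
            mirna, genes, [("m2", "gU"), ("m1", "gZ")], mode="same"
        )
        assert out == [] and len(skipped) == 2


def test_planted_eqtl_links_recovered(noise_free_cohort):
    """All planted dosage->expression links reach P < 0.01 and nothing
    else does, in the noise-free cohort."""
    c = noise_free_cohort
    from clonaltraj.exprdyn import presence_filter
    from clonaltraj.vartraj import per_generation_maf, trajectory_filter

    passing = [
        t.locus_id
        for t in per_generation_maf(c.genotypes)
        if t.defined and trajectory_filter(t).passes
    ]
    geno = c.genotypes.subset_loci(passing)
    pairs, _ = map_loci_to_genes(geno, c.annotation)
    records, _ = associate_pairs(geno, presence_filter(c.gene_expr), pairs)
    loci, genes = select_candidates(records, 0.01)
    truth = c.truth_loci[c.truth_loci.eqtl_gene != ""]
    assert set(loci) == set(truth.locus_id)
    assert set(genes) == set(truth.eqtl_gene)


def test_planted_concordant_pairs_exactly_recovered(noise_free_cohort):
    c = noise_free_cohort
    out, skipped = mirna_target_concordance(
        presence_filter(c.mirna_expr, 1.0),
        presence_filter(c.gene_expr),
        c.pairs,
        mode="same",
    )
    assert not skipped
    found = {(p.mirna_id, p.gene_id) for p in out if p.concordant}
    truth = c.truth_pairs[c.truth_pairs.planted_concordant]
    assert found == set(zip(truth.mirna_id, truth.gene_id))
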