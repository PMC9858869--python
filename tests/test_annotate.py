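"""Variant effect classification and GO enrichment."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom

from divscan import annotate as ann


class FakeFasta(dict):
    pass


@pytest.fixture(scope="module")
def toy_genome(tmp_path_factory):
    """A 400 bp chromosome with one plus-strand gene:

    gene   [101, 200]
    exon1  [101, 140] = 5'UTR [101,110] + CDS [111,140]
    intron [141, 160]
    exon2  [161, 200] = CDS [161,169] + 3'UTR [170,200]

    CDS (39 bp, in frame): ATG GCA TAA is planted at codons 1-3; the
    rest of the CDS is a neutral filler with a TAA stop at the end.
    """
    seq = list("A" * 400)
    filler = "ATGGCATAATGGCTACTGGCAGCTATTGCA"  # 30 bp, codons 1-10
    seq[110:140] = filler
    seq[160:169] = "GCTGCTTAA"  # codons 11-13, ends with stop
    # distinct bases elsewhere so flanks are not all-A
    genome = FakeFasta(chr1="".join(seq), chr2="C" * 400)
    gff = tmp_path_factory.mktemp("gff") / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
        "chr1\ttest\tmRNA\t101\t200\t.\t+\t.\tID=geneA.t1;Parent=geneA\n"
        "chr1\ttest\texon\t101\t140\t.\t+\t.\tParent=geneA.t1\n"
        "chr1\ttest\texon\t161\t200\t.\t+\t.\tParent=geneA.t1\n"
        "chr1\ttest\tfive_prime_UTR\t101\t110\t.\t+\t.\tParent=geneA.t1\n"
        "chr1\ttest\tCDS\t111\t140\t.\t+\t0\tID=geneA.c;Parent=geneA.t1\n"
        "chr1\ttest\tCDS\t161\t169\t.\t+\t0\tID=geneA.c;Parent=geneA.t1\n"
        "chr1\ttest\tthree_prime_UTR\t170\t200\t.\t+\t.\tParent=geneA.t1\n"
        "chr1\ttest\tgene\t350\t380\t.\t-\t.\tID=geneB\n"
        "chr1\ttest\tmRNA\t350\t380\t.\t-\t.\tID=geneB.t1;Parent=geneB\n"
        "chr1\ttest\texon\t350\t380\t.\t-\t.\tParent=geneB.t1\n"
        "chr1\ttest\tCDS\t350\t380\t.\t-\t.\tID=geneB.c;Parent=geneB.t1\n"
    )
    return genome, gff


@pytest.fixture(scope="module")
def annotator(toy_genome):
    genome, gff = toy_genome
    return ann.Annotator(gff, genome, updown_dist=50)


class TestClassifyVariant:
    def test_synonymous_stop_change(self, annotator, toy_genome):
        # codon 3 is TAA at 117-119; TAA->TAG is a synonymous stop
        genome, _ = toy_genome
        assert genome["chr1"][116:119] == "TAA"
        eff = annotator.classify("chr1", 119, "A", "G")
        assert eff.category == "synonymous_variant"

    def test_missense_ala_to_thr(self, annotator, toy_genome):
        # codon 2 is GCA at 114-116; G->A gives ACA (Ala->Thr)
        genome, _ = toy_genome
        assert genome["chr1"][113:116] == "GCA"
        eff = annotator.classify("chr1", 114, "G", "A")
        assert eff.category == "missense_variant"

    def test_start_lost_is_loss_of_function(self, annotator):
        eff = annotator.classify("chr1", 111, "A", "G")
        assert eff.category == "loss_of_function"
        assert eff.detail == "start_lost"

    def test_stop_gained_is_loss_of_function(self, annotator, toy_genome):
        # codon 4 TGG (Trp) at 120-122; TGG->TGA is stop-gained
        genome, _ = toy_genome
        assert genome["chr1"][119:122] == "TGG"
        eff = annotator.classify("chr1", 122, "G", "A")
        assert eff.category == "loss_of_function"
        assert eff.detail == "stop_gained"

    def test_splice_donor_and_region(self, annotator):
        assert annotator.classify("chr1", 141, "A", "G").category == "loss_of_function"
        assert annotator.classify("chr1", 142, "A", "G").category == "loss_of_function"
        assert (
            annotator.classify("chr1", 144, "A", "G").category
            == "splice_region_intron_variant"
        )
        assert annotator.classify("chr1", 150, "A", "G").category == "intron_variant"

    def test_utrs(self, annotator):
        assert annotator.classify("chr1", 105, "A", "G").category == "5'UTR"
        assert annotator.classify("chr1", 185, "A", "G").category == "3'UTR"

    def test_upstream_downstream_strand_aware(self, annotator):
        # 30 bp left of the plus-strand gene span: upstream
        assert (
            annotator.classify("chr1", 80, "A", "G").category
            == "upstream_gene_variant"
        )
        # 20 bp right of it: downstream
        assert (
            annotator.classify("chr1", 220, "A", "G").category
            == "downstream_gene_variant"
        )
        # right of the minus-strand gene: upstream for that gene
        eff = annotator.classify("chr1", 390, "A", "G")
        assert eff.category == "upstream_gene_variant"
        assert eff.gene_id == "geneB"

    def test_intergenic_beyond_updown_distance(self, annotator):
        assert (
            annotator.classify("chr1", 290, "A", "G").category
            == "intergenic_region"
        )

    def test_reference_mismatch_raises(self, annotator):
        with pytest.raises(ValueError, match="mismatch"):
            annotator.classify("chr1", 105, "T", "G")

    def test_broken_cds_skips_coding_effects(self, annotator):
        # geneB's CDS is 31 bp (not divisible by 3)
        with pytest.warns(UserWarning, match="divisible"):
            eff = annotator.classify("chr1", 360, "A", "G")
        assert eff.category == "intron_variant"

    def test_minus_strand_codon_logic(self, toy_genome, tmp_path):
        genome = FakeFasta(chr1="A" * 100)
        seq = list(genome["chr1"])
        # minus-strand CDS [41,49]: genomic reverse complement must
        # begin ATG and end TAA => genomic = TTA ... CAT
        seq[40:49] = "TTAGGCCAT"
        genome["chr1"] = "".join(seq)
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t41\t49\t.\t-\t.\tID=g\n"
            "chr1\tt\tmRNA\t41\t49\t.\t-\t.\tID=g.t;Parent=g\n"
            "chr1\tt\texon\t41\t49\t.\t-\t.\tParent=g.t\n"
            "chr1\tt\tCDS\t41\t49\t.\t-\t0\tID=g.c;Parent=g.t\n"
        )
        an = ann.Annotator(gff, genome)
        # codon 2 is GGC->GCC reading on the minus strand; genomic 45 G->G?
        # middle codon genomic [44,46] = "GGC" reversed-complement "GCC" (Ala)
        # change genomic 45 G->T: codon GTC revcomp -> GAC (Asp): missense
        eff = an.classify("chr1", 45, "G", "T")
        assert eff.category == "missense_variant"
        # start codon: genomic 49 ("T" of CAT) is the A of ATG... change
        # genomic 47 C->T makes revcomp codon1 ATG->ATA: start lost
        eff = an.classify("chr1", 47, "C", "T")
        assert eff.category == "loss_of_function"


class TestAssignGene:
    def test_containing_gene_wins(self, annotator):
        assert annotator.assign_gene("chr1", 150) == "geneA"

    def test_tie_broken_by_lower_start(self, toy_genome, tmp_path):
        genome = FakeFasta(chr1="A" * 1000)
        gff = tmp_path / "tie.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t100\t200\t.\t+\t.\tID=gA\n"
            "chr1\tt\tgene\t800\t900\t.\t+\t.\tID=gB\n"
        )
        an = ann.Annotator(gff, genome)
        assert an.assign_gene("chr1", 500) == "gA"  # equidistant

    def test_no_genes_returns_none(self, annotator):
        assert annotator.assign_gene("chr2", 10) is None

    def test_matches_brute_force_scan(self, annotator):
        genes = {"geneA": (101, 200), "geneB": (350, 380)}
        rng = np.random.default_rng(0)
        for pos in rng.integers(1, 400, size=20):
            def dist(span):
                s, e = span
                return 0 if s <= pos <= e else min(abs(pos - s), abs(pos - e))
            want = min(genes, key=lambda g: (dist(genes[g]), genes[g][0]))
            assert annotator.assign_gene("chr1", int(pos)) == want


class TestGoEnrichment:
    def test_hypergeometric_tail_example(self):
        """Background 20 genes, 5 with the term; study of 5 with 3."""
        bg = [f"g{i}" for i in range(20)]
        go = {g: {"GO:X"} if i < 5 else set() for i, g in enumerate(bg)}
        study = bg[:3] + bg[10:12]
        rows = ann.go_enrichment(study, bg, go)
        want = Fraction(1126, 15504)
        assert rows[0].p_value == pytest.approx(float(want), abs=1e-12)

    def test_study_equals_background_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        go = {g: {"GO:A"} for g in bg}
        rows = ann.go_enrichment(bg, bg, go)
        assert all(r.p_value == pytest.approx(1.0) for r in rows)

    def test_classic_matches_scipy_hypergeom(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            N = int(rng.integers(10, 40))
            bg = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            go = {g: ({"GO:T"} if i < K else set()) for i, g in enumerate(bg)}
            study = list(rng.choice(bg, size=n, replace=False))
            rows = [r for r in ann.go_enrichment(study, bg, go) if r.go_id == "GO:T"]
            k = len([g for g in study if g in bg[:K]])
            assert rows[0].p_value == pytest.approx(
                float(hypergeom.sf(k - 1, N, K, n)), abs=1e-12
            )

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(20):
            bg = [f"g{i}" for i in range(60)]
            terms = {f"GO:{t}" for t in range(6)}
            go = {g: set(rng.choice(sorted(terms), size=2, replace=False)) for g in bg}
            target = [g for g in bg if "GO:0" in go[g]]
            others = [g for g in bg if g not in target]
            study = target[:8] + others[:4]
            rows = ann.go_enrichment(study, bg, go)
            hits += rows[0].go_id == "GO:0"
        assert hits >= 18

    def test_elim_removes_child_genes_from_parent(self):
        bg = [f"g{i}" for i in range(30)]
        child_genes = set(bg[:8])
        go = {g: ({"GO:child"} if g in child_genes else {"GO:other"}) for g in bg}
        parents = {"GO:child": {"GO:parent"}, "GO:other": {"GO:parent"}}
        study = bg[:8]  # perfectly the child term
        classic = {r.go_id: r for r in ann.go_enrichment(study, bg, go, "classic", parents=parents)}
        elim = {r.go_id: r for r in ann.go_enrichment(study, bg, go, "elim", parents=parents)}
        assert classic["GO:parent"].p_value == pytest.approx(1.0)  # all genes have it
        # elim removes the significant child's genes before testing the parent
        assert elim["GO:child"].p_value == classic["GO:child"].p_value
        assert elim["GO:parent"].n_bg_with < classic["GO:parent"].n_bg_with

    def test_empty_study_warns(self):
        with pytest.warns(UserWarning):
            assert ann.go_enrichment([], ["g1"], {"g1": {"GO:A"}}) == []

    def test_study_outside_background_rejected(self):
        with pytest.raises(ValueError):
            ann.go_enrichment(["x"], ["g1"], {})


class TestTabulateEffects:
    def test_category_metadata_mapping(self):
        # coding categories are within-gene and transcribed; UTR/intron
        # within-gene but untranscribed... (untranslated/intronic)
        assert ann.CATEGORIES["synonymous_variant"] == (True, True)
        assert ann.CATEGORIES["intron_variant"] == (True, False)
        assert ann.CATEGORIES["3'UTR"] == (True, False)
        assert ann.CATEGORIES["intergenic_region"] == (False, False)
        assert ann.CATEGORIES["upstream_gene_variant"] == (False, False)

    def test_proportions_sum_to_one(self):
        effects = [
            ann.VariantEffect("intron_variant", "g1"),
            ann.VariantEffect("missense_variant", "g1"),
            ann.VariantEffect("intergenic_region", None),
        ]
        tab = ann.tabulate_effects(effects, [True, False, False])
        assert tab["highly_divergent_prop"].sum() == pytest.approx(1.0)
        assert tab["diagnostic_prop"].sum() == pytest.approx(1.0)

    def test_empty_diagnostic_column_is_zero(self):
        effects = [ann.VariantEffect("intron_variant", "g")]
        tab = ann.tabulate_effects(effects, [False])
        assert tab["diagnostic"].sum() == 0

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            ann.VariantEffect("weird", None)
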