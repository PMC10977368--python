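"""In-silico PCR product prediction and qPCR normalization."""

import numpy as np
import pytest

from skipdesign.gene_model import reverse_complement, spliced_sequence, simulate_exon_skip
from skipdesign.insilico_assay import (
    AssayError,
    PrimerPair,
    parse_primer_pairs,
    pcr_products,
    qpcr_relative,
    virtual_gel,
)
from skipdesign.synthetic_data import (
    IGFBP1_INNER_PRIMERS,
    IGFBP1_OUTER_PRIMERS,
    IGFBP1_PRODUCTS,
    IGFBP3_INNER_PRIMERS,
    IGFBP3_OUTER_PRIMERS,
    IGFBP3_PRODUCTS,
    FixtureSpec,
    make_toy_gene,
)


def _toy_template(rng, length=200):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestPcrProducts:
    def test_single_product_length_from_site_coordinates(self):
        rng = np.random.default_rng(0)
        tpl = _toy_template(rng)
        fwd = tpl[0:20]
        rev = reverse_complement(tpl[100:120])
        products = pcr_products(tpl, PrimerPair(fwd, rev))
        assert len(products) == 1
        assert products[0].length == 120
        assert (products[0].start, products[0].end) == (0, 120)

    def test_nested_inner_product_contained_and_shorter(self):
        rng = np.random.default_rng(1)
        tpl = _toy_template(rng)
        outer = PrimerPair(tpl[0:15], reverse_complement(tpl[160:175]))
        inner = PrimerPair(tpl[30:45], reverse_complement(tpl[120:135]))
        products = pcr_products(tpl, outer, inner)
        outer_prods = [p for p in products if p.round == "outer"]
        inner_prods = [p for p in products if p.round == "inner"]
        assert len(outer_prods) == 1 and len(inner_prods) == 1
        o, i = outer_prods[0], inner_prods[0]
        assert o.start <= i.start < i.end <= o.end
        assert i.length < o.length

    def test_no_site_gives_empty_list(self):
        products = pcr_products("ACGT" * 30, PrimerPair("G" * 15, "C" * 15))
        assert products == []

    def test_multiple_sites_reported_with_warning_flag(self):
        rng = np.random.default_rng(2)
        core = _toy_template(rng, 60)
        tpl = core + core  # duplicated forward site
        fwd = core[0:15]
        rev = reverse_complement(tpl[100:115])
        products = pcr_products(tpl, PrimerPair(fwd, rev))
        assert len(products) >= 2
        assert all(p.multi_site for p in products)

    def test_short_primer_rejected(self):
        with pytest.raises(AssayError, match="10"):
            PrimerPair("ACGTACG", "ACGTACGTACGT")

    @pytest.mark.parametrize(
        "fixture_name,inner,outer,sizes",
        [
            ("igfbp1-like", IGFBP1_INNER_PRIMERS, IGFBP1_OUTER_PRIMERS, IGFBP1_PRODUCTS),
            ("igfbp3-like", IGFBP3_INNER_PRIMERS, IGFBP3_OUTER_PRIMERS, IGFBP3_PRODUCTS),
        ],
    )
    def test_paperlike_band_sizes_differ_by_exon_length(
        self, request, fixture_name, inner, outer, sizes
    ):
        gene = request.getfixturevalue(
            "igfbp1_fixture" if fixture_name == "igfbp1-like" else "igfbp3_fixture"
        )
        t = gene.transcript()
        genome = gene.genome()
        wt = spliced_sequence(t, genome)
        skip = simulate_exon_skip(t, 2, genome).mrna
        outer_pair = PrimerPair(*outer, label="outer")
        inner_pair = PrimerPair(*inner, label="inner")
        wt_inner = [
            p for p in pcr_products(wt, outer_pair, inner_pair) if p.round == "inner"
        ]
        sk_inner = [
            p for p in pcr_products(skip, outer_pair, inner_pair) if p.round == "inner"
        ]
        assert [p.length for p in wt_inner] == [sizes["wt_inner"]]
        assert [p.length for p in sk_inner] == [sizes["skip_inner"]]
        exon_len = len(t.exons[1])
        assert sizes["wt_inner"] - sizes["skip_inner"] == exon_len

    def test_size_difference_equals_exon_length_on_random_fixtures(self):
        for seed in (21, 22, 23):
            gene = make_toy_gene(
                FixtureSpec(
                    seed=seed,
                    exon_lengths=(120, 70, 120, 60),
                    primers=None,
                )
            )
            t = gene.transcript()
            genome = gene.genome()
            wt = spliced_sequence(t, genome)
            skip = simulate_exon_skip(t, 2, genome).mrna
            pair = PrimerPair(wt[5:25], reverse_complement(wt[-40:-20]))
            wt_p = pcr_products(wt, pair)
            sk_p = pcr_products(skip, pair)
            assert len(wt_p) == 1 and len(sk_p) == 1
            assert wt_p[0].length - sk_p[0].length == 70

    def test_virtual_gel_sorted_by_size(self, igfbp1_fixture):
        t = igfbp1_fixture.transcript()
        wt = spliced_sequence(t, igfbp1_fixture.genome())
        products = pcr_products(
            wt,
            PrimerPair(*IGFBP1_OUTER_PRIMERS),
            PrimerPair(*IGFBP1_INNER_PRIMERS),
        )
        gel = virtual_gel(products)
        lengths = [int(ln.split()[0]) for ln in gel.splitlines()]
        assert lengths == sorted(lengths, reverse=True)


class TestQpcrRelative:
    def test_equal_cq_gives_unit_ratio(self):
        assert qpcr_relative(20, {"ref": 20}) == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles_expression(self):
        assert qpcr_relative(19, {"ref": 20}) == pytest.approx(2.0)

    def test_two_references_use_geometric_mean(self):
        # geometric mean of 2^-20 and 2^-22 equals 2^-21
        assert qpcr_relative(21, {"r1": 20, "r2": 22}) == pytest.approx(1.0)

    def test_scale_invariant_under_constant_cq_shift(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t_cq = float(rng.uniform(15, 30))
            refs = {"a": float(rng.uniform(15, 30)), "b": float(rng.uniform(15, 30))}
            shift = float(rng.uniform(-3, 3))
            shifted = {k: v + shift for k, v in refs.items()}
            assert qpcr_relative(t_cq, refs) == pytest.approx(
                qpcr_relative(t_cq + shift, shifted)
            )

    def test_replicates_averaged(self):
        assert qpcr_relative([19, 21], {"ref": [20, 20]}) == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(AssayError):
            qpcr_relative(20, {})

    def test_efficiency_bounds_enforced(self):
        with pytest.raises(AssayError):
            qpcr_relative(20, {"ref": 20}, e_target=2.5)

    def test_calibrator_normalization(self):
        ratio = qpcr_relative(
            19, {"ref": 20},
            calibrator_target_cq=20, calibrator_reference_cqs={"ref": 20},
        )
        assert ratio == pytest.approx(2.0)


class TestPrimerParsing:
    def test_two_column_text(self):
        pairs = parse_primer_pairs("ACGTACGTACGT\tTGCATGCATGCA\tmy_pair\n")
        assert pairs[0].label == "my_pair"

    def test_fasta_pairs(self):
        text = ">p1_f\nACGTACGTACGT\n>p1_r\nTGCATGCATGCA\n"
        pairs = parse_primer_pairs(text)
        assert pairs[0].forward == "ACGTACGTACGT"
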