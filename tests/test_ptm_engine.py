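"""Maturation rule engine: event bookkeeping, products, variants, digestion."""

import pytest
from hypothesis import given, settings, strategies as st

from bithionin.chem_core import WATER, monoisotopic_mass, ppm_error
from bithionin.ptm_engine import (
    EnzymeSet,
    MaturationError,
    ModificationEvent,
    PrecursorPeptide,
    apply_events,
    gluc_digest,
    kin_maturation,
    peptide_formula,
    processive_series,
    variant_predict,
)

CD = EnzymeSet.from_codes("C,D")
H2O = WATER.monoisotopic_mass()


class TestPeptideFormula:
    def test_diglycine(self):
        p = PrecursorPeptide(core="GG")
        f = peptide_formula(p)
        assert f.hill() == "C4H8N2O3"
        assert f.monoisotopic_mass() == pytest.approx(132.05349, abs=1e-5)

    def test_single_glycine(self):
        f = peptide_formula(PrecursorPeptide(core="G"))
        assert f.hill() == "C2H5NO2"
        assert f.monoisotopic_mass() == pytest.approx(75.03203, abs=1e-5)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            peptide_formula(PrecursorPeptide(core="GG"), (5, 4))

    def test_mature_product_formula(self, product7):
        """Full maturation of the demo precursor closes the published formula."""
        assert product7.formula.hill() == "C115H174N28O31S2"
        assert round(product7.mz(3), 4) == 836.7520


class TestEventBookkeeping:
    def test_single_dehydration_mass_drop(self, kina):
        base = peptide_formula(kina).monoisotopic_mass()
        product = apply_events(kina, [ModificationEvent("dehydration", (8,))])
        assert base - product.mass == pytest.approx(18.010565, abs=1e-6)
        assert product.residues[8] == "Dha"

    def test_eleven_dehydrations_nominal_198(self, kina, product11):
        base = peptide_formula(kina)
        assert product11.n_dehydrations == 11
        assert base.nominal_mass() - product11.nominal_mass == 198

    def test_phosphorylation_plus_80(self, kina):
        base = peptide_formula(kina)
        product = apply_events(kina, [ModificationEvent("phosphorylation", (2,))])
        assert product.nominal_mass - base.nominal_mass() == 80
        assert product.mass - base.monoisotopic_mass() == pytest.approx(79.96633, abs=1e-5)
        assert product.residues[2] == "pT"

    def test_decarboxylation_delta(self, kina, product11):
        events = list(product11.events) + [
            ModificationEvent("oxidative_decarboxylation", (27,))]
        product = apply_events(kina, events)
        assert product11.mass - product.mass == pytest.approx(46.00548, abs=1e-5)

    def test_crosslink_is_massless(self, kina, product11):
        events = list(product11.events) + [
            ModificationEvent("oxidative_decarboxylation", (27,)),
            ModificationEvent("thioether_crosslink", (11, 22, 27))]
        with_decarb = apply_events(kina, events[:-1])
        with_link = apply_events(kina, events)
        assert with_link.mass == pytest.approx(with_decarb.mass, abs=1e-12)
        assert with_link.crosslinks == ((11, 22, 27),)
        assert with_link.residues[22] == "Abu"

    @pytest.mark.parametrize("kind,sites,message", [
        ("dehydration", (1,), "not Ser/Thr"),            # Ile-1
        ("oxidative_decarboxylation", (11,), "C-terminal"),
        ("reduction_to_dala", (2,), "not Dha"),
        ("thioether_crosslink", (11, 22, 27), "decarboxylation"),
    ])
    def test_illegal_pairings_rejected(self, kina, kind, sites, message):
        with pytest.raises(MaturationError, match=message):
            apply_events(kina, [ModificationEvent(kind, sites)])

    @given(st.sets(st.sampled_from([2, 3, 4, 6, 7, 8, 13, 16, 18, 20, 22]),
                   min_size=1, max_size=11))
    @settings(max_examples=50, deadline=None)
    def test_mass_bookkeeping_two_routes(self, sites):
        """Formula-from-deltas equals the per-residue recomputation."""
        p = PrecursorPeptide(core="ITTTVTSSEICVSLVSVSWTATGDSAC")
        events = [ModificationEvent("dehydration", (s,)) for s in sorted(sites)]
        product = apply_events(p, events)
        via_deltas = product.mass
        via_residues = sum(product.effective_composition(pos)[1]
                           for pos in product.positions) + H2O
        assert via_deltas == pytest.approx(via_residues, abs=1e-9)


class TestMaturation:
    def test_kinase_only_monophospho(self, kina):
        product = kin_maturation(kina, EnzymeSet.from_codes("D"))
        assert product.label == "10"
        assert product.residues[2] == "pT"
        assert product.n_dehydrations == 0

    def test_cd_fully_dehydrated(self, product11):
        assert product11.label == "11"
        assert product11.n_dehydrations == 11
        assert product11.residues[7] == "Aaa"
        assert product11.residues[25] == "S"       # retained Ser
        assert product11.residues[11] == "C"       # free thiol
        assert product11.crosslinks == ()

    def test_adding_one_cyclase_component_changes_nothing(self, kina, product11):
        for codes in ("C,D,H", "C,D,I"):
            product = kin_maturation(kina, EnzymeSet.from_codes(codes))
            assert product.formula == product11.formula

    def test_cdhi_cyclised(self, kina, product11):
        product = kin_maturation(kina, EnzymeSet.from_codes("C,D,H,I"))
        assert product.label == "12"
        assert product.crosslinks == ((11, 22, 27),)
        assert product11.mass - product.mass == pytest.approx(46.00548, abs=1e-5)
        # Dha-13/16/18 stay unreduced without the reductase
        assert all(product.residues[p] == "Dha" for p in (13, 16, 18))

    def test_full_pathway_product(self, product7):
        assert product7.label == "7"
        assert product7.segment == (1, 27)          # leader removed
        assert product7.d_ala_sites == (13, 16, 18)
        assert round(product7.mass, 4) == 2507.2341

    def test_demethylated_product(self, kina, product7):
        product8 = kin_maturation(kina, EnzymeSet.from_codes("C,D,H,I,J,EF"))
        assert product8.label == "8"
        assert product7.mass - product8.mass == pytest.approx(
            monoisotopic_mass({"C": 2, "H": 4}), abs=1e-9)

    def test_decarboxylase_less_shunt(self, kina):
        """Without KinI the linear shunt keeps its C-terminal Cys and 8
        dehydro residues (1 Dha + 1 Aaa + 6 Dhb)."""
        product9 = kin_maturation(kina, EnzymeSet.from_codes("C,D,J,EF,O"))
        assert product9.label == "9"
        assert product9.residues[27] == "C"
        codes = [product9.residues[p] for p in product9.dehydro_residues]
        assert len(codes) == 8
        assert codes.count("Dha") == 1 and codes.count("Aaa") == 1
        assert codes.count("Dhb") == 6
        assert product9.d_ala_sites == (13, 16, 18)

    def test_inconsistent_set_rejected(self):
        with pytest.raises(MaturationError, match="KinC requires KinD"):
            EnzymeSet.from_codes("C")

    def test_motif_less_core_rejected(self):
        with pytest.raises(MaturationError, match="signature motif"):
            kin_maturation(PrecursorPeptide(core="GAVLGAVL"), CD)

    def test_dl_ala_ratio(self, product7):
        """3 d-Ala from Ser + 2 genetically encoded l-Ala: d:l = 3:2."""
        d = len(product7.d_ala_sites)
        l = sum(1 for p in product7.positions if product7.genetic(p) == "A")
        assert (d, l) == (3, 2)


class TestVariants:
    def test_single_ala_substitutions_inert(self, kina, product11):
        # Thr->Ala: Dhb(83) vs Ala(71) = 12; Ser->Ala: Dha(69) vs Ala(71) = -2
        for pos, delta in [(2, 12), (3, 12), (4, 12), (6, 12), (8, -2)]:
            (product,) = variant_predict(kina, {pos: "A"}, CD)
            assert product.n_dehydrations == 10
            assert product11.nominal_mass - product.nominal_mass == delta

    def test_t2a_exact_12(self, kina, product11):
        (product,) = variant_predict(kina, {2: "A"}, CD)
        assert product11.nominal_mass - product.nominal_mass == 12

    def test_s7t_methyl_aaa_plus_14(self, kina, product11):
        (product,) = variant_predict(kina, {7: "T"}, CD)
        assert product.nominal_mass - product11.nominal_mass == 14
        assert product.residues[7] == "mAaa"

    def test_ttoa_dual_products(self, kina):
        products = variant_predict(kina, {2: "A", 3: "A", 4: "A", 6: "A"}, CD)
        assert len(products) == 2
        full, partial = products
        assert partial.mass - full.mass == pytest.approx(18.010565, abs=1e-6)
        assert full.n_dehydrations == 7 and partial.n_dehydrations == 6
        assert partial.residues[7] == "S"          # Ser-7 retained
        assert [p.ratio for p in products] == [0.5, 0.5]

    def test_c11a_suppresses_cyclisation(self, kina):
        (product,) = variant_predict(
            kina, {11: "A"}, EnzymeSet.from_codes("C,D,H,I"))
        assert product.crosslinks == ()
        assert product.n_dehydrations == 11
        assert all(e.kind != "oxidative_decarboxylation" for e in product.events)

    def test_unknown_target_rejected(self, kina):
        with pytest.raises(MaturationError):
            variant_predict(kina, {99: "A"}, CD)


class TestGluCDigest:
    def test_unmodified_two_fragments(self, kina):
        product = apply_events(kina, [])
        frags = gluc_digest(product, accessible_sites=[-6, 9])
        spans = [(f.start, f.end) for f in frags]
        assert (-5, 9) in spans and (10, 27) in spans

    def test_monophospho_fragment_plus_phosphate(self, kina):
        plain = apply_events(kina, [])
        phospho = kin_maturation(kina, EnzymeSet.from_codes("D"))
        frag = next(f for f in gluc_digest(plain, [-6, 9]) if f.start == -5)
        frag_p = next(f for f in gluc_digest(phospho, [-6, 9]) if f.start == -5)
        assert frag_p.mass - frag.mass == pytest.approx(79.96633, abs=1e-5)
        assert round(frag_p.mz(2), 4) == pytest.approx(730.3133, abs=0.004)

    def test_dehydrated_core_fragment_ion(self, kina, product11):
        """GluC release of the dehydrated core (+5 leader residues) gives
        the reported doubly protonated ion within 5 ppm."""
        frag = next(f for f in gluc_digest(product11, [-6]) if f.start == -5)
        assert abs(ppm_error(frag.mz(2), 1481.1782)) < 5.0

    def test_disulfide_fragment(self, kina):
        """The C-terminal 18-mer, internally hydrolysed and disulfide-bridged,
        reproduces the reported ion to 4 decimals."""
        f = peptide_formula(kina, (10, 27))
        mass = f.monoisotopic_mass() + H2O - monoisotopic_mass({"H": 2})
        from bithionin.chem_core import mz_of_ion
        assert round(mz_of_ion(mass, 2), 4) == 907.9186

    def test_no_sites_single_fragment(self, kina):
        product = apply_events(kina, [])
        frags = gluc_digest(product, accessible_sites=[])
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (-30, 27)

    def test_non_glu_site_rejected(self, kina):
        with pytest.raises(MaturationError, match="not C-terminal to Glu"):
            gluc_digest(apply_events(kina, []), accessible_sites=[10])


class TestProcessiveSeries:
    def test_series_structure(self, kina, product11):
        series = processive_series(kina)
        assert len(series) == 22                     # 2 x 11 dehydratable sites
        assert series[0].residues[2] == "pT"         # starts at Thr-2
        assert series[-1].formula == product11.formula
        hpo3 = monoisotopic_mass({"H": 1, "P": 1, "O": 3})
        h3po4 = monoisotopic_mass({"H": 3, "P": 1, "O": 4})
        prior_mass = peptide_formula(kina).monoisotopic_mass()
        for phospho, eliminated in zip(series[0::2], series[1::2]):
            assert phospho.mass - prior_mass == pytest.approx(hpo3, abs=1e-9)
            assert phospho.mass - eliminated.mass == pytest.approx(h3po4, abs=1e-9)
            prior_mass = eliminated.mass


def test_fasta_round_trip(tmp_path, kina):
    path = tmp_path / "prec.faa"
    path.write_text(f">{kina.name} leader_len={len(kina.leader)}\n"
                    f"{kina.leader}{kina.core}\n")
    (loaded,) = PrecursorPeptide.from_fasta(path)
    assert (loaded.leader, loaded.core) == (kina.leader, kina.core)
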