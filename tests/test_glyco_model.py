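"""Glycan composition parsing, mass arithmetic and target-list bookkeeping."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hpglyco import masses
from hpglyco.glyco_model import (
    SITES,
    TABLE1_TRANSCRIPTION,
    GlycanClass,
    GlycanComposition,
    build_target_list,
    classify_glycan,
    glycan_mass,
    parse_glycan_code,
    precursor_mz,
    site_overlap_counts,
    y_ion_series,
)
from hpglyco.glyco_model import GlycanParseError, quantifier_fragments


@pytest.mark.parametrize(
    "code, expected",
    [
        ("5-6-1-3", (5, 6, 1, 3)),
        ("0-0-0-0", (0, 0, 0, 0)),
        ("4-5-0-2", (4, 5, 0, 2)),
    ],
)
def test_parse_glycan_code(code, expected):
    comp = parse_glycan_code(code)
    assert (comp.hexnac, comp.hex, comp.fuc, comp.neuac) == expected
    assert str(comp) == code


@pytest.mark.parametrize("bad", ["5-6-1", "5-6-1-3-2", "a-1-1-1", "1--1-1", "-1-1-1-1"])
def test_parse_glycan_code_rejects_malformed(bad):
    with pytest.raises(GlycanParseError):
        parse_glycan_code(bad)


@given(st.tuples(*(st.integers(0, 12),) * 4))
def test_parse_format_round_trip(counts):
    comp = GlycanComposition(*counts)
    assert parse_glycan_code(str(comp)) == comp


def test_glycan_mass_matches_residue_sum_oracle():
    # independent oracle: explicit sum over standard monosaccharide residue masses
    for counts in [(5, 6, 0, 3), (5, 6, 0, 2), (4, 5, 1, 2), (0, 0, 0, 0)]:
        comp = GlycanComposition(*counts)
        oracle = (
            counts[0] * 203.079373
            + counts[1] * 162.052824
            + counts[2] * 146.057909
            + counts[3] * 291.095417
        )
        assert glycan_mass(comp) == pytest.approx(oracle, abs=1e-9)
    assert glycan_mass(GlycanComposition(5, 6, 0, 3)) == pytest.approx(2861.0000, abs=1e-3)
    assert glycan_mass(GlycanComposition(5, 6, 0, 2)) == pytest.approx(2569.9046, abs=1e-3)


def test_glycan_mass_monotone_in_every_monosaccharide():
    base = GlycanComposition(2, 3, 0, 0)
    m0 = glycan_mass(base)
    for bump in [(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)]:
        bumped = GlycanComposition(*(c + b for c, b in zip((2, 3, 0, 0), bump)))
        assert glycan_mass(bumped) > m0


def test_site_peptide_masses_are_residue_sums():
    for site in SITES.values():
        oracle = sum(masses.RESIDUE_MASSES[aa] for aa in site.peptide_sequence) + masses.WATER
        assert site.peptide_monoisotopic_mass == pytest.approx(oracle, abs=1e-4)


@pytest.mark.parametrize(
    "code, charge, printed, tol",
    [
        ("5-6-0-3", 3, 1278.8295, 5e-5),   # triply sialylated glycoform
        ("5-6-0-2", 3, 1181.7977, 1e-3),   # doubly sialylated glycoform
        ("0-0-0-0", 1, 973.4738, 5e-5),    # bare peptide, residue-sum oracle
    ],
)
def test_precursor_mz_reproduces_printed_values(code, charge, printed, tol):
    site = SITES["Asn207"]
    assert precursor_mz(site, parse_glycan_code(code), charge) == pytest.approx(printed, abs=tol)


def test_precursor_mz_rejects_nonpositive_charge():
    with pytest.raises(ValueError):
        precursor_mz(SITES["Asn207"], parse_glycan_code("5-6-0-3"), 0)


@given(
    st.sampled_from(list(SITES)),
    st.tuples(st.integers(0, 8), st.integers(0, 9), st.integers(0, 2), st.integers(0, 4)),
    st.integers(1, 5),
)
def test_precursor_mass_additivity(site_id, counts, charge):
    site = SITES[site_id]
    comp = GlycanComposition(*counts)
    mz = precursor_mz(site, comp, charge)
    neutral = charge * mz - charge * masses.PROTON
    expected = site.peptide_monoisotopic_mass + glycan_mass(comp)
    assert neutral == pytest.approx(expected, rel=1e-6)


class TestYIonSeries:
    def test_six_quantifiers_match_printed_fragment_set_within_10ppm(self):
        printed = [1176.5498, 1379.6283, 1541.6814, 1703.7339, 1865.7873, 2230.9204]
        frags = quantifier_fragments(SITES["Asn207"], parse_glycan_code("5-6-0-3"))
        assert len(frags) == 6
        for ours, ref in zip(frags, printed):
            assert abs(ours - ref) / ref * 1e6 < 10

    def test_printed_y1_ions_of_all_three_sites_within_10ppm(self):
        printed = {"Asn184": 1940.9333, "Asn207": 1176.5484, "Asn241": 1998.0920}
        for site_id, ref in printed.items():
            y1 = next(
                ion.mz
                for ion in y_ion_series(SITES[site_id], parse_glycan_code("5-6-0-2"))
                if ion.label == "Y1"
            )
            assert abs(y1 - ref) / ref * 1e6 < 10

    def test_ladder_steps_are_monosaccharide_residue_masses(self):
        frags = quantifier_fragments(SITES["Asn207"], parse_glycan_code("5-6-0-3"))
        diffs = [b - a for a, b in itertools.pairwise(frags)]
        expected = [masses.HEXNAC, masses.HEX, masses.HEX, masses.HEX, masses.HEXNAC + masses.HEX]
        assert diffs == pytest.approx(expected, abs=1e-9)

    def test_bare_peptide_yields_y0_only(self):
        ions = y_ion_series(SITES["Asn184"], parse_glycan_code("0-0-0-0"))
        ladder = [i for i in ions if i.label.startswith("Y")]
        assert [i.label for i in ladder] == ["Y0"]
        assert not any(i.quantifier for i in ions)

    def test_short_composition_truncates_ladder(self):
        ions = y_ion_series(SITES["Asn207"], parse_glycan_code("2-1-0-0"))
        labels = [i.label for i in ions if i.label.startswith("Y")]
        assert labels == ["Y0", "Y1", "Y1+HexNAc", "Y1+HexNAc+Hex"]

    def test_oxonium_ions_flagged_non_quantifier(self):
        ions = y_ion_series(SITES["Asn207"], parse_glycan_code("5-6-0-3"))
        oxonium = [i for i in ions if not i.label.startswith("Y")]
        assert {i.label for i in oxonium} == {"HexNAc+", "HexNAc+-H2O", "Neu5Ac+", "Neu5Ac+-H2O"}
        assert not any(i.quantifier for i in oxonium)


@pytest.mark.parametrize(
    "code, expected",
    [
        ("5-6-0-3", GlycanClass.SIALYLATED),
        ("5-6-1-3", GlycanClass.SIALYLATED_FUCOSYLATED),
        ("4-5-0-0", GlycanClass.OTHER),
        ("4-5-1-0", GlycanClass.OTHER),  # fucosylated but not sialylated
    ],
)
def test_classify_glycan(code, expected):
    assert classify_glycan(parse_glycan_code(code)) == expected


class TestTargetList:
    def test_packaged_table_counts(self, targets):
        assert len(targets) == 72
        per_site = {s: [t for t in targets if t.site.site_id == s] for s in SITES}
        assert len(per_site["Asn184"]) == 13
        assert len({t.composition for t in per_site["Asn184"]}) == 11
        assert len(per_site["Asn241"]) == 16
        assert len({t.composition for t in per_site["Asn241"]}) == 12

    def test_charge_rule(self, targets):
        for t in targets:
            tri_antennary_sialylated = t.composition.hexnac - 2 >= 3 and t.composition.neuac >= 1
            if t.site.site_id == "Asn241" and tri_antennary_sialylated:
                assert t.charge == 4
            else:
                assert t.charge == 3

    def test_isomers_ordered_by_rt_within_window(self, targets):
        by_form = {}
        for t in targets:
            by_form.setdefault(t.key, []).append(t)
        for entries in by_form.values():
            entries = sorted(entries, key=lambda t: t.isomer_index)
            rts = [t.expected_rt for t in entries]
            assert rts == sorted(rts)
            lo, hi = entries[0].site.elution_window
            assert all(lo <= rt <= hi for rt in rts)

    def test_unparseable_cell_reports_cell_text(self):
        with pytest.raises(ValueError, match="5-6-x-1"):
            build_target_list({"Asn207": ["5-6-x-1"]})


class TestSiteOverlaps:
    def test_packaged_overlap_counts(self, targets):
        counts = site_overlap_counts(targets)
        assert counts[("Asn184", "Asn207", "Asn241")] == 7
        assert counts[("Asn184", "Asn207")] == 10
        assert counts[("Asn207", "Asn241")] == 11
        assert counts[("Asn184", "Asn241")] == 7

    def test_single_site_gives_zero_overlaps(self, targets):
        only = [t for t in targets if t.site.site_id == "Asn207"]
        counts = site_overlap_counts(only)
        assert all(v == 0 for v in counts.values())

    @given(st.data())
    def test_matches_brute_force_set_oracle(self, targets, data):
        subset = data.draw(st.lists(st.sampled_from(targets), min_size=2, max_size=40))
        counts = site_overlap_counts(subset)
        comps = {s: {t.composition for t in subset if t.site.site_id == s} for s in SITES}
        for (a, b) in itertools.combinations(sorted(SITES), 2):
            brute = sum(1 for c in comps[a] if c in comps[b])
            assert counts[(a, b)] == brute
        brute_triple = sum(
            1 for c in comps["Asn184"] if c in comps["Asn207"] and c in comps["Asn241"]
        )
        assert counts[("Asn184", "Asn207", "Asn241")] == brute_triple
        triple = counts[("Asn184", "Asn207", "Asn241")]
        assert all(triple <= counts[pair] for pair in itertools.combinations(sorted(SITES), 2))
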