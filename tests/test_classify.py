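import numpy as np
import pytest

from barcodiv import classify as cl
from barcodiv import trees as tr
from barcodiv.classify import GmycCategory, Performance
from barcodiv.gmyc import EntityPartition
from barcodiv.haplotypes import HaplotypeSet, collapse_haplotypes

from conftest import make_dataset


def partition(assignment):
    return EntityPartition.from_assignment(assignment)


class TestAssessPerformance:
    def _haps(self, membership, haplotypes=None):
        hids = sorted({h for hs in membership.values() for h in hs})
        return HaplotypeSet(
            haplotypes=haplotypes or {h: "ACGT" for h in hids},
            membership={r: list(hs) for r, hs in membership.items()},
        )

    def test_shared_haplotype_marks_both_species(self):
        tree = tr.parse_newick("((H1:1,H2:1):1,H3:2);")
        haps = self._haps({"r1": ["H1"], "r2": ["H1"], "r3": ["H2"],
                           "r4": ["H3"]})
        species = {"r1": "Pseudophilotes baton", "r2": "Pseudophilotes panoptes",
                   "r3": "Pseudophilotes baton", "r4": "Lysandra albicans"}
        perf = cl.assess_performance(tree, haps, species)
        assert perf["Pseudophilotes baton"] is Performance.SHARED
        assert perf["Pseudophilotes panoptes"] is Performance.SHARED
        assert perf["Lysandra albicans"] is Performance.MONOPHYLETIC

    def test_singleton_haplotype_monophyletic_by_convention(self):
        tree = tr.parse_newick("((H1:1,H2:1):1,H3:2);")
        haps = self._haps({"r1": ["H1"], "r2": ["H2"], "r3": ["H3"]})
        species = {"r1": "A sp", "r2": "B sp", "r3": "C sp"}
        perf = cl.assess_performance(tree, haps, species)
        assert all(v is Performance.MONOPHYLETIC for v in perf.values())

    def test_paraphyletic_species_detected(self):
        # species A's haplotypes H1, H4 are separated by species B's clade
        tree = tr.parse_newick("(((H1:1,(H2:0.5,H3:0.5):0.5):1,H4:2):1,H5:3);")
        haps = self._haps({f"r{i}": [f"H{i}"] for i in range(1, 6)})
        species = {"r1": "A sp", "r4": "A sp", "r2": "B sp", "r3": "B sp",
                   "r5": "C sp"}
        perf = cl.assess_performance(tree, haps, species)
        assert perf["A sp"] is Performance.PARA_POLYPHYLETIC
        assert perf["B sp"] is Performance.MONOPHYLETIC

    def test_missing_species_label_raises(self):
        tree = tr.parse_newick("((H1:1,H2:1):1,H3:2);")
        haps = self._haps({"r1": ["H1"], "r2": ["H2"], "r3": ["H3"]})
        with pytest.raises(ValueError, match="no species"):
            cl.assess_performance(tree, haps, {"r1": "A sp", "r2": "B sp"})


class TestClassifyVsEntities:
    def test_all_single_entity_when_partition_matches_species(self):
        species = {f"r{i}": f"sp{i % 3}" for i in range(9)}
        cls = cl.classify_vs_entities(species, partition(species))
        assert all(c is GmycCategory.SINGLE_ENTITY
                   for c in cls.categories.values())
        assert cls.summary()["entity_surplus"] == 0

    def test_lumped_pair(self):
        species = {"r1": "A sp", "r2": "B sp"}
        cls = cl.classify_vs_entities(species, partition({"r1": "e1", "r2": "e1"}))
        assert cls.categories["A sp"] is GmycCategory.LUMPED
        assert cls.categories["B sp"] is GmycCategory.LUMPED

    def test_me_pure_vs_me_mixed(self):
        species = {"a1": "A sp", "a2": "A sp", "b1": "B sp", "b2": "B sp"}
        pure = cl.classify_vs_entities(
            species, partition({"a1": "e1", "a2": "e2", "b1": "e3", "b2": "e3"}))
        assert pure.categories["A sp"] is GmycCategory.ME_PURE
        # both species split across two shared entities -> both ME_MIXED
        mixed = cl.classify_vs_entities(
            species, partition({"a1": "e1", "a2": "e2", "b1": "e1", "b2": "e2"}))
        assert mixed.categories["A sp"] is GmycCategory.ME_MIXED
        assert mixed.categories["B sp"] is GmycCategory.ME_MIXED

    def test_missing_specimen_raises(self):
        with pytest.raises(ValueError, match="missing"):
            cl.classify_vs_entities({"r1": "A sp"}, partition({"r2": "e1"}))

    def test_continental_survey_worked_example(self):
        """A 299-species composition with 167 SE / 49 lumped / 65 ME-pure /
        18 ME-mixed and 363 entities reproduces the published percentage
        table (55.9 / 16.4 / 21.7 / 6.0; surplus 64 = 21.4%)."""
        species_of, assignment = build_survey_composition()
        cls = cl.classify_vs_entities(species_of, partition(assignment))
        s = cls.summary()
        assert s["species_count"] == 299
        assert s["entity_count"] == 363
        assert s["counts"] == {"single_entity": 167, "lumped": 49,
                               "me_pure": 65, "me_mixed": 18}
        assert s["percentages"]["single_entity"] == 55.9
        assert s["percentages"]["lumped"] == 16.4
        assert s["percentages"]["me_pure"] == 21.7
        assert s["percentages"]["me_mixed"] == 6.0
        assert s["me_total"] == 83
        assert s["entity_surplus"] == 64
        assert s["surplus_percentage"] == 21.4

    def test_category_counts_sum_to_species_count(self):
        rng = np.random.default_rng(3)
        species = {f"r{i}": f"sp{rng.integers(0, 12)}" for i in range(60)}
        assign = {r: f"e{rng.integers(0, 20)}" for r in species}
        cls = cl.classify_vs_entities(species, partition(assign))
        s = cls.summary()
        assert sum(s["counts"].values()) == s["species_count"]

    def test_invariant_to_entity_relabelling(self):
        species = {f"r{i}": f"sp{i % 4}" for i in range(16)}
        assign = {r: f"e{i % 6}" for i, r in enumerate(species)}
        relabel = {e: f"z{e}" for e in set(assign.values())}
        a = cl.classify_vs_entities(species, partition(assign)).categories
        b = cl.classify_vs_entities(
            species, partition({r: relabel[e] for r, e in assign.items()})
        ).categories
        assert a == b


class TestDistancesAndSympatry:
    def test_min_interentity_distance_floor(self):
        # closest cross pair differs at 2 of 658 sites -> 0.3%
        base = "A" * 658
        two_diff = "T" * 2 + "A" * 656
        ds = make_dataset(
            {"r1": base, "r2": two_diff, "r3": "T" * 10 + "A" * 648},
            species={k: "Melitaea athalia" for k in ("r1", "r2", "r3")})
        part = partition({"r1": "e1", "r2": "e2", "r3": "e2"})
        assert cl.min_conspecific_entity_distance(ds, part, "Melitaea athalia") == 0.3

    def test_single_entity_errors(self):
        ds = make_dataset({"r1": "A" * 658})
        with pytest.raises(ValueError, match="single entity"):
            cl.min_conspecific_entity_distance(
                ds, partition({"r1": "e1"}), "Melitaea athalia")

    def test_three_entities_minimum_over_pairs(self):
        seqs = {"r1": "A" * 658,
                "r2": "T" * 20 + "A" * 638,
                "r3": "T" * 5 + "A" * 653}
        ds = make_dataset(seqs, species={k: "X sp" for k in seqs})
        part = partition({"r1": "e1", "r2": "e2", "r3": "e3"})
        # brute-force oracle over all cross pairs
        from barcodiv.haplotypes import p_distance
        from barcodiv.barcode_io import round1
        expected = round1(100 * min(
            p_distance(seqs["r1"], seqs["r2"]),
            p_distance(seqs["r1"], seqs["r3"]),
            p_distance(seqs["r2"], seqs["r3"])))
        assert cl.min_conspecific_entity_distance(ds, part, "X sp") == expected

    @pytest.mark.parametrize("lat2,expected", [
        (0.0, True),      # identical point: 0 km
        (0.449, True),    # ~49.9 km
        (0.46, False),    # ~51.2 km
    ])
    def test_sympatry_haversine(self, lat2, expected):
        assert cl.sympatric([(0.0, 0.0)], [(lat2, 0.0)]) is expected

    def test_empty_coordinates_error(self):
        with pytest.raises(ValueError, match="empty"):
            cl.sympatric([], [(0.0, 0.0)])

    def test_haversine_reference_value(self):
        # quarter meridian: 90 degrees of latitude
        assert cl.haversine_km(0, 0, 90, 0) == pytest.approx(
            np.pi / 2 * 6371.0, rel=1e-9)


class TestReports:
    def _classified_with_details(self):
        species = {"a1": "A sp", "a2": "A sp", "b1": "B sp", "c1": "C sp"}
        part = partition({"a1": "e1", "a2": "e2", "b1": "e3", "c1": "e4"})
        cls = cl.classify_vs_entities(species, part)
        cls.me_details["A sp"] = {
            "n_entities": 2, "min_interentity_distance_pct": 3.0,
            "sympatric": True}
        return cls

    def test_high_divergence_rows_and_fraction(self):
        cls = self._classified_with_details()
        table = cl.high_divergence_report(cls, floor_percent=2.5)
        assert len(table) == 1
        assert table.iloc[0]["species"] == "A sp"
        assert table.attrs["fraction_of_all_species_pct"] == 33.3

    def test_high_floor_empties_table(self):
        cls = self._classified_with_details()
        assert len(cl.high_divergence_report(cls, floor_percent=100.0)) == 0

    def test_family_summary_percentages_and_conservation(self):
        species = {f"r{i}": f"sp{i}" for i in range(6)}
        assign = {"r0": "e0", "r1": "e1", "r2": "e2",
                  "r3": "e3", "r4": "e4", "r5": "e5"}
        # split sp0..sp2 into two entities each
        species.update({f"x{i}": f"sp{i}" for i in range(3)})
        assign.update({f"x{i}": f"f{i}" for i in range(3)})
        cls = cl.classify_vs_entities(species, partition(assign))
        family_of = {f"sp{i}": "Papilionidae" for i in range(6)}
        table = cl.family_summary(cls, family_of)
        assert table.iloc[0]["n_species"] == 6
        assert table.iloc[0]["n_me"] == 3
        assert table.iloc[0]["pct_me"] == 50.0
        assert table["n_species"].sum() == cls.species_count


def build_survey_composition():
    """Reconstruct a specimen->species map and entity assignment realizing
    the published composition: 167 SE, 49 lumped (one triple, 18 pairs, 10
    lumped onto mixed-species entities), 65 ME-pure (2 entities each), 18
    ME-mixed (15 with 3 entities, 3 with 2), totalling 299 species and 363
    entities."""
    species_of, assignment = {}, {}
    rec, ent, spi = 0, 0, 0

    def add(sp, e):
        nonlocal rec
        species_of[f"r{rec}"] = sp
        assignment[f"r{rec}"] = e
        rec += 1

    def new_sp():
        nonlocal spi
        spi += 1
        return f"sp{spi:03d}"

    def new_ent():
        nonlocal ent
        ent += 1
        return f"e{ent:03d}"

    for _ in range(167):                      # single entities
        add(new_sp(), new_ent())
    triple = new_ent()                        # 3 species lumped together
    for _ in range(3):
        add(new_sp(), triple)
    for _ in range(18):                       # 18 lumped pairs (36 species)
        e = new_ent()
        add(new_sp(), e)
        add(new_sp(), e)
    mixed_shared = [new_ent() for _ in range(10)]
    for e in mixed_shared:                    # 10 lumped onto mixed entities
        add(new_sp(), e)
    for _ in range(65):                       # ME-pure: 2 entities each
        sp = new_sp()
        add(sp, new_ent())
        add(sp, new_ent())
    pair_shared = [new_ent() for _ in range(4)]
    mixed_slots = mixed_shared + [e for e in pair_shared for _ in (0, 1)]
    for i in range(18):                       # ME-mixed
        sp = new_sp()
        add(sp, mixed_slots[i])
        add(sp, new_ent())                    # private entity
        if i < 15:
            add(sp, new_ent())                # 15 species carry a third entity
    assert spi == 299
    return species_of, assignment
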