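"""Species-versus-entity classification and barcode-library performance audit.

Two layers:

* library performance — each named species is monophyletic on the haplotype
  tree, para/polyphyletic, or shares an identical barcode with another
  species (sharing takes precedence);

* delimitation audit — each named species is compared against the GMYC
  entity partition and classed as a single entity (SE), lumped with another
  species, or split into multiple entities (ME), the ME cases subdivided by
  whether all their entities are purely conspecific.

Divergence (minimum between-entity p-distance), 50-km sympatry and
per-family summaries annotate the ME cases, mirroring how a survey grades
candidate cryptic lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import dendropy
import numpy as np
import pandas as pd

from .barcode_io import BarcodeDataset, round1
from .gmyc import EntityPartition, NodeSupport
from .haplotypes import HaplotypeSet, encode, p_distance

EARTH_RADIUS_KM = 6371.0


class Performance(str, Enum):
    MONOPHYLETIC = "monophyletic"
    PARA_POLYPHYLETIC = "para_polyphyletic"
    SHARED = "shared"


class GmycCategory(str, Enum):
    SINGLE_ENTITY = "single_entity"
    LUMPED = "lumped"
    ME_PURE = "me_pure"
    ME_MIXED = "me_mixed"


# ---------------------------------------------------------------------------
# layer 1: barcode-library performance

def assess_performance(tree: dendropy.Tree, haps: HaplotypeSet,
                       species_of: dict[str, str],
                       exclude: set[str] | None = None) -> dict[str, Performance]:
    """Classify each species as monophyletic / para-polyphyletic / shared.

    ``tree`` is a rooted tree whose tips are haplotype ids; ``species_of``
    maps record ids to species.  A haplotype with members of two or more
    species marks all of them as sharing barcodes, which takes precedence
    over the tree-based categories; single-haplotype species count as
    monophyletic by convention.
    """
    exclude = exclude or set()
    tree.is_rooted = True   # contract: scoring is on a rooted tree
    hap_species: dict[str, set[str]] = {h: set() for h in haps.haplotypes}
    species_haps: dict[str, set[str]] = {}
    for rid, hids in haps.membership.items():
        if rid not in species_of:
            raise ValueError(f"record {rid!r} has no species label")
        sp = species_of[rid]
        if sp in exclude:
            continue
        for h in hids:
            hap_species[h].add(sp)
            species_haps.setdefault(sp, set()).add(h)

    shared: set[str] = set()
    for h, spp in hap_species.items():
        if len(spp) >= 2:
            shared |= spp

    tip_set = {l.taxon.label for l in tree.leaf_node_iter()}
    result: dict[str, Performance] = {}
    for sp, hids in species_haps.items():
        if sp in shared:
            result[sp] = Performance.SHARED
            continue
        tips = hids & tip_set
        if len(tips) <= 1:
            result[sp] = Performance.MONOPHYLETIC
            continue
        mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace
                               if t.label in tips])
        clade = {l.taxon.label for l in mrca.leaf_iter()}
        result[sp] = (Performance.MONOPHYLETIC if clade == tips
                      else Performance.PARA_POLYPHYLETIC)
    return result


def performance_summary(perf: dict[str, Performance],
                        family_of: dict[str, str] | None = None) -> dict:
    n = len(perf)
    counts = {c: sum(1 for v in perf.values() if v is c) for c in Performance}
    out = {
        "n_species": n,
        "counts": {c.value: counts[c] for c in Performance},
        "percentages": {c.value: round1(100.0 * counts[c] / n) if n else 0.0
                        for c in Performance},
        "fractions": {c.value: (counts[c] / n if n else 0.0)
                      for c in Performance},
    }
    if family_of:
        fam: dict[str, dict[str, int]] = {}
        for sp, cat in perf.items():
            f = family_of.get(sp, "?")
            fam.setdefault(f, {"n": 0, "monophyletic": 0})
            fam[f]["n"] += 1
            if cat is Performance.MONOPHYLETIC:
                fam[f]["monophyletic"] += 1
        out["per_family_pct_monophyletic"] = {
            f: round1(100.0 * d["monophyletic"] / d["n"])
            for f, d in sorted(fam.items())
        }
    return out


# ---------------------------------------------------------------------------
# layer 2: GMYC audit

@dataclass
class GmycClassification:
    """Per-species categories against an entity partition, with summary."""

    categories: dict[str, GmycCategory]
    species_entities: dict[str, frozenset[str]]   # species -> entity ids
    entity_species: dict[str, frozenset[str]]     # entity id -> species set
    entity_count: int
    me_details: dict[str, dict] = field(default_factory=dict)

    @property
    def species_count(self) -> int:
        return len(self.categories)

    def count(self, cat: GmycCategory) -> int:
        return sum(1 for v in self.categories.values() if v is cat)

    @property
    def me_species(self) -> list[str]:
        return sorted(s for s, c in self.categories.items()
                      if c in (GmycCategory.ME_PURE, GmycCategory.ME_MIXED))

    def summary(self) -> dict:
        n = self.species_count
        counts = {c.value: self.count(c) for c in GmycCategory}
        me_total = counts["me_pure"] + counts["me_mixed"]
        surplus = self.entity_count - n
        return {
            "species_count": n,
            "entity_count": self.entity_count,
            "counts": counts,
            "percentages": {k: round1(100.0 * v / n) for k, v in counts.items()},
            "fractions": {k: v / n for k, v in counts.items()},
            "me_total": me_total,
            "me_percentage": round1(100.0 * me_total / n),
            "me_fraction": me_total / n,
            "entity_surplus": surplus,
            "surplus_percentage": round1(100.0 * surplus / n),
            "surplus_fraction": surplus / n,
        }


def classify_vs_entities(species_of: dict[str, str],
                         partition: EntityPartition) -> GmycClassification:
    """Audit named species against a specimen-level entity partition.

    ``species_of`` and ``partition.assignment`` must be keyed by the same
    specimens.  A species with one entity is SE if that entity is purely
    conspecific, otherwise lumped; a species with several entities is ME,
    subdivided into pure (all entities conspecific) and mixed (some entity
    also holds other species).
    """
    missing = set(species_of) - set(partition.assignment)
    if missing:
        raise ValueError(f"specimens missing from partition: {sorted(missing)[:5]}")

    sp_ents: dict[str, set[str]] = {}
    ent_sps: dict[str, set[str]] = {}
    for specimen, sp in species_of.items():
        eid = partition.assignment[specimen]
        sp_ents.setdefault(sp, set()).add(eid)
        ent_sps.setdefault(eid, set()).add(sp)

    categories: dict[str, GmycCategory] = {}
    for sp, ents in sp_ents.items():
        pure = all(ent_sps[e] == {sp} for e in ents)
        if len(ents) == 1:
            categories[sp] = (GmycCategory.SINGLE_ENTITY if pure
                              else GmycCategory.LUMPED)
        else:
            categories[sp] = (GmycCategory.ME_PURE if pure
                              else GmycCategory.ME_MIXED)
    return GmycClassification(
        categories=categories,
        species_entities={s: frozenset(e) for s, e in sp_ents.items()},
        entity_species={e: frozenset(s) for e, s in ent_sps.items()},
        entity_count=len(ent_sps),
    )


def min_conspecific_entity_distance(ds: BarcodeDataset,
                                    partition: EntityPartition,
                                    species: str,
                                    min_overlap: int = 100) -> float:
    """Minimum between-entity p-distance for a split species, in percent.

    Over all pairs of entities holding at least one specimen of the species,
    take the smallest pairwise p-distance between specimens of different
    entities; reported as a percentage rounded to one decimal.
    """
    recs = {r.record_id: r for r in ds.records}
    by_entity: dict[str, list[str]] = {}
    for rid, r in recs.items():
        if r.species == species and rid in partition.assignment:
            by_entity.setdefault(partition.assignment[rid], []).append(rid)
    if len(by_entity) < 2:
        raise ValueError(f"species {species!r} has a single entity")
    masks = {rid: encode(recs[rid].sequence)
             for rids in by_entity.values() for rid in rids}
    ents = sorted(by_entity)
    best = math.inf
    for i in range(len(ents)):
        for j in range(i + 1, len(ents)):
            for ra in by_entity[ents[i]]:
                for rb in by_entity[ents[j]]:
                    d = p_distance(masks[ra], masks[rb],
                                   min_overlap=min_overlap, labels=(ra, rb))
                    best = min(best, d)
    return round1(100.0 * best)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def sympatric(coords_a: list[tuple[float, float]],
              coords_b: list[tuple[float, float]],
              threshold_km: float = 50.0) -> bool:
    """True iff the closest pair of (lat, lon) points is under the threshold."""
    if not coords_a or not coords_b:
        raise ValueError("empty coordinate set")
    return min(haversine_km(a[0], a[1], b[0], b[1])
               for a in coords_a for b in coords_b) < threshold_km


def annotate_me_species(ds: BarcodeDataset, partition: EntityPartition,
                        cls: GmycClassification,
                        supports: NodeSupport | None = None,
                        sympatry_km: float = 50.0,
                        min_overlap: int = 100) -> GmycClassification:
    """Attach divergence and sympatry details to each ME species in place."""
    recs = {r.record_id: r for r in ds.records}
    for sp in cls.me_species:
        by_entity: dict[str, list] = {}
        for rid, r in recs.items():
            if r.species == sp and rid in partition.assignment:
                by_entity.setdefault(partition.assignment[rid], []).append(r)
        detail = {
            "n_entities": len(by_entity),
            "min_interentity_distance_pct": min_conspecific_entity_distance(
                ds, partition, sp, min_overlap=min_overlap),
        }
        coord_sets = [
            [(r.latitude, r.longitude) for r in rs if r.has_coordinates]
            for rs in by_entity.values()
        ]
        coord_sets = [c for c in coord_sets if c]
        if len(coord_sets) >= 2:
            detail["sympatric"] = any(
                sympatric(coord_sets[i], coord_sets[j], sympatry_km)
                for i in range(len(coord_sets))
                for j in range(i + 1, len(coord_sets))
            )
        else:
            detail["sympatric"] = None
        cls.me_details[sp] = detail
    return cls


def high_divergence_report(cls: GmycClassification,
                           floor_percent: float = 2.5) -> pd.DataFrame:
    """ME species whose minimum inter-entity distance exceeds the floor.

    The returned frame carries a ``fraction_of_all_species_pct`` attribute:
    the qualifying species as a share of all classified species.
    """
    rows = []
    for sp in cls.me_species:
        d = cls.me_details.get(sp)
        if d and d["min_interentity_distance_pct"] > floor_percent:
            rows.append({
                "species": sp,
                "n_entities": d["n_entities"],
                "min_interentity_distance_pct": d["min_interentity_distance_pct"],
                "sympatric": d["sympatric"],
            })
    table = pd.DataFrame(rows, columns=["species", "n_entities",
                                        "min_interentity_distance_pct",
                                        "sympatric"])
    table.attrs["fraction_of_all_species_pct"] = round1(
        100.0 * len(rows) / cls.species_count) if cls.species_count else 0.0
    return table


def family_summary(cls: GmycClassification,
                   family_of: dict[str, str]) -> pd.DataFrame:
    """Per family: species counts, ME and lumped counts with percentages."""
    rows: dict[str, dict] = {}
    for sp, cat in cls.categories.items():
        if sp not in family_of:
            raise ValueError(f"species {sp!r} has no family")
        f = family_of[sp]
        row = rows.setdefault(f, {"family": f, "n_species": 0,
                                  "n_me": 0, "n_lumped": 0})
        row["n_species"] += 1
        if cat in (GmycCategory.ME_PURE, GmycCategory.ME_MIXED):
            row["n_me"] += 1
        elif cat is GmycCategory.LUMPED:
            row["n_lumped"] += 1
    table = pd.DataFrame(sorted(rows.values(), key=lambda r: r["family"]))
    table["pct_me"] = [round1(100.0 * m / n)
                       for m, n in zip(table["n_me"], table["n_species"])]
    table["pct_lumped"] = [round1(100.0 * m / n)
                           for m, n in zip(table["n_lumped"], table["n_species"])]
    return table
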