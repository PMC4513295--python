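"""Uncorrected p-distances and conservative haplotype collapsing.

Sequences are compared on IUPAC bit masks: A=1, C=2, G=4, T=8; ambiguity
codes are unions; gaps/'?' carry the empty set and impose no constraint.
Collapsing is "conservative": full-length unambiguous sequences define the
haplotypes by exact identity, and partial or ambiguous sequences are
multi-assigned to every haplotype they are compatible with, so fragments
never inflate the haplotype count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .barcode_io import BarcodeDataset

IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 0, "?": 0,
}
_MASK_TO_SYMBOL = {v: k for k, v in IUPAC_MASK.items() if k not in "?"}
_CONCRETE = frozenset({1, 2, 4, 8})


def encode(seq: str) -> np.ndarray:
    """IUPAC string -> uint8 bit-mask array."""
    try:
        return np.array([IUPAC_MASK[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol {exc.args[0]!r}") from None


def decode(mask: np.ndarray) -> str:
    return "".join(_MASK_TO_SYMBOL[int(m)] for m in mask)


def p_distance(a: str | np.ndarray, b: str | np.ndarray,
               min_overlap: int = 100,
               labels: tuple[str, str] = ("a", "b")) -> float:
    """Uncorrected p-distance under pairwise deletion.

    Only sites where *both* sequences carry a concrete base (A/C/G/T) are
    compared; gapped or ambiguous sites are excluded.  Raises if fewer than
    ``min_overlap`` comparable sites remain.
    """
    ma = encode(a) if isinstance(a, str) else a
    mb = encode(b) if isinstance(b, str) else b
    if ma.shape != mb.shape:
        raise ValueError("sequences are not aligned to a common frame")
    concrete_a = np.isin(ma, (1, 2, 4, 8))
    concrete_b = np.isin(mb, (1, 2, 4, 8))
    comparable = concrete_a & concrete_b
    n = int(comparable.sum())
    if n < min_overlap:
        raise ValueError(
            f"only {n} comparable sites between {labels[0]!r} and {labels[1]!r} "
            f"(min_overlap={min_overlap})"
        )
    diffs = int((ma[comparable] != mb[comparable]).sum())
    return diffs / n


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise fractions with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def build_distance_matrix(seqs: dict[str, str], min_overlap: int = 100) -> DistanceMatrix:
    """All pairwise p-distances, labels kept in the given (insertion) order."""
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    masks = [encode(seqs[l]) for l in labels]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(masks[i], masks[j], min_overlap=min_overlap,
                           labels=(labels[i], labels[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


@dataclass
class HaplotypeSet:
    """Unique haplotypes plus record membership (multi-assignment allowed)."""

    haplotypes: dict[str, str]              # haplotype_id -> sequence
    membership: dict[str, list[str]]        # record_id -> haplotype ids
    counts: dict[str, int] = field(default_factory=dict)  # uniquely-assigned records

    def __len__(self) -> int:
        return len(self.haplotypes)

    def representative_of(self, record_id: str) -> str:
        """Deterministic single haplotype for a record: smallest id."""
        return min(self.membership[record_id])

    def fractional_counts(self) -> dict[str, float]:
        """Each record contributes 1/k to each of its k haplotypes."""
        out = {h: 0.0 for h in self.haplotypes}
        for hids in self.membership.values():
            for h in hids:
                out[h] += 1.0 / len(hids)
        return out

    def to_tsv(self, path: str | Path) -> None:
        members: dict[str, list[str]] = {h: [] for h in self.haplotypes}
        for rid, hids in self.membership.items():
            for h in hids:
                members[h].append(rid)
        with open(path, "w") as fh:
            fh.write("haplotype_id\tsequence\tn_members\tmember_ids\n")
            for h in sorted(self.haplotypes):
                ms = sorted(members[h])
                fh.write(f"{h}\t{self.haplotypes[h]}\t{len(ms)}\t{';'.join(ms)}\n")

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for h in sorted(self.haplotypes):
                fh.write(f">{h}\n{self.haplotypes[h]}\n")


def _compatible(seq: np.ndarray, hap: np.ndarray) -> bool:
    # IUPAC sets must intersect wherever both carry information.
    both = (seq != 0) & (hap != 0)
    return bool(np.all((seq[both] & hap[both]) != 0))


def collapse_haplotypes(ds: BarcodeDataset) -> HaplotypeSet:
    """Collapse a dataset to unique haplotypes, multi-assigning fragments.

    Pass 1: full-length unambiguous sequences found base haplotypes by exact
    identity.  Pass 2: remaining sequences, processed by decreasing ungapped
    length (ties by record id), are assigned to every compatible haplotype;
    a sequence compatible with none founds a new haplotype.  A final sweep
    recomputes membership against the finished haplotype list so assignment
    does not depend on processing order.
    """
    masks = {r.record_id: encode(r.sequence) for r in ds.records}
    full = [r for r in ds.records
            if np.all(np.isin(masks[r.record_id], (1, 2, 4, 8)))]
    partial = [r for r in ds.records
               if not np.all(np.isin(masks[r.record_id], (1, 2, 4, 8)))]

    haplotypes: dict[str, np.ndarray] = {}
    key_to_hid: dict[bytes, str] = {}
    membership: dict[str, list[str]] = {}

    def new_hid() -> str:
        return f"H{len(haplotypes) + 1:05d}"

    for rec in full:
        key = masks[rec.record_id].tobytes()
        hid = key_to_hid.get(key)
        if hid is None:
            hid = new_hid()
            key_to_hid[key] = hid
            haplotypes[hid] = masks[rec.record_id]
        membership[rec.record_id] = [hid]

    # Founding sweep over partial/ambiguous sequences.
    order = sorted(partial, key=lambda r: (-r.ungapped_length, r.record_id))
    for rec in order:
        m = masks[rec.record_id]
        hits = [h for h, hm in haplotypes.items() if _compatible(m, hm)]
        if not hits:
            hid = new_hid()
            haplotypes[hid] = m
            hits = [hid]
        membership[rec.record_id] = hits

    # Final sweep: re-derive membership against the complete haplotype list.
    for rec in order:
        m = masks[rec.record_id]
        membership[rec.record_id] = [h for h, hm in haplotypes.items()
                                     if _compatible(m, hm)]

    counts = {h: 0 for h in haplotypes}
    for hids in membership.values():
        if len(hids) == 1:
            counts[hids[0]] += 1

    return HaplotypeSet(
        haplotypes={h: decode(m) for h, m in haplotypes.items()},
        membership=membership,
        counts=counts,
    )
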