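"""GMYC-suitability diagnostics: Ne from synonymous-site diversity, the
crown-age pure-birth speciation rate, and the Ne x SR band check.

The delimitation model performs best when the product of haploid effective
population size and speciation rate sits inside a known window; a survey can
check its own data against that window using per-species synonymous-site
nucleotide diversity (Nei-Gojobori counting under the invertebrate
mitochondrial code) and a crown-age Yule rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .haplotypes import encode

__all__ = [
    "synonymous_pi", "estimate_ne", "yule_crown_rate", "suitability_check",
    "detect_frame", "NeEstimate", "SuitabilityReport",
    "SLOW_RATE_PER_MYR", "FAST_RATE_PER_MYR", "OPTIMAL_BAND",
]

#: COI substitution rates for invertebrates, per site per Myr.
SLOW_RATE_PER_MYR = 0.0075
FAST_RATE_PER_MYR = 0.0115

#: Ne x SR window in which GMYC delimitation is reliable.
OPTIMAL_BAND = (1.8e3, 8e5)

_BASES = "ACGT"


@lru_cache(maxsize=4)
def _codon_maps(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    # fraction of one-step changes per position that are synonymous
    syn_sites: dict[str, float] = {}
    for codon in aa:
        if aa[codon] == "*":
            continue
        s = 0.0
        for pos in range(3):
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1:]
                if aa[mut] == aa[codon]:   # change to a stop is non-synonymous
                    s += 1.0 / 3.0
        syn_sites[codon] = s
    return aa, syn_sites


def _pairwise_syn(c1: str, c2: str, aa: dict[str, str]) -> tuple[float, float]:
    """(synonymous differences, total differences) for one codon pair,
    averaged over all mutational pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    nd = len(diff_pos)
    if nd == 0:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if aa[nxt] == "*":
                ok = False
                break
            steps.append(1.0 if aa[nxt] == aa[cur] else 0.0)
            cur = nxt
        if ok:
            pathways.append(sum(steps))
    if not pathways:   # every route crosses a stop; fall back to all routes
        for order in itertools.permutations(diff_pos):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                steps.append(1.0 if aa[nxt] == aa[cur] else 0.0)
                cur = nxt
            pathways.append(sum(steps))
    return float(np.mean(pathways)), float(nd)


def _clean_codons(a: str, b: str, offset: int) -> list[tuple[str, str]]:
    """Codon pairs comparable in both sequences (no gaps/ambiguity)."""
    out = []
    for i in range(offset, min(len(a), len(b)) - 2, 3):
        ca, cb = a[i:i + 3].upper(), b[i:i + 3].upper()
        if set(ca) <= set(_BASES) and set(cb) <= set(_BASES):
            out.append((ca, cb))
    return out


def _internal_stops(seq: str, offset: int, aa: dict[str, str]) -> int:
    n = 0
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3].upper()
        if set(codon) <= set(_BASES) and aa[codon] == "*":
            n += 1
    return n


def detect_frame(seqs: list[str], table_id: int = 5) -> int:
    """Reading-frame offset (0/1/2) minimizing internal stop codons."""
    aa, _ = _codon_maps(table_id)
    totals = [sum(_internal_stops(s, off, aa) for s in seqs) for off in (0, 1, 2)]
    return int(np.argmin(totals))


def pairwise_ps(a: str, b: str, table_id: int = 5,
                frame_offset: int = 0) -> float:
    """Proportion of synonymous differences per synonymous site (one pair)."""
    aa, syn_sites = _codon_maps(table_id)
    codons = _clean_codons(a, b, frame_offset)
    if not codons:
        raise ValueError("no comparable codons between the pair")
    S = 0.0
    sd = 0.0
    for ca, cb in codons:
        if aa[ca] == "*" or aa[cb] == "*":
            continue
        S += 0.5 * (syn_sites[ca] + syn_sites[cb])
        s, _n = _pairwise_syn(ca, cb, aa)
        sd += s
    if S == 0:
        raise ValueError("zero synonymous sites in the comparable region")
    return sd / S


def synonymous_pi(seqs: list[str], table_id: int = 5,
                  frame_offset: int | None = None,
                  min_sequences: int = 10) -> float:
    """Synonymous-site nucleotide diversity of one species (Nei-Gojobori).

    Mean over all sequence pairs of (synonymous differences / synonymous
    sites); codons with gaps or ambiguity in either sequence are excluded
    pairwise.  Requires at least ``min_sequences`` sequences (set lower only
    for toy data) and a frame without pervasive internal stops.
    """
    if len(seqs) < min_sequences:
        raise ValueError(f"need >= {min_sequences} sequences, got {len(seqs)}")
    aa, _ = _codon_maps(table_id)
    if frame_offset is None:
        frame_offset = detect_frame(seqs, table_id)
    # a frameshifted read shows stops at ~5% of codons; a coding frame may
    # still carry the odd stop (sequencing error, unconstrained simulation),
    # so the frame is rejected only when most sequences exceed a 2% density
    limit = max(1.0, 0.02 * (len(seqs[0]) - frame_offset) / 3)
    n_stopped = sum(1 for s in seqs
                    if _internal_stops(s, frame_offset, aa) > limit)
    if n_stopped > len(seqs) / 2:
        raise ValueError(
            f"frame {frame_offset} yields internal stops in {n_stopped}/{len(seqs)} "
            "sequences"
        )
    vals = [pairwise_ps(a, b, table_id, frame_offset)
            for a, b in itertools.combinations(seqs, 2)]
    return float(np.mean(vals))


def estimate_ne(pi_syn: float, rate_per_site_per_myr: float,
                generations_per_year: float = 1.0) -> float:
    """Haploid effective population size from synonymous diversity.

    For a uniparental marker theta = 2*Ne*mu, so Ne = pi / (2*mu) with mu
    the per-site per-generation rate derived from the per-Myr substitution
    rate and the generation time.
    """
    if pi_syn < 0:
        raise ValueError("pi_syn must be >= 0")
    if rate_per_site_per_myr <= 0:
        raise ValueError("substitution rate must be > 0")
    mu = rate_per_site_per_myr * 1e-6 / generations_per_year
    return pi_syn / (2.0 * mu)


@dataclass(frozen=True)
class NeEstimate:
    species: str
    n_specimens: int
    pi_syn: float
    ne_slow: float
    ne_fast: float

    @classmethod
    def from_pi(cls, species: str, n_specimens: int, pi_syn: float,
                generations_per_year: float = 1.0) -> "NeEstimate":
        return cls(
            species=species, n_specimens=n_specimens, pi_syn=pi_syn,
            ne_slow=estimate_ne(pi_syn, SLOW_RATE_PER_MYR, generations_per_year),
            ne_fast=estimate_ne(pi_syn, FAST_RATE_PER_MYR, generations_per_year),
        )


def yule_crown_rate(n_lineages: int, crown_age_myr: float) -> float:
    """Crown-age pure-birth ML net diversification rate, (ln n - ln 2) / t.

    This is the zero-extinction crown estimator of the standard
    Magallon-Sanderson family of rate estimators.
    """
    if n_lineages < 2:
        raise ValueError("need >= 2 lineages")
    if crown_age_myr <= 0:
        raise ValueError("crown age must be > 0")
    return (math.log(n_lineages) - math.log(2.0)) / crown_age_myr


@dataclass
class SuitabilityReport:
    speciation_rate: float
    ne_values: list[float]
    products: list[float]
    optimal_band: tuple[float, float]
    in_band_fraction: float
    verdict: str

    def summary(self) -> dict:
        return {
            "speciation_rate": self.speciation_rate,
            "n_estimates": len(self.ne_values),
            "product_min": min(self.products) if self.products else None,
            "product_max": max(self.products) if self.products else None,
            "product_mean": (float(np.mean(self.products))
                             if self.products else None),
            "optimal_band": list(self.optimal_band),
            "in_band_fraction": self.in_band_fraction,
            "verdict": self.verdict,
        }


def suitability_check(ne_values: list[float], sr: float,
                      band: tuple[float, float] = OPTIMAL_BAND) -> SuitabilityReport:
    """Check Ne x SR products against the optimal delimitation window."""
    if not ne_values:
        raise ValueError("need at least one Ne estimate")
    if band[0] >= band[1]:
        raise ValueError("band low must be < high")
    products = [ne * sr for ne in ne_values]
    inside = sum(1 for p in products if band[0] <= p <= band[1])
    frac = inside / len(products)
    return SuitabilityReport(
        speciation_rate=sr,
        ne_values=list(ne_values),
        products=products,
        optimal_band=band,
        in_band_fraction=frac,
        verdict="pass" if frac >= 0.5 else "warn",
    )
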