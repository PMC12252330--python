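"""Pedigree-based validation and evolutionary-order analysis.

A cultivar shows *ancestor-inclined distribution* when it falls in the same
cluster as at least one of its known parent species. The probability of
that event over all pedigreed cultivars measures how well a phenotype-based
clustering tracks breeding lines. Companion statistics: parental breeding
frequency (share of parental slots each parent occupies), the distribution
of taxonomic sections across clusters, and a Pearson correlation between an
ordinal coding of sections and of clusters (a morphology-based check of a
hypothesized evolutionary order).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import Partition
from .traitdata import CULTIVAR, SPECIES, GermplasmRegister
from .util import round_half_up

logger = logging.getLogger("phenotax")


@dataclass(frozen=True)
class PedigreeSet:
    """Cultivar -> known parents (1-2). Cultivars with one known parent have
    a partial pedigree; cultivars with no known parents do not belong here."""

    parents: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        for cid, par in self.parents:
            if not 1 <= len(par) <= 2:
                raise ValueError(f"cultivar {cid!r} must have 1-2 known parents")

    @classmethod
    def from_register(cls, reg: GermplasmRegister) -> "PedigreeSet":
        entries = tuple(
            (r.id, r.parents) for r in reg.records
            if r.rank == CULTIVAR and r.parents
        )
        return cls(entries)

    @classmethod
    def from_mapping(cls, mapping: dict[str, list[str]]) -> "PedigreeSet":
        return cls(tuple((c, tuple(p)) for c, p in mapping.items()))

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.parents)

    def is_partial(self, cultivar: str) -> bool:
        return len(dict(self.parents)[cultivar]) < 2

    def __len__(self) -> int:
        return len(self.parents)


def ancestor_inclined_probability(ped: PedigreeSet, p: Partition) -> float:
    """Percentage of pedigreed cultivars sharing a cluster with >= 1 known
    parent.

    Parents absent from the partition drop from that cultivar's check; a
    cultivar whose known parents are all absent leaves the denominator
    (logged). A cultivar counts once however many parents match.
    """
    if len(ped) == 0:
        raise ValueError("empty pedigree set")
    num = den = 0
    for cid, parents in ped.parents:
        if cid not in p.assignments:
            raise ValueError(f"pedigree cultivar {cid!r} absent from partition")
        present = [q for q in parents if q in p.assignments]
        if not present:
            logger.warning("cultivar %r: no known parent in partition; "
                           "excluded from denominator", cid)
            continue
        den += 1
        if any(p.assignments[q] == p.assignments[cid] for q in present):
            num += 1
    if den == 0:
        raise ValueError("no pedigreed cultivar has a parent in the partition")
    return 100.0 * num / den


def breeding_frequency(ped: PedigreeSet) -> tuple[dict[str, float], float]:
    """Share of parental slots per parent, in percent.

    Every cultivar contributes two parental slots; known parents fill one
    slot each and the remainder is unknown mass, so frequencies stay
    comparable across partial pedigrees. Returns (parent -> %, unknown %);
    the parts sum to 100.
    """
    if len(ped) == 0:
        raise ValueError("empty pedigree set")
    total_slots = 2 * len(ped)
    slot_counts: dict[str, int] = {}
    known = 0
    for _, parents in ped.parents:
        for q in parents:
            slot_counts[q] = slot_counts.get(q, 0) + 1
            known += 1
    freqs = {q: 100.0 * c / total_slots for q, c in slot_counts.items()}
    unknown = 100.0 * (total_slots - known) / total_slots
    return freqs, unknown


def section_distribution(p: Partition, reg: GermplasmRegister) -> pd.DataFrame:
    """Section x cluster table of percentages: how each section's species
    distribute across clusters. Rows sum to 100 (before 1-decimal rounding);
    species without a section are excluded and logged."""
    species = [g for g in p.assignments
               if g in reg and reg[g].rank == SPECIES]
    missing = [g for g in species if not reg[g].section]
    if missing:
        logger.warning("species without section excluded: %s", sorted(missing))
    species = [g for g in species if reg[g].section]
    if not species:
        raise ValueError("no sectioned species in partition")
    sections = sorted({reg[g].section for g in species})
    clusters = p.clusters()
    table = pd.DataFrame(0.0, index=sections, columns=clusters)
    for sec in sections:
        members = [g for g in species if reg[g].section == sec]
        for c in clusters:
            frac = sum(1 for g in members if p.assignments[g] == c) / len(members)
            table.at[sec, c] = round_half_up(100.0 * frac, 1)
    return table


def merge_clusters(p: Partition, mapping: dict[int, int | str]) -> Partition:
    """Relabel/merge clusters; the mapping must cover every label."""
    missing = [c for c in p.clusters() if c not in mapping]
    if missing:
        raise ValueError(f"mapping misses cluster label(s) {missing}")
    merged = {g: mapping[c] for g, c in p.assignments.items()}
    # normalize to integer labels by first occurrence
    relabel: dict = {}
    for v in merged.values():
        if v not in relabel:
            relabel[v] = len(relabel) + 1
    return Partition({g: relabel[v] for g, v in merged.items()},
                     level=f"{p.level}-merged")


@dataclass(frozen=True)
class OrderCoding:
    """Ordinal codes expressing a hypothesized evolutionary order for
    clusters and for taxonomic sections."""

    cluster_codes: tuple[tuple[int, int], ...]  # (cluster label, code)
    section_codes: tuple[tuple[str, int], ...]  # (section, code)

    def __post_init__(self) -> None:
        if not self.cluster_codes or not self.section_codes:
            raise ValueError("both code maps must be nonempty")
        for _, code in list(self.cluster_codes) + list(self.section_codes):
            if code < 1:
                raise ValueError("codes must be positive integers")


@dataclass
class OrderCorrelation:
    r: float
    r2: float
    p_value: float
    n: int


def order_correlation(coding: OrderCoding, p: Partition,
                      reg: GermplasmRegister) -> OrderCorrelation:
    """Pearson correlation between section codes and cluster codes over the
    species belonging to both a coded section and a coded cluster.

    Significance uses the exact t transform t = r sqrt((n-2)/(1-r^2)),
    two-sided (as delivered by scipy.stats.pearsonr)."""
    ccodes = dict(coding.cluster_codes)
    scodes = dict(coding.section_codes)
    xs, ys, excluded = [], [], []
    for g, c in p.assignments.items():
        if g not in reg or reg[g].rank != SPECIES:
            continue
        sec = reg[g].section
        if sec in scodes and c in ccodes:
            xs.append(scodes[sec])
            ys.append(ccodes[c])
        else:
            excluded.append(g)
    if excluded:
        logger.info("order_correlation: %d species in uncoded "
                    "sections/clusters excluded", len(excluded))
    n = len(xs)
    if n < 3:
        raise ValueError(f"only {n} coded species pairs (need >= 3)")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("constant code vector")
    res = stats.pearsonr(xs, ys)
    r = float(res.statistic)
    return OrderCorrelation(r=r, r2=r * r, p_value=float(res.pvalue), n=n)
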