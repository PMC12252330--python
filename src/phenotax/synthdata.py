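"""Synthetic germplasm generator with known group structure and pedigrees.

Real leaf-architecture surveys of this kind observe ~30 replicate leaves per
accession across a collection of wild species and pedigreed cultivars, score
a few dozen ordinal qualitative traits plus a handful of quantitative ones,
and rely on intraspecific uniformity / interspecific distinctness for the
statistics to work. The generator reproduces exactly that structure with
ground truth attached:

* species fall into latent groups; each group has its own level-probability
  vector per qualitative trait and its own mean per quantitative trait;
* traits may belong to *families* (leaf-size allometry, pigmentation, ...):
  family mates share a per-germplasm latent factor through a Gaussian
  copula, so they correlate across germplasms while each trait keeps
  exactly its configured per-group marginal distribution. This is what
  gives the PCA stage block structure and the pruning stage r > 0.8 pairs
  to work on;
* cultivars inherit from 1-2 parent species: one *inheritance parent* is
  drawn uniformly, and each trait is copied from it with probability
  ``inheritance_fidelity``, otherwise drawn from the population-wide
  (group-pooled) distribution;
* replicate leaves add multiplicative Gaussian noise tuned to a target
  within-germplasm CV (quantitative) or level-flip noise (qualitative).

A single integer seed drives one ``numpy.random.Generator``; identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .traitdata import (
    CULTIVAR,
    QUALITATIVE,
    QUANTITATIVE,
    SPECIES,
    GermplasmRecord,
    GermplasmRegister,
    ObservationTable,
    Trait,
    TraitCodebook,
)

logger = logging.getLogger("phenotax")

# Floor applied to quantitative draws pushed negative by noise; multiplicative
# CV noise at realistic levels makes this exceedingly rare.
_POSITIVE_FLOOR = 1e-8


@dataclass(frozen=True)
class QualitativeTraitSpec:
    """A qualitative trait: k ordered levels with per-group level
    probabilities, optional correlated family membership."""

    name: str
    k: int
    group_level_probs: tuple[tuple[float, ...], ...]  # n_groups x k
    flip_prob: float = 0.02  # per-replicate chance of scoring a wrong level
    family: str | None = None
    loading: float = 0.0  # copula loading on the family latent, [0, 1)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"{self.name!r}: k must be >= 1")
        for probs in self.group_level_probs:
            if len(probs) != self.k:
                raise ValueError(f"{self.name!r}: probability vector length != k")
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{self.name!r}: probabilities must be >=0, sum to 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError(f"{self.name!r}: flip_prob outside [0,1]")
        if not 0.0 <= self.loading < 1.0:
            raise ValueError(f"{self.name!r}: loading outside [0,1)")


@dataclass(frozen=True)
class QuantitativeTraitSpec:
    """A quantitative trait: per-group mean, among-group spread
    (germplasm_sd), within-germplasm CV target, optional family."""

    name: str
    group_means: tuple[float, ...]
    germplasm_sd: float  # sd of germplasm means around their group mean
    within_cv: float  # replicate-level CV target, percent
    units: str = ""
    family: str | None = None
    loading: float = 0.0

    def __post_init__(self) -> None:
        if self.within_cv < 0:
            raise ValueError(f"{self.name!r}: within_cv must be >= 0")
        if self.germplasm_sd < 0:
            raise ValueError(f"{self.name!r}: germplasm_sd must be >= 0")
        if not 0.0 <= self.loading < 1.0:
            raise ValueError(f"{self.name!r}: loading outside [0,1)")


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int
    n_cultivars: int
    n_groups: int
    qualitative: tuple[QualitativeTraitSpec, ...]
    quantitative: tuple[QuantitativeTraitSpec, ...]
    inheritance_fidelity: float = 0.9
    replicates_per_germplasm: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("zero groups")
        if self.n_species < 1 and self.n_cultivars > 0:
            raise ValueError("cultivars require at least one species")
        if not 0.0 <= self.inheritance_fidelity <= 1.0:
            raise ValueError("inheritance_fidelity outside [0,1]")
        if self.replicates_per_germplasm < 1:
            raise ValueError("need at least one replicate")
        for spec in self.qualitative:
            if len(spec.group_level_probs) != self.n_groups:
                raise ValueError(f"{spec.name!r}: needs {self.n_groups} probability vectors")
        for spec in self.quantitative:
            if len(spec.group_means) != self.n_groups:
                raise ValueError(f"{spec.name!r}: needs {self.n_groups} group means")


@dataclass
class SyntheticTruth:
    """Generator-side ground truth for recovery tests."""

    group: dict[str, int]  # germplasm id -> latent group
    pedigree: dict[str, tuple[str, ...]]  # cultivar id -> parent species ids
    inheritance_parent: dict[str, str]  # cultivar id -> the copied parent
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Default study-scale configuration
# ---------------------------------------------------------------------------

def _peaked_probs(k: int, peak: int, mass: float) -> tuple[float, ...]:
    """Probability vector with `mass` on `peak`, remainder uniform elsewhere."""
    if k == 1:
        return (1.0,)
    rest = (1.0 - mass) / (k - 1)
    return tuple(mass if i == peak else rest for i in range(k))


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-scale defaults: 34 species + 39 cultivars in 5 latent groups,
    39 qualitative + 11 quantitative candidate traits, 30 replicate leaves,
    inheritance fidelity 0.9.

    The candidate panel is built the way a real one looks, so every
    screening gate has work to do:

    * 13 qualitative traits are near-monomorphic (evolutionarily conserved;
      0.92 mass on one level in every group) — low diversity, screened out;
    * 26 qualitative traits are polymorphic with group-dependent preferred
      levels (0.75 mass), organized into 11 correlated families of 2-3;
    * 8 quantitative traits have low replicate noise (6% CV) and strong
      among-group separation (80% relative spread of group means), in 3
      correlated families — these pass both CV gates;
    * 2 quantitative traits carry 16% replicate noise (fail the
      intraspecific-uniformity gate) and 1 has no among-group separation
      (fails the distinctness gate).

    Family copula loadings are drawn in [0.80, 0.95), putting within-family
    correlations in the 0.65-0.9 band so that the r > 0.8 pruning threshold
    splits real redundancy from tolerable association, as in field data.
    """
    n_groups = 5
    rng = np.random.default_rng(seed + 104729)  # layout rng, separate from data rng

    qual: list[QualitativeTraitSpec] = []
    fam_sizes = [3, 2, 2, 3, 2, 2, 3, 2, 2, 3, 2]  # 26 diverse traits
    i = 0
    for f, fs in enumerate(fam_sizes):
        k = int(rng.integers(3, 6))
        peaks = rng.integers(0, k, n_groups)
        probs = tuple(_peaked_probs(k, int(p), 0.75) for p in peaks)
        for _ in range(fs):
            qual.append(QualitativeTraitSpec(
                f"qual_{i:02d}", k, probs,
                family=f"qfam{f}", loading=float(rng.uniform(0.80, 0.95))))
            i += 1
    for j in range(13):  # conserved, low-diversity traits
        k = int(rng.integers(2, 6))
        probs = tuple(_peaked_probs(k, 0, 0.92) for _ in range(n_groups))
        qual.append(QualitativeTraitSpec(f"qual_{i + j:02d}", k, probs))

    quant: list[QuantitativeTraitSpec] = []
    qfam_sizes = [3, 3, 2]  # 8 informative traits
    i = 0
    for f, fs in enumerate(qfam_sizes):
        base = float(rng.uniform(5, 40))
        for _ in range(fs):
            b = base * float(rng.uniform(0.8, 1.2))
            means = tuple(b * (1 + 0.8 * g / (n_groups - 1)) for g in range(n_groups))
            quant.append(QuantitativeTraitSpec(
                f"quant_{i:02d}", means, germplasm_sd=0.10 * b, within_cv=6.0,
                units="cm", family=f"sfam{f}", loading=float(rng.uniform(0.80, 0.95))))
            i += 1
    for j in range(2):  # high replicate noise: fails CVbar <= 10%
        b = float(rng.uniform(5, 40))
        means = tuple(b * (1 + 0.6 * g / (n_groups - 1)) for g in range(n_groups))
        quant.append(QuantitativeTraitSpec(
            f"quant_{i:02d}", means, germplasm_sd=0.08 * b, within_cv=16.0,
            units="cm"))
        i += 1
    b = float(rng.uniform(5, 40))  # flat: fails CV >= 15%
    quant.append(QuantitativeTraitSpec(
        f"quant_{i:02d}", tuple(b for _ in range(n_groups)),
        germplasm_sd=0.03 * b, within_cv=5.0, units="cm"))

    return SimulationConfig(
        n_species=34,
        n_cultivars=39,
        n_groups=n_groups,
        qualitative=tuple(qual),
        quantitative=tuple(quant),
        inheritance_fidelity=0.9,
        replicates_per_germplasm=30,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _build_codebook(cfg: SimulationConfig) -> TraitCodebook:
    traits = [
        Trait(s.name, QUALITATIVE,
              levels=tuple((f"L{c}", c) for c in range(s.k)))
        for s in cfg.qualitative
    ]
    traits += [Trait(s.name, QUANTITATIVE, units=s.units) for s in cfg.quantitative]
    return TraitCodebook(tuple(traits))


def _qual_from_z(z: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Inverse-CDF a standard-normal draw through a categorical marginal."""
    cum = np.cumsum(probs)
    cum[-1] = 1.0 + 1e-12  # guard against rounding at the top
    return np.searchsorted(cum, norm.cdf(z), side="right").clip(0, len(probs) - 1)


def generate_population(
    cfg: SimulationConfig,
) -> tuple[GermplasmRegister, TraitCodebook, ObservationTable, SyntheticTruth]:
    """Generate register, codebook, replicate observations, and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    codebook = _build_codebook(cfg)

    species_ids = [f"S{i + 1:03d}" for i in range(cfg.n_species)]
    cultivar_ids = [f"C{i + 1:03d}" for i in range(cfg.n_cultivars)]
    all_ids = species_ids + cultivar_ids
    n_all = len(all_ids)
    idx = {gid: i for i, gid in enumerate(all_ids)}
    # balanced group assignment keeps every group populated
    group = {sid: i % cfg.n_groups for i, sid in enumerate(species_ids)}
    sp_groups = np.array([group[s] for s in species_ids])

    # family latents (one per germplasm per family, shared by family mates)
    specs = list(cfg.qualitative) + list(cfg.quantitative)
    families = list(dict.fromkeys(s.family for s in specs if s.family))
    U = {fam: rng.standard_normal(n_all) for fam in families}

    def trait_z(spec) -> np.ndarray:
        eps = rng.standard_normal(n_all)
        if spec.family and spec.loading > 0:
            a = spec.loading
            return a * U[spec.family] + math.sqrt(1 - a * a) * eps
        return eps

    # germplasm-level latent trait values (species first; cultivar slots of
    # the z arrays feed the non-inherited pooled draws below)
    values: dict[str, dict[str, float]] = {gid: {} for gid in all_ids}
    pooled_z: dict[str, np.ndarray] = {}
    pooled_quant = {}
    for spec in cfg.qualitative:
        z = trait_z(spec)
        pooled_z[spec.name] = z
        probs = np.asarray(spec.group_level_probs, dtype=float)
        for g in range(cfg.n_groups):
            sel = np.where(sp_groups == g)[0]
            if len(sel):
                levels = _qual_from_z(z[sel], probs[g])
                for i, lv in zip(sel, levels):
                    values[species_ids[i]][spec.name] = float(lv)
    for spec in cfg.quantitative:
        z = trait_z(spec)
        pooled_z[spec.name] = z
        mu_pool = float(np.mean(spec.group_means))
        sd_pool = float(np.std(spec.group_means, ddof=0) + spec.germplasm_sd)
        pooled_quant[spec.name] = (mu_pool, sd_pool)
        for i, sid in enumerate(species_ids):
            v = spec.group_means[sp_groups[i]] + spec.germplasm_sd * z[i]
            values[sid][spec.name] = float(max(v, _POSITIVE_FLOOR))

    # cultivars: inheritance parent + per-trait copy-or-pooled-draw
    pedigree: dict[str, tuple[str, ...]] = {}
    inh_parent: dict[str, str] = {}
    pooled_probs = {
        spec.name: np.mean(np.asarray(spec.group_level_probs, dtype=float), axis=0)
        for spec in cfg.qualitative
    }
    for cid in cultivar_ids:
        n_par = int(rng.integers(1, 3))  # 1 or 2 parents
        parents = tuple(str(p) for p in rng.choice(species_ids, size=n_par,
                                                   replace=False))
        pedigree[cid] = parents
        ip = parents[rng.integers(len(parents))]
        inh_parent[cid] = ip
        group[cid] = group[ip]
        j = idx[cid]
        for spec in cfg.qualitative:
            if rng.random() < cfg.inheritance_fidelity:
                values[cid][spec.name] = values[ip][spec.name]
            else:
                p = pooled_probs[spec.name]
                lv = _qual_from_z(np.array([pooled_z[spec.name][j]]), p / p.sum())[0]
                values[cid][spec.name] = float(lv)
        for spec in cfg.quantitative:
            if rng.random() < cfg.inheritance_fidelity:
                values[cid][spec.name] = values[ip][spec.name]
            else:
                mu, sd = pooled_quant[spec.name]
                v = mu + sd * pooled_z[spec.name][j]
                values[cid][spec.name] = float(max(v, _POSITIVE_FLOOR))

    # replicate leaves
    n_clipped = 0
    rows: list[tuple[str, int, str, float]] = []
    R = cfg.replicates_per_germplasm
    for gid in all_ids:
        for spec in cfg.qualitative:
            base = int(values[gid][spec.name])
            if spec.flip_prob > 0 and spec.k > 1:
                flips = rng.random(R) < spec.flip_prob
                # uniform draw over the other k-1 levels
                others = rng.integers(0, spec.k - 1, size=R)
                others = np.where(others >= base, others + 1, others)
                reps = np.where(flips, others, base)
            else:
                reps = np.full(R, base)
            rows.extend((gid, r, spec.name, float(reps[r])) for r in range(R))
        for spec in cfg.quantitative:
            v = values[gid][spec.name]
            if spec.within_cv > 0:
                reps = v * (1.0 + (spec.within_cv / 100.0) * rng.standard_normal(R))
                clipped = reps <= 0
                n_clipped += int(clipped.sum())
                reps = np.where(clipped, _POSITIVE_FLOOR, reps)
            else:
                reps = np.full(R, v)
            rows.extend((gid, r, spec.name, float(reps[r])) for r in range(R))
    if n_clipped:
        logger.info("clipped %d negative replicate draws to %.0e",
                    n_clipped, _POSITIVE_FLOOR)

    section_names = [f"Sect{g + 1}" for g in range(cfg.n_groups)]
    records = [
        GermplasmRecord(sid, SPECIES, section=section_names[group[sid]])
        for sid in species_ids
    ] + [
        GermplasmRecord(cid, CULTIVAR, parents=pedigree[cid])
        for cid in cultivar_ids
    ]
    register = GermplasmRegister(tuple(records))
    obs = ObservationTable(pd.DataFrame(rows, columns=[
        "germplasm_id", "replicate_id", "trait_name", "value"]))
    truth = SyntheticTruth(group=group, pedigree=pedigree,
                           inheritance_parent=inh_parent, config=cfg)
    return register, codebook, obs, truth


def generate_uniform_trait(n: int, k: int) -> np.ndarray:
    """Trait column of n values where each of the k levels occurs exactly n/k
    times — a fixture with known maximal evenness."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if n % k != 0:
        raise ValueError(f"k={k} does not divide n={n}")
    return np.repeat(np.arange(k), n // k)
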