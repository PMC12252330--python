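"""Stage-1 trait screening: diversity indices and coefficients of variation.

Qualitative traits are screened on three indices computed over the n
germplasms, with ni germplasms at level i of k declared levels:

* Simpson's diversity (unbiased, pair-based form)
      D = 1 - sum_i ni (ni - 1) / (n (n - 1))
* Shannon-Wiener information index (nats)
      H = - sum_i (ni / n) ln(ni / n)
* evenness
      E = H / ln k          (E := 0 for the degenerate k = 1)

A trait passes when D >= d_min, H >= h_min and E >= e_min (all inclusive).

Quantitative traits are screened on two coefficients of variation: the mean
within-germplasm CV (intraspecific uniformity)
      CVbar = (1/n) sum_i (Si / Xbar_i) x 100%
with Si, Xbar_i the replicate sd and mean for germplasm i, and the
among-germplasm CV (interspecific distinctness)
      CV = S' / Xbar' x 100%
with S', Xbar' the sd and mean of the germplasm-level values. A trait
passes when CVbar <= cvbar_max and CV >= cv_min (inclusive). Standard
deviations are sample sds (ddof=1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traitdata import ObservationTable, TraitCodebook, TraitMatrix

logger = logging.getLogger("phenotax")


@dataclass(frozen=True)
class ScreeningThresholds:
    """Inclusive retention gates for both screening stages."""

    d_min: float = 0.50
    h_min: float = 0.80
    e_min: float = 0.60
    cvbar_max: float = 10.0  # percent
    cv_min: float = 15.0  # percent

    def __post_init__(self) -> None:
        for name in ("d_min", "h_min", "e_min", "cvbar_max", "cv_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# ---------------------------------------------------------------------------
# Index primitives
# ---------------------------------------------------------------------------

def simpson_d(level_counts) -> float:
    """Unbiased Simpson diversity: probability that two germplasms drawn
    without replacement carry different levels."""
    counts = np.asarray(level_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    n = counts.sum()
    if n < 2:
        raise ValueError("Simpson diversity needs n >= 2")
    return float(1.0 - (counts * (counts - 1)).sum() / (n * (n - 1)))


def shannon_h(level_counts) -> float:
    """Shannon-Wiener entropy of level frequencies in nats; empty levels
    contribute zero."""
    counts = np.asarray(level_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    n = counts.sum()
    if n < 1:
        raise ValueError("all counts zero")
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def evenness_e(h: float, k: int) -> float:
    """Evenness E = H / ln k; defined as 0 for a single-level trait."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        if h > 1e-12:
            raise ValueError("H > 0 impossible with a single level")
        return 0.0
    hmax = math.log(k)
    if h > hmax + 1e-9:
        raise ValueError(f"H={h} exceeds ln k={hmax}")
    return float(min(h / hmax, 1.0))


def mean_within_cv(obs: ObservationTable, trait: str) -> float:
    """Mean within-germplasm CV (%): average over germplasms of the
    replicate sd/mean ratio."""
    sub = obs.data[obs.data["trait_name"] == trait]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    cvs = []
    for gid, grp in sub.groupby("germplasm_id", sort=False):
        vals = grp["value"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"germplasm {gid!r} has <2 replicates for {trait!r}")
        mean = vals.mean()
        if mean == 0:
            raise ValueError(f"germplasm {gid!r} has zero mean for {trait!r}")
        cvs.append(vals.std(ddof=1) / mean * 100.0)
    return float(np.mean(cvs))


def among_cv(values) -> float:
    """Among-germplasm CV (%) of germplasm-level trait values."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("among-germplasm CV needs >= 2 germplasms")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("zero mean")
    return float(vals.std(ddof=1) / mean * 100.0)


# ---------------------------------------------------------------------------
# Per-trait tables and gates
# ---------------------------------------------------------------------------

def level_counts(matrix: TraitMatrix, trait: str) -> np.ndarray:
    """Count germplasms per declared level (absent levels count 0)."""
    t = matrix.codebook[trait]
    vals = matrix.data[trait].to_numpy().astype(int)
    return np.bincount(vals, minlength=t.k)


def compute_diversity(matrix: TraitMatrix,
                      traits: list[str] | None = None) -> pd.DataFrame:
    """D, H, E per qualitative trait of the germplasm-level matrix.

    k is the number of levels *declared* in the codebook; when fewer levels
    are observed this lowers E and is logged.
    """
    cb = matrix.codebook
    names = traits if traits is not None else [
        t for t in matrix.trait_names if cb.is_qualitative(t)]
    rows = []
    for trait in names:
        counts = level_counts(matrix, trait)
        k = cb[trait].k
        observed = int((counts > 0).sum())
        if observed < k:
            logger.info("trait %r: %d of %d declared levels observed",
                        trait, observed, k)
        h = shannon_h(counts)
        rows.append({
            "trait": trait,
            "n": int(counts.sum()),
            "k": k,
            "D": simpson_d(counts),
            "H": h,
            "E": evenness_e(h, k),
            "ni": ";".join(str(int(c)) for c in counts),
        })
    return pd.DataFrame(rows).set_index("trait")


def compute_variation(obs: ObservationTable, matrix: TraitMatrix,
                      traits: list[str] | None = None) -> pd.DataFrame:
    """CVbar (within) and CV (among) per quantitative trait."""
    cb = matrix.codebook
    names = traits if traits is not None else [
        t for t in matrix.trait_names if not cb.is_qualitative(t)]
    rows = []
    for trait in names:
        rows.append({
            "trait": trait,
            "mean_within_cv": mean_within_cv(obs, trait),
            "among_cv": among_cv(matrix.data[trait].to_numpy()),
        })
    return pd.DataFrame(rows).set_index("trait")


def screen_qualitative(div: pd.DataFrame,
                       th: ScreeningThresholds = ScreeningThresholds()) -> list[str]:
    """Retain qualitative traits passing all three inclusive gates."""
    retained = []
    for trait, row in div.iterrows():
        ok = (row["D"] >= th.d_min and row["H"] >= th.h_min
              and row["E"] >= th.e_min)
        if ok:
            retained.append(trait)
        else:
            gates = []
            if row["D"] < th.d_min:
                gates.append(f"D={row['D']:.3f}<{th.d_min}")
            if row["H"] < th.h_min:
                gates.append(f"H={row['H']:.3f}<{th.h_min}")
            if row["E"] < th.e_min:
                gates.append(f"E={row['E']:.3f}<{th.e_min}")
            logger.info("excluded qualitative trait %r (%s)", trait, ", ".join(gates))
    return retained


def screen_quantitative(var: pd.DataFrame,
                        th: ScreeningThresholds = ScreeningThresholds()) -> list[str]:
    """Retain quantitative traits with CVbar <= cvbar_max and CV >= cv_min."""
    retained = []
    for trait, row in var.iterrows():
        if row["mean_within_cv"] <= th.cvbar_max and row["among_cv"] >= th.cv_min:
            retained.append(trait)
        else:
            gates = []
            if row["mean_within_cv"] > th.cvbar_max:
                gates.append(f"CVbar={row['mean_within_cv']:.2f}%>{th.cvbar_max}%")
            if row["among_cv"] < th.cv_min:
                gates.append(f"CV={row['among_cv']:.2f}%<{th.cv_min}%")
            logger.info("excluded quantitative trait %r (%s)", trait, ", ".join(gates))
    return retained
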