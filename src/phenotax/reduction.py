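"""Stage-2 trait reduction: standardization, PCA retention, correlation pruning.

The screened germplasm-level matrix is z-scored column-wise, its trait
correlation matrix eigendecomposed, and components with eigenvalue
lambda >= lambda_min (default 0.90) retained. A trait is kept only if the
absolute value of its component loading (eigenvector entry x sqrt(lambda),
i.e. the trait-component correlation) on some retained component reaches
load_min (default 0.60); the rest are excluded as low-contribution.

Remaining redundancy is removed by pruning the graph of trait pairs with
|Pearson r| above r_max (default 0.80, strict). Survivors among correlated
pairs are chosen by an explicit, user-supplied preference list (the field
picks survivors on observational convenience, which no statistic encodes);
among non-preferred traits the highest-degree vertex is removed first, ties
broken alphabetically, until no conflicting pair remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .traitdata import TraitMatrix

logger = logging.getLogger("phenotax")

_LOAD_TOL = 1e-9


def standardize(m: TraitMatrix) -> TraitMatrix:
    """Column-wise z-scores (mean 0, sample sd 1, ddof=1)."""
    data = m.data.astype(float)
    sds = data.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    z = (data - data.mean()) / sds
    return TraitMatrix(z, m.codebook)


@dataclass
class PcaResult:
    """Eigenstructure of the trait correlation matrix.

    ``eigenvectors`` holds the raw orthonormal eigenvectors (V diag(lambda)
    V^T reconstructs the correlation matrix). ``loadings`` holds the
    component loadings V * sqrt(lambda) — each entry is the correlation
    between a trait and a component, the scale on which published component
    tables print and on which the low-contribution threshold operates."""

    eigenvalues: np.ndarray  # descending
    eigenvectors: pd.DataFrame  # traits x components, orthonormal columns
    loadings: pd.DataFrame  # traits x components, sqrt(lambda)-scaled
    contribution: np.ndarray  # percent of variance per component
    cumulative: np.ndarray  # running percent
    n_retained: int

    @property
    def retained_components(self) -> list[str]:
        return list(self.loadings.columns[: self.n_retained])

    def to_frame(self) -> pd.DataFrame:
        """Table with loadings plus eigenvalue / contribution footer rows."""
        out = self.loadings.copy()
        out.loc["Eigenvalue"] = self.eigenvalues
        out.loc["Variance contribution (%)"] = self.contribution
        out.loc["Cumulative contribution (%)"] = self.cumulative
        return out


def pca_retain(m: TraitMatrix, lambda_min: float = 0.90) -> PcaResult:
    """Eigendecompose the trait correlation matrix; keep components with
    eigenvalue >= lambda_min.

    The input should already be standardized (only column scale matters —
    the correlation matrix is recomputed here). Eigenvector signs follow the
    convention that the largest-magnitude entry is positive, so results are
    stable across linear-algebra backends. Slightly negative eigenvalues
    from rank deficiency are clipped at zero; anything below -1e-10 is an
    error.
    """
    X = m.data.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("PCA needs >= 2 traits and >= 3 germplasms")
    corr = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals.min() < -1e-10:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {evals.min()})")
    evals = np.clip(evals, 0.0, None)
    for j in range(p):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    contribution = evals / p * 100.0
    cols = [f"PC{j + 1}" for j in range(p)]
    eigenvectors = pd.DataFrame(evecs, index=m.trait_names, columns=cols)
    loadings = pd.DataFrame(evecs * np.sqrt(evals), index=m.trait_names,
                            columns=cols)
    n_retained = int((evals >= lambda_min - 1e-12).sum())
    return PcaResult(
        eigenvalues=evals,
        eigenvectors=eigenvectors,
        loadings=loadings,
        contribution=contribution,
        cumulative=np.cumsum(contribution),
        n_retained=n_retained,
    )


def low_contribution_filter(p: PcaResult, load_min: float = 0.60) -> list[str]:
    """Keep traits whose max |loading| over the retained components reaches
    load_min; order follows the input trait order."""
    if p.n_retained < 1:
        raise ValueError("no retained components")
    sub = p.loadings.iloc[:, : p.n_retained].abs()
    keep = sub.max(axis=1) >= load_min - _LOAD_TOL
    dropped = [t for t, k in keep.items() if not k]
    if dropped:
        logger.info("low-contribution traits excluded: %s", dropped)
    return [t for t, k in keep.items() if k]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class PruneReport:
    pairs: list[tuple[str, str, float]]  # conflicting pairs with their r
    removed: list[str]
    retained: list[str]
    preference: list[str]


def prune_conflicts(
    traits: list[str],
    edges: list[tuple[str, str, float]],
    preference: list[str] = (),
) -> PruneReport:
    """Greedy vertex removal on an explicit conflict graph.

    Preference-listed traits are kept; among non-preferred endpoints the
    highest-degree vertex is removed first (ties alphabetical). A conflict
    between two preferred traits keeps the earlier-listed one and removes
    the later, with a warning.
    """
    traits = list(traits)
    preference = [t for t in preference if t in traits]
    pref_rank = {t: i for i, t in enumerate(preference)}
    live = {(a, b) for a, b, _ in edges}
    removed: list[str] = []

    def degree(v: str) -> int:
        return sum(1 for a, b in live if v in (a, b))

    while live:
        candidates = sorted(
            {v for a, b in live for v in (a, b) if v not in pref_rank},
            key=lambda v: (-degree(v), v),
        )
        if candidates:
            victim = candidates[0]
        else:  # every remaining conflict is preferred-vs-preferred
            a, b = min(live)
            victim = a if pref_rank[a] > pref_rank[b] else b
            logger.warning(
                "conflict between preferred traits %r and %r; removing %r",
                a, b, victim,
            )
        removed.append(victim)
        live = {(a, b) for a, b in live if victim not in (a, b)}

    retained = [t for t in traits if t not in removed]
    return PruneReport(
        pairs=sorted(edges), removed=sorted(removed),
        retained=retained, preference=preference,
    )


def correlation_prune(
    m: TraitMatrix,
    traits: list[str] | None = None,
    r_max: float = 0.80,
    preference: list[str] = (),
) -> PruneReport:
    """Compute pairwise Pearson r among traits and prune pairs with |r| > r_max."""
    names = list(traits) if traits is not None else m.trait_names
    data = m.data[names]
    corr = data.corr(method="pearson")
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = corr.at[a, b]
            if abs(r) > r_max:
                edges.append((a, b, float(r)))
    report = prune_conflicts(names, edges, preference)
    # hard invariant: no retained pair above threshold
    for a, b, r in report.pairs:
        assert not (a in report.retained and b in report.retained), (a, b, r)
    return report
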