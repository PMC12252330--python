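"""Data model, encoding, validation and file I/O for phenotype trait tables.

The pipeline works on four artifacts:

* a **trait codebook** declaring each trait's kind (qualitative traits carry
  an ordered label->integer-code encoding; quantitative traits carry units),
* a **germplasm register** listing accessions (species or cultivars, with
  optional taxonomic section and parent ids),
* a leaf-level **observation table** (germplasm x replicate leaf x trait),
* an aggregated germplasm-level **trait matrix** used by all statistics.

All files are UTF-8, tab-delimited, '.' decimal separator. Codebooks may
also be stored as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("phenotax")

QUALITATIVE = "qualitative"
QUANTITATIVE = "quantitative"

SPECIES = "species"
CULTIVAR = "cultivar"


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trait:
    """One codebook entry.

    Qualitative traits use ordinal numerical coding: an ordered series of
    consecutive non-negative integer codes starting at 0 (binary traits are
    typically 0 = absent, 1 = present). Quantitative traits carry units and
    are used in numeric form directly.
    """

    name: str
    kind: str
    levels: tuple[tuple[str, int], ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (QUALITATIVE, QUANTITATIVE):
            raise ValueError(f"unknown trait kind {self.kind!r} for {self.name!r}")
        if self.kind == QUALITATIVE:
            if len(self.levels) < 1:
                raise ValueError(f"qualitative trait {self.name!r} has no levels")
            codes = [c for _, c in self.levels]
            if codes != list(range(len(codes))):
                raise ValueError(
                    f"trait {self.name!r}: non-consecutive codes {codes} "
                    "(must be 0,1,...,k-1)"
                )

    @property
    def k(self) -> int:
        """Number of declared levels (qualitative traits only)."""
        return len(self.levels)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for _, c in self.levels)


@dataclass(frozen=True)
class TraitCodebook:
    traits: tuple[Trait, ...]

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("no traits in codebook")
        names = [t.name for t in self.traits]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate trait name(s): {sorted(dupes)}")

    def __contains__(self, name: str) -> bool:
        return any(t.name == name for t in self.traits)

    def __getitem__(self, name: str) -> Trait:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def __iter__(self):
        return iter(self.traits)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    def qualitative(self) -> list[str]:
        return [t.name for t in self.traits if t.kind == QUALITATIVE]

    def quantitative(self) -> list[str]:
        return [t.name for t in self.traits if t.kind == QUANTITATIVE]

    def is_qualitative(self, name: str) -> bool:
        return self[name].kind == QUALITATIVE


def read_codebook(path: str | Path) -> TraitCodebook:
    """Read a codebook from JSON or TSV (dispatch on file extension).

    TSV columns: ``trait``, ``kind``, ``levels`` ("label:code;label:code"),
    ``units``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text(encoding="utf-8"))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.empty:
            raise ValueError(f"no traits in {path}")
        records = []
        for _, row in df.iterrows():
            rec = {"trait": row["trait"], "kind": row["kind"]}
            if row.get("levels"):
                rec["levels"] = [
                    {"label": part.rsplit(":", 1)[0], "code": int(part.rsplit(":", 1)[1])}
                    for part in row["levels"].split(";")
                    if part
                ]
            rec["units"] = row.get("units", "")
            records.append(rec)
    if not records:
        raise ValueError(f"no traits in {path}")
    traits = []
    for rec in records:
        levels = tuple(
            (lv["label"], int(lv["code"])) for lv in rec.get("levels") or ()
        )
        traits.append(
            Trait(name=rec["trait"], kind=rec["kind"], levels=levels,
                  units=rec.get("units", "") or "")
        )
    return TraitCodebook(tuple(traits))


def write_codebook(cb: TraitCodebook, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = [
            {
                "trait": t.name,
                "kind": t.kind,
                "levels": [{"label": lb, "code": c} for lb, c in t.levels],
                "units": t.units,
            }
            for t in cb.traits
        ]
        path.write_text(json.dumps(records, indent=1, ensure_ascii=False),
                        encoding="utf-8")
        return
    rows = [
        {
            "trait": t.name,
            "kind": t.kind,
            "levels": ";".join(f"{lb}:{c}" for lb, c in t.levels),
            "units": t.units,
        }
        for t in cb.traits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Germplasm register
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GermplasmRecord:
    id: str
    rank: str  # species | cultivar
    section: str | None = None
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rank not in (SPECIES, CULTIVAR):
            raise ValueError(f"unknown rank {self.rank!r} for {self.id!r}")


@dataclass(frozen=True)
class GermplasmRegister:
    records: tuple[GermplasmRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate germplasm id(s): {sorted(dupes)}")
        known = set(ids)
        for r in self.records:
            if r.section and r.rank != SPECIES:
                raise ValueError(f"section on non-species record {r.id!r}")
            for p in r.parents:
                if p not in known:
                    logger.warning(
                        "parent %r of %r not in register (flagged external)", p, r.id
                    )

    def __contains__(self, gid: str) -> bool:
        return any(r.id == gid for r in self.records)

    def __getitem__(self, gid: str) -> GermplasmRecord:
        for r in self.records:
            if r.id == gid:
                return r
        raise KeyError(gid)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def species_ids(self) -> list[str]:
        return [r.id for r in self.records if r.rank == SPECIES]

    def cultivar_ids(self) -> list[str]:
        return [r.id for r in self.records if r.rank == CULTIVAR]


def read_register(path: str | Path) -> GermplasmRegister:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = tuple(
        GermplasmRecord(
            id=row["id"],
            rank=row["rank"],
            section=row.get("section") or None,
            parents=tuple(p for p in (row.get("parents") or "").split("|") if p),
        )
        for _, row in df.iterrows()
    )
    return GermplasmRegister(records)


def write_register(reg: GermplasmRegister, path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "rank": r.rank,
            "section": r.section or "",
            "parents": "|".join(r.parents),
        }
        for r in reg.records
    ]
    pd.DataFrame(rows, columns=["id", "rank", "section", "parents"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Observation table
# ---------------------------------------------------------------------------

OBS_COLUMNS = ["germplasm_id", "replicate_id", "trait_name", "value"]


@dataclass
class ObservationTable:
    """Leaf-level replicate measurements, one row per (germplasm, leaf, trait)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation table missing column(s) {missing}")
        self.data = self.data[OBS_COLUMNS].copy()
        self.data["replicate_id"] = self.data["replicate_id"].astype(int)
        self.data["value"] = self.data["value"].astype(float)
        if (self.data["replicate_id"] < 0).any():
            raise ValueError("negative replicate id")
        if self.data["value"].isna().any():
            raise ValueError("missing observation value(s)")

    @property
    def germplasm_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["germplasm_id"]))

    @property
    def trait_names(self) -> list[str]:
        return list(dict.fromkeys(self.data["trait_name"]))

    def values_for(self, germplasm: str, trait: str) -> np.ndarray:
        sel = self.data[
            (self.data["germplasm_id"] == germplasm)
            & (self.data["trait_name"] == trait)
        ]
        return sel["value"].to_numpy()


def read_observations(path: str | Path) -> ObservationTable:
    df = pd.read_csv(path, sep="\t",
                     dtype={"germplasm_id": str, "trait_name": str})
    return ObservationTable(df)


def write_observations(obs: ObservationTable, path: str | Path) -> None:
    obs.data.to_csv(path, sep="\t", index=False)


def validate_observations(
    obs: ObservationTable,
    cb: TraitCodebook,
    register: GermplasmRegister | None = None,
) -> ObservationTable:
    """Check every observation against the codebook.

    Qualitative values must be valid integer codes. Rows for germplasms
    absent from the register are kept but logged (the register may be a
    subset of the measured collection). Unknown traits are errors.
    """
    unknown = set(obs.trait_names) - set(cb.names)
    if unknown:
        raise ValueError(f"trait(s) not in codebook: {sorted(unknown)}")
    for trait in obs.trait_names:
        t = cb[trait]
        if t.kind != QUALITATIVE:
            continue
        vals = obs.data.loc[obs.data["trait_name"] == trait, "value"]
        bad = vals[(vals % 1 != 0) | (vals < 0) | (vals > t.k - 1)]
        if not bad.empty:
            raise ValueError(
                f"trait {trait!r}: value(s) {sorted(set(bad))} outside codes 0..{t.k - 1}"
            )
    if register is not None:
        stray = set(obs.germplasm_ids) - set(register.ids)
        if stray:
            logger.warning(
                "%d germplasm(s) absent from register (rows kept): %s",
                len(stray), sorted(stray),
            )
    return obs


def _mode_smallest_code(values: np.ndarray) -> float:
    """Replicate mode; ties broken by the smallest code (deterministic)."""
    codes, counts = np.unique(values, return_counts=True)
    return float(codes[np.argmax(counts)])  # np.unique sorts ascending


# ---------------------------------------------------------------------------
# Trait matrix
# ---------------------------------------------------------------------------

@dataclass
class TraitMatrix:
    """Germplasm (rows) x trait (columns) numeric matrix with its codebook."""

    data: pd.DataFrame
    codebook: TraitCodebook

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("trait matrix has missing cells")
        extra = set(self.data.columns) - set(self.codebook.names)
        if extra:
            raise ValueError(f"matrix column(s) not in codebook: {sorted(extra)}")

    @property
    def germplasm_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, traits: list[str]) -> "TraitMatrix":
        return TraitMatrix(self.data[list(traits)].copy(), self.codebook)


def aggregate(obs: ObservationTable, cb: TraitCodebook) -> TraitMatrix:
    """Collapse replicate leaves to one row per germplasm.

    Quantitative traits take the replicate mean; qualitative traits take the
    replicate mode with ties broken by the smallest code. Both summaries are
    invariant to replicate order. A germplasm with zero replicates for any
    observed trait is an error (the design assumes complete observation).
    """
    validate_observations(obs, cb)
    germplasms = obs.germplasm_ids
    traits = obs.trait_names
    out = pd.DataFrame(index=pd.Index(germplasms, name="germplasm_id"),
                       columns=traits, dtype=float)
    grouped = obs.data.groupby(["germplasm_id", "trait_name"])["value"]
    cells = {key: grp.to_numpy() for key, grp in grouped}
    for g in germplasms:
        for trait in traits:
            vals = cells.get((g, trait))
            if vals is None or len(vals) == 0:
                raise ValueError(f"germplasm {g!r} has no replicates for {trait!r}")
            if cb.is_qualitative(trait):
                out.at[g, trait] = _mode_smallest_code(vals)
            else:
                out.at[g, trait] = float(np.mean(vals))
    return TraitMatrix(out, cb)


def write_matrix(m: TraitMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index=True)


def read_matrix(path: str | Path, cb: TraitCodebook) -> TraitMatrix:
    df = pd.read_csv(path, sep="\t", index_col="germplasm_id")
    df.index = df.index.astype(str)
    return TraitMatrix(df, cb)
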