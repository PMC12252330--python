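import numpy as np
import pandas as pd
import pytest

from phenotax import (
    GermplasmRecord,
    GermplasmRegister,
    ObservationTable,
    Trait,
    TraitCodebook,
    TraitMatrix,
    default_config,
    generate_population,
)


@pytest.fixture
def codebook() -> TraitCodebook:
    return TraitCodebook((
        Trait("Leaf texture", "qualitative",
              levels=(("Papery", 0), ("Leathery", 1))),
        Trait("Leaf apex shape", "qualitative",
              levels=(("Caudate", 0), ("Acuminate", 1), ("Acute", 2),
                      ("Obtuse", 3))),
        Trait("Leaf length", "quantitative", units="cm"),
    ))


@pytest.fixture
def observations() -> ObservationTable:
    rows = []
    for gid, tex, apex, lengths in [
        ("g1", [0, 0, 1], [1, 1, 1], [4.0, 6.0, 5.0]),
        ("g2", [1, 1, 1], [2, 2, 3], [8.0, 12.0, 10.0]),
        ("g3", [0, 1, 1], [0, 0, 0], [10.0, 10.0, 10.0]),
    ]:
        for r, (t, a, ln) in enumerate(zip(tex, apex, lengths)):
            rows += [(gid, r, "Leaf texture", float(t)),
                     (gid, r, "Leaf apex shape", float(a)),
                     (gid, r, "Leaf length", ln)]
    return ObservationTable(pd.DataFrame(
        rows, columns=["germplasm_id", "replicate_id", "trait_name", "value"]))


@pytest.fixture
def register() -> GermplasmRegister:
    return GermplasmRegister((
        GermplasmRecord("g1", "species", section="SectA"),
        GermplasmRecord("g2", "species", section="SectB"),
        GermplasmRecord("g3", "cultivar", parents=("g1",)),
    ))


@pytest.fixture(scope="session")
def population():
    """Study-scale synthetic dataset (34 species + 39 cultivars, seed 1)."""
    return generate_population(default_config(1))


def make_matrix(values: dict[str, list[float]],
                kinds: dict[str, str] | None = None,
                ids: list[str] | None = None) -> TraitMatrix:
    """Build a TraitMatrix from column lists; traits default to quantitative."""
    kinds = kinds or {}
    traits = []
    for name, col in values.items():
        kind = kinds.get(name, "quantitative")
        if kind == "qualitative":
            k = int(max(col)) + 1
            traits.append(Trait(name, "qualitative",
                                levels=tuple((f"L{c}", c) for c in range(k))))
        else:
            traits.append(Trait(name, "quantitative", units=""))
    cb = TraitCodebook(tuple(traits))
    n = len(next(iter(values.values())))
    idx = ids or [f"g{i + 1}" for i in range(n)]
    return TraitMatrix(pd.DataFrame(values, index=pd.Index(idx, name="germplasm_id"),
                                    dtype=float), cb)
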