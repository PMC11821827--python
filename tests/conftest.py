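"""Shared fixtures: a compact ten-trait schema and small synthetic inputs."""

import io

import numpy as np
import pandas as pd
import pytest

from benthovuln.schema import TraitDefinition, TraitSchema, default_schema
from benthovuln.trait_data import TraitTable


def make_toy_schema() -> TraitSchema:
    """Ten traits with small vocabularies: 5 nominal, 5 ordinal."""
    traits = []
    for i in range(10):
        code = chr(ord("A") + i)
        if i % 2 == 0:
            traits.append(
                TraitDefinition(code=code, name=f"nom{i}", kind="nominal", categories=("x", "y", "z"))
            )
        else:
            traits.append(
                TraitDefinition(
                    code=code, name=f"ord{i}", kind="ordinal", categories=("1", "2", "3", "4", "5")
                )
            )
    return TraitSchema(traits=tuple(traits))


@pytest.fixture(scope="session")
def toy_schema() -> TraitSchema:
    return make_toy_schema()


@pytest.fixture(scope="session")
def study_schema() -> TraitSchema:
    return default_schema()


def make_table(rows: dict[str, tuple], schema: TraitSchema, phylum: str = "Porifera") -> TraitTable:
    """Build a TraitTable from {species: 10-value signature}."""
    df = pd.DataFrame(
        {code: [sig[i] for sig in rows.values()] for i, code in enumerate(schema.codes)},
        index=pd.Index(list(rows), name="species"),
    )
    df.insert(0, "phylum", phylum)
    return TraitTable(df, schema)


@pytest.fixture
def toy_table(toy_schema) -> TraitTable:
    sig_a = ("x", "1", "x", "1", "x", "1", "x", "1", "x", "1")
    sig_b = ("y", "3", "x", "1", "x", "1", "x", "1", "x", "1")
    return make_table({"sp1": sig_a, "sp2": sig_a, "sp3": sig_b}, toy_schema)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210)


def random_table(schema: TraitSchema, n: int, rng: np.random.Generator, phylum="Cnidaria") -> TraitTable:
    rows = {}
    for i in range(n):
        sig = tuple(str(rng.choice(t.categories)) for t in schema)
        rows[f"s{i:04d}"] = sig
    return make_table(rows, schema, phylum=phylum)


def csv_buffer(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


def mc_hull_volume(points: np.ndarray, n_draws: int, rng) -> float:
    """Monte-Carlo rejection estimate of a convex-hull volume.

    Uniform draws in the bounding box are tested against the hull facet
    inequalities; an independent geometric oracle for the exact volume.
    """
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    box = np.prod(hi - lo)
    inside = 0
    eqs = hull.equations  # A x + b <= 0 inside
    for start in range(0, n_draws, 200_000):
        k = min(200_000, n_draws - start)
        draws = rng.uniform(lo, hi, size=(k, points.shape[1]))
        # facet blocks with progressive filtering: most draws fail early
        alive = draws
        for f0 in range(0, len(eqs), 48):
            blk = eqs[f0 : f0 + 48]
            ok = np.all(alive @ blk[:, :-1].T + blk[:, -1] <= 1e-12, axis=1)
            alive = alive[ok]
            if not len(alive):
                break
        inside += len(alive)
    return box * inside / n_draws
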