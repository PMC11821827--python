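"""Euclidean trait space from mixed nominal/ordinal traits.

Pipeline: Gower dissimilarity between trait signatures -> principal
coordinates analysis (classical metric scaling) -> choice of embedding
dimension m by minimizing the mean absolute deviation (mAD) between the
original Gower distances and the Euclidean distances in the first m axes.

Gower, per trait: nominal contributes 0/1 (match/mismatch); ordinal with K
ordered categories at ranks 1..K contributes |rank_i - rank_j| / (K - 1).
The dissimilarity is the unweighted mean over the ten traits, hence in
[0, 1]. No correction (Cailliez/Lingoes) is applied to negative PCoA
eigenvalues: their axes are dropped and their magnitudes reported, and mAD
selection operates on the uncorrected space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .schema import TraitSchema
from .trait_data import TraitTable, ValidationError, build_functional_entities

__all__ = [
    "DistanceMatrix",
    "TraitSpace",
    "gower_distance",
    "gower_from_signatures",
    "pcoa",
    "mad_quality",
    "select_dimension",
]

# eigenvalues below this fraction of the largest are treated as zero
_EIG_TOL = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with entries in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValidationError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path_or_buf) -> None:
        """Write the matrix as TSV with label headers on both axes."""
        import pandas as pd

        pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels)).to_csv(
            path_or_buf, sep="\t", index_label="label"
        )


@dataclass
class TraitSpace:
    """FE coordinates in a Euclidean embedding, with quality diagnostics.

    ``coordinates`` has one column per positive eigenvalue, ordered by
    descending eigenvalue; ``eigenvalues`` retains the full signed spectrum.
    ``mad_profile``/``m_selected`` are filled by :func:`select_dimension`.
    """

    labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    mad_profile: dict[int, float] = field(default_factory=dict)
    m_selected: int | None = None
    # memo for derived quantities (e.g. the global hull volume per dimension)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_positive_axes(self) -> int:
        return self.coordinates.shape[1]

    def selected_coordinates(self) -> np.ndarray:
        """Coordinates truncated to the selected dimensionality."""
        if self.m_selected is None:
            return self.coordinates
        return self.coordinates[:, : self.m_selected]

    def to_tsv(self, path_or_buf) -> None:
        """Write the coordinates as TSV (one row per label, one column per axis)."""
        import pandas as pd

        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        pd.DataFrame(self.coordinates, index=list(self.labels), columns=cols).to_csv(
            path_or_buf, sep="\t", index_label="label"
        )


def _podani_deltas(values: Sequence[str], trait) -> np.ndarray:
    """Tie-adjusted ordinal dissimilarities (Podani 1999) on realized values."""
    ranks = np.array([trait.rank(v) for v in values], dtype=float)
    r = rankdata(ranks)  # average ranks over realized data, ties shared
    # tie-group size for each object
    t = np.array([(ranks == x).sum() for x in ranks], dtype=float)
    rmin_mask = ranks == ranks.min()
    rmax_mask = ranks == ranks.max()
    t_min = rmin_mask.sum()
    t_max = rmax_mask.sum()
    denom = r.max() - r.min() - (t_max - 1) / 2 - (t_min - 1) / 2
    n = len(values)
    out = np.zeros((n, n))
    if denom <= 0:
        return out
    for i in range(n):
        num = np.abs(r[i] - r) - (t[i] - 1) / 2 - (t - 1) / 2
        out[i] = np.clip(num, 0.0, None) / denom
    out[np.equal.outer(ranks, ranks)] = 0.0
    return out


def gower_from_signatures(
    signatures: Sequence[tuple[str, ...]],
    labels: Sequence[str],
    schema: TraitSchema,
    ordinal: str = "classic",
) -> DistanceMatrix:
    """Gower dissimilarity matrix over a list of trait signatures.

    ``ordinal='classic'`` uses vocabulary ranks scaled by the vocabulary
    range (the default); ``'podani'`` uses tie-adjusted ranks computed on
    the realized values.
    """
    if len(signatures) < 2:
        raise ValidationError("need at least two rows to compute pairwise distances")
    if ordinal not in ("classic", "podani"):
        raise ValidationError(f"unknown ordinal mode {ordinal!r}")
    n = len(signatures)
    total = np.zeros((n, n))
    for k, trait in enumerate(schema):
        vals = [sig[k] for sig in signatures]
        if trait.kind == "nominal":
            codes = np.array([trait.rank(v) for v in vals])
            delta = (codes[:, None] != codes[None, :]).astype(float)
        elif ordinal == "podani":
            delta = _podani_deltas(vals, trait)
        else:
            ranks = np.array([trait.rank(v) for v in vals], dtype=float)
            if trait.n_categories == 1:
                delta = np.zeros((n, n))
            else:
                delta = np.abs(ranks[:, None] - ranks[None, :]) / (trait.n_categories - 1)
        total += delta
    d = total / len(schema.traits)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(labels), values=d)


def gower_distance(table: TraitTable, level: str = "fe", ordinal: str = "classic") -> DistanceMatrix:
    """Gower dissimilarities between species rows or FE signatures.

    At ``level='fe'`` one row per distinct signature is used, labelled by
    fe_id; at ``level='species'`` every row enters individually. Species
    sharing a signature are at distance zero, so the FE-level matrix is the
    species-level one with duplicate rows collapsed.
    """
    if level == "fe":
        fes = build_functional_entities(table)
        sigs = [fe.signature for fe in fes]
        labels = [fe.fe_id for fe in fes]
    elif level == "species":
        sigs = [table.signature(sp) for sp in table.species]
        labels = table.species
    else:
        raise ValidationError(f"level must be 'fe' or 'species', got {level!r}")
    return gower_from_signatures(sigs, labels, table.schema, ordinal=ordinal)


def pcoa(D: DistanceMatrix) -> TraitSpace:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centers -D^2/2, eigendecomposes, and returns coordinates on the
    positive-eigenvalue axes (columns sorted by descending eigenvalue),
    scaled by sqrt(eigenvalue). Negative eigenvalues are reported in the
    spectrum but contribute no axis.
    """
    n = D.n
    if n < 3:
        raise ValidationError(f"PCoA needs at least 3 points, got {n}")
    d2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = _EIG_TOL * max(abs(eigval).max(), 1e-300)
    pos = eigval > tol
    if not pos.any():
        # degenerate all-zero distance matrix: a single point
        return TraitSpace(labels=D.labels, coordinates=np.zeros((n, 1)), eigenvalues=eigval)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return TraitSpace(labels=D.labels, coordinates=coords, eigenvalues=eigval)


def mad_quality(D: DistanceMatrix, space: TraitSpace, m: int, rescale: bool = False) -> float:
    """Mean absolute deviation between input and embedded distances.

    Averages |d_gower(i,j) - d_euclid_m(i,j)| over all unordered pairs,
    where d_euclid_m uses the first m embedding axes. With ``rescale`` the
    embedded distances are first divided by their maximum, mapping them to
    [0, 1] like the Gower input.
    """
    if not 1 <= m <= space.n_positive_axes:
        raise ValidationError(
            f"m={m} outside available positive axes [1, {space.n_positive_axes}]"
        )
    emb = pdist(space.coordinates[:, :m])
    if rescale and emb.max() > 0:
        emb = emb / emb.max()
    orig = squareform(D.values, checks=False)
    return float(np.mean(np.abs(orig - emb)))


def select_dimension(
    D: DistanceMatrix,
    candidates: Iterable[int] = range(2, 11),
    rescale: bool = False,
) -> TraitSpace:
    """Embed and pick the dimensionality minimizing mAD.

    Candidates exceeding the number of positive axes are skipped. Ties —
    including floating-point-level ties on exactly Euclidean input — are
    broken toward the smallest m (within 1e-12 of the minimum).
    """
    space = pcoa(D)
    cands = sorted(c for c in candidates if 1 <= c <= space.n_positive_axes)
    if not cands:
        raise ValidationError(
            f"no candidate dimension within available axes (1..{space.n_positive_axes})"
        )
    profile = {m: mad_quality(D, space, m, rescale=rescale) for m in cands}
    best = min(profile.values())
    m_sel = min(m for m, v in profile.items() if v <= best + 1e-12)
    space.mad_profile = profile
    space.m_selected = m_sel
    return space
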