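"""Interaction-profile similarity and nearest-neighbor selection.

A gene's interaction profile is the vector of its measured S-scores against
all other genes in a screen.  Genes acting in the same pathway or complex
have correlated profiles, which is what makes a well-correlated "anchor" gene
from the overlap of two screens a usable stand-in for a gene screened in only
one of them.  Similarity is the Pearson correlation over co-measured
partners, with two exclusions: a gene's own column, and the mutual cell of
the two genes being compared (so a directly measured interaction between
them cannot inflate their similarity).

Correlations are computed from sufficient statistics (n, Σx, Σy, Σxy, Σx²,
Σy²) rather than from centered vectors.  This makes leave-one-out
withholding an O(#anchors) update (see :mod:`emaplink.validation`) and makes
exactly duplicated profiles yield r == 1.0 bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .emap_io import EMapMatrix
from .errors import ConfigurationError

#: default minimum number of co-measured partners required before a
#: correlation is trusted; at n = 70 a correlation of 0.6 has a two-sided
#: p-value below 1e-7, so chance similarity at this support is negligible.
DEFAULT_MIN_SUPPORT = 70

#: default similarity threshold a nearest neighbor must clear to be used.
DEFAULT_THRESHOLD = 0.6

# relative tolerance below which a restricted profile is treated as constant
# (correlation undefined) rather than risking a fabricated r of +/-1
_CONST_RTOL = 1e-12


@dataclass(frozen=True)
class ProfileSimilarity:
    """Pearson correlation between two genes' interaction profiles."""

    gene_x: str
    gene_y: str
    r: float
    n_common: int


@dataclass(frozen=True)
class NeighborAssignment:
    """A gene's best-correlated anchor within a designated anchor set."""

    gene: str
    neighbor: str
    r: float
    n_common: int


class _Sums(NamedTuple):
    """Per-anchor sufficient statistics of one query profile vs anchor profiles."""

    n: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    sxy: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    jm: np.ndarray  # (k, n_genes) joint measurement mask actually summed over


def matrix_arrays(emap: EMapMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Dense values and finite-mask of a matrix, in allele order."""
    v = emap.data.to_numpy(dtype=float)
    return v, np.isfinite(v)


def query_anchor_sums(
    values: np.ndarray, mask: np.ndarray, qi: int, anchor_idx: np.ndarray
) -> _Sums:
    """Sufficient statistics of gene ``qi``'s profile against each anchor row.

    Positions excluded from every comparison: column ``qi`` (the query's own
    column) and, per anchor, that anchor's own column — i.e. the mutual cell.
    """
    k = len(anchor_idx)
    my = mask[qi]
    jm = mask[anchor_idx] & my[None, :]
    jm[:, qi] = False
    jm[np.arange(k), anchor_idx] = False
    xm = np.where(jm, values[anchor_idx], 0.0)
    ym = np.where(jm, values[qi][None, :], 0.0)
    n = jm.sum(axis=1).astype(float)
    return _Sums(
        n=n,
        sx=xm.sum(axis=1),
        sy=ym.sum(axis=1),
        sxy=(xm * ym).sum(axis=1),
        sxx=(xm * xm).sum(axis=1),
        syy=(ym * ym).sum(axis=1),
        jm=jm,
    )


def r_from_sums(
    n: np.ndarray,
    sx: np.ndarray,
    sy: np.ndarray,
    sxy: np.ndarray,
    sxx: np.ndarray,
    syy: np.ndarray,
    min_support: int,
) -> np.ndarray:
    """Pearson r per anchor from sufficient statistics; NaN where undefined.

    Undefined when support is below ``min_support`` or either restricted
    profile is (numerically) constant.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        num = n * sxy - sx * sy
        ok = (n >= max(min_support, 2)) & (vx > _CONST_RTOL * n * sxx) & (
            vy > _CONST_RTOL * n * syy
        )
        r = np.where(ok, num / np.sqrt(vx * vy), np.nan)
    return np.clip(r, -1.0, 1.0)


def profile_similarity(
    emap: EMapMatrix, gene_x: str, gene_y: str, min_support: int = 3
) -> ProfileSimilarity | None:
    """Similarity of two genes' profiles, or None if undefined.

    Undefined when fewer than ``min_support`` partners are measured for both
    genes, or either restricted profile is constant.
    """
    if gene_x not in emap or gene_y not in emap:
        missing = gene_x if gene_x not in emap else gene_y
        raise KeyError(f"unknown allele {missing!r} in matrix {emap.name!r}")
    if gene_x == gene_y:
        return None
    values, mask = matrix_arrays(emap)
    pos = {g: i for i, g in enumerate(emap.alleles)}
    s = query_anchor_sums(values, mask, pos[gene_x], np.array([pos[gene_y]]))
    r = r_from_sums(s.n, s.sx, s.sy, s.sxy, s.sxx, s.syy, min_support)
    if np.isnan(r[0]):
        return None
    return ProfileSimilarity(gene_x, gene_y, float(r[0]), int(s.n[0]))


def similarity_matrix(
    emap: EMapMatrix,
    query_genes: Iterable[str],
    anchor_genes: Iterable[str],
    min_support: int = 3,
) -> list[ProfileSimilarity]:
    """All defined (query, anchor) profile similarities, ordered by identifier.

    A query appearing in the anchor set is never compared with itself.
    """
    queries = sorted(set(query_genes))
    anchors = sorted(set(anchor_genes))
    if not anchors:
        raise ConfigurationError("anchor set is empty")
    unknown = [g for g in queries + anchors if g not in emap]
    if unknown:
        raise KeyError(f"unknown allele(s) {unknown[:5]!r} in matrix {emap.name!r}")
    values, mask = matrix_arrays(emap)
    pos = {g: i for i, g in enumerate(emap.alleles)}
    anchor_idx = np.array([pos[a] for a in anchors])
    out: list[ProfileSimilarity] = []
    for q in queries:
        s = query_anchor_sums(values, mask, pos[q], anchor_idx)
        r = r_from_sums(s.n, s.sx, s.sy, s.sxy, s.sxx, s.syy, min_support)
        for a, ri, ni in zip(anchors, r, s.n):
            if a == q or np.isnan(ri):
                continue
            out.append(ProfileSimilarity(q, a, float(ri), int(ni)))
    return out


def nearest_neighbor(
    similarities: Iterable[ProfileSimilarity],
    gene: str,
    threshold: float,
) -> NeighborAssignment | None:
    """The gene's most-correlated anchor, if its r clears the threshold.

    Ties in r are broken by larger support, then lexicographically smaller
    anchor identifier — deterministic and seed-free.
    """
    best: ProfileSimilarity | None = None
    for s in similarities:
        if s.gene_x != gene:
            continue
        if best is None or (s.r, s.n_common, _revlex(s.gene_y)) > (
            best.r,
            best.n_common,
            _revlex(best.gene_y),
        ):
            best = s
    if best is None or best.r < threshold:
        return None
    return NeighborAssignment(gene, best.gene_y, best.r, best.n_common)


class _revlex(str):
    """String wrapper whose ordering is reversed, so max() picks the lexicographically smallest."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def best_anchor_table(
    emap: EMapMatrix,
    query_genes: Iterable[str],
    anchor_genes: Iterable[str],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> dict[str, NeighborAssignment]:
    """Per-query best anchor (no threshold applied), computed vectorized.

    Raising the similarity threshold never changes which anchor is nearest,
    only whether the assignment survives filtering, so the table is computed
    once and filtered downstream.
    """
    queries = sorted(set(query_genes))
    anchors = sorted(set(anchor_genes))
    if not anchors:
        raise ConfigurationError("anchor set is empty")
    values, mask = matrix_arrays(emap)
    pos = {g: i for i, g in enumerate(emap.alleles)}
    anchor_idx = np.array([pos[a] for a in anchors])
    table: dict[str, NeighborAssignment] = {}
    for q in queries:
        s = query_anchor_sums(values, mask, pos[q], anchor_idx)
        r = r_from_sums(s.n, s.sx, s.sy, s.sxy, s.sxx, s.syy, min_support)
        choice = _pick_best(anchors, r, s.n, exclude=q)
        if choice is not None:
            table[q] = NeighborAssignment(q, choice[0], choice[1], choice[2])
    return table


def _pick_best(
    anchors: Sequence[str], r: np.ndarray, n: np.ndarray, exclude: str | None = None
) -> tuple[str, float, int] | None:
    """Best (anchor, r, n) by r desc, support desc, identifier asc; None if all undefined."""
    best: tuple[float, float, _revlex, str] | None = None
    for a, ri, ni in zip(anchors, r, n):
        if a == exclude or np.isnan(ri):
            continue
        key = (ri, float(ni), _revlex(a))
        if best is None or key > best[:3]:
            best = (*key, a)
    if best is None:
        return None
    return best[3], float(best[0]), int(best[1])


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the t transformation.

    t = r * sqrt((n - 2) / (1 - r²)) follows Student's t with n - 2 degrees
    of freedom under the null of no correlation.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))
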