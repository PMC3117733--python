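"""Reading, writing and algebra for E-MAP S-score matrices and annotation data.

An E-MAP (Epistatic Miniarray Profile) screen yields a square, symmetric,
partially observed matrix of S-scores: a modified t-like statistic where
negative values indicate negative epistasis (the double disruption grows more
slowly than expected from the singles), positive values indicate positive
epistasis, and values near zero indicate the probable absence of an
interaction.  This module holds the matrix container plus the annotation,
gene-pair-category and protein-complex catalogs used downstream, and the
merging rules for combining several screens into one matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, SymmetryError, ValidationError

log = logging.getLogger(__name__)

#: cell contents treated as "not measured" when reading a matrix (case-insensitive)
MISSING_TOKENS = ("", "na", "nan", "none", "null")


def pair_key(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Canonical unordered representation of a gene pair."""
    if gene_a == gene_b:
        raise ValidationError(f"self-pair not allowed: {gene_a!r}")
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)


@dataclass
class EMapMatrix:
    """A symmetric, partially observed matrix of S-scores.

    ``data`` is a square float DataFrame indexed by allele identifiers on both
    axes; NaN marks a missing measurement.  Invariants (checked on
    construction): index equals columns and is unique, all present values are
    finite, the diagonal is absent (self-interactions are undefined), and the
    value at (i, j) is present iff it is present at (j, i), with equal values.
    """

    data: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("EMapMatrix.data must be a pandas DataFrame")
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValidationError(f"duplicate allele identifiers in matrix {self.name!r}")
        if not df.index.equals(df.columns):
            raise ValidationError(
                f"matrix {self.name!r}: row and column allele sets differ"
            )
        df = df.astype(float)
        a = df.to_numpy()
        if np.isinf(a).any():
            i, j = np.argwhere(np.isinf(a))[0]
            raise ValidationError(
                f"non-finite score at ({df.index[i]!r}, {df.columns[j]!r})"
            )
        if a.shape[0] and not np.all(np.isnan(np.diagonal(a))):
            bad = df.index[~np.isnan(np.diagonal(a))][0]
            raise ValidationError(f"diagonal entry present for allele {bad!r}")
        sym = (a == a.T) | (np.isnan(a) & np.isnan(a.T))
        if not sym.all():
            idx = np.argwhere(~sym)
            pairs = sorted(
                {pair_key(df.index[i], df.columns[j]) for i, j in idx[:20]}
            )
            raise SymmetryError(
                f"matrix {self.name!r} is not symmetric, e.g. at {pairs[:5]}", pairs
            )
        self.data = df

    # -- basic accessors ---------------------------------------------------

    @property
    def alleles(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_alleles(self) -> int:
        return len(self.data.index)

    def __contains__(self, allele: str) -> bool:
        return allele in self.data.index

    def get(self, gene_a: str, gene_b: str) -> float | None:
        """Return the measured S-score for a pair, or None if missing."""
        if gene_a not in self.data.index:
            raise KeyError(f"unknown allele {gene_a!r} in matrix {self.name!r}")
        if gene_b not in self.data.index:
            raise KeyError(f"unknown allele {gene_b!r} in matrix {self.name!r}")
        v = self.data.at[gene_a, gene_b]
        return None if pd.isna(v) else float(v)

    def is_measured(self, gene_a: str, gene_b: str) -> bool:
        return self.get(gene_a, gene_b) is not None

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        """Iterate measured unordered pairs as (allele_i, allele_j, score)."""
        a = self.data.to_numpy()
        idx = self.data.index
        for i, j in zip(*np.triu_indices(len(idx), k=1)):
            v = a[i, j]
            if not np.isnan(v):
                yield idx[i], idx[j], float(v)

    @property
    def n_measured(self) -> int:
        a = self.data.to_numpy()
        return int((~np.isnan(a[np.triu_indices(a.shape[0], k=1)])).sum())

    @property
    def missing_fraction(self) -> float:
        """Fraction of off-diagonal unordered pairs with no measurement."""
        n = self.n_alleles
        total = n * (n - 1) // 2
        return 1.0 - self.n_measured / total if total else 0.0

    def present_values(self) -> np.ndarray:
        """All measured S-scores, one entry per unordered pair."""
        a = self.data.to_numpy()
        tri = a[np.triu_indices(a.shape[0], k=1)]
        return tri[~np.isnan(tri)]

    def submatrix(self, alleles: Sequence[str]) -> "EMapMatrix":
        keep = [g for g in self.alleles if g in set(alleles)]
        return EMapMatrix(self.data.loc[keep, keep].copy(), name=self.name)

    def copy(self) -> "EMapMatrix":
        return EMapMatrix(self.data.copy(), name=self.name)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        alleles: Sequence[str],
        scores: Mapping[tuple[str, str], float],
        name: str = "",
    ) -> "EMapMatrix":
        """Build a matrix from an ordered allele list and unordered pair scores."""
        alleles = list(alleles)
        df = pd.DataFrame(np.nan, index=alleles, columns=alleles, dtype=float)
        for (a, b), v in scores.items():
            if a == b:
                raise ValidationError(f"diagonal entry given for allele {a!r}")
            df.at[a, b] = v
            df.at[b, a] = v
        return cls(df, name=name)


def read_emap(
    path: str | Path,
    *,
    dialect: str = "average",
    missing_tokens: Iterable[str] = MISSING_TOKENS,
    name: str | None = None,
) -> EMapMatrix:
    """Read an S-score matrix from a TSV file with row and column headers.

    Empty cells (or any token in ``missing_tokens``, case-insensitive) denote
    missing measurements.  Row and column allele sets are unioned into a square
    matrix.  Cells present in both orientations are reconciled per ``dialect``:
    ``"average"`` stores their arithmetic mean (with a logged warning when they
    disagree), ``"strict"`` raises :class:`SymmetryError` listing the offending
    pairs.  A cell present in only one orientation is taken at face value.
    """
    path = Path(path)
    if dialect not in ("average", "strict"):
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    tokens = {t.lower() for t in missing_tokens} | {""}
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = [str(x).strip() for x in raw.index]
    raw.columns = [str(x).strip() for x in raw.columns]
    if pd.Index(raw.index).has_duplicates or pd.Index(raw.columns).has_duplicates:
        raise FormatError(f"{path}: duplicate allele identifiers in headers")

    cells = raw.apply(lambda s: s.str.strip())
    is_missing = cells.apply(lambda s: s.str.lower().isin(tokens))
    num = cells.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & ~is_missing
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: unparseable value {cells.iat[i, j]!r} at row "
            f"{raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    inf = np.isinf(num.to_numpy())
    if inf.any():
        i, j = np.argwhere(inf)[0]
        raise ValidationError(
            f"{path}: non-finite score at row {raw.index[i]!r}, column {raw.columns[j]!r}"
        )

    order = list(raw.index) + [c for c in raw.columns if c not in set(raw.index)]
    full = pd.DataFrame(np.nan, index=order, columns=order, dtype=float)
    full.loc[raw.index, raw.columns] = num.to_numpy()

    a = full.to_numpy()
    upper, lower = a, a.T
    both = ~np.isnan(upper) & ~np.isnan(lower)
    conflict = both & (upper != lower)
    if conflict.any():
        idx = np.argwhere(conflict)
        offenders = sorted({pair_key(order[i], order[j]) for i, j in idx})
        if dialect == "strict":
            raise SymmetryError(
                f"{path}: asymmetric duplicate cells for pairs {offenders[:5]}"
                + ("..." if len(offenders) > 5 else ""),
                offenders,
            )
        log.warning(
            "%s: averaged %d asymmetric duplicate cell pair(s)", path, len(offenders)
        )
    merged = np.where(both, (upper + lower) / 2.0, np.where(~np.isnan(upper), upper, lower))
    np.fill_diagonal(merged, np.nan)
    out = pd.DataFrame(merged, index=order, columns=order)
    return EMapMatrix(out, name=name if name is not None else path.stem)


def write_emap(
    emap: EMapMatrix,
    path: str | Path,
    *,
    missing: str = "",
    float_format: str = "%.17g",
) -> None:
    """Write a matrix as TSV; ``%.17g`` round-trips float64 exactly."""
    emap.data.to_csv(path, sep="\t", na_rep=missing, float_format=float_format)


# ---------------------------------------------------------------------------
# Annotations, gene-pair categories, complex catalogs


@dataclass(frozen=True)
class AnnotationSet:
    """Mapping of annotation terms (GO Slim processes, phenotypes) to gene sets."""

    terms: Mapping[str, frozenset[str]]
    kind: str = "go_process"

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValidationError(f"annotation term {term!r} maps to no genes")

    def __len__(self) -> int:
        return len(self.terms)


def read_annotations(path: str | Path, kind: str = "go_process") -> AnnotationSet:
    """Read a two-column TSV (term, gene), no header."""
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'term<TAB>gene'")
        terms.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return AnnotationSet({t: frozenset(g) for t, g in terms.items()}, kind=kind)


def filter_annotations(ann: AnnotationSet, max_genes: int) -> AnnotationSet:
    """Drop every term annotating strictly more than ``max_genes`` genes.

    Broad terms ('viable', high-level GO processes) carry little pairwise
    functional signal; the conventional cutoffs are 1000 genes for GO Slim
    processes and 175 for phenotypes.  The bound is inclusive: a term with
    exactly ``max_genes`` genes is retained.
    """
    if max_genes < 1:
        raise ValidationError("max_genes must be >= 1")
    kept = {t: g for t, g in ann.terms.items() if len(g) <= max_genes}
    return AnnotationSet(kept, kind=ann.kind)


@dataclass(frozen=True)
class PairCategorySet:
    """A set of unordered gene pairs of one interaction polarity.

    The positive set typically aggregates 'Positive Genetic' and 'Synthetic
    Rescue' categories; the negative set 'Synthetic Lethality' and 'Synthetic
    Growth Defect'.
    """

    pairs: frozenset[tuple[str, str]]
    polarity: str = "negative"

    def __post_init__(self) -> None:
        canon = frozenset(pair_key(a, b) for a, b in self.pairs)
        object.__setattr__(self, "pairs", canon)

    def __len__(self) -> int:
        return len(self.pairs)


def read_pair_categories(
    path: str | Path, categories: Iterable[str], polarity: str
) -> PairCategorySet:
    """Read a three-column TSV (geneA, geneB, category) keeping listed categories."""
    wanted = set(categories)
    pairs: set[tuple[str, str]] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 'geneA<TAB>geneB<TAB>category'")
        a, b, cat = (p.strip() for p in parts[:3])
        if cat in wanted and a != b:
            pairs.add(pair_key(a, b))
    return PairCategorySet(frozenset(pairs), polarity=polarity)


@dataclass(frozen=True)
class ComplexCatalog:
    """Mapping of protein-complex names to member gene sets."""

    complexes: Mapping[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.complexes)

    def members_in(self, emap: EMapMatrix, name: str) -> set[str]:
        if name not in self.complexes:
            raise KeyError(f"unknown complex {name!r}")
        return set(self.complexes[name]) & set(emap.alleles)


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Read a two-column TSV (complex, gene), no header."""
    cx: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'complex<TAB>gene'")
        cx.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return ComplexCatalog({c: frozenset(g) for c, g in cx.items()})


# ---------------------------------------------------------------------------
# Matrix algebra


def _merge_with_counts(emaps: Sequence[EMapMatrix]) -> tuple[pd.DataFrame, np.ndarray]:
    """Union of allele sets; per-pair mean over the matrices measuring it."""
    order: list[str] = []
    seen: set[str] = set()
    for m in emaps:
        for g in m.alleles:
            if g not in seen:
                seen.add(g)
                order.append(g)
    n = len(order)
    pos = {g: i for i, g in enumerate(order)}
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for m in emaps:
        idx = np.array([pos[g] for g in m.alleles])
        a = m.data.to_numpy()
        mask = ~np.isnan(a)
        sums[np.ix_(idx, idx)] += np.where(mask, a, 0.0)
        counts[np.ix_(idx, idx)] += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        merged = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(merged, np.nan)
    np.fill_diagonal(counts, 0)
    return pd.DataFrame(merged, index=order, columns=order), counts


def merge_measured(emaps: Sequence[EMapMatrix]) -> EMapMatrix:
    """Merge several screens: per pair, the mean of all available measurements."""
    if not emaps:
        raise ConfigurationError("merge_measured requires at least one matrix")
    df, _ = _merge_with_counts(emaps)
    return EMapMatrix(df, name="+".join(m.name or "unnamed" for m in emaps))


def read_allele_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (allele, gene) collapsing allele names to genes."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'allele<TAB>gene'")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def collapse_alleles(emap: EMapMatrix, mapping: Mapping[str, str]) -> EMapMatrix:
    """Rename alleles to genes and average rows/columns that collapse together.

    Alleles absent from the mapping keep their identifier.  Useful before
    annotation or complex analysis, where external resources are keyed by gene
    rather than by allele (e.g. damp alleles).
    """
    new_names = [mapping.get(g, g) for g in emap.alleles]
    groups: dict[str, list[str]] = {}
    for old, new in zip(emap.alleles, new_names):
        groups.setdefault(new, []).append(old)
    parts = []
    for new, olds in groups.items():
        sub = emap.data.loc[olds, :].mean(axis=0, skipna=True)
        parts.append(sub.rename(new))
    rows = pd.DataFrame(parts)
    cols: dict[str, pd.Series] = {}
    for new, olds in groups.items():
        cols[new] = rows.loc[:, olds].mean(axis=1, skipna=True)
    out = pd.DataFrame(cols)
    out = out.loc[list(groups), list(groups)]
    # presence union: a pair measured in either orientation survives
    u = out.to_numpy()
    present = ~np.isnan(u) | ~np.isnan(u.T)
    avg = np.where(
        ~np.isnan(u) & ~np.isnan(u.T), (u + u.T) / 2.0, np.where(~np.isnan(u), u, u.T)
    )
    np.fill_diagonal(avg, np.nan)
    return EMapMatrix(
        pd.DataFrame(avg, index=out.index, columns=out.columns), name=emap.name
    )
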