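"""Combined E-MAP construction and monochromatic complex-link detection.

Protein complexes tend to interact with one another 'monochromatically': the
genetic interactions bridging two complexes are predominantly of one
polarity.  Given a combined matrix (measured screens plus cross-screen
predictions) and a complex catalog, a link between two complexes is called
when the median S-score of the values bridging their member genes is more
extreme than the medians of equal-sized random samples of interactions drawn
from the whole matrix.  Empirical p-values use the add-one correction and so
are never exactly zero; significance is conventionally P < 0.001 with 10^6
null samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .emap_io import ComplexCatalog, EMapMatrix, pair_key, _merge_with_counts
from .errors import ConfigurationError, ValidationError
from .predictor import PredictionSet

MEASURED, MEASURED_MULTI, PREDICTED = "measured", "measured_multi", "predicted"


@dataclass
class CombinedEMap:
    """A merged matrix with per-pair provenance (measured beats predicted)."""

    emap: EMapMatrix
    provenance: dict[tuple[str, str], str]

    def pool(self) -> np.ndarray:
        """All present values — the sampling pool for the permutation null."""
        return self.emap.present_values()


@dataclass(frozen=True)
class LinkTestConfig:
    n_samples: int = 1_000_000
    alpha: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ComplexLink:
    complex_a: str
    complex_b: str  # equal to complex_a for intra links
    n_interactions: int
    median_s: float
    p_value: float  # the smaller of the two one-sided tails
    polarity: str  # tail in which the median is extreme
    p_negative: float = 1.0  # lower-tail p: null medians <= observed
    p_positive: float = 1.0  # upper-tail p: null medians >= observed

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.complex_a, self.complex_b)))  # type: ignore[return-value]


def build_combined(
    measured: Sequence[EMapMatrix], predictions: Sequence[PredictionSet]
) -> CombinedEMap:
    """Merge screens and predictions into one matrix with provenance tags.

    Pairs measured in k screens take the mean of the k measurements (tag
    ``measured`` for k = 1, ``measured_multi`` for k > 1).  Predicted pairs are
    added only where no measurement exists; multiple predictions for one pair
    are averaged (tag ``predicted``).
    """
    if measured:
        merged_df, counts = _merge_with_counts(measured)
        order = list(merged_df.index)
    else:
        merged_df, counts = pd.DataFrame(dtype=float), np.zeros((0, 0), dtype=int)
        order = []
    pos = {g: i for i, g in enumerate(order)}

    pred_values: dict[tuple[str, str], list[float]] = {}
    for ps in predictions:
        for pair, score in ps.pair_scores().items():
            pred_values.setdefault(pair, []).append(score)

    new_genes = sorted(
        {g for pair in pred_values for g in pair if g not in pos}
    )
    full_order = order + new_genes
    n = len(full_order)
    fullpos = {g: i for i, g in enumerate(full_order)}
    a = np.full((n, n), np.nan)
    if order:
        a[: len(order), : len(order)] = merged_df.to_numpy()

    provenance: dict[tuple[str, str], str] = {}
    if order:
        m = merged_df.to_numpy()
        ii, jj = np.triu_indices(len(order), k=1)
        for i, j in zip(ii, jj):
            c = counts[i, j]
            if c > 0:
                provenance[pair_key(order[i], order[j])] = (
                    MEASURED if c == 1 else MEASURED_MULTI
                )
    for pair, vals in pred_values.items():
        if pair in provenance:
            continue  # a measured value is never overwritten by a prediction
        i, j = fullpos[pair[0]], fullpos[pair[1]]
        v = float(np.mean(vals))
        a[i, j] = a[j, i] = v
        provenance[pair] = PREDICTED
    df = pd.DataFrame(a, index=full_order, columns=full_order)
    name = "+".join([m.name or "unnamed" for m in measured] + (["predictions"] if predictions else []))
    return CombinedEMap(emap=EMapMatrix(df, name=name), provenance=provenance)


# ---------------------------------------------------------------------------
# Permutation test


def bridge_values(
    combined: CombinedEMap, catalog: ComplexCatalog, complex_a: str, complex_b: str
) -> list[float]:
    """Present S-scores connecting the two complexes' genes (or within one).

    For inter links, genes belonging to both complexes are excluded from both
    sides, so a value must connect two distinct genes, neither shared — an
    intra-complex value never counts as inter-complex evidence.  For intra
    links (``complex_a == complex_b``) all within-set pairs count.
    """
    genes_a = catalog.members_in(combined.emap, complex_a)
    genes_b = catalog.members_in(combined.emap, complex_b)
    vals: list[float] = []
    if complex_a == complex_b:
        for g, h in itertools.combinations(sorted(genes_a), 2):
            v = combined.emap.get(g, h)
            if v is not None:
                vals.append(v)
        return vals
    shared = genes_a & genes_b
    for g in sorted(genes_a - shared):
        for h in sorted(genes_b - shared):
            if g == h:
                continue
            v = combined.emap.get(g, h)
            if v is not None:
                vals.append(v)
    return vals


def _null_medians(pool: np.ndarray, k: int, n_samples: int, seed: int) -> np.ndarray:
    """Sorted medians of ``n_samples`` draws of k values without replacement.

    The generator is keyed on (seed, k), so every test of a bridge of size k
    under the same configuration sees the same null sample — a single pair
    test and a catalog-wide scan therefore agree exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
    n_pool = len(pool)
    if k > n_pool:
        raise ConfigurationError(
            f"bridge size {k} exceeds the {n_pool} available interactions"
        )
    meds = np.empty(n_samples)
    for t in range(n_samples):
        idx = rng.permutation(n_pool)[:k]
        meds[t] = np.median(pool[idx])
    meds.sort()
    return meds


def complex_link_test(
    combined: CombinedEMap,
    catalog: ComplexCatalog,
    pair: tuple[str, str],
    config: LinkTestConfig = LinkTestConfig(),
    _null_cache: dict[int, np.ndarray] | None = None,
) -> ComplexLink | None:
    """Median-interaction permutation test for one complex pair (or one complex).

    The observed statistic is the median of the bridging values; the null is
    the median of equal-sized random samples drawn without replacement from
    all present values of the combined matrix.  Each tail's empirical p uses
    the add-one correction, p = (1 + #{null at least as extreme}) / (1 + N);
    the smaller tail is reported with its polarity.  Returns None when no
    value bridges the pair.
    """
    values = bridge_values(combined, catalog, pair[0], pair[1])
    if not values:
        return None
    k = len(values)
    obs = float(np.median(values))
    if _null_cache is not None and k in _null_cache:
        meds = _null_cache[k]
    else:
        meds = _null_medians(combined.pool(), k, config.n_samples, config.seed)
        if _null_cache is not None:
            _null_cache[k] = meds
    n = len(meds)
    n_low = int(np.searchsorted(meds, obs, side="right"))  # null medians <= obs
    n_high = n - int(np.searchsorted(meds, obs, side="left"))  # null medians >= obs
    p_neg = (1 + n_low) / (1 + n)
    p_pos = (1 + n_high) / (1 + n)
    if p_neg <= p_pos:
        p, polarity = p_neg, "negative"
    else:
        p, polarity = p_pos, "positive"
    a, b = sorted(pair)
    return ComplexLink(
        complex_a=a,
        complex_b=b,
        n_interactions=k,
        median_s=obs,
        p_value=min(p, 1.0),
        polarity=polarity,
        p_negative=min(p_neg, 1.0),
        p_positive=min(p_pos, 1.0),
    )


def all_links(
    combined: CombinedEMap,
    catalog: ComplexCatalog,
    config: LinkTestConfig = LinkTestConfig(),
    mode: str = "inter",
) -> list[ComplexLink]:
    """All significant (p < alpha) inter- or intra-complex links.

    Complexes with fewer than two member genes in the matrix are skipped.
    Null medians are cached per bridge size, so the scan draws each size's
    null distribution once.
    """
    if mode not in ("inter", "intra"):
        raise ConfigurationError(f"mode must be 'inter' or 'intra', got {mode!r}")
    eligible = sorted(
        name
        for name in catalog.complexes
        if len(catalog.members_in(combined.emap, name)) >= 2
    )
    cache: dict[int, np.ndarray] = {}
    links: list[ComplexLink] = []
    if mode == "inter":
        candidates = itertools.combinations(eligible, 2)
    else:
        candidates = ((name, name) for name in eligible)
    for pair in candidates:
        link = complex_link_test(combined, catalog, pair, config, _null_cache=cache)
        if link is not None and link.p_value < config.alpha:
            links.append(link)
    links.sort(key=lambda l: (l.p_value, l.complex_a, l.complex_b))
    return links


@dataclass
class LinkDelta:
    """How the significant-link set changed when predictions were added."""

    novel: list[ComplexLink]
    reinforced: list[ComplexLink]
    unchanged: list[ComplexLink]
    lost: list[ComplexLink]


def link_delta(
    links_without: Sequence[ComplexLink], links_with: Sequence[ComplexLink]
) -> LinkDelta:
    """Classify links as novel, reinforced (more bridging support) or unchanged."""
    before = {l.key: l for l in links_without}
    after = {l.key: l for l in links_with}
    novel = [l for k, l in sorted(after.items()) if k not in before]
    reinforced = [
        l
        for k, l in sorted(after.items())
        if k in before and l.n_interactions > before[k].n_interactions
    ]
    unchanged = [
        l
        for k, l in sorted(after.items())
        if k in before and l.n_interactions == before[k].n_interactions
    ]
    lost = [l for k, l in sorted(before.items()) if k not in after]
    return LinkDelta(novel=novel, reinforced=reinforced, unchanged=unchanged, lost=lost)


# ---------------------------------------------------------------------------
# Export


def links_table(links: Sequence[ComplexLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "complex_a": l.complex_a,
                "complex_b": l.complex_b,
                "n_interactions": l.n_interactions,
                "median_s": l.median_s,
                "p_value": l.p_value,
                "polarity": l.polarity,
            }
            for l in links
        ],
        columns=["complex_a", "complex_b", "n_interactions", "median_s", "p_value", "polarity"],
    )


def write_links(links: Sequence[ComplexLink], path: str | Path) -> None:
    links_table(links).to_csv(path, sep="\t", index=False)


def links_to_graph(links: Sequence[ComplexLink]):
    """Signed complex-link graph: nodes are complexes, edges carry the test result."""
    import networkx as nx

    g = nx.Graph()
    for l in links:
        if l.complex_a == l.complex_b:
            g.add_node(l.complex_a, intra_median=l.median_s, intra_p=l.p_value)
        else:
            g.add_edge(
                l.complex_a,
                l.complex_b,
                median_s=l.median_s,
                p_value=l.p_value,
                polarity=l.polarity,
                n_interactions=l.n_interactions,
            )
    return g
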