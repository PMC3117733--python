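"""Annotation and interaction-category enrichment of predicted gene pairs.

Strongly epistatic gene pairs tend to act in the same biological process, so
accurate predictions should be enriched — relative to the background of all
predicted pairs — for shared GO Slim process annotations, shared phenotypes,
and prior identification in genetic-interaction screens (synthetic
sick/lethal categories for negative pairs, positive-genetic categories for
positive pairs).  Enrichment is the ratio of observed to expected overlap and
significance is the one-sided hypergeometric upper tail, matching the
direction of the claim being tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Set, Tuple

from scipy import stats

from .emap_io import AnnotationSet, PairCategorySet, pair_key
from .errors import ConfigurationError
from .predictor import NEGATIVE, POSITIVE, EpistasisThresholds, PredictionSet, classify

Pair = Tuple[str, str]


@dataclass(frozen=True)
class PairUniverse:
    """The background set of unordered gene pairs an enrichment is judged against."""

    pairs: frozenset[Pair]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", frozenset(pair_key(a, b) for a, b in self.pairs)
        )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EnrichmentResult:
    label: str
    polarity: str
    overlap: int
    expected: float
    enrichment: float
    p_value: float
    q_value: float | None = None  # Benjamini-Hochberg, filled by suite runs


def shared_annotation_pairs(universe: PairUniverse, ann: AnnotationSet) -> set[Pair]:
    """Pairs of the universe whose two genes co-occur in at least one term."""
    gene_terms: dict[str, set[str]] = {}
    for term, genes in ann.terms.items():
        for g in genes:
            gene_terms.setdefault(g, set()).add(term)
    out: set[Pair] = set()
    for a, b in universe.pairs:
        ta = gene_terms.get(a)
        if ta and not ta.isdisjoint(gene_terms.get(b, ())):
            out.add((a, b))
    return out


def enrich(
    tested_pairs: Set[Pair],
    property_pairs: Set[Pair],
    universe: PairUniverse,
    label: str = "",
    polarity: str = "",
) -> EnrichmentResult:
    """Fold enrichment and hypergeometric upper-tail p of tested vs property pairs.

    With N = |universe|, K = |property ∩ universe|, n = |tested| and k the
    observed overlap: expected = nK/N, enrichment = k/expected, and
    p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    """
    tested = {pair_key(a, b) for a, b in tested_pairs}
    prop = {pair_key(a, b) for a, b in property_pairs} & universe.pairs
    if not universe.pairs:
        raise ConfigurationError("empty pair universe")
    if not tested:
        raise ConfigurationError("empty tested pair set")
    if not tested <= universe.pairs:
        raise ConfigurationError("tested pairs must be a subset of the universe")
    N, K, n = len(universe.pairs), len(prop), len(tested)
    k = len(tested & prop)
    expected = n * K / N
    enrichment = k / expected if expected > 0 else 0.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        label=label,
        polarity=polarity,
        overlap=k,
        expected=expected,
        enrichment=enrichment,
        p_value=min(p, 1.0),
    )


def enrichment_suite(
    predset: PredictionSet,
    go: AnnotationSet,
    phenotypes: AnnotationSet,
    positive_categories: PairCategorySet,
    negative_categories: PairCategorySet,
    thresholds: EpistasisThresholds | None = None,
) -> list[EnrichmentResult]:
    """Enrichment of strong-positive and strong-negative predictions.

    For each polarity, the tested set is the predicted pairs of that class and
    the background universe is all predicted pairs from the same run (any
    class) — enrichment is judged against what the method could have called.
    Four properties per polarity: shared GO process term, shared phenotype,
    known positive-genetic pair, known synthetic-sick/lethal pair.  Raw
    p-values are reported; a Benjamini-Hochberg q-value column is filled in
    alongside for convenience.
    """
    th = thresholds if thresholds is not None else predset.thresholds
    universe = PairUniverse(
        frozenset(predset.pairs()), description="all predicted pairs of this run"
    )
    if not universe.pairs:
        raise ConfigurationError("prediction set is empty")
    by_class: dict[str, set[Pair]] = {POSITIVE: set(), NEGATIVE: set()}
    for pair, score in predset.pair_scores().items():
        cls = classify(score, th)
        if cls in by_class:
            by_class[cls].add(pair)
    properties = [
        ("go_process", shared_annotation_pairs(universe, go)),
        ("phenotype", shared_annotation_pairs(universe, phenotypes)),
        ("positive_genetic", set(positive_categories.pairs)),
        ("synthetic_sick", set(negative_categories.pairs)),
    ]
    results: list[EnrichmentResult] = []
    for polarity in (POSITIVE, NEGATIVE):
        tested = by_class[polarity]
        if not tested:
            warnings.warn(f"no predicted {polarity} pairs; skipping that polarity")
            continue
        for label, prop in properties:
            results.append(enrich(tested, prop, universe, label=label, polarity=polarity))
    if results:
        qs = stats.false_discovery_control([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results
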