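"""Cross-screen prediction of S-scores by constrained symmetric nearest neighbors.

Given two screens A and B sharing an overlap set A∩B, the method predicts the
S-score of an unmeasured pair (i, j) with i ∈ A\\B and j ∈ B\\A:

1. Within A, find i's nearest neighbor i' among the overlap genes (highest
   Pearson profile correlation); within B, find j's nearest neighbor j'.
2. A neighbor qualifies only if its correlation clears a similarity
   threshold (default 0.6) and is supported by enough co-measured partners
   (default 70).
3. If (i', j) is measured in B it is a source; if (i, j') is measured in A
   it is a source.  The prediction is the mean of the available sources; no
   prediction is emitted when neither exists.  Only the single nearest
   neighbor is consulted — there is no fallback to the second nearest.

Predictions are classified as positive (S > 2.0), negative (S < -2.5) or
neutral, the conventional strong-interaction cutoffs for E-MAP data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .emap_io import EMapMatrix, pair_key
from .errors import ConfigurationError, ValidationError
from .similarity import (
    DEFAULT_MIN_SUPPORT,
    DEFAULT_THRESHOLD,
    NeighborAssignment,
    best_anchor_table,
)

POSITIVE, NEUTRAL, NEGATIVE = "positive", "neutral", "negative"
CLASSES = (NEGATIVE, NEUTRAL, POSITIVE)


@dataclass(frozen=True)
class EpistasisThresholds:
    """S-score cutoffs separating strong interactions from neutral ones."""

    positive_min: float = 2.0
    negative_max: float = -2.5

    def __post_init__(self) -> None:
        if not (self.negative_max < 0.0 < self.positive_min):
            raise ValidationError(
                "epistasis thresholds must satisfy negative_max < 0 < positive_min"
            )


def classify(score: float, thresholds: EpistasisThresholds = EpistasisThresholds()) -> str:
    """Class of an S-score: strict inequalities, boundary values are neutral."""
    if not math.isfinite(score):
        raise ValidationError(f"cannot classify non-finite score {score!r}")
    if score < thresholds.negative_max:
        return NEGATIVE
    if score > thresholds.positive_min:
        return POSITIVE
    return NEUTRAL


@dataclass(frozen=True)
class PredictionSource:
    """Provenance of one measured value feeding a prediction."""

    matrix: str  # screen the value was read from
    pair: tuple[str, str]  # the measured pair (neighbor, target)
    value: float
    neighbor: str  # the anchor gene standing in for the unscreened gene
    r: float  # the neighbor's profile correlation


@dataclass(frozen=True)
class Prediction:
    gene_a: str  # from A \ B
    gene_b: str  # from B \ A
    score: float
    sources: tuple[PredictionSource, ...]
    epistasis_class: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.sources) <= 2:
            raise ValidationError("a prediction needs one or two sources")


@dataclass
class PredictionSet:
    """All predictions from one run, with the configuration that produced them."""

    predictions: list[Prediction]
    threshold: float
    min_support: int
    thresholds: EpistasisThresholds
    screen_a: str
    screen_b: str

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self) -> Iterator[Prediction]:
        return iter(self.predictions)

    def pair_scores(self) -> dict[tuple[str, str], float]:
        """Unordered-pair → predicted score."""
        return {pair_key(p.gene_a, p.gene_b): p.score for p in self.predictions}

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.pair_scores())


@dataclass(frozen=True)
class ThresholdCounts:
    total: int
    positive: int
    negative: int
    neutral: int


def qualifying_neighbors(
    emap: EMapMatrix,
    queries: Sequence[str],
    anchors: Sequence[str],
    threshold: float,
    min_support: int,
) -> dict[str, NeighborAssignment]:
    """Nearest overlap anchor per query gene, filtered at the threshold."""
    table = best_anchor_table(emap, queries, anchors, min_support)
    return {g: na for g, na in table.items() if na.r >= threshold}


def predict_cross(
    emap_a: EMapMatrix,
    emap_b: EMapMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
    thresholds: EpistasisThresholds = EpistasisThresholds(),
) -> PredictionSet:
    """Predict S-scores for every (A\\B) × (B\\A) pair with at least one source."""
    if not -1.0 <= threshold <= 1.0:
        raise ConfigurationError("similarity threshold must be in [-1, 1]")
    set_b = set(emap_b.alleles)
    set_a = set(emap_a.alleles)
    overlap = [g for g in emap_a.alleles if g in set_b]
    if not overlap:
        raise ConfigurationError(
            f"screens {emap_a.name!r} and {emap_b.name!r} share no alleles"
        )
    a_only = [g for g in emap_a.alleles if g not in set_b]
    b_only = [g for g in emap_b.alleles if g not in set_a]

    na = qualifying_neighbors(emap_a, a_only, overlap, threshold, min_support)
    nb = qualifying_neighbors(emap_b, b_only, overlap, threshold, min_support)

    vb = emap_b.data
    va = emap_a.data
    predictions: list[Prediction] = []
    for i in a_only:
        nbr_i = na.get(i)
        row_b = vb.loc[nbr_i.neighbor] if nbr_i is not None else None
        for j in b_only:
            sources: list[PredictionSource] = []
            if nbr_i is not None:
                v = row_b[j]
                if not pd.isna(v):
                    sources.append(
                        PredictionSource(
                            matrix=emap_b.name,
                            pair=(nbr_i.neighbor, j),
                            value=float(v),
                            neighbor=nbr_i.neighbor,
                            r=nbr_i.r,
                        )
                    )
            nbr_j = nb.get(j)
            if nbr_j is not None:
                v = va.at[i, nbr_j.neighbor]
                if not pd.isna(v):
                    sources.append(
                        PredictionSource(
                            matrix=emap_a.name,
                            pair=(i, nbr_j.neighbor),
                            value=float(v),
                            neighbor=nbr_j.neighbor,
                            r=nbr_j.r,
                        )
                    )
            if sources:
                score = float(np.mean([s.value for s in sources]))
                predictions.append(
                    Prediction(
                        gene_a=i,
                        gene_b=j,
                        score=score,
                        sources=tuple(sources),
                        epistasis_class=classify(score, thresholds),
                    )
                )
    return PredictionSet(
        predictions=predictions,
        threshold=threshold,
        min_support=min_support,
        thresholds=thresholds,
        screen_a=emap_a.name,
        screen_b=emap_b.name,
    )


def threshold_counts(
    predset: PredictionSet, thresholds: EpistasisThresholds | None = None
) -> ThresholdCounts:
    """Partition a prediction set into positive / negative / neutral counts."""
    th = thresholds if thresholds is not None else predset.thresholds
    pos = neg = neu = 0
    for p in predset:
        c = classify(p.score, th)
        if c == POSITIVE:
            pos += 1
        elif c == NEGATIVE:
            neg += 1
        else:
            neu += 1
    return ThresholdCounts(total=len(predset), positive=pos, negative=neg, neutral=neu)


# ---------------------------------------------------------------------------
# TSV interchange


def write_predictions(predset: PredictionSet, path: str | Path) -> None:
    rows = []
    for p in predset:
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "score": repr(p.score),
                "class": p.epistasis_class,
                "n_sources": len(p.sources),
                "sources": json.dumps(
                    [
                        {
                            "matrix": s.matrix,
                            "pair": list(s.pair),
                            "value": s.value,
                            "neighbor": s.neighbor,
                            "r": s.r,
                        }
                        for s in p.sources
                    ]
                ),
            }
        )
    header = "# screen_a=%s\tscreen_b=%s\tthreshold=%r\tmin_support=%d\tpositive_min=%r\tnegative_max=%r\n" % (
        predset.screen_a,
        predset.screen_b,
        predset.threshold,
        predset.min_support,
        predset.thresholds.positive_min,
        predset.thresholds.negative_max,
    )
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "score", "class", "n_sources", "sources"]
        ).to_csv(fh, sep="\t", index=False)


def read_predictions(path: str | Path) -> PredictionSet:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ConfigurationError(f"{path}: missing prediction-set header line")
        meta = dict(item.split("=", 1) for item in header[2:].rstrip("\n").split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype={"gene_a": str, "gene_b": str})
    thresholds = EpistasisThresholds(
        positive_min=float(meta["positive_min"]), negative_max=float(meta["negative_max"])
    )
    predictions = []
    for row in df.to_dict("records"):
        sources = tuple(
            PredictionSource(
                matrix=s["matrix"],
                pair=tuple(s["pair"]),
                value=float(s["value"]),
                neighbor=s["neighbor"],
                r=float(s["r"]),
            )
            for s in json.loads(row["sources"])
        )
        predictions.append(
            Prediction(
                gene_a=row["gene_a"],
                gene_b=row["gene_b"],
                score=float(row["score"]),
                sources=sources,
                epistasis_class=row["class"],
            )
        )
    return PredictionSet(
        predictions=predictions,
        threshold=float(meta["threshold"]),
        min_support=int(meta["min_support"]),
        thresholds=thresholds,
        screen_a=meta["screen_a"],
        screen_b=meta["screen_b"],
    )
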