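"""Accuracy quantification: leave-one-out validation, NRMSE/correlation, precision/recall.

The leave-one-out protocol withholds measured values between a screen-specific
gene i and an overlap gene s one cell at a time, re-derives i's nearest
neighbor from the remaining data, and attempts to predict the withheld value
through the same symmetric rule used for genuinely unmeasured pairs: one
source is the value (i', s) measured in the same screen via i's neighbor i';
the other is (i, s') via s's nearest neighbor s' determined in the partner
screen.  Both screens take each role in turn.

Withholding is applied as an O(#anchors) downdate of the correlation
sufficient statistics; a brute-force recomputation oracle in the test suite
checks agreement to 1e-10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .emap_io import EMapMatrix, pair_key
from .errors import ConfigurationError
from .predictor import (
    CLASSES,
    EpistasisThresholds,
    PredictionSet,
    classify,
)
from .similarity import (
    DEFAULT_MIN_SUPPORT,
    DEFAULT_THRESHOLD,
    _pick_best,
    best_anchor_table,
    matrix_arrays,
    query_anchor_sums,
    r_from_sums,
)

_CONST_RTOL = 1e-12


@dataclass(frozen=True)
class PairedRecord:
    observed: float
    predicted: float
    pair: tuple[str, str]
    threshold: float


@dataclass
class PairedScores:
    """Observed/predicted S-score pairs from a validation run."""

    records: list[PairedRecord]

    def __len__(self) -> int:
        return len(self.records)

    def observed(self) -> np.ndarray:
        return np.array([r.observed for r in self.records], dtype=float)

    def predicted(self) -> np.ndarray:
        return np.array([r.predicted for r in self.records], dtype=float)


@dataclass(frozen=True)
class SourceCandidate:
    """A potential prediction source for one withheld cell (threshold-free)."""

    value: float | None  # None when the neighbor qualifies but the cell is missing
    r: float
    neighbor: str


@dataclass(frozen=True)
class LooCandidate:
    """One withheld cell with its threshold-independent source candidates."""

    gene: str  # screen-specific gene (the A\B role)
    anchor: str  # overlap gene whose value was withheld
    screen: str
    observed: float
    via_gene_neighbor: SourceCandidate | None
    via_anchor_neighbor: SourceCandidate | None


@dataclass
class AccuracyReport:
    threshold: float | None
    n: int
    r_obs_pred: float | None
    nrmse: float | None
    confusion: pd.DataFrame  # observed class (rows) x predicted class (columns)


@dataclass(frozen=True)
class PrecisionRecall:
    epistasis_class: str
    precision: float | None
    recall: float | None
    tp: int
    fp: int
    fn: int


# ---------------------------------------------------------------------------
# Pearson helper (sums-based so identical vectors give exactly r = 1.0)


def pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation; None when either vector is (numerically) constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = float(len(x))
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= _CONST_RTOL * n * sxx or vy <= _CONST_RTOL * n * syy:
        return None
    r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Leave-one-out


def _direction_candidates(
    screen: EMapMatrix, partner: EMapMatrix, min_support: int
) -> list[LooCandidate]:
    """Candidates for withheld (gene, overlap) cells of one screen."""
    partner_set = set(partner.alleles)
    overlap = sorted(g for g in screen.alleles if g in partner_set)
    queries = sorted(g for g in screen.alleles if g not in partner_set)
    if not overlap or not queries:
        return []
    # each overlap gene's nearest neighbor within the partner screen (full data;
    # the withheld cell lives in `screen`, so partner-side similarities are fixed)
    partner_nn = best_anchor_table(partner, overlap, overlap, min_support)

    values, mask = matrix_arrays(screen)
    pos = {g: i for i, g in enumerate(screen.alleles)}
    anchor_idx = np.array([pos[s] for s in overlap])
    out: list[LooCandidate] = []
    for gene in queries:
        qi = pos[gene]
        base = query_anchor_sums(values, mask, qi, anchor_idx)
        for s_name in overlap:
            cs = pos[s_name]
            if not mask[qi, cs]:
                continue
            colmask = base.jm[:, cs]
            x_s = np.where(colmask, values[anchor_idx, cs], 0.0)
            y_s = np.where(colmask, values[qi, cs], 0.0)
            n = base.n - colmask
            r = r_from_sums(
                n,
                base.sx - x_s,
                base.sy - y_s,
                base.sxy - x_s * y_s,
                base.sxx - x_s * x_s,
                base.syy - y_s * y_s,
                min_support,
            )
            via_gene = None
            choice = _pick_best(overlap, r, n)
            if choice is not None:
                nbr, rbest, _ = choice
                v = values[pos[nbr], cs]
                via_gene = SourceCandidate(
                    value=float(v) if np.isfinite(v) else None, r=rbest, neighbor=nbr
                )
            via_anchor = None
            nb = partner_nn.get(s_name)
            if nb is not None:
                v = values[qi, pos[nb.neighbor]]
                via_anchor = SourceCandidate(
                    value=float(v) if np.isfinite(v) else None,
                    r=nb.r,
                    neighbor=nb.neighbor,
                )
            out.append(
                LooCandidate(
                    gene=gene,
                    anchor=s_name,
                    screen=screen.name,
                    observed=float(values[qi, cs]),
                    via_gene_neighbor=via_gene,
                    via_anchor_neighbor=via_anchor,
                )
            )
    return out


def loo_candidates(
    emap_a: EMapMatrix, emap_b: EMapMatrix, min_support: int = DEFAULT_MIN_SUPPORT
) -> list[LooCandidate]:
    """Threshold-independent leave-one-out candidates, both screen roles."""
    if not set(emap_a.alleles) & set(emap_b.alleles):
        raise ConfigurationError(
            f"screens {emap_a.name!r} and {emap_b.name!r} share no alleles"
        )
    return _direction_candidates(emap_a, emap_b, min_support) + _direction_candidates(
        emap_b, emap_a, min_support
    )


def evaluate_candidates(
    candidates: Iterable[LooCandidate], threshold: float
) -> PairedScores:
    """Apply a similarity threshold to candidates and emit paired scores."""
    records: list[PairedRecord] = []
    for c in candidates:
        vals = [
            sc.value
            for sc in (c.via_gene_neighbor, c.via_anchor_neighbor)
            if sc is not None and sc.r >= threshold and sc.value is not None
        ]
        if vals:
            records.append(
                PairedRecord(
                    observed=c.observed,
                    predicted=float(np.mean(vals)),
                    pair=(c.gene, c.anchor),
                    threshold=threshold,
                )
            )
    return PairedScores(records)


def leave_one_out(
    emap_a: EMapMatrix,
    emap_b: EMapMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> PairedScores:
    """Withhold each measured (screen-specific, overlap) value and predict it."""
    return evaluate_candidates(loo_candidates(emap_a, emap_b, min_support), threshold)


# ---------------------------------------------------------------------------
# Reports


def accuracy_report(
    pairs: PairedScores,
    thresholds: EpistasisThresholds = EpistasisThresholds(),
    normalizer: str = "stdev",
) -> AccuracyReport:
    """Correlation, NRMSE and 3x3 class confusion of observed vs predicted.

    NRMSE is the root mean squared prediction error divided by the sample
    standard deviation of the observed values (``normalizer="range"`` divides
    by max - min instead).  Both are None when the denominator degenerates.
    """
    if normalizer not in ("stdev", "range"):
        raise ConfigurationError(f"unknown NRMSE normalizer {normalizer!r}")
    n = len(pairs)
    confusion = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    threshold = None
    ts = {r.threshold for r in pairs.records}
    if len(ts) == 1:
        threshold = ts.pop()
    if n == 0:
        return AccuracyReport(threshold, 0, None, None, confusion)
    obs = pairs.observed()
    pred = pairs.predicted()
    for o, p in zip(obs, pred):
        confusion.at[classify(o, thresholds), classify(p, thresholds)] += 1
    r = pearson(obs, pred) if n >= 3 else None
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if normalizer == "stdev":
        denom = float(np.std(obs, ddof=1)) if n >= 2 else 0.0
    else:
        denom = float(np.ptp(obs))
    nrmse = rmse / denom if denom > 0 else None
    return AccuracyReport(threshold, n, r, nrmse, confusion)


def threshold_sweep(
    emap_a: EMapMatrix,
    emap_b: EMapMatrix,
    thresholds_list: Sequence[float],
    min_support: int = DEFAULT_MIN_SUPPORT,
    class_thresholds: EpistasisThresholds = EpistasisThresholds(),
) -> list[AccuracyReport]:
    """One accuracy report per similarity threshold, sharing one LOO pass.

    Candidate sources are threshold-independent (the nearest neighbor does not
    change as the threshold rises, only whether it qualifies), so one candidate
    computation serves every threshold and the reports are identical to
    independent single-threshold runs.
    """
    if not thresholds_list:
        raise ConfigurationError("thresholds_list must be non-empty")
    for t in thresholds_list:
        if not -1.0 <= t <= 1.0:
            raise ConfigurationError(f"similarity threshold {t!r} outside [-1, 1]")
    cands = loo_candidates(emap_a, emap_b, min_support)
    return [
        accuracy_report(evaluate_candidates(cands, t), class_thresholds)
        for t in thresholds_list
    ]


def precision_recall(
    predicted: Union[PredictionSet, PairedScores],
    gold: EMapMatrix,
    thresholds: EpistasisThresholds = EpistasisThresholds(),
) -> dict[str, PrecisionRecall]:
    """Per-class precision/recall of predictions against a gold-standard screen.

    Only pairs measured in the gold matrix are evaluated.  TP for class c
    counts pairs predicted c whose gold value also classifies as c; FP counts
    predicted-c pairs the gold contradicts; FN counts gold-c pairs predicted
    as some other class.  Precision is None when nothing was predicted as c.
    """
    if isinstance(predicted, PredictionSet):
        items = list(predicted.pair_scores().items())
    else:
        items = [(pair_key(*r.pair), r.predicted) for r in predicted.records]
    gold_genes = set(gold.alleles)
    observed_pairs: list[tuple[str, str]] = []
    for (a, b), score in items:
        if a in gold_genes and b in gold_genes and gold.get(a, b) is not None:
            observed_pairs.append(((a, b), score))  # type: ignore[arg-type]
    if not observed_pairs:
        warnings.warn("no predicted pair is measured in the gold-standard matrix")
        return {}
    labeled = [
        (classify(gold.get(a, b), thresholds), classify(score, thresholds))
        for (a, b), score in observed_pairs
    ]
    out: dict[str, PrecisionRecall] = {}
    for cls in CLASSES:
        tp = sum(1 for g, p in labeled if g == cls and p == cls)
        fp = sum(1 for g, p in labeled if g != cls and p == cls)
        fn = sum(1 for g, p in labeled if g == cls and p != cls)
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
        out[cls] = PrecisionRecall(cls, precision, recall, tp, fp, fn)
    return out
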