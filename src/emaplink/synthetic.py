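"""Ground-truthed synthetic overlapping E-MAP screens.

The generator emulates the statistical structure the cross-screen predictor
exploits, without modeling any particular organism: genes belong to latent
functional modules; a sparse subset of module pairs carries a nonzero mean
S-score (a planted monochromatic block, mostly negative, as strong negative
epistasis dominates real screens); every gene pair adds an independent
Gaussian residual.  Two screens observe noisy copies of this ground truth
over overlapping gene sets, each with its own independent missingness mask.

Defaults mirror the regimes reported for published screen pairs: about a
hundred shared genes, 12-35% missing entries per screen, and a cross-screen
correlation of roughly 0.5-0.7 over co-measured pairs.  With block density
0.10, block magnitudes U(2.5, 6) (70% negative), unit pairwise residual and
screen noise sd 1.2, the replicate correlation is Var(truth)/(Var(truth) +
noise²) ≈ 0.65.

All randomness flows from one seed through named SeedSequence children, so
each sub-stream (modules, blocks, residuals, per-screen noise and masks) is
independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .emap_io import ComplexCatalog, EMapMatrix
from .errors import ValidationError
from .predictor import EpistasisThresholds, PredictionSet
from .validation import AccuracyReport, PairedRecord, PairedScores, accuracy_report


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic screen pair."""

    n_shared: int = 100
    n_a_only: int = 150
    n_b_only: int = 150
    n_modules: int = 20
    #: explicit per-module-pair mean S-scores keyed by unordered (m1, m2);
    #: None plants blocks at random per the density/magnitude settings below
    block_effects: Mapping[tuple[int, int], float] | None = None
    block_density: float = 0.10
    block_magnitude: tuple[float, float] = (2.5, 6.0)
    negative_fraction: float = 0.7
    residual_sd: float = 1.0
    noise_sd: float = 1.2
    missing_frac_a: float = 0.30
    missing_frac_b: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_shared, self.n_a_only, self.n_b_only) < 0:
            raise ValidationError("gene counts must be >= 0")
        if self.n_modules < 1:
            raise ValidationError("need at least one module")
        for f in (self.missing_frac_a, self.missing_frac_b):
            if not 0.0 <= f < 1.0:
                raise ValidationError("missing fractions must be in [0, 1)")
        if self.noise_sd < 0 or self.residual_sd < 0:
            raise ValidationError("noise/residual sd must be >= 0")


@dataclass
class SyntheticTruth:
    """A fully observed truth matrix with its two masked, noisy screens."""

    truth: EMapMatrix
    screen_a: EMapMatrix
    screen_b: EMapMatrix
    module_assignment: dict[str, int]
    catalog: ComplexCatalog
    block_effects: dict[tuple[int, int], float]
    config: SyntheticConfig

    @property
    def shared_genes(self) -> list[str]:
        in_b = set(self.screen_b.alleles)
        return [g for g in self.screen_a.alleles if g in in_b]


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Symmetric matrix of iid N(0, sd) per unordered pair (exact zeros at sd=0)."""
    a = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    draws = rng.normal(0.0, 1.0, size=len(iu[0])) * sd
    a[iu] = draws
    return a + a.T


def _symmetric_mask(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """Boolean mask (True = missing) symmetric over unordered pairs."""
    m = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.random(len(iu[0])) < frac
    return m | m.T


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Draw one ground-truthed screen pair under the configured conditions."""
    if config.n_shared == 0 and (config.n_a_only or config.n_b_only):
        warnings.warn(
            "screens share no genes; downstream cross-screen prediction will fail"
        )
    ss = np.random.SeedSequence(config.seed)
    s_mod, s_block, s_res, s_noise_a, s_noise_b, s_mask_a, s_mask_b = ss.spawn(7)

    shared = [f"gs{i:03d}" for i in range(config.n_shared)]
    a_only = [f"ga{i:03d}" for i in range(config.n_a_only)]
    b_only = [f"gb{i:03d}" for i in range(config.n_b_only)]
    genes = shared + a_only + b_only
    n = len(genes)

    rng_mod = np.random.default_rng(s_mod)
    modules = rng_mod.integers(0, config.n_modules, size=n)
    module_assignment = dict(zip(genes, (int(m) for m in modules)))

    if config.block_effects is not None:
        effects = {
            tuple(sorted(k)): float(v) for k, v in config.block_effects.items()
        }
    else:
        rng_block = np.random.default_rng(s_block)
        effects = {}
        lo, hi = config.block_magnitude
        for m1 in range(config.n_modules):
            for m2 in range(m1, config.n_modules):
                if rng_block.random() < config.block_density:
                    mag = rng_block.uniform(lo, hi)
                    sign = -1.0 if rng_block.random() < config.negative_fraction else 1.0
                    effects[(m1, m2)] = sign * mag

    block_lut = np.zeros((config.n_modules, config.n_modules))
    for (m1, m2), v in effects.items():
        block_lut[m1, m2] = block_lut[m2, m1] = v
    truth_vals = block_lut[np.ix_(modules, modules)] + _symmetric_noise(
        np.random.default_rng(s_res), n, config.residual_sd
    )
    np.fill_diagonal(truth_vals, np.nan)
    truth_df = pd.DataFrame(truth_vals, index=genes, columns=genes)
    truth = EMapMatrix(truth_df, name="synthetic_truth")

    def _screen(gene_list, noise_seed, mask_seed, frac, label):
        idx = [genes.index(g) for g in gene_list]
        sub = truth_vals[np.ix_(idx, idx)].copy()
        k = len(gene_list)
        sub = sub + _symmetric_noise(np.random.default_rng(noise_seed), k, config.noise_sd)
        mask = _symmetric_mask(np.random.default_rng(mask_seed), k, frac)
        sub[mask] = np.nan
        np.fill_diagonal(sub, np.nan)
        return EMapMatrix(
            pd.DataFrame(sub, index=gene_list, columns=gene_list), name=label
        )

    screen_a = _screen(shared + a_only, s_noise_a, s_mask_a, config.missing_frac_a, "synthetic_A")
    screen_b = _screen(shared + b_only, s_noise_b, s_mask_b, config.missing_frac_b, "synthetic_B")

    members: dict[str, set[str]] = {}
    for g, m in module_assignment.items():
        members.setdefault(f"M{m:02d}", set()).add(g)
    catalog = ComplexCatalog({c: frozenset(gs) for c, gs in sorted(members.items())})

    return SyntheticTruth(
        truth=truth,
        screen_a=screen_a,
        screen_b=screen_b,
        module_assignment=module_assignment,
        catalog=catalog,
        block_effects=effects,
        config=config,
    )


def score_predictions(
    predset: PredictionSet,
    truth: SyntheticTruth,
    thresholds: EpistasisThresholds = EpistasisThresholds(),
) -> AccuracyReport:
    """Accuracy of cross-screen predictions against the ground-truth matrix."""
    records = []
    for pair, score in predset.pair_scores().items():
        a, b = pair
        if a not in truth.truth or b not in truth.truth:
            raise ValidationError(f"predicted pair {pair!r} absent from the truth matrix")
        tv = truth.truth.get(a, b)
        if tv is None:
            raise ValidationError(f"truth value missing for pair {pair!r}")
        records.append(
            PairedRecord(
                observed=tv, predicted=score, pair=pair, threshold=predset.threshold
            )
        )
    return accuracy_report(PairedScores(records), thresholds)
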