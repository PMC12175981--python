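"""Synthetic volatile profiles and behavioral trials with planted structure.

The generator plants a latent attractiveness axis ``a`` (one value per
product, evenly spaced then jittered) and builds compound proportions as

    value[i, j] = baseline[j] * (1 + alpha[j]*a[i] + gamma[j]*h[i]) * lognormal noise

where ``h`` is a second latent direction orthogonal to ``a`` (and to the
constant), used by panel "hybrid" compounds. Group baselines are balanced so
that every row total is constant before noise: closure to 100% is then a
constant rescale and, at ``noise_sd = 0``, planted compounds are *exactly*
linear in ``a`` — positives/negatives reach Pearson r = ±1 with the
attractiveness score, hybrids land strictly between, and null compounds are
constant.

The planted panel block is positives + negatives + hybrids; the seed set
mirrors the published structure (1 positive seed + all negative compounds).

Behavioral generators choose arms by a softmax on ``a``. At ``noise_sd = 0``
they emit rounded expected counts (deterministic); otherwise counts are
multinomial draws. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .profiles import ProfileMatrix, normalize_proportions, write_profile_table
from .tmaze import ChoiceTrial
from .trap import TrapTrial

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_profiles",
    "generate_choice_trials",
    "generate_trap_trials",
    "write_bundle",
]

#: ratio of hybrid h-loading to a-loading; sets how far hybrid correlations
#: fall below |r| = 1 (must stay clear of both 1 and the panel min_r).
_HYBRID_RATIO = 1.2


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic generator (defaults mirror the published
    9-product x 110-compound, 10-positive/4-negative, 21-panel geometry)."""

    n_products: int = 9
    n_compounds: int = 110
    n_pos: int = 10
    n_neg: int = 4
    panel_block: int = 21
    effect: float = 0.35
    noise_sd: float = 0.1
    choice_beta: float = 4.0
    p_nochoice: float = 0.2
    n_flies: int = 100
    n_blinds: int = 0
    blind_latents: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_products < 2:
            raise ConfigError("need at least 2 products")
        if self.n_pos < 0 or self.n_neg < 0 or self.n_blinds < 0:
            raise ConfigError("counts must be >= 0")
        if self.n_pos + self.n_neg > self.panel_block:
            raise ConfigError("panel_block must contain the positive and negative sets")
        if self.panel_block > self.n_compounds:
            raise ConfigError("panel_block cannot exceed n_compounds")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("need at least one positive and one negative compound")
        if not 0 < self.effect < 1.0 / (1.0 + _HYBRID_RATIO):
            raise ConfigError(
                f"effect must lie in (0, {1.0 / (1.0 + _HYBRID_RATIO):.3f}) "
                "to keep proportions positive"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.p_nochoice < 1:
            raise ConfigError("p_nochoice must be in [0, 1)")
        if self.n_flies < 1:
            raise ConfigError("n_flies must be >= 1")
        if self.blind_latents is not None and len(self.blind_latents) != self.n_blinds:
            raise ConfigError("blind_latents length must equal n_blinds")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_toml(cls, path) -> "SynthConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "blind_latents" in raw and raw["blind_latents"] is not None:
            raw["blind_latents"] = tuple(raw["blind_latents"])
        return cls(**raw)


@dataclass
class SynthTruth:
    """Ground truth planted by the generator."""

    latent: dict[str, float]  # product -> latent attractiveness (incl. blinds)
    benchmarks: list[str]
    blinds: list[str]
    planted_positive: list[str]
    planted_negative: list[str]
    planted_panel: list[str]
    seeds: list[str]
    true_ranking: list[str]  # benchmarks sorted by latent, most attractive first

    # internals needed to extend the generator to new latent values
    h_coeffs: tuple[float, float, float] = (0.0, 0.0, 1.0)  # c0, c1, scale

    def h_of(self, a: float) -> float:
        c0, c1, scale = self.h_coeffs
        return (a * a - c0 - c1 * a) / scale

    def score(self, product: str) -> int:
        """Planted attractiveness score (n + 1 - true rank) of a benchmark."""
        n = len(self.true_ranking)
        return n - self.true_ranking.index(product)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2)


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _latents(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    a = np.linspace(-1.0, 1.0, cfg.n_products)
    if cfg.noise_sd > 0:
        spacing = 2.0 / (cfg.n_products - 1)
        a = a + rng.normal(0.0, 0.25 * cfg.noise_sd * spacing, size=a.size)
    return a


def _orthogonal_factor(a: np.ndarray) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Quadratic direction orthogonalized against [1, a], scaled to max|h|=1."""
    design = np.column_stack([np.ones_like(a), a])
    coef, *_ = np.linalg.lstsq(design, a * a, rcond=None)
    h = a * a - design @ coef
    scale = float(np.max(np.abs(h)))
    if scale <= 0:  # < 3 distinct products: no quadratic direction
        return np.zeros_like(a), (float(coef[0]), float(coef[1]), 1.0)
    return h / scale, (float(coef[0]), float(coef[1]), scale)


def generate_profiles(cfg: SynthConfig) -> tuple[ProfileMatrix, SynthTruth]:
    """Generate the products x compounds proportion matrix plus ground truth."""
    rng = _rng(cfg, 1)
    a = _latents(cfg, rng)
    h, h_coeffs = _orthogonal_factor(a)

    benchmarks = [f"P{i + 1:02d}" for i in range(cfg.n_products)]
    if cfg.blind_latents is not None:
        blind_a = np.asarray(cfg.blind_latents, dtype=float)
    else:
        blind_a = rng.uniform(-1.0, 1.0, size=cfg.n_blinds)
    blinds = [f"B{i + 1:02d}" for i in range(cfg.n_blinds)]

    compounds = [f"C{i + 1:03d}" for i in range(cfg.n_compounds)]
    order = rng.permutation(cfg.n_compounds)
    n_h = cfg.panel_block - cfg.n_pos - cfg.n_neg
    pos_idx = order[: cfg.n_pos]
    neg_idx = order[cfg.n_pos : cfg.n_pos + cfg.n_neg]
    hyb_idx = order[cfg.n_pos + cfg.n_neg : cfg.panel_block]

    baselines = rng.lognormal(mean=0.0, sigma=0.8, size=cfg.n_compounds)
    alpha = np.zeros(cfg.n_compounds)
    gamma = np.zeros(cfg.n_compounds)
    magnitude = cfg.effect * rng.uniform(0.7, 1.0, size=cfg.n_compounds)
    alpha[pos_idx] = magnitude[pos_idx]
    alpha[neg_idx] = -magnitude[neg_idx]
    # hybrids: a-loading plus an orthogonal h-loading in fixed ratio, split
    # into a +/+ and a -/- group so both sums can be balanced at once
    n_plus = (n_h + 1) // 2
    hyb_plus, hyb_minus = hyb_idx[:n_plus], hyb_idx[n_plus:]
    alpha[hyb_plus] = magnitude[hyb_plus]
    gamma[hyb_plus] = _HYBRID_RATIO * magnitude[hyb_plus]
    alpha[hyb_minus] = -magnitude[hyb_minus]
    gamma[hyb_minus] = -_HYBRID_RATIO * magnitude[hyb_minus]

    # balance the weighted loading sums so row totals are constant pre-noise
    pos_sum = float(np.sum(baselines[pos_idx] * alpha[pos_idx]))
    neg_sum = float(np.sum(baselines[neg_idx] * -alpha[neg_idx]))
    baselines[neg_idx] *= pos_sum / neg_sum
    if len(hyb_minus):
        plus_sum = float(np.sum(baselines[hyb_plus] * alpha[hyb_plus]))
        minus_sum = float(np.sum(baselines[hyb_minus] * -alpha[hyb_minus]))
        baselines[hyb_minus] *= plus_sum / minus_sum
    elif len(hyb_plus):
        # no counter-group: cancel against an enlarged negative group instead
        plus_sum = float(np.sum(baselines[hyb_plus] * alpha[hyb_plus]))
        baselines[neg_idx] *= 1.0 + plus_sum / pos_sum

    all_ids = benchmarks + blinds
    all_a = np.concatenate([a, blind_a])
    all_h = np.concatenate([h, [_h_from(h_coeffs, v) for v in blind_a]])
    structure = 1.0 + np.outer(all_a, alpha) + np.outer(all_h, gamma)
    if (structure <= 0).any():
        raise ConfigError("internal: non-positive structural term; lower effect")
    values = structure * baselines[np.newaxis, :]
    if cfg.noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, cfg.noise_sd, size=values.shape))
        frame = pd.DataFrame(values, index=all_ids, columns=compounds)
        matrix = normalize_proportions(ProfileMatrix(frame))
    else:
        # noiseless rows have identical totals in exact arithmetic; divide by
        # one scalar so null columns stay exactly constant (no per-row float
        # jitter) and planted columns stay exactly linear in the latent
        scale = 100.0 / float(np.mean(values.sum(axis=1)))
        matrix = ProfileMatrix(
            pd.DataFrame(values * scale, index=all_ids, columns=compounds)
        )

    latent = dict(zip(all_ids, map(float, all_a)))
    bench_sorted = [p for p in sorted(benchmarks, key=lambda p: -latent[p])]
    planted_pos = [compounds[i] for i in sorted(pos_idx)]
    planted_neg = [compounds[i] for i in sorted(neg_idx)]
    planted_panel = sorted(
        planted_pos + planted_neg + [compounds[i] for i in sorted(hyb_idx)]
    )
    seeds = [planted_pos[0]] + planted_neg  # 1 positive + all negatives
    truth = SynthTruth(
        latent=latent,
        benchmarks=benchmarks,
        blinds=blinds,
        planted_positive=planted_pos,
        planted_negative=planted_neg,
        planted_panel=planted_panel,
        seeds=seeds,
        true_ranking=bench_sorted,
        h_coeffs=h_coeffs,
    )
    return matrix, truth


def _h_from(h_coeffs: tuple[float, float, float], a: float) -> float:
    c0, c1, scale = h_coeffs
    return (a * a - c0 - c1 * a) / scale


def _choice_counts(
    p1: float, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[int, int, int]:
    """(n arm 1, n arm 2, n no-choice) for one trial."""
    if cfg.noise_sd == 0:
        responders = int(round(cfg.n_flies * (1.0 - cfg.p_nochoice)))
        n1 = int(round(responders * p1))
        return n1, responders - n1, cfg.n_flies - responders
    probs = [(1 - cfg.p_nochoice) * p1, (1 - cfg.p_nochoice) * (1 - p1), cfg.p_nochoice]
    n1, n2, none = rng.multinomial(cfg.n_flies, probs)
    return int(n1), int(n2), int(none)


def _softmax_pair(a1: float, a2: float, beta: float) -> float:
    from scipy.special import expit

    return float(expit(beta * (a1 - a2)))


def generate_choice_trials(
    truth: SynthTruth,
    cfg: SynthConfig,
    design: Literal["round_robin", "calibrator"] = "calibrator",
) -> list[ChoiceTrial]:
    """Simulate T-maze trials among the benchmark products.

    ``round_robin`` emits one trial per unordered pair in a single round.
    ``calibrator`` walks products from least to most attractive: round r's
    calibrator meets every not-yet-excluded product, then leaves the pool
    (the most attractive product is never a calibrator).
    """
    rng = _rng(cfg, 2)
    products = truth.benchmarks
    if len(products) < 2:
        raise ConfigError("need >= 2 products for choice trials")
    lat = truth.latent
    trials: list[ChoiceTrial] = []
    if design == "round_robin":
        for i, p in enumerate(products):
            for q in products[i + 1 :]:
                p1 = _softmax_pair(lat[p], lat[q], cfg.choice_beta)
                n1, n2, none = _choice_counts(p1, cfg, rng)
                trials.append(ChoiceTrial(1, p, q, n1, n2, none))
        return trials
    if design != "calibrator":
        raise ValueError(f"unknown design {design!r}")
    ascending = sorted(products, key=lambda p: lat[p])
    for rnd, calibrator in enumerate(ascending[:-1], start=1):
        for opponent in ascending[rnd:]:
            p1 = _softmax_pair(lat[calibrator], lat[opponent], cfg.choice_beta)
            n1, n2, none = _choice_counts(p1, cfg, rng)
            trials.append(
                ChoiceTrial(rnd, calibrator, opponent, n1, n2, none, calibrator=calibrator)
            )
    return trials


def generate_trap_trials(
    truth: SynthTruth,
    cfg: SynthConfig,
    pairs: Sequence[tuple[str, str]],
) -> list[TrapTrial]:
    """Simulate paired trapping-arena catches for the given product pairs."""
    rng = _rng(cfg, 3)
    trials = []
    for k, (p, q) in enumerate(pairs, start=1):
        for prod in (p, q):
            if prod not in truth.latent:
                raise ConfigError(f"unknown product {prod!r} in trap pair")
        p1 = _softmax_pair(truth.latent[p], truth.latent[q], cfg.choice_beta)
        n1, n2, none = _choice_counts(p1, cfg, rng)
        trials.append(TrapTrial(f"T{k:02d}", p, q, n1, n2, none))
    return trials


def write_bundle(cfg: SynthConfig, outdir) -> SynthTruth:
    """Write profiles.csv, trials.csv, traps.csv and truth.json to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    matrix, truth = generate_profiles(cfg)
    write_profile_table(matrix, os.path.join(outdir, "profiles.csv"), dialect="wide")

    trials = generate_choice_trials(truth, cfg, design="calibrator")
    pd.DataFrame(
        [
            {
                "round_id": t.round_id,
                "sample_a": t.sample_a,
                "sample_b": t.sample_b,
                "n_a": t.n_a,
                "n_b": t.n_b,
                "n_none": t.n_none,
                "calibrator": t.calibrator or "",
            }
            for t in trials
        ]
    ).to_csv(os.path.join(outdir, "trials.csv"), index=False)

    rng = _rng(cfg, 4)
    products = truth.benchmarks + truth.blinds
    pairs = []
    for _ in range(len(products)):
        i, j = rng.choice(len(products), size=2, replace=False)
        pairs.append((products[i], products[j]))
    traps = generate_trap_trials(truth, cfg, pairs)
    pd.DataFrame(
        [
            {
                "pair_id": t.pair_id,
                "sample_1": t.sample_1,
                "sample_2": t.sample_2,
                "n_1": t.n_1,
                "n_2": t.n_2,
                "n_none": t.n_none,
            }
            for t in traps
        ]
    ).to_csv(os.path.join(outdir, "traps.csv"), index=False)

    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    return truth
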