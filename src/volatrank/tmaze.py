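"""Two-choice T-maze trials -> choosing ratios -> attractiveness ranking.

Two aggregation modes are provided. ``pooled`` averages each product's
choosing ratio over every trial it appears in. ``calibrator`` follows a
sequential design in which each round is anchored by one calibrator product:
the round's trials fix (freeze) the calibrator's mean choosing ratio and the
calibrator is excluded from all later rounds; products that are never a
calibrator freeze after the last round, over all of their trials.

The ranking's numeric response variable is ``attractiveness_score = n + 1 -
rank`` so that a higher score means a more attractive product and a compound
rising with attractiveness gets a positive correlation sign downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import TrialError
from .profiles import canonical_name

__all__ = [
    "ChoiceTrial",
    "RankEntry",
    "AttractivenessRanking",
    "choosing_ratio",
    "rank_products",
    "read_choice_trials",
]

Denominator = Literal["responders", "all"]


@dataclass(frozen=True)
class ChoiceTrial:
    """Counts from one two-choice T-maze trial."""

    round_id: int
    sample_a: str
    sample_b: str
    n_a: int
    n_b: int
    n_none: int = 0
    calibrator: str | None = None

    def __post_init__(self) -> None:
        if self.round_id < 1:
            raise TrialError(f"round_id must be >= 1, got {self.round_id}")
        for name, count in (("n_a", self.n_a), ("n_b", self.n_b), ("n_none", self.n_none)):
            if int(count) != count or count < 0:
                raise TrialError(f"{self} has invalid count {name}={count}")
        if canonical_name(self.sample_a) == canonical_name(self.sample_b):
            raise TrialError(f"trial compares a product with itself: {self.sample_a!r}")

    def label(self) -> str:
        return f"round {self.round_id}: {self.sample_a} vs {self.sample_b}"


def choosing_ratio(
    t: ChoiceTrial, denominator: Denominator = "responders"
) -> tuple[float, float]:
    """Fraction of flies choosing each arm.

    ``responders`` divides by the flies that made a choice; ``all`` divides by
    every released fly including no-choices.
    """
    if denominator == "responders":
        denom = t.n_a + t.n_b
    elif denominator == "all":
        denom = t.n_a + t.n_b + t.n_none
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise TrialError(f"zero denominator ({denominator}) in trial [{t.label()}]")
    return t.n_a / denom, t.n_b / denom


@dataclass(frozen=True)
class RankEntry:
    product_id: str
    rank: int
    mean_choosing_ratio: float


@dataclass
class AttractivenessRanking:
    """Ordered product ranking; rank 1 = most attractive."""

    entries: list[RankEntry]
    tie_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranks = sorted(e.rank for e in self.entries)
        if ranks != list(range(1, len(self.entries) + 1)):
            raise TrialError(f"ranks are not a permutation of 1..n: {ranks}")
        self.entries = sorted(self.entries, key=lambda e: e.rank)

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def products(self) -> list[str]:
        return [e.product_id for e in self.entries]

    def rank_of(self, product_id: str) -> int:
        can = canonical_name(product_id)
        for e in self.entries:
            if canonical_name(e.product_id) == can:
                return e.rank
        raise TrialError(f"product {product_id!r} not in ranking")

    def score_of(self, product_id: str) -> int:
        """Attractiveness score: n + 1 - rank (higher = more attractive)."""
        return self.n + 1 - self.rank_of(product_id)

    def scores(self) -> dict[str, int]:
        return {e.product_id: self.n + 1 - e.rank for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "product_id": [e.product_id for e in self.entries],
                "rank": [e.rank for e in self.entries],
                "mean_choosing_ratio": [e.mean_choosing_ratio for e in self.entries],
                "attractiveness_score": [self.n + 1 - e.rank for e in self.entries],
            }
        )

    @classmethod
    def from_ranks(cls, ranks: dict[str, int], ratios: dict[str, float] | None = None):
        entries = [
            RankEntry(p, r, (ratios or {}).get(p, float("nan"))) for p, r in ranks.items()
        ]
        return cls(entries)


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def _ranking_from_means(means: dict[str, float]) -> AttractivenessRanking:
    ordered = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [
        RankEntry(product, rank, mean)
        for rank, (product, mean) in enumerate(ordered, start=1)
    ]
    tie_groups: list[list[str]] = []
    by_value: dict[float, list[str]] = {}
    for product, mean in means.items():
        by_value.setdefault(mean, []).append(product)
    for value, group in by_value.items():
        if len(group) > 1:
            tie_groups.append(sorted(group))
            warnings.warn(
                f"tie at mean choosing ratio {value:.6g} between {sorted(group)}; "
                "broken lexicographically",
                stacklevel=3,
            )
    return AttractivenessRanking(entries, tie_groups)


def rank_products(
    trials: Iterable[ChoiceTrial],
    mode: Literal["pooled", "calibrator"] = "pooled",
    denominator: Denominator = "responders",
    products: Sequence[str] | None = None,
) -> AttractivenessRanking:
    """Aggregate two-choice trials into an attractiveness ranking.

    Parameters
    ----------
    trials:
        The trial counts. In ``calibrator`` mode every round must declare
        exactly one calibrator, and a calibrator may not appear in any later
        round.
    mode:
        ``pooled`` (default) or ``calibrator``; see module docstring.
    denominator:
        Passed to :func:`choosing_ratio`.
    products:
        Optional product universe; members with no trials are dropped with a
        warning.
    """
    trials = list(trials)
    if not trials:
        raise TrialError("no trials given")

    ratios: dict[str, list[tuple[int, float]]] = {}
    spelling: dict[str, str] = {}
    for t in trials:
        ra, rb = choosing_ratio(t, denominator)
        for sample, ratio in ((t.sample_a, ra), (t.sample_b, rb)):
            can = canonical_name(sample)
            spelling.setdefault(can, sample.strip())
            ratios.setdefault(can, []).append((t.round_id, ratio))

    if len(ratios) < 2:
        raise TrialError("trials must cover at least 2 distinct products")
    if products is not None:
        missing = [p for p in products if canonical_name(p) not in ratios]
        if missing:
            warnings.warn(f"products with no trials excluded from ranking: {missing}")

    if mode == "pooled":
        means = {
            spelling[can]: _mean([r for _, r in obs]) for can, obs in ratios.items()
        }
        return _ranking_from_means(means)
    if mode != "calibrator":
        raise ValueError(f"unknown mode {mode!r}")

    # calibrator mode: one calibrator per round, frozen at exclusion
    rounds = sorted({t.round_id for t in trials})
    calibrator_of: dict[int, str] = {}
    for rid in rounds:
        cals = {canonical_name(t.calibrator) for t in trials if t.round_id == rid and t.calibrator}
        declared = {t.calibrator for t in trials if t.round_id == rid}
        if len(cals) != 1 or None in declared:
            raise TrialError(
                f"round {rid} must declare exactly one calibrator on every trial, "
                f"got {sorted(c for c in cals if c)}"
            )
        calibrator_of[rid] = next(iter(cals))

    frozen: dict[str, float] = {}
    excluded: set[str] = set()
    for rid in rounds:
        cal = calibrator_of[rid]
        if cal in excluded:
            raise TrialError(
                f"calibrator {spelling.get(cal, cal)!r} reappears in round {rid} "
                "after exclusion"
            )
        round_trials = [t for t in trials if t.round_id == rid]
        for t in round_trials:
            for sample in (t.sample_a, t.sample_b):
                if canonical_name(sample) in excluded:
                    raise TrialError(
                        f"excluded calibrator {sample!r} reappears in round {rid}"
                    )
        cal_ratios = [r for r, rnd_r in _round_ratios(round_trials, cal, denominator)]
        if not cal_ratios:
            raise TrialError(
                f"calibrator {spelling.get(cal, cal)!r} has no trials in its round {rid}"
            )
        frozen[cal] = _mean(cal_ratios)
        excluded.add(cal)

    for can, obs in ratios.items():
        if can not in frozen:  # never a calibrator: freeze after last round
            frozen[can] = _mean([r for _, r in obs])
    means = {spelling[can]: mean for can, mean in frozen.items()}
    return _ranking_from_means(means)


def _round_ratios(round_trials, product_can, denominator):
    out = []
    for t in round_trials:
        ra, rb = choosing_ratio(t, denominator)
        if canonical_name(t.sample_a) == product_can:
            out.append((ra, t.round_id))
        elif canonical_name(t.sample_b) == product_can:
            out.append((rb, t.round_id))
    return out


def read_choice_trials(source, sep: str | None = None) -> list[ChoiceTrial]:
    """Read trials from a CSV/TSV with columns
    ``round_id, sample_a, sample_b, n_a, n_b, n_none[, calibrator]``."""
    if sep is None:
        sep = "\t" if str(source).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    required = ["round_id", "sample_a", "sample_b", "n_a", "n_b", "n_none"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise TrialError(f"trials table missing columns {missing}")
    trials = []
    for i, row in table.iterrows():
        cal = row.get("calibrator", "")
        cal = str(cal).strip() or None
        try:
            trials.append(
                ChoiceTrial(
                    round_id=int(row["round_id"]),
                    sample_a=row["sample_a"],
                    sample_b=row["sample_b"],
                    n_a=int(row["n_a"]),
                    n_b=int(row["n_b"]),
                    n_none=int(row["n_none"]),
                    calibrator=cal,
                )
            )
        except (ValueError, TrialError) as exc:
            raise TrialError(f"trials table row {i + 2}: {exc}") from exc
    return trials
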