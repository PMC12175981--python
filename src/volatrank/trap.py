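"""Trapping-arena blind-test validation.

Pairwise trap catches are reduced to trap-indices (fraction of responding
flies caught by each product's trap) and regressed, with intercept, on a
chem-derived value per pair. The paper's pairing rule is not published, so
three modes are provided; ``score_difference`` is the default (predicted
attractiveness-score gap between the two samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemindex import ChemIndexResult
from .errors import TrialError
from .profiles import canonical_name

__all__ = [
    "TrapTrial",
    "trap_index",
    "pair_chem_value",
    "ValidationResult",
    "validate",
    "read_trap_trials",
]

ChemValueMode = Literal["index_difference", "score_difference", "sample1_similarity_to_top"]


@dataclass(frozen=True)
class TrapTrial:
    """Catch counts from one paired trapping-arena test."""

    pair_id: str
    sample_1: str
    sample_2: str
    n_1: int
    n_2: int
    n_none: int = 0

    def __post_init__(self) -> None:
        for name, count in (("n_1", self.n_1), ("n_2", self.n_2), ("n_none", self.n_none)):
            if int(count) != count or count < 0:
                raise TrialError(f"pair {self.pair_id!r}: invalid count {name}={count}")
        if canonical_name(self.sample_1) == canonical_name(self.sample_2):
            raise TrialError(f"pair {self.pair_id!r} traps a product against itself")


def trap_index(
    t: TrapTrial, denominator: Literal["responders", "all"] = "responders"
) -> tuple[float, float]:
    """Fraction of flies caught by each trap of the pair."""
    if denominator == "responders":
        denom = t.n_1 + t.n_2
    elif denominator == "all":
        denom = t.n_1 + t.n_2 + t.n_none
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise TrialError(f"zero denominator ({denominator}) in pair {t.pair_id!r}")
    return t.n_1 / denom, t.n_2 / denom


def _result_for(results: Mapping[str, ChemIndexResult], product: str) -> ChemIndexResult:
    can = canonical_name(product)
    for key, value in results.items():
        if canonical_name(key) == can:
            return value
    raise TrialError(f"no chem-index result for product {product!r}")


def pair_chem_value(
    t: TrapTrial,
    results: Mapping[str, ChemIndexResult],
    mode: ChemValueMode = "score_difference",
) -> float:
    """Chem-derived predictor for one trap pair.

    * ``score_difference`` — estimated attractiveness score of sample 1 minus
      sample 2 (positive = model predicts sample 1 wins);
    * ``index_difference`` — chem-index of sample 2 against the rank-1
      benchmark minus that of sample 1 (same orientation: positive = sample 1
      closer to the most attractive benchmark);
    * ``sample1_similarity_to_top`` — minus sample 1's chem-index against the
      rank-1 benchmark.
    """
    r1 = _result_for(results, t.sample_1)
    r2 = _result_for(results, t.sample_2)
    if mode == "score_difference":
        return float(r1.estimated_score - r2.estimated_score)
    if mode == "index_difference":
        return float(r2.index_against_rank(1) - r1.index_against_rank(1))
    if mode == "sample1_similarity_to_top":
        return float(-r1.index_against_rank(1))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ValidationResult:
    """Simple linear regression of trap-index on chem value across pairs."""

    points: pd.DataFrame  # columns: pair_id, chem_value, trap_index
    slope: float
    intercept: float
    r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    mode: str = ""

    @property
    def n(self) -> int:
        return len(self.points)


def validate(
    points: Iterable[Sequence],
    mode: str = "",
) -> ValidationResult:
    """Ordinary least squares (with intercept) of trap-index on chem value.

    ``points`` holds ``(chem_value, trap_index)`` pairs, optionally prefixed
    with a pair id. Reports r² (squared Pearson r), the F statistic
    ``r²·(n-2)/(1-r²)`` on (1, n-2) degrees of freedom and its survival
    p-value.
    """
    rows = []
    for i, point in enumerate(points):
        point = list(point)
        if len(point) == 2:
            rows.append((f"pair{i + 1}", float(point[0]), float(point[1])))
        elif len(point) == 3:
            rows.append((str(point[0]), float(point[1]), float(point[2])))
        else:
            raise TrialError(f"point {i}: expected 2 or 3 fields, got {len(point)}")
    frame = pd.DataFrame(rows, columns=["pair_id", "chem_value", "trap_index"])
    n = len(frame)
    if n < 3:
        raise TrialError(f"need >= 3 points for validation, got {n}")
    x = frame["chem_value"].to_numpy()
    y = frame["trap_index"].to_numpy()
    if np.ptp(x) == 0:
        raise TrialError("chem values are constant: regression undefined")
    if np.ptp(y) == 0:
        # zero-variance response: slope 0, no association
        return ValidationResult(frame, 0.0, float(y[0]), 0.0, 0.0, (1, n - 2), 1.0, mode)
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    if r2 >= 1.0:
        f_stat = float("inf")
        p = 0.0
    else:
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return ValidationResult(
        points=frame,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        f_stat=float(f_stat),
        df=(1, n - 2),
        p_value=p,
        mode=mode,
    )


def validate_trials(
    trials: Iterable[TrapTrial],
    results: Mapping[str, ChemIndexResult],
    mode: ChemValueMode = "score_difference",
    denominator: Literal["responders", "all"] = "responders",
) -> ValidationResult:
    """End-to-end helper: trap trials + chem-index results -> regression."""
    points = []
    for t in trials:
        i1, _ = trap_index(t, denominator)
        points.append((t.pair_id, pair_chem_value(t, results, mode), i1))
    return validate(points, mode=mode)


def read_trap_trials(source, sep: str | None = None) -> list[TrapTrial]:
    """Read trials from a CSV/TSV with columns
    ``pair_id, sample_1, sample_2, n_1, n_2, n_none``."""
    if sep is None:
        sep = "\t" if str(source).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    required = ["pair_id", "sample_1", "sample_2", "n_1", "n_2", "n_none"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise TrialError(f"trap table missing columns {missing}")
    trials = []
    for i, row in table.iterrows():
        try:
            trials.append(
                TrapTrial(
                    pair_id=str(row["pair_id"]).strip(),
                    sample_1=row["sample_1"],
                    sample_2=row["sample_2"],
                    n_1=int(row["n_1"]),
                    n_2=int(row["n_2"]),
                    n_none=int(row["n_none"]),
                )
            )
        except (ValueError, TrialError) as exc:
            raise TrialError(f"trap table row {i + 2}: {exc}") from exc
    return trials
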