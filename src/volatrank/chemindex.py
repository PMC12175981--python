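"""Zero-intercept similarity model: chem-index scoring and rank estimation.

A blind product's panel proportions (``y``) are regressed through the origin
on each benchmark's panel proportions (``x``). With ``m = Σxy / Σx²`` and
residuals ``e = y - m·x``, the spreadsheet no-intercept conventions give

* ``se_m = sqrt((Σe² / (n - 1)) / Σx²)`` (n - 1 residual degrees of freedom),
* ``r² = 1 - Σe² / Σy²`` (uncentered).

The chem-index is ``|m - 1| + |r² - 1| + se_m``: zero iff the blind equals
the benchmark, growing with any scale or shape mismatch. The estimated rank
of a blind product is the attractiveness rank of the benchmark with the
minimal chem-index.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FitError
from .profiles import (
    PanelAlignment,
    ProfileMatrix,
    VolatileProfile,
    align_panel,
    canonical_name,
)
from .tmaze import AttractivenessRanking

__all__ = [
    "OriginFitStats",
    "origin_least_squares",
    "chem_index",
    "ChemIndexModel",
    "BenchmarkFit",
    "ChemIndexResult",
    "estimate_rank",
    "multiple_regression_slopes",
]


@dataclass(frozen=True)
class OriginFitStats:
    """Statistics of a least-squares line through the origin."""

    m: float
    se_m: float
    r2: float
    n: int

    def chem_index(self) -> float:
        return abs(self.m - 1.0) + abs(self.r2 - 1.0) + self.se_m


def origin_least_squares(y: Sequence[float], x: Sequence[float]) -> OriginFitStats:
    """Fit ``y = m·x`` by least squares; see module docstring for conventions.

    ``y`` is the blind (regressand), ``x`` the benchmark (regressor).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise FitError(f"length mismatch: y{y.shape} vs x{x.shape}")
    n = y.size
    if n < 2:
        raise FitError(f"need n >= 2 points, got {n}")
    sxx = float(x @ x)
    if sxx <= 0:
        raise FitError("benchmark vector is all zeros: slope undefined")
    m = float(x @ y) / sxx
    e = y - m * x
    sse = float(e @ e)
    syy = float(y @ y)
    se_m = float(np.sqrt((sse / (n - 1)) / sxx))
    if syy > 0:
        r2 = 1.0 - sse / syy
    else:
        warnings.warn("blind vector is all zeros: r2 set to 0 by convention")
        r2 = 0.0
    return OriginFitStats(m=m, se_m=se_m, r2=r2, n=n)


def chem_index(y: Sequence[float], x: Sequence[float]) -> float:
    """Similarity score ``|m-1| + |r²-1| + se_m`` of blind ``y`` vs benchmark ``x``.

    Non-negative; 0 exactly when ``y`` equals ``x``.
    """
    return origin_least_squares(y, x).chem_index()


@dataclass
class ChemIndexModel:
    """Benchmark panel matrix plus attractiveness ranks: the published model.

    ``benchmarks`` must already be restricted to the panel (in panel order);
    ``benchmark_ranks`` maps each benchmark product to its rank 1..n.
    """

    panel: list[str]
    benchmarks: ProfileMatrix
    benchmark_ranks: dict[str, int]

    def __post_init__(self) -> None:
        if not self.panel:
            raise FitError("empty panel")
        if [canonical_name(c) for c in self.benchmarks.compounds] != [
            canonical_name(c) for c in self.panel
        ]:
            raise FitError("benchmark matrix columns do not match the panel")
        n = len(self.benchmarks.products)
        ranks = sorted(self.benchmark_ranks.values())
        if ranks != list(range(1, n + 1)):
            raise FitError(
                f"benchmark_ranks must be a bijection onto 1..{n}, got {ranks}"
            )
        keys = {canonical_name(k) for k in self.benchmark_ranks}
        if keys != {canonical_name(p) for p in self.benchmarks.products}:
            raise FitError("benchmark_ranks products do not match the benchmark matrix")

    @property
    def n_benchmarks(self) -> int:
        return len(self.benchmarks.products)

    def rank_of(self, benchmark_id: str) -> int:
        can = canonical_name(benchmark_id)
        for key, rank in self.benchmark_ranks.items():
            if canonical_name(key) == can:
                return rank
        raise FitError(f"unknown benchmark {benchmark_id!r}")

    def benchmark_at_rank(self, rank: int) -> str:
        for key, value in self.benchmark_ranks.items():
            if value == rank:
                return key
        raise FitError(f"no benchmark at rank {rank}")

    @classmethod
    def build(
        cls,
        profiles: ProfileMatrix,
        ranking: AttractivenessRanking,
        panel: Sequence[str],
    ) -> "ChemIndexModel":
        """Assemble a model from full benchmark profiles, their ranking and a panel."""
        bench_products = [p for p in ranking.products]
        restricted = profiles.restrict_products(bench_products)
        aligned: PanelAlignment = align_panel(restricted, panel)
        if aligned.zero_filled:
            warnings.warn(
                f"panel compounds absent from benchmarks, zero-filled: {aligned.zero_filled}"
            )
        ranks = {p: ranking.rank_of(p) for p in bench_products}
        return cls(list(panel), aligned.matrix, ranks)

    # -- plain-text persistence (panel.txt + benchmarks.csv + ranks.csv) ---
    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "panel.txt"), "w", encoding="utf-8") as fh:
            fh.writelines(name + "\n" for name in self.panel)
        out = self.benchmarks.data.copy()
        out.index.name = "product_id"
        out.to_csv(os.path.join(directory, "benchmarks.csv"))
        pd.DataFrame(
            sorted(self.benchmark_ranks.items(), key=lambda kv: kv[1]),
            columns=["product_id", "rank"],
        ).to_csv(os.path.join(directory, "ranks.csv"), index=False)

    @classmethod
    def load(cls, directory) -> "ChemIndexModel":
        with open(os.path.join(directory, "panel.txt"), encoding="utf-8") as fh:
            panel = [line.strip() for line in fh if line.strip()]
        bench = pd.read_csv(os.path.join(directory, "benchmarks.csv"), index_col=0)
        ranks_frame = pd.read_csv(os.path.join(directory, "ranks.csv"))
        ranks = dict(zip(ranks_frame["product_id"], ranks_frame["rank"].astype(int)))
        return cls(panel, ProfileMatrix(bench), ranks)


@dataclass(frozen=True)
class BenchmarkFit:
    """Similarity of one blind product to one benchmark."""

    benchmark_id: str
    rank: int
    stats: OriginFitStats
    chem_index: float


@dataclass
class ChemIndexResult:
    """Per-benchmark chem-indices of one blind product plus its estimated rank."""

    blind_id: str
    per_benchmark: dict[str, BenchmarkFit]
    best_benchmark: str
    estimated_rank: int
    chem_index: float
    n_benchmarks: int
    tie: bool = False
    zero_filled: list[str] = field(default_factory=list)

    @property
    def estimated_score(self) -> int:
        """Attractiveness score of the estimated rank (n + 1 - rank)."""
        return self.n_benchmarks + 1 - self.estimated_rank

    def index_against(self, benchmark_id: str) -> float:
        can = canonical_name(benchmark_id)
        for key, fit in self.per_benchmark.items():
            if canonical_name(key) == can:
                return fit.chem_index
        raise FitError(f"no fit against benchmark {benchmark_id!r}")

    def index_against_rank(self, rank: int) -> float:
        for fit in self.per_benchmark.values():
            if fit.rank == rank:
                return fit.chem_index
        raise FitError(f"no benchmark at rank {rank}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fit in sorted(self.per_benchmark.values(), key=lambda f: f.rank):
            rows.append(
                {
                    "blind_id": self.blind_id,
                    "benchmark_id": fit.benchmark_id,
                    "benchmark_rank": fit.rank,
                    "m": fit.stats.m,
                    "se_m": fit.stats.se_m,
                    "r2": fit.stats.r2,
                    "chem_index": fit.chem_index,
                    "is_best": fit.benchmark_id == self.best_benchmark,
                    "estimated_rank": self.estimated_rank,
                }
            )
        return pd.DataFrame(rows)


def estimate_rank(blind: VolatileProfile, model: ChemIndexModel) -> ChemIndexResult:
    """Score a blind product against every benchmark and estimate its rank.

    The blind profile is aligned to the model panel (absent compounds = 0).
    Ties in the minimal chem-index are resolved toward the more attractive
    (numerically smaller) rank and flagged.
    """
    blind_matrix = ProfileMatrix(
        pd.DataFrame([blind.proportions], index=[blind.product_id])
    )
    aligned = align_panel(blind_matrix, model.panel)
    y = aligned.matrix.values()[0]
    fits: dict[str, BenchmarkFit] = {}
    for product in model.benchmarks.products:
        x = model.benchmarks.values()[model.benchmarks.products.index(product)]
        stats = origin_least_squares(y, x)
        fits[product] = BenchmarkFit(product, model.rank_of(product), stats, stats.chem_index())

    best = min(fits.values(), key=lambda f: (f.chem_index, f.rank))
    tied = [f for f in fits.values() if f.chem_index == best.chem_index]
    tie = len(tied) > 1
    if tie:
        warnings.warn(
            f"blind {blind.product_id!r}: chem-index tie between "
            f"{sorted(f.benchmark_id for f in tied)}; resolved toward rank {best.rank}"
        )
    return ChemIndexResult(
        blind_id=blind.product_id,
        per_benchmark=fits,
        best_benchmark=best.benchmark_id,
        estimated_rank=best.rank,
        chem_index=best.chem_index,
        n_benchmarks=model.n_benchmarks,
        tie=tie,
        zero_filled=aligned.zero_filled,
    )


def multiple_regression_slopes(
    blind: VolatileProfile, model: ChemIndexModel
) -> dict[str, float]:
    """Sensitivity-analysis variant: one joint no-intercept regression of the
    blind panel vector on all benchmark vectors at once. Returns per-benchmark
    coefficients; not used by :func:`estimate_rank`."""
    blind_matrix = ProfileMatrix(
        pd.DataFrame([blind.proportions], index=[blind.product_id])
    )
    y = align_panel(blind_matrix, model.panel).matrix.values()[0]
    X = model.benchmarks.values().T  # panel compounds x benchmarks
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return dict(zip(model.benchmarks.products, map(float, coef)))


def results_to_frame(results: Mapping[str, ChemIndexResult]) -> pd.DataFrame:
    """Concatenate per-blind result tables (CSV layout of `volatrank predict`)."""
    return pd.concat([r.to_frame() for r in results.values()], ignore_index=True)


def results_from_frame(frame: pd.DataFrame) -> dict[str, ChemIndexResult]:
    """Inverse of :func:`results_to_frame`."""
    out: dict[str, ChemIndexResult] = {}
    for blind_id, sub in frame.groupby("blind_id", sort=False):
        fits = {}
        for _, row in sub.iterrows():
            stats = OriginFitStats(
                m=float(row["m"]), se_m=float(row["se_m"]), r2=float(row["r2"]), n=0
            )
            fits[row["benchmark_id"]] = BenchmarkFit(
                row["benchmark_id"], int(row["benchmark_rank"]), stats, float(row["chem_index"])
            )
        best_rows = sub[sub["is_best"]]
        best = best_rows["benchmark_id"].iloc[0]
        out[str(blind_id)] = ChemIndexResult(
            blind_id=str(blind_id),
            per_benchmark=fits,
            best_benchmark=best,
            estimated_rank=int(best_rows["estimated_rank"].iloc[0]),
            chem_index=float(fits[best].chem_index),
            n_benchmarks=len(fits),
        )
    return out
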