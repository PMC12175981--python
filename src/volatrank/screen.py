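"""Screens of compound proportions against the attractiveness ranking.

Three stages:

* :func:`correlate_with_ranking` — Pearson r of every compound against the
  attractiveness score, the global correlation screen;
* :func:`regress_rank_on_odorant` — per-compound ordinary least squares with a
  two-sided t-test on the slope, selecting significant seed compounds;
* :func:`pattern_search` — expansion of seed compounds into a key-odorant
  panel by correlating every other compound against each seed.

Correlations use the attractiveness *score* (``n + 1 - rank``; higher = more
attractive), not the raw rank number, so a compound that rises with
attractiveness gets a positive r. Pearson r is invariant to per-compound
affine scaling, so no autoscaling option is offered: autoscaled and raw
proportions give identical screens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ScreenError
from .profiles import ProfileMatrix, canonical_name
from .tmaze import AttractivenessRanking

__all__ = [
    "pearson_r",
    "CorrelationScreen",
    "correlate_with_ranking",
    "RegressionScreen",
    "regress_rank_on_odorant",
    "BiomarkerPanel",
    "pattern_search",
]

SignRule = Literal["positive_only", "absolute"]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    p is computed from ``t = r * sqrt((n-2) / (1 - r^2))`` on ``n - 2``
    degrees of freedom. A constant input makes r undefined: ``(nan, nan)`` is
    returned with a warning and the compound is skipped by the screens.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ScreenError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ScreenError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Pearson r undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationScreen:
    """Per-compound correlation with the attractiveness score."""

    frame: pd.DataFrame  # columns: compound, r, p, sign
    skipped: list[str] = field(default_factory=list)

    def top_positive(self, k: int) -> list[str]:
        sub = self.frame.sort_values("r", ascending=False, kind="mergesort")
        return list(sub["compound"].head(k))

    def top_negative(self, k: int) -> list[str]:
        sub = self.frame.sort_values("r", ascending=True, kind="mergesort")
        return list(sub["compound"].head(k))

    def r_of(self, compound: str) -> float:
        row = self.frame[self.frame["compound"] == compound]
        if row.empty:
            raise ScreenError(f"compound {compound!r} not in screen")
        return float(row["r"].iloc[0])


def _aligned_score_vector(
    m: ProfileMatrix, ranking: AttractivenessRanking
) -> tuple[ProfileMatrix, np.ndarray]:
    mine = {canonical_name(p) for p in m.products}
    theirs = {canonical_name(p) for p in ranking.products}
    if mine != theirs:
        raise ScreenError(
            "product sets differ between profiles and ranking; "
            f"profiles-only={sorted(mine - theirs)}, ranking-only={sorted(theirs - mine)}"
        )
    ordered = m.restrict_products(ranking.products)
    scores = np.array([ranking.score_of(p) for p in ordered.products], dtype=float)
    return ordered, scores


def correlate_with_ranking(
    m: ProfileMatrix, ranking: AttractivenessRanking
) -> CorrelationScreen:
    """Pearson r (+p) of every non-constant compound against the score."""
    ordered, scores = _aligned_score_vector(m, ranking)
    rows = []
    skipped = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for compound in ordered.compounds:
            x = ordered.compound_vector(compound)
            if np.ptp(x) == 0:
                skipped.append(compound)
                continue
            r, p = pearson_r(x, scores)
            rows.append((compound, r, p, "positive" if r >= 0 else "negative"))
    if skipped:
        warnings.warn(f"{len(skipped)} constant compounds skipped in correlation screen")
    frame = pd.DataFrame(rows, columns=["compound", "r", "p", "sign"])
    return CorrelationScreen(frame, skipped)


@dataclass
class RegressionScreen:
    """Per-compound OLS of attractiveness score on proportion."""

    frame: pd.DataFrame  # columns: compound, slope, intercept, p_slope, selected
    alpha: float
    skipped: list[str] = field(default_factory=list)

    def selected_compounds(self) -> list[str]:
        return list(self.frame.loc[self.frame["selected"], "compound"])


def regress_rank_on_odorant(
    m: ProfileMatrix,
    ranking: AttractivenessRanking,
    alpha: float = 0.05,
    adjust: Literal["none", "bh"] = "none",
) -> RegressionScreen:
    """Per-compound simple OLS (with intercept) of score on proportion.

    ``selected`` is ``p_slope < alpha`` on the raw two-sided t-test p-values;
    ``adjust="bh"`` applies a Benjamini-Hochberg correction first (off by
    default: the published screen used raw significance).
    """
    if not 0 <= alpha <= 1:
        raise ScreenError(f"alpha must be in [0, 1], got {alpha}")
    ordered, scores = _aligned_score_vector(m, ranking)
    rows = []
    skipped = []
    for compound in ordered.compounds:
        x = ordered.compound_vector(compound)
        if np.ptp(x) == 0:
            skipped.append(compound)
            continue
        fit = stats.linregress(x, scores)
        rows.append((compound, float(fit.slope), float(fit.intercept), float(fit.pvalue)))
    frame = pd.DataFrame(rows, columns=["compound", "slope", "intercept", "p_slope"])
    pvals = frame["p_slope"].to_numpy()
    if adjust == "bh":
        pvals = stats.false_discovery_control(pvals, method="bh")
        frame["p_adjusted"] = pvals
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    frame["selected"] = pvals < alpha
    return RegressionScreen(frame, alpha, skipped)


@dataclass
class BiomarkerPanel:
    """Key-odorant panel: seeds plus their strongest correlates.

    ``panel`` is ordered by descending mean proportion across products, the
    order in which members are reported and consumed downstream.
    """

    seeds: list[str]
    per_seed_top: dict[str, list[tuple[str, float]]]
    panel: list[str]

    def __post_init__(self) -> None:
        kept = {c for tops in self.per_seed_top.values() for c, _ in tops}
        kept |= set(self.seeds)
        orphans = [c for c in self.panel if c not in kept]
        if orphans:
            raise ScreenError(f"panel members neither seed nor correlate: {orphans}")

    def __len__(self) -> int:
        return len(self.panel)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name in self.panel:
                fh.write(name + "\n")

    @staticmethod
    def load_names(path) -> list[str]:
        with open(path, encoding="utf-8") as fh:
            return [line.strip() for line in fh if line.strip()]


def pattern_search(
    m: ProfileMatrix,
    seeds: Sequence[str],
    top_k: int = 25,
    min_r: float = 0.0,
    sign_rule: SignRule = "positive_only",
) -> BiomarkerPanel:
    """Expand seed compounds into a panel of co-varying key odorants.

    For each seed, every other compound is correlated (Pearson) against the
    seed's proportion vector across products; the ``top_k`` correlates are
    kept, after discarding ``r < min_r`` (``positive_only``) or
    ``|r| < min_r`` (``absolute``). The panel is the deduplicated union of
    seeds and kept correlates.
    """
    if top_k < 1:
        raise ScreenError(f"top_k must be >= 1, got {top_k}")
    if sign_rule not in ("positive_only", "absolute"):
        raise ValueError(f"unknown sign_rule {sign_rule!r}")
    seeds = list(seeds)
    if not seeds:
        raise ScreenError("no seeds given")
    by_canonical = {canonical_name(c): c for c in m.compounds}
    resolved = []
    for seed in seeds:
        name = by_canonical.get(canonical_name(seed))
        if name is None:
            raise ScreenError(f"seed {seed!r} not among matrix compounds")
        resolved.append(name)

    values = m.data
    per_seed_top: dict[str, list[tuple[str, float]]] = {}
    for seed in resolved:
        sv = values[seed].to_numpy(dtype=float)
        if np.ptp(sv) == 0:
            raise ScreenError(f"seed {seed!r} is constant across products")
        scored: list[tuple[str, float]] = []
        for compound in m.compounds:
            if compound == seed:
                continue
            x = values[compound].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue  # undefined correlation; silently not a correlate
            r = float(np.corrcoef(x, sv)[0, 1])
            key = r if sign_rule == "positive_only" else abs(r)
            if key < min_r:
                continue
            scored.append((compound, r))
        scored.sort(key=lambda cr: (-(cr[1] if sign_rule == "positive_only" else abs(cr[1])), cr[0]))
        per_seed_top[seed] = scored[:top_k]

    members: dict[str, None] = dict.fromkeys(resolved)
    for tops in per_seed_top.values():
        for compound, _ in tops:
            members.setdefault(compound)
    mean_prop = values.mean(axis=0)
    panel = sorted(members, key=lambda c: (-float(mean_prop[c]), c))
    return BiomarkerPanel(resolved, per_seed_top, panel)
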