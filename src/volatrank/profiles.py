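"""Reading, validation, normalization and panel alignment of volatile-proportion tables.

A profile table holds, for each product, the proportion (in % of total peak
area) of every identified volatile compound. Two on-disk dialects are
supported:

* ``wide``  — first column ``product_id``, one column per compound;
* ``long``  — columns ``product_id, compound, proportion``.

Compound and product names are matched exactly after whitespace trimming and
case-folding; no synonym resolution is attempted. A compound that is absent
for a product means "not detected" and is stored as 0.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ProfileError

__all__ = [
    "VolatileProfile",
    "ProfileMatrix",
    "canonical_name",
    "read_profile_table",
    "write_profile_table",
    "normalize_proportions",
    "align_panel",
]

#: Tolerance on row sums after normalization.
NORMALIZED_SUM_TOL = 1e-6


def canonical_name(name: str) -> str:
    """Canonical form used for product/compound identity: strip + casefold."""
    return str(name).strip().casefold()


@dataclass(frozen=True)
class VolatileProfile:
    """Volatile proportions of a single product.

    Parameters
    ----------
    product_id:
        Product label.
    proportions:
        Mapping compound name -> proportion in % of total peak area.
    """

    product_id: str
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        for compound, value in self.proportions.items():
            if not np.isfinite(value) or value < 0:
                raise ProfileError(
                    f"product {self.product_id!r}: compound {compound!r} has "
                    f"invalid proportion {value!r} (must be finite and >= 0)"
                )

    def total(self) -> float:
        return float(sum(self.proportions.values()))


class ProfileMatrix:
    """Products x compounds grid of volatile proportions (%).

    Thin wrapper around a :class:`pandas.DataFrame` (products on the index,
    compounds on the columns) that enforces the domain invariants: unique
    canonical names on both axes and finite, non-negative cells.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = [str(p).strip() for p in data.index]
        data.columns = [str(c).strip() for c in data.columns]
        _check_unique(data.index, "product_id")
        _check_unique(data.columns, "compound")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            bad = data.index[np.where(~np.isfinite(values))[0][0]]
            raise ProfileError(f"non-finite proportion in product {bad!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ProfileError(
                f"negative proportion for product {data.index[r]!r}, "
                f"compound {data.columns[c]!r}: {values[r, c]}"
            )
        self._data = data.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """Underlying DataFrame (copy-safe: do not mutate)."""
        return self._data

    @property
    def products(self) -> list[str]:
        return list(self._data.index)

    @property
    def compounds(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def values(self) -> np.ndarray:
        return self._data.to_numpy(dtype=float)

    def profile(self, product_id: str) -> VolatileProfile:
        key = _locate(self._data.index, product_id, "product")
        row = self._data.loc[key]
        return VolatileProfile(key, row.to_dict())

    def compound_vector(self, compound: str) -> np.ndarray:
        key = _locate(self._data.columns, compound, "compound")
        return self._data[key].to_numpy(dtype=float)

    def restrict_products(self, products: Sequence[str]) -> "ProfileMatrix":
        keys = [_locate(self._data.index, p, "product") for p in products]
        return ProfileMatrix(self._data.loc[keys])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, k = self.shape
        return f"ProfileMatrix({n} products x {k} compounds)"


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: dict[str, str] = {}
    for lab in labels:
        can = canonical_name(lab)
        if can in seen:
            raise ProfileError(f"duplicate {what} {lab!r} (clashes with {seen[can]!r})")
        seen[can] = lab


def _locate(labels: pd.Index, name: str, what: str) -> str:
    """Find a label by canonical identity; return the stored spelling."""
    can = canonical_name(name)
    for lab in labels:
        if canonical_name(lab) == can:
            return lab
    raise ProfileError(f"unknown {what} {name!r}")


def _resolve_sep(source, sep: str | None) -> str:
    if sep is not None:
        return sep
    name = source if isinstance(source, (str, os.PathLike)) else getattr(source, "name", "")
    return "\t" if str(name).endswith((".tsv", ".tab", ".txt")) else ","


def read_profile_table(source, dialect: str = "wide", sep: str | None = None) -> ProfileMatrix:
    """Read a delimited profile table into a :class:`ProfileMatrix`.

    Parameters
    ----------
    source:
        Path or text stream. CSV/TSV is auto-detected from the extension
        unless ``sep`` is given.
    dialect:
        ``"wide"`` (first column product, remaining columns compounds) or
        ``"long"`` (columns ``product_id, compound, proportion``).
    """
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _resolve_sep(source, sep)
    try:
        table = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises several parser error types
        raise ProfileError(f"cannot parse profile table: {exc}") from exc
    if table.shape[1] < 2:
        raise ProfileError(
            f"profile table needs >= 2 columns, got {table.shape[1]} "
            "(wrong delimiter?)"
        )

    if dialect == "wide":
        prod_col = table.columns[0]
        frame = table.set_index(prod_col)
        parsed = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
        for col in frame.columns:
            parsed[col] = [
                _parse_proportion(v, row, col) for row, v in frame[col].items()
            ]
        return ProfileMatrix(parsed)

    # long dialect
    if table.shape[1] < 3:
        raise ProfileError("long dialect requires columns (product_id, compound, proportion)")
    pid_col, cmp_col, val_col = table.columns[:3]
    seen: set[tuple[str, str]] = set()
    records: list[tuple[str, str, float]] = []
    for i, row in table.iterrows():
        pid = str(row[pid_col]).strip()
        compound = str(row[cmp_col]).strip()
        value = _parse_proportion(row[val_col], pid, compound)
        key = (canonical_name(pid), canonical_name(compound))
        if key in seen:
            raise ProfileError(
                f"row {i + 2}: duplicate cell for product {pid!r}, compound {compound!r}"
            )
        seen.add(key)
        records.append((pid, compound, value))
    frame = pd.DataFrame(records, columns=["product_id", "compound", "proportion"])
    wide = frame.pivot(index="product_id", columns="compound", values="proportion")
    # preserve first-appearance order of products and compounds
    wide = wide.reindex(
        index=list(dict.fromkeys(frame["product_id"])),
        columns=list(dict.fromkeys(frame["compound"])),
    )
    return ProfileMatrix(wide.fillna(0.0))


def _parse_proportion(raw, row_id, col_id) -> float:
    text = str(raw).strip()
    if text == "":
        return 0.0
    try:
        value = float(text)
    except ValueError as exc:
        raise ProfileError(
            f"product {row_id!r}, compound {col_id!r}: "
            f"proportion {raw!r} is not a number"
        ) from exc
    if not np.isfinite(value) or value < 0:
        raise ProfileError(
            f"product {row_id!r}, compound {col_id!r}: "
            f"proportion {value} must be finite and >= 0"
        )
    return value


def write_profile_table(m: ProfileMatrix, target, dialect: str = "wide", sep: str | None = None) -> None:
    """Write a matrix back to delimited text; inverse of :func:`read_profile_table`."""
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _resolve_sep(target, sep)
    if dialect == "wide":
        out = m.data.copy()
        out.index.name = "product_id"
        out.to_csv(target, sep=sep)
        return
    rows = m.data.stack().reset_index()
    rows.columns = ["product_id", "compound", "proportion"]
    rows.to_csv(target, sep=sep, index=False)


def normalize_proportions(
    m: ProfileMatrix, totals: Mapping[str, float] | None = None
) -> ProfileMatrix:
    """Rescale every product row to sum to 100.

    By default each row is divided by its own sum (normalization over the
    identified compounds present in the table). If ``totals`` maps product ids
    to externally measured total peak areas, rows are divided by those instead
    (normalization over all detected peaks, identified or not); in that case
    row sums may legitimately fall below 100.
    """
    data = m.data
    if totals is None:
        denom = data.sum(axis=1)
    else:
        denom = pd.Series(
            [float(totals[_match_key(totals, p)]) for p in data.index], index=data.index
        )
    zero = denom <= 0
    if zero.any():
        bad = list(data.index[zero])
        raise ProfileError(f"cannot normalize products with non-positive total: {bad}")
    return ProfileMatrix(data.div(denom, axis=0) * 100.0)


def _match_key(mapping: Mapping[str, float], product: str) -> str:
    can = canonical_name(product)
    for key in mapping:
        if canonical_name(key) == can:
            return key
    raise ProfileError(f"no total provided for product {product!r}")


@dataclass
class PanelAlignment:
    """Result of :func:`align_panel`: the restricted matrix plus a report of
    panel compounds that were absent from the source and zero-filled."""

    matrix: ProfileMatrix
    zero_filled: list[str] = field(default_factory=list)


def align_panel(m: ProfileMatrix, panel: Sequence[str]) -> PanelAlignment:
    """Restrict a matrix to ``panel`` compounds, in panel order.

    Compounds absent from ``m`` become all-zero columns and are listed in the
    returned report; retained values are never altered.
    """
    panel = list(panel)
    if not panel:
        raise ProfileError("panel must be non-empty")
    _check_unique(panel, "panel compound")
    by_canonical = {canonical_name(c): c for c in m.compounds}
    columns: dict[str, np.ndarray] = {}
    missing: list[str] = []
    n = len(m.products)
    for name in panel:
        source = by_canonical.get(canonical_name(name))
        if source is None:
            missing.append(name)
            columns[name] = np.zeros(n)
        else:
            columns[name] = m.data[source].to_numpy(dtype=float)
    aligned = pd.DataFrame(columns, index=m.products)
    return PanelAlignment(ProfileMatrix(aligned), missing)
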