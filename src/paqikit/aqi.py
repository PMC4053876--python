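"""Individual air-quality indexes and the composite particulate index PAQI.

The individual index (IAQI) of one pollutant maps its concentration
through an ordered ladder of (concentration, index) breakpoints by linear
interpolation within the containing segment, per the Chinese AQI standard;
concentrations beyond the last breakpoint are capped at the ladder's top
index.

PAQI combines the individual particulate indexes with index-proportional
weights

    Q_i = I_i / sum_j I_j,

then applies an extreme-value modification: with s the count of weights in
[0, low_cut) and t the count in (high_cut, 1], when both an extremely
small and an extremely large weight are present (s >= 1 and t >= 1 — the
dust-storm configuration, where the PM10 index dwarfs the PM2.5 index)
the near-zero weights are truncated to 0 and the remainder renormalized
to sum 1; otherwise the weights are unchanged.  The composite is then
PAQI = sum_i P_i I_i.  Defaults low_cut = 0.05 and high_cut = 0.5.  The
scheme accepts any number of pollutants >= 2 (PM1, PM0.5, ... ladders can
be added as data).

Note: the published rendering of the weighting equations is partly
illegible; the forms above are the reconstruction consistent with the
stated weight bounds, the s/t definitions, and the dust-storm motivation
(see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .rasters import GridField, align_check

__all__ = [
    "BreakpointTable",
    "IndexBundle",
    "default_breakpoints",
    "default_scheme",
    "iaqi",
    "raw_weights",
    "modify_weights",
    "paqi",
    "paqi_grid",
    "classify",
]


@dataclass(frozen=True)
class BreakpointTable:
    """Ordered (concentration µg/m³, index) breakpoints for one pollutant."""

    pollutant: str
    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("breakpoint table needs at least 2 pairs")
        conc = [c for c, _ in self.pairs]
        idx = [i for _, i in self.pairs]
        if self.pairs[0] != (0.0, 0.0):
            raise ValueError("first breakpoint pair must be (0, 0)")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("breakpoint concentrations must be strictly increasing")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("breakpoint index values must be strictly increasing")

    @property
    def cap_index(self) -> float:
        return self.pairs[-1][1]

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.pairs], float)

    @property
    def indexes(self) -> np.ndarray:
        return np.array([i for _, i in self.pairs], float)

    @classmethod
    def from_dict(cls, d: Mapping) -> "BreakpointTable":
        return cls(
            pollutant=d["pollutant"],
            pairs=tuple((float(c), float(i)) for c, i in d["pairs"]),
        )

    def to_dict(self) -> dict:
        return {"pollutant": self.pollutant, "pairs": [list(p) for p in self.pairs]}


def default_breakpoints(pollutant: str | None = None):
    """Default Chinese-standard 24-h particulate ladders (shipped as data).

    Returns one table when *pollutant* is given, else the full mapping.
    """
    text = resources.files("paqikit.data").joinpath("breakpoints_cn.json").read_text()
    raw = json.loads(text)
    tables = {k: BreakpointTable.from_dict(v) for k, v in raw.items() if k != "comment"}
    if pollutant is None:
        return tables
    try:
        return tables[pollutant]
    except KeyError:
        raise KeyError(f"no default breakpoint table for {pollutant!r}") from None


def load_breakpoints(path: str | Path) -> dict[str, BreakpointTable]:
    raw = json.loads(Path(path).read_text())
    return {k: BreakpointTable.from_dict(v) for k, v in raw.items() if k != "comment"}


def default_scheme() -> list[tuple[float, str]]:
    """Default index classification scheme: ordered (lower bound, label)."""
    text = resources.files("paqikit.data").joinpath("classification_cn.json").read_text()
    return [(float(lo), str(lab)) for lo, lab in json.loads(text)["scheme"]]


def iaqi(
    concentration,
    table: BreakpointTable,
    integer: bool = False,
):
    """Individual air-quality index by breakpoint interpolation.

    Locates the segment [C_lo, C_hi] containing the concentration and
    returns IAQI_lo + (IAQI_hi - IAQI_lo) * (C - C_lo) / (C_hi - C_lo).
    Concentrations above the last breakpoint return the cap index.  With
    ``integer=True`` the result is rounded up to the next integer
    (reporting convention); default is the unrounded real value, which the
    weighting and grid maps require.

    Accepts scalars or arrays.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    conc = table.concentrations
    idx = table.indexes
    # segment index: conc[k] <= c < conc[k+1]
    k = np.clip(np.searchsorted(conc, c, side="right") - 1, 0, len(conc) - 2)
    c_lo, c_hi = conc[k], conc[k + 1]
    i_lo, i_hi = idx[k], idx[k + 1]
    out = i_lo + (i_hi - i_lo) * (c - c_lo) / (c_hi - c_lo)
    out = np.where(c >= conc[-1], table.cap_index, out)
    if integer:
        out = np.ceil(out)
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


def raw_weights(indexes: Sequence[float]) -> np.ndarray:
    """Index-proportional weights Q_i = I_i / sum_j I_j."""
    I = np.asarray(indexes, dtype=float)
    if np.any(I < 0):
        raise ValueError("individual indexes must be non-negative")
    total = I.sum()
    if total <= 0:
        raise ValueError("all individual indexes are zero; weighting undefined")
    return I / total


def modify_weights(
    Q: Sequence[float],
    low_cut: float = 0.05,
    high_cut: float = 0.5,
    tol: float = 1e-9,
) -> tuple[np.ndarray, int, int]:
    """Extreme-value weight modification.

    Returns (P, s, t) with s = #{Q_i in [0, low_cut)} and
    t = #{Q_i in (high_cut, 1]}.  When s >= 1 and t >= 1, weights below
    low_cut are zeroed and the rest renormalized; otherwise P = Q.
    """
    Q = np.asarray(Q, dtype=float)
    if abs(Q.sum() - 1.0) > max(tol, 1e-6):
        raise ValueError(f"weights must sum to 1, got {Q.sum()}")
    s = int(np.count_nonzero((Q >= 0) & (Q < low_cut)))
    t = int(np.count_nonzero((Q > high_cut) & (Q <= 1)))
    if s >= 1 and t >= 1:
        P = np.where(Q < low_cut, 0.0, Q)
        P = P / P.sum()
    else:
        P = Q.copy()
    return P, s, t


@dataclass(frozen=True)
class IndexBundle:
    """Individual indexes with raw/modified weights and the composite PAQI."""

    indexes: np.ndarray
    raw: np.ndarray       # Q_i
    modified: np.ndarray  # P_i
    s: int
    t: int
    value: float          # PAQI


def paqi(
    indexes: Sequence[float],
    low_cut: float = 0.05,
    high_cut: float = 0.5,
) -> IndexBundle:
    """Composite particulate index: weighted sum with extreme-value handling."""
    I = np.asarray(indexes, dtype=float)
    Q = raw_weights(I)
    P, s, t = modify_weights(Q, low_cut=low_cut, high_cut=high_cut)
    return IndexBundle(
        indexes=I, raw=Q, modified=P, s=s, t=t, value=float(P @ I)
    )


def paqi_grid(
    index_fields: Mapping[str, GridField],
    low_cut: float = 0.05,
    high_cut: float = 0.5,
) -> GridField:
    """Per-cell PAQI over aligned individual-index rasters.

    Cells masked in any input are masked in the output.  Cells where every
    individual index is exactly zero get PAQI = 0 (clean-air limit).
    """
    if len(index_fields) < 2:
        raise ValueError("paqi_grid needs at least 2 pollutant index fields")
    align_check(dict(index_fields))
    fields = list(index_fields.values())
    mask = np.logical_and.reduce([f.mask for f in fields])
    stack = np.stack([np.where(mask, f.values, 0.0) for f in fields])  # (k, r, c)
    if np.any(stack[:, mask] < 0):
        raise ValueError("individual index rasters must be non-negative")
    total = stack.sum(axis=0)
    safe_total = np.where(total > 0, total, 1.0)
    Q = stack / safe_total
    s = ((Q >= 0) & (Q < low_cut)).sum(axis=0)
    tcount = ((Q > high_cut) & (Q <= 1)).sum(axis=0)
    modify = (s >= 1) & (tcount >= 1) & (total > 0)
    P = np.where(modify & (Q < low_cut), 0.0, Q)
    P_sum = P.sum(axis=0)
    P = P / np.where(P_sum > 0, P_sum, 1.0)
    values = (P * stack).sum(axis=0)
    values = np.where(total > 0, values, 0.0)
    out = fields[0].with_values(values, name="PAQI")
    out.mask = mask
    return out


def classify(
    value,
    scheme: Sequence[tuple[float, str]] | None = None,
):
    """Category label of an index value under an ordered bound scheme.

    Intervals are half-open [lo_k, lo_{k+1}): a value exactly on a bound
    takes the upper (more severe) category.  Accepts scalars or arrays
    (arrays return an object array of labels).
    """
    if scheme is None:
        scheme = default_scheme()
    bounds = np.array([lo for lo, _ in scheme], float)
    labels = np.array([lab for _, lab in scheme], object)
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("scheme bounds must be strictly increasing")
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("index value must be non-negative")
    k = np.clip(np.searchsorted(bounds, v, side="right") - 1, 0, len(bounds) - 1)
    out = labels[k]
    if np.isscalar(value) or np.ndim(value) == 0:
        return str(out)
    return out
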