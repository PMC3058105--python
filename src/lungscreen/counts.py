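"""Diagnosis count tables — the calibration currency.

A :class:`CountTable` holds diagnosis counts (observed integers or
simulated expectations) on a fixed cell layout: trial arm x detection
mode x stage group, optionally further stratified by cell type.  The
canonical marginal layout has 2 x 2 x 2 = 8 cells, of which the
(clinically_diagnosed, II_minus) cells are structural zeros — clinical
surfacing only happens in stage group III+.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .natural_history import CellType
from .screening import DetectionMode, StageGroup

ARMS = ("intervention", "control")
MODES = (DetectionMode.SCREEN_DETECTED.value, DetectionMode.CLINICALLY_DIAGNOSED.value)
STAGE_GROUPS = (StageGroup.II_MINUS.value, StageGroup.III_PLUS.value)

_BASE_LEVELS = ("arm", "mode", "stage_group")


def _canonical_index(by_cell_type: bool) -> pd.MultiIndex:
    levels = [ARMS, MODES, STAGE_GROUPS]
    names = list(_BASE_LEVELS)
    if by_cell_type:
        levels.append(tuple(ct.value for ct in CellType))
        names.append("cell_type")
    return pd.MultiIndex.from_product(levels, names=names)


@dataclass
class CountTable:
    """Counts indexed by (arm, mode, stage_group[, cell_type]).

    ``sources`` optionally labels each cell's provenance (e.g.
    ``fixture`` vs ``observed``) so synthetic fill-in cells can never be
    silently presented as trial data.
    """

    counts: pd.Series
    sources: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        s = self.counts
        if not isinstance(s, pd.Series) or not isinstance(s.index, pd.MultiIndex):
            raise TypeError("counts must be a MultiIndex-ed pandas Series")
        if list(s.index.names)[: len(_BASE_LEVELS)] != list(_BASE_LEVELS):
            raise ValueError(f"index levels must start with {_BASE_LEVELS}")
        if s.index.has_duplicates:
            raise ValueError("duplicate cells in count table")
        if (np.asarray(s.to_numpy(), dtype=float) < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = s.astype(float).sort_index()
        if self.sources is not None:
            self.sources = self.sources.reindex(self.counts.index)

    # ---------------------------------------------------------------- layout
    @property
    def by_cell_type(self) -> bool:
        return "cell_type" in self.counts.index.names

    @property
    def stratification(self) -> str:
        return "by_stage_and_celltype" if self.by_cell_type else "by_stage"

    def same_layout(self, other: "CountTable") -> bool:
        return self.counts.index.equals(other.counts.index)

    # ------------------------------------------------------------- accessors
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def cell(self, arm: str, mode: str, stage_group: str) -> float:
        idx = self.counts.index
        mask = (
            (idx.get_level_values("arm") == arm)
            & (idx.get_level_values("mode") == mode)
            & (idx.get_level_values("stage_group") == stage_group)
        )
        return float(self.counts[mask].sum())

    def arm_total(self, arm: str, mode: Optional[str] = None) -> float:
        sub = self.counts.xs(arm, level="arm")
        if mode is not None:
            sub = sub.xs(mode, level="mode")
        return float(sub.sum())

    def total(self) -> float:
        return float(self.counts.sum())

    def is_integer(self) -> bool:
        v = self.values()
        return bool(np.allclose(v, np.round(v)))

    def collapse_cell_type(self) -> "CountTable":
        if not self.by_cell_type:
            return self
        return CountTable(self.counts.groupby(level=list(_BASE_LEVELS)).sum())

    # ----------------------------------------------------------- constructors
    @classmethod
    def zeros(cls, by_cell_type: bool = False) -> "CountTable":
        idx = _canonical_index(by_cell_type)
        return cls(pd.Series(0.0, index=idx))

    @classmethod
    def from_dict(
        cls,
        cells: Mapping[tuple, float],
        by_cell_type: bool = False,
        sources: Optional[Mapping[tuple, str]] = None,
    ) -> "CountTable":
        """Build on the canonical layout; unspecified cells are zero."""
        idx = _canonical_index(by_cell_type)
        s = pd.Series(0.0, index=idx)
        for key, val in cells.items():
            if key not in s.index:
                raise KeyError(f"cell {key} not in canonical layout")
            s.loc[key] = float(val)
        src = None
        if sources is not None:
            src = pd.Series("", index=idx, dtype=object)
            for key, val in sources.items():
                src.loc[key] = val
        return cls(s, src)

    # ------------------------------------------------------------------- I/O
    def to_dataframe(self) -> pd.DataFrame:
        df = self.counts.rename("count").reset_index()
        if self.sources is not None:
            df["source"] = self.sources.to_numpy()
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CountTable":
        df = pd.read_csv(path)
        levels = [c for c in df.columns if c not in ("count", "source")]
        s = df.set_index(levels)["count"].rename(None)
        src = df.set_index(levels)["source"] if "source" in df.columns else None
        return cls(s, src)
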