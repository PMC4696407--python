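"""Descriptor matrices and unit-interval normalization.

Descriptor computation itself (e.g. PaDEL's 1D/2D/3D descriptor sets) happens
outside this package; matrices arrive as delimited text with a header row of
descriptor names and a first column of compound ids.  Here they are aligned
with compound records, min-max scaled to [0,1] column-wise, and the graded
target (number of inhibited isoforms, 0-5) is mapped to count/5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors, NaN marking missing values."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.astype(float)

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    @classmethod
    def from_arrays(cls, ids, names, values) -> "DescriptorMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float), index=list(ids), columns=list(names)))

    @classmethod
    def read_csv(cls, path, sep=",") -> "DescriptorMatrix":
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    def to_csv(self, path, sep=",") -> None:
        self.frame.to_csv(path, sep=sep)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


@dataclass
class NormalizationParams:
    """Per-descriptor min/max fitted on the modeling set; constants flagged."""

    mins: dict[str, float] = field(default_factory=dict)
    maxs: dict[str, float] = field(default_factory=dict)
    constant: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "mins": dict(sorted(self.mins.items())),
            "maxs": dict(sorted(self.maxs.items())),
            "constant": sorted(self.constant),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(mins=dict(d["mins"]), maxs=dict(d["maxs"]), constant=set(d["constant"]))


def fit_normalization(matrix: DescriptorMatrix) -> NormalizationParams:
    """Column-wise min/max over non-missing entries; constants flagged.

    Raises on an all-missing descriptor or on fewer than two compounds.
    """
    if len(matrix.ids) < 2:
        raise ValueError("need at least two compounds to fit normalization")
    params = NormalizationParams()
    for name in matrix.names:
        col = matrix.column(name)
        finite = col[~np.isnan(col)]
        if finite.size == 0:
            raise ValueError(f"descriptor {name!r} is entirely missing")
        lo, hi = float(finite.min()), float(finite.max())
        params.mins[name] = lo
        params.maxs[name] = hi
        if lo == hi:
            params.constant.add(name)
    return params


def apply_normalization(params: NormalizationParams, matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Scale each column to (x - min)/(max - min), clipped to [0,1].

    Out-of-range values on unseen compounds clip to the boundary so every
    downstream network input stays inside the unit interval.  Descriptors
    flagged constant at fit time are dropped.  Unknown descriptor names raise
    KeyError.
    """
    unknown = [n for n in matrix.names if n not in params.mins]
    if unknown:
        raise KeyError(f"descriptors not covered by normalization params: {unknown}")
    keep = [n for n in matrix.names if n not in params.constant]
    frame = matrix.frame[keep].copy()
    for name in keep:
        lo, hi = params.mins[name], params.maxs[name]
        frame[name] = np.clip((frame[name] - lo) / (hi - lo), 0.0, 1.0)
    return DescriptorMatrix(frame)


def normalize_label(count) -> float | np.ndarray:
    """Map an inhibited-isoform count (0-5) to the unit interval as count/5."""
    arr = np.asarray(count, dtype=float)
    if np.any((arr < 0) | (arr > 5)):
        raise ValueError("counts must be within 0..5")
    out = arr / 5.0
    return float(out) if out.ndim == 0 else out
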