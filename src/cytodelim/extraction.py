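"""Point sampling of environmental layers, collinearity pruning, standardization.

The niche analysis needs one complete row of environmental values per
occurrence record. Records that fall outside any layer's extent or hit a
nodata cell are dropped (and reported) rather than imputed. Highly collinear
predictors (|Pearson r| above a threshold, 0.8 by default) are pruned before
ordination so no climatic axis is double-counted, and the surviving columns
are z-scored on the pooled two-species matrix so that PCA operates on the
correlation structure rather than raw units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rasters import EnvLayer
from .thinning import OccurrenceSet


@dataclass
class EnvMatrix:
    """Records x environmental-variables table with processing provenance.

    ``data`` rows are indexed by the positional index of the record in the
    originating :class:`OccurrenceSet`; ``species`` is aligned to the same
    index. ``pruned`` lists (variable, |r| that removed it, partner variable).
    """

    data: pd.DataFrame
    species: pd.Series
    standardized: bool = False
    pruned: list[dict] = field(default_factory=list)
    dropped_records: list[dict] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def copy_with(self, data: pd.DataFrame, **kw) -> "EnvMatrix":
        out = EnvMatrix(
            data=data,
            species=self.species.loc[data.index],
            standardized=kw.get("standardized", self.standardized),
            pruned=list(self.pruned) + list(kw.get("new_pruned", [])),
            dropped_records=list(self.dropped_records),
        )
        return out


def extract_at_points(
    layers: Sequence[EnvLayer], occ: OccurrenceSet
) -> EnvMatrix:
    """Sample every layer at every occurrence point (containing cell, no
    interpolation); drop and report records that are incomplete in any layer.
    """
    if not layers:
        raise ValueError("at least one environmental layer is required")
    crs = layers[0].crs
    for lay in layers:
        if lay.crs != crs:
            raise ValueError(f"layer {lay.name} CRS {lay.crs} != {crs}")
    if occ.crs != crs:
        raise ValueError(f"occurrence CRS {occ.crs} does not match layer CRS {crs}")

    names = [lay.name for lay in layers]
    rows: dict[int, list[float]] = {}
    dropped: list[dict] = []
    for i, rec in enumerate(occ.records):
        vals: list[float] = []
        missing_in: str | None = None
        for lay in layers:
            v = lay.value_at(rec.lon, rec.lat)
            if v is None:
                missing_in = lay.name
                break
            vals.append(v)
        if missing_in is None:
            rows[i] = vals
        else:
            dropped.append(
                {"index": i, "species": rec.species, "lon": rec.lon, "lat": rec.lat,
                 "missing_in": missing_in}
            )
    data = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    species = pd.Series(
        {i: occ.records[i].species for i in data.index}, name="species", dtype=object
    )
    return EnvMatrix(data=data, species=species, dropped_records=dropped)


def prune_correlated(
    m: EnvMatrix,
    r_threshold: float = 0.8,
    keep_list: Sequence[str] = (),
) -> EnvMatrix:
    """Iteratively drop predictors until no retained pair has |r| > threshold.

    At each step, among variables involved in a still-violating pair (and not
    protected by ``keep_list``), the one with the largest mean |r| over its
    violating pairs is removed; ties break toward the later column. Constant
    columns carry no information and are dropped first with a warning.
    Pearson r is invariant to affine rescaling, so standardized and raw input
    give identical decisions.
    """
    if m.data.shape[1] < 2:
        raise ValueError("need at least two variables to prune")
    keep = set(keep_list)
    data = m.data.copy()
    new_pruned: list[dict] = []

    for col in list(data.columns):
        if data[col].nunique() <= 1:
            if col in keep:
                raise ValueError(f"keep_list variable {col!r} is constant")
            warnings.warn(f"dropping constant column {col!r} before correlation pruning")
            new_pruned.append({"variable": col, "abs_r": None, "partner": None,
                               "reason": "constant"})
            data = data.drop(columns=[col])

    while True:
        corr = data.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        violating = corr > r_threshold
        if not violating.to_numpy().any():
            break
        candidates = [c for c in data.columns if violating[c].any() and c not in keep]
        if not candidates:
            bad = [c for c in data.columns if violating[c].any()]
            raise ValueError(
                f"keep_list pins mutually correlated variables: {sorted(bad)}"
            )
        # mean |r| over the violating pairs each candidate participates in
        mean_viol = {
            c: float(corr.loc[violating[c], c].mean()) for c in candidates
        }
        order = {c: i for i, c in enumerate(data.columns)}
        drop = max(candidates, key=lambda c: (mean_viol[c], order[c]))
        partner = corr[drop].idxmax()
        new_pruned.append(
            {"variable": drop, "abs_r": float(corr.loc[partner, drop]),
             "partner": partner, "reason": "correlated"}
        )
        data = data.drop(columns=[drop])

    return m.copy_with(data, new_pruned=new_pruned)


def zscore(m: EnvMatrix) -> EnvMatrix:
    """Standardize each column to mean 0, SD 1 (ddof=1), pooled across species."""
    data = m.data
    sd = data.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be standardized: {constant}")
    out = (data - data.mean()) / sd
    return m.copy_with(out, standardized=True)
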