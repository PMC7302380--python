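"""RPKM/FPKM quantification and lineage abundance/activity ranking.

RPKM (reads) and FPKM (fragments) share one formula,

    mapped / ((length_bp / 1e3) * (library_size / 1e6)),

normalising each feature's mapped-read count by feature length and the
layer's library size. Metagenome mapping to whole MAGs measures
relative *abundance*; metatranscriptome mapping to genes measures
*activity* (expression). Layers with no library (e.g. deep layers whose
RNA failed QC) are absent from the matrix, not zero — absence and zero
are distinct observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CountTable",
    "QuantMatrix",
    "AggregateResult",
    "RankingResult",
    "rpkm",
    "quantify",
    "aggregate_by_group",
    "rank_lineages",
]

ROLES = ("metagenome", "metatranscriptome")
_COLUMNS = ["feature_id", "layer", "mapped", "length_bp", "library_size"]


@dataclass
class CountTable:
    """Long-form mapped-count records: one row per (feature, layer)."""

    records: pd.DataFrame
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"role: must be one of {ROLES}")
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"records: missing columns {missing}")
        r = self.records
        if r.duplicated(["feature_id", "layer"]).any():
            dup = r[r.duplicated(["feature_id", "layer"])].iloc[0]
            raise ValidationError(
                f"records: duplicate (feature, layer) = ({dup.feature_id!r}, {dup.layer!r})"
            )
        if (r["mapped"] < 0).any():
            raise ValidationError("records: mapped counts must be nonnegative")
        if (r["length_bp"] <= 0).any():
            raise ValidationError("records: feature lengths must be positive")
        if (r["library_size"] <= 0).any():
            raise ValidationError("records: library sizes must be positive")
        if (r["mapped"] > r["library_size"]).any():
            raise ValidationError("records: mapped exceeds library_size")


@dataclass
class QuantMatrix:
    """Feature x layer matrix of RPKM/FPKM values; NaN marks a
    (feature, layer) pair with no record (absent, not zero)."""

    values: pd.DataFrame
    role: str
    provenance: str = ""

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if (finite < 0).any() or np.isinf(finite).any():
            raise ValidationError("values: must be nonnegative and finite")

    @property
    def layers(self) -> list:
        return list(self.values.columns)


def rpkm(mapped: float, length_bp: float, library_size: float) -> float:
    """Reads (or fragments) per kilobase per million mapped reads."""
    if length_bp <= 0:
        raise ValidationError("length_bp: must be positive")
    if library_size <= 0:
        raise ValidationError("library_size: must be positive")
    return mapped / ((length_bp / 1e3) * (library_size / 1e6))


def quantify(counts: CountTable) -> QuantMatrix:
    """Elementwise RPKM/FPKM over all (feature, layer) records."""
    r = counts.records
    vals = r["mapped"] / ((r["length_bp"] / 1e3) * (r["library_size"] / 1e6))
    wide = (
        r.assign(value=vals)
        .pivot(index="feature_id", columns="layer", values="value")
        .rename_axis(index=None, columns=None)
    )
    return QuantMatrix(values=wide, role=counts.role)


@dataclass
class AggregateResult:
    table: pd.DataFrame      # group x layer
    reducer: str
    n_ungrouped: int
    ungrouped_features: tuple


def aggregate_by_group(
    matrix: QuantMatrix,
    grouping: Mapping[str, str],
    reducer: str = "sum",
) -> AggregateResult:
    """Reduce feature-level values to group x layer (e.g. genes to
    pathways, or MAGs to lineages). Features absent from ``grouping``
    are excluded and reported."""
    if reducer not in ("sum", "mean"):
        raise ValidationError(f"reducer: unknown reducer {reducer!r}")
    features = list(matrix.values.index)
    grouped = [f for f in features if f in grouping]
    ungrouped = tuple(f for f in features if f not in grouping)
    sub = matrix.values.loc[grouped]
    keys = pd.Series([grouping[f] for f in grouped], index=sub.index)
    agg = sub.groupby(keys).sum(min_count=1) if reducer == "sum" else sub.groupby(keys).mean()
    return AggregateResult(
        table=agg.rename_axis(index=None),
        reducer=reducer,
        n_ungrouped=len(ungrouped),
        ungrouped_features=ungrouped,
    )


@dataclass
class RankingResult:
    """Per-layer lineage rankings for abundance (DNA) and activity (RNA).

    ``consensus`` maps role -> the lineage ranked first in every layer
    of that role, or None when layers disagree.
    """

    abundance: pd.DataFrame   # lineage x layer summed RPKM (metagenome)
    activity: pd.DataFrame    # lineage x layer summed RPKM (metatranscriptome)
    top_abundant: dict        # layer -> lineage
    top_active: dict          # layer -> lineage
    consensus: dict           # {"abundance": lineage|None, "activity": lineage|None}


def _tops(table: pd.DataFrame) -> dict:
    return {layer: table[layer].idxmax() for layer in table.columns}


def rank_lineages(
    dna: QuantMatrix,
    rna: QuantMatrix,
    lineage_map: Mapping[str, str],
) -> RankingResult:
    """Rank lineages by summed RPKM, separately for abundance and
    activity; each role is ranked over its own layers, but the two
    matrices must share at least one layer."""
    if not set(dna.layers) & set(rna.layers):
        raise ValidationError("dna and rna layer sets are disjoint")
    ab = aggregate_by_group(dna, lineage_map, "sum").table.fillna(0.0)
    act = aggregate_by_group(rna, lineage_map, "sum").table.fillna(0.0)
    if ab.empty or act.empty:
        raise ValidationError("lineage_map covers no features")
    top_ab, top_act = _tops(ab), _tops(act)

    def _consensus(tops: dict):
        vals = set(tops.values())
        return vals.pop() if len(vals) == 1 else None

    return RankingResult(
        abundance=ab,
        activity=act,
        top_abundant=top_ab,
        top_active=top_act,
        consensus={"abundance": _consensus(top_ab), "activity": _consensus(top_act)},
    )
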