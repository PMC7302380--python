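"""Plain-text readers and writers for every pipeline artifact.

All formats are TSV or JSON so intermediates stay inspectable:

* OTU tables — rows are OTUs, columns samples, first column ``otu_id``
  (the in-memory orientation is samples x OTUs; transposed on IO);
  optionally a minimal BIOM-style (v1.0, JSON) export.
* taxonomy — two-column TSV ``otu_id<TAB>lineage`` plus a one-per-line
  methanogen-lineage list file.
* MAG annotations — TSV (mag_id, gene_id, marker_label, length_bp,
  lineage); empty marker_label means an unannotated gene.
* count tables — TSV (feature_id, layer, count, length_bp,
  library_size).
* network — edge-list TSV (otu_a, otu_b, rho, p, q), GraphML, and O/R
  screen results TSV.
* quant — long TSV (feature, layer, value, role); rankings as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .network import CooccurrenceNetwork, IncidenceRatioResult, OtuTable
from .pathway import Gene, MagAnnotation
from .quant import CountTable, QuantMatrix


# ---------------------------------------------------------------- OTU tables

def write_otu_tsv(table: OtuTable, path) -> None:
    frame = table.counts.T
    frame.index.name = "otu_id"
    frame.to_csv(path, sep="\t")


def write_taxonomy_tsv(table: OtuTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tlineage\n")
        for otu in table.otu_ids:
            fh.write(f"{otu}\t{table.lineage_map[otu]}\n")


def write_methanogen_list(table: OtuTable, path) -> None:
    with open(path, "w") as fh:
        for lin in sorted(table.methanogen_lineages):
            fh.write(lin + "\n")


def read_otu_table(otu_path, taxonomy_path, methanogen_path=None) -> OtuTable:
    frame = pd.read_csv(otu_path, sep="\t", index_col="otu_id").T
    frame = frame.astype(int)
    tax = pd.read_csv(taxonomy_path, sep="\t")
    lineage_map = dict(zip(tax["otu_id"], tax["lineage"]))
    methanogens: frozenset = frozenset()
    if methanogen_path is not None:
        lines = Path(methanogen_path).read_text().split()
        methanogens = frozenset(lines)
    return OtuTable(counts=frame, lineage_map=lineage_map,
                    methanogen_lineages=methanogens)


def write_biom_json(table: OtuTable, path) -> None:
    """Minimal BIOM v1.0 (dense) JSON export of an OTU table."""
    data = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "methanonet",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [len(table.otu_ids), len(table.sample_ids)],
        "rows": [
            {"id": o, "metadata": {"taxonomy": table.lineage_map[o]}}
            for o in table.otu_ids
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.counts.T.to_numpy().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


# ------------------------------------------------------------- annotations

def write_annotations_tsv(mags: Sequence[MagAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("mag_id\tgene_id\tmarker_label\tlength_bp\tlineage\n")
        for mag in mags:
            for g in mag.genes:
                marker = g.marker or ""
                fh.write(f"{mag.mag_id}\t{g.gene_id}\t{marker}\t{g.length_bp}\t{mag.lineage}\n")


def read_annotations_tsv(path) -> list[MagAnnotation]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    mags = []
    for mag_id, sub in frame.groupby("mag_id", sort=False):
        lineages = sub["lineage"].unique()
        if len(lineages) != 1:
            raise ValidationError(f"{mag_id}: conflicting lineage labels {list(lineages)}")
        genes = tuple(
            Gene(row.gene_id, row.marker_label or None, int(row.length_bp))
            for row in sub.itertuples()
        )
        mags.append(MagAnnotation(mag_id=mag_id, lineage=lineages[0], genes=genes))
    return mags


# ------------------------------------------------------------ count tables

def write_counts_tsv(counts: CountTable, path) -> None:
    out = counts.records.rename(columns={"mapped": "count"})
    out.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, role: str) -> CountTable:
    frame = pd.read_csv(path, sep="\t").rename(columns={"count": "mapped"})
    return CountTable(records=frame, role=role)


# ----------------------------------------------------------------- network

def write_edges_tsv(net: CooccurrenceNetwork, path) -> None:
    net.edges_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def write_or_results_tsv(results: Iterable[IncidenceRatioResult], path) -> None:
    rows = []
    for r in results:
        rows.append({
            "lineage_a": r.lineage_a,
            "lineage_b": r.lineage_b,
            "observed": r.observed,
            "expected": r.expected,
            "or_ratio": r.or_ratio,
            "null_model": r.null_model,
            "perm_p": "" if r.perm_p is None else r.perm_p,
            "n_permutations": "" if r.n_permutations is None else r.n_permutations,
            "retained": "" if r.retained is None else r.retained,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- quant

def write_quant_tsv(matrix: QuantMatrix, path) -> None:
    long = (
        matrix.values.rename_axis(index="feature", columns="layer")
        .stack(future_stack=True)
        .rename("value")
        .reset_index()
        .dropna(subset=["value"])
    )
    long["role"] = matrix.role
    long.to_csv(path, sep="\t", index=False)


def read_quant_tsv(path) -> QuantMatrix:
    frame = pd.read_csv(path, sep="\t")
    roles = frame["role"].unique()
    if len(roles) != 1:
        raise ValidationError(f"{path}: expected a single role, got {list(roles)}")
    wide = frame.pivot(index="feature", columns="layer", values="value")
    return QuantMatrix(values=wide.rename_axis(index=None, columns=None),
                       role=roles[0])


# --------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
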