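"""Synthetic microbial-community data with planted, recoverable ground truth.

Three generators emulate the three input kinds of the analysis chain:

* :func:`generate_otu_table` — fixed-depth amplicon OTU count tables
  (samples x OTUs) in which selected OTU pairs share a latent log-normal
  factor, so their relative abundances are rank-correlated with a
  tunable coupling strength;
* :func:`generate_mag_annotations` — per-MAG marker-gene inventories
  derived from lineage templates, with Bernoulli marker dropout
  emulating genome incompleteness;
* :func:`generate_count_tables` — read-mapping count tables (reads per
  MAG and fragments per gene, per sediment layer) for a metagenome and
  a metatranscriptome, with abundance and activity planted separately
  so that one lineage can be made the most abundant while another is
  the most active.

All randomness flows through a single integer seed per generator call;
identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import OtuTable
from .pathway import MagAnnotation, Gene, default_marker_config
from .quant import CountTable

__all__ = [
    "CommunitySpec",
    "PathwayTemplate",
    "AbundanceActivitySpec",
    "generate_otu_table",
    "generate_mag_annotations",
    "generate_count_tables",
    "default_templates",
]


# --------------------------------------------------------------------------
# community spec / OTU tables
# --------------------------------------------------------------------------

# sd of across-OTU base log-abundances (even-ish communities; see
# generate_otu_table for why this is not tied to the per-sample sigma)
_BASE_LOG_SPREAD = 0.5

@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic amplicon community.

    ``planted_pairs`` is a list of ``(otu_a, otu_b, strength)`` triples;
    each pair shares a latent per-sample Gaussian factor with loading
    ``sqrt(strength)`` on both members, so the latent log-abundance
    correlation of the pair equals ``strength`` and the expected sample
    Spearman correlation increases monotonically with it.
    """

    n_samples: int
    n_otus: int
    lineage_map: Mapping[str, str]
    methanogen_lineages: frozenset = frozenset()
    planted_pairs: tuple = ()
    depth_per_sample: int = 100_000
    base_abundance_dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples: must be a positive count")
        if self.n_otus < 1:
            raise ValidationError("n_otus: must be a positive count")
        if len(self.lineage_map) != self.n_otus:
            raise ValidationError(
                f"lineage_map: expected {self.n_otus} OTUs, got {len(self.lineage_map)}"
            )
        if self.depth_per_sample < self.n_otus:
            raise ValidationError("depth_per_sample: must be >= n_otus")
        if self.base_abundance_dispersion <= 0:
            raise ValidationError("base_abundance_dispersion: must be positive")
        lineages = set(self.lineage_map.values())
        unknown = set(self.methanogen_lineages) - lineages
        if unknown:
            raise ValidationError(
                f"methanogen_lineages: not present in lineage_map: {sorted(unknown)}"
            )
        load = {}
        for k, (a, b, s) in enumerate(self.planted_pairs):
            if a == b:
                raise ValidationError(f"planted_pairs[{k}]: OTUs must be distinct")
            for o in (a, b):
                if o not in self.lineage_map:
                    raise ValidationError(f"planted_pairs[{k}]: unknown OTU {o!r}")
            if not (0.0 < s <= 1.0):
                raise ValidationError(f"planted_pairs[{k}]: strength must be in (0, 1]")
            load[a] = load.get(a, 0.0) + s
            load[b] = load.get(b, 0.0) + s
        bad = [o for o, v in load.items() if v > 1.0 + 1e-12]
        if bad:
            raise ValidationError(
                f"planted_pairs: summed strengths exceed 1 for OTUs {sorted(bad)}"
            )

    @classmethod
    def from_lineage_sizes(
        cls,
        sizes: Mapping[str, int],
        methanogen_lineages: Sequence[str] = (),
        n_samples: int = 78,
        planted_pairs: tuple = (),
        depth_per_sample: int = 100_000,
        base_abundance_dispersion: float = 1.0,
        seed: int = 0,
    ) -> "CommunitySpec":
        """Build a spec from per-lineage OTU counts.

        OTU ids are ``<lineage>_<i>`` so that tests and demos can refer
        to them without bookkeeping.
        """
        lineage_map = {}
        for lin, n in sizes.items():
            for i in range(n):
                lineage_map[f"{lin}_{i}"] = lin
        return cls(
            n_samples=n_samples,
            n_otus=len(lineage_map),
            lineage_map=lineage_map,
            methanogen_lineages=frozenset(methanogen_lineages),
            planted_pairs=tuple(planted_pairs),
            depth_per_sample=depth_per_sample,
            base_abundance_dispersion=base_abundance_dispersion,
            seed=seed,
        )


def generate_otu_table(spec: CommunitySpec) -> OtuTable:
    """Draw a fixed-depth OTU count table from the community spec.

    Per-sample latent log-abundances are ``mu_i + sigma * z_{s,i}`` with
    ``z`` standard normal except that planted pairs load on a shared
    factor; counts are multinomial at ``depth_per_sample`` on the
    softmax of the latent abundances, emulating the compositionality of
    fixed-depth amplicon data.
    """
    rng = np.random.default_rng(spec.seed)
    otu_ids = list(spec.lineage_map)
    idx = {o: i for i, o in enumerate(otu_ids)}
    n, p = spec.n_samples, spec.n_otus
    sigma = spec.base_abundance_dispersion

    # Across-OTU base spread is kept moderate and independent of the
    # per-sample dispersion: if single OTUs dominate the per-sample
    # denominator, compositional closure induces spurious correlations
    # between unplanted pairs, breaking their conditional independence.
    mu = rng.normal(0.0, _BASE_LOG_SPREAD, size=p)
    n_pairs = len(spec.planted_pairs)
    loadings = np.zeros((p, n_pairs))
    for k, (a, b, s) in enumerate(spec.planted_pairs):
        loadings[idx[a], k] = math.sqrt(s)
        loadings[idx[b], k] = math.sqrt(s)
    resid_sd = np.sqrt(np.clip(1.0 - (loadings**2).sum(axis=1), 0.0, None))

    factors = rng.standard_normal((n, n_pairs)) if n_pairs else np.zeros((n, 0))
    eps = rng.standard_normal((n, p))
    z = factors @ loadings.T + resid_sd * eps
    w = np.exp(mu + sigma * z)
    probs = w / w.sum(axis=1, keepdims=True)

    counts = np.empty((n, p), dtype=np.int64)
    for s in range(n):
        counts[s] = rng.multinomial(spec.depth_per_sample, probs[s])

    frame = pd.DataFrame(
        counts,
        index=[f"S{j:03d}" for j in range(n)],
        columns=otu_ids,
    )
    return OtuTable(
        counts=frame,
        lineage_map=dict(spec.lineage_map),
        methanogen_lineages=frozenset(spec.methanogen_lineages),
    )


# --------------------------------------------------------------------------
# MAG annotation templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayTemplate:
    """Intended marker inventory of one synthetic MAG.

    ``dropout_rate`` is the per-marker probability of being missing from
    the generated annotation, emulating genome incompleteness.
    """

    lineage: str
    present_markers: frozenset
    dropout_rate: float = 0.0
    mag_id: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate: must be in [0, 1)")


def default_templates(dropout_rate: float = 0.0) -> list[PathwayTemplate]:
    """Lineage templates for the six sediment methanogen groups.

    MM (Methanomicrobiales) carries the full hydrogenotrophic core plus
    Ech/Eha/Ehb hydrogenases and the RHP carbon-fixation gene set; MS
    (Methanosarcinales) the union of all three methanogenesis pathways;
    MF (Methanofastidiosa) and MMA (Methanomassiliicoccales) are
    MTR-lacking methylotrophs with the HdrABC/MvhADG complex (MMA also
    Fpo+HdrD); MB and MC are mcr-less partial hydrogenotrophic bins.
    """
    hydro = {"fwd", "ftr", "mch", "mtd", "mer", "mtr", "mcr"}
    hdr_mvh = {"hdrA", "hdrB", "hdrC", "mvhA", "mvhD", "mvhG"}
    return [
        PathwayTemplate("MM", frozenset(hydro | {"ech", "eha", "ehb", "rhp"}),
                        dropout_rate, "MM1"),
        PathwayTemplate("MS", frozenset(hydro | {"acs", "cdh", "mts", "mta", "mtm",
                                                 "mtb", "mtt"}),
                        dropout_rate, "MS1"),
        PathwayTemplate("MF", frozenset({"mts", "mta", "mtb", "mtt", "mcr", "ehb"}
                                        | hdr_mvh),
                        dropout_rate, "MF1"),
        PathwayTemplate("MMA", frozenset({"mts", "mta", "mtm", "mtb", "mtt", "mcr",
                                          "fpo", "hdrD"} | hdr_mvh),
                        dropout_rate, "MMA1"),
        # partial bins: hydrogenotrophic fragments, no mcr recovered
        PathwayTemplate("MB", frozenset({"fwd", "ftr", "mch", "mtd"}),
                        dropout_rate, "MB"),
        PathwayTemplate("MC", frozenset({"ftr", "mch", "mtd", "mer"}),
                        dropout_rate, "MC"),
    ]


def generate_mag_annotations(
    templates: Sequence[PathwayTemplate],
    seed: int,
    n_background_genes: int = 20,
    vocabulary: frozenset | None = None,
    gene_length_range: tuple[int, int] = (300, 3000),
) -> list[MagAnnotation]:
    """Materialise MAG gene inventories from lineage templates.

    Each template marker is retained independently with probability
    ``1 - dropout_rate``; every retained marker becomes one gene, plus
    ``n_background_genes`` unannotated genes. Gene lengths are uniform
    on ``gene_length_range`` (typical prokaryotic CDS range).
    """
    if not templates:
        raise ValidationError("templates: must be non-empty")
    if vocabulary is None:
        vocabulary = default_marker_config().vocabulary
    unknown = sorted(
        {m for t in templates for m in t.present_markers} - set(vocabulary)
    )
    if unknown:
        raise ValidationError(f"unknown marker labels: {unknown}")

    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    mags = []
    for k, tpl in enumerate(templates):
        mag_id = tpl.mag_id or f"{tpl.lineage}_{k}"
        markers = sorted(tpl.present_markers)
        keep = rng.random(len(markers)) >= tpl.dropout_rate
        genes = []
        g = 0
        for m, ok in zip(markers, keep):
            if ok:
                genes.append(Gene(f"{mag_id}_g{g:04d}", m,
                                  int(rng.integers(lo, hi + 1))))
                g += 1
        for _ in range(n_background_genes):
            genes.append(Gene(f"{mag_id}_g{g:04d}", None,
                              int(rng.integers(lo, hi + 1))))
            g += 1
        mags.append(MagAnnotation(mag_id=mag_id, lineage=tpl.lineage,
                                  genes=tuple(genes)))
    return mags


# --------------------------------------------------------------------------
# abundance / activity count tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceActivitySpec:
    """Planted lineage abundance and activity across sediment layers.

    ``true_abundance`` is a lineage x layer DataFrame whose per-layer
    (column) relative abundances sum to 1; ``activity_multiplier``
    scales transcription relative to abundance, decoupling "most
    active" from "most abundant". ``library_size_rna`` may cover only a
    subset of layers (layers without RNA libraries are simply absent
    from the transcriptome table, mirroring real incomplete profiles).
    """

    true_abundance: pd.DataFrame
    activity_multiplier: pd.DataFrame
    library_size_dna: Mapping[str, int]
    library_size_rna: Mapping[str, int]
    seed: int = 0

    def __post_init__(self):
        ab, act = self.true_abundance, self.activity_multiplier
        if list(ab.index) != list(act.index) or list(ab.columns) != list(act.columns):
            raise ValidationError(
                "activity_multiplier: must share index/columns with true_abundance "
                f"(expected shape {ab.shape})"
            )
        if (ab.to_numpy() < 0).any():
            raise ValidationError("true_abundance: entries must be nonnegative")
        if (act.to_numpy() < 0).any():
            raise ValidationError("activity_multiplier: entries must be nonnegative")
        colsums = ab.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValidationError(
                "true_abundance: per-layer abundances must sum to 1 "
                f"(got {colsums.to_dict()})"
            )
        for name, libs in (("library_size_dna", self.library_size_dna),
                           ("library_size_rna", self.library_size_rna)):
            unknown = set(libs) - set(ab.columns)
            if unknown:
                raise ValidationError(f"{name}: unknown layers {sorted(unknown)}")
            if any(v <= 0 for v in libs.values()):
                raise ValidationError(f"{name}: library sizes must be positive")
        if not self.library_size_dna:
            raise ValidationError("library_size_dna: at least one layer required")


def _mag_length(mag: MagAnnotation) -> int:
    return sum(g.length_bp for g in mag.genes)


def generate_count_tables(
    spec: AbundanceActivitySpec,
    mags: Sequence[MagAnnotation],
) -> tuple[CountTable, CountTable]:
    """Draw metagenome (per-MAG) and metatranscriptome (per-gene) counts.

    DNA reads per layer are multinomial over MAGs with weights
    ``abundance(lineage) * mag_length``; RNA fragments are multinomial
    over genes with weights ``abundance * activity * gene_length``.
    Returns ``(dna_counts, rna_counts)``.
    """
    if not mags:
        raise ValidationError("mags: must be non-empty")
    lineages = set(spec.true_abundance.index)
    missing = sorted({m.lineage for m in mags} - lineages)
    if missing:
        raise ValidationError(
            "true_abundance: missing rows for MAG lineages "
            f"{missing} (expected shape ({len(lineages) + len(missing)} lineages, "
            f"{spec.true_abundance.shape[1]} layers))"
        )
    rng = np.random.default_rng(spec.seed)

    mag_len = np.array([_mag_length(m) for m in mags], dtype=float)
    dna_rows = []
    for layer in spec.true_abundance.columns:
        if layer not in spec.library_size_dna:
            continue
        lib = int(spec.library_size_dna[layer])
        ab = np.array([spec.true_abundance.loc[m.lineage, layer] for m in mags])
        w = ab * mag_len
        if w.sum() <= 0:
            raise ValidationError(f"true_abundance: all-zero weights in layer {layer!r}")
        draws = rng.multinomial(lib, w / w.sum())
        for m, ml, c in zip(mags, mag_len, draws):
            dna_rows.append((m.mag_id, layer, int(c), int(ml), lib))

    gene_ids = [g.gene_id for m in mags for g in m.genes]
    gene_len = np.array([g.length_bp for m in mags for g in m.genes], dtype=float)
    gene_lineage = [m.lineage for m in mags for _ in m.genes]
    rna_rows = []
    for layer in spec.true_abundance.columns:
        if layer not in spec.library_size_rna:
            continue
        lib = int(spec.library_size_rna[layer])
        ab = np.array([spec.true_abundance.loc[lin, layer] for lin in gene_lineage])
        act = np.array([spec.activity_multiplier.loc[lin, layer] for lin in gene_lineage])
        w = ab * act * gene_len
        if w.sum() <= 0:
            raise ValidationError(
                f"activity_multiplier: all-zero expression weights in layer {layer!r}"
            )
        draws = rng.multinomial(lib, w / w.sum())
        for gid, gl, c in zip(gene_ids, gene_len, draws):
            rna_rows.append((gid, layer, int(c), int(gl), lib))

    cols = ["feature_id", "layer", "mapped", "length_bp", "library_size"]
    dna = CountTable(pd.DataFrame(dna_rows, columns=cols), role="metagenome")
    rna = CountTable(pd.DataFrame(rna_rows, columns=cols), role="metatranscriptome")
    return dna, rna
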