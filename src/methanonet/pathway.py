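"""Methanogenesis pathway calls from MAG marker-gene inventories.

A MAG's annotation is reduced to the set of marker labels it carries;
each configured pathway is an ordered list of required steps, a step
being satisfied when any of its acceptable marker groups is fully
present (synonyms are ORed, complex subunits ANDed). Completeness is
the unweighted fraction of satisfied steps and a pathway is *complete*
only at completeness 1.0 — so an incomplete genome (e.g. a bin lacking
mcr) can never be called complete, and mcr, being a required step of
all three pathways, gates every complete call.

Variant flags capture lineage-diagnostic gene modules: the
HdrABC/MvhADG complex, membrane-bound hydrogenases (Ech/Eha/Ehb),
Fpo+HdrD coupling, and the RHP carbon-fixation gene set. The
``h2_dependent_methylotrophic`` flag marks MAGs with a complete
methylotrophic pathway, no MTR complex, and Hdr/Mvh present — the
physiology of Methanofastidiosa and Methanomassiliicoccales, which
reduce methyl compounds with H2 instead of running the membrane-bound
methyl transfer step.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "Gene",
    "MagAnnotation",
    "Step",
    "PathwayDef",
    "ModuleDef",
    "FlagDef",
    "MarkerSetConfig",
    "PathwayCall",
    "CohortProfile",
    "load_marker_config",
    "default_marker_config",
    "call_pathways",
    "profile_cohort",
]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    marker: str | None
    length_bp: int


@dataclass(frozen=True)
class MagAnnotation:
    """Per-MAG gene inventory; ``completeness_estimate`` is an optional
    external genome-completeness percentage (0–100)."""

    mag_id: str
    lineage: str
    genes: tuple
    completeness_estimate: float | None = None

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"{self.mag_id}: duplicate gene ids")
        if any(g.length_bp <= 0 for g in self.genes):
            raise ValidationError(f"{self.mag_id}: gene lengths must be positive")

    def marker_set(self) -> frozenset:
        return frozenset(g.marker for g in self.genes if g.marker is not None)


@dataclass(frozen=True)
class Step:
    name: str
    any_of: tuple  # tuple of frozensets of markers; groups ORed, members ANDed

    def satisfied_by(self, markers: frozenset) -> bool:
        return any(group <= markers for group in self.any_of)


@dataclass(frozen=True)
class PathwayDef:
    name: str
    steps: tuple


@dataclass(frozen=True)
class ModuleDef:
    name: str
    any_of: tuple

    def satisfied_by(self, markers: frozenset) -> bool:
        return any(group <= markers for group in self.any_of)


@dataclass(frozen=True)
class FlagDef:
    name: str
    requires_complete: str
    requires_absent_markers: tuple
    requires_module: str | None


@dataclass(frozen=True)
class MarkerSetConfig:
    pathways: tuple
    modules: tuple
    flags: tuple
    aux_markers: tuple = ()

    @property
    def vocabulary(self) -> frozenset:
        vocab = set(self.aux_markers)
        for p in self.pathways:
            for s in p.steps:
                for group in s.any_of:
                    vocab |= set(group)
        for m in self.modules:
            for group in m.any_of:
                vocab |= set(group)
        return frozenset(vocab)

    def pathway(self, name: str) -> PathwayDef:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)


def _parse_any_of(raw, where: str, problems: list) -> tuple:
    if not isinstance(raw, list) or not raw:
        problems.append(f"{where}.any_of: expected a non-empty list of marker groups")
        return ()
    groups = []
    for i, group in enumerate(raw):
        if not isinstance(group, list) or not group or not all(
            isinstance(m, str) for m in group
        ):
            problems.append(f"{where}.any_of[{i}]: expected a non-empty list of marker labels")
            continue
        groups.append(frozenset(group))
    return tuple(groups)


def _parse_config(data, source: str) -> MarkerSetConfig:
    problems: list[str] = []
    if not isinstance(data, dict):
        raise SchemaError(f"{source}: expected a mapping at top level")

    pathways = []
    raw_paths = data.get("pathways")
    if not isinstance(raw_paths, list) or not raw_paths:
        problems.append(f"{source}.pathways: expected a non-empty list")
        raw_paths = []
    for pi, p in enumerate(raw_paths):
        where = f"{source}.pathways[{pi}]"
        if not isinstance(p, dict) or "name" not in p or "steps" not in p:
            problems.append(f"{where}: expected mapping with 'name' and 'steps'")
            continue
        steps = []
        seen = set()
        for si, s in enumerate(p["steps"] or []):
            swhere = f"{where}.steps[{si}]"
            if not isinstance(s, dict) or "name" not in s:
                problems.append(f"{swhere}: expected mapping with 'name' and 'any_of'")
                continue
            if s["name"] in seen:
                problems.append(f"{swhere}: duplicate step label {s['name']!r}")
                continue
            seen.add(s["name"])
            steps.append(Step(s["name"], _parse_any_of(s.get("any_of"), swhere, problems)))
        if not steps:
            problems.append(f"{where}: pathway has no steps")
        pathways.append(PathwayDef(p["name"], tuple(steps)))
    names = [p.name for p in pathways]
    if len(set(names)) != len(names):
        problems.append(f"{source}.pathways: duplicate pathway names")

    modules = []
    for mi, m in enumerate(data.get("modules") or []):
        where = f"{source}.modules[{mi}]"
        if not isinstance(m, dict) or "name" not in m:
            problems.append(f"{where}: expected mapping with 'name' and 'any_of'")
            continue
        modules.append(ModuleDef(m["name"], _parse_any_of(m.get("any_of"), where, problems)))

    flags = []
    module_names = {m.name for m in modules}
    for fi, f in enumerate(data.get("flags") or []):
        where = f"{source}.flags[{fi}]"
        if not isinstance(f, dict) or "name" not in f or "requires_complete" not in f:
            problems.append(f"{where}: expected mapping with 'name' and 'requires_complete'")
            continue
        if f["requires_complete"] not in {p.name for p in pathways}:
            problems.append(f"{where}.requires_complete: unknown pathway {f['requires_complete']!r}")
            continue
        mod = f.get("requires_module")
        if mod is not None and mod not in module_names:
            problems.append(f"{where}.requires_module: unknown module {mod!r}")
            continue
        flags.append(FlagDef(
            f["name"],
            f["requires_complete"],
            tuple(f.get("requires_absent_markers") or ()),
            mod,
        ))

    if problems:
        raise SchemaError(problems)
    return MarkerSetConfig(
        pathways=tuple(pathways),
        modules=tuple(modules),
        flags=tuple(flags),
        aux_markers=tuple(data.get("aux_markers") or ()),
    )


def load_marker_config(path: str | Path) -> MarkerSetConfig:
    """Load and schema-check a marker-set YAML; all violations are
    reported at once with the path to each offending key."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise SchemaError(f"{path}: empty config file")
    return _parse_config(data, str(path))


_DEFAULT_CONFIG: MarkerSetConfig | None = None


def default_marker_config() -> MarkerSetConfig:
    """The packaged default: three methanogenesis pathways (CO2/H2,
    acetate, methyl compounds) and four auxiliary modules."""
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        ref = importlib.resources.files("methanonet.data") / "markers.yaml"
        data = yaml.safe_load(ref.read_text())
        _DEFAULT_CONFIG = _parse_config(data, "markers.yaml")
    return _DEFAULT_CONFIG


@dataclass(frozen=True)
class PathwayCall:
    """One MAG x pathway verdict. ``variant_flags`` carries the MAG's
    satisfied auxiliary modules (``<module>_present``) plus any
    conditional flags tied to this pathway."""

    mag_id: str
    pathway: str
    steps_present: tuple
    completeness: float
    complete: bool
    variant_flags: tuple = ()


def call_pathways(
    mag: MagAnnotation,
    config: MarkerSetConfig | None = None,
    soft_complete_threshold: float | None = None,
) -> list[PathwayCall]:
    """Evaluate every configured pathway against one MAG.

    ``soft_complete_threshold`` (off by default) lowers the bar for the
    ``complete`` flag below 1.0 for exploratory use; completeness
    itself is always the exact fraction of satisfied steps. Missing
    markers are data, not errors.
    """
    config = config or default_marker_config()
    markers = mag.marker_set()

    module_flags = tuple(
        f"{m.name}_present" for m in config.modules if m.satisfied_by(markers)
    )
    threshold = 1.0 if soft_complete_threshold is None else soft_complete_threshold

    calls = []
    completeness_by = {}
    for pdef in config.pathways:
        present = tuple(s.name for s in pdef.steps if s.satisfied_by(markers))
        completeness = len(present) / len(pdef.steps)
        completeness_by[pdef.name] = completeness
        calls.append(PathwayCall(
            mag_id=mag.mag_id,
            pathway=pdef.name,
            steps_present=present,
            completeness=completeness,
            complete=completeness >= threshold,
            variant_flags=module_flags,
        ))

    # conditional flags attach to the pathway they qualify
    module_ok = {m.name: m.satisfied_by(markers) for m in config.modules}
    out = []
    for call in calls:
        extra = []
        for f in config.flags:
            if f.requires_complete != call.pathway:
                continue
            if not call.complete:
                continue
            if any(m in markers for m in f.requires_absent_markers):
                continue
            if f.requires_module is not None and not module_ok[f.requires_module]:
                continue
            extra.append(f.name)
        out.append(
            call if not extra else PathwayCall(
                call.mag_id, call.pathway, call.steps_present,
                call.completeness, call.complete,
                call.variant_flags + tuple(extra),
            )
        )
    return out


@dataclass
class CohortProfile:
    """MAG x pathway completeness matrix plus per-MAG flags."""

    completeness: pd.DataFrame  # mag_id x pathway, fractions in [0, 1]
    complete: pd.DataFrame      # mag_id x pathway, booleans
    flags: dict                 # mag_id -> tuple of flags (union over calls)
    n_complete: pd.Series       # mag_id -> number of complete pathways


def profile_cohort(
    mags: Sequence[MagAnnotation],
    config: MarkerSetConfig | None = None,
) -> CohortProfile:
    """Pathway calls for a MAG cohort as matrices.

    A MAG with no mcr marker necessarily reports zero complete
    pathways, since mcr is a required step of every pathway.
    """
    if not mags:
        raise ValidationError("mags: at least one MAG required")
    ids = [m.mag_id for m in mags]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate mag_id in cohort")
    config = config or default_marker_config()

    comp_rows, bool_rows, flags = {}, {}, {}
    for mag in mags:
        calls = call_pathways(mag, config)
        comp_rows[mag.mag_id] = {c.pathway: c.completeness for c in calls}
        bool_rows[mag.mag_id] = {c.pathway: c.complete for c in calls}
        flags[mag.mag_id] = tuple(sorted({f for c in calls for f in c.variant_flags}))
    completeness = pd.DataFrame.from_dict(comp_rows, orient="index").loc[ids]
    complete = pd.DataFrame.from_dict(bool_rows, orient="index").loc[ids]
    return CohortProfile(
        completeness=completeness,
        complete=complete,
        flags=flags,
        n_complete=complete.sum(axis=1),
    )
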