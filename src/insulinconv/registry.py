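"""Assay and data-source registries, sample curation and pair merging.

The package ships built-in registries describing the eight insulin
immunoassays (CLIA, RIA and ELISA families) and the eleven data sources whose
pairwise comparisons back the conversion models — thirteen distinct assay
pairs in total.  Paired measurements are curated (exogenous-insulin samples
dropped, values outside an assay's quantification limits removed, diluted
samples within limits kept), merged across sources into one dataset per
unordered pair, and summarised as an undirected comparison graph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "Assay", "DataSource", "PairedSample", "ComparisonDataset",
    "DEFAULT_ASSAYS", "DEFAULT_SOURCES",
    "load_assay_registry", "load_source_registry",
    "curate_samples", "merge_sources", "merge_oriented_sources",
    "validate_counts", "build_pair_graph",
    "read_paired_csv", "write_paired_csv", "canonical_pair",
]

ASSAY_FAMILIES = ("CLIA", "RIA", "ELISA")


@dataclass(frozen=True)
class Assay:
    """One insulin immunoassay: id letter, vendor name, family, LoQ limits."""

    id: str
    name: str
    family: str
    loq_lower: float | None = None
    loq_upper: float | None = None

    def __post_init__(self):
        if self.family not in ASSAY_FAMILIES:
            raise ValidationError(f"unknown assay family {self.family!r} for assay {self.id!r}")
        if self.loq_lower is not None and self.loq_upper is not None \
                and not self.loq_lower < self.loq_upper:
            raise ValidationError(f"assay {self.id!r}: loq_lower must be < loq_upper")


@dataclass(frozen=True)
class DataSource:
    """One data source: citation label and its declared pair/sample counts."""

    source_id: str
    citation: str
    comparisons: tuple[tuple[tuple[str, str], int], ...]  # ((assay, assay), n)
    comment: str = ""

    def __post_init__(self):
        for (a, b), n in self.comparisons:
            if n <= 0:
                raise ValidationError(f"source {self.source_id!r}: declared count must be > 0")
            if a == b:
                raise ValidationError(f"source {self.source_id!r}: self-comparison {a} vs {a}")


@dataclass(frozen=True)
class PairedSample:
    """One sample measured on two assays, concentrations in uIU/mL."""

    source_id: str
    x: float
    y: float
    diluted: bool = False
    exogenous: bool = False

    def __post_init__(self):
        import math
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError("paired sample values must be finite")
        if self.x < 0 or self.y < 0:
            raise ValidationError("insulin concentrations must be non-negative")


@dataclass
class ComparisonDataset:
    """Curated, merged paired data for one unordered assay pair.

    The pair is stored in canonical lexicographic order; ``x`` belongs to the
    first assay of the pair and ``y`` to the second.
    """

    pair: tuple[str, str]
    samples: list[PairedSample] = field(default_factory=list)

    def __post_init__(self):
        if self.pair[0] >= self.pair[1]:
            raise ValidationError(f"pair {self.pair} is not in canonical order")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def source_ids(self) -> set[str]:
        return {s.source_id for s in self.samples}


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValidationError(f"a comparison pair needs two distinct assays, got {a!r} twice")
    return (a, b) if a < b else (b, a)


# --- built-in registries ---------------------------------------------------
# Quantification limits of the individual assays are not public in a citable
# form, so the default registry leaves them unset (no limit-based curation);
# configured registries may supply them.

DEFAULT_ASSAYS: tuple[Assay, ...] = (
    Assay("A", "ADVIA Centaur Insulin Assay, Siemens Healthcare", "CLIA"),
    Assay("B", "Coat-A-Count Insulin, Siemens Healthcare", "RIA"),
    Assay("C", "Immulite 1000 Insulin Assay, Siemens Healthcare", "CLIA"),
    Assay("D", "Immulite 2000 Insulin Assay, Siemens Healthcare", "CLIA"),
    Assay("E", "Immulite 2000XPi Insulin Assay, Siemens Healthcare", "CLIA"),
    Assay("F", "Insulin(e) IRMA KIT, Immunotech, Beckman Coulter", "RIA"),
    Assay("G", "Equine Insulin ELISA, Mercodia", "ELISA"),
    Assay("H", "Porcine Insulin RIA, Merck Millipore", "RIA"),
)

DEFAULT_SOURCES: tuple[DataSource, ...] = (
    DataSource("oberg2011", "Öberg et al., 2011", ((("B", "G"), 80),)),
    DataSource("tinworth2011", "Tinworth et al., 2011", ((("B", "G"), 18),)),
    DataSource("borer_weir2012", "Borer-Weir et al., 2012", ((("B", "G"), 29),)),
    DataSource("warnken2016", "Warnken et al., 2016",
               ((("A", "G"), 36), (("A", "H"), 39), (("G", "H"), 36))),
    DataSource("carslake2017", "Carslake et al., 2017", ((("B", "D"), 16),)),
    DataSource("carslake2021", "Carslake et al., 2021", ((("D", "E"), 39),)),
    DataSource("de_laat2022", "De Laat et al., 2022", ((("E", "G"), 302),),
               comment="Raw data kindly provided by Boehringer Ingelheim"),
    DataSource("durham_unpub", "Durham, unpublished", ((("C", "E"), 70),),
               comment="Diagnostic samples"),
    DataSource("fey_unpub", "Fey, unpublished", ((("A", "B"), 496),),
               comment="Diagnostic samples"),
    DataSource("warnken_delarocque_unpub", "Warnken and Delarocque, unpublished",
               ((("C", "G"), 60), (("A", "G"), 77), (("A", "C"), 60)),
               comment="Ethics committee file number 33.8-42502-04-17/2646"),
    # the two "Warnken, unpublished" table rows are one contributor (eleven
    # sources in total); the pair/count structure of both rows is preserved
    DataSource("warnken_unpub", "Warnken, unpublished",
               ((("C", "G"), 21), (("C", "F"), 21), (("F", "G"), 131), (("A", "G"), 30)),
               comment="Ethics committee file number 3.14-42502-04-13/1259; "
                       "diagnostic samples"),
)


def load_assay_registry(config=None) -> list[Assay]:
    """Load an assay registry from JSON (path or parsed list); ``None`` ->
    the built-in default of eight assays."""
    if config is None:
        return list(DEFAULT_ASSAYS)
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    assays = [a if isinstance(a, Assay) else Assay(
        id=a["id"], name=a.get("name", ""), family=a["family"],
        loq_lower=a.get("loq_lower"), loq_upper=a.get("loq_upper"),
    ) for a in config]
    ids = [a.id for a in assays]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate assay ids in registry")
    return assays


def load_source_registry(config=None, assays: list[Assay] | None = None) -> list[DataSource]:
    """Load a data-source registry; ``None`` -> the built-in default of
    eleven sources covering thirteen assay pairs."""
    if config is None:
        sources = list(DEFAULT_SOURCES)
    else:
        if isinstance(config, (str, Path)):
            config = json.loads(Path(config).read_text())
        sources = [s if isinstance(s, DataSource) else DataSource(
            source_id=s["source_id"], citation=s.get("citation", s["source_id"]),
            comparisons=tuple(
                ((c["assays"][0], c["assays"][1]), int(c["n"])) for c in s["comparisons"]),
            comment=s.get("comment", ""),
        ) for s in config]
    ids = [s.source_id for s in sources]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate source ids in registry")
    if assays is not None:
        known = {a.id for a in assays}
        for s in sources:
            for (a, b), _ in s.comparisons:
                if a not in known or b not in known:
                    raise ValidationError(
                        f"source {s.source_id!r} references unknown assay in pair ({a}, {b})")
    return sources


# --- curation / merging ----------------------------------------------------

def _limit_reason(value: float, assay: Assay, axis: str) -> str | None:
    if assay.loq_lower is not None and value < assay.loq_lower:
        return f"{axis}_below_loq"
    if assay.loq_upper is not None and value > assay.loq_upper:
        return f"{axis}_above_loq"
    return None


def curate_samples(samples: list[PairedSample], assay_x: Assay, assay_y: Assay):
    """Apply the sample retention rules.

    Samples containing exogenous insulin are dropped; samples with either
    value outside the respective assay's quantification limits are dropped;
    diluted samples whose values lie within the limits are kept.

    Returns
    -------
    (kept, report)
        ``kept`` is the retained sample list; ``report`` is a DataFrame with
        columns ``source_id, reason, count`` (empty when nothing was dropped).
    """
    kept: list[PairedSample] = []
    rejected: list[tuple[str, str]] = []
    for s in samples:
        if s.exogenous:
            rejected.append((s.source_id, "exogenous"))
            continue
        reason = _limit_reason(s.x, assay_x, "x") or _limit_reason(s.y, assay_y, "y")
        if reason:
            rejected.append((s.source_id, reason))
            continue
        kept.append(s)
    if rejected:
        report = (pd.DataFrame(rejected, columns=["source_id", "reason"])
                  .value_counts().rename("count").reset_index()
                  .sort_values(["source_id", "reason"]).reset_index(drop=True))
    else:
        report = pd.DataFrame(columns=["source_id", "reason", "count"])
    return kept, report


def merge_sources(sources: list[tuple[str, list[PairedSample]]],
                  pair: tuple[str, str]) -> ComparisonDataset:
    """Pool per-source samples for one unordered assay pair.

    ``pair`` gives each source's orientation as recorded — ``(X, Y)`` meaning
    the source's x column was measured on X.  Sources recorded against the
    reversed orientation must be swapped by the caller beforehand via the
    per-source pair; here a single orientation per call is assumed, and the
    merged dataset is normalised to canonical lexicographic pair order.
    """
    canon = canonical_pair(*pair)
    swap = pair[0] != canon[0]
    merged: list[PairedSample] = []
    for source_id, samples in sources:
        for s in samples:
            if s.source_id != source_id:
                raise ValidationError(
                    f"sample labelled {s.source_id!r} found under source {source_id!r}")
            if swap:
                s = PairedSample(source_id=s.source_id, x=s.y, y=s.x,
                                 diluted=s.diluted, exogenous=s.exogenous)
            merged.append(s)
    merged.sort(key=lambda s: (s.x, s.y, s.source_id))
    return ComparisonDataset(pair=canon, samples=merged)


def merge_oriented_sources(oriented: list[tuple[str, tuple[str, str], list[PairedSample]]]
                           ) -> ComparisonDataset:
    """Merge sources that may be recorded in either orientation of one pair.

    Each entry is ``(source_id, (assay_x, assay_y), samples)``; all entries
    must concern the same unordered pair.
    """
    pairs = {canonical_pair(*p) for _, p, _ in oriented}
    if len(pairs) != 1:
        raise ValidationError(f"cannot merge mixed assay pairs: {sorted(pairs)}")
    canon = pairs.pop()
    merged: list[PairedSample] = []
    for source_id, p, samples in oriented:
        ds = merge_sources([(source_id, samples)], p)
        merged.extend(ds.samples)
    merged.sort(key=lambda s: (s.x, s.y, s.source_id))
    return ComparisonDataset(pair=canon, samples=merged)


def validate_counts(dataset: ComparisonDataset, sources: list[DataSource],
                    strict: bool = False) -> None:
    """Compare loaded sample counts against the registry's declared counts."""
    declared = 0
    for s in sources:
        for (a, b), n in s.comparisons:
            if canonical_pair(a, b) == dataset.pair and s.source_id in dataset.source_ids:
                declared += n
    if declared and declared != dataset.n:
        msg = (f"pair {dataset.pair}: loaded {dataset.n} samples but the registry "
               f"declares {declared}")
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)


def build_pair_graph(datasets: list[ComparisonDataset],
                     sources: list[DataSource] | None = None) -> nx.Graph:
    """Undirected comparison graph: assays as nodes, one edge per pair,
    annotated with total sample count ``n`` and distinct ``n_studies``."""
    g = nx.Graph()
    for ds in datasets:
        a, b = ds.pair
        if g.has_edge(a, b):
            raise ValidationError(f"duplicate dataset for pair {ds.pair}")
        g.add_edge(a, b, n=ds.n, n_studies=len(ds.source_ids))
    return g


# --- paired-sample CSV i/o --------------------------------------------------
# columns: source_id, assay_x, assay_y, x_uIU_per_mL, y_uIU_per_mL,
#          diluted (0/1, optional), exogenous (0/1, optional)

def read_paired_csv(path) -> list[tuple[str, tuple[str, str], list[PairedSample]]]:
    """Read paired measurements, grouped by (source, oriented assay pair)."""
    df = pd.read_csv(path)
    required = {"source_id", "assay_x", "assay_y", "x_uIU_per_mL", "y_uIU_per_mL"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"paired-data file {path} is missing columns: {sorted(missing)}")
    for flag in ("diluted", "exogenous"):
        if flag not in df.columns:
            df[flag] = 0
    df[["diluted", "exogenous"]] = df[["diluted", "exogenous"]].fillna(0)
    groups = []
    for (src, ax, ay), sub in df.groupby(["source_id", "assay_x", "assay_y"], sort=True):
        samples = [
            PairedSample(source_id=str(src), x=float(r.x_uIU_per_mL), y=float(r.y_uIU_per_mL),
                         diluted=bool(r.diluted), exogenous=bool(r.exogenous))
            for r in sub.itertuples()
        ]
        groups.append((str(src), (str(ax), str(ay)), samples))
    return groups


def write_paired_csv(path, source_id: str, pair: tuple[str, str],
                     samples: list[PairedSample]) -> None:
    df = pd.DataFrame({
        "source_id": [source_id] * len(samples),
        "assay_x": [pair[0]] * len(samples),
        "assay_y": [pair[1]] * len(samples),
        "x_uIU_per_mL": [s.x for s in samples],
        "y_uIU_per_mL": [s.y for s in samples],
        "diluted": [int(s.diluted) for s in samples],
        "exogenous": [int(s.exogenous) for s in samples],
    })
    df.to_csv(path, index=False)
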