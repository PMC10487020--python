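"""End-to-end fitting pipeline: files -> curated datasets -> model store.

Glues the registry, curation and model layers together for the CLI and for
programmatic batch fitting.  Every unordered assay pair with enough curated
samples yields two directed models; underpowered or degenerate pairs are
skipped and reported, never fitted silently.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ModelStore
from .exceptions import DegenerateDataError, ValidationError
from .model import fit_conversion
from .registry import (Assay, ComparisonDataset, DataSource, canonical_pair,
                       curate_samples, merge_oriented_sources, read_paired_csv,
                       validate_counts)
from .splines import SplineSpec

__all__ = ["build_datasets", "fit_store", "fit_from_files", "outlier_flags"]

#: standardised residuals beyond this are flagged in diagnostics
OUTLIER_Z = 4.0


def build_datasets(groups, assays: list[Assay],
                   sources: list[DataSource] | None = None,
                   strict: bool = False):
    """Curate and merge grouped samples into one dataset per unordered pair.

    ``groups`` are ``(source_id, (assay_x, assay_y), samples)`` triples as
    returned by :func:`~insulinconv.registry.read_paired_csv`.

    Returns ``(datasets, curation_report)``.
    """
    amap = {a.id: a for a in assays}
    by_pair: dict[tuple[str, str], list] = defaultdict(list)
    reports = []
    for source_id, pair, samples in groups:
        for aid in pair:
            if aid not in amap:
                raise ValidationError(f"unknown assay id {aid!r} in source {source_id!r}")
        kept, report = curate_samples(samples, amap[pair[0]], amap[pair[1]])
        if not report.empty:
            reports.append(report)
        if kept:
            by_pair[canonical_pair(*pair)].append((source_id, pair, kept))
    datasets = [merge_oriented_sources(entries) for _, entries in sorted(by_pair.items())]
    if sources is not None:
        for ds in datasets:
            validate_counts(ds, sources, strict=strict)
    curation_report = (pd.concat(reports, ignore_index=True) if reports
                       else pd.DataFrame(columns=["source_id", "reason", "count"]))
    return datasets, curation_report


def outlier_flags(model, dataset: ComparisonDataset) -> int:
    """Count training samples with |standardised residual| above the threshold."""
    xs = np.array([s.x for s in dataset.samples])
    ys = np.array([s.y for s in dataset.samples])
    if model.from_assay != dataset.pair[0]:
        xs, ys = ys, xs
    if model.sigma == 0:
        return 0
    z = (ys - model.predict(xs)) / model.sigma
    return int(np.sum(np.abs(z) > OUTLIER_Z))


def fit_store(datasets: list[ComparisonDataset], spec: SplineSpec | None = None,
              strict: bool = False):
    """Fit both directed models for every dataset.

    Returns ``(store, diagnostics, skipped)``: the model store, a per-model
    diagnostics DataFrame (n, r², input range, active coefficients, outlier
    flags), and a list of ``(direction, reason)`` for pairs that could not be
    fitted.  In strict mode a failed fit raises instead of being skipped.
    """
    store = ModelStore()
    rows = []
    skipped: list[tuple[str, str]] = []
    for ds in datasets:
        for from_assay, to_assay in (ds.pair, ds.pair[::-1]):
            label = f"{from_assay}->{to_assay}"
            try:
                model = fit_conversion(ds, from_assay, to_assay, spec=spec)
            except DegenerateDataError as exc:
                if strict:
                    raise
                skipped.append((label, str(exc)))
                continue
            store.add(model)
            rows.append({
                "from_assay": from_assay, "to_assay": to_assay,
                "n": model.n_train, "r_squared": model.r_squared,
                "input_min": model.input_min, "input_cap": model.input_cap,
                "sigma": model.sigma,
                "n_active": len(model.active_idx) + (1 if model.intercept > 0 else 0),
                "n_outliers": outlier_flags(model, ds),
            })
    diagnostics = pd.DataFrame(rows)
    return store, diagnostics, skipped


def fit_from_files(data_files, assays: list[Assay],
                   sources: list[DataSource] | None = None,
                   spec: SplineSpec | None = None, strict: bool = False):
    """Read paired-sample CSV files and fit the full model store."""
    groups = []
    for f in sorted(Path(p) for p in data_files):
        groups.extend(read_paired_csv(f))
    datasets, curation_report = build_datasets(groups, assays, sources, strict=strict)
    store, diagnostics, skipped = fit_store(datasets, spec=spec, strict=strict)
    return store, datasets, diagnostics, curation_report, skipped
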