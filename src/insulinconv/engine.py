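"""User-facing conversion workflow.

A :class:`ModelStore` holds the fitted directed conversion models.  Every
conversion is gated to the model's supported input range — the spline is
never evaluated below the smallest training value or above the cap (largest
training value minus one), so no extrapolation ever happens.  Converting an
assay to itself is the identity with a zero-width interval.

Chained conversion through an intermediate assay is supported but must be
requested explicitly: because the two hops are separate regressions, the
reported interval (taken from the final hop) understates the true
uncertainty, and a warning is emitted accordingly.

Cut-off tables convert the published decision threshold itself to a common
reference assay — the recommended direction of travel, since converting each
diagnostic measurement instead would import the field's less-controlled
sources of variation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

from . import __version__
from .exceptions import (BundleError, ChainingError, PairUnavailableError,
                         RangeError, ValidationError)
from .model import ConversionModel

__all__ = [
    "ConversionResult", "CutoffRecord", "ModelStore",
    "convert", "convert_all", "convert_chained", "convert_cutoff_table",
    "export_bundle", "import_bundle", "read_cutoff_csv", "write_cutoff_csv",
    "round_sig",
]

logger = logging.getLogger(__name__)

BUNDLE_FORMAT = "insulinconv-bundle"
BUNDLE_VERSION = 1

_MODEL_FIELDS = (
    "from_assay", "to_assay", "spec", "intercept", "coefficients", "sigma",
    "dof", "active_idx", "gram_inverse", "input_min", "input_cap",
    "n_train", "r_squared",
)


@dataclass(frozen=True)
class ConversionResult:
    """One converted value: estimate, prediction interval and provenance."""

    from_assay: str
    to_assay: str
    input_value: float
    estimate: float
    pi_lower: float
    pi_upper: float
    level: float
    chained: bool = False
    hops: tuple[str, ...] = ()
    capped_range: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.pi_lower <= self.estimate <= self.pi_upper:
            raise ValidationError("interval must contain the estimate")
        if self.estimate < 0:
            raise ValidationError("estimate must be non-negative")
        if self.chained and len(self.hops) < 3:
            raise ValidationError("a chained result needs at least three hops")


@dataclass
class CutoffRecord:
    """One published basal-insulin cut-off and its converted value."""

    reference: str
    assay_id: str
    feeding: str = ""
    outcome: str = ""
    metric: str = ""
    cutoff: float = 0.0
    converted_cutoff: float | None = None
    convertible: bool | None = None
    note: str = ""

    def __post_init__(self):
        if not self.cutoff > 0:
            raise ValidationError(f"cut-off must be > 0 uIU/mL, got {self.cutoff}")


def round_sig(value: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (presentation only)."""
    if value == 0:
        return 0.0
    return round(value, digits - 1 - int(math.floor(math.log10(abs(value)))))


class ModelStore:
    """Container of fitted directed conversion models, keyed (from, to)."""

    def __init__(self, models: list[ConversionModel] | None = None):
        self._models: dict[tuple[str, str], ConversionModel] = {}
        for m in models or []:
            self.add(m)

    def add(self, model: ConversionModel) -> None:
        key = (model.from_assay, model.to_assay)
        if key[0] == key[1]:
            raise ValidationError("a conversion model cannot map an assay to itself")
        self._models[key] = model

    def get(self, from_assay: str, to_assay: str) -> ConversionModel:
        try:
            return self._models[(from_assay, to_assay)]
        except KeyError:
            raise PairUnavailableError(from_assay, to_assay) from None

    def has(self, from_assay: str, to_assay: str) -> bool:
        return (from_assay, to_assay) in self._models

    def models(self) -> list[ConversionModel]:
        return [self._models[k] for k in sorted(self._models)]

    def assays(self) -> list[str]:
        return sorted({a for k in self._models for a in k})

    def targets_from(self, from_assay: str) -> list[str]:
        return sorted({t for f, t in self._models if f == from_assay})

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self._models)
        return g

    def __len__(self) -> int:
        return len(self._models)


def _validate_value(value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"input must be a finite non-negative concentration, got {value}")
    return value


def convert(value: float, from_assay: str, to_assay: str, store: ModelStore,
            level: float = 0.95) -> ConversionResult:
    """Convert one concentration between assays, with a prediction interval.

    Self-conversion returns the value unchanged with a zero-width interval.
    Raises :class:`PairUnavailableError` when no directed model exists and
    :class:`RangeError` when the value falls outside the model's supported
    input range.
    """
    value = _validate_value(value)
    if not 0.0 < level < 1.0:
        raise ValidationError(f"interval level must be in (0, 1), got {level}")
    if from_assay == to_assay:
        return ConversionResult(from_assay, to_assay, value, value, value, value,
                                level=level)
    model = store.get(from_assay, to_assay)
    if not model.in_range(value):
        raise RangeError(value, model.input_min, model.input_cap, from_assay, to_assay)
    est, lo, hi = model.predict_with_interval(value, level=level)
    return ConversionResult(from_assay, to_assay, value, est, lo, hi, level=level,
                            capped_range=(model.input_min, model.input_cap))


def convert_all(value: float, from_assay: str, store: ModelStore,
                level: float = 0.95):
    """Fan a value out to every assay reachable by a direct model.

    Returns ``(results, unavailable)`` where ``unavailable`` maps assay ids
    to the reason no result was produced (typically the range refusal).
    """
    value = _validate_value(value)
    results: list[ConversionResult] = []
    unavailable: dict[str, str] = {}
    for target in store.targets_from(from_assay):
        try:
            results.append(convert(value, from_assay, target, store, level=level))
        except RangeError as exc:
            unavailable[target] = str(exc)
    return results, unavailable


def convert_chained(value: float, from_assay: str, to_assay: str, store: ModelStore,
                    level: float = 0.95, max_hops: int = 3) -> ConversionResult:
    """Convert through intermediate assays when no direct model exists.

    The estimate is propagated hop by hop along the shortest directed path;
    the interval reported is that of the final hop only, so it understates
    the accumulated uncertainty — the result is flagged ``chained`` and a
    warning is logged.  Refuses to run when a direct model exists.
    """
    value = _validate_value(value)
    if from_assay == to_assay:
        raise ChainingError("chained conversion between an assay and itself is meaningless")
    if store.has(from_assay, to_assay):
        raise ChainingError(
            f"a direct model {from_assay}->{to_assay} exists; use convert() instead")
    g = store.digraph()
    if from_assay not in g or to_assay not in g:
        raise ChainingError(f"no conversion path from {from_assay} to {to_assay}")
    try:
        path = nx.shortest_path(g, from_assay, to_assay)
    except nx.NetworkXNoPath:
        raise ChainingError(f"no conversion path from {from_assay} to {to_assay}") from None
    if len(path) - 1 > max_hops:
        raise ChainingError(
            f"shortest path {'->'.join(path)} exceeds max_hops={max_hops}")

    current = value
    result = None
    for a, b in zip(path[:-1], path[1:]):
        try:
            result = convert(current, a, b, store, level=level)
        except RangeError as exc:
            raise ChainingError(
                f"intermediate value {current:g} uIU/mL is out of range at hop "
                f"{a}->{b}: {exc}") from exc
        current = result.estimate
    logger.warning(
        "chained conversion %s: the reported interval reflects the final hop only "
        "and understates the accumulated uncertainty", "->".join(path))
    return replace(result, from_assay=from_assay, to_assay=to_assay,
                   input_value=value, chained=True, hops=tuple(path))


def convert_cutoff_table(records: list[CutoffRecord], reference_assay: str,
                         store: ModelStore) -> list[CutoffRecord]:
    """Convert published cut-offs to a common reference assay.

    Records already on the reference assay pass through unchanged; records
    whose assay has no direct model to the reference, or whose cut-off falls
    outside the model's range, are marked unconvertible with a note.  Order
    is preserved.
    """
    out: list[CutoffRecord] = []
    for rec in records:
        rec = replace(rec)
        try:
            res = convert(rec.cutoff, rec.assay_id, reference_assay, store)
            rec.converted_cutoff = res.estimate
            rec.convertible = True
        except (PairUnavailableError, RangeError) as exc:
            rec.converted_cutoff = None
            rec.convertible = False
            rec.note = str(exc)
        out.append(rec)
    return out


# --- bundle serialisation ----------------------------------------------------

def export_bundle(store: ModelStore, path=None, created: str | None = None) -> dict:
    """Serialise a model store to a versioned JSON bundle.

    The bundle holds the extracted formula of every model (knots,
    coefficients, residual scale, interval machinery, input range) and is
    self-contained: importing it reproduces every estimate and interval
    exactly, without the training data.
    """
    bundle = {
        "format": BUNDLE_FORMAT,
        "version": BUNDLE_VERSION,
        "created": created,
        "library_version": __version__,
        "models": [m.to_dict() for m in store.models()],
    }
    if path is not None:
        Path(path).write_text(json.dumps(bundle, indent=1, sort_keys=True) + "\n")
    return bundle


def import_bundle(source) -> ModelStore:
    """Load a model store from a bundle (path, JSON string, or parsed dict)."""
    if isinstance(source, dict):
        bundle = source
    else:
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ) else source
        bundle = json.loads(text)
    if bundle.get("format") != BUNDLE_FORMAT:
        raise BundleError(f"not a model bundle: format={bundle.get('format')!r}")
    if bundle.get("version") != BUNDLE_VERSION:
        raise BundleError(
            f"unsupported bundle version {bundle.get('version')!r}; expected {BUNDLE_VERSION}")
    if "models" not in bundle:
        raise BundleError("bundle is missing field 'models'")
    store = ModelStore()
    for i, m in enumerate(bundle["models"]):
        for f in _MODEL_FIELDS:
            if f not in m:
                raise BundleError(f"bundle model #{i} is missing field '{f}'")
        store.add(ConversionModel.from_dict(m))
    return store


# --- cut-off table CSV i/o ---------------------------------------------------

_CUTOFF_COLS = ["reference", "assay_id", "feeding", "outcome", "metric", "cutoff"]


def read_cutoff_csv(path) -> list[CutoffRecord]:
    import pandas as pd
    df = pd.read_csv(path).fillna("")
    missing = set(_CUTOFF_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"cut-off table {path} is missing columns: {sorted(missing)}")
    return [CutoffRecord(reference=str(r.reference), assay_id=str(r.assay_id),
                         feeding=str(r.feeding), outcome=str(r.outcome),
                         metric=str(r.metric), cutoff=float(r.cutoff))
            for r in df.itertuples()]


def write_cutoff_csv(records: list[CutoffRecord], path, sig_figs: int | None = None) -> None:
    import pandas as pd
    rows = []
    for r in records:
        conv = r.converted_cutoff
        if conv is not None and sig_figs:
            conv = round_sig(conv, sig_figs)
        rows.append({
            "reference": r.reference, "assay_id": r.assay_id, "feeding": r.feeding,
            "outcome": r.outcome, "metric": r.metric, "cutoff": r.cutoff,
            "converted_cutoff": "" if conv is None else conv,
            "convertible": "" if r.convertible is None else int(r.convertible),
            "note": r.note,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
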