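"""Synthetic paired-assay data with the structure the method assumes.

The real paired measurements behind the published conversion models are not
publicly deposited, so this module generates stand-in datasets for testing
and calibration experiments: monotone non-decreasing true conversion curves,
heteroscedastic measurement noise, per-source (inter-laboratory) offsets, and
a registry fixture replicating the real study layout source-by-source
(11 sources, 13 assay pairs, the declared per-source sample counts).

Inputs are drawn from a right-skewed log-normal (median ~20 uIU/mL) so most
mass sits in the diagnostically relevant range with a tail to a few hundred
uIU/mL, mirroring basal and post-challenge insulin concentrations in horses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model import MonotoneSplineRegressor
from .registry import (DEFAULT_ASSAYS, DEFAULT_SOURCES, Assay, DataSource,
                       PairedSample, canonical_pair, write_paired_csv)

__all__ = [
    "DEFAULT_SEED", "TruthSpec", "NoiseSpec",
    "generate_pair_samples", "generate_registry_fixture",
    "simulate_pi_coverage", "recovery_experiment",
]

#: default seed for every simulation in the package
DEFAULT_SEED = 20230824

_FORMS = ("identity", "affine", "power_affine", "saturating")


@dataclass(frozen=True)
class TruthSpec:
    """A true inter-assay conversion curve, monotone and non-negative.

    Forms (parameters in ``params``):

    - ``identity``:      g(x) = x
    - ``affine``:        g(x) = a + b*x                     (a >= 0, b >= 0)
    - ``power_affine``:  g(x) = a + b*x + c*sqrt(x)         (a, b, c >= 0)
    - ``saturating``:    g(x) = a + vmax * x / (km + x)     (a, vmax >= 0, km > 0)
    """

    form: str
    params: dict = field(default_factory=dict)
    support: tuple[float, float] = (1.0, 300.0)

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValidationError(f"unknown truth form {self.form!r}; expected one of {_FORMS}")
        lo, hi = self.support
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo < hi):
            raise ValidationError(f"invalid support {self.support}")
        grid = np.linspace(lo, hi, 1000)
        g = self(grid)
        if np.any(np.diff(g) < -1e-12):
            raise ValidationError("truth curve must be non-decreasing on its support")
        if np.any(g < 0):
            raise ValidationError("truth curve must be non-negative on its support")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.form == "identity":
            return x.copy()
        if self.form == "affine":
            return p.get("a", 0.0) + p.get("b", 1.0) * x
        if self.form == "power_affine":
            return p.get("a", 0.0) + p.get("b", 1.0) * x + p.get("c", 0.0) * np.sqrt(x)
        return p.get("a", 0.0) + p.get("vmax", 100.0) * x / (p.get("km", 50.0) + x)

    def to_dict(self) -> dict:
        return {"form": self.form, "params": dict(self.params), "support": list(self.support)}


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for the converted axis.

    ``sd(x) = sd0`` (constant), ``cv * g(x)`` (proportional) or
    ``sd0 + cv * g(x)`` (mixed).  ``source_offset_sd`` is the standard
    deviation of an additive per-source shift emulating inter-laboratory
    technical variation.
    """

    model: str = "constant"
    sd0: float = 10.0
    cv: float = 0.0
    source_offset_sd: float = 0.0

    def __post_init__(self):
        if self.model not in ("constant", "proportional", "mixed"):
            raise ValidationError(f"unknown noise model {self.model!r}")
        if min(self.sd0, self.cv, self.source_offset_sd) < 0:
            raise ValidationError("noise scale parameters must be >= 0")

    def sd_at(self, g_of_x):
        g = np.asarray(g_of_x, dtype=float)
        if self.model == "constant":
            return np.full_like(g, self.sd0)
        if self.model == "proportional":
            return self.cv * g
        return self.sd0 + self.cv * g

    def to_dict(self) -> dict:
        return {"model": self.model, "sd0": self.sd0, "cv": self.cv,
                "source_offset_sd": self.source_offset_sd}


#: default fixture noise regime: mixed sd(x) = 2 + 0.08 g(x), offsets sd 3
DEFAULT_FIXTURE_NOISE = NoiseSpec(model="mixed", sd0=2.0, cv=0.08, source_offset_sd=3.0)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_inputs(rng: np.random.Generator, n: int, support: tuple[float, float],
                 median: float = 20.0, log_sd: float = 0.8) -> np.ndarray:
    """Right-skewed concentrations: log-normal, clipped to the support."""
    x = rng.lognormal(mean=np.log(median), sigma=log_sd, size=n)
    return np.clip(x, support[0], support[1])


def generate_pair_samples(truth: TruthSpec, noise: NoiseSpec, n: int, seed,
                          source_id: str = "sim", offset: float = 0.0
                          ) -> list[PairedSample]:
    """Draw ``n`` paired measurements: x from the input distribution,
    ``y = truth(x) + offset + noise`` with negatives clipped to zero."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = _rng(seed)
    x = _draw_inputs(rng, n, truth.support)
    g = truth(x)
    y = g + offset + rng.normal(0.0, 1.0, size=n) * noise.sd_at(g)
    y = np.maximum(y, 0.0)
    return [PairedSample(source_id=source_id, x=float(xi), y=float(yi))
            for xi, yi in zip(x, y)]


def _random_truth(rng: np.random.Generator, support=(1.0, 300.0)) -> TruthSpec:
    form = rng.choice(["affine", "power_affine", "saturating", "identity"],
                      p=[0.35, 0.35, 0.15, 0.15])
    if form == "identity":
        return TruthSpec("identity", support=support)
    if form == "affine":
        params = {"a": float(rng.uniform(0, 5)), "b": float(rng.uniform(0.6, 1.8))}
    elif form == "power_affine":
        params = {"a": float(rng.uniform(0, 5)), "b": float(rng.uniform(0.5, 1.5)),
                  "c": float(rng.uniform(0, 4))}
    else:
        params = {"a": float(rng.uniform(0, 5)), "vmax": float(rng.uniform(150, 400)),
                  "km": float(rng.uniform(80, 200))}
    return TruthSpec(str(form), params, support=support)


def generate_registry_fixture(seed=DEFAULT_SEED, out_dir=None,
                              noise: NoiseSpec = DEFAULT_FIXTURE_NOISE):
    """Generate a full study-shaped fixture.

    Reproduces the built-in source registry structure exactly: 11 sources,
    the recorded assay pair(s) of each source with the declared sample
    counts, one shared true curve per unordered pair, and an independent
    per-(source, pair) offset.  When ``out_dir`` is given, one CSV per
    (source, pair) plus registry JSON files and a manifest are written.

    Returns ``(assays, sources, samples_by_source_pair, manifest)`` where the
    sample map is keyed ``(source_id, (assay_x, assay_y))``.
    """
    rng = np.random.default_rng(seed)
    # fixture assays: the default registry plus configured quantification limits
    assays = [Assay(a.id, a.name, a.family, loq_lower=0.5, loq_upper=1500.0)
              for a in DEFAULT_ASSAYS]
    sources: list[DataSource] = list(DEFAULT_SOURCES)

    pairs = sorted({canonical_pair(a, b) for s in sources for (a, b), _ in s.comparisons})
    truths = {pair: _random_truth(np.random.default_rng(rng.integers(2**31)))
              for pair in pairs}

    samples: dict[tuple[str, tuple[str, str]], list[PairedSample]] = {}
    manifest = {"seed": int(seed) if np.isscalar(seed) else None,
                "noise": noise.to_dict(),
                "truths": {f"{a}-{b}": truths[(a, b)].to_dict() for a, b in pairs},
                "files": []}
    for src in sources:
        for (a, b), n in src.comparisons:
            canon = canonical_pair(a, b)
            truth = truths[canon]
            offset = float(rng.normal(0.0, noise.source_offset_sd))
            sub_seed = int(rng.integers(2**31))
            drawn = generate_pair_samples(truth, noise, n, sub_seed,
                                          source_id=src.source_id, offset=offset)
            if (a, b) != canon:  # record in the source's own orientation
                drawn = [PairedSample(s.source_id, x=s.y, y=s.x,
                                      diluted=s.diluted, exogenous=s.exogenous)
                         for s in drawn]
            samples[(src.source_id, (a, b))] = drawn
            entry = {"source_id": src.source_id, "assay_x": a, "assay_y": b,
                     "n": n, "seed": sub_seed, "offset": offset}
            if out_dir is not None:
                fname = f"{src.source_id}__{a}{b}.csv"
                write_paired_csv(Path(out_dir) / fname, src.source_id, (a, b), drawn)
                entry["file"] = fname
            manifest["files"].append(entry)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "assays.json").write_text(json.dumps(
            [{"id": a.id, "name": a.name, "family": a.family,
              "loq_lower": a.loq_lower, "loq_upper": a.loq_upper} for a in assays],
            indent=1) + "\n")
        (out / "sources.json").write_text(json.dumps(
            [{"source_id": s.source_id, "citation": s.citation, "comment": s.comment,
              "comparisons": [{"assays": list(p), "n": n} for p, n in s.comparisons]}
             for s in sources], indent=1) + "\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return assays, sources, samples, manifest


def simulate_pi_coverage(truth: TruthSpec, noise: NoiseSpec, n_train: int = 200,
                         n_test: int = 2000, level: float = 0.95, reps: int = 20,
                         seed=DEFAULT_SEED):
    """Monte-Carlo check of prediction-interval coverage.

    Each replicate fits a fresh model on ``n_train`` pairs, then evaluates the
    fraction of ``n_test`` fresh observations (restricted to the model's
    admitted input range) that fall inside the level-``level`` interval.

    Returns ``(per_rep, pooled)``: the per-replicate coverage fractions and
    the pooled coverage over all admitted test points.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = _rng(seed)
    per_rep = np.empty(reps)
    covered_total = 0
    tested_total = 0
    for r in range(reps):
        train = generate_pair_samples(truth, noise, n_train, rng)
        xt = np.array([s.x for s in train])
        yt = np.array([s.y for s in train])
        reg = MonotoneSplineRegressor().fit(xt, yt)
        test = generate_pair_samples(truth, noise, n_test, rng)
        xs = np.array([s.x for s in test])
        ys = np.array([s.y for s in test])
        admit = (xs >= reg.input_min_) & (xs <= reg.input_cap_)
        est, lo, hi = reg.predict_interval(xs[admit], level=level)
        inside = (ys[admit] >= lo) & (ys[admit] <= hi)
        per_rep[r] = inside.mean()
        covered_total += int(inside.sum())
        tested_total += int(inside.size)
    return per_rep, covered_total / tested_total


def recovery_experiment(truth: TruthSpec, noise: NoiseSpec, n_grid,
                        seed=DEFAULT_SEED, reps: int = 5) -> pd.DataFrame:
    """How well the fitted curve recovers the true one as n grows.

    For each sample size, ``reps`` independent fits are evaluated against the
    truth on a fixed grid; curve RMSE is averaged across replicates.  Returns
    a DataFrame with columns ``n, rmse, r_squared`` sorted by ``n``.
    """
    n_grid = sorted(n_grid)
    if not n_grid:
        raise ValidationError("n_grid must be non-empty")
    rng = _rng(seed)
    lo, hi = truth.support
    eval_grid = np.linspace(max(lo, 5.0), min(hi, 100.0), 200)
    g = truth(eval_grid)
    rows = []
    for n in n_grid:
        rmses, r2s = [], []
        for _ in range(reps):
            train = generate_pair_samples(truth, noise, n, rng)
            x = np.array([s.x for s in train])
            y = np.array([s.y for s in train])
            reg = MonotoneSplineRegressor().fit(x, y)
            rmses.append(float(np.sqrt(np.mean((reg.predict(eval_grid) - g) ** 2))))
            r2s.append(reg.r_squared_)
        rows.append({"n": n, "rmse": float(np.mean(rmses)), "r_squared": float(np.mean(r2s))})
    return pd.DataFrame(rows).sort_values("n").reset_index(drop=True)
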