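import numpy as np
import pytest

from insulinconv.model import fit_conversion
from insulinconv.engine import ModelStore
from insulinconv.pipeline import fit_from_files
from insulinconv.registry import ComparisonDataset, PairedSample, load_assay_registry
from insulinconv.synthetic import (DEFAULT_SEED, NoiseSpec, TruthSpec,
                                   generate_pair_samples, generate_registry_fixture)


def dataset_from_truth(pair, truth, noise, n, seed, source_id="sim"):
    """Build a canonical ComparisonDataset from a synthetic truth curve."""
    samples = generate_pair_samples(truth, noise, n, seed, source_id=source_id)
    samples = sorted(samples, key=lambda s: (s.x, s.y))
    return ComparisonDataset(pair=pair, samples=samples)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The study-shaped synthetic fixture written to disk (11 sources, 13 pairs)."""
    d = tmp_path_factory.mktemp("fixture")
    assays, sources, samples, manifest = generate_registry_fixture(DEFAULT_SEED, d)
    return {"dir": d, "assays": assays, "sources": sources,
            "samples": samples, "manifest": manifest}


@pytest.fixture(scope="session")
def full_store(fixture_dir):
    """All 26 directed models fitted from the study-shaped fixture."""
    files = sorted(fixture_dir["dir"].glob("*__*.csv"))
    store, datasets, diagnostics, curation, skipped = fit_from_files(
        files, fixture_dir["assays"], fixture_dir["sources"])
    return {"store": store, "datasets": datasets, "diagnostics": diagnostics,
            "skipped": skipped}


@pytest.fixture(scope="session")
def doubling_store():
    """Two-assay store with known truth y = 2x and low noise (C <-> G)."""
    truth = TruthSpec("affine", {"a": 0.0, "b": 2.0})
    noise = NoiseSpec("constant", sd0=0.5)
    ds = dataset_from_truth(("C", "G"), truth, noise, 400, seed=11)
    store = ModelStore([fit_conversion(ds, "C", "G"), fit_conversion(ds, "G", "C")])
    return store


@pytest.fixture(scope="session")
def chain_store():
    """Identity-truth models H->G and G->C with no direct H->C model."""
    truth = TruthSpec("identity")
    noise = NoiseSpec("constant", sd0=0.5)
    ds_gh = dataset_from_truth(("G", "H"), truth, noise, 300, seed=21)
    ds_cg = dataset_from_truth(("C", "G"), truth, noise, 300, seed=22)
    return ModelStore([fit_conversion(ds_gh, "H", "G"), fit_conversion(ds_cg, "G", "C")])


@pytest.fixture(scope="session")
def default_assays():
    return load_assay_registry()
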