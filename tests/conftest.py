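"""Shared fixtures.

BLAS threading is pinned to one thread before NumPy loads so numerical
results are bit-identical regardless of the host's core count.

The expensive paired training experiments (baseline vs bias-ablated on the
synthetic benchmarks) are session-scoped: several tests assert different
properties of the same runs.
"""

import os

for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
           "NUMEXPR_NUM_THREADS", "VECLIB_MAXIMUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np  # noqa: E402
import pytest  # noqa: E402

BENCHMARK_SEEDS = (1, 2, 3, 4, 5)
DEGENERATE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def removable_benchmark():
    """Paired baseline/ablated runs on the removable-confound cohorts."""
    from histobias.benchmark import removable_confound_benchmark

    return removable_confound_benchmark(BENCHMARK_SEEDS)


@pytest.fixture(scope="session")
def degenerate_benchmark():
    """Paired runs on the single-class-glass (inseparable) cohorts."""
    from histobias.benchmark import degenerate_glass_benchmark

    return [degenerate_glass_benchmark(s) for s in DEGENERATE_SEEDS]


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by cheap structural tests."""
    from histobias.synthgen import SynthConfig, synthesize_dataset

    cfg = SynthConfig(n_patients=40, tiles_per_patient_range=(8, 12),
                      msi_prevalence=0.25, tile_px=32, seed=11,
                      project_confound=0.5, glass_class_purity=0.5)
    return synthesize_dataset(cfg)


@pytest.fixture(scope="session")
def lambda_zero_pair():
    """Baseline vs λ=0 ablated training on identical data and seed."""
    from histobias.model import NetworkSpec
    from histobias.synthgen import SynthConfig, synthesize_dataset
    from histobias.train import TrainConfig, grouped_kfold_split, train_model

    cfg = SynthConfig(n_patients=40, tiles_per_patient_range=(8, 12),
                      msi_prevalence=0.25, tile_px=32, seed=17,
                      project_confound=0.6)
    ds = synthesize_dataset(cfg)
    plan = grouped_kfold_split(ds.manifest, k=5, seed=17)
    tc = TrainConfig(network=NetworkSpec(), lam=0.0, batch_size=64, epochs=2,
                     seed=17, log_dc=False)
    base = train_model(ds.manifest, ds.images, plan, 0, tc, ablate=False)
    ablated = train_model(ds.manifest, ds.images, plan, 0, tc, ablate=True)
    return base, ablated


@pytest.fixture(scope="session")
def tissue_classifier_setup():
    """Nine-texture dataset split in two plus a classifier trained on half."""
    from histobias.preprocess import train_tissue_classifier
    from histobias.synthgen import synthesize_tissue_dataset

    images, labels = synthesize_tissue_dataset(n_per_class=50, tile_px=48,
                                               seed=5)
    rng = np.random.Generator(np.random.PCG64(5))
    order = rng.permutation(len(labels))
    half = len(order) // 2
    tr, te = order[:half], order[half:]
    clf = train_tissue_classifier(images[tr], labels[tr], epochs=30, seed=5)
    return clf, images[te], labels[te]
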