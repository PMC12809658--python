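"""Shared fixtures.

The expensive end-to-end pipeline (simulate -> centroid -> deconvolve ->
segment at the default study conditions) is run once per session for a fixed
set of seeds and shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import pearsonr

from otmsi.annotate import monoisotopic_intensities
from otmsi.deconv import DeconvolutionConfig, deconvolve_dataset
from otmsi.segment import (
    SegmentationConfig,
    kmeans_threshold_segment,
    segmentation_accuracy,
    spatial_dgmm_segment,
)
from otmsi.simulate import SimulationConfig, simulate_dataset
from otmsi.spectra import centroid_dataset

LIPIDS = ["PC(38:1)", "PA(44:0)", "PC(38:0)"]
PIPELINE_SEEDS = [101, 102, 103, 104, 105]


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def envelopes(sim_config):
    return sim_config.envelopes()


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """One full-size simulated dataset (40x40) with ground truth."""
    return simulate_dataset(sim_config, seed=11)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced 12x12 simulated dataset for fast annotation-level tests."""
    cfg = SimulationConfig(width=12, height=12)
    ds, truth = simulate_dataset(cfg, seed=5)
    return cfg, ds, truth


def run_pipeline(seed: int, cfg: SimulationConfig | None = None) -> dict:
    """Simulate, centroid, deconvolve and segment at the study conditions.

    Returns per-lipid monoisotopic/deconvolved correlations with the true ion
    counts and naive/spatially-aware segmentation accuracies.
    """
    cfg = cfg or SimulationConfig()
    ds, truth = simulate_dataset(cfg, seed=seed)
    cds = centroid_dataset(ds, height_fraction=0.2, max_width=0.4)
    envelopes = cfg.envelopes()
    images = deconvolve_dataset(
        cds, envelopes, DeconvolutionConfig(0.2, 0.5), scale="tic"
    )
    out: dict = {"seed": seed, "truth": truth, "images": images}
    seg_cfg = SegmentationConfig(k=2, r=3, beta=6.0)
    for env in envelopes:
        label = env.label
        counts = np.array(
            [truth.counts[label][y, x] for x, y, _ in cds.pixels], dtype=float
        )
        mono = monoisotopic_intensities(cds, env, match_window=0.05)
        out[f"mono_rho_{label}"] = pearsonr(counts, mono).statistic
        out[f"deconv_rho_{label}"] = pearsonr(
            truth.counts[label].ravel(), images[label].values.ravel()
        ).statistic
        naive = kmeans_threshold_segment(images[label], k=2, seed=seed)
        aware = spatial_dgmm_segment(images[label], seg_cfg, seed=seed)
        out[f"naive_acc_{label}"] = segmentation_accuracy(naive, truth.high_mask[label])
        out[f"aware_acc_{label}"] = segmentation_accuracy(aware, truth.high_mask[label])
    return out


@pytest.fixture(scope="session")
def pipeline_runs():
    """Full pipeline at default conditions over five seeds."""
    return [run_pipeline(seed) for seed in PIPELINE_SEEDS]


def mean_over_runs(runs, key: str) -> float:
    return float(np.mean([r[key] for r in runs]))
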