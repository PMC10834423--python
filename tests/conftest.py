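"""Shared fixtures: a small synthetic genome, its training set and a trained
classifier.  Session-scoped because CNN training is the expensive step."""

from __future__ import annotations

import numpy as np
import pytest

import cnnee as C


@pytest.fixture(scope="session")
def genome_fixture():
    spec = C.SyntheticGenomeSpec(
        chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000},
        n_enhancers=50,
        signal_gain=5.0,
        noise_sd=0.1,
        seed=5,
    )
    return C.make_genome_fixture(spec)


@pytest.fixture(scope="session")
def training_dataset(genome_fixture):
    fx = genome_fixture
    tx = C.transcript_peaks(fx.genes)
    pos = C.call_positive_regions(
        fx.peaks["ATAC"], fx.peaks["H3K27ac"], fx.peaks["H3K4me3"], tx
    )
    neg = C.sample_negatives(pos, fx.chrom_sizes, seed=5)
    return C.make_dataset(pos, neg, fx.tracks, fx.chrom_sizes), pos, neg


@pytest.fixture(scope="session")
def trained_model(training_dataset):
    dataset, _, _ = training_dataset
    model = C.build_model(C.ModelSpec.from_catalogue(6), init_seed=1)
    C.train(model, dataset, C.TrainConfig(epochs=5, seed=1))
    return model


@pytest.fixture(scope="session")
def expression_fixture():
    ids = [f"eRNA{i:05d}" for i in range(200)]
    spec = C.SyntheticExpressionSpec(
        tissues={f"t{i:02d}": 4 for i in range(15)},
        n_ernas=200,
        planted_specific={"t00": {ids[0], ids[1], ids[2]},
                          "t01": {ids[3], ids[4]},
                          "t02": {ids[5]}},
        planted_housekeeping=set(ids[6:12]),
        specific_fold=6.0,
        seed=7,
    )
    return C.make_expression_fixture(spec)


def classify_with_truth_libs(fx):
    """TMM + RPM + classification using the fixture's true library sizes."""
    libs = fx.truth["library_sizes"].to_numpy(float)
    factors = C.tmm_factors(fx.counts, library_sizes=libs)
    expr = C.rpm_normalize(fx.counts, factors, fx.tissue_labels,
                           library_sizes=libs)
    return expr, C.classify_ernas(expr)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
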