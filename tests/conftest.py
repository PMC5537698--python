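"""Shared fixtures: brute-force interval oracles and synthetic studies."""

from __future__ import annotations

import pytest

from mirnome.intervals import GenomicInterval
from mirnome.synthetic_data import (
    make_ct,
    make_expression,
    make_genome_and_annotation,
    make_overexpression,
    make_scna_events,
    make_scna_profiles,
)


def bases(iv: GenomicInterval) -> set[tuple[str, int]]:
    """Per-base oracle: the set of (chrom, position) covered by an interval."""
    return {(iv.chrom, p) for p in range(iv.start, iv.end + 1)}


def random_interval(rng, max_coord: int = 10_000, chroms=("chrA", "chrB")) -> GenomicInterval:
    start = int(rng.integers(1, max_coord))
    end = start + int(rng.integers(0, 200))
    return GenomicInterval(chroms[int(rng.integers(0, len(chroms)))], start, end)


class ZeroNoiseStudy:
    """A complete synthetic study generated with every noise term at zero."""

    def __init__(self, seed: int = 11):
        self.truth = make_genome_and_annotation(
            n_chroms=4, n_genes=60, n_mirnas=40, frac_intragenic=0.5, seed=seed
        )
        make_scna_events(self.truth, n_events=12)
        self.segments = make_scna_profiles(
            self.truth, n_samples=100, carrier_frac=0.3, noise_sd=0.0
        )
        self.expression = make_expression(
            self.truth, n_tumour=72, n_control=16, coupling=2.0, noise_sd=0.0
        )
        self.ct = make_ct(self.truth, n_tumour=50, n_control=16,
                          carrier_frac=1.0, sd_ct=0.0)
        (self.de48, self.de72, self.predictions,
         self.gbm_stats) = make_overexpression(self.truth, noise_sd=0.0)


@pytest.fixture(scope="session")
def zero_noise_study() -> ZeroNoiseStudy:
    return ZeroNoiseStudy()


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A small synthetic study written to disk for I/O and CLI tests."""
    from mirnome.synthetic_data import simulate_study

    outdir = tmp_path_factory.mktemp("study")
    paths = simulate_study(outdir, seed=3, n_samples=40)
    return paths
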