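"""Canonical benchmark constructions used by the validation suite.

Each function builds one study condition end to end — proteome, target-
decoy database, spectra, ground truth — so that the same conditions are
reproducible from a single seed. Problem sizes are chosen to exercise the
statistics at desk scale: 50-500 spectra against a 50-protein proteome
(plus equal-size decoy database).
"""

from __future__ import annotations

import math

import numpy as np

from .core_io import Config, DeconvSpectrum, GroundTruth, PrecursorFeature, Protein
from .demultiplex import run_pipeline
from .pseudo_multiplex import (
    IdentifiedSpectrum,
    SpectrumPair,
    is_nonmultiplexed,
    make_rpms_datasets,
    pair_rpms,
)
from .search_engine import build_decoy_db
from .synthetic_data import SimParams, gen_benchmark

PROTON = 1.00728


def _with_decoys(proteome: list[Protein], seed: int) -> list[Protein]:
    return proteome + build_decoy_db(proteome, seed)


def perfect_info_benchmark(n_spectra: int = 50, seed: int = 42):
    """Noise-free, error-free, full-coverage HetM spectra."""
    params = SimParams(coverage=1.0, mass_error_ppm=0.0, n_noise=0, seed=seed)
    cfg = Config(seed=seed)
    proteome, spectra, truths = gen_benchmark(params, n_spectra, {"normal": 1.0}, cfg)
    return _with_decoys(proteome, seed), spectra, truths, cfg


def swapped_benchmark(n_spectra: int = 200, seed: int = 42):
    """Swapped-intensity HetM spectra (coverage 0.8, 5 noise masses): the
    intensity order contradicts the fragment evidence on every spectrum."""
    params = SimParams(coverage=0.8, n_noise=5, seed=seed)
    cfg = Config(seed=seed)
    proteome, spectra, truths = gen_benchmark(
        params, n_spectra, {"swapped-intensity": 1.0}, cfg
    )
    return _with_decoys(proteome, seed), spectra, truths, cfg


def normal_benchmark(n_spectra: int = 200, seed: int = 7):
    """Normal HetM spectra, both proteoforms at coverage 0.8."""
    params = SimParams(coverage=0.8, n_noise=5, seed=seed)
    cfg = Config(seed=seed)
    proteome, spectra, truths = gen_benchmark(params, n_spectra, {"normal": 1.0}, cfg)
    return _with_decoys(proteome, seed), spectra, truths, cfg


def mixed_benchmark(n_spectra: int = 150, seed: int = 42):
    """Half normal, half swapped-intensity; the delta/gamma sweep condition."""
    params = SimParams(coverage=0.8, n_noise=5, seed=seed)
    cfg = Config(seed=seed)
    proteome, spectra, truths = gen_benchmark(
        params, n_spectra, {"normal": 0.5, "swapped-intensity": 0.5}, cfg
    )
    return _with_decoys(proteome, seed), spectra, truths, cfg


def noise_benchmark(n_spectra: int = 500, n_frag: int = 30, seed: int = 5):
    """All-noise spectra against a 50-target + 50-decoy database; no true
    identification is possible, so every hit is a false positive."""
    params = SimParams(seed=seed)
    proteome = gen_benchmark(params, 0)[0]
    db = _with_decoys(proteome, seed)
    cfg = Config(seed=seed)
    rng = np.random.default_rng(seed)
    spectra = []
    for i in range(n_spectra):
        masses = np.sort(rng.uniform(200.0, 6000.0, size=n_frag))
        mass = float(rng.uniform(3500.0, 6500.0))
        charge = max(1, round(mass / 900.0))
        prec = PrecursorFeature(
            feature_id=i + 1,
            neutral_mass=mass,
            charge=charge,
            avg_mz=mass / charge + PROTON,
            intensity=1000.0,
            rank=1,
        )
        spectra.append(
            DeconvSpectrum(
                spectrum_id=f"NOISE_{i + 1:04d}",
                iso_lo=prec.avg_mz - 2.0,
                iso_hi=prec.avg_mz + 2.0,
                precursors=(prec,),
                frag_masses=tuple(masses.tolist()),
                frag_intensities=tuple([100.0] * n_frag),
            )
        )
    return db, spectra, cfg


def rpms_series(
    n_singles: int = 120,
    n_pairs: int = 25,
    seed: int = 12,
) -> tuple[dict[float, list[tuple[DeconvSpectrum, GroundTruth]]], list[Protein], Config]:
    """Identified single-proteoform spectra paired into an 11-ratio RPMS
    series.

    Two coverage cohorts are simulated — sparse spectra that can serve as
    bases and dense spectra rich enough to donate fragments — and pairs
    are additionally required to keep round(2 x n_base) additive
    fragments available, so no ratio in the series needs clamping.
    """
    cfg = Config(seed=seed)
    sparse = SimParams(coverage=0.35, n_noise=5, seed=seed)
    dense = SimParams(coverage=0.9, n_noise=5, seed=seed + 1)
    proteome, spectra_lo, _ = gen_benchmark(sparse, n_singles // 2, {"single": 1.0})
    _, spectra_hi, _ = gen_benchmark(dense, n_singles // 2, {"single": 1.0})
    spectra_hi = [
        DeconvSpectrum(
            spectrum_id="HI_" + s.spectrum_id,
            iso_lo=s.iso_lo,
            iso_hi=s.iso_hi,
            precursors=s.precursors,
            frag_masses=s.frag_masses,
            frag_intensities=s.frag_intensities,
        )
        for s in spectra_hi
    ]
    singles = spectra_lo + spectra_hi
    db = _with_decoys(proteome, seed)
    ids = run_pipeline(singles, db, cfg)
    by_id = {s.spectrum_id: s for s in singles}
    identified = [
        IdentifiedSpectrum(by_id[p.spectrum_id], p)
        for p in ids.prsms
        if is_nonmultiplexed(by_id[p.spectrum_id])
    ]
    pairs = pair_rpms(identified, cfg, db, max_pairs_per_base=1)
    pairs = [
        p
        for p in pairs
        if len(p.additive.spectrum.frag_masses)
        >= round(2.0 * len(p.base.spectrum.frag_masses))
    ][:n_pairs]
    datasets = make_rpms_datasets(pairs, seed=seed)
    return datasets, db, cfg


def binomial_se(p_hat: float, n: int) -> float:
    """Standard error of a rate, floored at the minimal detectable rate 1/n."""
    p = max(p_hat, 1.0 / n)
    return math.sqrt(p * (1.0 - p) / n)
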