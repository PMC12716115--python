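import numpy as np
import pytest

from topdemux.core_io import Config, DeconvSpectrum, PrecursorFeature, Protein
from topdemux.search_engine import build_decoy_db, theoretical_prefix_masses
from topdemux.synthetic_data import SimParams, gen_proteome


@pytest.fixture(scope="session")
def cfg() -> Config:
    return Config()


@pytest.fixture(scope="session")
def small_proteome() -> list[Protein]:
    return gen_proteome(SimParams(n_proteins=10, seed=1))


@pytest.fixture(scope="session")
def target_decoy_db(small_proteome) -> list[Protein]:
    return small_proteome + build_decoy_db(small_proteome, seed=1)


def make_precursor(
    neutral_mass: float,
    intensity: float = 1000.0,
    rank: int = 1,
    feature_id: int = 1,
    charge: int | None = None,
) -> PrecursorFeature:
    if charge is None:
        charge = max(1, round(neutral_mass / 900.0))
    return PrecursorFeature(
        feature_id=feature_id,
        neutral_mass=neutral_mass,
        charge=charge,
        avg_mz=neutral_mass / charge + 1.00728,
        intensity=intensity,
        rank=rank,
    )


def make_spectrum(
    frag_masses,
    precursors,
    spectrum_id: str = "S1",
) -> DeconvSpectrum:
    masses = tuple(sorted(frag_masses))
    mzs = [p.avg_mz for p in precursors]
    return DeconvSpectrum(
        spectrum_id=spectrum_id,
        iso_lo=min(mzs) - 2.0,
        iso_hi=max(mzs) + 2.0,
        precursors=tuple(precursors),
        frag_masses=masses,
        frag_intensities=tuple(100.0 for _ in masses),
    )


def exact_by_ions(sequence: str, shift: float = 0.0, split: int = 0) -> np.ndarray:
    """All 2(L-1) theoretical b/y masses of a proteoform, optionally with one
    shift localized after ``split`` (prefixes >= split shifted)."""
    form = theoretical_prefix_masses(sequence)
    p = form.prefix_masses
    total = form.proteoform_mass + shift
    prefixes = np.concatenate([p[:split], p[split:] + shift])
    return np.concatenate([prefixes, total - prefixes])
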