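"""Ground-truthed simulator of proteomes and multiplexed deconvoluted spectra.

The generator emulates the statistical structure of heterogeneous
multiplexed (HetM) top-down DDA spectra after deconvolution: two
co-isolated proteoforms from different proteins, partial b/y fragment
coverage, ppm-scale Gaussian mass error, uniform noise masses, and
optionally one unknown mass shift per proteoform. Intensities are
attached to precursors directly (isolation-window precursor intensities);
MS1 feature peaks can be emitted separately for exercising the
isolation-window intensity computation.

Scenarios
---------
``normal``
    The higher-intensity proteoform contributes at least as many
    fragments as the lower-intensity one.
``swapped-intensity``
    The precursor intensity order contradicts the fragment evidence: the
    lower-intensity proteoform contributes at least twice (here, about
    three times) the fragments of the higher-intensity one, and the pair
    is chosen so the spurious shifted match of the dominant fragments to
    the top precursor falls inside the search shift window. This induces
    precursor selection errors under a naive intensity-first search.
``single``
    One proteoform, one precursor (source material for the
    pseudo-multiplexed benchmark builders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    Config,
    DeconvSpectrum,
    GroundTruth,
    PrecursorFeature,
    Protein,
    write_fasta,
    write_spectra,
    write_truth_tsv,
)
from .search_engine import theoretical_prefix_masses

logger = logging.getLogger(__name__)

PROTON = 1.00728

#: m/z the simulated charge assignment aims precursors at; co-isolated
#: species share an isolation window, so simulated features cluster here.
TARGET_MZ = 900.0

NORMAL = "normal"
SWAPPED = "swapped-intensity"
SINGLE_FORM = "single"


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions.

    coverage : probability each theoretical b/y ion is observed.
    mass_error_ppm : standard deviation of the relative fragment mass error.
    n_noise : uniform noise masses added per spectrum.
    shift_prob : probability a proteoform carries one unknown mass shift.
    shift_range_da : interval the true shifts are drawn from; kept inside
        the default search window (-50..200 Da).
    intensity_ratio_range : I2/I1 range for the second precursor.
    """

    n_proteins: int = 50
    len_range: tuple[int, int] = (30, 60)
    coverage: float = 0.8
    mass_error_ppm: float = 5.0
    n_noise: int = 5
    shift_prob: float = 0.3
    shift_range_da: tuple[float, float] = (10.0, 150.0)
    intensity_ratio_range: tuple[float, float] = (0.3, 0.9)
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if not 0.0 <= self.shift_prob <= 1.0:
            raise ValueError("shift_prob must lie in [0, 1]")
        if self.len_range[0] < 10:
            raise ValueError("minimum protein length is 10 residues")
        lo, hi = self.intensity_ratio_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("intensity_ratio_range must lie within (0, 1]")


def gen_proteome(params: SimParams) -> list[Protein]:
    """Random proteome: i.i.d. uniform residues, lengths uniform in range."""
    rng = np.random.default_rng(params.seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteins = []
    lo, hi = params.len_range
    for i in range(params.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        proteins.append(Protein(f"SYN_{i + 1:04d}", seq))
    return proteins


@dataclass
class _Proteoform:
    protein: Protein
    shift_da: float
    split: int
    observed_masses: np.ndarray  # true (unperturbed) observed fragment masses
    neutral_mass: float  # proteoform mass incl. shift


def _draw_proteoform(protein: Protein, params: SimParams, rng: np.random.Generator) -> _Proteoform:
    form = theoretical_prefix_masses(protein.sequence, protein.accession)
    p = form.prefix_masses
    shift = 0.0
    split = 0
    if rng.random() < params.shift_prob:
        shift = float(rng.uniform(*params.shift_range_da))
        split = int(rng.integers(0, len(p) + 1))
    total = form.proteoform_mass + shift
    prefixes = np.concatenate([p[:split], p[split:] + shift])
    suffixes = total - prefixes
    theo = np.concatenate([prefixes, suffixes])
    observed = theo[rng.random(len(theo)) < params.coverage]
    return _Proteoform(protein, shift, split, observed, total)


def _charge_for(mass: float, rng: np.random.Generator) -> int:
    return max(1, int(round(mass / TARGET_MZ + rng.uniform(-0.5, 0.5))))


def _assemble_spectrum(
    spectrum_id: str,
    forms: list[tuple[_Proteoform, float]],  # (proteoform, intensity)
    params: SimParams,
    rng: np.random.Generator,
    feature_id_start: int,
) -> tuple[DeconvSpectrum, GroundTruth]:
    masses: list[float] = []
    origins: list[int] = []  # 0 = first proteoform, 1 = second, -1 = noise
    for k, (pf, _) in enumerate(forms):
        err = rng.normal(0.0, params.mass_error_ppm * 1e-6, size=len(pf.observed_masses))
        masses.extend((pf.observed_masses * (1.0 + err)).tolist())
        origins.extend([k] * len(pf.observed_masses))
    max_mass = max(pf.neutral_mass for pf, _ in forms)
    for _ in range(params.n_noise):
        masses.append(float(rng.uniform(200.0, 0.95 * max_mass)))
        origins.append(-1)

    order = np.argsort(masses)
    sorted_masses: list[float] = []
    sorted_origins: list[int] = []
    for idx in order:
        m = float(masses[idx])
        if sorted_masses and m <= sorted_masses[-1]:
            continue  # drop exact duplicates to keep strict monotonicity
        sorted_masses.append(m)
        sorted_origins.append(origins[idx])

    precursors = []
    for k, (pf, intensity) in enumerate(forms):
        charge = _charge_for(pf.neutral_mass, rng)
        avg_mz = pf.neutral_mass / charge + PROTON
        precursors.append(
            PrecursorFeature(
                feature_id=feature_id_start + k,
                neutral_mass=pf.neutral_mass,
                charge=charge,
                avg_mz=avg_mz,
                intensity=intensity,
                rank=k + 1,
            )
        )
    center = [p.avg_mz for p in precursors]
    iso_lo, iso_hi = min(center) - 2.0, max(center) + 2.0

    base_ids = frozenset(i for i, o in enumerate(sorted_origins) if o == 0)
    add_ids = frozenset(i for i, o in enumerate(sorted_origins) if o == 1)
    truth = GroundTruth(
        spectrum_id=spectrum_id,
        base_accession=forms[0][0].protein.accession,
        additive_accession=forms[1][0].protein.accession if len(forms) > 1 else "",
        base_shift_da=forms[0][0].shift_da,
        additive_shift_da=forms[1][0].shift_da if len(forms) > 1 else 0.0,
        base_frag_ids=base_ids,
        additive_frag_ids=add_ids,
    )
    spec = DeconvSpectrum(
        spectrum_id=spectrum_id,
        iso_lo=iso_lo,
        iso_hi=iso_hi,
        precursors=tuple(precursors),
        frag_masses=tuple(sorted_masses),
        frag_intensities=tuple(round(float(v), 2) for v in rng.uniform(10.0, 1000.0, size=len(sorted_masses))),
    )
    return spec, truth


def gen_spectrum(
    protein_a: Protein,
    protein_b: Protein | None,
    params: SimParams,
    scenario: str = NORMAL,
    rng: np.random.Generator | None = None,
    spectrum_id: str = "SYN_SP_0001",
    feature_id_start: int = 1,
) -> tuple[DeconvSpectrum, GroundTruth]:
    """Simulate one deconvoluted spectrum with ground truth.

    ``protein_a`` owns the higher-intensity precursor. In the
    swapped-intensity scenario its observed fragments are subsampled to a
    third of ``protein_b``'s (minimum 5), so the fragment evidence
    contradicts the intensity order.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pf_a = _draw_proteoform(protein_a, params, rng)
    forms: list[tuple[_Proteoform, float]]
    i1 = float(rng.uniform(500.0, 1000.0))
    if protein_b is None:
        forms = [(pf_a, i1)]
    else:
        pf_b = _draw_proteoform(protein_b, params, rng)
        if scenario == SWAPPED:
            n_keep = min(len(pf_a.observed_masses), max(5, len(pf_b.observed_masses) // 3))
            keep = rng.choice(len(pf_a.observed_masses), size=n_keep, replace=False)
            pf_a.observed_masses = pf_a.observed_masses[np.sort(keep)]
        elif len(pf_b.observed_masses) > len(pf_a.observed_masses):
            # the higher-intensity precursor goes with the proteoform that
            # contributes at least as many fragments; swap roles, keeping
            # both coverages intact
            pf_a, pf_b = pf_b, pf_a
        i2 = i1 * float(rng.uniform(*params.intensity_ratio_range))
        forms = [(pf_a, i1), (pf_b, i2)]
    return _assemble_spectrum(spectrum_id, forms, params, rng, feature_id_start)


def _pick_pair_swapped(
    proteome: Sequence[Protein],
    params: SimParams,
    rng: np.random.Generator,
    cfg: Config,
    max_tries: int = 500,
) -> tuple[Protein, Protein, float]:
    """Pick (a, b, shift_a) so that mass(a)+shift_a - mass(b) lies inside
    the search shift window; otherwise the dominant proteoform's fragments
    could never be mis-assigned to the top precursor at all."""
    masses = {p.accession: theoretical_prefix_masses(p.sequence).proteoform_mass for p in proteome}
    margin = 5.0
    for _ in range(max_tries):
        a, b = rng.choice(len(proteome), size=2, replace=False)
        pa, pb = proteome[a], proteome[b]
        shift = 0.0
        if rng.random() < params.shift_prob:
            shift = float(rng.uniform(*params.shift_range_da))
        diff = masses[pa.accession] + shift - masses[pb.accession]
        if cfg.shift_min_da + margin <= diff <= cfg.shift_max_da - margin and abs(diff) > cfg.zero_shift_tol_da:
            return pa, pb, shift
    logger.warning("swapped-intensity pair sampling exhausted %d tries", max_tries)
    a, b = rng.choice(len(proteome), size=2, replace=False)
    return proteome[a], proteome[b], 0.0


def gen_benchmark(
    params: SimParams,
    n_spectra: int,
    scenario_mix: dict[str, float] | None = None,
    cfg: Config | None = None,
) -> tuple[list[Protein], list[DeconvSpectrum], list[GroundTruth]]:
    """Generate a proteome plus a ground-truthed spectrum collection.

    ``scenario_mix`` maps scenario name to sampling weight (default all
    ``normal``). Deterministic for fixed params.
    """
    if scenario_mix is None:
        scenario_mix = {NORMAL: 1.0}
    if cfg is None:
        cfg = Config()
    proteome = gen_proteome(params)
    rng = np.random.default_rng(params.seed + 1)
    names = sorted(scenario_mix)
    weights = np.array([scenario_mix[n] for n in names], dtype=float)
    weights /= weights.sum()

    spectra: list[DeconvSpectrum] = []
    truths: list[GroundTruth] = []
    n_real = {n: 0 for n in names}
    feature_id = 1
    for i in range(n_spectra):
        scenario = str(rng.choice(names, p=weights))
        n_real[scenario] += 1
        sid = f"SYN_SP_{i + 1:04d}"
        if scenario == SINGLE_FORM:
            a = proteome[int(rng.integers(len(proteome)))]
            spec, truth = gen_spectrum(
                a, None, params, SINGLE_FORM, rng, sid, feature_id
            )
        elif scenario == SWAPPED:
            pa, pb, shift = _pick_pair_swapped(proteome, params, rng, cfg)
            spec, truth = _gen_swapped_with_shift(pa, pb, shift, params, rng, sid, feature_id)
        else:
            ia, ib = rng.choice(len(proteome), size=2, replace=False)
            spec, truth = gen_spectrum(
                proteome[ia], proteome[ib], params, NORMAL, rng, sid, feature_id
            )
        spectra.append(spec)
        truths.append(truth)
        feature_id += len(spec.precursors)
    logger.info("generated %d spectra (%s)", n_spectra, n_real)
    return proteome, spectra, truths


def _gen_swapped_with_shift(
    protein_a: Protein,
    protein_b: Protein,
    shift_a: float,
    params: SimParams,
    rng: np.random.Generator,
    spectrum_id: str,
    feature_id_start: int,
) -> tuple[DeconvSpectrum, GroundTruth]:
    """Swapped-intensity spectrum with a's shift fixed by the pair sampler."""
    form_a = theoretical_prefix_masses(protein_a.sequence, protein_a.accession)
    split = int(rng.integers(0, len(form_a.prefix_masses) + 1)) if shift_a else 0
    p = form_a.prefix_masses
    total_a = form_a.proteoform_mass + shift_a
    prefixes = np.concatenate([p[:split], p[split:] + shift_a])
    theo_a = np.concatenate([prefixes, total_a - prefixes])
    obs_a = theo_a[rng.random(len(theo_a)) < params.coverage]
    pf_a = _Proteoform(protein_a, shift_a, split, obs_a, total_a)

    pf_b = _draw_proteoform(protein_b, params, rng)
    n_keep = min(len(pf_a.observed_masses), max(5, len(pf_b.observed_masses) // 3))
    keep = rng.choice(len(pf_a.observed_masses), size=n_keep, replace=False)
    pf_a.observed_masses = pf_a.observed_masses[np.sort(keep)]

    i1 = float(rng.uniform(500.0, 1000.0))
    i2 = i1 * float(rng.uniform(*params.intensity_ratio_range))
    return _assemble_spectrum(
        spectrum_id, [(pf_a, i1), (pf_b, i2)], params, rng, feature_id_start
    )


def ms1_feature_peaks(
    precursor: PrecursorFeature, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Emit 3 MS1 peaks per feature spread +-1 m/z around its average m/z,
    splitting the feature's isolation-window intensity across them."""
    shares = rng.dirichlet([2.0, 2.0, 2.0])
    offsets = (-1.0, 0.0, 1.0)
    return [
        (precursor.avg_mz + off, float(precursor.intensity * s))
        for off, s in zip(offsets, shares)
    ]


def write_benchmark(
    proteome: Sequence[Protein],
    spectra: Sequence[DeconvSpectrum],
    truths: Sequence[GroundTruth],
    outdir: str | Path,
    prefix: str = "benchmark",
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "spectra": outdir / f"{prefix}.spec.txt",
        "truth": outdir / f"{prefix}.truth.tsv",
    }
    write_fasta(proteome, paths["fasta"])
    write_spectra(spectra, paths["spectra"])
    write_truth_tsv(truths, paths["truth"])
    return paths
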