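"""Deconvoluted-mass database search with zero or one unknown mass shift.

This is a deliberately small search engine for precursor-fragment paired
spectra (PFPS): each candidate proteoform is a database sequence carrying
either no mass shift (precursor mass agrees with the unmodified protein
within an isotope-absorbing window) or exactly one unknown shift equal to
the precursor-vs-protein mass difference, localized at the split position
that maximizes the number of matched fragment masses. Fragments follow the
b/y model of HCD spectra: N-terminal prefix masses and their precursor
complements. Scoring is by matched-fragment count; significance comes from
a binomial null in which each theoretical mass matches a random spectrum
fragment with probability proportional to the tolerance window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pyteomics import mass as _pmass
from scipy import stats

from .core_io import DECOY_PREFIX, Config, PrecursorFeature, Protein, PrSM

logger = logging.getLogger(__name__)

WATER_MONO = 18.010565

#: Monoisotopic residue masses for the 20 standard amino acids.
AA_MASS = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

EVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class TheoreticalForm:
    """Theoretical fragment masses of one database sequence.

    ``prefix_masses[i]`` is the neutral b-ion mass of the first ``i+1``
    residues; suffix (y-ion) masses are precursor complements and are
    derived on the fly during matching.
    """

    accession: str
    prefix_masses: np.ndarray
    proteoform_mass: float

    @property
    def n_theoretical(self) -> int:
        return 2 * len(self.prefix_masses)


def theoretical_prefix_masses(sequence: str, accession: str = "") -> TheoreticalForm:
    """Compute prefix (b-type) masses and the unmodified proteoform mass."""
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues (1 cleavage site)")
    residues = np.array([AA_MASS[aa] for aa in sequence])
    prefixes = np.cumsum(residues)[:-1]
    return TheoreticalForm(
        accession=accession,
        prefix_masses=prefixes,
        proteoform_mass=float(residues.sum() + WATER_MONO),
    )


def build_forms(db: Sequence[Protein]) -> dict[str, TheoreticalForm]:
    return {p.accession: theoretical_prefix_masses(p.sequence, p.accession) for p in db}


def _matched_mask(frags: np.ndarray, theo: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Boolean mask over ``frags`` marking masses within tol of any theoretical."""
    mask = np.zeros(len(frags), dtype=bool)
    if len(frags) == 0 or len(theo) == 0:
        return mask
    rel = tol_ppm * 1e-6
    lo = np.searchsorted(frags, theo * (1.0 - rel), side="left")
    hi = np.searchsorted(frags, theo * (1.0 + rel), side="right")
    for a, b in zip(lo, hi):
        if b > a:
            mask[a:b] = True
    return mask


def match_zero_shift(
    frag_masses: Sequence[float],
    form: TheoreticalForm,
    precursor_mass: float,
    tol_ppm: float,
) -> frozenset[float]:
    """Matched experimental masses against unshifted prefix/suffix ions.

    Suffix masses are precursor complements ``precursor_mass - prefix``,
    so an off-by-isotope precursor propagates into suffixes, which the
    ppm tolerance handles for the small masses tested here and the
    zero-shift precursor window bounds in general.
    """
    frags = np.asarray(frag_masses, dtype=float)
    theo = np.concatenate([form.prefix_masses, precursor_mass - form.prefix_masses])
    mask = _matched_mask(frags, theo, tol_ppm)
    return frozenset(frags[mask].tolist())


def match_one_shift(
    frag_masses: Sequence[float],
    form: TheoreticalForm,
    shift_da: float,
    tol_ppm: float,
) -> tuple[frozenset[float], int]:
    """Best single-shift match over all split positions.

    The shift is localized after split ``i`` in ``0..L-1``: prefixes with
    index < i are unshifted, prefixes with index >= i carry the shift;
    suffixes mirror (the complement of an unshifted prefix contains the
    shift and vice versa). The shifted precursor mass is
    ``proteoform_mass + shift_da``. Returns the matched experimental mass
    set of the best split and the split index (smallest index on ties).
    """
    frags = np.asarray(frag_masses, dtype=float)
    p = form.prefix_masses
    n_sites = len(p)
    shifted_precursor = form.proteoform_mass + shift_da
    best_set: frozenset[float] = frozenset()
    best_count = -1
    best_split = 0
    for i in range(n_sites + 1):
        prefixes = np.concatenate([p[:i], p[i:] + shift_da])
        suffixes = np.concatenate(
            [shifted_precursor - p[:i], form.proteoform_mass - p[i:]]
        )
        mask = _matched_mask(frags, np.concatenate([prefixes, suffixes]), tol_ppm)
        count = int(mask.sum())
        if count > best_count:
            best_count = count
            best_set = frozenset(frags[mask].tolist())
            best_split = i
    return best_set, best_split


def evalue(
    x: int,
    n_frag: int,
    n_theo: int,
    tol_da_mean: float,
    mass_range: float,
    n_candidates: int,
) -> float:
    """Binomial-null E-value for a match of ``x`` fragments.

    Null model: each of ``n_theo`` theoretical masses independently hits a
    random spectrum mass with probability
    ``p = min(1, n_frag * 2 * tol_da_mean / mass_range)``; the E-value is
    ``n_candidates * P[Binomial(n_theo, p) >= x]``, floored at 1e-300.
    """
    if mass_range <= 0:
        raise ValueError("mass_range must be positive")
    if x > n_theo:
        logger.info("evalue: x=%d exceeds n_theo=%d; clamping", x, n_theo)
        x = n_theo
    p = min(1.0, n_frag * 2.0 * tol_da_mean / mass_range)
    tail = float(stats.binom.sf(x - 1, n_theo, p))  # P[X >= x]
    return max(n_candidates * tail, EVALUE_FLOOR)


def _candidate_evalue(
    x: int, n_frag: int, form: TheoreticalForm, tol_ppm: float, n_candidates: int
) -> float:
    tol_da_mean = tol_ppm * 1e-6 * form.proteoform_mass / 2.0
    return evalue(x, n_frag, form.n_theoretical, tol_da_mean, form.proteoform_mass, n_candidates)


def search_pfps(
    precursor: PrecursorFeature,
    frag_masses: Sequence[float],
    db: Sequence[Protein],
    cfg: Config,
    forms: dict[str, TheoreticalForm] | None = None,
) -> PrSM | None:
    """Search one PFPS against the database; return the best PrSM or None.

    A database sequence is tried with zero shifts when its unmodified mass
    agrees with the precursor within ``cfg.zero_shift_tol_da``, otherwise
    with one unknown shift equal to the mass difference when that lies in
    ``[shift_min_da, shift_max_da]``; other sequences cannot explain the
    precursor and are skipped. The best candidate maximizes matched count,
    with ties broken by fewer shifts, lower E-value, then accession; a
    match below ``cfg.min_match`` fragments is not reported.
    """
    if not db:
        return None
    if forms is None:
        forms = build_forms(db)
    n_frag = len(frag_masses)
    n_candidates = len(db)
    best: tuple | None = None  # (-x, y, evalue, accession, M, shift)
    for protein in db:
        form = forms[protein.accession]
        diff = precursor.neutral_mass - form.proteoform_mass
        if abs(diff) <= cfg.zero_shift_tol_da:
            matched = match_zero_shift(
                frag_masses, form, precursor.neutral_mass, cfg.frag_tol_ppm
            )
            y, shift = 0, 0.0
        elif cfg.shift_min_da <= diff <= cfg.shift_max_da:
            matched, _ = match_one_shift(frag_masses, form, diff, cfg.frag_tol_ppm)
            y, shift = 1, diff
        else:
            continue
        x = len(matched)
        if x < cfg.min_match:
            continue
        ev = _candidate_evalue(x, n_frag, form, cfg.frag_tol_ppm, n_candidates)
        key = (-x, y, ev, protein.accession)
        if best is None or key < best[:4]:
            best = key + (matched, shift, protein)
    if best is None:
        return None
    _, y, ev, accession, matched, shift, protein = (
        best[0], best[1], best[2], best[3], best[4], best[5], best[6],
    )
    z = precursor.rank - 1
    x = len(matched)
    return PrSM(
        spectrum_id="",
        precursor_rank=z,
        accession=accession,
        proteoform_mass=precursor.neutral_mass,
        shift_count=y,
        shift_da=shift,
        matched_masses=matched,
        nnmfm=x - y * cfg.delta - z * cfg.gamma,
        evalue=ev,
        is_decoy=protein.is_decoy,
    )


def build_decoy_db(db: Sequence[Protein], seed: int) -> list[Protein]:
    """One shuffled decoy per target, deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    decoys = []
    for protein in db:
        residues = np.array(list(protein.sequence))
        rng.shuffle(residues)
        decoys.append(
            Protein(DECOY_PREFIX + protein.accession, "".join(residues), is_decoy=True)
        )
    return decoys
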