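"""Pseudo-multiplexed benchmark construction and error-rate evaluation.

Starting from identified non-multiplexed spectra, two benchmark families
are built by merging fragment lists of spectrum pairs:

SPMS (simple paired multiplexed spectra)
    every pair whose precursors have different charge states, average m/z
    within 1.5, and identifications from two different proteins; the
    member with more matched fragment masses is the base spectrum and all
    additive fragments are merged in.

RPMS (ratio paired multiplexed spectra)
    pairs additionally requiring average m/z within 20 and, after
    removing additive fragments that randomly match the base proteoform's
    b/y ions, at least twice as many additive as base-matched fragments;
    one dataset per additive-base (A-B) ratio r in 0%, 20%, ..., 200%,
    each spectrum carrying round(r x n_base) randomly chosen additive
    fragments.

Identification results on these spectra are scored per precursor role as
correct, precursor selection error (PSE: matched to the *other* role's
protein), or random matching error (RME: matched to neither), plus a
delta/gamma grid-sweep harness over the selection penalties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    Config,
    DeconvSpectrum,
    GroundTruth,
    PrecursorFeature,
    Protein,
    PrSM,
    DEFAULT_AB_RATIOS,
)
from .demultiplex import (
    MULTIPLEXED,
    classify_spectrum,
    detect_error_prone,
    filter_evalue,
    filter_fdr,
    nnmfm,
    search_pfps,
    two_round_search,
)
from .search_engine import (
    TheoreticalForm,
    build_forms,
    match_one_shift,
    match_zero_shift,
    theoretical_prefix_masses,
)

logger = logging.getLogger(__name__)

SPMS = "SPMS"
RPMS = "RPMS"

CORRECT = "correct"
PSE = "PSE"
RME = "RME"

BASE = "base"
ADDITIVE = "additive"


@dataclass(frozen=True)
class IdentifiedSpectrum:
    spectrum: DeconvSpectrum
    prsm: PrSM

    @property
    def precursor(self) -> PrecursorFeature:
        return self.spectrum.precursors[0]


@dataclass(frozen=True)
class SpectrumPair:
    base: IdentifiedSpectrum
    additive: IdentifiedSpectrum
    pair_kind: str  # SPMS | RPMS

    @property
    def shift_class(self) -> str:
        return f"Base{self.base.prsm.shift_count}-Add{self.additive.prsm.shift_count}"


def is_nonmultiplexed(spec: DeconvSpectrum, threshold: float = 0.85) -> bool:
    """True iff the top precursor holds >= threshold of total precursor intensity."""
    total = sum(p.intensity for p in spec.precursors)
    if total <= 0:
        return False
    return spec.precursors[0].intensity / total >= threshold


def pair_spms(identified: Sequence[IdentifiedSpectrum]) -> list[SpectrumPair]:
    """All unordered pairs meeting the SPMS criteria.

    (1) different precursor charge states, (2) average precursor m/z
    within 1.5, (3) identifications from two different proteins. The
    member with more matched fragment masses is the base (lexicographic
    smaller spectrum id on ties); base precursor gets the higher intensity
    at merge time.
    """
    pairs = []
    for i in range(len(identified)):
        for j in range(i + 1, len(identified)):
            s1, s2 = identified[i], identified[j]
            if s1.precursor.charge == s2.precursor.charge:
                continue
            if abs(s1.precursor.avg_mz - s2.precursor.avg_mz) > 1.5:
                continue
            if s1.prsm.accession == s2.prsm.accession:
                continue
            n1, n2 = s1.prsm.matched_count, s2.prsm.matched_count
            if n1 > n2 or (n1 == n2 and s1.spectrum.spectrum_id < s2.spectrum.spectrum_id):
                base, add = s1, s2
            else:
                base, add = s2, s1
            pairs.append(SpectrumPair(base, add, SPMS))
    return pairs


def _base_theoretical_match(
    base: IdentifiedSpectrum,
    masses: Sequence[float],
    form: TheoreticalForm,
    cfg: Config,
) -> frozenset[float]:
    """Masses randomly matching the base proteoform's b/y ions."""
    masses = sorted(masses)
    if base.prsm.shift_count == 0:
        return match_zero_shift(
            masses, form, base.precursor.neutral_mass, cfg.frag_tol_ppm
        )
    matched, _ = match_one_shift(masses, form, base.prsm.shift_da, cfg.frag_tol_ppm)
    return matched


def valid_rpms_additive(
    base: IdentifiedSpectrum,
    cand: IdentifiedSpectrum,
    cfg: Config,
    forms: dict[str, TheoreticalForm] | None = None,
    db: Sequence[Protein] | None = None,
) -> bool:
    """RPMS additive-validity: different charges, average m/z within 20,
    different proteins, and after discarding additive fragments that
    randomly match the base proteoform's ions at least twice as many
    additive fragments as base-matched fragments remain.

    Either prebuilt theoretical ``forms`` or the protein ``db`` must be
    supplied so the base proteoform's ions can be computed.
    """
    if base.precursor.charge == cand.precursor.charge:
        return False
    if abs(base.precursor.avg_mz - cand.precursor.avg_mz) > 20.0:
        return False
    if base.prsm.accession == cand.prsm.accession:
        return False
    if forms is None:
        if db is None:
            raise ValueError("valid_rpms_additive needs forms or db")
        forms = build_forms(db)
    form = forms[base.prsm.accession]
    rand = _base_theoretical_match(base, cand.spectrum.frag_masses, form, cfg)
    n_remaining = len(cand.spectrum.frag_masses) - len(rand)
    return n_remaining >= 2 * base.prsm.matched_count


def pair_rpms(
    identified: Sequence[IdentifiedSpectrum],
    cfg: Config,
    db: Sequence[Protein],
    max_pairs_per_base: int = 1,
) -> list[SpectrumPair]:
    """Valid (base, additive) RPMS pairs; per base, up to ``max_pairs_per_base``
    valid additives per additive shift class (0 or 1 unknown shifts)."""
    forms = build_forms(db)
    pairs = []
    for base in identified:
        taken = {0: 0, 1: 0}
        for cand in identified:
            if cand is base:
                continue
            cls = cand.prsm.shift_count
            if taken[cls] >= max_pairs_per_base:
                continue
            if valid_rpms_additive(base, cand, cfg, forms):
                pairs.append(SpectrumPair(base, cand, RPMS))
                taken[cls] += 1
    return pairs


def merge_pair(
    pair: SpectrumPair,
    ab_ratio: float | None,
    seed: int,
) -> tuple[DeconvSpectrum, GroundTruth]:
    """Merge a spectrum pair into one pseudo-multiplexed spectrum.

    ``ab_ratio=None`` (SPMS) keeps every additive fragment; otherwise
    ``round(ab_ratio * n_base)`` additive fragments are sampled uniformly
    without replacement (clamped to the available count, logged when
    clamping occurs). The base precursor always receives the strictly
    higher intensity. Exact duplicate masses collapse to one entry keeping
    the larger intensity.
    """
    if ab_ratio is not None and not 0.0 <= ab_ratio <= 2.0:
        raise ValueError(f"ab_ratio {ab_ratio} outside [0, 2]")
    base_spec = pair.base.spectrum
    add_spec = pair.additive.spectrum
    n_base = len(base_spec.frag_masses)

    add_idx = np.arange(len(add_spec.frag_masses))
    if ab_ratio is not None:
        k = int(round(ab_ratio * n_base))
        if k > len(add_idx):
            logger.info(
                "merge_pair %s|%s: clamping additive count %d -> %d",
                base_spec.spectrum_id, add_spec.spectrum_id, k, len(add_idx),
            )
            k = len(add_idx)
        rng = np.random.default_rng(seed)
        add_idx = np.sort(rng.choice(add_idx, size=k, replace=False))

    entries: dict[float, tuple[float, int]] = {}  # mass -> (intensity, origin)
    for m, it in zip(base_spec.frag_masses, base_spec.frag_intensities):
        entries[m] = (it, 0)
    for i in add_idx:
        m = add_spec.frag_masses[i]
        it = add_spec.frag_intensities[i]
        if m in entries:
            entries[m] = (max(entries[m][0], it), entries[m][1])
        else:
            entries[m] = (it, 1)
    masses = sorted(entries)
    intensities = [entries[m][0] for m in masses]
    origins = [entries[m][1] for m in masses]

    base_prec_src = pair.base.precursor
    add_prec_src = pair.additive.precursor
    i1 = max(base_prec_src.intensity, 1.0)
    i2 = 0.5 * i1
    ratio_tag = "spms" if ab_ratio is None else f"r{int(round(ab_ratio * 100)):03d}"
    sid = f"{base_spec.spectrum_id}|{add_spec.spectrum_id}|{ratio_tag}"
    precursors = (
        PrecursorFeature(
            feature_id=base_prec_src.feature_id,
            neutral_mass=base_prec_src.neutral_mass,
            charge=base_prec_src.charge,
            avg_mz=base_prec_src.avg_mz,
            intensity=i1,
            rank=1,
        ),
        PrecursorFeature(
            feature_id=add_prec_src.feature_id,
            neutral_mass=add_prec_src.neutral_mass,
            charge=add_prec_src.charge,
            avg_mz=add_prec_src.avg_mz,
            intensity=i2,
            rank=2,
        ),
    )
    mzs = [p.avg_mz for p in precursors]
    spec = DeconvSpectrum(
        spectrum_id=sid,
        iso_lo=min(mzs) - 2.0,
        iso_hi=max(mzs) + 2.0,
        precursors=precursors,
        frag_masses=tuple(masses),
        frag_intensities=tuple(intensities),
    )
    truth = GroundTruth(
        spectrum_id=sid,
        base_accession=pair.base.prsm.accession,
        additive_accession=pair.additive.prsm.accession,
        base_shift_da=pair.base.prsm.shift_da,
        additive_shift_da=pair.additive.prsm.shift_da,
        base_frag_ids=frozenset(i for i, o in enumerate(origins) if o == 0),
        additive_frag_ids=frozenset(i for i, o in enumerate(origins) if o == 1),
    )
    return spec, truth


def make_spms_dataset(
    pairs: Sequence[SpectrumPair], seed: int
) -> list[tuple[DeconvSpectrum, GroundTruth]]:
    return [merge_pair(p, None, seed) for p in pairs]


def make_rpms_datasets(
    pairs: Sequence[SpectrumPair],
    ratios: Sequence[float] = DEFAULT_AB_RATIOS,
    seed: int = 1,
) -> dict[float, list[tuple[DeconvSpectrum, GroundTruth]]]:
    """One dataset per A-B ratio; every dataset holds |pairs| spectra and
    shares base fragments per pair across ratios; deterministic per seed."""
    ss = np.random.SeedSequence(seed)
    datasets: dict[float, list[tuple[DeconvSpectrum, GroundTruth]]] = {}
    for ir, ratio in enumerate(ratios):
        dataset = []
        for ip, pair in enumerate(pairs):
            child = int(
                np.random.SeedSequence([seed, ir, ip]).generate_state(1)[0] % (2**31)
            )
            dataset.append(merge_pair(pair, ratio, child))
        datasets[ratio] = dataset
    del ss
    return datasets


def classify_error(prsm: PrSM, truth: GroundTruth, role: str) -> str:
    """correct / PSE / RME for one identification of one precursor role."""
    own = truth.base_accession if role == BASE else truth.additive_accession
    other = truth.additive_accession if role == BASE else truth.base_accession
    if prsm.accession == own:
        return CORRECT
    if other and prsm.accession == other:
        return PSE
    return RME


@dataclass
class ErrorReport:
    """Per-role identification outcome counts over a ground-truthed dataset."""

    counts: dict[str, dict[str, int]]

    def rate(self, role: str, kind: str) -> float:
        c = self.counts[role]
        total = c["n_truth"]
        return c[kind] / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role, c in self.counts.items():
            rows.append({"role": role, **c})
        return pd.DataFrame(rows)


def evaluate_results(
    prsms: Sequence[PrSM], truths: Sequence[GroundTruth]
) -> ErrorReport:
    """Score PrSMs against ground truth per precursor role.

    The role is resolved through the precursor rank: the base proteoform
    owns the higher-intensity (rank 0) precursor in every generated
    dataset. Counts per role sum to the number of truth entries carrying
    that role.
    """
    by_spectrum: dict[tuple[str, int], PrSM] = {}
    for p in prsms:
        by_spectrum[(p.spectrum_id, p.precursor_rank)] = p
    counts = {
        role: {"n_truth": 0, "n_correct": 0, "n_pse": 0, "n_rme": 0, "n_missed": 0}
        for role in (BASE, ADDITIVE)
    }
    for truth in truths:
        roles = [(BASE, 0)]
        if truth.additive_accession:
            roles.append((ADDITIVE, 1))
        for role, rank in roles:
            c = counts[role]
            c["n_truth"] += 1
            prsm = by_spectrum.get((truth.spectrum_id, rank))
            if prsm is None:
                c["n_missed"] += 1
                continue
            outcome = classify_error(prsm, truth, role)
            c[{CORRECT: "n_correct", PSE: "n_pse", RME: "n_rme"}[outcome]] += 1
    return ErrorReport(counts)


# ---------------------------------------------------------------------------
# delta/gamma sweep with cached searches


@dataclass
class _SpectrumCache:
    spec: DeconvSpectrum
    multiplexed: bool
    prsm1: PrSM | None  # PFPS search of rank-1 precursor, all fragments
    prsm2: PrSM | None  # PFPS search of rank-2 precursor, all fragments
    two_round: dict[int, "object"]  # primary rank -> TwoRoundResult


def _precompute(
    spectra: Sequence[DeconvSpectrum],
    db: Sequence[Protein],
    cfg: Config,
) -> list[_SpectrumCache]:
    """Run every delta/gamma-independent search once.

    The selection penalties enter only through the NNMFM comparison, so
    PFPS searches and both possible two-round outcomes can be shared
    across the whole parameter grid.
    """
    forms = build_forms(db)
    caches = []
    for spec in spectra:
        multiplexed = classify_spectrum(spec, cfg.alpha) == MULTIPLEXED
        prsm1 = prsm2 = None
        rounds: dict[int, object] = {}
        if multiplexed:
            from dataclasses import replace as _replace

            prsm1 = search_pfps(spec.precursors[0], spec.frag_masses, db, cfg, forms)
            prsm2 = search_pfps(spec.precursors[1], spec.frag_masses, db, cfg, forms)
            if prsm1 is not None:
                prsm1 = _replace(prsm1, spectrum_id=spec.spectrum_id)
            if prsm2 is not None:
                prsm2 = _replace(prsm2, spectrum_id=spec.spectrum_id)
            for primary_rank in (0, 1):
                rounds[primary_rank] = two_round_search(
                    spec, db, cfg, forms, primary_rank
                )
        else:
            prsm1 = search_pfps(spec.precursors[0], spec.frag_masses, db, cfg, forms)
            if prsm1 is not None:
                from dataclasses import replace as _replace

                prsm1 = _replace(prsm1, spectrum_id=spec.spectrum_id)
        caches.append(_SpectrumCache(spec, multiplexed, prsm1, prsm2, rounds))
    return caches


def _select_rank(cache: _SpectrumCache, cfg: Config) -> int:
    if cache.prsm1 is not None and cache.prsm2 is None:
        return 0
    if cache.prsm1 is None and cache.prsm2 is not None:
        return 1
    if cache.prsm1 is None and cache.prsm2 is None:
        return 0
    if not detect_error_prone(cache.prsm1, cache.prsm2, cfg.beta):
        return 0
    s1 = nnmfm(cache.prsm1.matched_count, cache.prsm1.shift_count, 0, cfg.delta, cfg.gamma)
    s2 = nnmfm(cache.prsm2.matched_count, cache.prsm2.shift_count, 1, cfg.delta, cfg.gamma)
    return 1 if s2 > s1 else 0


def _pipeline_from_cache(
    caches: Sequence[_SpectrumCache], cfg: Config, use_fdr: bool = True
) -> list[PrSM]:
    round1, round2 = [], []
    for cache in caches:
        if not cache.multiplexed:
            if cache.prsm1 is not None:
                round1.append(cache.prsm1)
            continue
        rank = _select_rank(cache, cfg)
        result = cache.two_round[rank]
        if result.round1 is not None:
            round1.append(result.round1)
        if result.round2 is not None:
            round2.append(result.round2)
    if use_fdr:
        return filter_fdr(round1, cfg.fdr_spectrum) + filter_fdr(round2, cfg.fdr_spectrum)
    return filter_evalue(round1, cfg.evalue_cutoff) + filter_evalue(round2, cfg.evalue_cutoff)


def sweep_delta_gamma(
    dataset: Sequence[tuple[DeconvSpectrum, GroundTruth]],
    db: Sequence[Protein],
    delta_grid: Sequence[float],
    gamma_grid: Sequence[float],
    cfg: Config,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Error rates of the full pipeline across the selection-penalty grid.

    Returns one row per (delta, gamma) with per-role PSE/RME/identification
    rates. Searches are computed once and shared across the grid.
    """
    spectra = [s for s, _ in dataset]
    truths = [t for _, t in dataset]
    caches = _precompute(spectra, db, cfg)
    rows = []
    for delta in delta_grid:
        for gamma in gamma_grid:
            point = cfg.with_overrides(delta=float(delta), gamma=float(gamma))
            prsms = _pipeline_from_cache(caches, point, use_fdr)
            report = evaluate_results(prsms, truths)
            row = {"delta": float(delta), "gamma": float(gamma)}
            for role in (BASE, ADDITIVE):
                row[f"pse_rate_{role}"] = report.rate(role, "n_pse")
                row[f"rme_rate_{role}"] = report.rate(role, "n_rme")
                row[f"id_rate_{role}"] = 1.0 - report.rate(role, "n_missed")
                row[f"correct_rate_{role}"] = report.rate(role, "n_correct")
            rows.append(row)
    return pd.DataFrame(rows)
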