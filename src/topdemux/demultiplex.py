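"""Primary-precursor selection and two-round identification of multiplexed
top-down DDA spectra.

A spectrum with two co-isolated precursors is classified as multiplexed
when the second precursor carries at least a fraction ``alpha`` of the
first's isolation-window intensity. Both precursor-fragment paired spectra
(PFPS) are searched; if the two identifications point at the same protein
or share most matched fragments, the spectrum is error-prone — one of the
two is a precursor selection error (PSE) — and the precursor whose PrSM
has the higher NNMFM (matched count minus shift and intensity-rank
penalties, x - y*delta - z*gamma) is searched first. The first round's
matched fragment masses are subtracted before the second round, so each
fragment supports at most one identification. Round-1 and round-2 PrSM
pools are filtered separately by target-decoy FDR, merged, clustered into
proteoform groups (same feature, or same protein within 1.2 Da precursor
mass), and the groups filtered again at the proteoform level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core_io import Config, DeconvSpectrum, Protein, ProteoformGroup, PrSM
from .search_engine import TheoreticalForm, build_forms, search_pfps

logger = logging.getLogger(__name__)

MULTIPLEXED = "multiplexed"
SINGLE = "single"


def precursor_intensity(
    feature_peaks: Iterable[tuple[float, float]], iso_lo: float, iso_hi: float
) -> float:
    """Isolation-window precursor intensity: summed intensity of the
    feature's MS1 peaks with m/z inside [iso_lo, iso_hi]."""
    return float(sum(i for mz, i in feature_peaks if iso_lo <= mz <= iso_hi))


def classify_spectrum(spec: DeconvSpectrum, alpha: float) -> str:
    """Multiplexed iff a second precursor reaches I2/I1 >= alpha (inclusive)."""
    if len(spec.precursors) < 2:
        return SINGLE
    i1 = spec.precursors[0].intensity
    i2 = spec.precursors[1].intensity
    if i1 == 0:
        logger.info("spectrum %s: zero top precursor intensity", spec.spectrum_id)
        return SINGLE
    return MULTIPLEXED if i2 / i1 >= alpha else SINGLE


def shared_match_ratio(m1: frozenset[float], m2: frozenset[float]) -> float:
    """|M1 n M2| / min(|M1|, |M2|); 0 when either set is empty."""
    if not m1 or not m2:
        logger.info("shared_match_ratio: empty matched set")
        return 0.0
    return len(m1 & m2) / min(len(m1), len(m2))


def detect_error_prone(prsm1: PrSM, prsm2: PrSM, beta: float) -> bool:
    """Error-prone iff same protein, or shared matched-mass ratio >= beta."""
    if prsm1.accession == prsm2.accession:
        return True
    return shared_match_ratio(prsm1.matched_masses, prsm2.matched_masses) >= beta


def nnmfm(x: int, y: int, z: int, delta: float, gamma: float) -> float:
    """Number of normalized matched fragment masses, x - y*delta - z*gamma."""
    return x - y * delta - z * gamma


@dataclass(frozen=True)
class PrimarySelection:
    primary_rank: int  # 0 = highest-intensity precursor is primary
    prsm1: PrSM | None  # PFPS of the rank-1 precursor
    prsm2: PrSM | None  # PFPS of the rank-2 precursor
    error_prone: bool


def select_primary(
    spec: DeconvSpectrum,
    db: Sequence[Protein],
    cfg: Config,
    forms: dict[str, TheoreticalForm] | None = None,
) -> PrimarySelection:
    """Choose the round-1 precursor of a multiplexed spectrum.

    Both PFPSs (each precursor paired with all fragment masses) are
    searched. If only one yields a PrSM, its precursor is primary. If both
    do and the pair is error-prone, the higher NNMFM wins (F1 on ties);
    otherwise, and when neither yields a PrSM, F1 is primary.
    """
    if forms is None:
        forms = build_forms(db)
    prsm1 = search_pfps(spec.precursors[0], spec.frag_masses, db, cfg, forms)
    prsm2 = search_pfps(spec.precursors[1], spec.frag_masses, db, cfg, forms)
    if prsm1 is not None:
        prsm1 = replace(prsm1, spectrum_id=spec.spectrum_id)
    if prsm2 is not None:
        prsm2 = replace(prsm2, spectrum_id=spec.spectrum_id)

    if prsm1 is not None and prsm2 is None:
        return PrimarySelection(0, prsm1, prsm2, False)
    if prsm1 is None and prsm2 is not None:
        return PrimarySelection(1, prsm1, prsm2, False)
    if prsm1 is None and prsm2 is None:
        return PrimarySelection(0, None, None, False)

    error_prone = detect_error_prone(prsm1, prsm2, cfg.beta)
    if not error_prone:
        return PrimarySelection(0, prsm1, prsm2, False)
    score1 = nnmfm(prsm1.matched_count, prsm1.shift_count, 0, cfg.delta, cfg.gamma)
    score2 = nnmfm(prsm2.matched_count, prsm2.shift_count, 1, cfg.delta, cfg.gamma)
    return PrimarySelection(1 if score2 > score1 else 0, prsm1, prsm2, True)


@dataclass(frozen=True)
class TwoRoundResult:
    round1: PrSM | None
    round2: PrSM | None

    @property
    def prsms(self) -> list[PrSM]:
        return [p for p in (self.round1, self.round2) if p is not None]


def two_round_search(
    spec: DeconvSpectrum,
    db: Sequence[Protein],
    cfg: Config,
    forms: dict[str, TheoreticalForm] | None = None,
    primary_rank: int = 0,
) -> TwoRoundResult:
    """Search-and-subtract identification of one multiplexed spectrum.

    Round 1 searches the primary precursor with all fragment masses; its
    matched masses (literal spectrum entries) are removed before round 2
    searches the secondary precursor. If both rounds identify the same
    protein only the lower-E-value PrSM is kept.
    """
    if forms is None:
        forms = build_forms(db)
    primary = spec.precursors[primary_rank]
    secondary = spec.precursors[1 - primary_rank]

    prsm_a = search_pfps(primary, spec.frag_masses, db, cfg, forms)
    remaining = spec.frag_masses
    if prsm_a is not None:
        prsm_a = replace(prsm_a, spectrum_id=spec.spectrum_id)
        remaining = tuple(m for m in spec.frag_masses if m not in prsm_a.matched_masses)
    prsm_b = search_pfps(secondary, remaining, db, cfg, forms)
    if prsm_b is not None:
        prsm_b = replace(prsm_b, spectrum_id=spec.spectrum_id)

    if (
        prsm_a is not None
        and prsm_b is not None
        and prsm_a.accession == prsm_b.accession
    ):
        if prsm_a.evalue <= prsm_b.evalue:
            prsm_b = None
        else:
            prsm_a = None
    return TwoRoundResult(prsm_a, prsm_b)


def filter_fdr(prsms: Sequence[PrSM], cutoff: float) -> list[PrSM]:
    """Target-decoy FDR filter.

    PrSMs are sorted by ascending E-value (decoys first on ties); at each
    prefix the FDR estimate is #decoys / max(1, #targets), monotonized by
    a cumulative minimum from the largest prefix (the q-value
    construction). Targets of the largest prefix with q <= cutoff pass.
    """
    if not prsms:
        return []
    ordered = sorted(
        prsms, key=lambda p: (p.evalue, not p.is_decoy, p.accession, p.spectrum_id)
    )
    n_decoy = 0
    n_target = 0
    fdrs = []
    for p in ordered:
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(1, n_target))
    # monotonize from the bottom
    qvals = fdrs[:]
    for i in range(len(qvals) - 2, -1, -1):
        qvals[i] = min(qvals[i], qvals[i + 1])
    keep = 0
    for i, q in enumerate(qvals):
        if q <= cutoff:
            keep = i + 1
    return [p for p in ordered[:keep] if not p.is_decoy]


def filter_evalue(prsms: Sequence[PrSM], cutoff: float) -> list[PrSM]:
    return [p for p in prsms if not p.is_decoy and p.evalue <= cutoff]


def feature_map(spectra: Iterable[DeconvSpectrum]) -> dict[tuple[str, int], int]:
    """Map (spectrum_id, precursor rank z) -> proteoform feature id."""
    return {
        (spec.spectrum_id, prec.rank - 1): prec.feature_id
        for spec in spectra
        for prec in spec.precursors
    }


def group_proteoforms(
    prsms: Sequence[PrSM],
    feature_of: dict[tuple[str, int], int],
    cfg: Config,
) -> list[ProteoformGroup]:
    """Single-linkage clustering of PrSMs into proteoform groups.

    Two PrSMs are linked when their precursors come from the same
    proteoform feature, or they match the same protein with precursor
    masses within ``cfg.group_mass_tol_da``. Groups are ranked by their
    best (minimum) member E-value.
    """
    n = len(prsms)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    feats = [feature_of.get((p.spectrum_id, p.precursor_rank)) for p in prsms]
    for i in range(n):
        for j in range(i + 1, n):
            same_feature = feats[i] is not None and feats[i] == feats[j]
            same_protein_close = (
                prsms[i].accession == prsms[j].accession
                and abs(prsms[i].proteoform_mass - prsms[j].proteoform_mass)
                < cfg.group_mass_tol_da
            )
            if same_feature or same_protein_close:
                union(i, j)

    clusters: dict[int, list[PrSM]] = {}
    for i, p in enumerate(prsms):
        clusters.setdefault(find(i), []).append(p)
    groups = []
    for members in clusters.values():
        rep = min(members, key=lambda p: (p.evalue, p.accession, p.spectrum_id))
        groups.append(
            ProteoformGroup(
                members=sorted(members, key=lambda p: (p.evalue, p.spectrum_id)),
                accession=rep.accession,
                representative_mass=rep.proteoform_mass,
                best_evalue=rep.evalue,
            )
        )
    groups.sort(key=lambda g: (g.best_evalue, g.accession))
    return groups


@dataclass
class PipelineResult:
    prsms: list[PrSM]  # spectrum-level survivors, both rounds merged
    groups: list[ProteoformGroup]  # proteoform-level survivors
    decisions: list[dict]  # per-spectrum log of classification/selection


def run_pipeline(
    spectra: Sequence[DeconvSpectrum],
    db: Sequence[Protein],
    cfg: Config,
    primary_selection: bool = True,
    second_round: bool = True,
    use_fdr: bool = True,
) -> PipelineResult:
    """Full identification pipeline over a spectrum collection.

    ``primary_selection=False`` always searches the highest-intensity
    precursor first; combined with ``second_round=False`` this is the
    naive single-precursor baseline (at most one PrSM per spectrum, no
    PSE correction).
    """
    forms = build_forms(db)
    round1_pool: list[PrSM] = []
    round2_pool: list[PrSM] = []
    decisions: list[dict] = []
    for spec in spectra:
        label = classify_spectrum(spec, cfg.alpha)
        decision = {
            "spectrum_id": spec.spectrum_id,
            "classification": label,
            "error_prone": False,
            "primary_rank": 0,
        }
        if label == SINGLE or not second_round:
            primary_rank = 0
            if label == MULTIPLEXED and primary_selection:
                sel = select_primary(spec, db, cfg, forms)
                primary_rank = sel.primary_rank
                decision["error_prone"] = sel.error_prone
                decision["primary_rank"] = sel.primary_rank
            prsm = search_pfps(
                spec.precursors[primary_rank], spec.frag_masses, db, cfg, forms
            )
            if prsm is not None:
                round1_pool.append(replace(prsm, spectrum_id=spec.spectrum_id))
        else:
            if primary_selection:
                sel = select_primary(spec, db, cfg, forms)
                primary_rank = sel.primary_rank
                decision["error_prone"] = sel.error_prone
                decision["primary_rank"] = sel.primary_rank
            else:
                primary_rank = 0
            result = two_round_search(spec, db, cfg, forms, primary_rank)
            if result.round1 is not None:
                round1_pool.append(result.round1)
            if result.round2 is not None:
                round2_pool.append(result.round2)
        decisions.append(decision)

    if use_fdr:
        kept1 = filter_fdr(round1_pool, cfg.fdr_spectrum)
        kept2 = filter_fdr(round2_pool, cfg.fdr_spectrum)
    else:
        kept1 = filter_evalue(round1_pool, cfg.evalue_cutoff)
        kept2 = filter_evalue(round2_pool, cfg.evalue_cutoff)
    merged = kept1 + kept2

    fmap = feature_map(spectra)
    groups = group_proteoforms(merged, fmap, cfg)
    reps = [g.members[0] for g in groups]
    if use_fdr:
        kept_reps = {id(p) for p in filter_fdr(reps, cfg.fdr_proteoform)}
    else:
        kept_reps = {id(p) for p in filter_evalue(reps, cfg.evalue_cutoff)}
    groups = [g for g, r in zip(groups, reps) if id(r) in kept_reps]
    return PipelineResult(prsms=merged, groups=groups, decisions=decisions)
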