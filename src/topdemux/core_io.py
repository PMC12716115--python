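"""Domain types and file I/O for deconvoluted top-down spectra.

All fragment and precursor masses are **neutral monoisotopic masses** in
Daltons; m/z appears only in isolation-window bounds and the per-feature
average m/z carried through from upstream feature detection.

The on-disk spectrum format is a small self-describing text dialect
(``BEGIN IONS``/``END IONS`` blocks with ``KEY=VALUE`` headers followed by
``mass<TAB>intensity`` fragment lines). It is deliberately minimal: one
spectrum per block, one or two candidate precursors per spectrum, each
precursor carrying the isolation-window intensity used to rank it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

DECOY_PREFIX = "DECOY_"

#: 11 default additive-base ratios for the RPMS benchmark series.
DEFAULT_AB_RATIOS = tuple(round(0.2 * i, 1) for i in range(11))

PRSM_TSV_COLUMNS = (
    "spectrum_id",
    "precursor_rank",
    "accession",
    "is_decoy",
    "proteoform_mass",
    "shift_count",
    "shift_da",
    "matched_count",
    "nnmfm",
    "evalue",
)

GROUP_TSV_COLUMNS = (
    "group_id",
    "accession",
    "representative_mass",
    "best_evalue",
    "n_members",
    "spectrum_ids",
)

TRUTH_TSV_COLUMNS = (
    "spectrum_id",
    "base_accession",
    "additive_accession",
    "base_shift_da",
    "additive_shift_da",
    "base_frag_count",
    "additive_frag_count",
)


@dataclass(frozen=True)
class Config:
    """Pipeline parameters.

    alpha : intensity ratio I2/I1 at or above which a spectrum is
        classified as multiplexed (default 0.2).
    beta : shared matched-fragment ratio at or above which a spectrum
        pair of identifications is flagged error-prone (default 0.7).
    delta : NNMFM penalty per unknown mass shift (fragment-count units).
    gamma : NNMFM penalty for the lower-intensity precursor.
    frag_tol_ppm : fragment mass tolerance in parts per million.
    shift_min_da, shift_max_da : allowed unknown-shift window in Daltons.
    zero_shift_tol_da : precursor-vs-proteoform mass agreement that counts
        as "no shift" (absorbs +-1 isotope error; default 1.2 Da).
    min_match : minimum matched fragments for a reportable PrSM.
    evalue_cutoff : E-value filter used when FDR filtering is disabled.
    fdr_spectrum, fdr_proteoform : target-decoy FDR cutoffs.
    group_mass_tol_da : precursor mass difference below which same-protein
        identifications are grouped as one proteoform (default 1.2 Da).
    """

    alpha: float = 0.2
    beta: float = 0.7
    delta: float = 5.0
    gamma: float = 4.0
    frag_tol_ppm: float = 15.0
    shift_min_da: float = -50.0
    shift_max_da: float = 200.0
    zero_shift_tol_da: float = 1.2
    min_match: int = 4
    evalue_cutoff: float = 0.01
    fdr_spectrum: float = 0.01
    fdr_proteoform: float = 0.01
    group_mass_tol_da: float = 1.2
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.delta < 0 or self.gamma < 0:
            raise ValueError("delta and gamma must be non-negative")
        if self.shift_min_da >= self.shift_max_da:
            raise ValueError("shift_min_da must be < shift_max_da")
        for name in ("frag_tol_ppm", "zero_shift_tol_da", "group_mass_tol_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_overrides(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Protein:
    accession: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")


@dataclass(frozen=True)
class PrecursorFeature:
    """One candidate precursor of an MS/MS spectrum.

    ``intensity`` is the isolation-window precursor intensity: the summed
    intensity of the feature's MS1 peaks inside the isolation window.
    ``rank`` 1 marks the highest-intensity candidate.
    """

    feature_id: int
    neutral_mass: float
    charge: int
    avg_mz: float
    intensity: float
    rank: int

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.rank not in (1, 2):
            raise ValueError("rank must be 1 or 2")


@dataclass(frozen=True)
class DeconvSpectrum:
    """A deconvoluted MS/MS spectrum with 1-2 candidate precursors."""

    spectrum_id: str
    iso_lo: float
    iso_hi: float
    precursors: tuple[PrecursorFeature, ...]
    frag_masses: tuple[float, ...]
    frag_intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.iso_lo >= self.iso_hi:
            raise ValueError("iso_lo must be < iso_hi")
        if not 1 <= len(self.precursors) <= 2:
            raise ValueError("a spectrum carries 1 or 2 precursors")
        if len(self.frag_masses) != len(self.frag_intensities):
            raise ValueError("frag_masses and frag_intensities differ in length")
        if any(m2 <= m1 for m1, m2 in zip(self.frag_masses, self.frag_masses[1:])):
            raise ValueError("frag_masses must be strictly increasing")
        ints = [p.intensity for p in self.precursors]
        if ints != sorted(ints, reverse=True):
            raise ValueError("precursors must be sorted by descending intensity")


@dataclass(frozen=True)
class PrSM:
    """A proteoform-spectrum match.

    ``precursor_rank`` is z: 0 for the highest-intensity precursor, 1 for
    the second. ``proteoform_mass`` is the observed precursor neutral mass
    of the matched proteoform. ``nnmfm`` = x - y*delta - z*gamma under the
    governing :class:`Config`.
    """

    spectrum_id: str
    precursor_rank: int
    accession: str
    proteoform_mass: float
    shift_count: int
    shift_da: float
    matched_masses: frozenset[float]
    nnmfm: float
    evalue: float
    is_decoy: bool
    #: set only by read_prsm_tsv, where the on-disk row keeps the count but
    #: not the mass set itself
    count_override: int | None = None

    def __post_init__(self) -> None:
        if self.precursor_rank not in (0, 1):
            raise ValueError("precursor_rank must be 0 or 1")
        if self.shift_count not in (0, 1):
            raise ValueError("shift_count must be 0 or 1")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")

    @property
    def matched_count(self) -> int:
        if self.count_override is not None and not self.matched_masses:
            return self.count_override
        return len(self.matched_masses)


@dataclass
class ProteoformGroup:
    members: list[PrSM]
    accession: str
    representative_mass: float
    best_evalue: float


@dataclass(frozen=True)
class GroundTruth:
    """Per-spectrum record of the true co-isolated proteoforms.

    ``base_frag_ids``/``additive_frag_ids`` index into the spectrum's
    ``frag_masses``; for single-proteoform spectra ``additive_accession``
    is empty.
    """

    spectrum_id: str
    base_accession: str
    additive_accession: str
    base_shift_da: float
    additive_shift_da: float
    base_frag_ids: frozenset[int] = frozenset()
    additive_frag_ids: frozenset[int] = frozenset()


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Protein]:
    """Read a protein database; decoy records are recognized by accession prefix."""
    path = Path(path)
    proteins: list[Protein] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        sequence = str(record.seq).upper()
        bad = set(sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"illegal residue(s) {sorted(bad)} in record {accession!r}"
            )
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r}")
        seen.add(accession)
        proteins.append(
            Protein(accession, sequence, is_decoy=accession.startswith(DECOY_PREFIX))
        )
    if not proteins:
        raise ValueError(f"no FASTA records in {path}")
    return proteins


def write_fasta(proteins: Iterable[Protein], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.accession}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Spectrum dialect

_MANDATORY_KEYS = (
    "ID",
    "ISO_LO",
    "ISO_HI",
    "PRECURSOR_MASS_1",
    "PRECURSOR_CHARGE_1",
    "PRECURSOR_MZ_1",
    "PRECURSOR_INTENSITY_1",
    "PRECURSOR_FEATURE_1",
)


def _parse_block(lines: list[str], block_no: int) -> DeconvSpectrum:
    header: dict[str, str] = {}
    frags: list[tuple[float, float]] = []
    for line in lines:
        if "=" in line and "\t" not in line:
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
        else:
            mass_s, _, int_s = line.partition("\t")
            frags.append((float(mass_s), float(int_s or "0")))
    missing = [k for k in _MANDATORY_KEYS if k not in header]
    if missing:
        sid = header.get("ID", f"<block {block_no}>")
        raise ValueError(f"spectrum {sid}: missing mandatory key(s) {missing}")

    precursors = []
    for suffix in ("1", "2"):
        if f"PRECURSOR_MASS_{suffix}" not in header:
            continue
        precursors.append(
            dict(
                feature_id=int(header[f"PRECURSOR_FEATURE_{suffix}"]),
                neutral_mass=float(header[f"PRECURSOR_MASS_{suffix}"]),
                charge=int(header[f"PRECURSOR_CHARGE_{suffix}"]),
                avg_mz=float(header[f"PRECURSOR_MZ_{suffix}"]),
                intensity=float(header[f"PRECURSOR_INTENSITY_{suffix}"]),
            )
        )
    precursors.sort(key=lambda d: -d["intensity"])
    feats = tuple(
        PrecursorFeature(rank=i + 1, **d) for i, d in enumerate(precursors)
    )

    masses = [m for m, _ in frags]
    if any(b <= a for a, b in zip(masses, masses[1:])):
        logger.info("spectrum %s: fragment masses not sorted; sorting", header["ID"])
        frags.sort(key=lambda t: t[0])
    return DeconvSpectrum(
        spectrum_id=header["ID"],
        iso_lo=float(header["ISO_LO"]),
        iso_hi=float(header["ISO_HI"]),
        precursors=feats,
        frag_masses=tuple(m for m, _ in frags),
        frag_intensities=tuple(i for _, i in frags),
    )


def read_spectra(path: str | Path) -> list[DeconvSpectrum]:
    """Read deconvoluted spectra from the BEGIN IONS/END IONS text dialect."""
    spectra: list[DeconvSpectrum] = []
    block: list[str] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line == "BEGIN IONS":
                block = []
            elif line == "END IONS":
                if block is None:
                    raise ValueError("END IONS without BEGIN IONS")
                spectra.append(_parse_block(block, len(spectra)))
                block = None
            elif block is not None and line.strip():
                block.append(line)
    return spectra


def write_spectra(spectra: Iterable[DeconvSpectrum], path: str | Path) -> None:
    """Write spectra in the dialect; masses at 5 decimals, intensities at 2."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"ID={spec.spectrum_id}\n")
            fh.write(f"ISO_LO={spec.iso_lo:.5f}\n")
            fh.write(f"ISO_HI={spec.iso_hi:.5f}\n")
            for i, p in enumerate(spec.precursors, start=1):
                fh.write(f"PRECURSOR_MASS_{i}={p.neutral_mass:.5f}\n")
                fh.write(f"PRECURSOR_CHARGE_{i}={p.charge}\n")
                fh.write(f"PRECURSOR_MZ_{i}={p.avg_mz:.5f}\n")
                fh.write(f"PRECURSOR_INTENSITY_{i}={p.intensity:.2f}\n")
                fh.write(f"PRECURSOR_FEATURE_{i}={p.feature_id}\n")
            for m, it in zip(spec.frag_masses, spec.frag_intensities):
                fh.write(f"{m:.5f}\t{it:.2f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# TSV tables


def write_prsm_tsv(prsms: Sequence[PrSM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PRSM_TSV_COLUMNS) + "\n")
        for p in prsms:
            fh.write(
                "\t".join(
                    [
                        p.spectrum_id,
                        str(p.precursor_rank),
                        p.accession,
                        str(int(p.is_decoy)),
                        f"{p.proteoform_mass:.5f}",
                        str(p.shift_count),
                        f"{p.shift_da:.5f}",
                        str(p.matched_count),
                        f"{p.nnmfm:g}",
                        f"{p.evalue:.6g}",
                    ]
                )
                + "\n"
            )


def read_prsm_tsv(path: str | Path) -> list[PrSM]:
    """Read a PrSM table back.

    Matched masses are not stored on disk; ``matched_masses`` comes back
    empty and the row's count is kept in ``count_override``.
    """
    prsms = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < len(PRSM_TSV_COLUMNS):
                continue
            prsms.append(
                PrSM(
                    spectrum_id=f[idx["spectrum_id"]],
                    precursor_rank=int(f[idx["precursor_rank"]]),
                    accession=f[idx["accession"]],
                    proteoform_mass=float(f[idx["proteoform_mass"]]),
                    shift_count=int(f[idx["shift_count"]]),
                    shift_da=float(f[idx["shift_da"]]),
                    matched_masses=frozenset(),
                    nnmfm=float(f[idx["nnmfm"]]),
                    evalue=float(f[idx["evalue"]]),
                    is_decoy=bool(int(f[idx["is_decoy"]])),
                    count_override=int(f[idx["matched_count"]]),
                )
            )
    return prsms


def write_groups_tsv(groups: Sequence[ProteoformGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GROUP_TSV_COLUMNS) + "\n")
        for gid, g in enumerate(groups):
            fh.write(
                "\t".join(
                    [
                        str(gid),
                        g.accession,
                        f"{g.representative_mass:.5f}",
                        f"{g.best_evalue:.6g}",
                        str(len(g.members)),
                        ",".join(m.spectrum_id for m in g.members),
                    ]
                )
                + "\n"
            )


def write_truth_tsv(truths: Sequence[GroundTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_TSV_COLUMNS) + "\n")
        for t in truths:
            fh.write(
                "\t".join(
                    [
                        t.spectrum_id,
                        t.base_accession,
                        t.additive_accession,
                        f"{t.base_shift_da:.5f}",
                        f"{t.additive_shift_da:.5f}",
                        str(len(t.base_frag_ids)),
                        str(len(t.additive_frag_ids)),
                    ]
                )
                + "\n"
            )


def read_truth_tsv(path: str | Path) -> list[GroundTruth]:
    truths = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                continue
            truths.append(
                GroundTruth(
                    spectrum_id=f[idx["spectrum_id"]],
                    base_accession=f[idx["base_accession"]],
                    additive_accession=f[idx["additive_accession"]],
                    base_shift_da=float(f[idx["base_shift_da"]]),
                    additive_shift_da=float(f[idx["additive_shift_da"]]),
                )
            )
    return truths
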