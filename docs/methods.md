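# Methods

## Problem setting

A top-down DDA MS/MS spectrum is acquired by isolating a narrow m/z
window and fragmenting everything inside it. When two proteoform species
co-elute in the window, the resulting heterogeneous multiplexed (HetM)
spectrum contains b/y fragment masses of two different proteins. After
spectral deconvolution the spectrum is a list of neutral monoisotopic
fragment masses plus one or two candidate precursors, each carrying the
summed MS1 intensity of its feature's peaks inside the isolation window
(the isolation-window precursor intensity).

Two failure modes of conventional single-precursor search motivate the
pipeline. First, only one of the two proteoforms can ever be reported.
Second, when the lower-intensity species dominates the fragment
evidence, the search pairs the top precursor with the other species'
fragments and reports the wrong protein, usually absorbing the precursor
mass discrepancy as a spurious unknown mass shift — a precursor
selection error (PSE).

## Search model

Each database sequence is expanded into N-terminal prefix (b-ion) masses
`p_1 < … < p_{L−1}` (cumulative monoisotopic residue masses from
`pyteomics`) and an unmodified proteoform mass `M = Σ residues + water`.
Suffix (y-ion) masses are precursor complements. A candidate explains a
precursor of observed neutral mass `m` in exactly one of two ways:

* **zero shift** if `|m − M| ≤ 1.2 Da` (`zero_shift_tol_da`, absorbing a
  ±1 isotope error in the deconvoluted precursor), matching fragments
  against `{p_j} ∪ {m − p_j}`;
* **one shift** of `Δ = m − M` if `Δ ∈ [−50, 200] Da`
  (`shift_min_da`/`shift_max_da`). The shift is localized after a split
  index `i ∈ {0 … L−1}`: prefixes with index ≥ i carry Δ, and suffixes
  mirror (the complement of an unshifted prefix contains the shift). The
  matcher returns the split maximizing the number of matched
  experimental masses, smallest split on ties. Only Δ and the matched
  set matter downstream; the split is not reported as a localization.

Other sequences cannot explain the precursor and are skipped. A fragment
matches a theoretical mass within `frag_tol_ppm` (default 15 ppm, a
typical Orbitrap top-down tolerance); each experimental mass counts at
most once. The best candidate maximizes matched count, with ties broken
by fewer shifts, lower E-value, then accession; matches below
`min_match = 4` fragments are not reported, which keeps one- or
two-fragment coincidences from steering precursor selection.

**E-value.** Under the null, each of the `n_theo = 2(L−1)` theoretical
masses hits a random spectrum mass with probability
`p = min(1, n_frag · 2·tol_da_mean / mass_range)`, with
`tol_da_mean = frag_tol_ppm·10⁻⁶·M/2` (the tolerance at the mean
fragment mass, half the precursor) and `mass_range = M`. The E-value is
`|db| · P[Binomial(n_theo, p) ≥ x]`, floored at 1e−300. This is a
deliberately simple surrogate for the generating-function E-values of
full spectral-alignment engines — it is not numerically equivalent, but
it is monotone in the matched count, symmetric between targets and
decoys (the property FDR estimation needs), and calibrates well on
simulated noise (target/decoy hit counts statistically indistinguishable;
see the validation suite).

## Demultiplexing pipeline

1. **Classification.** Multiplexed iff a second precursor has
   `I2/I1 ≥ α` (default 0.2, boundary inclusive).
2. **Primary selection.** Both PFPSs (each precursor with all fragment
   masses) are searched. If only one yields a PrSM its precursor is
   primary. If both do, the spectrum is error-prone when the accessions
   agree or the shared matched-mass ratio `|M1∩M2|/min(|M1|,|M2|)` is
   ≥ β (default 0.7, inclusive); then the higher NNMFM
   (`x − y·δ − z·γ`, δ = 5, γ = 4, z = 1 for the lower-intensity
   precursor) decides, F1 on ties. Non-error-prone spectra and spectra
   where neither PFPS identifies keep F1 primary (both rounds still run
   in the latter case — nothing was subtracted).
3. **Two rounds.** Round 1 searches the primary with all fragments;
   matched masses (literal spectrum entries, not tolerance
   neighborhoods) are removed; round 2 searches the secondary on the
   remainder — so the two matched sets are disjoint by construction. If
   both rounds hit the same protein only the lower-E-value PrSM is kept.
4. **Filtering and grouping.** Round-1 and round-2 pools are filtered
   *separately* at 1 % spectrum-level target-decoy FDR (decoy/target
   prefix ratio monotonized by a cumulative minimum from the largest
   prefix — the standard q-value construction; decoys precede targets on
   E-value ties, the conservative order). Survivors are merged and
   single-linkage clustered: two PrSMs join one proteoform group when
   their precursors share a feature id, or they match the same protein
   with observed precursor masses within 1.2 Da (raw precursor neutral
   masses; `PrSM.proteoform_mass` stores exactly that observed mass).
   Group representatives are filtered again at 1 % proteoform-level FDR.

The naive baseline used in every comparison disables selection and the
second round: the top precursor is searched once per spectrum.

## Synthetic data

The simulator emulates deconvoluted HetM spectra, not raw spectra: no
isotopic envelopes, charge-state-resolved peaks or elution profiles.
Defaults (chosen once as desk-scale, Orbitrap-plausible conditions):

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 50 | i.i.d.-residue proteome, accessions `SYN_0001…` |
| `len_range` | (30, 60) | residues; masses ≈ 3.3–6.6 kDa |
| `coverage` | 0.8 | i.i.d. Bernoulli observation per theoretical b/y ion |
| `mass_error_ppm` | 5 | Gaussian relative fragment mass error |
| `n_noise` | 5 | uniform noise masses in [200, 0.95·max proteoform mass] |
| `shift_prob` | 0.3 | probability a proteoform carries one unknown shift |
| `shift_range_da` | (10, 150) | true shifts, inside the search window |
| `intensity_ratio_range` | (0.3, 0.9) | I2/I1, always multiplexed at α = 0.2 |

Charges aim precursors at ≈ 900 m/z (charge = mass/900 with ±0.5
jitter), so simulated features cluster where pairing criteria can bite.
Fragment observation is i.i.d. per ion; real coverage is
position-dependent, but the pipeline's decisions depend only on counts.

Scenarios: **normal** assigns the higher-intensity precursor to the
proteoform contributing at least as many observed fragments (roles are
swapped rather than fragments subsampled, so both proteoforms keep their
nominal coverage); **swapped-intensity** subsamples the high-intensity
proteoform's fragments to one third of the other's (minimum 5, hence
always satisfying the ≥ 2× imbalance that defines the scenario) *and*
rejection-samples protein pairs until the wrong-assignment mass
difference `m(A)+shift − m(B)` lies inside the search shift window.
Without that mass compatibility no shifted mis-assignment is possible at
all, which leads to a structural observation worth stating explicitly:

**What PSEs require here.** In this engine a PSE can only arise when the
wrong precursor's mass is explainable by the other proteoform within the
shift window. SPMS/RPMS pairing demands *different* charge states with
*close* average m/z, which forces neutral masses apart by roughly one
charge × 900 Da — far outside any shift window. Synthetic
pseudo-multiplexed series therefore probe sensitivity, subtraction and
RME robustness, but produce essentially no naive-baseline PSEs; in real
data that channel runs through terminal truncations, which are
deliberately out of scope. PSE induction and correction are instead
exercised by the swapped-intensity HetM scenario. Consequently, passing
the pseudo-multiplexed tests says nothing about truncation-mediated
PSEs on real spectra.

## Pseudo-multiplexed benchmarks

From identified non-multiplexed spectra (top precursor holding ≥ 85 % of
total precursor intensity):

* **SPMS** pairs: different precursor charges, average m/z within 1.5,
  different proteins; the member with more matched fragment masses is
  the base (lexicographically smaller spectrum id on ties); all additive
  fragments are merged, exact duplicates collapsing to the
  higher-intensity entry.
* **RPMS** pairs additionally require average m/z within 20 and, after
  discarding additive fragments that randomly match the base
  proteoform's ions (the only matching operation the system defines, at
  `frag_tol_ppm`), at least 2× as many additive as base-matched
  fragments. Eleven datasets are built at A-B ratios 0, 0.2, …, 2.0;
  each spectrum carries exactly `round(r·n_base)` uniformly sampled
  additive fragments (clamped to availability, logged; the validation
  series additionally requires additive spectra with ≥ 2×n_base
  fragments so no clamping occurs). The merged base precursor always
  receives the strictly higher intensity.

Identifications are scored per precursor role (base = rank-0 precursor):
**correct** (own protein), **PSE** (the other role's protein), **RME**
(neither). The δ/γ sweep reruns selection and assembly across the grid
from per-spectrum search results computed once — the penalties enter
only through the NNMFM comparison, never the matcher or E-values — which
turns an 81-point grid from hours into seconds.

## Numerical and design choices

* Masses are neutral monoisotopic throughout; m/z only in isolation
  windows and feature averages (whose upstream definition we carry as an
  input field without recomputing).
* Decoys are seeded uniform residue shuffles, one per target,
  `DECOY_`-prefixed, equal database size.
* The spectrum dialect round-trips bit-exactly at 5 decimals for masses,
  2 for intensities; fragment lists are strictly increasing (exact
  duplicates dropped at generation).
* All randomness flows through `numpy` Generators seeded from explicit
  integers; every generator and benchmark is byte-reproducible per seed.
* Validation problem sizes (50–500 spectra, 50-protein proteome, 100-
  to 200-case oracle sweeps) are the package's chosen desk-scale study
  conditions; rates at these sizes carry binomial standard errors of a
  few percent, and statistical assertions use ±2 SE with a 1/n floor so
  all-zero rate comparisons remain well-defined.

## Known limitations

* No terminal truncations, multiple shifts per proteoform, PTM
  dictionaries, c/z (ETD) ions, internal fragments, or isotope-error
  enumeration beyond the 1.2 Da precursor window — and hence no
  truncation-mediated PSE channel (above).
* The binomial E-value is a surrogate; absolute E-values are not
  comparable to spectral-alignment engines, only their ordering and
  target/decoy symmetry are relied upon.
* At most two co-isolated precursors per spectrum; homogeneous
  multiplexed spectra (two proteoforms of the *same* protein) are not
  separable by this design.
* The simulator's i.i.d. fragment observation and uniform noise are
  idealizations; passing synthetic benchmarks demonstrates the logic of
  selection/subtraction/FDR, not performance on real instrument data.
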