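# Methods

## Energy model

The package operates on an additive real-space energy partition: for an
N-atom system, E_tot = Σ_A E_intra(A) + Σ_{A<B} V_inter(A,B). Pair
terms are stored once per *unordered* pair, so the factor ½ that
appears in the ordered-pair double sum of the IQA literature is
implicit — it exists there only to undo double counting, and adding it
here would be a bug. `TermKey` canonicalises pair order (atoms sorted
by element then index), making file orientation irrelevant.

The interatomic composition V_inter = V_cl + V_xc (+ V_D3) treats the
pairwise dispersion correction as just another interatomic term type:
it flows unchanged through validation, aggregation and REG. Profiles
without dispersion rows are legitimate inputs; missing V_D3 terms count
as zero and the validator notes this once per profile.

The charge-transfer/polarisation split V_ct = q_A q_B / r_AB,
V_pl = V_cl − V_ct uses user-supplied per-point charges (QTAIM-style
populations in real data) and positions; no charge model is computed
internally because that requires the wavefunction. The split is
algebraically exact by the remainder definition; in floating point the
re-summation V_ct + V_pl can differ from V_cl by one ulp of the larger
operand when |V_ct| ≫ |V_cl|, and tests check closure at that scale.

Fragment (IQF) terms between two disjoint atom groups are plain sums of
the member cross-pair terms; within-group pairs and group-internal
intra-atomic terms are not part of the between-group interaction.
Because space-filling basins leave no overlap to correct for, linearity
is exact: the REG value of a fragment term equals the sum of the member
atomistic REG values, which the tests verify in both orders
(aggregate-then-regress vs regress-then-sum). Fragment schemes require
pairwise-disjoint groups; published analyses whose lettered groups nest
(a singleton oxygen also sitting inside a larger shell) are expressed
as separate schemes, one per disjoint comparison.

## The REG statistic

For a segment of M ≥ 3 geometries, each term is regressed on the total
energy by ordinary least squares after mean-centring both series:
m_REG,i = cov(E_tot, E_i)/var(E_tot), computed as a quotient of inner
products of centred vectors. Properties that follow directly and are
enforced as tests:

- **Partition sum.** Σ_i m_REG,i = 1 over any complete additive
  partition (least squares is linear in the regressand).
- **Translation invariance.** Constant offsets to any term, or to
  E_tot, change nothing (mean-centring).
- **Scale covariance.** Scaling one term by λ (holding E_tot fixed as
  an independent input series) scales its slope by λ.

The control coordinate s never enters the numerics; it orders the
points and delimits segments only. The default segment is the whole
profile, matching the single TS → closed-conformer barrier analysed in
practice; multi-segment analyses pass explicit (start, stop) ranges and
no automatic critical-point detection is attempted. The sign
convention — positive REG favours the formation of the final-point
conformer — is a profile-ordering convention, documented rather than
enforced.

Diagnostics: Pearson R of (E_tot, E_i) over the same segment, R² = R²,
and an admissibility flag at R² ≥ 0.8 (the conventional linearity
threshold; configurable). Zero-variance terms get slope 0, R = NaN,
inadmissible. A zero-variance E_tot is a degenerate segment and an
error. Ranking is by slope, most positive first (rank 1); ties break
deterministically by term-type name then canonical participant order.

REG Ratios divide a positive reference (the most positive atomistic REG
value of the same system) by each REG value; the self-ratio is exactly
1, negative values give negative ratios, and entries with |REG| below a
floor (default 1e-6) are flagged unstable because the quotient is then
numerically meaningless. Reports round REG to 1 decimal, R to 2
decimals and ratios to the nearest integer (half-up, as in published
tables); full precision is retained internally and available via
`--full-precision`.

## Experiment comparison

Computed closed-minus-open conformer energy differences are benchmarked
against solvation-model-derived experimental values by RMSE and the
squared Pearson correlation (not regression through the origin), both
in kJ/mol. The NMR route to experiment is ΔG = −RT ln K with
K = [closed]/[open] and R = 8.31446 J mol⁻¹ K⁻¹. The shipped reference
table carries the four formamide-balance rows at printed precision;
from those columns the statistics evaluate to RMSE 4.0 and 1.4 kJ/mol
and R² 0.786 and 0.835. The corresponding published R² values (0.78,
0.84) were evidently computed from unrounded energies, so tests assert
agreement within one unit of the last printed digit rather than exact
reproduction after rounding. The same caveat applies to published
integer REG Ratios: recomputed from rounded REG values, most but not
all integers reproduce exactly, and tests pin down exactly the
reproducible ones.

## Synthetic data

The generator emulates the statistical structure the analysis relies
on, not the physics that produces it. Given n atoms and M points it
emits the complete partition (E_intra per atom; V_cl, V_xc, V_D3 per
pair) as E_i(s) = m_i·base(s) + c_i + ε_i(s), where:

- **base(s)** is the total-energy shape over s ∈ [0,1]: "barrier"
  (default) is a monotone quadratic decaying from the amplitude to 0 —
  transition state first, minimum last, matching the sign convention —
  "linear" decays linearly, or arbitrary samples may be passed.
  Default amplitude 0.02 hartree (~52 kJ/mol), a typical conformational
  rotation barrier.
- **m_i** are ground-truth slopes constrained to sum to 1; drawn
  N(1/K, 1/K) per term (K = term count) and renormalised when not
  prescribed.
- **c_i** are per-term offsets, N(0, 1e-2 hartree), present so that
  translation invariance is actually exercised.
- **ε_i** is N(0, σ) noise, mean-projected per point (column mean
  subtracted across terms) so the per-point sum of noise is exactly
  zero; the stored E_tot is the literal float sum of the terms, making
  the additive partition exact to the last bit despite noise. Without
  the projection, the partition-sum invariant Σ REG = 1 would hold only
  approximately.
- Default noise σ = 0 for exactness tests; recovery tests use
  σ ∈ {0, 1e-5, 1e-3} hartree and verify that mean slope-recovery
  error is nondecreasing in σ over 20 seeds each.

All randomness flows through numpy's default PCG64 generator seeded
explicitly; identical seeds give bit-identical profiles. Optional atom
tables place atoms on a jittered chain (2.5 bohr spacing) with N(0,
0.3 e) base charges plus small per-point drift — sufficient to exercise
the charge-transfer split, with no pretence of realistic geometry.

`generate_balance_like` builds a 12-atom amide/carbonyl-labelled system
with designated slopes (dominant positive amide pair +4.7, dominant
negative nitrogen steric −2.3, counterbalancing carbonyl pairs ±0.7,
small random remainder summing the partition to 1) and a fragment
scheme with singleton (A, B) and three-atom (E, F) groups, so ranked
tables, fragment aggregation and ratio reports all exercise realistic
shapes.

What passing on synthetic data does *not* show: anything about basin
integration error, functional choice, geometry relaxation artefacts or
the actual energetics of any molecule. The generator guarantees exact
additivity and known slopes; real partitioned data carry integration
noise (typically well above machine precision), which is why the
identity checks default to a 1e-8 hartree tolerance (configurable)
rather than the 1e-12 the generator satisfies.

## Numerical and interface choices

- Energies are stored and computed in hartree; reports convert with
  1 hartree = 2625.4996 kJ/mol where requested.
- Profile CSVs are written with 17 significant digits and read back
  with pandas' round-trip float parser, so write→read is bit-identical.
- Profiles with M < 3 are readable and writable (storage is agnostic)
  but rejected by the REG engine, which owns the statistical
  precondition.
- Validation is a reporting operation: it returns per-point residuals
  and flags rather than raising, so noisy real data can be inspected.
- Problem sizes in the default test run and the acceptance script
  (5–12 atoms, 8–21 points, 100 seeds for property sweeps) keep the
  whole suite in the seconds range while exercising every code path;
  the invariants tested are size-independent identities, so small
  systems lose no generality.
- CLI exit codes: 0 success, 2 input/schema error, 3 unmet statistical
  precondition, 4 internal inconsistency.

## Known limitations

- No parsing of wavefunction files, Gaussian logs or AIMAll outputs;
  converting such summaries into the CSV interchange schema is left to
  a thin external adapter.
- No multipolar (Taylor) expansion of V_cl; the monopolar
  charge-transfer split is the only electrostatic refinement.
- No automatic PES segmentation at critical points.
- Published REG tables are shipped at printed precision only, so
  derived quantities inherit last-digit rounding effects (documented
  above).
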