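# Methods

## Model

A metabolite with `C_Max` carbons observed on an isotope-resolving mass
spectrometer yields one intensity per ¹³C count, `I_M+0 … I_M+C_Max`.  The
model assumes: (i) every isotopologue peak is resolved and correctly
identified, so each index is a pure ¹²C/¹³C species; (ii) each of the
`C_Max − n` non-tracer carbons of a molecule with `n` tracer carbons is
independently ¹³C with probability `na` (the fractional natural abundance);
(iii) contributions from ¹⁴C and from minor isotopes of H, N, O, P and S are
negligible or resolved away, so carbon correction is a pure two-isotope
binomial problem.  Under (ii) the number of natural-abundance heavy atoms
added to an `n`-labeled molecule is Binomial(`C_Max − n`, `na`), giving the
redistribution weight

    B(n, k) = C(C_Max − n, k − n) · na^(k−n) · (1 − na)^(C_Max − k)

and the loss fraction `B_sum(n) = Σ_{k>n} B(n, k) = 1 − (1 − na)^(C_Max−n)`.
`B_sum` strictly decreases with `n` (the "tapering" of contamination as
fewer unlabeled carbons remain); at `n = C_Max` it is zero, so a fully
labeled spectrum is a fixed point of the correction.

The sequential correction inverts the forward model in ascending mass
order; the forward (contamination) transform is its exact algebraic
inverse.  Both are linear and scale-invariant: intensities may be raw or
fractional, and output is reported on the scale of the summed observed
intensities (`normalization_basis`).

Nitrogen labeling is the identical model with `N_Max`/`na_15N`
substituted.  Dual ¹³C/¹⁵N labeling factorizes, because the two elements'
natural abundances act independently: each matrix cell `(x, y)` spreads
with weight `B_C(x, i) · B_N(y, j)`, so the 2-D transform is the 1-D carbon
transform along columns composed with the nitrogen transform along rows,
and its inverse is two triangular solves evaluated row-major ascending.

## Iterative algorithm

Real observed sets have missing (sub-detection) peaks and noise-induced
inconsistencies.  Each iteration runs:

1. **supplement** — missing entries are filled with 0 on the first pass and
   with the previous iteration's recalculated contaminated intensity
   thereafter; present entries are never altered;
2. **correct** — the single-pass sequential (or dual) correction;
3. **flatten** — negative corrected intensities are clipped to zero (they
   have no physical meaning; they arise from measurement error);
4. **renormalize** — the corrected set is rescaled so its total equals the
   sum of the *originally observed* entries (supplemented values are model
   echoes and do not enter the basis);
5. **contaminate** — the forward model recomputes expected observed
   intensities;
6. **residual** — the aggregate |observed − recalculated| over genuinely
   observed entries.

An iteration is accepted only if its residual strictly decreases; the loop
returns the last improving state, with a hard cap of 100 iterations
(`converged=False` if the cap stops a still-improving run; real cases
converge in well under 10).  On complete, self-consistent input the loop
reduces to the single-pass correction accepted at iteration 1.

The residual doubles as an independent quality-control score: natural
abundance couples all isotopologues of a metabolite, so the score is
sensitive to error anywhere in the set and vanishes only for exactly
self-consistent data.  No accept/reject threshold is imposed — the score is
reported, interpretation is the analyst's.

### Design choices where the procedure was open

- **Convergence test**: no numeric tolerance — terminate on the first
  non-improving iteration.  The residual aggregation is L1 by default
  (`linf` available); supplemented indices are excluded from it.
- **First-pass seed for missing peaks**: 0, since no model estimate exists
  yet; the first pass generates the estimate used thereafter.
- **Order of step 3 and 4**: flatten, then renormalize.
- **Renormalization basis**: the sum of originally observed entries only.
  A consequence worth knowing: if a *large* peak is missing, the corrected
  total is pinned to the deficient observed total, so compensation is
  partial by construction; recovery is accurate when missing peaks are
  weak — which is the realistic case, since peaks go missing by falling
  below the detection limit.
- **Explicit zeros vs missing**: an explicitly present zero intensity is
  observed data and is never supplemented; only absent indices are missing.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `na_13c` | fractional ¹³C natural abundance | 0.01109 (overridable) |
| `na_15n` | fractional ¹⁵N natural abundance | none — must be set explicitly; `NA_15N_IUPAC = 0.00364` is the documented choice |
| `precision_mode` | `double` or `extended` | `double` |
| `max_iterations` | iteration cap | 100 |
| `residual_norm` | `l1` or `linf` | `l1` |

Nitrogen modes refuse to run without an explicit abundance because the
appropriate ¹⁵N value is source-dependent and silently assuming one would
bias every corrected intensity.

## Numerical choices

- Binomial terms are built by a multiplicative row recurrence
  (`B(n, k+1) = B(n, k) · na/(1−na) · (C_Max−k)/(k−n+1)` from the diagonal
  `B(n, n) = (1−na)^(C_Max−n)`), so no factorial or bare binomial
  coefficient is ever formed.
- The diagonal weight used by both transforms is `1 − B_sum(n)` with
  `B_sum` obtained by summing the off-diagonal terms, which makes
  correct/contaminate exact algebraic inverses and every redistribution row
  sum to exactly 1 in working precision; the closed form
  `1 − (1−na)^(C_Max−n)` is verified in tests instead.
- Double mode is limited to `C_Max ≤ 269`; beyond that the dynamic range of
  the terms exceeds 64-bit floats and a capability error names the limit.
  Extended mode (mpmath, 50 decimal digits) lifts it; a 500-carbon round
  trip stays below 10⁻¹² relative error.  Terms below the double underflow
  threshold flush to zero in double mode, which does not affect round-trip
  exactness.
- Single-label correction is a forward substitution (triangular solve),
  which is precisely the ascending-order sequential evaluation; dual-label
  correction is two such solves.
- Degenerate inputs (all-missing, all-zero, zero-sum after flattening)
  raise a dedicated error rather than returning NaNs.

## Synthetic data

The generator produces delta-mixture labeling patterns — a chosen fraction
of molecules at each tracer count — and their contaminated counterparts.
Built-in scenarios for a 20-carbon metabolite: `unlabeled-20c` (all
intensity at count 0; correction must collapse the contaminated spectrum
back to a single monoisotopic peak), `mixed-8-10-12` (equal thirds at 8, 10
and 12 labeled carbons, showing the tapering phenomenon), and
`fully-labeled-20c` (fixed point).  `lipid-42c` is a *synthetic* 42-carbon
lipid-like pattern with equal fractions at counts 0–4 and 16–20, standing
in for a real phosphatidylcholine-style measurement: low counts mimic
labeled-glycerol/head-group incorporation and 16–20 mimic fatty-acid acetyl
incorporation.  Noise for robustness and QC tests is uniform multiplicative
(±5% by default in tests), seeded and reproducible.

What the generator does *not* emulate: peak shapes, m/z axes, resolution or
assignment errors, detector saturation, or correlated noise between
isotopologues.  Passing tests therefore demonstrate the correctness of the
correction mathematics and the behavior of the iteration under idealized
missingness and simple noise — not robustness to misassigned peaks or
structured instrumental error, which are upstream concerns.

An independent brute-force oracle validates the analytic transforms: it
enumerates the binomial mass function per label count with exact integer
coefficients (`math.comb`) and plain powers, sharing no code with the
production path, and agrees with it to ≤ 10⁻¹² relative error on random
spectra (element maxima up to 40; dual label up to 12 × 6).

## Problem sizes used in the test suite

The robustness sweep exercises every `C_Max` from 1 to 269 in double mode
with three-component labeling patterns; extended mode is exercised at
`C_Max = 500`.  Oracle equivalence uses 1000 random spectra (800 single-
label, 200 dual).  These sizes keep the full suite at a few seconds while
covering the entire supported double-precision range.

## Known limitations

- Only C and N labeling, at most two simultaneous labels; other elements'
  minor isotopes are assumed resolved away upstream.
- Dual-label transforms run in double mode only (extended precision is
  single-label; dual matrices of that size do not arise in practice).
- No statistical error propagation through the correction; the residual is
  reported as a raw QC signal without an accept/reject threshold.
- Peak picking, m/z assignment and formula identification are out of
  scope: inputs are already-identified isotopologue intensity tables.
- Trailing unobserved isotopologues matter: if `--cmax` is omitted, the
  largest observed index is used and a warning is issued, because the
  correction depends on the true carbon count.
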