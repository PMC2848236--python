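"""Natural-abundance correction for isotope-resolved isotopologue intensities.

Ultra-high-resolution FT-ICR mass spectrometry resolves and identifies the
individual isotopologue peaks of a metabolite — the species carrying 0, 1, 2,
... heavy atoms of a tracer isotope (¹³C and/or ¹⁵N).  In a stable-isotope
tracing experiment the observed intensity at each label count mixes two
sources: atoms incorporated from the enriched precursor, and atoms that are
heavy simply because of the isotope's natural abundance (NA).  Because every
peak is isotopically resolved and identified, removing the NA contribution
(deisotoping) is analytically solvable: the intensity a molecule with ``n``
tracer-derived heavy atoms contributes to the peak at total count ``k`` is a
single binomial term

    B(n, k) = C(M - n, k - n) * na**(k - n) * (1 - na)**(M - k)

where ``M`` is the number of atoms of that element in the molecule, ``na`` the
fractional natural abundance, and ``C`` the binomial coefficient.  Correction
subtracts, in ascending mass order, the contamination leaked from every
lower-count isotopologue and rescales by the retained fraction
``1 - B_sum(i)``; the forward (contamination) model is its exact algebraic
inverse.  Dual ¹³C/¹⁵N labeling factorizes into a product of one carbon and
one nitrogen binomial term per matrix cell.

On top of the single-pass transforms sits an iterative loop that copes with
real data: missing isotopologue peaks are supplemented from the previous
iteration's forward model, small negative corrected intensities (noise
artifacts) are flattened to zero, the corrected set is renormalized to the
observed total, and iteration continues while the L1 discrepancy between
observed and re-contaminated intensities keeps shrinking.  That residual
doubles as an independent quality-control score for the observed set.

This module is organised in the order the method runs: constants and domain
types, the binomial table, single-pass correct/contaminate (single and dual
label), the iterative algorithm, synthetic-data generation with brute-force
oracles, and delimited-table IO.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import mpmath
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

__all__ = [
    "NA_13C_DEFAULT",
    "NA_15N_IUPAC",
    "DOUBLE_MODE_MAX_ELEMENTS",
    "CorrectionError",
    "CapabilityError",
    "DegenerateInputError",
    "CorrectionConstants",
    "IsotopologueSpectrum",
    "BinomialTable",
    "binomial_term",
    "loss_fraction_sum",
    "build_binomial_table",
    "correct_sequential",
    "contaminate_sequential",
    "correct_dual",
    "contaminate_dual",
    "CorrectionResult",
    "supplement_missing",
    "flatten_negatives",
    "renormalize",
    "iterative_correct",
    "quality_residual",
    "LabelingScenario",
    "BUILTIN_SCENARIOS",
    "get_scenario",
    "generate_clean_spectrum",
    "brute_force_contaminate",
    "perturb_spectrum",
    "IsotopologueTable",
    "read_table",
    "write_table",
    "write_result",
]

logger = logging.getLogger("nacorr")

# --------------------------------------------------------------------------
# Constants and configuration
# --------------------------------------------------------------------------

#: Fractional natural abundance of ¹³C used throughout unless overridden.
NA_13C_DEFAULT = 0.01109

#: IUPAC representative fractional natural abundance of ¹⁵N.  Nitrogen modes
#: never assume this silently: ``CorrectionConstants.na_15n`` defaults to
#: ``None`` and must be set explicitly (pass this constant to accept it).
NA_15N_IUPAC = 0.00364

#: Largest element count supported in double-precision mode.  Beyond this the
#: dynamic range of the binomial terms exceeds what 64-bit floats represent
#: reliably; use ``precision_mode="extended"``.
DOUBLE_MODE_MAX_ELEMENTS = 269

#: Decimal digits carried by the extended (arbitrary-precision) mode.
EXTENDED_MODE_DPS = 50

#: Iteration cap of the iterative algorithm (real cases converge in <10).
DEFAULT_MAX_ITERATIONS = 100


class CorrectionError(ValueError):
    """Invalid argument or inconsistent inputs to a correction operation."""


class CapabilityError(CorrectionError):
    """Requested computation exceeds the active precision mode's limit."""


class DegenerateInputError(CorrectionError):
    """Spectrum carries no usable intensity (empty, all-missing, all-zero)."""


@dataclass(frozen=True)
class CorrectionConstants:
    """Natural-abundance fractions and the numeric-precision mode.

    Parameters
    ----------
    na_13c :
        Fractional natural abundance of ¹³C, in [0, 0.5).
    na_15n :
        Fractional natural abundance of ¹⁵N, or ``None`` (the default).
        Nitrogen correction refuses to run until a value is set explicitly;
        :data:`NA_15N_IUPAC` is the documented choice.
    precision_mode :
        ``"double"`` (64-bit floats, element counts up to
        :data:`DOUBLE_MODE_MAX_ELEMENTS`) or ``"extended"`` (arbitrary
        precision via mpmath, no practical size limit).
    """

    na_13c: float = NA_13C_DEFAULT
    na_15n: float | None = None
    precision_mode: str = "double"

    def __post_init__(self) -> None:
        for name, value in (("na_13c", self.na_13c), ("na_15n", self.na_15n)):
            if value is None:
                continue
            if not (0.0 <= value < 0.5):
                raise CorrectionError(
                    f"{name} must be a fraction in [0, 0.5); got {value!r}"
                )
        if self.precision_mode not in ("double", "extended"):
            raise CorrectionError(
                f"precision_mode must be 'double' or 'extended'; "
                f"got {self.precision_mode!r}"
            )

    def require_nitrogen(self) -> float:
        """Return ``na_15n``, refusing if it was never set explicitly."""
        if self.na_15n is None:
            raise CorrectionError(
                "nitrogen correction requires an explicit na_15n value "
                "(e.g. the IUPAC constant NA_15N_IUPAC = 0.00364); none was set"
            )
        return self.na_15n


@dataclass
class IsotopologueSpectrum:
    """Isotopologue intensities for one metabolite, indexed by label count.

    ``intensities`` is a 1-D vector of length ``C_Max + 1`` (or ``N_Max + 1``)
    for single-label data, or a ``(C_Max + 1, N_Max + 1)`` matrix for dual
    ¹³C/¹⁵N labeling.  ``NaN`` marks a missing (unobserved) isotopologue —
    distinct from an observed zero.  ``element_maxima`` maps element symbol
    ("C", "N") to atom count; ``normalization_basis`` is the total intensity
    scale (by convention the sum of observed entries).
    """

    intensities: np.ndarray
    element_maxima: dict[str, int]
    normalization_basis: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim not in (1, 2):
            raise CorrectionError("intensities must be a 1-D vector or 2-D matrix")
        expected = tuple(m + 1 for m in self.element_maxima.values())
        if self.intensities.ndim != len(expected):
            raise CorrectionError(
                f"{self.intensities.ndim}-D intensities inconsistent with "
                f"element_maxima {self.element_maxima}"
            )
        if self.intensities.shape != expected:
            raise CorrectionError(
                f"intensity shape {self.intensities.shape} does not match "
                f"element maxima {self.element_maxima} (expected {expected})"
            )
        present = self.intensities[~np.isnan(self.intensities)]
        if present.size and (present < 0).any():
            raise CorrectionError("observed intensities must be non-negative")

    @property
    def is_dual(self) -> bool:
        return self.intensities.ndim == 2

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.intensities)

    def observed_sum(self) -> float:
        return float(np.nansum(self.intensities))


# --------------------------------------------------------------------------
# Core math: binomial table
# --------------------------------------------------------------------------


def _as_number(value, extended: bool):
    return mpmath.mpf(value) if extended else float(value)


def binomial_term(n: int, k: int, element_max: int, na: float) -> float:
    """Fraction of intensity with ``n`` tracer atoms observed at count ``k``.

    ``B(n, k) = C(M - n, k - n) * na**(k - n) * (1 - na)**(M - k)`` for a
    molecule with ``M = element_max`` atoms of the element: the probability
    that natural abundance adds exactly ``k - n`` heavy atoms among the
    ``M - n`` unlabeled positions.

    Parameters are validated: requires ``0 <= n <= k <= element_max`` and
    ``0 <= na < 1``.
    """
    if not (0 <= n <= k <= element_max):
        raise CorrectionError(
            f"require 0 <= n <= k <= element_max; got n={n}, k={k}, "
            f"element_max={element_max}"
        )
    if not (0.0 <= na < 1.0):
        raise CorrectionError(f"natural abundance must be in [0, 1); got {na}")
    m, j = element_max - n, k - n
    # multiplicative accumulation: C(m, j) * na**j built one factor at a time,
    # never forming the (potentially astronomically large) coefficient alone
    term = (1.0 - na) ** (element_max - k)
    for step in range(1, j + 1):
        term *= na * (m - step + 1) / step
    return term


def loss_fraction_sum(n: int, element_max: int, na: float) -> float:
    """Fraction of intensity at label count ``n`` leaked to higher counts.

    ``B_sum(n) = sum_{k=n+1..M} B(n, k)``; equals ``1 - (1 - na)**(M - n)``
    up to rounding.  Zero at ``n = element_max`` (no atoms left to gain).
    """
    if not (0 <= n <= element_max):
        raise CorrectionError(
            f"require 0 <= n <= element_max; got n={n}, element_max={element_max}"
        )
    return float(
        sum(binomial_term(n, k, element_max, na) for k in range(n + 1, element_max + 1))
    )


@dataclass
class BinomialTable:
    """Precomputed binomial terms ``B(n, k)`` and loss sums for one element.

    ``terms`` is an upper-triangular ``(M+1, M+1)`` array (``float64`` in
    double mode, ``object`` holding ``mpmath.mpf`` in extended mode);
    ``loss_sums[n]`` is the summed off-diagonal mass of row ``n``.  The
    diagonal satisfies ``terms[n, n] = (1 - na)**(M - n)`` and every row sums
    to 1: contamination redistributes intensity, it never creates or destroys
    it.
    """

    element_max: int
    abundance: float
    terms: np.ndarray
    loss_sums: np.ndarray
    precision_mode: str = "double"

    @property
    def extended(self) -> bool:
        return self.precision_mode == "extended"

    def retained_fraction(self, n: int):
        """``1 - B_sum(n)``: the diagonal weight used by both transforms."""
        one = _as_number(1, self.extended)
        return one - self.loss_sums[n]


def build_binomial_table(
    element_max: int,
    na: float,
    precision_mode: str = "double",
) -> BinomialTable:
    """Precompute all ``B(n, k)`` terms and loss sums for one element.

    Rows are filled by the recurrence
    ``B(n, k+1) = B(n, k) * na / (1 - na) * (M - k) / (k - n + 1)``
    starting from the diagonal ``B(n, n) = (1 - na)**(M - n)``, so no
    factorial is ever formed.  Double mode is limited to
    ``element_max <= DOUBLE_MODE_MAX_ELEMENTS``; extended mode carries
    ``EXTENDED_MODE_DPS`` decimal digits and has no practical limit.
    """
    if element_max < 0:
        raise CorrectionError(f"element_max must be >= 0; got {element_max}")
    if not (0.0 <= na < 1.0):
        raise CorrectionError(f"natural abundance must be in [0, 1); got {na}")
    if precision_mode not in ("double", "extended"):
        raise CorrectionError(f"unknown precision_mode {precision_mode!r}")
    extended = precision_mode == "extended"
    if not extended and element_max > DOUBLE_MODE_MAX_ELEMENTS:
        raise CapabilityError(
            f"element_max={element_max} exceeds the "
            f"{DOUBLE_MODE_MAX_ELEMENTS}-element limit of double-precision "
            f"mode; use precision_mode='extended'"
        )

    size = element_max + 1
    if extended:
        with mpmath.workdps(EXTENDED_MODE_DPS):
            na_x = mpmath.mpf(repr(na))
            one = mpmath.mpf(1)
            terms = np.zeros((size, size), dtype=object)
            loss = np.zeros(size, dtype=object)
            for n in range(size):
                value = (one - na_x) ** (element_max - n)
                terms[n, n] = value
                row_loss = mpmath.mpf(0)
                for k in range(n, element_max):
                    value = value * na_x / (one - na_x) * (element_max - k)
                    value /= k - n + 1
                    terms[n, k + 1] = value
                    row_loss += value
                loss[n] = row_loss
    else:
        terms = np.zeros((size, size))
        loss = np.zeros(size)
        for n in range(size):
            m = element_max - n
            if m == 0:
                terms[n, n] = 1.0
                continue
            # cumulative product of per-step ratios off the diagonal start
            steps = np.arange(1, m + 1)
            ratios = na / (1.0 - na) * (m - steps + 1) / steps
            row = (1.0 - na) ** m * np.concatenate(([1.0], np.cumprod(ratios)))
            terms[n, n:] = row
            loss[n] = row[1:].sum()
    return BinomialTable(
        element_max=element_max,
        abundance=na,
        terms=terms,
        loss_sums=loss,
        precision_mode=precision_mode,
    )


def _check_vector(values: np.ndarray, table: BinomialTable) -> None:
    if values.ndim != 1:
        raise CorrectionError("expected a 1-D intensity vector")
    if values.shape[0] != table.element_max + 1:
        raise CorrectionError(
            f"spectrum length {values.shape[0]} does not match table for "
            f"element_max={table.element_max} (expected {table.element_max + 1})"
        )
    if np.isnan(values.astype(float, copy=False) if values.dtype != object else
                np.array([float(v) for v in values])).any():
        raise CorrectionError(
            "spectrum contains missing entries; supplement them first "
            "(iterative_correct handles partial spectra)"
        )


def _weight_matrix(table: BinomialTable) -> np.ndarray:
    """Off-diagonal terms with diagonal replaced by the retained fraction.

    Using ``1 - loss_sums`` (the summed complement) rather than the closed
    form keeps correct/contaminate exact algebraic inverses of each other and
    makes each row sum to exactly 1 in the working precision.
    """
    w = table.terms.copy()
    size = table.element_max + 1
    for n in range(size):
        w[n, n] = table.retained_fraction(n)
    return w


def _spectrum_values(spectrum) -> np.ndarray:
    if isinstance(spectrum, IsotopologueSpectrum):
        return spectrum.intensities
    return np.asarray(spectrum)


# --------------------------------------------------------------------------
# Core math: single-pass transforms (single label)
# --------------------------------------------------------------------------


def correct_sequential(observed, table: BinomialTable) -> np.ndarray:
    """Remove natural-abundance contamination from a complete vector.

    Applies, in strictly ascending label-count order,

        I[i] = (I_NA[i] - sum_{x<i} I[x] * B(x, i)) / (1 - B_sum(i))

    i.e. subtracts the contamination leaked into peak ``i`` by every already
    corrected lower peak, then rescales by the fraction peak ``i`` retained.
    The output may contain small negative entries on noisy input; flattening
    them is the iterative layer's job.
    """
    values = _spectrum_values(observed)
    _check_vector(values, table)
    w = _weight_matrix(table)
    if table.extended:
        with mpmath.workdps(EXTENDED_MODE_DPS):
            vals = [
                v if isinstance(v, mpmath.mpf) else mpmath.mpf(repr(float(v)))
                for v in values
            ]
            out = [mpmath.mpf(0)] * len(vals)
            for i in range(len(vals)):
                acc = vals[i]
                for x in range(i):
                    acc -= out[x] * w[x, i]
                out[i] = acc / w[i, i]
            return np.array(out, dtype=object)
    values = np.asarray(values, dtype=float)
    # forward substitution on the transposed (lower-triangular) weight matrix
    # is exactly the ascending-order sequential evaluation
    return solve_triangular(w.T, values, lower=True)


def contaminate_sequential(corrected, table: BinomialTable) -> np.ndarray:
    """Forward model: add natural-abundance contamination to a clean vector.

    ``I_NA[i] = I[i] * (1 - B_sum(i)) + sum_{x<i} I[x] * B(x, i)`` — the exact
    algebraic inverse of :func:`correct_sequential`.  Total intensity is
    conserved because every row of the weight matrix sums to 1.
    """
    values = _spectrum_values(corrected)
    _check_vector(values, table)
    w = _weight_matrix(table)
    if table.extended:
        with mpmath.workdps(EXTENDED_MODE_DPS):
            vals = [
                v if isinstance(v, mpmath.mpf) else mpmath.mpf(repr(float(v)))
                for v in values
            ]
            out = []
            for k in range(len(vals)):
                out.append(sum((vals[x] * w[x, k] for x in range(k + 1)),
                               mpmath.mpf(0)))
            return np.array(out, dtype=object)
    return np.asarray(values, dtype=float) @ w


# --------------------------------------------------------------------------
# Core math: single-pass transforms (dual ¹³C/¹⁵N label)
# --------------------------------------------------------------------------


def _check_matrix(values, carbon: BinomialTable, nitrogen: BinomialTable) -> None:
    if values.ndim != 2:
        raise CorrectionError("dual-label operations expect a 2-D matrix")
    expected = (carbon.element_max + 1, nitrogen.element_max + 1)
    if values.shape != expected:
        raise CorrectionError(
            f"matrix shape {values.shape} does not match tables "
            f"(expected {expected})"
        )
    if np.isnan(np.asarray(values, dtype=float)).any():
        raise CorrectionError("matrix contains missing entries; supplement first")


def contaminate_dual(
    corrected, carbon_table: BinomialTable, nitrogen_table: BinomialTable
) -> np.ndarray:
    """Forward model for dual ¹³C/¹⁵N labeling.

    Each clean cell ``(x, y)`` spreads over cells ``(i >= x, j >= y)`` with
    weight ``B_C(x, i) * B_N(y, j)`` — carbon and nitrogen natural abundance
    act independently, so the 2-D kernel is the outer product of the two 1-D
    kernels and the transform factorizes into a row pass and a column pass.
    """
    values = np.asarray(_spectrum_values(corrected), dtype=float)
    _check_matrix(values, carbon_table, nitrogen_table)
    wc = _weight_matrix(carbon_table)
    wn = _weight_matrix(nitrogen_table)
    if carbon_table.extended or nitrogen_table.extended:
        raise CorrectionError("dual-label transforms support double mode only")
    return wc.T @ values @ wn


def correct_dual(
    observed, carbon_table: BinomialTable, nitrogen_table: BinomialTable
) -> np.ndarray:
    """Remove carbon and nitrogen natural abundance from a dual-label matrix.

    Evaluated row-major ascending so that every cell ``(x, y)`` with
    ``x <= i, y <= j`` precedes ``(i, j)``:

        I[i,j] = (I_NA[i,j] - sum_{(x,y)<(i,j)} I[x,y] B_C(x,i) B_N(y,j))
                 / (B_C(i,i) B_N(j,j))

    Implemented as two triangular solves (the exact inverse of the factorized
    forward model); ``N_Max = 0`` reduces to :func:`correct_sequential`.
    """
    values = np.asarray(_spectrum_values(observed), dtype=float)
    _check_matrix(values, carbon_table, nitrogen_table)
    if carbon_table.extended or nitrogen_table.extended:
        raise CorrectionError("dual-label transforms support double mode only")
    wc = _weight_matrix(carbon_table)
    wn = _weight_matrix(nitrogen_table)
    half = solve_triangular(wc.T, values, lower=True)
    return solve_triangular(wn.T, half.T, lower=True).T


# --------------------------------------------------------------------------
# Iterative algorithm: supplement -> correct -> flatten -> renormalize ->
# contaminate -> residual, while the residual keeps improving
# --------------------------------------------------------------------------


@dataclass
class CorrectionResult:
    """Outcome of :func:`iterative_correct`.

    ``corrected`` holds the non-negative corrected intensities;
    ``recalculated_observed`` is the forward model applied to them (the basis
    of the quality residual); ``residual`` the aggregate observed-vs-
    recalculated discrepancy over genuinely observed entries at the accepted
    iteration; ``flattened_indices``/``supplemented_indices`` record which
    entries were clipped at zero or filled in.  ``converged`` is False only
    when the iteration cap stopped an otherwise still-improving loop.
    """

    corrected: np.ndarray
    recalculated_observed: np.ndarray
    iterations: int
    residual: float
    flattened_indices: tuple
    supplemented_indices: tuple
    converged: bool
    residual_norm: str = "l1"
    residual_history: list[float] = field(default_factory=list)
    element_maxima: dict[str, int] = field(default_factory=dict)
    normalization_basis: float = 0.0


def supplement_missing(
    observed: np.ndarray, current_estimate: np.ndarray | None = None
) -> tuple[np.ndarray, tuple]:
    """Fill missing (NaN) entries of a partial spectrum.

    On the first iteration (no estimate yet) missing entries are seeded with
    0; on later iterations they take the previous iteration's recalculated
    contaminated intensity.  Present entries are never altered.  Returns the
    completed array and the sorted tuple of filled indices (ints for vectors,
    ``(i, j)`` pairs for matrices).
    """
    observed = np.asarray(observed, dtype=float)
    missing = np.isnan(observed)
    present = observed[~missing]
    if present.size == 0 or not (present > 0).any():
        raise DegenerateInputError(
            "spectrum has no positive observed intensity to correct"
        )
    filled = observed.copy()
    if current_estimate is None:
        filled[missing] = 0.0
    else:
        estimate = np.asarray(current_estimate, dtype=float)
        if estimate.shape != observed.shape:
            raise CorrectionError("estimate shape does not match observed")
        filled[missing] = estimate[missing]
    if observed.ndim == 1:
        indices = tuple(int(i) for i in np.flatnonzero(missing))
    else:
        indices = tuple((int(i), int(j)) for i, j in np.argwhere(missing))
    return filled, indices


def flatten_negatives(spectrum: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Clip negative intensities to zero; they have no physical meaning.

    Returns the clipped array and the sorted tuple of indices that changed.
    """
    values = np.asarray(spectrum, dtype=float)
    negative = values < 0
    out = np.where(negative, 0.0, values)
    if values.ndim == 1:
        indices = tuple(int(i) for i in np.flatnonzero(negative))
    else:
        indices = tuple((int(i), int(j)) for i, j in np.argwhere(negative))
    return out, indices


def renormalize(spectrum: np.ndarray, basis: float) -> np.ndarray:
    """Rescale so the total equals ``basis`` (the observed-intensity sum).

    Needed because supplementation and flattening perturb the total.  A
    zero-sum spectrum (everything flattened away) is degenerate.
    """
    values = np.asarray(spectrum, dtype=float)
    total = values.sum()
    if not basis > 0:
        raise DegenerateInputError(f"normalization basis must be > 0; got {basis}")
    if not total > 0:
        raise DegenerateInputError(
            "spectrum sums to zero after flattening; nothing to renormalize"
        )
    return values * (basis / total)


def _residual(observed, recalculated, mask, norm: str) -> float:
    diff = np.abs(np.asarray(observed, dtype=float) - recalculated)[mask]
    if norm == "l1":
        return float(diff.sum())
    if norm == "linf":
        return float(diff.max()) if diff.size else 0.0
    raise CorrectionError(f"unknown residual norm {norm!r}; use 'l1' or 'linf'")


def _tables_for(
    element_maxima: Mapping[str, int], constants: CorrectionConstants
) -> list[BinomialTable]:
    tables = []
    for element, maximum in element_maxima.items():
        if element == "C":
            na = constants.na_13c
        elif element == "N":
            na = constants.require_nitrogen()
        else:
            raise CorrectionError(
                f"unsupported element {element!r}; only C and N labeling is handled"
            )
        tables.append(build_binomial_table(maximum, na, constants.precision_mode))
    return tables


def iterative_correct(
    observed,
    element_maxima: Mapping[str, int] | int,
    constants: CorrectionConstants | None = None,
    *,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    residual_norm: str = "l1",
) -> CorrectionResult:
    """Full iterative natural-abundance correction of a (possibly partial)
    observed isotopologue spectrum.

    Each iteration runs: supplement missing peaks (first pass with zeros,
    thereafter with the previous forward-model estimate) → single-pass
    correction → flatten negatives → renormalize to the observed total →
    forward-contaminate → measure the residual against the genuinely observed
    entries.  The loop accepts an iteration only if its residual strictly
    decreases and returns the last improving state; a hard cap guards
    termination.  On complete, self-consistent input this reduces to the
    single-pass correction accepted at iteration 1.

    Parameters
    ----------
    observed :
        1-D vector (single label) or 2-D matrix (dual ¹³C/¹⁵N), NaN = missing.
    element_maxima :
        ``{"C": c_max}``, ``{"N": n_max}`` or ``{"C": ..., "N": ...}``; a bare
        int means carbon.
    constants :
        Abundances and precision mode; defaults to ¹³C at 0.01109, double.
    """
    if constants is None:
        constants = CorrectionConstants()
    if isinstance(element_maxima, int):
        element_maxima = {"C": element_maxima}
    element_maxima = dict(element_maxima)

    if isinstance(observed, IsotopologueSpectrum):
        observed = observed.intensities
    observed = np.asarray(observed, dtype=float)
    expected = tuple(m + 1 for m in element_maxima.values())
    if observed.shape != expected:
        raise CorrectionError(
            f"observed shape {observed.shape} inconsistent with element maxima "
            f"{element_maxima} (expected {expected})"
        )

    tables = _tables_for(element_maxima, constants)
    dual = observed.ndim == 2
    if dual and len(tables) != 2:
        raise CorrectionError("dual-label input needs both C and N maxima")

    def _correct(vec):
        return correct_dual(vec, *tables) if dual else correct_sequential(vec, tables[0])

    def _contaminate(vec):
        return (
            contaminate_dual(vec, *tables) if dual
            else contaminate_sequential(vec, tables[0])
        )

    mask = ~np.isnan(observed)
    basis = float(observed[mask].sum()) if mask.any() else 0.0
    if not basis > 0:
        raise DegenerateInputError(
            "spectrum has no positive observed intensity to correct"
        )

    extended = constants.precision_mode == "extended"
    estimate: np.ndarray | None = None
    best: CorrectionResult | None = None
    previous = math.inf
    history: list[float] = []
    converged = False

    for iteration in range(1, max_iterations + 1):
        filled, supplemented = supplement_missing(observed, estimate)
        corrected = _correct(filled)
        if extended:
            corrected = np.array([float(v) for v in corrected])
        corrected, flattened = flatten_negatives(corrected)
        corrected = renormalize(corrected, basis)
        recalculated = _contaminate(corrected)
        if extended:
            recalculated = np.array([float(v) for v in recalculated])
        residual = _residual(observed, recalculated, mask, residual_norm)
        logger.debug(
            "iteration %d: residual=%.6e (%s)", iteration, residual, residual_norm
        )
        if residual < previous:
            history.append(residual)
            best = CorrectionResult(
                corrected=corrected,
                recalculated_observed=recalculated,
                iterations=iteration,
                residual=residual,
                flattened_indices=flattened,
                supplemented_indices=supplemented,
                converged=True,
                residual_norm=residual_norm,
                residual_history=history,
                element_maxima=element_maxima,
                normalization_basis=basis,
            )
            previous = residual
            estimate = recalculated
            if residual == 0.0:
                converged = True
                break
        else:
            converged = True
            break
    else:
        converged = best is not None and len(history) < max_iterations
    assert best is not None  # basis > 0 guarantees at least one accepted pass
    if not converged and len(history) == max_iterations:
        best.converged = False
        logger.warning(
            "iterative correction still improving at the %d-iteration cap "
            "(residual %.3e)", max_iterations, best.residual,
        )
    logger.info(
        "converged=%s after %d iteration(s), residual=%.3e",
        best.converged, best.iterations, best.residual,
    )
    return best


def quality_residual(observed, result: CorrectionResult) -> float:
    """Aggregate |observed − recalculated| over genuinely observed entries.

    The forward model couples all isotopologues of a metabolite through
    natural abundance, so this discrepancy is sensitive to errors anywhere in
    the observed set and serves as an independent quality-control score: it
    is zero iff the observed intensities are exactly self-consistent.
    Supplemented entries are excluded — they echo the model, not the data.
    """
    if isinstance(observed, IsotopologueSpectrum):
        observed = observed.intensities
    observed = np.asarray(observed, dtype=float)
    mask = ~np.isnan(observed)
    return _residual(observed, result.recalculated_observed, mask,
                     result.residual_norm)


# --------------------------------------------------------------------------
# Synthetic data: labeling scenarios and brute-force oracles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelingScenario:
    """A clean (pre-contamination) labeling pattern for one metabolite.

    ``labeled_fractions`` places a fraction of the total intensity at each
    label count (int for single label, ``(c, n)`` pair for dual); fractions
    must be non-negative and sum to 1.
    """

    name: str
    element_maxima: Mapping[str, int]
    labeled_fractions: Mapping[int | tuple[int, int], float]
    constants: CorrectionConstants = field(default_factory=CorrectionConstants)

    def __post_init__(self) -> None:
        fracs = dict(self.labeled_fractions)
        if not fracs:
            raise CorrectionError("scenario needs at least one labeled fraction")
        values = np.array(list(fracs.values()), dtype=float)
        if (values < 0).any():
            raise CorrectionError("labeled fractions must be non-negative")
        if abs(values.sum() - 1.0) > 1e-12:
            raise CorrectionError(
                f"labeled fractions must sum to 1; got {values.sum()!r}"
            )
        maxima = list(self.element_maxima.values())
        for count in fracs:
            idx = (count,) if isinstance(count, int) else tuple(count)
            if len(idx) != len(maxima):
                raise CorrectionError(
                    f"label count {count!r} does not match element_maxima"
                )
            for c, m in zip(idx, maxima):
                if not (0 <= c <= m):
                    raise CorrectionError(
                        f"label count {count!r} outside 0..{m}"
                    )


def _builtin_scenarios() -> dict[str, LabelingScenario]:
    c20 = {"C": 20}
    return {
        # 20-carbon metabolite with no tracer incorporation: every observed
        # heavy isotopologue is pure natural abundance and correction must
        # collapse the spectrum to the monoisotopic peak
        "unlabeled-20c": LabelingScenario("unlabeled-20c", c20, {0: 1.0}),
        # equal thirds labeled at 8, 10 and 12 carbons: shows the tapering of
        # natural-abundance spread as fewer unlabeled carbons remain
        "mixed-8-10-12": LabelingScenario(
            "mixed-8-10-12", c20, {8: 1 / 3, 10: 1 / 3, 12: 1 / 3}
        ),
        # 100% labeled: natural abundance has no carbon left to act on, so
        # the spectrum is a fixed point of the correction
        "fully-labeled-20c": LabelingScenario("fully-labeled-20c", c20, {20: 1.0}),
        # synthetic 42-carbon lipid-like pattern (glycerol/choline labeling at
        # low counts, fatty-acid acetyl incorporation at 16-20); a constructed
        # stand-in, not measured data
        "lipid-42c": LabelingScenario(
            "lipid-42c",
            {"C": 42},
            {c: 0.1 for c in (0, 1, 2, 3, 4, 16, 17, 18, 19, 20)},
        ),
    }


BUILTIN_SCENARIOS: dict[str, LabelingScenario] = _builtin_scenarios()


def get_scenario(name: str) -> LabelingScenario:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise CorrectionError(
            f"unknown scenario {name!r}; available: "
            + ", ".join(sorted(BUILTIN_SCENARIOS))
        ) from None


def generate_clean_spectrum(scenario: LabelingScenario) -> IsotopologueSpectrum:
    """Build the delta-mixture intensity array a scenario describes."""
    shape = tuple(m + 1 for m in scenario.element_maxima.values())
    values = np.zeros(shape)
    for count, fraction in scenario.labeled_fractions.items():
        idx = (count,) if isinstance(count, int) else tuple(count)
        values[idx] += fraction
    return IsotopologueSpectrum(
        intensities=values,
        element_maxima=dict(scenario.element_maxima),
        normalization_basis=1.0,
    )


def brute_force_contaminate(clean, constants: CorrectionConstants | None = None,
                            element_maxima: Mapping[str, int] | None = None
                            ) -> np.ndarray:
    """Independent forward-model oracle by explicit binomial enumeration.

    For each label count ``n`` the remaining ``M - n`` light atoms each turn
    heavy independently with probability ``na``, so the added-atom count is
    Binomial(M − n, na); the mass function is enumerated directly with exact
    integer coefficients (``math.comb``) and plain powers, sharing no code
    with the analytic transforms.  Dual label uses the product of the two
    independent per-element distributions.
    """
    if constants is None:
        constants = CorrectionConstants()
    if isinstance(clean, IsotopologueSpectrum):
        element_maxima = clean.element_maxima
        clean = clean.intensities
    if element_maxima is None:
        raise CorrectionError("element_maxima required for plain-array input")
    values = np.asarray(clean, dtype=float)
    maxima = list(element_maxima.items())

    def pmf(m: int, na: float) -> list[float]:
        return [math.comb(m, j) * na**j * (1.0 - na) ** (m - j) for j in range(m + 1)]

    if values.ndim == 1:
        (element, maximum), = maxima
        na = constants.na_13c if element == "C" else constants.require_nitrogen()
        out = np.zeros_like(values)
        for n, intensity in enumerate(values):
            if intensity == 0:
                continue
            for j, p in enumerate(pmf(maximum - n, na)):
                out[n + j] += intensity * p
        return out
    (_, c_max), (_, n_max) = maxima
    na_c = constants.na_13c
    na_n = constants.require_nitrogen()
    out = np.zeros_like(values)
    for x in range(c_max + 1):
        for y in range(n_max + 1):
            intensity = values[x, y]
            if intensity == 0:
                continue
            pc = pmf(c_max - x, na_c)
            pn = pmf(n_max - y, na_n)
            for j, pcj in enumerate(pc):
                for l, pnl in enumerate(pn):
                    out[x + j, y + l] += intensity * pcj * pnl
    return out


def perturb_spectrum(spectrum, relative_noise: float, seed: int) -> np.ndarray:
    """Apply reproducible multiplicative noise, clipping at zero.

    Each entry is scaled by ``1 + u`` with ``u ~ Uniform(-noise, +noise)``
    drawn from ``numpy.random.default_rng(seed)``.
    """
    if relative_noise < 0:
        raise CorrectionError("relative_noise must be >= 0")
    values = np.asarray(_spectrum_values(spectrum), dtype=float)
    rng = np.random.default_rng(seed)
    factors = 1.0 + rng.uniform(-relative_noise, relative_noise, size=values.shape)
    return np.clip(values * factors, 0.0, None)


# --------------------------------------------------------------------------
# Table IO
# --------------------------------------------------------------------------

_SINGLE_COLUMNS = ("isotopologue_index", "intensity")
_DUAL_COLUMNS = ("c_index", "n_index", "intensity")
_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


@dataclass
class IsotopologueTable:
    """One metabolite's isotopologue rows as read from a delimited file.

    ``rows`` maps a label-count tuple — ``(i,)`` or ``(i, j)`` — to its
    intensity; absent indices stay absent (missing, not zero).
    """

    metabolite_id: str
    rows: dict[tuple[int, ...], float]
    element_maxima: dict[str, int] | None = None
    provenance: str = ""

    @property
    def is_dual(self) -> bool:
        return len(next(iter(self.rows))) == 2

    def to_spectrum(
        self, c_max: int | None = None, n_max: int | None = None
    ) -> IsotopologueSpectrum:
        """Materialize as an intensity array with NaN for missing indices.

        Maxima default to the largest observed index (with a warning, since
        unobserved trailing isotopologues change the correction).
        """
        dual = self.is_dual
        observed_c = max(idx[0] for idx in self.rows)
        if c_max is None:
            c_max = observed_c
            logger.warning(
                "%s: C_Max not given; inferred %d from the largest observed "
                "index", self.metabolite_id, c_max,
            )
        if dual:
            observed_n = max(idx[1] for idx in self.rows)
            if n_max is None:
                n_max = observed_n
                logger.warning(
                    "%s: N_Max not given; inferred %d from the largest "
                    "observed index", self.metabolite_id, n_max,
                )
            shape: tuple[int, ...] = (c_max + 1, n_max + 1)
            maxima = {"C": c_max, "N": n_max}
        else:
            shape = (c_max + 1,)
            maxima = {"C": c_max}
        values = np.full(shape, np.nan)
        for idx, intensity in self.rows.items():
            if any(i > m for i, m in zip(idx, shape)):
                raise CorrectionError(
                    f"{self.metabolite_id}: observed index {idx} exceeds the "
                    f"given element maxima {maxima}"
                )
            values[idx] = intensity
        return IsotopologueSpectrum(
            intensities=values,
            element_maxima=maxima,
            normalization_basis=float(np.nansum(values)),
        )


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise CorrectionError(f"unknown table format {fmt!r}; use 'tsv' or 'csv'")
    return "\t" if fmt == "tsv" else ","


def read_table(path, fmt: str | None = None) -> list[IsotopologueTable]:
    """Read one or more metabolites' isotopologue intensities.

    Expects a header line; ``#`` lines are comments.  Single-label files have
    columns ``isotopologue_index, intensity``; dual-label files
    ``c_index, n_index, intensity``; an optional ``metabolite_id`` column
    separates metabolites.  Absent indices are recorded as missing, never as
    zero.  Malformed rows and duplicate indices raise with the offending
    location.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    try:
        frame = pd.read_csv(path, sep=sep, comment="#", dtype=str,
                            skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty table", path)
        return []
    frame.columns = [c.strip() for c in frame.columns]
    if set(_DUAL_COLUMNS) <= set(frame.columns):
        index_cols: tuple[str, ...] = _DUAL_COLUMNS[:2]
    elif set(_SINGLE_COLUMNS) <= set(frame.columns):
        index_cols = _SINGLE_COLUMNS[:1]
    else:
        raise CorrectionError(
            f"{path}: expected columns {_SINGLE_COLUMNS} or {_DUAL_COLUMNS}; "
            f"found {tuple(frame.columns)}"
        )
    if frame.empty:
        logger.warning("%s: table has a header but no data rows", path)
        return []
    if "metabolite_id" not in frame.columns:
        frame = frame.assign(metabolite_id="metabolite")

    tables: list[IsotopologueTable] = []
    for metabolite, group in frame.groupby("metabolite_id", sort=False):
        rows: dict[tuple[int, ...], float] = {}
        for line, record in group.iterrows():
            lineno = int(line) + 2  # 1-based, after the header
            try:
                idx = tuple(int(record[c]) for c in index_cols)
                intensity = float(record["intensity"])
            except (TypeError, ValueError) as exc:
                raise CorrectionError(
                    f"{path}:{lineno}: malformed row ({exc})"
                ) from None
            if any(i < 0 for i in idx):
                raise CorrectionError(f"{path}:{lineno}: negative index {idx}")
            if not math.isfinite(intensity) or intensity < 0:
                raise CorrectionError(
                    f"{path}:{lineno}: intensity must be finite and >= 0; "
                    f"got {intensity}"
                )
            if idx in rows:
                raise CorrectionError(
                    f"{path}:{lineno}: duplicate index {idx} for "
                    f"metabolite {metabolite!r}"
                )
            rows[idx] = intensity
        tables.append(
            IsotopologueTable(
                metabolite_id=str(metabolite), rows=rows, provenance=str(path)
            )
        )
    return tables


def write_table(
    spectrum,
    path,
    fmt: str | None = None,
    metabolite_id: str = "metabolite",
    header_comment: str | None = None,
) -> None:
    """Write an intensity array as a table ``read_table`` accepts.

    NaN entries (missing isotopologues) are omitted, not written as zero.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    values = np.asarray(_spectrum_values(spectrum), dtype=float)
    records = []
    if values.ndim == 1:
        for i, v in enumerate(values):
            if not math.isnan(v):
                records.append((metabolite_id, i, _FLOAT_FMT % v))
        columns = ["metabolite_id", *_SINGLE_COLUMNS]
    else:
        for (i, j), v in np.ndenumerate(values):
            if not math.isnan(v):
                records.append((metabolite_id, i, j, _FLOAT_FMT % v))
        columns = ["metabolite_id", *_DUAL_COLUMNS]
    with open(path, "w") as handle:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        pd.DataFrame(records, columns=columns).to_csv(handle, sep=sep, index=False)


def write_result(
    result: CorrectionResult,
    path,
    fmt: str | None = None,
    metabolite_id: str = "metabolite",
    observed: np.ndarray | None = None,
) -> None:
    """Write corrected (and observed) intensities with run metadata.

    The ``intensity`` column holds the corrected values so the file round-
    trips through :func:`read_table`; the observed intensities sit alongside
    in ``observed_intensity`` (empty where the peak was missing).  Iteration
    count, residual, and the flattened/supplemented index sets go into ``#``
    header comments.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    corrected = np.asarray(result.corrected, dtype=float)
    if observed is None:
        observed = np.full_like(corrected, np.nan)
        for idx in np.ndindex(corrected.shape):
            observed[idx] = result.recalculated_observed[idx]
        for idx in result.supplemented_indices:
            observed[idx] = np.nan
    observed = np.asarray(observed, dtype=float)

    def fmt_obs(v: float) -> str:
        return "" if math.isnan(v) else _FLOAT_FMT % v

    records = []
    if corrected.ndim == 1:
        columns = ["metabolite_id", *_SINGLE_COLUMNS, "observed_intensity"]
        for i, v in enumerate(corrected):
            records.append((metabolite_id, i, _FLOAT_FMT % v, fmt_obs(observed[i])))
    else:
        columns = ["metabolite_id", *_DUAL_COLUMNS, "observed_intensity"]
        for (i, j), v in np.ndenumerate(corrected):
            records.append(
                (metabolite_id, i, j, _FLOAT_FMT % v, fmt_obs(observed[i, j]))
            )
    meta = (
        f"metabolite_id: {metabolite_id}\n"
        f"iterations: {result.iterations}\n"
        f"residual ({result.residual_norm}): {_FLOAT_FMT % result.residual}\n"
        f"converged: {result.converged}\n"
        f"flattened_indices: {sorted(result.flattened_indices)}\n"
        f"supplemented_indices: {sorted(result.supplemented_indices)}\n"
        f"normalization_basis: {_FLOAT_FMT % result.normalization_basis}"
    )
    with open(path, "w") as handle:
        for line in meta.splitlines():
            handle.write(f"# {line}\n")
        pd.DataFrame(records, columns=columns).to_csv(handle, sep=sep, index=False)
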