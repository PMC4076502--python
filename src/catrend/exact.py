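"""Exact joint distribution of the three CA trend statistics and exact p-values.

Model
-----
Conditional on the arm sizes, the case genotype counts (X1, X2, X3) and the
control counts (Y1, Y2, Y3) are independent trinomials with probability
triples (p1, p2, p3) and (q1, q2, q3).  The joint law of the additive,
dominant, and recessive trend statistics is two-dimensional (T3 = T1 - T2)
and is carried by the symmetrized integer coordinates

    Z1 = R_Y X3 - R_X Y3,      Z2 = R_Y X2 - R_X Y2.

Each pair (Y2, Y3) with Y2 + Y3 <= R_Y translates the triangular lattice
{(X2, X3): X2 + X3 <= R_X} to a "triangle" of (R_X+1)(R_X+2)/2 support
points; there are (R_Y+1)(R_Y+2)/2 such triangles and they overlap at
multiples of gcd(R_X, R_Y).

The exact p-value orders outcomes by probability: it is the total mass of
all support cells whose probability is less than or equal to that of the
observed cell (probability-ordering / two-sided exact test on a discrete
lattice).

Three computational regimes, dispatched on gcd(R_X, R_Y):

``coprime``
    Triangles overlap only at the origin, where exactly three meet.  Every
    other cell's mass is a single product f_X * f_Y, so the p-value is the
    probability that the product of two independent trinomial masses falls
    at or below the observed one.  Sorting the case-arm log-masses once and
    binary-searching per control cell evaluates this in
    O((R^2) log R) without materializing the support.

``equal``
    R_X = R_Y = R.  The support is sparse: Z1, Z2 are multiples of R, so
    the condensed lattice (Z1/R, Z2/R) is a (2R+1) x (2R+1) matrix — the
    2-D cross-correlation of the case and control trinomial arrays,
    computed by exact direct summation.

``general``
    Per-cell accumulation of all contributing triangle terms into a sparse
    map, in one deterministic pass.

A full brute-force enumerator (`joint_pmf_brute_force`) over all
(X2, X3, Y2, Y3) combinations serves as the independent oracle for every
optimized path.

All trinomial masses are computed in log space from precomputed
log-factorials (masses underflow double precision long before the lattice
does); per-cell sums and the p-value accumulate in linear space, where
underflowed cells contribute exactly their (negligible) rounded mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from scipy.special import gammaln

from .tables import GenotypeTable, ValidationError, z_coordinates

#: Default relative tolerance for the "equally or less probable" tie rule.
DEFAULT_TIE_TOL = 1e-12

#: Default ceiling on elementary trinomial-product terms.
DEFAULT_MAX_CELLS = 1e11

#: Ceiling on stored support cells for the sparse general-scenario path.
GENERAL_STORAGE_LIMIT = 5e7

#: Brute-force oracle guard on (r_x+1)^2 (r_y+1)^2 / 4.
BRUTE_FORCE_LIMIT = 1e7

ProbsMode = Literal["pooled", "separate", "fixed"]
Scenario = Literal["coprime", "equal", "general", "brute_force"]


class ResourceError(RuntimeError):
    """Raised when a computation would exceed the configured cell budget."""


@dataclass(frozen=True)
class NullGenotypeProbs:
    """Genotype probability triples for cases (p) and controls (q)."""

    p: tuple[float, float, float]
    q: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, triple in (("p", self.p), ("q", self.q)):
            if len(triple) != 3:
                raise ValidationError(f"{name} must have 3 components")
            if any(v < 0 for v in triple):
                raise ValidationError(f"{name} has negative entries: {triple}")
            if abs(sum(triple) - 1.0) > 1e-9:
                raise ValidationError(
                    f"{name} does not sum to 1 (got {sum(triple)!r})"
                )


def null_genotype_probs(
    table: GenotypeTable,
    mode: ProbsMode = "pooled",
    fixed: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
) -> NullGenotypeProbs:
    """Genotype probability triples feeding the joint pmf.

    ``pooled`` (default) estimates a common triple from the column totals,
    p_i = q_i = C_i / N — the maximum-likelihood estimate under the null
    constraint p = q, which is required for a null reference distribution.
    ``separate`` uses the per-arm estimates p_i = X_i/R_X, q_i = Y_i/R_Y
    (exposed for completeness; under these the observed table is modal and
    the probability-ordering p-value is degenerate at 1).
    ``fixed`` takes user-supplied triples.
    """
    if mode == "pooled":
        n = table.n
        t = tuple(c / n for c in table.columns)
        return NullGenotypeProbs(p=t, q=t)
    if mode == "separate":
        rx, ry = table.r_x, table.r_y
        return NullGenotypeProbs(
            p=tuple(v / rx for v in table.cases),
            q=tuple(v / ry for v in table.controls),
        )
    if mode == "fixed":
        if fixed is None:
            raise ValidationError("mode='fixed' requires explicit probability triples")
        return NullGenotypeProbs(p=tuple(fixed[0]), q=tuple(fixed[1]))
    raise ValidationError(f"unknown probs mode {mode!r}")


@dataclass
class JointPMF:
    """Sparse joint pmf of (Z1, Z2) as a map from lattice point to mass."""

    r_x: int
    r_y: int
    probs: NullGenotypeProbs
    masses: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def total_mass(self) -> float:
        return math.fsum(self.masses.values())

    def mass_at(self, z1: int, z2: int) -> float:
        return self.masses.get((z1, z2), 0.0)

    def pvalue_at(self, z1: int, z2: int, tie_tol: float = DEFAULT_TIE_TOL) -> float:
        """Probability-ordering p-value of an observed (z1, z2) on this pmf."""
        f_obs = self.mass_at(z1, z2)
        if f_obs <= 0.0:
            raise ValidationError(
                f"observed point ({z1}, {z2}) has zero probability under the null"
            )
        thresh = f_obs * (1.0 + tie_tol)
        return math.fsum(v for v in self.masses.values() if v <= thresh)


@dataclass(frozen=True)
class ExactResult:
    """Exact joint-model p-value and diagnostics."""

    z1: int
    z2: int
    f_obs: float
    p_value: float
    scenario: Scenario
    cells: int  # elementary trinomial-product terms enumerated


# ---------------------------------------------------------------------------
# Triangle lattice helpers
# ---------------------------------------------------------------------------


def triangle_count(r_y: int) -> int:
    """Number of solution-space triangles, (R_Y+1)(R_Y+2)/2."""
    if r_y < 0:
        raise ValidationError(f"r_y must be >= 0, got {r_y}")
    return (r_y + 1) * (r_y + 2) // 2


def gcd_scenario(r_x: int, r_y: int) -> Scenario:
    """Classify (R_X, R_Y) into the coprime / equal / general regimes."""
    if r_x < 1 or r_y < 1:
        raise ValidationError("r_x and r_y must be >= 1")
    if r_x == r_y:
        return "equal"
    if math.gcd(r_x, r_y) == 1:
        return "coprime"
    return "general"


def _triangle_cells(r: int) -> tuple[np.ndarray, np.ndarray]:
    """All (k2, k3) with k2 + k3 <= r, row-major in k2 then k3."""
    k2, k3 = np.meshgrid(np.arange(r + 1), np.arange(r + 1), indexing="ij")
    keep = (k2 + k3) <= r
    return k2[keep].astype(np.int64), k3[keep].astype(np.int64)


def _log_trinomial(r: int, probs: tuple[float, float, float],
                   k2: np.ndarray, k3: np.ndarray) -> np.ndarray:
    """Log trinomial pmf at counts (r-k2-k3, k2, k3); 0*log(0) treated as 0."""
    k1 = r - k2 - k3
    out = gammaln(r + 1) - gammaln(k1 + 1) - gammaln(k2 + 1) - gammaln(k3 + 1)
    for k, p in ((k1, probs[0]), (k2, probs[1]), (k3, probs[2])):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(k > 0, k * np.log(p), 0.0)
        out = out + term
    return out


def _arm_arrays(r: int, probs: tuple[float, float, float]):
    k2, k3 = _triangle_cells(r)
    return k2, k3, _log_trinomial(r, probs, k2, k3)


def n_terms(r_x: int, r_y: int) -> int:
    """Elementary trinomial-product terms for a full pmf pass."""
    return triangle_count(r_x) * triangle_count(r_y)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def joint_pmf_brute_force(
    r_x: int, r_y: int, probs: NullGenotypeProbs
) -> JointPMF:
    """Full enumeration of the joint pmf over every (X2, X3, Y2, Y3).

    The independent oracle for all optimized paths.  Guarded to small arm
    sizes; larger problems must use `exact_pvalue`, which never
    materializes the full support.
    """
    guard = (r_x + 1) ** 2 * (r_y + 1) ** 2 / 4
    if guard > BRUTE_FORCE_LIMIT:
        raise ResourceError(
            f"brute-force enumeration of r_x={r_x}, r_y={r_y} needs ~{guard:.2g} "
            f"cells (limit {BRUTE_FORCE_LIMIT:.2g}); use exact_pvalue instead"
        )
    x2, x3, lfx = _arm_arrays(r_x, probs.p)
    y2, y3, lfy = _arm_arrays(r_y, probs.q)
    fx = np.exp(lfx)
    fy = np.exp(lfy)
    pmf = JointPMF(r_x=r_x, r_y=r_y, probs=probs)
    masses = pmf.masses
    for j in range(len(y2)):
        z1s = r_y * x3 - r_x * y3[j]
        z2s = r_y * x2 - r_x * y2[j]
        w = fy[j] * fx
        for z1, z2, m in zip(z1s.tolist(), z2s.tolist(), w.tolist()):
            key = (z1, z2)
            masses[key] = masses.get(key, 0.0) + m
    return pmf


def triangle_overlap_counts(r_x: int, r_y: int) -> dict[tuple[int, int], int]:
    """Number of (Y2, Y3) triangles contributing to each support point.

    Constructive enumeration used to verify the triangle combinatorics:
    there are (R_Y+1)(R_Y+2)/2 triangles of (R_X+1)(R_X+2)/2 points each,
    and for coprime arm sizes the only multi-triangle point is the origin,
    where exactly three triangles meet.
    """
    x2, x3 = _triangle_cells(r_x)
    y2, y3 = _triangle_cells(r_y)
    counts: dict[tuple[int, int], int] = {}
    for j in range(len(y2)):
        z1s = r_y * x3 - r_x * y3[j]
        z2s = r_y * x2 - r_x * y2[j]
        for z1, z2 in zip(z1s.tolist(), z2s.tolist()):
            key = (z1, z2)
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Scenario 1: coprime arm sizes
# ---------------------------------------------------------------------------


def _observed_or_raise(lf_obs: float, z: tuple[int, int]) -> None:
    if lf_obs == -np.inf:
        raise ValidationError(
            f"observed point {z} has zero probability under the null triples"
        )


def exact_pvalue_coprime(
    table: GenotypeTable,
    probs: NullGenotypeProbs,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> ExactResult:
    """Exact p-value when gcd(R_X, R_Y) = 1.

    Every cell's mass is the single product f_X(X2,X3) f_Y(Y2,Y3) except
    the origin, which pools the three extreme combinations
    (X=(·,0,0), Y=(·,0,0)), (X=(0,R_X,0), Y=(0,R_Y,0)),
    (X=(0,0,R_X), Y=(0,0,R_Y)).  Sorting the case-arm masses once turns
    the p-value sum into one binary search per control cell.
    """
    r_x, r_y = table.r_x, table.r_y
    if math.gcd(r_x, r_y) != 1 or r_x == r_y:
        raise AssertionError("dispatcher error: coprime path requires gcd=1, r_x != r_y")
    x2, x3, lfx = _arm_arrays(r_x, probs.p)
    y2, y3, lfy = _arm_arrays(r_y, probs.q)

    def x_index(a: int, b: int) -> int:
        return int(np.flatnonzero((x2 == a) & (x3 == b))[0])

    def y_index(a: int, b: int) -> int:
        return int(np.flatnonzero((y2 == a) & (y3 == b))[0])

    # The three (X, Y) combinations pooled at the origin.
    origin_pairs = [
        (x_index(0, 0), y_index(0, 0)),
        (x_index(r_x, 0), y_index(r_y, 0)),
        (x_index(0, r_x), y_index(0, r_y)),
    ]
    l_origin = [lfx[i] + lfy[j] for i, j in origin_pairs]
    f_origin = float(np.sum(np.exp(l_origin)))

    z1, z2 = z_coordinates(table)
    if (z1, z2) == (0, 0):
        lf_obs = math.log(f_origin) if f_origin > 0 else -np.inf
        f_obs = f_origin
    else:
        i = x_index(table.x2, table.x3)
        j = y_index(table.y2, table.y3)
        lf_obs = float(lfx[i] + lfy[j])
        f_obs = float(np.exp(lf_obs))
    _observed_or_raise(lf_obs, (z1, z2))

    log_band = lf_obs + math.log1p(tie_tol)
    lfx_sorted = np.sort(lfx)
    prefix = np.concatenate([[0.0], np.cumsum(np.exp(lfx_sorted))])
    k = np.searchsorted(lfx_sorted, log_band - lfy, side="right")
    total = float(np.sum(np.exp(lfy) * prefix[k]))

    # Swap the three origin terms, counted individually above, for the
    # pooled origin cell.
    for l in l_origin:
        if l <= log_band:
            total -= float(np.exp(l))
    if f_origin > 0 and math.log(f_origin) <= log_band:
        total += f_origin

    return ExactResult(
        z1=z1, z2=z2, f_obs=f_obs, p_value=min(total, 1.0),
        scenario="coprime", cells=len(lfx) * len(lfy),
    )


# ---------------------------------------------------------------------------
# Scenario 2: equal arm sizes
# ---------------------------------------------------------------------------


def condensed_pmf_equal(r: int, probs: NullGenotypeProbs) -> np.ndarray:
    """Condensed (2R+1) x (2R+1) pmf matrix for equal arms.

    With R_X = R_Y = R the support sits on multiples of R:
    Z1 = R (X3 - Y3), Z2 = R (X2 - Y2).  Entry [d2 + R, d1 + R] holds the
    mass at (Z1, Z2) = (R d1, R d2) — the 2-D cross-correlation of the
    case and control trinomial arrays, accumulated by exact direct
    summation (scatter-add over triangle-cell pairs, chunked over control
    cells to bound memory).
    """
    x2, x3, lfx = _arm_arrays(r, probs.p)
    y2, y3, lfy = _arm_arrays(r, probs.q)
    fx = np.exp(lfx)
    fy = np.exp(lfy)
    side = 2 * r + 1
    out = np.zeros(side * side)
    chunk = max(1, int(4e6) // len(fx))
    for j0 in range(0, len(fy), chunk):
        j1 = min(j0 + chunk, len(fy))
        d2 = x2[None, :] - y2[j0:j1, None] + r
        d1 = x3[None, :] - y3[j0:j1, None] + r
        keys = (d2 * side + d1).ravel()
        mass = (fy[j0:j1, None] * fx[None, :]).ravel()
        out += np.bincount(keys, weights=mass, minlength=side * side)
    return out.reshape(side, side)


def exact_pvalue_equal(
    table: GenotypeTable,
    probs: NullGenotypeProbs,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> ExactResult:
    """Exact p-value when R_X = R_Y = R, on the condensed sparse lattice.

    Only the condensed matrix is ever stored; the raw (Z1, Z2) lattice
    (spacing R) is never materialized.
    """
    r = table.r_x
    if table.r_y != r:
        raise AssertionError("dispatcher error: equal path requires r_x == r_y")
    m = condensed_pmf_equal(r, probs)
    d1 = table.x3 - table.y3
    d2 = table.x2 - table.y2
    f_obs = float(m[d2 + r, d1 + r])
    if f_obs <= 0.0:
        raise ValidationError(
            f"observed point ({r * d1}, {r * d2}) has zero probability under the null"
        )
    thresh = f_obs * (1.0 + tie_tol)
    sel = (m > 0.0) & (m <= thresh)
    p = float(np.sum(m[sel]))
    return ExactResult(
        z1=r * d1, z2=r * d2, f_obs=f_obs, p_value=min(p, 1.0),
        scenario="equal", cells=n_terms(r, r),
    )


# ---------------------------------------------------------------------------
# Scenario 3: general arm sizes
# ---------------------------------------------------------------------------


def exact_pvalue_general(
    table: GenotypeTable,
    probs: NullGenotypeProbs,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> ExactResult:
    """Exact p-value for arbitrary arm sizes.

    Accumulates, for every support cell, the trinomial-product mass of all
    contributing (Y2, Y3) triangles (overlaps fall on multiples of
    gcd(R_X, R_Y)) into a sparse map keyed by (Z1, Z2), then sums the
    probability-ordering band in one pass.  Iteration is row-major over
    triangles, so results are bit-reproducible.
    """
    r_x, r_y = table.r_x, table.r_y
    if n_terms(r_x, r_y) > GENERAL_STORAGE_LIMIT:
        raise ResourceError(
            f"general-scenario support for r_x={r_x}, r_y={r_y} "
            f"(~{n_terms(r_x, r_y):.2g} terms) exceeds the sparse storage limit "
            f"{GENERAL_STORAGE_LIMIT:.2g}"
        )
    x2, x3, lfx = _arm_arrays(r_x, probs.p)
    y2, y3, lfy = _arm_arrays(r_y, probs.q)
    fx = np.exp(lfx)
    fy = np.exp(lfy)

    # Aggregate masses per lattice key; keys fit int64 comfortably.
    width = 2 * r_x * r_y + 1
    keys_parts = []
    mass_parts = []
    for j in range(len(y2)):
        z1s = r_y * x3 - r_x * y3[j]
        z2s = r_y * x2 - r_x * y2[j]
        keys_parts.append((z1s + r_x * r_y) * width + (z2s + r_x * r_y))
        mass_parts.append(fy[j] * fx)
    keys = np.concatenate(keys_parts)
    mass = np.concatenate(mass_parts)
    uniq, inv = np.unique(keys, return_inverse=True)
    agg = np.bincount(inv, weights=mass, minlength=len(uniq))

    z1, z2 = z_coordinates(table)
    obs_key = (z1 + r_x * r_y) * width + (z2 + r_x * r_y)
    pos = np.searchsorted(uniq, obs_key)
    if pos >= len(uniq) or uniq[pos] != obs_key or agg[pos] <= 0.0:
        raise ValidationError(
            f"observed point ({z1}, {z2}) has zero probability under the null"
        )
    f_obs = float(agg[pos])
    thresh = f_obs * (1.0 + tie_tol)
    p = float(np.sum(agg[(agg > 0.0) & (agg <= thresh)]))
    return ExactResult(
        z1=z1, z2=z2, f_obs=f_obs, p_value=min(p, 1.0),
        scenario="general", cells=len(keys),
    )


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------


def exact_pvalue(
    table: GenotypeTable,
    probs_mode: ProbsMode = "pooled",
    fixed: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
    max_cells: float = DEFAULT_MAX_CELLS,
    probs: NullGenotypeProbs | None = None,
) -> ExactResult:
    """Probability-ordering exact p-value for one 2x3 genotype table.

    Dispatches on the gcd regime of the arm sizes.  ``probs`` overrides
    ``probs_mode``/``fixed`` when given.  Deterministic for fixed inputs.
    """
    if probs is None:
        probs = null_genotype_probs(table, probs_mode, fixed)
    est = n_terms(table.r_x, table.r_y)
    if est > max_cells:
        raise ResourceError(
            f"exact p-value for r_x={table.r_x}, r_y={table.r_y} needs "
            f"~{est:.2g} elementary terms, above the budget {max_cells:.2g}; "
            "raise max_cells to proceed"
        )
    scenario = gcd_scenario(table.r_x, table.r_y)
    if scenario == "equal":
        return exact_pvalue_equal(table, probs, tie_tol)
    if scenario == "coprime":
        return exact_pvalue_coprime(table, probs, tie_tol)
    return exact_pvalue_general(table, probs, tie_tol)


def export_pmf(pmf: JointPMF, path: str) -> None:
    """Write a sparse pmf as a 3-column TSV (z1, z2, probability)."""
    with open(path, "w") as fh:
        fh.write("z1\tz2\tprobability\n")
        for (z1, z2) in sorted(pmf.masses):
            fh.write(f"{z1}\t{z2}\t{pmf.masses[(z1, z2)]:.17g}\n")
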