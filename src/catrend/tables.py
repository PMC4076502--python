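"""Core data types for 2x3 case-control genotype tables and trend statistics.

A di-allelic SNP is summarized by the 2x3 contingency table of genotype
counts in cases and controls.  Columns are fixed in the order (AA, Aa, aa)
where ``a`` is the minor (risk) allele; callers must map their input columns
to this order explicitly.

The unnormalized Cochran-Armitage trend statistic for weights t is

    W = sum_i t_i (R_Y X_i - R_X Y_i)

with weights (0,1,2), (0,1,1), (0,0,1) for the additive, dominant, and
recessive genetic models (statistics T1, T2, T3).  Since T3 = T1 - T2,
the joint law of the three statistics lives on the 2-dimensional integer
lattice; the symmetrized coordinates

    Z1 = R_Y X3 - R_X Y3      (= T3)
    Z2 = R_Y X2 - R_X Y2      (= 2 T2 - T1)

with inverse T1 = 2 Z1 + Z2, T2 = Z1 + Z2, are used internally everywhere.
All statistics are exact Python integers so probability-mass lookups and
tie comparisons are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

ModelLabel = Literal["additive", "dominant", "recessive"]

#: Genetic-model weight triples for genotype columns (AA, Aa, aa).
MODEL_WEIGHTS: dict[str, tuple[int, int, int]] = {
    "additive": (0, 1, 2),
    "dominant": (0, 1, 1),
    "recessive": (0, 0, 1),
}

MODELS: tuple[str, ...] = ("additive", "dominant", "recessive")


class ValidationError(ValueError):
    """Raised for structurally invalid tables, weights, or probabilities."""


@dataclass(frozen=True)
class TrendWeights:
    """Genotype weights (AA, Aa, aa) for one genetic model."""

    model: str

    def __post_init__(self) -> None:
        if self.model not in MODEL_WEIGHTS:
            raise ValidationError(
                f"unknown genetic model {self.model!r}; "
                f"expected one of {sorted(MODEL_WEIGHTS)}"
            )

    @property
    def weights(self) -> tuple[int, int, int]:
        return MODEL_WEIGHTS[self.model]

    @property
    def t1(self) -> int:
        return self.weights[0]

    @property
    def t2(self) -> int:
        return self.weights[1]

    @property
    def t3(self) -> int:
        return self.weights[2]


@dataclass(frozen=True)
class GenotypeTable:
    """2x3 case-control genotype count table with margins.

    Cases (x1, x2, x3) and controls (y1, y2, y3) hold counts of genotypes
    AA, Aa, aa.  Margins: r_x cases, r_y controls, column totals c1..c3,
    grand total n.
    """

    x1: int
    x2: int
    x3: int
    y1: int
    y2: int
    y3: int

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3", "y1", "y2", "y3"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, int):
                # accept numpy integers by coercion
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    raise ValidationError(f"cell {name}={v!r} is not an integer")
                if iv != v:
                    raise ValidationError(f"cell {name}={v!r} is not an integer")
                object.__setattr__(self, name, iv)
            if getattr(self, name) < 0:
                raise ValidationError(f"cell {name}={v} is negative")
        if self.r_x == 0:
            raise ValidationError("case arm is empty (r_x = 0)")
        if self.r_y == 0:
            raise ValidationError("control arm is empty (r_y = 0)")

    @property
    def cases(self) -> tuple[int, int, int]:
        return (self.x1, self.x2, self.x3)

    @property
    def controls(self) -> tuple[int, int, int]:
        return (self.y1, self.y2, self.y3)

    @property
    def r_x(self) -> int:
        return self.x1 + self.x2 + self.x3

    @property
    def r_y(self) -> int:
        return self.y1 + self.y2 + self.y3

    @property
    def c1(self) -> int:
        return self.x1 + self.y1

    @property
    def c2(self) -> int:
        return self.x2 + self.y2

    @property
    def c3(self) -> int:
        return self.x3 + self.y3

    @property
    def columns(self) -> tuple[int, int, int]:
        return (self.c1, self.c2, self.c3)

    @property
    def n(self) -> int:
        return self.r_x + self.r_y

    def swapped(self) -> "GenotypeTable":
        """Table with case and control rows exchanged."""
        return GenotypeTable(self.y1, self.y2, self.y3, self.x1, self.x2, self.x3)


@dataclass(frozen=True)
class TrendStatistics:
    """The three unnormalized trend statistics and their (Z1, Z2) transform."""

    t1_stat: int
    t2_stat: int
    t3_stat: int
    z1: int
    z2: int

    def __post_init__(self) -> None:
        assert self.t3_stat == self.t1_stat - self.t2_stat
        assert self.z1 == self.t1_stat - self.t2_stat
        assert self.z2 == 2 * self.t2_stat - self.t1_stat


def make_table(x1: int, x2: int, x3: int, y1: int, y2: int, y3: int) -> GenotypeTable:
    """Build a validated 2x3 genotype table (cases AA,Aa,aa; controls AA,Aa,aa)."""
    return GenotypeTable(x1, x2, x3, y1, y2, y3)


def trend_statistic(table: GenotypeTable, weights: TrendWeights | str) -> int:
    """Exact integer trend statistic W = sum_i t_i (R_Y X_i - R_X Y_i)."""
    if isinstance(weights, str):
        weights = TrendWeights(weights)
    rx, ry = table.r_x, table.r_y
    t = weights.weights
    x = table.cases
    y = table.controls
    return sum(t[i] * (ry * x[i] - rx * y[i]) for i in range(3))


def compute_statistics(table: GenotypeTable) -> TrendStatistics:
    """All three trend statistics plus the symmetrized (Z1, Z2) coordinates."""
    t1 = trend_statistic(table, "additive")
    t2 = trend_statistic(table, "dominant")
    t3 = trend_statistic(table, "recessive")
    return TrendStatistics(
        t1_stat=t1, t2_stat=t2, t3_stat=t3, z1=t1 - t2, z2=2 * t2 - t1
    )


def z_coordinates(table: GenotypeTable) -> tuple[int, int]:
    """Observed (Z1, Z2) = (R_Y X3 - R_X Y3, R_Y X2 - R_X Y2)."""
    rx, ry = table.r_x, table.r_y
    return (ry * table.x3 - rx * table.y3, ry * table.x2 - rx * table.y2)


def t_from_z(z1: int, z2: int) -> tuple[int, int]:
    """Map symmetrized coordinates back to (T1, T2) = (2 Z1 + Z2, Z1 + Z2)."""
    return (2 * z1 + z2, z1 + z2)


def z_from_t(t1: int, t2: int) -> tuple[int, int]:
    """Map (T1, T2) to the symmetrized coordinates (Z1, Z2)."""
    return (t1 - t2, 2 * t2 - t1)
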