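"""Case-control replicate generator and type-1-error / power experiments.

Genotypes are drawn under Hardy-Weinberg equilibrium from the minor allele
frequency m: genotype probabilities ((1-m)^2, 2m(1-m), m^2) for (AA, Aa,
aa).  Disease status follows the logistic model

    logit P(Z = 1) = beta0 + beta1 * X,

where X codes the genotype under the generating genetic model (additive
0/1/2, dominant 0/1, recessive 0/1) and beta1 is the log odds ratio.
Individuals are simulated prospectively and accrued into the case and
control arms in draw order until both quotas are met; excess individuals
of a filled arm are discarded.  This retrospective quota-filling is the
standard reading of a fixed case/control design.

`run_experiment` evaluates, per replicate, any subset of the methods
(single-model asymptotic tests, min-p, Bonferroni, exact joint p-value)
and reports Monte-Carlo rejection proportions with standard errors.

Randomness discipline: one root seed spawns one independent child stream
per replicate (`numpy.random.SeedSequence.spawn`), so any subset of
replicates is reproducible in isolation and runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .asymptotic import all_trend_tests
from .exact import DEFAULT_MAX_CELLS, exact_pvalue
from .tables import GenotypeTable, ValidationError

#: Genotype coding X per generating model, indexed by genotype class 0/1/2.
GENOTYPE_CODING: dict[str, tuple[int, int, int]] = {
    "additive": (0, 1, 2),
    "dominant": (0, 1, 1),
    "recessive": (0, 0, 1),
}

METHODS: tuple[str, ...] = (
    "additive_only",
    "dominant_only",
    "recessive_only",
    "min_p",
    "bonferroni",
    "exact",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation experiment.

    Defaults mirror the null-hypothesis study conditions: MAF 40%,
    beta0 = -2.5, beta1 = log(1) (no effect), 1000 cases / 1000 controls,
    1000 replicates, alpha = 0.05.
    """

    maf: float = 0.4
    beta0: float = -2.5
    beta1: float = 0.0
    coding: str = "additive"
    n_cases: int = 1000
    n_controls: int = 1000
    n_replicates: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        if not (math.isfinite(self.beta0) and math.isfinite(self.beta1)):
            raise ValidationError("beta0 and beta1 must be finite")
        if self.coding not in GENOTYPE_CODING:
            raise ValidationError(f"unknown genotype coding {self.coding!r}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0) and self.alpha != 1.0:
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass
class ExperimentResult:
    """Per-method Monte-Carlo rejection proportions with standard errors."""

    config: SimulationConfig
    rejection_rate: dict[str, float]
    std_error: dict[str, float]
    n_replicates: int
    n_evaluated: dict[str, int] = field(default_factory=dict)
    p_values: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def hwe_genotype_probs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities (AA, Aa, aa) at MAF m."""
    if not (0.0 < maf <= 0.5):
        raise ValidationError(f"maf must be in (0, 0.5], got {maf}")
    return ((1.0 - maf) ** 2, 2.0 * maf * (1.0 - maf), maf * maf)


def simulate_genotype(maf: float, rng: np.random.Generator) -> int:
    """Draw one genotype class (0=AA, 1=Aa, 2=aa) under HWE."""
    return int(rng.choice(3, p=hwe_genotype_probs(maf)))


def simulate_replicate(
    config: SimulationConfig, rng: np.random.Generator
) -> GenotypeTable:
    """One replicate 2x3 table under the logistic disease model.

    Individuals are drawn in batches for speed; case/control accrual
    follows draw order exactly, so the result matches one-at-a-time
    sequential simulation.
    """
    probs = hwe_genotype_probs(config.maf)
    coding = np.array(GENOTYPE_CODING[config.coding])
    # Batch size: expected draws needed to fill the rarer arm, padded 25%.
    p_case = 1.0 / (1.0 + math.exp(-config.beta0))
    rarer = max(min(p_case, 1.0 - p_case), 1e-3)
    batch = max(1024, int(1.25 * (config.n_cases + config.n_controls) / rarer))
    g_parts: list[np.ndarray] = []
    z_parts: list[np.ndarray] = []
    n_cases = n_controls = 0
    while n_cases < config.n_cases or n_controls < config.n_controls:
        g = rng.choice(3, size=batch, p=probs)
        x = coding[g]
        pr = 1.0 / (1.0 + np.exp(-(config.beta0 + config.beta1 * x)))
        z = rng.random(batch) < pr
        g_parts.append(g)
        z_parts.append(z)
        n_cases += int(np.sum(z))
        n_controls += int(np.sum(~z))
    g_all = np.concatenate(g_parts)
    z_all = np.concatenate(z_parts)
    # The accrued arms are the first n_cases cases and first n_controls
    # controls in draw order, regardless of interleaving.
    case_g = g_all[z_all][: config.n_cases]
    control_g = g_all[~z_all][: config.n_controls]
    cases = np.bincount(case_g, minlength=3)
    controls = np.bincount(control_g, minlength=3)
    return GenotypeTable(
        int(cases[0]), int(cases[1]), int(cases[2]),
        int(controls[0]), int(controls[1]), int(controls[2]),
    )


def replicate_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Per-replicate child generators spawned from one root seed."""
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in root.spawn(n)]


def methods_pvalues(
    table: GenotypeTable,
    methods: tuple[str, ...],
    max_cells: float = DEFAULT_MAX_CELLS,
) -> dict[str, float]:
    """P-values of the requested methods for one table."""
    out: dict[str, float] = {}
    single = all_trend_tests(table)
    singles = {
        "additive_only": single["additive"].p_value,
        "dominant_only": single["dominant"].p_value,
        "recessive_only": single["recessive"].p_value,
    }
    mp = min(singles.values())
    for m in methods:
        if m in singles:
            out[m] = singles[m]
        elif m == "min_p":
            out[m] = mp
        elif m == "bonferroni":
            out[m] = min(1.0, 3.0 * mp)
        elif m == "exact":
            out[m] = exact_pvalue(table, max_cells=max_cells).p_value
        else:
            raise ValidationError(f"unknown method {m!r}")
    return out


def run_experiment(
    config: SimulationConfig,
    methods: tuple[str, ...] = ("additive_only", "dominant_only", "recessive_only",
                                "min_p", "bonferroni"),
    exact_max_cells: float = DEFAULT_MAX_CELLS,
    exact_subsample: int | None = None,
    keep_pvalues: bool = False,
) -> ExperimentResult:
    """Monte-Carlo rejection proportions at ``config.alpha`` per method.

    Include ``"exact"`` in ``methods`` to evaluate the exact joint test;
    its per-replicate cost depends on the arm sizes (coprime arm sizes are
    by far the cheapest — see the exact-distribution module).  When the
    exact test is too heavy for every replicate, ``exact_subsample=k``
    evaluates it on the first k replicate streams only; its rejection
    proportion and standard error are then based on k replicates.
    """
    for m in methods:
        if m not in METHODS:
            raise ValidationError(f"unknown method {m!r}")
    if exact_subsample is not None and exact_subsample < 1:
        raise ValidationError("exact_subsample must be >= 1")
    streams = replicate_streams(config.seed, config.n_replicates)
    pvals: dict[str, list[float]] = {m: [] for m in methods}
    for i, rng in enumerate(streams):
        table = simulate_replicate(config, rng)
        wanted = tuple(
            m for m in methods
            if not (m == "exact" and exact_subsample is not None
                    and i >= exact_subsample)
        )
        for m, p in methods_pvalues(table, wanted, exact_max_cells).items():
            pvals[m].append(p)
    rates = {}
    ses = {}
    arrays = {m: np.asarray(v) for m, v in pvals.items()}
    for m, arr in arrays.items():
        rate = float(np.mean(arr <= config.alpha))
        rates[m] = rate
        ses[m] = math.sqrt(rate * (1.0 - rate) / len(arr))
    return ExperimentResult(
        config=config,
        rejection_rate=rates,
        std_error=ses,
        n_replicates=config.n_replicates,
        n_evaluated={m: len(arr) for m, arr in arrays.items()},
        p_values=arrays if keep_pvalues else {},
    )
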