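"""Monte Carlo generation of the simulated case-control sample.

The pipeline, run by :func:`simulate`:

1. solve the multi-logistic coefficients from the epidemiological spec;
2. assign each of the N individuals a genotype per genetic factor
   (independent loci, categorical draws from the genotype frequencies);
3. assign exposures per environmental factor (independent draws from each
   exposure distribution);
4. compute each individual's disease risk from the causal gene/environment
   pair only — the remaining factors are noisy background;
5. assign affected status by an independent Bernoulli draw per individual
   (status 1 iff a uniform [0,1) draw is strictly below the risk).

One root seed is expanded into independent named streams (genotypes,
exposures, status), so adding or reordering factors of one kind never
perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mlm import (
    EnvironmentDistribution,
    GeneralCoefficientTable,
    MLMCoefficients,
    logistic,
)
from .solver import (
    InteractionModel,
    PopulationSpec,
    SolverResult,
    solve_coefficients,
)

__all__ = [
    "Dataset",
    "sample_allele_freqs",
    "hwe_genotype_freqs",
    "assign_genotypes",
    "assign_exposures",
    "assign_risk",
    "assign_status",
    "simulate",
    "case_control_subsample",
]

_ALLELE_FREQ_LOW = 0.1
_ALLELE_FREQ_HIGH = 0.9


@dataclass
class Dataset:
    """Simulated sample: genotypes, exposures, per-individual risk and status.

    ``genotypes`` is N x G with values in {1, 2, 3} (AA/Aa/aa); ``exposures``
    is N x E.  ``risk`` and ``status`` are filled by :func:`assign_risk` and
    :func:`assign_status`.
    """

    genotypes: np.ndarray
    exposures: np.ndarray
    risk: np.ndarray | None = None
    status: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be an N x G matrix")
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.exposures.ndim != 2:
            raise ValueError("exposures must be an N x E matrix")
        if self.exposures.shape[0] != self.genotypes.shape[0]:
            raise ValueError("genotypes and exposures disagree on N")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_genes(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_envs(self) -> int:
        return self.exposures.shape[1]

    def to_dataframe(self, include_risk: bool = False) -> pd.DataFrame:
        """Tabular view: id, G* columns as risk-allele counts 0/1/2, E*, status."""
        if self.status is None:
            raise RuntimeError("dataset has no status yet; run the full pipeline")
        cols: dict[str, np.ndarray] = {"id": np.arange(1, self.n + 1)}
        for g in range(self.n_genes):
            cols[f"G{g + 1}"] = (self.genotypes[:, g] - 1).astype(np.int8)
        for e in range(self.n_envs):
            cols[f"E{e + 1}"] = self.exposures[:, e]
        if include_risk:
            if self.risk is None:
                raise RuntimeError("dataset has no risk column")
            cols["risk"] = self.risk
        cols["status"] = self.status.astype(np.int8)
        return pd.DataFrame(cols)

    def to_tsv(self, path, include_risk: bool = False) -> None:
        self.to_dataframe(include_risk).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def sample_allele_freqs(count: int, rng: np.random.Generator) -> np.ndarray:
    """Random allele frequencies, uniform on [0.1, 0.9]."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return rng.uniform(_ALLELE_FREQ_LOW, _ALLELE_FREQ_HIGH, size=count)


def hwe_genotype_freqs(p: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies (p^2, 2p(1-p), (1-p)^2).

    ``p`` is the frequency of the allele whose homozygote is the reference
    genotype (index 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must lie in (0, 1), got {p}")
    q = 1.0 - p
    return (p * p, 2.0 * p * q, q * q)


def _check_triple(t: Sequence[float]) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.shape != (3,) or np.any(t < 0) or abs(t.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid genotype-frequency triple {t}")
    return t


def assign_genotypes(
    n: int,
    freqs_per_gene: Sequence[Sequence[float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """N x G genotype matrix; column g ~ categorical(freqs_per_gene[g]), i.i.d."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = []
    for triple in freqs_per_gene:
        triple = _check_triple(triple)
        # inverse-CDF draw keeps the sampling scheme explicit and stream-stable
        cuts = np.cumsum(triple)[:2]
        cols.append(1 + np.searchsorted(cuts, rng.random(n), side="right"))
    return np.column_stack(cols).astype(np.int8)


def assign_exposures(
    n: int,
    dists: Sequence[EnvironmentDistribution],
    rng: np.random.Generator,
) -> np.ndarray:
    """N x E exposure matrix; column e drawn i.i.d. from dists[e]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.column_stack([d.sample(n, rng) for d in dists])


def assign_risk(
    dataset: Dataset,
    coeffs: MLMCoefficients | GeneralCoefficientTable,
    causal_gene_index: int | Sequence[int] = 0,
    causal_env_index: int | Sequence[int] = 0,
) -> Dataset:
    """Fill ``dataset.risk`` from the causal factor(s) only.

    With :class:`MLMCoefficients`, a single gene column and a single exposure
    column are causal.  With a :class:`GeneralCoefficientTable`, the index
    arguments list one gene column per table locus and one exposure column per
    covariate.  Noise columns never enter the risk.
    """
    if isinstance(coeffs, MLMCoefficients):
        gi = int(np.atleast_1d(causal_gene_index)[0])
        ei = int(np.atleast_1d(causal_env_index)[0])
        if not 0 <= gi < dataset.n_genes:
            raise ValueError(f"causal gene index {gi} out of range")
        if not 0 <= ei < dataset.n_envs:
            raise ValueError(f"causal environment index {ei} out of range")
        g = dataset.genotypes[:, gi]
        x = dataset.exposures[:, ei]
        alpha = np.asarray(coeffs.alpha)[g - 1]
        beta = np.asarray(coeffs.beta)[g - 1]
        dataset.risk = logistic(alpha + beta * x)
    else:
        gidx = [int(i) for i in np.atleast_1d(causal_gene_index)]
        eidx = [int(i) for i in np.atleast_1d(causal_env_index)]
        if len(gidx) != coeffs.n_genes or len(eidx) != coeffs.n_envs:
            raise ValueError(
                "causal index lists must match the coefficient table's "
                f"{coeffs.n_genes} loci and {coeffs.n_envs} covariates"
            )
        if any(not 0 <= i < dataset.n_genes for i in gidx):
            raise ValueError("causal gene index out of range")
        if any(not 0 <= i < dataset.n_envs for i in eidx):
            raise ValueError("causal environment index out of range")
        dataset.risk = logistic(
            coeffs.linear_predictor(
                dataset.genotypes[:, gidx], dataset.exposures[:, eidx]
            )
        )
    return dataset


def assign_status(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Bernoulli status: affected (1) iff a uniform draw is strictly < risk."""
    if dataset.risk is None:
        raise RuntimeError("assign_status requires risks; call assign_risk first")
    dataset.status = (rng.random(dataset.n) < dataset.risk).astype(np.int8)
    return dataset


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("genotypes", "exposures", "status")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


def simulate(
    spec: PopulationSpec,
    seed: int,
    coefficient_table: GeneralCoefficientTable | None = None,
) -> Dataset:
    """Run the full generation pipeline; deterministic given (spec, seed).

    For the four solvable interaction models the coefficients come from
    :func:`gxesim.solver.solve_coefficients` (any infeasibility surfaces
    before sampling starts).  For the CUSTOM model a
    :class:`GeneralCoefficientTable` must be supplied; its loci map onto the
    first gene columns and its covariates onto the first exposure columns.
    """
    if spec.model is InteractionModel.CUSTOM:
        if coefficient_table is None:
            raise ValueError("CUSTOM model requires a coefficient table")
        if coefficient_table.n_genes > spec.n_genes:
            raise ValueError("coefficient table uses more loci than the spec has genes")
        if coefficient_table.n_envs > spec.n_envs:
            raise ValueError(
                "coefficient table uses more covariates than the spec has environments"
            )
        result = None
    else:
        result = solve_coefficients(spec)

    rngs = _streams(seed)
    ds = Dataset(
        genotypes=assign_genotypes(
            spec.n_individuals, spec.genotype_freqs, rngs["genotypes"]
        ),
        exposures=assign_exposures(
            spec.n_individuals, spec.env_dists, rngs["exposures"]
        ),
    )
    if result is not None:
        assign_risk(
            ds,
            result.coefficients,
            spec.causal_gene_index,
            spec.causal_env_index,
        )
    else:
        assign_risk(
            ds,
            coefficient_table,
            list(range(coefficient_table.n_genes)),
            list(range(coefficient_table.n_envs)),
        )
    assign_status(ds, rngs["status"])
    ds.provenance = {
        "spec": spec.to_dict(),
        "seed": int(seed),
        "solver": result.to_dict() if result is not None else None,
        "coefficient_table": (
            coefficient_table.to_dict() if coefficient_table is not None else None
        ),
    }
    return ds


def case_control_subsample(
    dataset: Dataset,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> Dataset:
    """Draw a fixed cases:controls design from a simulated cohort.

    Convenience utility for matched study designs: the generation pipeline
    itself assigns status by independent Bernoulli draws, so case counts are
    binomial, not fixed.  Raises if the cohort holds too few of either group.
    """
    if dataset.status is None:
        raise RuntimeError("subsampling requires assigned status")
    cases = np.flatnonzero(dataset.status == 1)
    controls = np.flatnonzero(dataset.status == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"cohort has {len(cases)} cases / {len(controls)} controls; "
            f"requested {n_cases}/{n_controls}"
        )
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(cases, size=n_cases, replace=False),
                rng.choice(controls, size=n_controls, replace=False),
            ]
        )
    )
    return Dataset(
        genotypes=dataset.genotypes[keep],
        exposures=dataset.exposures[keep],
        risk=None if dataset.risk is None else dataset.risk[keep],
        status=dataset.status[keep],
        provenance={**dataset.provenance, "subsample": [n_cases, n_controls]},
    )
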