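"""Multi-logistic disease-risk model.

Disease risk is modelled as a logistic function of environmental exposure
whose coefficients are selected by genotype: an individual carrying genotype
``i`` of the causal biallelic SNP and exposed at level ``x`` has risk

    R(i, x) = expit(alpha_i + beta_i * x),   expit(z) = 1 / (1 + exp(-z))

so ``alpha_i`` is the basal (exposure-free) log-odds of disease for that
genotype and ``beta_i`` is the log odds ratio per one-unit increase in
exposure.  With G genes and E environmental covariates the model generalises
to one ``(alpha, beta-vector)`` pair per multi-locus genotype combination:

    R(g, x) = expit(alpha_g + sum_b beta_gb * x_b)

The *total risk* of a genotype is its risk marginalised over the exposure
distribution, TR_i = E_x[R(i, x)]; ratios of total risks are the relative
risks (RR_kl = TR_k / TR_l) used to parametrise the simulator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit as _expit

__all__ = [
    "GENOTYPES",
    "EnvironmentDistribution",
    "MLMCoefficients",
    "GeneralCoefficientTable",
    "logistic",
    "logit",
    "risk_1x1",
    "risk_general",
    "total_risk",
    "relative_risk",
    "heterozygote_rr",
]

#: Valid genotype indices: 1 = reference homozygote (AA), 2 = heterozygote
#: (Aa), 3 = high-risk homozygote (aa).
GENOTYPES = (1, 2, 3)

# Fixed Gauss-Legendre scheme for continuous-environment expectations:
# 256 nodes, integration range [mean - 8*sd, mean + 8*sd] for the normal
# (tail mass beyond 8 sigma is ~1e-15, far below the 1e-10 residual target).
_QUAD_NODES = 256
_NORMAL_RANGE_SIGMAS = 8.0
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_QUAD_NODES)

# expit saturates to exactly 0.0/1.0 in float beyond |z| ~ 745; risks are
# defined on the open interval, so clamp to the nearest representable
# neighbours.
_RISK_LO = np.nextafter(0.0, 1.0)
_RISK_HI = np.nextafter(1.0, 0.0)


def logistic(z):
    """Logistic (inverse-logit) function, strictly inside (0, 1).

    Parameters
    ----------
    z : float or array-like
        Log-odds.  Must be finite.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logistic requires finite log-odds input")
    out = np.clip(_expit(z), _RISK_LO, _RISK_HI)
    return float(out) if out.ndim == 0 else out


def logit(p):
    """Inverse of :func:`logistic` for p strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("logit requires probabilities strictly inside (0, 1)")
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def _check_genotype(i: int) -> int:
    if i not in GENOTYPES:
        raise ValueError(f"genotype index must be one of {GENOTYPES}, got {i!r}")
    return int(i)


@dataclass(frozen=True)
class EnvironmentDistribution:
    """Exposure law of one environmental factor.

    ``kind`` is one of ``"normal"`` (params mean, sd), ``"uniform"`` (params
    low, high) or ``"discrete"`` (explicit support values with probabilities).
    """

    kind: str
    mean: float | None = None
    sd: float | None = None
    low: float | None = None
    high: float | None = None
    values: tuple[float, ...] | None = None
    probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "normal":
            if self.mean is None or self.sd is None:
                raise ValueError("normal environment requires mean and sd")
            if not (self.sd > 0):
                raise ValueError("normal environment requires sd > 0")
        elif self.kind == "uniform":
            if self.low is None or self.high is None:
                raise ValueError("uniform environment requires low and high")
            if not (self.low < self.high):
                raise ValueError("uniform environment requires low < high")
        elif self.kind == "discrete":
            if not self.values or self.probs is None:
                raise ValueError("discrete environment requires values and probs")
            object.__setattr__(self, "values", tuple(float(v) for v in self.values))
            object.__setattr__(self, "probs", tuple(float(p) for p in self.probs))
            if len(self.values) != len(self.probs):
                raise ValueError("values and probs must have equal length")
            if any(p < 0 for p in self.probs):
                raise ValueError("discrete probabilities must be nonnegative")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError("discrete probabilities must sum to 1 (tol 1e-9)")
        else:
            raise ValueError(f"unknown environment kind {self.kind!r}")

    # --- convenience constructors -------------------------------------
    @classmethod
    def normal_dist(cls, mean: float, sd: float) -> "EnvironmentDistribution":
        return cls(kind="normal", mean=float(mean), sd=float(sd))

    @classmethod
    def uniform_dist(cls, low: float, high: float) -> "EnvironmentDistribution":
        return cls(kind="uniform", low=float(low), high=float(high))

    @classmethod
    def discrete_dist(
        cls, values: Sequence[float], probs: Sequence[float]
    ) -> "EnvironmentDistribution":
        return cls(kind="discrete", values=tuple(values), probs=tuple(probs))

    @classmethod
    def point_mass(cls, x: float) -> "EnvironmentDistribution":
        return cls.discrete_dist([x], [1.0])

    # --- properties ----------------------------------------------------
    @property
    def support_min(self) -> float:
        """Lower edge of the (numerical) support used by the quadrature."""
        if self.kind == "discrete":
            return min(self.values)
        if self.kind == "uniform":
            return float(self.low)
        return float(self.mean - _NORMAL_RANGE_SIGMAS * self.sd)

    def expectation(self) -> float:
        if self.kind == "discrete":
            return float(np.dot(self.values, self.probs))
        if self.kind == "uniform":
            return 0.5 * (self.low + self.high)
        return float(self.mean)

    def quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        """Nodes and normalised weights approximating E[f(x)] = sum w f(x)."""
        if self.kind == "discrete":
            return np.asarray(self.values), np.asarray(self.probs)
        if self.kind == "uniform":
            half = 0.5 * (self.high - self.low)
            x = 0.5 * (self.high + self.low) + half * _GL_X
            w = _GL_W * 0.5  # uniform density 1/(high-low) times half-width
        else:  # normal, truncated at +/- 8 sigma
            half = _NORMAL_RANGE_SIGMAS * self.sd
            x = self.mean + half * _GL_X
            pdf = np.exp(-0.5 * ((x - self.mean) / self.sd) ** 2) / (
                self.sd * math.sqrt(2.0 * math.pi)
            )
            w = _GL_W * half * pdf
        return x, w / w.sum()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "discrete":
            return rng.choice(np.asarray(self.values), size=n, p=np.asarray(self.probs))
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        return rng.normal(self.mean, self.sd, size=n)

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind == "normal":
            d.update(mean=self.mean, sd=self.sd)
        elif self.kind == "uniform":
            d.update(low=self.low, high=self.high)
        else:
            d.update(values=list(self.values), probs=list(self.probs))
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnvironmentDistribution":
        kind = d["kind"]
        if kind == "normal":
            return cls.normal_dist(d["mean"], d["sd"])
        if kind == "uniform":
            return cls.uniform_dist(d["low"], d["high"])
        if kind == "discrete":
            return cls.discrete_dist(d["values"], d["probs"])
        raise ValueError(f"unknown environment kind {kind!r}")


@dataclass(frozen=True)
class MLMCoefficients:
    """Per-genotype intercepts and slopes of the one-gene multi-logistic model.

    ``alpha[i-1]``/``beta[i-1]`` are the coefficients of genotype ``i`` for
    i in 1..3 (AA, Aa, aa).
    """

    alpha: tuple[float, float, float]
    beta: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if len(self.alpha) != 3 or len(self.beta) != 3:
            raise ValueError("one-gene model needs exactly three (alpha, beta) pairs")
        if not all(math.isfinite(v) for v in self.alpha + self.beta):
            raise ValueError("coefficients must be finite")

    def pairs(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.alpha, self.beta))

    def to_dict(self) -> dict:
        return {"alpha": list(self.alpha), "beta": list(self.beta)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MLMCoefficients":
        return cls(alpha=tuple(d["alpha"]), beta=tuple(d["beta"]))


class GeneralCoefficientTable:
    """Coefficients of the general (multi-gene, multi-environment) model.

    One ``(alpha, beta-vector)`` entry per multi-locus genotype combination;
    all ``3**G`` combinations must be present and every beta vector must have
    one slope per environmental covariate.  Serialised as JSON with keys like
    ``"1,3,2"``.
    """

    def __init__(self, entries: Mapping[tuple[int, ...], tuple[float, Sequence[float]]]):
        if not entries:
            raise ValueError("coefficient table must not be empty")
        keys = list(entries)
        g = len(keys[0])
        e = len(entries[keys[0]][1])
        expected = 3**g
        norm: dict[tuple[int, ...], tuple[float, tuple[float, ...]]] = {}
        for key, (alpha, beta) in entries.items():
            key = tuple(_check_genotype(i) for i in key)
            if len(key) != g:
                raise ValueError("all genotype tuples must have the same length")
            beta = tuple(float(b) for b in beta)
            if len(beta) != e:
                raise ValueError(
                    f"beta vector for {key} has length {len(beta)}, expected {e}"
                )
            norm[key] = (float(alpha), beta)
        if len(norm) != expected:
            raise ValueError(
                f"table must cover all {expected} genotype combinations for "
                f"G={g}; got {len(norm)}"
            )
        self._entries = norm
        self.n_genes = g
        self.n_envs = e
        # dense arrays in mixed-radix genotype order, for vectorised lookup
        self._alpha_arr = np.empty(expected)
        self._beta_arr = np.empty((expected, e))
        for key, (alpha, beta) in norm.items():
            idx = self._flat_index(np.asarray(key)[None, :])[0]
            self._alpha_arr[idx] = alpha
            self._beta_arr[idx] = beta

    @staticmethod
    def _flat_index(genotypes: np.ndarray) -> np.ndarray:
        # genotype tuple (i_1 .. i_G) in 1..3 -> base-3 integer
        g = genotypes.shape[1]
        radix = 3 ** np.arange(g - 1, -1, -1)
        return (genotypes - 1) @ radix

    def __contains__(self, key: tuple[int, ...]) -> bool:
        return tuple(key) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, key: tuple[int, ...]) -> tuple[float, tuple[float, ...]]:
        try:
            return self._entries[tuple(key)]
        except KeyError:
            raise KeyError(f"genotype combination {tuple(key)} not in table") from None

    def items(self):
        return self._entries.items()

    def linear_predictor(
        self, genotypes: np.ndarray, exposures: np.ndarray
    ) -> np.ndarray:
        """Vectorised alpha_g + beta_g . x for row-wise genotype/exposure data."""
        genotypes = np.atleast_2d(np.asarray(genotypes, dtype=int))
        exposures = np.atleast_2d(np.asarray(exposures, dtype=float))
        if genotypes.shape[1] != self.n_genes:
            raise ValueError("genotype tuple length does not match table")
        if exposures.shape[1] != self.n_envs:
            raise ValueError("exposure vector length does not match table")
        idx = self._flat_index(genotypes)
        return self._alpha_arr[idx] + np.einsum(
            "ne,ne->n", self._beta_arr[idx], exposures
        )

    # --- JSON round trip ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            ",".join(map(str, key)): {"alpha": alpha, "beta": list(beta)}
            for key, (alpha, beta) in sorted(self._entries.items())
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneralCoefficientTable":
        entries = {
            tuple(int(t) for t in key.split(",")): (v["alpha"], v["beta"])
            for key, v in d.items()
        }
        return cls(entries)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GeneralCoefficientTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_mlm(cls, coeffs: MLMCoefficients) -> "GeneralCoefficientTable":
        """Embed a one-gene/one-environment model as a general table."""
        return cls(
            {(i,): (coeffs.alpha[i - 1], (coeffs.beta[i - 1],)) for i in GENOTYPES}
        )


def risk_1x1(coeffs: MLMCoefficients, genotype: int, exposure: float):
    """Disease risk of one individual under the one-gene model.

    Returns ``logistic(alpha_i + beta_i * x)``; vectorised over ``exposure``.
    """
    i = _check_genotype(genotype)
    x = np.asarray(exposure, dtype=float)
    return logistic(coeffs.alpha[i - 1] + coeffs.beta[i - 1] * x)


def risk_general(
    table: GeneralCoefficientTable,
    genotypes: Sequence[int],
    exposures: Sequence[float],
) -> float:
    """Disease risk for one individual under the general model."""
    key = tuple(int(i) for i in genotypes)
    alpha, beta = table[key]  # raises KeyError on missing combination
    x = np.asarray(exposures, dtype=float)
    if x.shape != (len(beta),):
        raise ValueError(
            f"exposure vector length {x.size} does not match {len(beta)} covariates"
        )
    return float(logistic(alpha + float(np.dot(beta, x))))


def total_risk(alpha: float, beta: float, env: EnvironmentDistribution) -> float:
    """Total (marginal) risk TR = E_x[logistic(alpha + beta x)].

    Exact weighted sum for a discrete exposure; 256-node Gauss-Legendre
    quadrature (normalised weights) over the distribution's numerical support
    for continuous exposures.
    """
    x, w = env.quadrature()
    tr = float(np.dot(w, logistic(alpha + beta * x)))
    if not math.isfinite(tr):
        raise ArithmeticError(
            f"total-risk quadrature diverged: TR={tr!r} for alpha={alpha}, "
            f"beta={beta}, env={env.kind}"
        )
    # the weighted mean of values in (0,1) can round to exactly 0 or 1 in
    # float at extreme coefficients; keep the result on the open interval
    return float(np.clip(tr, _RISK_LO, _RISK_HI))


def relative_risk(tr_k: float, tr_l: float) -> float:
    """Relative risk RR_kl = TR_k / TR_l."""
    if tr_l == 0:
        raise ZeroDivisionError("relative risk undefined for zero reference risk")
    return tr_k / tr_l


def heterozygote_rr(rr31: float, w: float) -> float:
    """Heterozygote relative risk RR21 = 1 + W * (RR31 - 1).

    The inheritance weight ``W`` interpolates on the relative-risk scale
    between the recessive (W=0, RR21=1) and dominant (W=1, RR21=RR31)
    endpoints, guaranteeing 1 <= RR21 <= RR31.
    """
    if not rr31 >= 1.0:
        raise ValueError(f"rr31 must be >= 1, got {rr31}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"inheritance weight must lie in [0, 1], got {w}")
    return 1.0 + w * (rr31 - 1.0)
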