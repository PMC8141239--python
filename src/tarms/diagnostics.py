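"""Diagnostic-test evaluation against a reference test.

Two routes are provided for a 2x2 cross-tabulation of an index test against
a reference test:

* conventional metrics, treating the reference as a gold standard —
  sensitivity, specificity, PPV and NPV with exact Clopper-Pearson 95%
  confidence intervals; and

* the Hui-Walter Bayesian latent class model, which treats BOTH tests as
  imperfect: each animal has a latent true status, prevalence pi and the two
  tests' Se/Sp generate the four cell probabilities

      p11 = pi Se1 Se2         + (1-pi)(1-Sp1)(1-Sp2)
      p10 = pi Se1 (1-Se2)     + (1-pi)(1-Sp1) Sp2
      p01 = pi (1-Se1) Se2     + (1-pi) Sp1 (1-Sp2)
      p00 = pi (1-Se1)(1-Se2)  + (1-pi) Sp1 Sp2

  and inference is by Gibbs sampling with latent-status augmentation: the
  full conditionals are conjugate (binomial splits of the four observed
  cells, then Beta updates), so the sampler is exact by construction.

A single population with two tests gives 3 degrees of freedom for 5
parameters: the model is only partially identifiable and priors matter. With
all-uniform priors a prominent warning is emitted. Exposed statsmodels-style
as ``HuiWalterModel(...).fit() -> HuiWalterResults``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CrossTab",
    "BetaPrior",
    "LatentClassPrior",
    "MetricEstimate",
    "conventional_metrics",
    "ppv_npv_from",
    "HuiWalterModel",
    "HuiWalterResults",
    "hui_walter_gibbs",
    "bayesian_p_value",
    "gelman_rubin",
]

CELLS = ("n11", "n10", "n01", "n00")
BASE_PARAMS = ("pi", "se1", "sp1", "se2", "sp2")
DERIVED_PARAMS = ("ppv1", "npv1", "ppv2", "npv2")
ALL_PARAMS = BASE_PARAMS + DERIVED_PARAMS


@dataclass(frozen=True)
class CrossTab:
    """2x2 cross-tabulation: index test (1) vs reference test (2).

    ``n11`` = index+/ref+, ``n10`` = index+/ref-, ``n01`` = index-/ref+,
    ``n00`` = index-/ref-.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for cell in CELLS:
            v = getattr(self, cell)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{cell} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("cross-tabulation must contain at least one observation")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        return np.array([self.n11, self.n10, self.n01, self.n00], dtype=np.int64)


@dataclass(frozen=True)
class BetaPrior:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta prior parameters must be strictly positive")

    @property
    def is_uniform(self) -> bool:
        return self.alpha == 1.0 and self.beta == 1.0


@dataclass(frozen=True)
class LatentClassPrior:
    """Beta priors for prevalence and the two tests' accuracies.

    Defaults: Beta(1,1) on prevalence, Beta(2,1) on every Se/Sp — mild
    regularization toward informative tests, since the one-population
    two-test model is not fully identifiable from data alone.
    """

    pi: BetaPrior = BetaPrior(1.0, 1.0)
    se1: BetaPrior = BetaPrior(2.0, 1.0)
    sp1: BetaPrior = BetaPrior(2.0, 1.0)
    se2: BetaPrior = BetaPrior(2.0, 1.0)
    sp2: BetaPrior = BetaPrior(2.0, 1.0)

    @property
    def all_uniform(self) -> bool:
        return all(
            getattr(self, p).is_uniform for p in BASE_PARAMS
        )


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact (Clopper-Pearson) 95% interval."""

    name: str
    numerator: int
    denominator: int
    estimate: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.estimate is not None

    @property
    def pct(self) -> float | None:
        return None if self.estimate is None else 100.0 * self.estimate


def _metric(name: str, num: int, den: int) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(name, num, den, None, None, None)
    lo, hi = proportion_confint(num, den, alpha=0.05, method="beta")
    lo = 0.0 if np.isnan(lo) else float(lo)
    hi = 1.0 if np.isnan(hi) else float(hi)
    return MetricEstimate(name, num, den, num / den, lo, hi)


def conventional_metrics(ct: CrossTab) -> dict[str, MetricEstimate]:
    """Se/Sp/PPV/NPV of the index test taking the reference as gold standard.

    Zero denominators yield an undefined (flagged) metric rather than an
    error.
    """
    return {
        "sensitivity": _metric("sensitivity", ct.n11, ct.n11 + ct.n01),
        "specificity": _metric("specificity", ct.n00, ct.n00 + ct.n10),
        "ppv": _metric("ppv", ct.n11, ct.n11 + ct.n10),
        "npv": _metric("npv", ct.n00, ct.n00 + ct.n01),
    }


def ppv_npv_from(
    se: float, sp: float, prevalence: float
) -> tuple[float | None, float | None]:
    """Predictive values from Se, Sp and prevalence via Bayes' rule.

    ppv = se*pi / (se*pi + (1-sp)(1-pi)); npv = sp(1-pi) / (sp(1-pi) +
    (1-se)pi). A 0/0 denominator yields None for that value.
    """
    for name, v in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    num_p = se * prevalence
    den_p = num_p + (1.0 - sp) * (1.0 - prevalence)
    num_n = sp * (1.0 - prevalence)
    den_n = num_n + (1.0 - se) * prevalence
    # boundary prevalences make the corresponding conditional vacuous
    ppv = None if (den_p == 0 or prevalence == 0) else num_p / den_p
    npv = None if (den_n == 0 or prevalence == 1) else num_n / den_n
    return ppv, npv


def _cell_probs(theta: np.ndarray) -> np.ndarray:
    """Cell probabilities (..., 4) from parameter draws (..., 5)."""
    pi, se1, sp1, se2, sp2 = (theta[..., i] for i in range(5))
    p11 = pi * se1 * se2 + (1 - pi) * (1 - sp1) * (1 - sp2)
    p10 = pi * se1 * (1 - se2) + (1 - pi) * (1 - sp1) * sp2
    p01 = pi * (1 - se1) * se2 + (1 - pi) * sp1 * (1 - sp2)
    p00 = pi * (1 - se1) * (1 - se2) + (1 - pi) * sp1 * sp2
    return np.stack([p11, p10, p01, p00], axis=-1)


def gelman_rubin(chains: Sequence[np.ndarray] | np.ndarray) -> float:
    """Potential scale reduction factor (classic Gelman-Rubin R-hat).

    ``chains`` is an (m, n) array or a sequence of m equal-length draw
    vectors, m >= 2. Returns sqrt(((n-1)/n W + B/n) / W); equals
    sqrt((n-1)/n) ~ 1 for identical chains and grows with between-chain
    disagreement.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must form a 2-D (m, n) array of draws")
    m, n = arr.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs >=2 chains; run more chains")
    if n < 2:
        raise ValueError("chains must contain >=2 draws")
    means = arr.mean(axis=1)
    within = arr.var(axis=1, ddof=1).mean()
    between_over_n = means.var(ddof=1)  # = B/n
    if within == 0:
        return 1.0 if between_over_n == 0 else float("inf")
    var_hat = (n - 1) / n * within + between_over_n
    return float(np.sqrt(var_hat / within))


def bayesian_p_value(
    ct: CrossTab,
    cell_prob_draws: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Posterior-predictive mid-p value per cell of the 2x2 table.

    For each posterior draw a replicate table is simulated from
    Multinomial(N, p(theta)); the per-cell tail probability
    P(rep > obs) + 0.5 P(rep = obs) centers at 0.5 under perfect fit.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = np.asarray(cell_prob_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != 4:
        raise ValueError("cell_prob_draws must have shape (draws, 4)")
    obs = ct.as_array()
    reps = rng.multinomial(ct.total, draws)  # (draws, 4)
    greater = (reps > obs).mean(axis=0)
    equal = (reps == obs).mean(axis=0)
    p = greater + 0.5 * equal
    return dict(zip(CELLS, (float(x) for x in p)))


@dataclass(frozen=True)
class HuiWalterResults:
    """Posterior summaries from the Hui-Walter Gibbs sampler.

    ``draws`` has shape (chains, kept_iterations, 9) in the parameter order
    pi, se1, sp1, se2, sp2, ppv1, npv1, ppv2, npv2.
    """

    crosstab: CrossTab
    prior: LatentClassPrior
    draws: np.ndarray
    chains: int
    iterations: int
    burn_in: int
    seed: int
    bayes_p: dict[str, float]
    rhat: dict[str, float] = field(default_factory=dict)

    def flat(self, param: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.draws[..., ALL_PARAMS.index(param)].reshape(-1)

    def median(self, param: str) -> float:
        return float(np.median(self.flat(param)))

    def interval(self, param: str, prob: float = 0.95) -> tuple[float, float]:
        """Central posterior probability interval."""
        a = (1.0 - prob) / 2.0
        lo, hi = np.quantile(self.flat(param), [a, 1.0 - a])
        return float(lo), float(hi)

    def summary(self) -> pd.DataFrame:
        """Posterior median, 95% probability interval and R-hat per parameter."""
        rows = []
        for p in ALL_PARAMS:
            lo, hi = self.interval(p)
            rows.append(
                {
                    "parameter": p,
                    "median": self.median(p),
                    "ci2.5": lo,
                    "ci97.5": hi,
                    "rhat": self.rhat.get(p, float("nan")),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def __str__(self) -> str:
        head = (
            f"Hui-Walter latent class model: {self.chains} chains x "
            f"{self.iterations} iterations ({self.burn_in} burn-in), "
            f"seed {self.seed}\n"
        )
        pp = ", ".join(f"{k}={v:.3f}" for k, v in self.bayes_p.items())
        return head + self.summary().to_string(float_format="%.4f") + (
            f"\nposterior-predictive p: {pp}"
        )


class HuiWalterModel:
    """One-population, two-test Bayesian latent class model.

    Conditional independence of the two tests given the latent status is
    assumed. ``fit`` runs latent-status-augmented Gibbs sampling; identical
    (seed, inputs) give identical output.
    """

    def __init__(self, crosstab: CrossTab, prior: LatentClassPrior | None = None):
        self.crosstab = crosstab
        self.prior = prior or LatentClassPrior()
        if self.prior.all_uniform:
            warnings.warn(
                "All five priors are uniform: the one-population two-test "
                "latent class model has 5 parameters but only 3 degrees of "
                "freedom, so the posterior is driven by the priors in two "
                "directions. Provide informative priors for at least two "
                "parameters; proceeding anyway.",
                UserWarning,
                stacklevel=2,
            )

    def fit(
        self,
        chains: int = 2,
        iterations: int = 20_000,
        burn_in: int = 5_000,
        seed: int = 0,
        constrain_accuracy: bool = False,
    ) -> HuiWalterResults:
        """Run the Gibbs sampler and summarize the posterior.

        ``constrain_accuracy=True`` opts into the label-switching guard that
        restricts each test to Se + Sp > 1 (rejection within the conjugate
        updates, i.e. sampling from the truncated full conditionals).
        """
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        if chains < 2:
            raise ValueError("need >=2 chains for convergence diagnostics")
        n = self.crosstab.as_array()
        pri = self.prior
        root = np.random.SeedSequence(seed)
        chain_seeds = root.spawn(chains + 1)
        kept = iterations - burn_in
        draws = np.empty((chains, kept, len(ALL_PARAMS)))

        for c in range(chains):
            rng = np.random.default_rng(chain_seeds[c])
            draws[c] = _run_chain(
                n, pri, iterations, burn_in, rng, constrain_accuracy
            )

        rhat = {
            p: gelman_rubin(draws[:, :, i]) for i, p in enumerate(ALL_PARAMS)
        }
        cell_probs = _cell_probs(draws[..., :5].reshape(-1, 5))
        bayes_p = bayesian_p_value(
            self.crosstab, cell_probs, np.random.default_rng(chain_seeds[-1])
        )
        return HuiWalterResults(
            crosstab=self.crosstab,
            prior=pri,
            draws=draws,
            chains=chains,
            iterations=iterations,
            burn_in=burn_in,
            seed=seed,
            bayes_p=bayes_p,
            rhat=rhat,
        )


def _beta_constrained(
    rng: np.random.Generator, a: float, b: float, floor: float | None
) -> float:
    """Beta(a, b) draw, optionally rejected below a moving floor."""
    if floor is None:
        return rng.beta(a, b)
    for _ in range(1000):
        x = rng.beta(a, b)
        if x > floor:
            return x
    # extremely concentrated conditional below the floor: fall back to the
    # truncation boundary neighbourhood via inverse-cdf-free clamping
    return max(rng.beta(a, b), np.nextafter(floor, 1.0))


def _run_chain(
    n: np.ndarray,
    pri: LatentClassPrior,
    iterations: int,
    burn_in: int,
    rng: np.random.Generator,
    constrain_accuracy: bool,
) -> np.ndarray:
    n11, n10, n01, n00 = (int(x) for x in n)
    total = int(n.sum())
    # initialize from the priors
    pi = rng.beta(pri.pi.alpha, pri.pi.beta)
    se1 = rng.beta(pri.se1.alpha, pri.se1.beta)
    sp1 = rng.beta(pri.sp1.alpha, pri.sp1.beta)
    se2 = rng.beta(pri.se2.alpha, pri.se2.beta)
    sp2 = rng.beta(pri.sp2.alpha, pri.sp2.beta)

    kept = iterations - burn_in
    out = np.empty((kept, len(ALL_PARAMS)))
    for it in range(iterations):
        # (a) latent-status split of each observed cell
        pos = np.array(
            [
                pi * se1 * se2,
                pi * se1 * (1 - se2),
                pi * (1 - se1) * se2,
                pi * (1 - se1) * (1 - se2),
            ]
        )
        neg = np.array(
            [
                (1 - pi) * (1 - sp1) * (1 - sp2),
                (1 - pi) * (1 - sp1) * sp2,
                (1 - pi) * sp1 * (1 - sp2),
                (1 - pi) * sp1 * sp2,
            ]
        )
        denom = pos + neg
        prob_pos = np.where(denom > 0, pos / np.where(denom > 0, denom, 1.0), 0.0)
        y = rng.binomial([n11, n10, n01, n00], prob_pos)
        y11, y10, y01, y00 = (int(v) for v in y)
        d = y11 + y10 + y01 + y00  # latent positives

        # (b) conjugate Beta updates
        pi = rng.beta(pri.pi.alpha + d, pri.pi.beta + total - d)
        floor1 = (1 - sp1) if constrain_accuracy else None
        se1 = _beta_constrained(
            rng, pri.se1.alpha + y11 + y10, pri.se1.beta + y01 + y00, floor1
        )
        floor1 = (1 - se1) if constrain_accuracy else None
        sp1 = _beta_constrained(
            rng,
            pri.sp1.alpha + (n01 - y01) + (n00 - y00),
            pri.sp1.beta + (n11 - y11) + (n10 - y10),
            floor1,
        )
        floor2 = (1 - sp2) if constrain_accuracy else None
        se2 = _beta_constrained(
            rng, pri.se2.alpha + y11 + y01, pri.se2.beta + y10 + y00, floor2
        )
        floor2 = (1 - se2) if constrain_accuracy else None
        sp2 = _beta_constrained(
            rng,
            pri.sp2.alpha + (n10 - y10) + (n00 - y00),
            pri.sp2.beta + (n11 - y11) + (n01 - y01),
            floor2,
        )

        if it >= burn_in:
            ppv1, npv1 = ppv_npv_from(se1, sp1, pi)
            ppv2, npv2 = ppv_npv_from(se2, sp2, pi)
            out[it - burn_in] = (
                pi, se1, sp1, se2, sp2,
                np.nan if ppv1 is None else ppv1,
                np.nan if npv1 is None else npv1,
                np.nan if ppv2 is None else ppv2,
                np.nan if npv2 is None else npv2,
            )
    return out


def hui_walter_gibbs(
    ct: CrossTab,
    prior: LatentClassPrior | None = None,
    chains: int = 2,
    iterations: int = 20_000,
    burn_in: int = 5_000,
    seed: int = 0,
    constrain_accuracy: bool = False,
) -> HuiWalterResults:
    """Functional facade over :class:`HuiWalterModel` (see its docs)."""
    return HuiWalterModel(ct, prior).fit(
        chains=chains,
        iterations=iterations,
        burn_in=burn_in,
        seed=seed,
        constrain_accuracy=constrain_accuracy,
    )
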