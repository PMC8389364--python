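"""Probability model of countercurrent fractionation.

The countercurrent apparatus gives each fly ``n`` successive opportunities
(default 5) to walk toward a light; the fly's final tube index equals the
number of positive choices.  Two generative accounts of the resulting tube
occupancy are treated side by side:

* **spontaneity** — every fly shares one walk probability ``p`` and makes
  history-independent choices, so tube counts follow Binomial(n, p);
* **individuality** — each fly owns a latent walk probability drawn from
  Beta(alpha, beta), so tube counts follow the beta-binomial distribution,
  and a fly's first-session tube is informative about its retest.

Both models are fitted to observed tube counts by maximum likelihood under
a multinomial sampling model and compared by AIC; the beta-binomial fit
yields closed-form posterior-predictive retest curves: conditioning on a
first-session tube k gives p ~ Beta(alpha+k, beta+n-k), hence an expected
second-session Performance Index of n*(alpha+k)/(alpha+beta+n), strictly
increasing in k — the signature of individuality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import betaln, gammaln

from .indices import CPPTubeCounts

__all__ = [
    "ChoiceSequence",
    "TubeDistribution",
    "ModelFit",
    "RetestPrediction",
    "tube_assignment",
    "tube_distribution_binomial",
    "tube_distribution_betabinomial",
    "fit_tube_model",
    "likelihood_ratio_test",
    "predict_retest",
]

ChoiceSequence = Sequence[int]


@dataclass(frozen=True)
class TubeDistribution:
    """Probability mass over tubes 0..n_choices under a named model."""

    probs: np.ndarray
    model: str
    params: dict

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("tube probabilities must be non-negative and sum to 1")

    @property
    def n_choices(self) -> int:
        return self.probs.size - 1

    def mean_pi(self) -> float:
        """Expected Performance Index under this distribution."""
        return float(np.arange(self.probs.size) @ self.probs)

    def tv_distance(self, other: "TubeDistribution | np.ndarray") -> float:
        """Total-variation distance to another distribution or frequency vector."""
        q = other.probs if isinstance(other, TubeDistribution) else np.asarray(other, float)
        return 0.5 * float(np.abs(self.probs - q).sum())


@dataclass
class ModelFit:
    """Maximum-likelihood fit of a tube-occupancy model."""

    model: str
    params: dict
    loglik: float
    aic: float
    n_choices: int
    n_flies: int
    converged: bool = True
    boundary: bool = False

    def distribution(self) -> TubeDistribution:
        if self.model == "binomial":
            return tube_distribution_binomial(self.params["p"], self.n_choices)
        return tube_distribution_betabinomial(
            self.params["alpha"], self.params["beta"], self.n_choices
        )


@dataclass(frozen=True)
class RetestPrediction:
    """Posterior-predictive second-session outcome for one first-session tube."""

    first_tube: int
    tube_probs: np.ndarray
    mean_pi: float
    posterior: tuple[float, float] | None  # (alpha, beta) or None for binomial


def tube_assignment(seq: ChoiceSequence) -> int:
    """Tube index of one fly: the number of walk (1) outcomes in its sequence.

    Order-invariant by construction — the apparatus cannot distinguish two
    sequences with the same number of positive choices.
    """
    tube = 0
    for c in seq:
        if isinstance(c, bool):
            c = int(c)
        if c not in (0, 1):
            raise ValueError(f"choice outcomes must be 0 or 1, got {c!r}")
        tube += c
    return tube


def tube_distribution_binomial(p: float, n_choices: int = 5) -> TubeDistribution:
    """Tube occupancy under a shared walk probability: Binomial(n_choices, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    probs = stats.binom.pmf(np.arange(n_choices + 1), n_choices, p)
    probs = probs / probs.sum()
    return TubeDistribution(probs, "binomial", {"p": float(p)})


def tube_distribution_betabinomial(alpha: float, beta: float,
                                   n_choices: int = 5) -> TubeDistribution:
    """Tube occupancy under Beta(alpha, beta) latent preferences."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta-binomial shapes must be positive")
    probs = stats.betabinom.pmf(np.arange(n_choices + 1), n_choices, alpha, beta)
    probs = probs / probs.sum()
    return TubeDistribution(probs, "betabinomial",
                            {"alpha": float(alpha), "beta": float(beta)})


def _as_counts(observed: CPPTubeCounts | Sequence[int]) -> np.ndarray:
    if isinstance(observed, CPPTubeCounts):
        return np.asarray(observed.counts, dtype=float)
    return np.asarray(observed, dtype=float)


def fit_tube_model(observed: CPPTubeCounts | Sequence[int],
                   model: str = "betabinomial",
                   tol: float = 1e-8) -> ModelFit:
    """Maximum-likelihood fit of tube counts under the multinomial likelihood.

    The binomial MLE is the closed-form mean walk fraction; the
    beta-binomial likelihood is maximized over log-shapes from the fixed
    starting point alpha = beta = 1 (Nelder–Mead, tolerance ``tol``), which
    makes the fit deterministic.  Degenerate data with all flies in a single
    tube drives either model to its boundary; the fit is returned with
    ``boundary=True`` rather than raising.
    """
    counts = _as_counts(observed)
    n = counts.size - 1
    total = counts.sum()
    if total <= 0:
        raise ValueError("no flies observed in any tube")
    ks = np.arange(n + 1)

    if model == "binomial":
        p_hat = float(ks @ counts) / (n * total)
        with np.errstate(divide="ignore"):
            logpmf = stats.binom.logpmf(ks, n, p_hat)
        ll = float(counts[counts > 0] @ logpmf[counts > 0])
        return ModelFit("binomial", {"p": p_hat}, ll, 2 * 1 - 2 * ll,
                        n, int(total), boundary=p_hat in (0.0, 1.0))

    if model != "betabinomial":
        raise ValueError("model must be 'binomial' or 'betabinomial'")

    log_choose = gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)

    def negll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        logpmf = log_choose + betaln(ks + a, n - ks + b) - betaln(a, b)
        return -float(counts[counts > 0] @ logpmf[counts > 0])

    res = optimize.minimize(
        negll, x0=np.array([0.0, 0.0]), method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": 4000},
    )
    a_hat, b_hat = np.exp(res.x)
    ll = -float(res.fun)
    # shapes running off to +/- inf on the log scale signal a boundary fit
    # (pure binomial limit or a point mass in tube 0 or n)
    boundary = bool(np.any(np.abs(res.x) > math.log(1e6)))
    return ModelFit("betabinomial", {"alpha": float(a_hat), "beta": float(b_hat)},
                    ll, 2 * 2 - 2 * ll, n, int(total),
                    converged=bool(res.success), boundary=boundary)


def likelihood_ratio_test(fit_binomial: ModelFit,
                          fit_betabinomial: ModelFit) -> tuple[float, float]:
    """Approximate LRT of binomial (null) vs beta-binomial (alternative).

    Returns (statistic, p-value) using the chi-square reference with 1 df.
    The binomial model sits on the boundary of the beta-binomial family
    (infinite shapes), so the reference distribution is approximate and
    conservative; AIC comparison is the primary criterion.
    """
    stat = 2.0 * (fit_betabinomial.loglik - fit_binomial.loglik)
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


def predict_retest(first_tube: int,
                   model: ModelFit | TubeDistribution | dict,
                   n_choices: int = 5) -> RetestPrediction:
    """Expected second-session tube distribution for one first-session tube.

    Under the beta-binomial (individuality) model the latent preference of
    a fly observed in tube k has posterior Beta(alpha+k, beta+n-k), so the
    predicted second-session occupancy is beta-binomial with those shapes
    and the expected PI is n*(alpha+k)/(alpha+beta+n) — strictly increasing
    in k.  Under the binomial (spontaneity) model the prediction ignores k.
    """
    if not 0 <= first_tube <= n_choices:
        raise ValueError(f"first_tube must lie in 0..{n_choices}")
    if isinstance(model, (ModelFit, TubeDistribution)):
        name, params = model.model, model.params
    else:
        params = dict(model)
        name = "betabinomial" if "alpha" in params else "binomial"

    if name == "binomial":
        dist = tube_distribution_binomial(params["p"], n_choices)
        return RetestPrediction(first_tube, dist.probs,
                                n_choices * params["p"], None)
    a = params["alpha"] + first_tube
    b = params["beta"] + n_choices - first_tube
    dist = tube_distribution_betabinomial(a, b, n_choices)
    return RetestPrediction(first_tube, dist.probs,
                            n_choices * a / (a + b), (a, b))
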