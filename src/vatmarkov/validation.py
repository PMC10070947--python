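"""Qualitative and quantitative model validation statistics.

Qualitative scoring: each microenvironment defines an expected ordering of
phenotype frequencies (e.g. "Th1 > Th2" under IL-12 + IFN-g).  The model's
stationary distribution is checked against that relation at every noise
level; a satisfied relation scores 1, a failed one 0.  The pooled successes
feed a one-tailed exact binomial test against p0 = 0.5 — is the model right
more often than a coin flip? — reported together with the one-sided exact
(Clopper-Pearson) lower confidence bound on the success probability.

Quantitative scoring: simulated phenotype frequencies are correlated with
observed (e.g. flow-cytometry) frequencies; the report carries the multiple
correlation coefficient R_xx, the squared Pearson coefficient R2, the
adjusted R2 and the F-test p-value of the single-predictor regression.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BinomialReport", "QualitativeTrial", "CorrelationReport",
    "binomial_one_tailed", "score_trials", "multiple_correlation",
]

log = logging.getLogger(__name__)

ZERO_EPS = 1e-9


@dataclass(frozen=True)
class BinomialReport:
    """One-tailed exact binomial test of success probability vs p0."""

    successes: int
    trials: int
    p_hat: float
    ci_lower: float
    alpha: float
    p_value: float
    p0: float = 0.5

    def summary(self) -> str:
        """Human-readable one-liner in the validation-table row format."""
        return (f"Trials n = {self.trials}, "
                f"Binomial probability of success = {self.p_hat:.4g}, "
                f"CI: {self.ci_lower:.4f} - 1, "
                f"alpha = {self.alpha * 100:g}%, "
                f"p-value = {self.p_value:.4g}")


def binomial_one_tailed(successes: int, trials: int, p0: float = 0.5,
                        alpha: float = 0.05) -> BinomialReport:
    """Exact one-tailed binomial test (alternative: p > p0).

    The p-value is the exact upper tail sum
    ``sum_{k=successes}^{trials} C(trials, k) p0^k (1-p0)^(trials-k)``
    (no normal approximation), and the confidence bound is the one-sided
    exact Clopper-Pearson lower limit, i.e. the Beta(alpha; s, n-s+1)
    quantile, with 0 when there are no successes.
    """
    successes = int(successes)
    trials = int(trials)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ValueError(f"successes must be in [0, {trials}]")
    p_value = float(stats.binomtest(successes, trials, p=p0,
                                    alternative="greater").pvalue)
    if successes == 0:
        ci_lower = 0.0
    else:
        ci_lower = float(stats.beta.ppf(alpha, successes,
                                        trials - successes + 1))
    return BinomialReport(successes=successes, trials=trials,
                          p_hat=successes / trials, ci_lower=ci_lower,
                          alpha=alpha, p_value=p_value, p0=p0)


# --------------------------------------------------------------------------
# Qualitative trial scoring
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QualitativeTrial:
    """One scored relation under one microenvironment at one noise level."""

    condition: str
    relation: str
    noise: float
    score: int
    detail: str = ""


_REL_GT = re.compile(r"^\s*(?P<a>.+?)\s*>\s*(?P<b>.+?)\s*$")
_REL_ZERO = re.compile(r"^\s*others\s*=\s*0\s*%?\s*$", re.IGNORECASE)


def _mass(term: str, dist: Mapping[str, float],
          valid_labels: Iterable[str] | None) -> float:
    """Frequency mass of a relation term.

    A term is an exact phenotype label, or a marker token such as "GLUT4+"
    or "TNF-" that aggregates every label containing it (the adipocyte
    relations are stated over single markers).
    """
    if term in dist:
        return float(dist[term])
    token_hits = [l for l in dist if term in l.split()]
    if token_hits:
        return float(sum(dist[l] for l in token_hits))
    universe = set(valid_labels or ())
    if term in universe or any(term in l.split() for l in universe):
        return 0.0  # a legitimate phenotype that simply never appeared
    raise ValueError(f"relation references unknown phenotype {term!r}")


def evaluate_relation(relation: str, dist: Mapping[str, float],
                      valid_labels: Iterable[str] | None = None,
                      baseline: str | None = None,
                      zero_eps: float = ZERO_EPS) -> tuple[int, str]:
    """Score one relation against a phenotype-frequency mapping.

    Supported forms:

    * ``"A > B"``        — strict inequality of masses; ties score 0.
    * ``"A > others"``   — A's mass strictly exceeds every other label's.
    * ``"Others = 0%"``  — all labels except the ``baseline`` have mass
      below ``zero_eps``.
    """
    if _REL_ZERO.match(relation):
        if baseline is None:
            raise ValueError('"Others = 0%" needs a baseline phenotype')
        residual = sum(v for l, v in dist.items() if l != baseline)
        ok = all(v < zero_eps for l, v in dist.items() if l != baseline)
        return int(ok), f"non-{baseline} mass = {residual:.3g}"
    m = _REL_GT.match(relation)
    if not m:
        raise ValueError(f"cannot parse relation {relation!r}")
    a, b = m.group("a"), m.group("b")
    ma = _mass(a, dist, valid_labels)
    if b.lower() == "others":
        others = {l: v for l, v in dist.items() if l != a}
        ok = all(ma > v for v in others.values()) if others else True
        top = max(others.values(), default=0.0)
        if ma == top:
            log.warning("relation %r tied (%.4g); ties score 0", relation, ma)
        return int(ok), f"{a} = {ma:.4g}, max other = {top:.4g}"
    mb = _mass(b, dist, valid_labels)
    if ma == mb:
        log.warning("relation %r tied at %.4g; ties score 0", relation, ma)
    return int(ma > mb), f"{a} = {ma:.4g}, {b} = {mb:.4g}"


def score_trials(distributions: Mapping[tuple[str, float], Mapping[str, float]],
                 trial_specs: Sequence[Mapping[str, object]],
                 valid_labels: Iterable[str] | None = None,
                 p0: float = 0.5, alpha: float = 0.05
                 ) -> tuple[list[QualitativeTrial], BinomialReport]:
    """Score relation specs against per-(condition, noise) distributions.

    ``trial_specs`` entries carry ``condition``, ``relation`` and optionally
    ``baseline`` (for the zero-assertion) and ``noise_levels``; absent
    noise_levels means every noise level available for that condition.
    Each (spec, noise) pair is one Bernoulli trial; pooled totals feed the
    one-tailed binomial test.
    """
    trial_specs = list(trial_specs)
    if not trial_specs:
        raise ValueError("empty trial list — refusing a vacuous pass")
    trials: list[QualitativeTrial] = []
    for spec in trial_specs:
        condition = str(spec["condition"])
        relation = str(spec["relation"])
        baseline = spec.get("baseline")
        noises = spec.get("noise_levels")
        if noises is None:
            noises = sorted({n for (c, n) in distributions if c == condition})
        if not noises:
            raise ValueError(f"no distributions for condition {condition!r}")
        for noise in noises:
            key = (condition, float(noise))
            if key not in distributions:
                raise ValueError(f"missing distribution for {key!r}")
            dist = distributions[key]
            if hasattr(dist, "as_dict"):
                dist = dist.as_dict()
            score, detail = evaluate_relation(relation, dist, valid_labels,
                                              baseline=baseline)
            trials.append(QualitativeTrial(condition, relation, float(noise),
                                           score, detail))
    report = binomial_one_tailed(sum(t.score for t in trials), len(trials),
                                 p0=p0, alpha=alpha)
    return trials, report


# --------------------------------------------------------------------------
# Quantitative correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationReport:
    """Paired-frequency correlation of simulated vs observed phenotypes."""

    r_xx: float
    r2: float
    r2_adj: float
    p_value: float
    n: int


def multiple_correlation(simulated: Sequence[float],
                         observed: Sequence[float]) -> CorrelationReport:
    """Correlate simulated with observed phenotype frequencies.

    R2 is the squared Pearson correlation of the paired frequencies, R_xx
    its positive square root, adjusted R2 uses one predictor, and the
    p-value comes from the F statistic of the single-predictor regression.
    """
    x = np.asarray(simulated, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("simulated and observed must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired frequencies")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    r, _ = stats.pearsonr(x, y)
    r2 = float(r ** 2)
    p = 1  # predictors
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    if math.isclose(r2, 1.0, abs_tol=1e-15):
        p_value = 0.0
    else:
        f_stat = r2 / (1 - r2) * (n - p - 1) / p
        p_value = float(stats.f.sf(f_stat, p, n - p - 1))
    return CorrelationReport(r_xx=abs(float(r)), r2=r2, r2_adj=float(r2_adj),
                             p_value=p_value, n=n)
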