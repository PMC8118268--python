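"""Model/Results interface for rate estimation and species delimitation.

Two model classes cover the three inference modes:

``SpeciationRateModel``
    Tree plus a *complete* species partition; ``fit()`` maximizes the
    partition likelihood over the speciation-completion rate ``sigma`` and
    attaches a Fisher-information confidence interval ("tempo" mode).

``DelimitationModel``
    Tree (or posterior sample of trees) plus an optional constraint set.
    With constraints and no fixed rate, ``fit()`` first estimates ``sigma``
    on the tree induced by the constrained tips and then ranks every
    compatible partition of the full tree at the estimate (constrained
    mode).  With a caller-supplied rate it ranks candidates directly
    (unconstrained / fixed-rate mode).

Boundary cases are results, not errors: a single-block partition drives the
rate estimate to 0 and an all-singletons partition to infinity, mirroring
the behaviour of all-conspecific and all-heterospecific constraint sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

from .exceptions import InputError
from .likelihood import (
    RankedPartitionTable,
    _build_table,
    partition_log_probability,
    rank_partitions,
)
from .partition import (
    DEFAULT_PARTITION_CAP,
    ConstraintSet,
    SpeciesPartition,
    enumerate_compatible_partitions,
)
from .tree import LineageTree

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciationRateModel",
    "SpeciationRateResults",
    "DelimitationModel",
    "DelimitationResults",
    "sigma_log_likelihood",
    "estimate_sigma",
    "sigma_confidence_interval",
    "constrained_delimitation",
    "unconstrained_delimitation",
    "average_over_trees",
]

# sigma is optimized on a log scale over this bracket, in units of the
# reciprocal mean branch duration of the tree being fitted
_BRACKET_LO = 1e-8
_BRACKET_HI = 1e3
_LOG_TOL = 1e-8

BOUNDARY_NONE = "interior"
BOUNDARY_ZERO = "zero"
BOUNDARY_INFINITE = "infinite"


def sigma_log_likelihood(
    tree: LineageTree, partition: SpeciesPartition, sigma: float
) -> float:
    """Log-likelihood of ``sigma`` given a complete species partition.

    Zero-probability partitions yield ``-inf`` rather than raising.  For a
    constrained analysis, callers first restrict the tree to the constrained
    tips (``tree.extract_induced_tree``) and use the constraint partition.
    """
    return partition_log_probability(tree, partition, sigma)


@dataclass
class SpeciationRateResults:
    """Maximum-likelihood speciation-completion rate and its uncertainty."""

    model: "SpeciationRateModel"
    sigma_hat: float
    log_likelihood: float
    boundary: str = BOUNDARY_NONE
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    se: Optional[float] = None
    alpha: float = 0.05
    ci_method: str = "fisher"
    ci_defined: bool = False

    @property
    def speciation_completion_time(self) -> float:
        """Expected waiting time 1/sigma for one lineage to complete
        speciation (infinite at the zero boundary)."""
        if self.sigma_hat == 0.0:
            return math.inf
        return 1.0 / self.sigma_hat

    def summary(self) -> str:
        lines = [
            "Speciation-completion rate estimate",
            "===================================",
            f"tips:                  {self.model.tree.n_leaves}",
            f"species (blocks):      {self.model.partition.n_species}",
            f"sigma_hat:             {_fmt(self.sigma_hat)}"
            + ("" if self.boundary == BOUNDARY_NONE else f"  [{self.boundary} boundary]"),
            f"log-likelihood:        {_fmt(self.log_likelihood)}",
        ]
        if self.ci_defined:
            lines.append(
                f"{100 * (1 - self.alpha):.0f}% CI ({self.ci_method}):"
                f"       [{_fmt(self.ci_low)}, {_fmt(self.ci_high)}]"
            )
        else:
            lines.append("confidence interval:   undefined")
        lines.append(
            f"completion time 1/s:   {_fmt(self.speciation_completion_time)}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "sigma_hat": None if math.isinf(self.sigma_hat) else self.sigma_hat,
            "log_likelihood": self.log_likelihood,
            "boundary_flag": self.boundary,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se": self.se,
            "alpha": self.alpha,
            "ci_method": self.ci_method,
            "ci_defined": self.ci_defined,
        }


class SpeciationRateModel:
    """Likelihood model for the completion rate given known species identities.

    Parameters
    ----------
    tree : LineageTree
    partition : SpeciesPartition
        Complete species assignment of the tree's tips.
    """

    def __init__(self, tree: LineageTree, partition: SpeciesPartition):
        if partition.labels != tree.leaf_label_set:
            raise InputError("partition must cover exactly the tree's leaves")
        self.tree = tree
        self.partition = partition
        self._mean_tau = float(np.mean(tree.branch_lengths))

    @classmethod
    def from_constraints(
        cls, tree: LineageTree, constraints: ConstraintSet
    ) -> "SpeciationRateModel":
        """Restrict the tree to the constrained tips and use their partition."""
        constraints.validate_against(tree)
        sub = tree.extract_induced_tree(constraints.constrained_labels)
        return cls(sub, constraints.constrained_partition())

    def loglike(self, sigma: float) -> float:
        return sigma_log_likelihood(self.tree, self.partition, sigma)

    def fit(self, alpha: float = 0.05) -> SpeciationRateResults:
        n = self.tree.n_leaves
        if self.partition.n_species == 1:
            # only conspecific information: no completion events anywhere
            return SpeciationRateResults(
                model=self,
                sigma_hat=0.0,
                log_likelihood=0.0,
                boundary=BOUNDARY_ZERO,
                alpha=alpha,
            )
        if self.partition.n_species == n:
            # only heterospecific information: likelihood -> 1 as sigma -> inf
            return SpeciationRateResults(
                model=self,
                sigma_hat=math.inf,
                log_likelihood=0.0,
                boundary=BOUNDARY_INFINITE,
                alpha=alpha,
            )
        lo = math.log(_BRACKET_LO / self._mean_tau)
        hi = math.log(_BRACKET_HI / self._mean_tau)
        res = minimize_scalar(
            lambda x: -self.loglike(math.exp(x)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _LOG_TOL},
        )
        sigma_hat = math.exp(res.x)
        loglike = -res.fun
        out = SpeciationRateResults(
            model=self,
            sigma_hat=sigma_hat,
            log_likelihood=loglike,
            boundary=BOUNDARY_NONE,
            alpha=alpha,
        )
        ci = sigma_confidence_interval(
            self.tree, self.partition, sigma_hat, alpha=alpha
        )
        if ci is not None:
            out.ci_low, out.ci_high, out.se = ci
            out.ci_defined = True
        else:
            logger.warning(
                "non-positive log-likelihood curvature at sigma_hat=%g; "
                "Fisher confidence interval undefined",
                sigma_hat,
            )
        return out


def sigma_confidence_interval(
    tree: LineageTree,
    partition: SpeciesPartition,
    sigma_hat: float,
    alpha: float = 0.05,
):
    """Fisher-information interval at an interior maximum.

    Observed information is the negated central second difference of the
    log-likelihood at ``sigma_hat`` (step ``max(1e-6, 1e-4 * sigma_hat)``);
    the interval is ``sigma_hat +/- z * I^{-1/2}``, truncated below at zero.
    Returns ``(ci_low, ci_high, se)``, or None when the curvature is not
    positive (flat likelihood).
    """
    if not (math.isfinite(sigma_hat) and sigma_hat > 0):
        raise InputError("confidence interval requires a finite interior rate")
    h = max(1e-6, 1e-4 * sigma_hat)
    ll = lambda s: partition_log_probability(tree, partition, s)
    curvature = (ll(sigma_hat + h) - 2.0 * ll(sigma_hat) + ll(max(sigma_hat - h, 1e-300))) / (h * h)
    info = -curvature
    if not (info > 0 and math.isfinite(info)):
        return None
    se = 1.0 / math.sqrt(info)
    z = norm.ppf(1.0 - alpha / 2.0)
    return (max(0.0, sigma_hat - z * se), sigma_hat + z * se, se)


@dataclass
class DelimitationResults:
    """Ranked species partitions, with the rate estimate when one was made."""

    model: "DelimitationModel"
    table: RankedPartitionTable
    rate: Optional[SpeciationRateResults] = None

    @property
    def sigma(self) -> float:
        return self.table.sigma

    @property
    def map_partition(self) -> SpeciesPartition:
        return self.table.map_partition

    def conspecificity_probability(self, targets: Iterable[str]) -> float:
        """Probability that all target tips are conspecific, summed over the
        ranked candidate partitions."""
        targets = set(targets)
        if len(targets) < 2:
            raise InputError("need at least two target tips")
        total = 0.0
        for p, cp in zip(
            self.table.partitions, self.table.conditional_probabilities
        ):
            if p.same_species(targets):
                total += float(cp)
        return min(1.0, total)

    def summary(self, max_rows: int = 10) -> str:
        t = self.table
        lines = [
            "Species delimitation",
            "====================",
            f"candidate partitions:  {len(t)}",
            f"sigma used:            {_fmt(t.sigma)}"
            + ("  (estimated from constraints)" if self.rate is not None else "  (fixed)"),
            f"credibility set size:  {t.credibility_set_size} "
            f"(level {t.credibility_level:g})",
            "",
        ]
        df = t.as_dataframe().head(max_rows)
        lines.append(
            df.to_string(
                index=False,
                columns=[
                    "rank",
                    "n_species",
                    "conditional_probability",
                    "cumulative_conditional_probability",
                    "partition",
                ],
                float_format=lambda x: f"{x:.6g}",
            )
        )
        if len(t) > max_rows:
            lines.append(f"... ({len(t) - max_rows} further partitions)")
        if self.rate is not None:
            lines.append("")
            lines.append(self.rate.summary())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "sigma": self.table.sigma,
            "credibility_level": self.table.credibility_level,
            "n_candidate_partitions": len(self.table),
            "partitions": self.table.to_records(),
        }
        if self.rate is not None:
            out["rate_estimate"] = self.rate.to_dict()
        return out


class DelimitationModel:
    """Species delimitation on one lineage tree or a posterior sample.

    Parameters
    ----------
    trees : LineageTree or sequence of LineageTree
        With several trees (sharing one leaf set) the unconditional partition
        probabilities are arithmetically averaged across trees before
        normalization, approximating the average over tree uncertainty.
    constraints : ConstraintSet, optional
        A-priori species identities for a subset of tips.
    cap : int, optional
        Refuse candidate sets larger than this (default 2e7).
    """

    def __init__(
        self,
        trees: Union[LineageTree, Sequence[LineageTree]],
        constraints: Optional[ConstraintSet] = None,
        cap: Optional[int] = DEFAULT_PARTITION_CAP,
    ):
        if isinstance(trees, LineageTree):
            trees = [trees]
        trees = list(trees)
        if not trees:
            raise InputError("at least one tree is required")
        leaf_set = trees[0].leaf_label_set
        for t in trees[1:]:
            if t.leaf_label_set != leaf_set:
                raise InputError("all trees must share one leaf set")
        self.trees = trees
        self.tree = trees[0]
        self.constraints = constraints or ConstraintSet()
        self.constraints.validate_against(self.tree)
        self.cap = cap

    def fit(
        self,
        sigma: Optional[float] = None,
        alpha: float = 0.05,
        credibility_level: float = 0.95,
    ) -> DelimitationResults:
        rate = None
        if sigma is None:
            if not self.constraints:
                raise InputError(
                    "without constraints a speciation-completion rate must "
                    "be supplied"
                )
            if not (
                self.constraints.has_conspecific_pair()
                and self.constraints.has_heterospecific_pair()
            ):
                logger.warning(
                    "constraints lack a conspecific or a heterospecific "
                    "pair; only a boundary rate estimate is possible"
                )
            rate = SpeciationRateModel.from_constraints(
                self.tree, self.constraints
            ).fit(alpha=alpha)
            sigma = rate.sigma_hat
            if math.isinf(sigma):
                raise InputError(
                    "constraints are all heterospecific (rate estimate "
                    "infinite); supply a finite rate explicitly"
                )
        elif sigma < 0:
            raise InputError(f"negative completion rate {sigma}")
        table = self._rank(sigma, credibility_level)
        return DelimitationResults(model=self, table=table, rate=rate)

    def _rank(self, sigma: float, credibility_level: float) -> RankedPartitionTable:
        if len(self.trees) == 1:
            return rank_partitions(
                self.trees[0],
                self.constraints,
                sigma,
                cap=self.cap,
                credibility_level=credibility_level,
            )
        parts = list(
            enumerate_compatible_partitions(
                self.tree.leaf_labels, self.constraints, cap=self.cap
            )
        )
        logps = np.empty((len(self.trees), len(parts)))
        for i, t in enumerate(self.trees):
            for j, p in enumerate(parts):
                logps[i, j] = partition_log_probability(t, p, sigma)
        # arithmetic mean of per-tree unconditional probabilities
        mean_logp = logsumexp(logps, axis=0) - math.log(len(self.trees))
        return _build_table(parts, mean_logp, sigma, credibility_level)


# -- functional forms ------------------------------------------------------


def estimate_sigma(
    tree: LineageTree, partition: SpeciesPartition, alpha: float = 0.05
) -> SpeciationRateResults:
    """ML estimate of the completion rate from a complete species partition."""
    return SpeciationRateModel(tree, partition).fit(alpha=alpha)


def constrained_delimitation(
    tree: LineageTree,
    constraints: ConstraintSet,
    cap: Optional[int] = DEFAULT_PARTITION_CAP,
    alpha: float = 0.05,
) -> DelimitationResults:
    """Two-stage constrained mode: estimate sigma on the constrained-tip
    induced tree, then rank every compatible partition of the full tree."""
    return DelimitationModel(tree, constraints, cap=cap).fit(alpha=alpha)


def unconstrained_delimitation(
    tree: LineageTree,
    sigma: float,
    cap: Optional[int] = DEFAULT_PARTITION_CAP,
) -> DelimitationResults:
    """Rank all Bell(n) partitions of the tree at a caller-supplied rate."""
    if not sigma > 0:
        raise InputError("unconstrained mode requires a positive rate")
    return DelimitationModel(tree, cap=cap).fit(sigma=sigma)


def average_over_trees(
    trees: Sequence[LineageTree],
    constraints: Optional[ConstraintSet],
    sigma: float,
    cap: Optional[int] = DEFAULT_PARTITION_CAP,
) -> RankedPartitionTable:
    """Rank partitions under the mean of per-tree partition probabilities
    across a posterior sample of trees."""
    return DelimitationModel(trees, constraints, cap=cap).fit(sigma=sigma).table


def _fmt(x) -> str:
    if x is None:
        return "n/a"
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return f"{x:.6g}"
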