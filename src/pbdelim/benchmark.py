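"""Simulation benchmarks of the three inference modes.

Each benchmark mirrors one of the method's validation studies on simulated
protracted-speciation data, at a configurable (typically desk-scale) size:

``run_constrained_benchmark``
    Hide the species identities of a random subset of tips, re-infer them
    with the rate estimated from the constrained remainder, and score whether
    the highest-probability partition matches the truth and whether the truth
    sits inside the 95% credibility set.

``run_unconstrained_benchmark``
    No constraints; candidates are ranked at the *true* rate, probing how
    much the tree alone can say about species boundaries.

``run_tempo_benchmark``
    The species identities of all tips are given; only the completion rate
    is estimated, with Fisher-information confidence intervals.

All randomness is derived from the config seed; tip hiding uses a dedicated
RNG stream so the same trees are reused across constraint levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EnumerationCapError, InputError
from .model import (
    BOUNDARY_NONE,
    DelimitationModel,
    SpeciationRateModel,
)
from .partition import DEFAULT_PARTITION_CAP, ConstraintSet
from .simulate import PBDParams, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "BenchmarkSummary", "run_constrained_benchmark",
           "run_unconstrained_benchmark", "run_tempo_benchmark"]


@dataclass
class BenchmarkConfig:
    """Study design for one benchmark run."""

    mode: str  # constrained | unconstrained | tempo
    n_tips: int = 20
    n_unconstrained: int = 5  # constrained mode only
    sigmas: Sequence[float] = (0.001, 0.005, 0.01, 0.05, 0.1)
    isolation_rate: float = 0.1
    extinction_rate: float = 0.0
    replicates: int = 100
    seed: int = 0
    cap: int = DEFAULT_PARTITION_CAP
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.mode not in ("constrained", "unconstrained", "tempo"):
            raise InputError(f"unknown benchmark mode {self.mode!r}")
        if self.replicates < 1:
            raise InputError("at least one replicate required")
        if self.mode == "constrained" and not (
            0 <= self.n_unconstrained < self.n_tips
        ):
            raise InputError("n_unconstrained must be below n_tips")

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BenchmarkSummary:
    """Per-replicate records plus per-condition aggregates."""

    config: BenchmarkConfig
    replicates: pd.DataFrame = field(repr=False)
    conditions: pd.DataFrame = field(repr=False)

    def write(self, output_dir=None) -> dict:
        out = Path(output_dir or self.config.output_dir or ".")
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "replicates": out / f"{self.config.mode}_replicates.tsv",
            "conditions": out / f"{self.config.mode}_summary.csv",
        }
        self.replicates.to_csv(paths["replicates"], sep="\t", index=False)
        self.conditions.to_csv(paths["conditions"], index=False)
        return paths

    def plot(self, path=None):
        """Rate-recovery ribbon (tempo) or accuracy-by-rate bars; optional,
        requires matplotlib."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        if self.config.mode == "tempo":
            g = self.conditions
            ax.plot(g["sigma_true"], g["sigma_hat_median"], "o-",
                    label="median estimate")
            if "ci_low_min" in g:
                ax.fill_between(g["sigma_true"], g["ci_low_min"],
                                g["ci_high_max"], alpha=0.25,
                                label="95% CI envelope")
            ax.plot(g["sigma_true"], g["sigma_true"], "k--", lw=1,
                    label="truth")
            ax.set_xscale("log")
            ax.set_yscale("log")
            ax.set_xlabel("true speciation-completion rate")
            ax.set_ylabel("estimated rate")
        else:
            g = self.conditions
            ax.plot(g["sigma_true"], g["map_correct"], "o-",
                    label="MAP correct")
            if "truth_in_credibility_set" in g:
                ax.plot(g["sigma_true"], g["truth_in_credibility_set"], "s-",
                        label="truth in 95% set")
            ax.set_xscale("log")
            ax.set_ylim(0, 1.05)
            ax.set_xlabel("true speciation-completion rate")
            ax.set_ylabel("proportion of replicates")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _species_count_stats(df: pd.DataFrame) -> dict:
    return {
        "n_species_mean": df["n_species_true"].mean(),
        "n_species_sd": df["n_species_true"].std(ddof=1),
    }


def run_constrained_benchmark(config: BenchmarkConfig) -> BenchmarkSummary:
    """Constrained-mode study: hidden identities re-inferred, sigma estimated."""
    params_base = dict(
        isolation_rate=config.isolation_rate,
        extinction_rate=config.extinction_rate,
    )
    root = np.random.default_rng(config.seed)
    tree_seeds = root.integers(0, 2**31 - 1, size=(len(config.sigmas),
                                                   config.replicates))
    hide_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
    rows = []
    for si, sigma in enumerate(config.sigmas):
        params = PBDParams(completion_rate=sigma, **params_base)
        for rep in range(config.replicates):
            ds = simulate_dataset(params, config.n_tips,
                                  seed=int(tree_seeds[si, rep]))
            labels = sorted(ds.tree.leaf_label_set)
            hidden = set(
                hide_rng.choice(labels, size=config.n_unconstrained,
                                replace=False)
            )
            names = ds.partition.names
            assignments = {
                label: names[ds.partition.block_of(label)]
                for label in labels
                if label not in hidden
            }
            constraints = ConstraintSet(assignments)
            row = {
                "mode": "constrained",
                "sigma_true": sigma,
                "replicate": rep,
                "n_tips": config.n_tips,
                "n_unconstrained": config.n_unconstrained,
                "n_species_true": ds.n_species,
            }
            try:
                res = DelimitationModel(
                    ds.tree, constraints, cap=config.cap
                ).fit()
            except EnumerationCapError as exc:
                logger.warning("replicate skipped: %s", exc)
                row.update(skipped=True)
                rows.append(row)
                continue
            except InputError as exc:
                logger.warning("replicate skipped: %s", exc)
                row.update(skipped=True)
                rows.append(row)
                continue
            row.update(
                skipped=False,
                sigma_hat=res.rate.sigma_hat if res.rate else math.nan,
                sigma_boundary=res.rate.boundary if res.rate else "",
                map_correct=res.map_partition == ds.partition,
                truth_in_credibility_set=res.table.in_credibility_set(
                    ds.partition
                ),
                n_species_map=res.map_partition.n_species,
                credibility_set_size=res.table.credibility_set_size,
                n_candidates=len(res.table),
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    done = df[~df["skipped"]] if "skipped" in df else df
    conditions = (
        done.groupby("sigma_true")
        .apply(
            lambda g: pd.Series(
                {
                    "replicates": len(g),
                    "map_correct": g["map_correct"].mean(),
                    "truth_in_credibility_set": g[
                        "truth_in_credibility_set"
                    ].mean(),
                    **_species_count_stats(g),
                    "sigma_hat_median": g["sigma_hat"].median(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return BenchmarkSummary(config, df, conditions)


def run_unconstrained_benchmark(config: BenchmarkConfig) -> BenchmarkSummary:
    """Unconstrained-mode study: full Bell-number ranking at the true rate."""
    root = np.random.default_rng(config.seed)
    tree_seeds = root.integers(0, 2**31 - 1, size=(len(config.sigmas),
                                                   config.replicates))
    rows = []
    for si, sigma in enumerate(config.sigmas):
        params = PBDParams(
            isolation_rate=config.isolation_rate,
            extinction_rate=config.extinction_rate,
            completion_rate=sigma,
        )
        for rep in range(config.replicates):
            ds = simulate_dataset(params, config.n_tips,
                                  seed=int(tree_seeds[si, rep]))
            row = {
                "mode": "unconstrained",
                "sigma_true": sigma,
                "replicate": rep,
                "n_tips": config.n_tips,
                "n_species_true": ds.n_species,
            }
            try:
                res = DelimitationModel(ds.tree, cap=config.cap).fit(
                    sigma=sigma
                )
            except EnumerationCapError as exc:
                logger.warning("replicate skipped: %s", exc)
                row.update(skipped=True)
                rows.append(row)
                continue
            row.update(
                skipped=False,
                map_correct=res.map_partition == ds.partition,
                truth_in_credibility_set=res.table.in_credibility_set(
                    ds.partition
                ),
                truth_rank=res.table.rank_of(ds.partition),
                credibility_set_size=res.table.credibility_set_size,
                n_candidates=len(res.table),
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    done = df[~df["skipped"]] if "skipped" in df else df
    conditions = (
        done.groupby("sigma_true")
        .apply(
            lambda g: pd.Series(
                {
                    "replicates": len(g),
                    "map_correct": g["map_correct"].mean(),
                    "truth_in_credibility_set": g[
                        "truth_in_credibility_set"
                    ].mean(),
                    **_species_count_stats(g),
                    "credibility_set_size_median": g[
                        "credibility_set_size"
                    ].median(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return BenchmarkSummary(config, df, conditions)


def run_tempo_benchmark(config: BenchmarkConfig) -> BenchmarkSummary:
    """Tempo-mode study: rate estimation from fully known species identities."""
    root = np.random.default_rng(config.seed)
    tree_seeds = root.integers(0, 2**31 - 1, size=(len(config.sigmas),
                                                   config.replicates))
    rows = []
    for si, sigma in enumerate(config.sigmas):
        params = PBDParams(
            isolation_rate=config.isolation_rate,
            extinction_rate=config.extinction_rate,
            completion_rate=sigma,
        )
        for rep in range(config.replicates):
            ds = simulate_dataset(params, config.n_tips,
                                  seed=int(tree_seeds[si, rep]))
            res = SpeciationRateModel(ds.tree, ds.partition).fit()
            covered = (
                res.ci_defined
                and res.ci_low <= sigma <= res.ci_high
            )
            rows.append(
                {
                    "mode": "tempo",
                    "sigma_true": sigma,
                    "replicate": rep,
                    "n_tips": config.n_tips,
                    "n_species_true": ds.n_species,
                    "sigma_hat": res.sigma_hat,
                    "boundary": res.boundary,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "ci_defined": res.ci_defined,
                    "ci_covers_truth": covered,
                }
            )
    df = pd.DataFrame(rows)
    interior = df[df["boundary"] == BOUNDARY_NONE]

    def agg(g: pd.DataFrame) -> pd.Series:
        gi = g[g["boundary"] == BOUNDARY_NONE]
        q1, med, q3 = (
            gi["sigma_hat"].quantile([0.25, 0.5, 0.75])
            if len(gi)
            else (math.nan, math.nan, math.nan)
        )
        return pd.Series(
            {
                "replicates": len(g),
                "boundary_replicates": (g["boundary"] != BOUNDARY_NONE).sum(),
                "sigma_hat_median": med,
                "sigma_hat_q1": q1,
                "sigma_hat_q3": q3,
                "ci_low_min": gi["ci_low"].min() if len(gi) else math.nan,
                "ci_high_max": gi["ci_high"].max() if len(gi) else math.nan,
                "ci_coverage": (
                    gi["ci_covers_truth"].mean() if len(gi) else math.nan
                ),
                **_species_count_stats(g),
            }
        )

    conditions = (
        df.groupby("sigma_true").apply(agg, include_groups=False).reset_index()
    )
    _ = interior
    return BenchmarkSummary(config, df, conditions)
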