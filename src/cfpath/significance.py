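"""Empirical rank p-values for knockout specificity.

An enzyme that tops the ranking for *many* metabolites is unspecific: its
knockout lengthens paths everywhere. To quantify specificity, the full
knockout scan is repeated with N background source metabolites and each
enzyme's ranking positions X_1..X_N form an empirical CDF F*_N (each
observation carries mass 1/N). The p-value of an enzyme observed at
position k in the study scan is F*_N(k): the probability of an equal-or-
better position for a random metabolite. The smallest attainable p-value is
1/N, the resolution of the sample; reported p-values are clamped at that
floor (the literal empirical-CDF value is available via
``clamp_floor=False``).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ACCUMULATION
from .knockout import RankingTable, scan_knockouts
from .network import CarbonArcTable, MetabolicNetwork, ValidationError, carbon_graph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankSample:
    """Ranking positions of one enzyme over N background source metabolites."""

    enzyme: str
    positions: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class EmpiricalCdf:
    """Right-continuous step CDF with mass 1/N per observation."""

    support: tuple[int, ...]  # sorted observations (with repeats)
    n: int

    def __call__(self, x: float) -> float:
        return bisect.bisect_right(self.support, x) / self.n


def build_cdf(sample: RankSample) -> EmpiricalCdf:
    if sample.n < 1:
        raise ValidationError(f"empty rank sample for enzyme {sample.enzyme!r}")
    return EmpiricalCdf(support=tuple(sorted(sample.positions)), n=sample.n)


def pvalue(cdf: EmpiricalCdf, k: int, clamp_floor: bool = True) -> float:
    """p = F*_N(k), clamped below at the Monte-Carlo floor 1/N.

    Positions that never occur in the background would give a literal
    empirical-CDF value of 0; the sample cannot resolve probabilities below
    1/N, so the floor is reported instead unless ``clamp_floor`` is False.
    """
    if k < 1:
        raise ValidationError("ranking positions start at 1")
    p = cdf(k)
    if clamp_floor:
        return max(p, 1.0 / cdf.n)
    return p


def eligible_sources(arcs: CarbonArcTable, exclude=()) -> tuple[str, ...]:
    """Non-hub carbon-graph metabolites usable as background sources."""
    g = carbon_graph(arcs)
    return tuple(sorted(set(g.nodes) - set(exclude)))


def sample_positions(
    network: MetabolicNetwork,
    arcs: CarbonArcTable,
    enzymes=None,
    direction: str = ACCUMULATION,
    n_samples: int | None = None,
    seed: int = 0,
    exclude=(),
    with_replacement: bool = False,
    rank_nonviable: bool = False,
    solver=None,
    big_M: float = 1000.0,
    time_limit: float | None = 60.0,
) -> dict[str, RankSample]:
    """Background rank samples: one full knockout scan per sampled source.

    Sources are drawn uniformly without replacement (default) from the
    non-hub carbon-graph metabolites, excluding ``exclude`` (typically the
    study metabolite). ``n_samples=None`` uses every eligible source. An
    enzyme absent from a scan's ranking (non-viable there, or fully
    disconnecting) is assigned that scan's worst rank plus one. A source
    whose scan fails is resampled and logged. Deterministic under ``seed``.
    """
    if enzymes is None:
        enzymes = network.internal_original_ids
    pool = list(eligible_sources(arcs, exclude=exclude))
    if n_samples is None:
        n_samples = len(pool)
    if n_samples < 1:
        raise ValidationError("need at least one background sample")
    if not with_replacement and n_samples > len(pool):
        raise ValidationError(
            f"cannot draw {n_samples} sources without replacement from {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    if with_replacement:
        order = list(rng.choice(len(pool), size=4 * n_samples + 16, replace=True))
    else:
        order = list(rng.permutation(len(pool)))
    positions: dict[str, list[int]] = {e: [] for e in enzymes}
    collected = 0
    for idx in order:
        if collected == n_samples:
            break
        src = pool[idx]
        try:
            ranking = scan_knockouts(
                network,
                arcs,
                src,
                direction=direction,
                rank_nonviable=rank_nonviable,
                solver=solver,
                big_M=big_M,
                time_limit=time_limit,
            )
        except Exception as exc:  # resample, never silently drop the quota
            logger.warning("background scan for %r failed (%s); resampling", src, exc)
            continue
        worst = max(ranking.positions.values(), default=0)
        for e in enzymes:
            positions[e].append(ranking.positions.get(e, worst + 1))
        collected += 1
    if collected < n_samples:
        raise ValidationError(
            f"only {collected} of {n_samples} background scans succeeded"
        )
    return {e: RankSample(enzyme=e, positions=tuple(p)) for e, p in positions.items()}


def attach_pvalues(
    ranking: RankingTable,
    samples: dict[str, RankSample],
    clamp_floor: bool = True,
) -> RankingTable:
    """Fill ``ranking.pvalues`` for every ranked enzyme from its rank sample."""
    for enzyme, k in ranking.positions.items():
        if enzyme not in samples:
            continue
        ranking.pvalues[enzyme] = pvalue(build_cdf(samples[enzyme]), k, clamp_floor=clamp_floor)
    return ranking


def rank_with_pvalues(
    network: MetabolicNetwork,
    arcs: CarbonArcTable,
    source: str,
    direction: str = ACCUMULATION,
    n_samples: int | None = None,
    seed: int = 0,
    rank_nonviable: bool = False,
    solver=None,
    big_M: float = 1000.0,
    time_limit: float | None = 60.0,
) -> tuple[RankingTable, dict[str, RankSample]]:
    """Full pipeline: study scan, background sampling, p-value attachment."""
    from .cfp import CfpSolver

    if solver is None:
        solver = CfpSolver(network, arcs, big_M=big_M, time_limit=time_limit)
    ranking = scan_knockouts(
        network, arcs, source, direction=direction, rank_nonviable=rank_nonviable,
        solver=solver, time_limit=time_limit,
    )
    samples = sample_positions(
        network,
        arcs,
        direction=direction,
        n_samples=n_samples,
        seed=seed,
        exclude=(source,),
        rank_nonviable=rank_nonviable,
        solver=solver,
        big_M=big_M,
        time_limit=time_limit,
    )
    return attach_pvalues(ranking, samples), samples


def pvalue_frame(
    ranking: RankingTable, samples: dict[str, RankSample], seed: int
) -> pd.DataFrame:
    records = []
    for enzyme, k in sorted(ranking.positions.items(), key=lambda kv: (kv[1], kv[0])):
        sample = samples.get(enzyme)
        records.append(
            {
                "enzyme": enzyme,
                "observed_position": k,
                "p_value": ranking.pvalues.get(enzyme),
                "N": sample.n if sample else 0,
                "seed": seed,
            }
        )
    return pd.DataFrame(records, columns=["enzyme", "observed_position", "p_value", "N", "seed"])
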