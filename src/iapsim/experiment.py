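"""Parameter-grid experiments and the Easy/Hard cross-over summary.

The default grid mirrors the study conditions: population sizes
{30, 50, 100, 200, 500} with mean degree ``n**0.677`` and clustering target
0.25, five sampled networks per size, five runs of 1000 iterations per
condition (one run per network), loss probability p in {1/500, 1/200}, and
both transmission modes.  Per-condition means and standard deviations of the
end-of-run measures are aggregated into a long-form table, and
:func:`crossover_summary` extracts, per condition and measure, the trend of
the relative Hard proportion with population size and the cross-over size at
which Easy overtakes Hard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as _st

from .core import EASY, HARD, LearningThresholds
from .metrics import MEASURE_SUCCESSFUL, records_to_frame
from .networks import NetworkSpec, sample_network
from .simulation import HORIZONTAL, VERTICAL, SimulationConfig, run

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_grid",
    "crossover_summary",
    "derive_seed",
]

logger = logging.getLogger(__name__)

_GROUP_COLS = [
    "n",
    "p",
    "mode",
    "measure",
    "convention_class",
    "normalization",
    "knowledge_basis",
]


def derive_seed(base_seed: int, *codes: int) -> int:
    """Deterministic per-task seed from a base seed and an index path."""
    ss = np.random.SeedSequence([int(base_seed), *[int(c) for c in codes]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid definition; defaults reproduce the full study conditions."""

    population_sizes: tuple[int, ...] = (30, 50, 100, 200, 500)
    beta: float = 1.677
    target_C: float = 0.25
    networks_per_n: int = 5
    runs_per_condition: int = 5
    p_values: tuple[float, ...] = (1 / 500, 1 / 200)
    modes: tuple[str, ...] = (HORIZONTAL, VERTICAL)
    iterations: int = 1000
    thresholds: LearningThresholds = field(default_factory=LearningThresholds)
    class_prob: float = 0.5
    base_seed: int = 0
    crossed: bool = False  # True: every run repeated on every network
    tolerance: float = 0.005
    sampler_max_steps: int | None = None  # None: scaled with edge count

    def __post_init__(self) -> None:
        if not self.population_sizes:
            raise ValueError("population_sizes must be non-empty")
        if self.networks_per_n < 1 or self.runs_per_condition < 1:
            raise ValueError("networks_per_n and runs_per_condition must be >= 1")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        for p in self.p_values:
            if not 0.0 < p <= 1.0:
                raise ValueError(f"p values must be in (0, 1], got {p}")
        for mode in self.modes:
            if mode not in (HORIZONTAL, VERTICAL):
                raise ValueError(f"unknown mode {mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def network_spec(self, n: int) -> NetworkSpec:
        max_steps = self.sampler_max_steps
        if max_steps is None:
            # denser graphs need proportionally longer chains to move C
            spec0 = NetworkSpec.from_beta(n, self.beta, target_C=self.target_C)
            max_steps = max(200_000, 40 * spec0.edges)
        return NetworkSpec.from_beta(
            n,
            self.beta,
            target_C=self.target_C,
            tolerance=self.tolerance,
            max_steps=max_steps,
        )


@dataclass
class ExperimentResult:
    """Long-form records, per-condition summary, and network realizations."""

    records: pd.DataFrame
    summary: pd.DataFrame
    network_stats: pd.DataFrame
    networks: dict
    config: ExperimentConfig


def run_grid(config: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Sample networks, run every condition, and aggregate final metrics."""
    networks: dict[tuple[int, int], object] = {}
    net_rows = []
    for ni, n in enumerate(config.population_sizes):
        spec = config.network_spec(n)
        for gi in range(config.networks_per_n):
            seed = derive_seed(config.base_seed, 1, ni, gi)
            G = sample_network(spec, seed)
            networks[(n, gi)] = G
            net_rows.append(
                {
                    "n": n,
                    "network_id": gi,
                    "seed": seed,
                    "realized_k": G.graph["realized_k"],
                    "realized_C": G.graph["realized_C"],
                    "converged": G.graph["converged"],
                }
            )
            logger.info(
                "sampled network n=%d #%d: k=%.2f C=%.4f converged=%s",
                n, gi, G.graph["realized_k"], G.graph["realized_C"],
                G.graph["converged"],
            )
    net_frame = pd.DataFrame(net_rows)
    network_stats = (
        net_frame.groupby("n")
        .agg(
            mean_k=("realized_k", "mean"),
            sd_k=("realized_k", "std"),
            mean_C=("realized_C", "mean"),
            sd_C=("realized_C", "std"),
            graphs=("realized_k", "size"),
        )
        .reset_index()
    )

    all_records = []
    for ni, n in enumerate(config.population_sizes):
        for pi, p in enumerate(config.p_values):
            for mi, mode in enumerate(config.modes):
                for ri in range(config.runs_per_condition):
                    if config.crossed:
                        net_ids = range(config.networks_per_n)
                    else:
                        net_ids = [ri % config.networks_per_n]
                    for gi in net_ids:
                        seed = derive_seed(config.base_seed, 2, ni, pi, mi, ri, gi)
                        sim_cfg = SimulationConfig(
                            mode=mode,
                            p=p,
                            iterations=config.iterations,
                            thresholds=config.thresholds,
                            class_prob=config.class_prob,
                            seed=seed,
                        )
                        result = run(
                            networks[(n, gi)],
                            sim_cfg,
                            run_keys={"run_id": ri, "network_id": gi},
                        )
                        all_records.extend(result.records)
                        if progress:
                            print(
                                f"run n={n} p={p:g} mode={mode} run={ri} done",
                                flush=True,
                            )
    records = records_to_frame(all_records)
    final = records[records["iteration"] == config.iterations]
    summary = (
        final.groupby(_GROUP_COLS, dropna=False)["value"]
        .agg(mean="mean", sd="std", runs="size")
        .reset_index()
    )
    return ExperimentResult(
        records=records,
        summary=summary,
        network_stats=network_stats,
        networks=networks,
        config=config,
    )


def crossover_summary(
    result: ExperimentResult | pd.DataFrame,
    *,
    measures: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Trend of the relative Hard proportion with population size.

    For each (p, mode, measure, knowledge basis): the Hard relative
    proportion at each population size (condition means), its Spearman rank
    correlation with n, the trend sign, a strict-monotone-decrease flag, and
    the smallest population size at which the Easy mean exceeds the Hard
    mean (``crossover_n``, NaN when Easy never overtakes Hard).
    """
    summary = result.summary if isinstance(result, ExperimentResult) else result
    rel = summary[summary["normalization"] == "relative"]
    if measures is not None:
        rel = rel[rel["measure"].isin(measures)]
    sizes = sorted(rel["n"].unique())
    if len(sizes) < 3:
        raise ValueError(
            f"cross-over analysis needs >= 3 population sizes, got {len(sizes)}"
        )
    rows = []
    keys = ["p", "mode", "measure", "knowledge_basis"]
    for key_vals, grp in rel.groupby(keys, dropna=False):
        pivot = grp.pivot_table(
            index="n", columns="convention_class", values="mean"
        ).sort_index()
        if EASY not in pivot or HARD not in pivot:
            continue
        ns = pivot.index.to_numpy()
        hard = pivot[HARD].to_numpy()
        easy = pivot[EASY].to_numpy()
        if np.allclose(hard, hard[0]):
            rho = float("nan")
            sign = 0
        else:
            rho = float(_st.spearmanr(ns, hard).statistic)
            sign = int(np.sign(rho)) if np.isfinite(rho) else 0
        above = np.nonzero(easy > hard)[0]
        crossover_n = int(ns[above[0]]) if above.size else float("nan")
        rows.append(
            dict(
                zip(keys, key_vals),
                sizes=tuple(int(x) for x in ns),
                hard_relative=tuple(float(x) for x in hard),
                spearman_rho=rho,
                trend_sign=sign,
                monotone_decreasing=bool(np.all(np.diff(hard) < 0)),
                crossover_n=crossover_n,
            )
        )
    return pd.DataFrame(rows)
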