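"""Benchmark harness: recovery and false-positive rates vs pool size.

Runs the deconvolution over a grid of in-silico pools and aggregates,
per (pool size k, locus set):

* the fraction of pools in which *all* parental strains were called,
* the fraction of pools with at least one false positive,
* mean true-positive rate, mean false-positive count, mean model error.

Pools are independent tasks and the aggregation is order-independent, so
results are reproducible regardless of evaluation order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .deconvolution import DeconvolutionConfig, deconvolve
from .genotype_model import StrainProfile
from .locus_metrics import PoolDesign, recovery_stats
from .synthetic_data import SimulationConfig

__all__ = [
    "BenchmarkSummary",
    "PoolOutcome",
    "run_benchmark",
    "write_summary",
    "load_config",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PoolOutcome:
    """Per-pool record of the benchmark."""

    pool_id: str
    k: int
    loci_set: str
    called: tuple[str, ...]
    tpr: float
    n_false_positives: int
    glm_error: float
    all_parental: bool
    failed: bool = False


@dataclass(frozen=True)
class GroupSummary:
    """Aggregate over one (k, loci_set) cell."""

    k: int
    loci_set: str
    n_reps: int
    frac_all_parental: float
    frac_any_false_positive: float
    mean_tpr: float
    mean_false_positives: float
    mean_glm_error: float
    n_failed: int


@dataclass(frozen=True)
class BenchmarkSummary:
    """Full benchmark outcome: per-cell aggregates plus per-pool records."""

    groups: tuple[GroupSummary, ...]
    outcomes: tuple[PoolOutcome, ...]
    runtime_seconds: float

    def group(self, k: int, loci_set: str) -> GroupSummary:
        for g in self.groups:
            if g.k == k and g.loci_set == loci_set:
                return g
        raise KeyError(f"no benchmark cell (k={k}, loci_set={loci_set!r})")


def run_benchmark(reference: Sequence[StrainProfile],
                  pools: Sequence[PoolDesign],
                  config: DeconvolutionConfig | None = None,
                  loci_set: str = "all.loci",
                  loci_subset: Sequence[str] | None = None
                  ) -> BenchmarkSummary:
    """Deconvolve every pool against the reference and aggregate.

    ``loci_subset``, when given, restricts the reference profiles before
    fitting (pools are expected to be generated on the same subset);
    ``loci_set`` labels the grouping.  Per-pool solver failures are
    logged and counted, not fatal.
    """
    if not pools:
        raise ValueError("no pools to benchmark")
    config = config or DeconvolutionConfig()
    ref = list(reference)
    if loci_subset is not None:
        ref = [p.restrict(loci_subset) for p in ref]
    ref_ids = {p.strain_id for p in ref}
    for pool in pools:
        missing = pool.parental_ids - ref_ids
        if missing:
            raise ValueError(
                f"pool {pool.pool_id!r}: parental strain(s) {sorted(missing)} "
                "not in the reference")

    t0 = time.perf_counter()
    outcomes: list[PoolOutcome] = []
    for pool in pools:
        k = pool.n_parental
        try:
            result = deconvolve(ref, pool.observed, config)
        except Exception:  # noqa: BLE001 -- benchmark must stay total
            log.exception("deconvolution failed for pool %s", pool.pool_id)
            outcomes.append(PoolOutcome(
                pool_id=pool.pool_id, k=k, loci_set=loci_set, called=(),
                tpr=0.0, n_false_positives=0, glm_error=100.0,
                all_parental=False, failed=True))
            continue
        stats = recovery_stats(result.selected, pool)
        log.info("pool %s: %d strains called, lambda=%.4g, glm_error=%.2f",
                 pool.pool_id, len(result.selected), result.lambda_chosen,
                 result.glm_error)
        outcomes.append(PoolOutcome(
            pool_id=pool.pool_id, k=k, loci_set=loci_set,
            called=tuple(result.selected), tpr=stats.tpr,
            n_false_positives=stats.n_false_positives,
            glm_error=result.glm_error,
            all_parental=stats.tpr == 100.0))
    elapsed = time.perf_counter() - t0

    groups = []
    for k in sorted({o.k for o in outcomes}):
        cell = [o for o in outcomes if o.k == k]
        n = len(cell)
        groups.append(GroupSummary(
            k=k, loci_set=loci_set, n_reps=n,
            frac_all_parental=sum(o.all_parental for o in cell) / n,
            frac_any_false_positive=sum(o.n_false_positives > 0 for o in cell) / n,
            mean_tpr=sum(o.tpr for o in cell) / n,
            mean_false_positives=sum(o.n_false_positives for o in cell) / n,
            mean_glm_error=sum(o.glm_error for o in cell) / n,
            n_failed=sum(o.failed for o in cell)))
    return BenchmarkSummary(groups=tuple(groups), outcomes=tuple(outcomes),
                            runtime_seconds=elapsed)


def merge_summaries(*summaries: BenchmarkSummary) -> BenchmarkSummary:
    """Combine benchmark runs (e.g. different locus sets) into one report."""
    groups = tuple(g for s in summaries for g in s.groups)
    outcomes = tuple(o for s in summaries for o in s.outcomes)
    return BenchmarkSummary(groups=groups, outcomes=outcomes,
                            runtime_seconds=sum(s.runtime_seconds for s in summaries))


def write_summary(summary: BenchmarkSummary, out_dir) -> tuple[Path, Path]:
    """Write the benchmark as summary TSV + full JSON; bit-stable.

    The TSV has one row per (k, loci_set) with fractions at 3 decimals;
    the JSON carries every per-pool record.  Runtime metadata is kept out
    of both files so identical inputs give byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "benchmark_summary.tsv"
    json_path = out_dir / "benchmark_pools.json"

    rows = []
    for g in sorted(summary.groups, key=lambda g: (g.loci_set, g.k)):
        rows.append({
            "k": g.k, "loci_set": g.loci_set, "n_reps": g.n_reps,
            "frac_all_parental": f"{g.frac_all_parental:.3f}",
            "frac_any_false_positive": f"{g.frac_any_false_positive:.3f}",
            "mean_tpr": f"{g.mean_tpr:.3f}",
            "mean_false_positives": f"{g.mean_false_positives:.3f}",
            "mean_glm_error": f"{g.mean_glm_error:.3f}",
            "n_failed": g.n_failed,
        })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)

    payload = {
        "groups": [asdict(g) for g in
                   sorted(summary.groups, key=lambda g: (g.loci_set, g.k))],
        "pools": [asdict(o) for o in summary.outcomes],
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return tsv_path, json_path


def _coerce(value, typ, key):
    if typ is bool:
        if isinstance(value, bool):
            return value
        raise ValueError(f"config key {key!r}: expected a boolean, got {value!r}")
    if typ is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ValueError(f"config key {key!r}: expected an integer, got {value!r}")
        return value
    if typ is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValueError(f"config key {key!r}: expected a number, got {value!r}")
        return float(value)
    return value


def load_config(path) -> tuple[DeconvolutionConfig, SimulationConfig]:
    """Load solver + simulation settings from a flat YAML file.

    Unknown keys raise (listing them); omitted keys keep their defaults.
    The effective configuration is echoed to the module logger.
    """
    raw = yaml.safe_load(Path(path).read_text()) if Path(path).exists() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of key: value")

    decon_fields = {f.name: f for f in fields(DeconvolutionConfig)}
    sim_fields = {f.name: f for f in fields(SimulationConfig)}
    unknown = [k for k in raw if k not in decon_fields and k not in sim_fields]
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")

    hints_d = {"n_folds": int, "lambda_path_size": int, "seed": int,
               "max_iter": int, "lambda_min_ratio": float, "coef_epsilon": float,
               "tol": float, "standardize": bool, "cv_metric": str}
    hints_s = {"n_strains": int, "alleles_per_locus": int, "repeat_unit": int,
               "base_length": int, "het_prob": float, "n_clusters": int,
               "within_cluster_mut_prob": float, "stutter_prob": float,
               "seed": int}
    d_kwargs = {k: _coerce(v, hints_d.get(k, object), k)
                for k, v in raw.items() if k in decon_fields}
    s_kwargs = {k: _coerce(v, hints_s.get(k, object), k)
                for k, v in raw.items() if k in sim_fields}
    if "loci" in s_kwargs:
        s_kwargs["loci"] = tuple(s_kwargs["loci"])
    decon = DeconvolutionConfig(**d_kwargs)
    sim = SimulationConfig(**s_kwargs)
    log.info("effective deconvolution config: %s", decon)
    log.info("effective simulation config: %s", sim)
    return decon, sim
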