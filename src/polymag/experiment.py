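"""Field-response experiments: replica protocol and parameter sweeps.

A single experiment follows the published protocol: build the vesicle,
equilibrate it field-free (the *basic state*), then switch the field on and
equilibrate anew, measuring observables in both states.  Replicas differ
only in the initial orientational distribution of the MNP moments (and in
their thermal noise); results are replica-averaged with standard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import DipoleSet, MembraneAssembly, build_system
from .dynamics import LangevinIntegrator, RunProtocol, equilibrate
from .forces import PairEnergyParams
from .observables import (ObservableRecord, cavity_volume, chain_stats,
                          elongation, mean_moment_projection, shape_semi_axes,
                          volume_defect)
from .params import ModelParams

__all__ = ["ReplicaResult", "ExperimentResult", "measure", "replica_seeds",
           "run_field_experiment", "sweep"]

FIELD_DIRECTION = (0.0, 0.0, 1.0)


@dataclass
class ReplicaResult:
    seed: int
    basic: ObservableRecord
    fielded: ObservableRecord
    converged_basic: bool
    converged_fielded: bool
    area_drift: float
    error: str | None = None


@dataclass
class ExperimentResult:
    params: ModelParams
    xi: float
    replicas: list[ReplicaResult]

    def _values(self, attr: str, stage: str) -> np.ndarray:
        return np.array([getattr(getattr(r, stage), attr)
                         for r in self.replicas if r.error is None])

    def aggregate(self) -> dict:
        """Replica means with standard errors."""
        out: dict = {"q": self.params.q, "xi": self.xi,
                     "n_replicas": sum(r.error is None for r in self.replicas)}
        for stage in ("basic", "fielded"):
            for attr in ("epsilon", "volume", "volume_defect",
                         "mean_moment_projection", "mean_chain_length",
                         "max_chain_length", "chain_alignment",
                         "polar_zone_occupancy"):
                v = self._values(attr, stage)
                v = v[np.isfinite(v)]
                key = f"{stage}_{attr}"
                out[key] = float(v.mean()) if len(v) else np.nan
                out[key + "_se"] = (float(v.std(ddof=1) / np.sqrt(len(v)))
                                    if len(v) > 1 else np.nan)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.replicas:
            for stage in ("basic", "fielded"):
                row = {"seed": r.seed, "stage": stage, "error": r.error}
                if r.error is None:
                    row.update(getattr(r, stage).to_dict())
                rows.append(row)
        return pd.DataFrame(rows)


def replica_seeds(base_seed: int, n: int) -> list[int]:
    """Independent per-replica seeds derived from the base seed."""
    return [int(np.random.SeedSequence([base_seed, r]).generate_state(1)[0]
                % 2**31) for r in range(n)]


def measure(assembly: MembraneAssembly, dipoles: DipoleSet,
            integ: LangevinIntegrator, protocol: RunProtocol,
            v_basic: float = np.nan) -> tuple[ObservableRecord, float]:
    """Production sampling: average observables over a short run.

    Returns (averaged record, relative total-shell-area drift during the
    sampling stretch).
    """
    n = assembly.n_beads_per_shell
    pair = integ.ff.pair
    area0 = (assembly.inner.total_area(integ.state.pos_beads[:n])
             + assembly.outer.total_area(integ.state.pos_beads[n:]))
    records = []
    drift = 0.0
    n_samples = max(1, protocol.production_steps // protocol.sample_interval)
    for _ in range(n_samples):
        integ.run(protocol.sample_interval)
        s = integ.state
        a, b, c = shape_semi_axes(s.pos_beads[n:], FIELD_DIRECTION)
        V = cavity_volume(assembly.inner, s.pos_beads[:n])
        cs = chain_stats(dipoles, pair, FIELD_DIRECTION,
                         positions=s.pos_mnps, orientations=s.orientations)
        area = (assembly.inner.total_area(s.pos_beads[:n])
                + assembly.outer.total_area(s.pos_beads[n:]))
        drift = max(drift, abs(area - area0) / area0)
        records.append(ObservableRecord(
            xi=s.xi, semi_axes=(a, b, c), epsilon=elongation(a, b, c),
            volume=V, volume_basic=v_basic,
            volume_defect=(volume_defect(V, v_basic)
                           if np.isfinite(v_basic) else np.nan),
            mean_moment_projection=mean_moment_projection(
                s.orientations, FIELD_DIRECTION),
            n_chains=cs.n_chains, mean_chain_length=cs.mean_length,
            max_chain_length=cs.max_length, chain_alignment=cs.alignment,
            polar_zone_occupancy=cs.polar_zone_occupancy,
            total_shell_area=area))
    mean = ObservableRecord(xi=integ.state.xi)
    axes = np.mean([r.semi_axes for r in records], axis=0)
    mean.semi_axes = tuple(float(x) for x in axes)
    for attr in ("epsilon", "volume", "volume_basic", "volume_defect",
                 "mean_moment_projection", "mean_chain_length",
                 "chain_alignment", "polar_zone_occupancy",
                 "total_shell_area"):
        setattr(mean, attr, float(np.mean([getattr(r, attr)
                                           for r in records])))
    mean.n_chains = int(round(np.mean([r.n_chains for r in records])))
    mean.max_chain_length = int(round(np.mean([r.max_chain_length
                                               for r in records])))
    return mean, drift


def run_field_experiment(params: ModelParams, protocol: RunProtocol,
                         xi_field: float | None = None,
                         n_replicas: int | None = None,
                         basic_protocol: RunProtocol | None = None,
                         raise_on_error: bool = False) -> ExperimentResult:
    """Replica-averaged field response of one vesicle size.

    Each replica: build -> equilibrate at xi=0 -> measure the basic state ->
    switch the field on instantaneously -> equilibrate -> measure again.
    ``basic_protocol`` optionally shortens the field-free stage (the basic
    state relaxes much faster than the fielded restructuring).  Replicas
    are independent; a failing replica is recorded and skipped unless
    ``raise_on_error``.
    """
    xi_field = params.xi if xi_field is None else xi_field
    n_rep = params.n_replicas if n_replicas is None else n_replicas
    basic_protocol = basic_protocol or protocol
    seeds = replica_seeds(params.seed, n_rep)
    replicas = []
    for seed in seeds:
        try:
            assembly, dipoles = build_system(params, orientation_seed=seed)
            integ = LangevinIntegrator(assembly, dipoles, params, seed)
            integ.state.xi = 0.0
            _, conv0 = equilibrate(integ, basic_protocol)
            basic, drift0 = measure(assembly, dipoles, integ, basic_protocol)
            integ.state.xi = xi_field
            _, conv1 = equilibrate(integ, protocol)
            fielded, drift1 = measure(assembly, dipoles, integ, protocol,
                                      v_basic=basic.volume)
            replicas.append(ReplicaResult(
                seed=seed, basic=basic, fielded=fielded,
                converged_basic=conv0, converged_fielded=conv1,
                area_drift=max(drift0, drift1)))
        except (FloatingPointError, RuntimeError, ValueError) as exc:
            if raise_on_error:
                raise
            replicas.append(ReplicaResult(
                seed=seed, basic=ObservableRecord(xi=0.0),
                fielded=ObservableRecord(xi=xi_field),
                converged_basic=False, converged_fielded=False,
                area_drift=np.nan, error=str(exc)))
    return ExperimentResult(params=params, xi=xi_field, replicas=replicas)


def sweep(base_params: ModelParams, q_values, xi_values,
          protocol: RunProtocol, out_dir: str | Path,
          n_replicas: int | None = None) -> pd.DataFrame:
    """Size x field sweep; one results directory per cell, resumable.

    Completed cells (with a ``summary.json``) are skipped, so an
    interrupted sweep can be resumed by re-running the same command.
    """
    q_values = list(q_values)
    xi_values = list(xi_values)
    if not xi_values:
        raise ValueError("empty xi list")
    if not q_values:
        raise ValueError("empty q list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for q in q_values:
        for xi in xi_values:
            cell = out / f"q{q:g}_xi{xi:g}"
            summary_path = cell / "summary.json"
            if summary_path.exists():
                rows.append(json.loads(summary_path.read_text()))
                continue
            cell.mkdir(parents=True, exist_ok=True)
            d = base_params.to_dict()
            d.update(q=float(q), xi=float(xi))
            params = ModelParams.from_dict(d)
            res = run_field_experiment(params, protocol,
                                       n_replicas=n_replicas)
            agg = res.aggregate()
            agg["realized_phi"] = params.realized_phi()
            agg["n_mnp"] = params.n_mnp()
            res.to_frame().to_csv(cell / "replicas.csv", index=False)
            summary_path.write_text(json.dumps(agg, indent=1))
            rows.append(agg)
    table = pd.DataFrame(rows)
    table.to_csv(out / "combined.csv", index=False)
    for col, name in (("fielded_epsilon", "epsilon"),
                      ("fielded_volume_defect", "volume_defect")):
        pivot = table.pivot(index="xi", columns="q", values=col)
        pivot.to_csv(out / f"{name}.csv")
    return table
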