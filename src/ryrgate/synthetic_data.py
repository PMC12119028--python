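"""Synthetic open-probability datasets emulating the published study design.

The study pooled 8 concentration-response relations (54 observations) into
three data groups: cardiac RyR2 with cytosolic ATP (Ca-dependence at fixed
Mg2+ of 0/600/940 uM plus Mg-dependence at fixed Ca2+ of 0.1/0.41 uM),
RyR2 without ATP (Ca-dependence 0.1-4000 uM) and skeletal RyR1 without ATP
(two laboratories' Ca-dependence curves).  :func:`paper_design` reproduces
that layout with log-spaced concentration grids; :func:`generate_dataset`
evaluates the COI model at a ground-truth parameter set per group and adds
observation noise, so fitting and parameter-recovery behavior can be tested
without the original recordings.

Noise models
------------
``gaussian_sem``
    po_mean = clip(P_O + N(0, sem), 0, 1) with sem = clip(sem_frac * P_O,
    sem_floor, sem_cap).  The defaults (floor 0.005, 15% relative, cap 0.10)
    mirror the SEM scale visible in the published figures.  Clipping keeps
    observations in [0, 1] at the price of a small upward bias where
    P_O << sem_floor.
``binomial_events``
    po_mean = Binomial(N, P_O)/N with sem = max(sem_floor,
    sqrt(P_O (1 - P_O) / N)): the sampling error of N independent gating
    observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coi_model import CoiParameters, IonCondition, open_probability, reference_parameters
from .coi_fit import (
    FitSpec,
    PoDataset,
    PoObservation,
    global_fit,
    normalize_group,
    table8_fitspec,
    FitConvergenceError,
)

__all__ = [
    "Sweep",
    "ExperimentDesign",
    "NoiseModel",
    "paper_design",
    "paper_truth",
    "generate_dataset",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass(frozen=True)
class Sweep:
    """One concentration-response relation: one axis swept, the other fixed."""

    group: str
    axis: str                 # 'ca' or 'mg'
    fixed_uM: float           # concentration of the co-ion
    grid_uM: tuple            # swept concentrations
    replicates: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", normalize_group(self.group))
        object.__setattr__(self, "grid_uM", tuple(float(c) for c in self.grid_uM))
        if self.axis not in ("ca", "mg"):
            raise ValueError(f"axis must be 'ca' or 'mg', got {self.axis!r}")
        if any(c <= 0 for c in self.grid_uM):
            raise ValueError("swept concentrations must be strictly positive")
        if self.fixed_uM < 0:
            raise ValueError("fixed co-ion concentration must be >= 0")

    def conditions(self):
        for c in self.grid_uM:
            if self.axis == "ca":
                yield c, self.fixed_uM
            else:
                yield self.fixed_uM, c


@dataclass(frozen=True)
class ExperimentDesign:
    sweeps: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "sweeps", tuple(self.sweeps))

    @property
    def groups(self):
        seen = []
        for s in self.sweeps:
            if s.group not in seen:
                seen.append(s.group)
        return tuple(seen)

    @property
    def n_points(self) -> int:
        return sum(len(s.grid_uM) * s.replicates for s in self.sweeps)

    def validate_against(self, spec: FitSpec) -> None:
        unknown = set(self.groups) - set(spec.groups)
        if unknown:
            raise ValueError(f"design groups not in fit spec: {sorted(unknown)}")


def _logspace(lo: float, hi: float, n: int) -> tuple:
    return tuple(np.logspace(np.log10(lo), np.log10(hi), n))


def paper_design() -> ExperimentDesign:
    """The published three-group design: 8 relations, 54 points in total.

    Per-relation point counts are spread evenly (7/7/6 for the three
    Ca-sweeps with ATP, 6/6 for the Mg-sweeps, 8 for RyR2 without ATP and
    7+7 for the two RyR1 source laboratories).
    """
    sweeps = [
        Sweep("RyR2+ATP", "ca", 0.0, _logspace(0.1, 100.0, 7)),
        Sweep("RyR2+ATP", "ca", 600.0, _logspace(0.1, 100.0, 7)),
        Sweep("RyR2+ATP", "ca", 940.0, _logspace(0.1, 100.0, 6)),
        Sweep("RyR2+ATP", "mg", 0.1, _logspace(20.0, 1300.0, 6)),
        Sweep("RyR2+ATP", "mg", 0.41, _logspace(20.0, 1300.0, 6)),
        Sweep("RyR2-ATP", "ca", 0.0, _logspace(0.1, 4000.0, 8)),
        Sweep("RyR1-ATP", "ca", 0.0, _logspace(0.1, 4000.0, 7)),
        Sweep("RyR1-ATP", "ca", 0.0, _logspace(0.15, 3000.0, 7)),
    ]
    return ExperimentDesign(sweeps=sweeps)


def paper_truth() -> dict:
    """Published best-fit parameters per group, the generator's ground truth."""
    return {g: reference_parameters(g) for g in ("RyR2+ATP", "RyR2-ATP", "RyR1-ATP")}


@dataclass(frozen=True)
class NoiseModel:
    kind: str = "gaussian_sem"        # or "binomial_events"
    sem_floor: float = 0.005
    sem_frac: float = 0.15
    sem_cap: float = 0.10
    events: int = 400                 # binomial_events only
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_sem", "binomial_events"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sem_floor <= 0:
            raise ValueError("sem floor must be > 0")


def generate_dataset(truth: dict, design: ExperimentDesign, noise: NoiseModel,
                     seed: int | None = None):
    """Simulate grouped observations; deterministic under a fixed seed.

    ``truth`` maps each design group to its CoiParameters.  Returns a list
    of PoDataset in design group order.  A sweep whose generated means are
    all zero triggers an uninformative-design warning.
    """
    truth = {normalize_group(g): p for g, p in truth.items()}
    missing = set(design.groups) - set(truth)
    if missing:
        raise KeyError(f"no truth parameters for groups: {sorted(missing)}")
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    by_group: dict = {g: [] for g in design.groups}
    for sweep in design.sweeps:
        p = truth[sweep.group]
        sweep_obs = []
        for ca, mg in sweep.conditions():
            po = open_probability(p, IonCondition.from_uM(ca, mg))
            for _ in range(sweep.replicates):
                if noise.kind == "gaussian_sem":
                    sem = float(np.clip(noise.sem_frac * po, noise.sem_floor, noise.sem_cap))
                    mean = float(np.clip(po + rng.normal(0.0, sem), 0.0, 1.0))
                else:
                    n = noise.events
                    mean = rng.binomial(n, po) / n
                    sem = max(noise.sem_floor, float(np.sqrt(po * (1.0 - po) / n)))
                sweep_obs.append(PoObservation(
                    ca_uM=ca, mg_uM=mg, po_mean=mean, po_sem=sem,
                    source=f"synthetic:{sweep.axis}@{sweep.fixed_uM:g}",
                ))
        if all(o.po_mean == 0.0 for o in sweep_obs):
            warnings.warn(
                f"sweep {sweep.group} {sweep.axis}@{sweep.fixed_uM:g} uM generated "
                "all-zero open probabilities (uninformative design)",
                stacklevel=2,
            )
        by_group[sweep.group].extend(sweep_obs)
    return [PoDataset(group=g, observations=obs) for g, obs in by_group.items()]


def noise_free(truth: dict, design: ExperimentDesign, sem: float = 1e-4):
    """Exact model means with a tiny nominal SEM (for recovery oracles)."""
    truth = {normalize_group(g): p for g, p in truth.items()}
    by_group: dict = {g: [] for g in design.groups}
    for sweep in design.sweeps:
        p = truth[sweep.group]
        for ca, mg in sweep.conditions():
            po = open_probability(p, IonCondition.from_uM(ca, mg))
            by_group[sweep.group].append(
                PoObservation(ca_uM=ca, mg_uM=mg, po_mean=min(po, 1.0),
                              po_sem=sem, source="synthetic:noise-free")
            )
    return [PoDataset(group=g, observations=obs) for g, obs in by_group.items()]


@dataclass
class RecoveryReport:
    """Per-parameter recovery statistics over replicate fits."""

    truth: dict                    # free slot -> true value
    per_parameter: pd.DataFrame    # bias, rmse, 2-SE coverage per free slot
    replicates: pd.DataFrame       # one row per replicate and free slot
    n_replicates: int
    n_failed: int
    dependency_warnings: int


def _truth_free_values(truth: dict, spec: FitSpec) -> dict:
    vals = {}
    for slot, pairs in spec.free_slots().items():
        p, g = pairs[0]
        vals[slot] = getattr(truth[g], p)
    return vals


def recovery_experiment(truth: dict, design: ExperimentDesign, noise: NoiseModel,
                        n_replicates: int, seed: int, spec: FitSpec | None = None
                        ) -> RecoveryReport:
    """Repeatedly simulate + fit; report bias, RMSE and 2-SE coverage.

    Coverage is evaluated in log-space, |ln(fit) - ln(truth)| <= 2 SE(ln),
    matching the log-space parameterization of the optimizer.
    """
    spec = spec or table8_fitspec()
    truth = {normalize_group(g): p for g, p in truth.items()}
    design.validate_against(spec)
    truth_vals = _truth_free_values(truth, spec)

    rows = []
    n_failed = 0
    dep_warn = 0
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        datasets = generate_dataset(truth, design, noise, seed=rep_seed)
        try:
            res = global_fit(datasets, spec)
        except FitConvergenceError:
            n_failed += 1
            continue
        if any("near-redundant" in w for w in res.warnings):
            dep_warn += 1
        for slot, t in truth_vals.items():
            v = res.free_values[slot]
            se = res.free_stderr[slot]
            se_ln = se / v if v > 0 else float("nan")
            covered = (
                abs(np.log(v) - np.log(t)) <= 2.0 * se_ln if se_ln == se_ln else False
            )
            rows.append(dict(replicate=rep, parameter=slot, truth=t, estimate=v,
                             stderr=se, covered=bool(covered)))
    reps = pd.DataFrame(rows)
    per = []
    for slot, t in truth_vals.items():
        sub = reps[reps.parameter == slot]
        est = sub.estimate.to_numpy()
        with np.errstate(over="ignore"):  # runaway ridge estimates -> inf RMSE
            per.append(dict(
                parameter=slot, truth=t,
                mean=float(est.mean()) if len(est) else float("nan"),
                bias=float(est.mean() - t) if len(est) else float("nan"),
                rmse=float(np.sqrt(np.mean((est - t) ** 2))) if len(est) else float("nan"),
                coverage_2se=float(sub.covered.mean()) if len(sub) else float("nan"),
            ))
    return RecoveryReport(
        truth=truth_vals,
        per_parameter=pd.DataFrame(per).set_index("parameter"),
        replicates=reps,
        n_replicates=n_replicates,
        n_failed=n_failed,
        dependency_warnings=dep_warn,
    )
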