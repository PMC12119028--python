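"""Constrained global fit of COI open-probability curves.

Grouped single-channel open-probability observations (mean +/- SEM at given
cytosolic [Ca2+], [Mg2+]) are fitted jointly by weighted least squares
(Levenberg-Marquardt via lmfit).  Every model parameter has, per data group,
one of three statuses: fixed at a value, shared across groups under a tag,
or free for that group alone.  The objective is the pooled chi-square

    chi2 = sum_i ((P_O(model; ca_i, mg_i) - po_mean_i) / po_sem_i)^2 .

All dissociation constants and allosteric factors are strictly positive, so
free parameters are optimized in log-space (no hard bounds); standard errors
are mapped back to the natural scale by the delta method, SE(K) = K * SE(ln K).
By default the covariance is not rescaled by the reduced chi-square, which is
the correct choice when the per-point SEMs are true standard errors; pass
``scale_covar=True`` in the spec for real data of uncertain SEM quality.

A per-parameter dependency diagnostic, 1 - 1/VIF computed from the
correlation matrix of the estimates, flags near-redundant parameters
(threshold 0.99); redundancy between the inhibition-site factor h_M and the
site-interaction factor h_CaM is the expected case -- only their product is
well constrained by bell-shaped Po curves.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .coi_model import (
    CoiParameters,
    IonCondition,
    TABLE_GROUPS,
    open_probability,
    reference_parameters,
)

__all__ = [
    "PoObservation",
    "PoDataset",
    "Fixed",
    "Shared",
    "Free",
    "FitSpec",
    "FitResult",
    "FitConvergenceError",
    "uniform_fitspec",
    "fitspec_to_dict",
    "fitspec_from_dict",
    "load_fitspec",
    "chi_square",
    "global_fit",
    "coefficient_of_determination",
    "table8_fitspec",
    "sensitivity_scan",
    "normalize_group",
    "datasets_to_frame",
    "frame_to_datasets",
    "read_po_csv",
    "write_po_csv",
    "import_s4_workbook",
]

DEPENDENCY_THRESHOLD = 0.99

PARAM_NAMES = tuple(f.name for f in dataclasses.fields(CoiParameters))


class FitConvergenceError(RuntimeError):
    """The optimizer did not converge; carries the optimizer trace message."""


def normalize_group(label: str) -> str:
    """Canonicalize a group label (Unicode minus, stray spaces)."""
    return label.replace("−", "-").replace(" ", "")


# --------------------------------------------------------------------------
# observations

@dataclass(frozen=True)
class PoObservation:
    ca_uM: float
    mg_uM: float
    po_mean: float
    po_sem: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.po_mean <= 1.0:
            raise ValueError(f"po_mean outside [0,1]: {self.po_mean}")
        if not (self.po_sem > 0):
            raise ValueError(
                f"po_sem must be > 0 (no silent unweighted fallback): {self.po_sem}"
            )
        if self.ca_uM < 0 or self.mg_uM < 0:
            raise ValueError("negative concentration in observation")


@dataclass(frozen=True)
class PoDataset:
    group: str
    observations: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", normalize_group(self.group))
        object.__setattr__(self, "observations", tuple(self.observations))

    def __len__(self) -> int:
        return len(self.observations)


def datasets_to_frame(datasets) -> pd.DataFrame:
    rows = [
        dict(group=ds.group, ca_uM=o.ca_uM, mg_uM=o.mg_uM,
             po_mean=o.po_mean, po_sem=o.po_sem, source=o.source)
        for ds in datasets
        for o in ds.observations
    ]
    return pd.DataFrame(rows, columns=["group", "ca_uM", "mg_uM", "po_mean", "po_sem", "source"])


def frame_to_datasets(df: pd.DataFrame):
    required = {"group", "ca_uM", "mg_uM", "po_mean", "po_sem"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for group, sub in df.groupby("group", sort=True):
        obs = [
            PoObservation(
                ca_uM=float(r.ca_uM), mg_uM=float(r.mg_uM),
                po_mean=float(r.po_mean), po_sem=float(r.po_sem),
                source=str(getattr(r, "source", "") or ""),
            )
            for r in sub.itertuples(index=False)
        ]
        out.append(PoDataset(group=str(group), observations=obs))
    return out


def read_po_csv(path):
    """Read datasets from CSV with header group,ca_uM,mg_uM,po_mean,po_sem,source."""
    return frame_to_datasets(pd.read_csv(path))


def write_po_csv(datasets, path) -> None:
    datasets_to_frame(datasets).to_csv(path, index=False)


def import_s4_workbook(path, sheet_groups=None):
    """Import open-probability observations from a spreadsheet workbook.

    Expected layout: one sheet per figure panel, a header row naming
    calcium/magnesium concentration columns (uM) and the Po mean and SEM,
    plus either a ``group`` column or an entry in ``sheet_groups`` mapping
    the sheet name to a data-group label.  Column names are matched
    case-insensitively by keyword (ca/mg/po/sem), so the published
    source-data layout and re-exports of our own CSV dialect both load.
    """
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    sheet_groups = sheet_groups or {}
    frames = []
    for ws in wb.worksheets:
        rows = [[c for c in row] for row in ws.iter_rows(values_only=True)]
        header_idx = None
        for i, row in enumerate(rows):
            cells = [str(c).lower() for c in row if c is not None]
            if any("po" in c or "open" in c for c in cells) and any("ca" in c for c in cells):
                header_idx = i
                break
        if header_idx is None:
            continue
        header = [str(c).strip() if c is not None else "" for c in rows[header_idx]]

        def find(*keys, exclude=()):
            for j, name in enumerate(header):
                low = name.lower()
                if any(k in low for k in keys) and not any(e in low for e in exclude):
                    return j
            return None

        j_ca = find("ca", exclude=("cam",))
        j_mg = find("mg")
        j_sem = find("sem", "s.e.m", "error")
        j_po = find("po", "open", exclude=("sem", "error"))
        j_group = find("group")
        j_source = find("source", "ref")
        if j_ca is None or j_po is None or j_sem is None:
            continue
        for row in rows[header_idx + 1:]:
            if row is None or row[j_po] is None or row[j_ca] is None:
                continue
            group = (
                str(row[j_group]) if j_group is not None and row[j_group] is not None
                else sheet_groups.get(ws.title, ws.title)
            )
            frames.append(dict(
                group=group,
                ca_uM=float(row[j_ca]),
                mg_uM=float(row[j_mg]) if j_mg is not None and row[j_mg] is not None else 0.0,
                po_mean=float(row[j_po]),
                po_sem=float(row[j_sem]),
                source=str(row[j_source]) if j_source is not None and row[j_source] is not None else ws.title,
            ))
    wb.close()
    if not frames:
        raise ValueError(f"no observation tables recognized in {path}")
    return frame_to_datasets(pd.DataFrame(frames))


# --------------------------------------------------------------------------
# fit specification

@dataclass(frozen=True)
class Fixed:
    value: float


@dataclass(frozen=True)
class Shared:
    tag: str


@dataclass(frozen=True)
class Free:
    pass


@dataclass
class FitSpec:
    """Per-parameter, per-group statuses plus optimizer settings.

    ``status[param][group]`` is Fixed(v) | Shared(tag) | Free().  Every
    CoiParameters symbol must have exactly one status per group.  Initial
    values may be overridden via ``initial`` keyed by the public free-slot
    name (the shared tag, or ``"param[group]"`` for group-specific slots).
    """

    groups: tuple
    status: dict
    initial: dict = field(default_factory=dict)
    max_nfev: int = 20000
    tol: float = 1e-10
    scale_covar: bool = False

    def __post_init__(self) -> None:
        self.groups = tuple(normalize_group(g) for g in self.groups)
        for p in PARAM_NAMES:
            if p not in self.status:
                raise ValueError(f"no status for parameter {p}")
            for g in self.groups:
                if g not in self.status[p]:
                    raise ValueError(f"no status for {p} in group {g}")
        # shared tags must be tag-consistent: one tag never spans two params
        tag_owner = {}
        for p in PARAM_NAMES:
            for g in self.groups:
                st = self.status[p][g]
                if isinstance(st, Shared):
                    if tag_owner.setdefault(st.tag, p) != p:
                        raise ValueError(f"shared tag {st.tag!r} used by two parameters")

    # -- free slots ---------------------------------------------------------
    def free_slots(self):
        """Public name -> list of (param, group) it controls, insertion-ordered."""
        slots = {}
        for p in PARAM_NAMES:
            for g in self.groups:
                st = self.status[p][g]
                if isinstance(st, Shared):
                    slots.setdefault(st.tag, []).append((p, g))
                elif isinstance(st, Free):
                    slots.setdefault(f"{p}[{g}]", []).append((p, g))
        return slots

    @property
    def n_free(self) -> int:
        return len(self.free_slots())

    def replace_status(self, param: str, groups, new_status) -> "FitSpec":
        status = {p: dict(d) for p, d in self.status.items()}
        for g in groups:
            status[param][normalize_group(g)] = new_status
        return dataclasses.replace(self, status=status)


def uniform_fitspec(groups, free=(), fixed=None, **kwargs) -> FitSpec:
    """Spec where ``free`` parameters are free per group and the rest fixed.

    ``fixed`` maps parameter names to fixed values; unlisted parameters are
    fixed at the CoiParameters defaults (factors at 1).
    """
    groups = tuple(normalize_group(g) for g in groups)
    defaults = CoiParameters().to_dict()
    fixed = {**defaults, **(fixed or {})}
    status = {}
    for p in PARAM_NAMES:
        if p in free:
            status[p] = {g: Free() for g in groups}
        else:
            status[p] = {g: Fixed(fixed[p]) for g in groups}
    return FitSpec(groups=groups, status=status, **kwargs)


def table8_fitspec(groups=TABLE_GROUPS) -> FitSpec:
    """The published fixing/sharing scheme (exactly 8 free parameter slots).

    K_O0 = K_I0 = 10800, K_M = 546 uM, f_Mg = 3.25 and h_MgM = 1 fixed in
    all groups; h_M fixed at 1 for both RyR2 groups and free for RyR1;
    K_Ca and K_Mg shared across all groups; f_Ca free per group; h_CaM free
    for RyR2+ATP and shared between the two ATP-free groups.
    """
    groups = tuple(normalize_group(g) for g in groups)
    status = {}
    fixed_all = {
        "K_O0": 10800.0, "K_I0": 10800.0, "K_M": 546.0,
        "f_Mg": 3.25, "h_MgM": 1.0,
        # reduced-form unity factors
        "f_M": 1.0, "h_Ca": 1.0, "h_Mg": 1.0,
        "f_CaM": 1.0, "f_MgM": 1.0, "g_CaM": 1.0, "g_MgM": 1.0,
    }
    for p, v in fixed_all.items():
        status[p] = {g: Fixed(v) for g in groups}
    status["K_Ca"] = {g: Shared("K_Ca") for g in groups}
    status["K_Mg"] = {g: Shared("K_Mg") for g in groups}
    status["f_Ca"] = {g: Free() for g in groups}
    status["h_CaM"] = {
        g: (Free() if g == "RyR2+ATP" else Shared("h_CaM_noATP")) for g in groups
    }
    status["h_M"] = {
        g: (Free() if g == "RyR1-ATP" else Fixed(1.0)) for g in groups
    }
    return FitSpec(groups=groups, status=status)


def fitspec_to_dict(spec: FitSpec) -> dict:
    """Flat mapping form of a FitSpec (YAML/JSON friendly)."""
    params = {}
    for p in PARAM_NAMES:
        per_group = {}
        for g in spec.groups:
            st = spec.status[p][g]
            if isinstance(st, Fixed):
                per_group[g] = {"fixed": st.value}
            elif isinstance(st, Shared):
                per_group[g] = {"shared": st.tag}
            else:
                per_group[g] = "free"
        params[p] = per_group
    return {
        "groups": list(spec.groups),
        "parameters": params,
        "initial": dict(spec.initial),
        "max_nfev": spec.max_nfev,
        "tol": spec.tol,
        "scale_covar": spec.scale_covar,
    }


def _status_from_entry(entry):
    if entry == "free" or entry == {"free": True}:
        return Free()
    if isinstance(entry, dict) and "fixed" in entry:
        return Fixed(float(entry["fixed"]))
    if isinstance(entry, dict) and "shared" in entry:
        return Shared(str(entry["shared"]))
    raise ValueError(f"unrecognized parameter status {entry!r}")


def fitspec_from_dict(d: dict) -> FitSpec:
    groups = tuple(normalize_group(g) for g in d["groups"])
    status = {}
    for p in PARAM_NAMES:
        entry = d["parameters"].get(p)
        if entry is None:
            # unlisted parameters default to fixed at the neutral value
            default = CoiParameters().to_dict()[p]
            status[p] = {g: Fixed(default) for g in groups}
        elif isinstance(entry, dict) and not ({"fixed", "shared", "free"} & set(entry)):
            # mapping keyed by group label
            status[p] = {
                normalize_group(g): _status_from_entry(v) for g, v in entry.items()
            }
        else:
            # one status applied to every group
            status[p] = {g: _status_from_entry(entry) for g in groups}
    return FitSpec(
        groups=groups,
        status=status,
        initial=dict(d.get("initial", {})),
        max_nfev=int(d.get("max_nfev", 20000)),
        tol=float(d.get("tol", 1e-10)),
        scale_covar=bool(d.get("scale_covar", False)),
    )


def load_fitspec(path) -> FitSpec:
    """Load a FitSpec from YAML/JSON; the literal name ``table8`` is a preset."""
    import yaml

    if str(path) == "table8":
        return table8_fitspec()
    with open(path) as fh:
        return fitspec_from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# objective

def chi_square(params_by_group: dict, datasets) -> float:
    """Pooled chi-square of the model against grouped observations."""
    total = 0.0
    for ds in datasets:
        if ds.group not in params_by_group:
            raise KeyError(f"no parameters for group {ds.group!r}")
        p = params_by_group[ds.group]
        for o in ds.observations:
            model = open_probability(p, IonCondition.from_uM(o.ca_uM, o.mg_uM))
            total += ((model - o.po_mean) / o.po_sem) ** 2
    return total


def coefficient_of_determination(params_by_group: dict, datasets, weighted: bool = False) -> float:
    """COD = 1 - SS_res/SS_tot over the pooled dataset.

    The primary (default) definition is unweighted; ``weighted=True`` uses
    1/sem^2 weights for both sums (diagnostic variant).
    """
    y, f, w = [], [], []
    for ds in datasets:
        p = params_by_group[ds.group]
        for o in ds.observations:
            y.append(o.po_mean)
            f.append(open_probability(p, IonCondition.from_uM(o.ca_uM, o.mg_uM)))
            w.append(1.0 / o.po_sem ** 2)
    y = np.array(y); f = np.array(f); w = np.array(w)
    if len(y) < 2:
        raise ValueError("COD undefined for fewer than 2 observations")
    if not weighted:
        w = np.ones_like(w)
    ybar = np.average(y, weights=w)
    ss_res = np.sum(w * (y - f) ** 2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    return float(1.0 - ss_res / ss_tot)


# --------------------------------------------------------------------------
# global fit

@dataclass
class FitResult:
    params_by_group: dict
    free_values: dict
    free_stderr: dict
    chi_square: float
    n_obs: int
    n_free: int
    dof: int
    cod: float
    cod_weighted: float
    residuals: pd.DataFrame
    dependency: dict
    correlation: pd.DataFrame
    success: bool
    message: str
    warnings: list

    def report(self) -> str:
        """Human-readable text table mirroring the published layout."""
        buf = io.StringIO()
        groups = sorted(self.params_by_group)
        buf.write("Parameter".ljust(10) + "".join(g.rjust(16) for g in groups) + "\n")
        for p in PARAM_NAMES:
            vals = []
            for g in groups:
                v = getattr(self.params_by_group[g], p)
                # a free slot named "p[g]" or a shared slot whose tag resolves to p
                se = self.free_stderr.get(f"{p}[{g}]")
                if se is None:
                    for slot, se_ in self.free_stderr.items():
                        if "[" not in slot and math.isclose(
                            self.free_values[slot], v, rel_tol=0, abs_tol=0
                        ) and slot.startswith(p):
                            se = se_
                vals.append(f"{v:.4g}±{se:.2g}" if se == se and se is not None else f"{v:.4g}")
            buf.write(p.ljust(10) + "".join(s.rjust(16) for s in vals) + "\n")
        buf.write(f"chi-square {self.chi_square:.4g}  dof {self.dof}  "
                  f"COD {self.cod:.4g} (weighted {self.cod_weighted:.4g})\n")
        for w in self.warnings:
            buf.write(f"warning: {w}\n")
        return buf.getvalue()

    def to_json_dict(self) -> dict:
        return {
            "free_values": self.free_values,
            "free_stderr": self.free_stderr,
            "chi_square": self.chi_square,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "dof": self.dof,
            "cod": self.cod,
            "cod_weighted": self.cod_weighted,
            "dependency": self.dependency,
            "success": self.success,
            "message": self.message,
            "warnings": self.warnings,
            "params_by_group": {g: p.to_dict() for g, p in self.params_by_group.items()},
        }


_SAFE = re.compile(r"[^0-9a-zA-Z_]")


def _lm_name(public: str) -> str:
    # '+'/'-' both matter in group labels (RyR2+ATP vs RyR2-ATP); keep them distinct
    mangled = public.replace("+", "_plus_").replace("-", "_minus_")
    return "ln__" + _SAFE.sub("_", mangled)


def _initial_value(slot: str, pairs, spec: FitSpec) -> float:
    if slot in spec.initial:
        return float(spec.initial[slot])
    param, group = pairs[0]
    try:
        return getattr(reference_parameters(group), param)
    except KeyError:
        # unknown group label: dissociation constants start at 1 uM, factors at 1
        return 1.0


def _resolve_params(spec: FitSpec, values: dict) -> dict:
    """Map free-slot values (natural scale) + fixed statuses to CoiParameters per group."""
    out = {}
    for g in spec.groups:
        kw = {}
        for p in PARAM_NAMES:
            st = spec.status[p][g]
            if isinstance(st, Fixed):
                kw[p] = st.value
            elif isinstance(st, Shared):
                kw[p] = values[st.tag]
            else:
                kw[p] = values[f"{p}[{g}]"]
        out[g] = CoiParameters(**kw)
    return out


def _canonical_datasets(datasets):
    """Sort groups and observations so reported values are order-invariant."""
    merged = {}
    for ds in datasets:
        merged.setdefault(ds.group, []).extend(ds.observations)
    out = []
    for g in sorted(merged):
        obs = sorted(merged[g], key=lambda o: (o.ca_uM, o.mg_uM, o.po_mean, o.po_sem, o.source))
        out.append(PoDataset(group=g, observations=obs))
    return out


def global_fit(datasets, spec: FitSpec, seed=None) -> FitResult:
    """Constrained global weighted least-squares fit of all data groups.

    ``seed`` is accepted for interface symmetry with the stochastic
    commands; the deterministic Levenberg-Marquardt path ignores it.
    """
    datasets = _canonical_datasets(datasets)
    if not datasets or all(len(ds) == 0 for ds in datasets):
        raise ValueError("no observations to fit")
    for ds in datasets:
        if ds.group not in spec.groups:
            raise KeyError(f"dataset group {ds.group!r} not in fit spec groups {spec.groups}")
    slots = spec.free_slots()
    if not slots:
        raise ValueError("fit spec has no free parameters")

    lm = lmfit.Parameters()
    slot_by_lm = {}
    for slot, pairs in slots.items():
        name = _lm_name(slot)
        slot_by_lm[name] = slot
        lm.add(name, value=math.log(_initial_value(slot, pairs, spec)))

    obs = [(ds.group, o) for ds in datasets for o in ds.observations]

    def residual(lmpars):
        # clamp the log-values: e^(+-500) is far outside any physical range
        # but keeps the optimizer finite when it explores a redundancy ridge
        vals = {slot_by_lm[n]: math.exp(min(max(v, -500.0), 500.0))
                for n, v in lmpars.valuesdict().items()}
        pbg = _resolve_params(spec, vals)
        return np.array([
            (open_probability(pbg[g], IonCondition.from_uM(o.ca_uM, o.mg_uM)) - o.po_mean)
            / o.po_sem
            for g, o in obs
        ])

    minres = lmfit.minimize(
        residual, lm, method="leastsq", scale_covar=spec.scale_covar,
        max_nfev=spec.max_nfev, xtol=spec.tol, ftol=spec.tol,
    )
    if not minres.success:
        raise FitConvergenceError(f"global fit did not converge: {minres.message}")

    warns = []
    free_values, free_stderr = {}, {}
    for name, par in minres.params.items():
        slot = slot_by_lm[name]
        v = math.exp(min(max(par.value, -500.0), 500.0))
        free_values[slot] = v
        if par.stderr is None:
            free_stderr[slot] = float("nan")
            warns.append(f"no standard error available for {slot}")
        else:
            free_stderr[slot] = v * par.stderr  # delta method from log-scale

    pbg = _resolve_params(spec, free_values)

    # dependency = 1 - 1/VIF from the correlation matrix of the estimates
    order = [slot_by_lm[n] for n in minres.var_names]
    dependency = {s: float("nan") for s in order}
    corr = pd.DataFrame(np.nan, index=order, columns=order)
    if minres.covar is not None:
        cov = np.asarray(minres.covar)
        d = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            cmat = cov / np.outer(d, d)
        corr = pd.DataFrame(cmat, index=order, columns=order)
        try:
            vif = np.diag(np.linalg.inv(cmat))
            for s, v in zip(order, vif):
                # VIF < 1 or non-finite means the correlation matrix is
                # numerically singular: redundancy beyond resolution
                dependency[s] = float(1.0 - 1.0 / v) if np.isfinite(v) and v >= 1.0 else 1.0
        except np.linalg.LinAlgError:
            dependency = {s: 1.0 for s in order}
            warns.append("near-redundant parameters suspected: correlation matrix is singular")
    else:
        warns.append("near-redundant parameters suspected: no covariance estimate from the optimizer")
    for s, dep in dependency.items():
        if dep == dep and dep > DEPENDENCY_THRESHOLD:
            warns.append(
                f"near-redundant parameter {s}: dependency {dep:.4f} > {DEPENDENCY_THRESHOLD}"
            )

    resid_rows = []
    for (g, o), r in zip(obs, residual(minres.params)):
        resid_rows.append(dict(group=g, ca_uM=o.ca_uM, mg_uM=o.mg_uM,
                               po_mean=o.po_mean, po_sem=o.po_sem,
                               weighted_residual=float(r)))
    residuals = pd.DataFrame(resid_rows)

    chisq = float(np.sum(residuals.weighted_residual ** 2))
    n_obs = len(obs)
    n_free = len(slots)
    return FitResult(
        params_by_group=pbg,
        free_values=free_values,
        free_stderr=free_stderr,
        chi_square=chisq,
        n_obs=n_obs,
        n_free=n_free,
        dof=n_obs - n_free,
        cod=coefficient_of_determination(pbg, datasets),
        cod_weighted=coefficient_of_determination(pbg, datasets, weighted=True),
        residuals=residuals,
        dependency=dependency,
        correlation=corr,
        success=True,
        message=str(minres.message),
        warnings=warns,
    )


# --------------------------------------------------------------------------
# sensitivity scan

def sensitivity_scan(param_name: str, values, datasets, spec: FitSpec, groups=None) -> pd.DataFrame:
    """Re-fit with ``param_name`` pinned at each value; tabulate the drift.

    By default the parameter is pinned in the groups where it is currently
    fixed (the published procedure: probing the effect of an assumed fixed
    value); pass ``groups`` to pin it elsewhere, overriding free/shared
    statuses there.  Returns one row per scan value with the chi-square, its
    change relative to the baseline fit, the COD, and every co-fitted free
    parameter.  Fit failures are recorded per row and the scan continues.
    """
    if param_name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {param_name!r}")
    if groups is None:
        groups = [g for g in spec.groups if isinstance(spec.status[param_name][g], Fixed)]
        if not groups:
            groups = list(spec.groups)
    groups = [normalize_group(g) for g in groups]

    probe = spec.replace_status(param_name, groups, Fixed(1.0))
    if probe.n_free == 0:
        raise ValueError("scan would leave no free parameters")

    base = global_fit(datasets, spec)
    rows = []
    for v in values:
        scan_spec = spec.replace_status(param_name, groups, Fixed(float(v)))
        row = {"value": float(v)}
        try:
            res = global_fit(datasets, scan_spec)
            row.update(
                chi_square=res.chi_square,
                delta_chi_rel=(res.chi_square - base.chi_square) / base.chi_square,
                cod=res.cod,
                success=True,
            )
            row.update({f"fit:{s}": val for s, val in res.free_values.items()})
        except (FitConvergenceError, ValueError) as exc:
            row.update(chi_square=float("nan"), delta_chi_rel=float("nan"),
                       cod=float("nan"), success=False, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
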