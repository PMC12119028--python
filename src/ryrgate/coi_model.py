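"""Equilibrium COI (closed-open-inactivated) model of RyR channel gating.

The ryanodine receptor (RyR) is a homotetrameric Ca2+-release channel.  In
the COI model the tetramer occupies one of three concerted macrostates --
closed (C, including the primed sub-state), open (O) or inactivated (I) --
following the Monod-Wyman-Changeux picture: all four monomers switch
together, and binding of ions to the per-monomer activation site (Ca2+ or,
competitively, Mg2+) and inhibition site (any divalent, M2+ = Ca2+ + Mg2+)
shifts the relative free energy of the macrostates.

Each macrostate carries a per-monomer statistical weight w_C, w_O, w_I
summing the six binding configurations of the two sites (activation site
empty/Ca/Mg x inhibition site empty/M).  The tetramer open probability is

    P_O = (w_O^4 / K_O0) / (w_O^4 / K_O0 + w_C^4 + w_I^4 / K_I0)

where K_O0 and K_I0 are the equilibrium constants of the ligand-free open
and inactivated macrostates relative to the closed one (large values mean
the unliganded channel strongly prefers the closed state).

Allosteric coefficients multiply dissociation constants in the non-reference
macrostates: a factor < 1 means increased affinity in that macrostate, 1
means no allosteric coupling, and > 1 decreased affinity.  The reduced
parameterization keeps 8 independent parameters by setting
f_M = h_Ca = h_Mg = f_CaM = f_MgM = g_CaM = g_MgM = 1.

Concentrations are stored in mol/l; constructors and accessors ending in
``_uM`` convert from/to micromolar (1 uM = 1e-6 mol/l), the unit used at all
user interfaces.  Dissociation constants are expressed in uM throughout, as
in the fitted parameter tables; only concentration/K ratios enter the
weights, so the two conventions meet in :func:`macrostate_weights` where
concentrations are converted back to uM.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "MOLAR_PER_UM",
    "IonCondition",
    "CoiParameters",
    "MacrostateWeights",
    "MacrostateDistribution",
    "macrostate_weights",
    "open_probability",
    "macrostate_distribution",
    "microstate_oracle_po",
    "po_curve",
    "TABLE_GROUPS",
    "reference_parameters",
]

#: mol/l per micromolar -- the single place the unit conversion lives.
MOLAR_PER_UM = 1e-6

#: Data-group labels of the published fit (extensible; labels are data, not code).
TABLE_GROUPS = ("RyR2+ATP", "RyR2-ATP", "RyR1-ATP")


class ParameterDomainError(ValueError):
    """A dissociation constant or allosteric factor is outside (0, inf)."""


@dataclass(frozen=True)
class IonCondition:
    """Cytosolic free divalent-ion concentrations, stored in mol/l.

    ``m`` (total divalent, the ligand of the inhibition site) is always
    derived as ``ca + mg`` and cannot be set independently.
    """

    ca: float
    mg: float

    def __post_init__(self) -> None:
        if self.ca < 0 or self.mg < 0:
            raise ValueError(f"negative concentration: ca={self.ca}, mg={self.mg}")

    @property
    def m(self) -> float:
        return self.ca + self.mg

    @classmethod
    def from_uM(cls, ca_uM: float, mg_uM: float = 0.0) -> "IonCondition":
        return cls(ca=ca_uM * MOLAR_PER_UM, mg=mg_uM * MOLAR_PER_UM)

    @property
    def ca_uM(self) -> float:
        return self.ca / MOLAR_PER_UM

    @property
    def mg_uM(self) -> float:
        return self.mg / MOLAR_PER_UM


# parameter symbol -> is it an equilibrium/dissociation constant (True) or factor
_K_NAMES = ("K_O0", "K_I0", "K_Ca", "K_Mg", "K_M")
_FACTOR_NAMES = (
    "f_Ca", "f_Mg", "f_M",
    "h_Ca", "h_Mg", "h_M",
    "f_CaM", "f_MgM", "g_CaM", "g_MgM", "h_CaM", "h_MgM",
)
#: factors forced to 1 in the reduced (8-parameter) form
REDUCED_UNITY = ("f_M", "h_Ca", "h_Mg", "f_CaM", "f_MgM", "g_CaM", "g_MgM")


@dataclass(frozen=True)
class CoiParameters:
    """All equilibrium constants and allosteric/interaction factors.

    K_O0, K_I0 are dimensionless macrostate equilibrium constants; K_Ca,
    K_Mg (activation site) and K_M (inhibition site) are dissociation
    constants in uM.  f_* act in the open macrostate, h_* in the
    inactivated one, g_* couple doubly-occupied monomers in the closed one.
    """

    K_O0: float = 10800.0
    K_I0: float = 10800.0
    K_Ca: float = 1.0
    K_Mg: float = 1.0
    K_M: float = 1.0
    f_Ca: float = 1.0
    f_Mg: float = 1.0
    f_M: float = 1.0
    h_Ca: float = 1.0
    h_Mg: float = 1.0
    h_M: float = 1.0
    f_CaM: float = 1.0
    f_MgM: float = 1.0
    g_CaM: float = 1.0
    g_MgM: float = 1.0
    h_CaM: float = 1.0
    h_MgM: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterDomainError(f"{f.name} must be finite and > 0, got {v}")

    @classmethod
    def reduced(cls, **kwargs) -> "CoiParameters":
        """Construct a reduced-form (8-parameter) set; the extra factors are 1."""
        for name in REDUCED_UNITY:
            if name in kwargs and kwargs[name] != 1.0:
                raise ParameterDomainError(
                    f"{name} is identically 1 in the reduced form"
                )
            kwargs[name] = 1.0
        return cls(**kwargs)

    @property
    def is_reduced(self) -> bool:
        return all(getattr(self, n) == 1.0 for n in REDUCED_UNITY)

    def as_reduced(self) -> "CoiParameters":
        """Copy with the non-reduced factors forced to 1."""
        return replace(self, **{n: 1.0 for n in REDUCED_UNITY})

    # -- flat key/value serialization (JSON or YAML mappings) ---------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CoiParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CoiParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class MacrostateWeights:
    """Per-monomer statistical weights; each >= 1 for non-negative ions."""

    w_C: float
    w_O: float
    w_I: float


@dataclass(frozen=True)
class MacrostateDistribution:
    p_closed: float
    p_open: float
    p_inactivated: float


def _per_monomer_terms(p: CoiParameters, cond: IonCondition) -> dict:
    """The six binding-configuration terms of each weight.

    Term order: (empty), Ca@act, Mg@act, M@inh, Ca@act+M@inh, Mg@act+M@inh.
    Dissociation constants are in uM, so concentrations are converted to uM.
    """
    ca = cond.ca / MOLAR_PER_UM
    mg = cond.mg / MOLAR_PER_UM
    m = ca + mg
    t_C = (
        1.0,
        ca / p.K_Ca,
        mg / p.K_Mg,
        m / p.K_M,
        ca * m / (p.g_CaM * p.K_Ca * p.K_M),
        mg * m / (p.g_MgM * p.K_Mg * p.K_M),
    )
    t_O = (
        1.0,
        ca / (p.f_Ca * p.K_Ca),
        mg / (p.f_Mg * p.K_Mg),
        m / (p.f_M * p.K_M),
        ca * m / (p.f_CaM * p.f_Ca * p.K_Ca * p.f_M * p.K_M),
        mg * m / (p.f_MgM * p.f_Mg * p.K_Mg * p.f_M * p.K_M),
    )
    t_I = (
        1.0,
        ca / (p.h_Ca * p.K_Ca),
        mg / (p.h_Mg * p.K_Mg),
        m / (p.h_M * p.K_M),
        ca * m / (p.h_CaM * p.h_Ca * p.K_Ca * p.h_M * p.K_M),
        mg * m / (p.h_MgM * p.h_Mg * p.K_Mg * p.h_M * p.K_M),
    )
    return {"C": t_C, "O": t_O, "I": t_I}


def macrostate_weights(
    params: CoiParameters, cond: IonCondition, form: str = "full"
) -> MacrostateWeights:
    """Per-monomer statistical weights w_C, w_O, w_I.

    ``form='reduced'`` evaluates the same expressions with the seven
    non-reduced factors forced to 1, so the reduction identity holds by
    construction (the full form is the single source of truth).
    """
    if form not in ("full", "reduced"):
        raise ValueError(f"form must be 'full' or 'reduced', got {form!r}")
    if form == "reduced":
        params = params.as_reduced()
    t = _per_monomer_terms(params, cond)
    return MacrostateWeights(
        w_C=float(sum(t["C"])), w_O=float(sum(t["O"])), w_I=float(sum(t["I"]))
    )


def _distribution_from_weights(
    p: CoiParameters, w: MacrostateWeights, exponent: int = 4
) -> MacrostateDistribution:
    # rescale by the largest weight before the 4th power: at mM divalent
    # concentrations weights reach ~1e7 and w^4 would lose range otherwise
    m = max(w.w_C, w.w_O, w.w_I)
    a_o = (w.w_O / m) ** exponent / p.K_O0
    a_c = (w.w_C / m) ** exponent
    a_i = (w.w_I / m) ** exponent / p.K_I0
    z = a_o + a_c + a_i
    return MacrostateDistribution(
        p_closed=a_c / z, p_open=a_o / z, p_inactivated=a_i / z
    )


def open_probability(
    params: CoiParameters, cond: IonCondition, form: str = "full"
) -> float:
    """Equilibrium tetramer open probability P_O (value in (0, 1))."""
    w = macrostate_weights(params, cond, form=form)
    return _distribution_from_weights(params, w).p_open


def macrostate_distribution(
    params: CoiParameters, cond: IonCondition, form: str = "full"
) -> MacrostateDistribution:
    """Normalized probabilities of the closed, open and inactivated macrostates."""
    w = macrostate_weights(params, cond, form=form)
    return _distribution_from_weights(params, w)


def microstate_oracle_po(
    params: CoiParameters, cond: IonCondition, n_monomers: int = 4
) -> float:
    """Brute-force P_O by enumerating all tetramer occupation microstates.

    Every monomer is in one of six binding configurations (the six terms of
    its weight); the tetramer weight of a macrostate is the sum over all
    6^n assignments of the product of per-monomer terms, which the
    partition-function formula collapses to w^n by the multinomial theorem.
    This enumeration is deliberately independent of that identity and serves
    as the correctness oracle for :func:`open_probability`.
    """
    t = _per_monomer_terms(params, cond)
    sums = {}
    for state in ("C", "O", "I"):
        total = 0.0
        for combo in itertools.product(range(6), repeat=n_monomers):
            prod = 1.0
            for i in combo:
                prod *= t[state][i]
            total += prod
        sums[state] = total
    a_o = sums["O"] / params.K_O0
    a_c = sums["C"]
    a_i = sums["I"] / params.K_I0
    return a_o / (a_o + a_c + a_i)


def po_curve(
    params: CoiParameters,
    ca_uM,
    mg_uM,
    form: str = "full",
) -> np.ndarray:
    """Vectorized P_O over arrays of cytosolic [Ca2+] and [Mg2+] in uM."""
    ca = np.atleast_1d(np.asarray(ca_uM, dtype=float))
    mg = np.atleast_1d(np.asarray(mg_uM, dtype=float))
    ca, mg = np.broadcast_arrays(ca, mg)
    out = np.empty(ca.shape, dtype=float)
    it = np.nditer(ca, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = open_probability(
            params, IonCondition.from_uM(ca[idx], mg[idx]), form=form
        )
    return out


def reference_parameters(group: str) -> CoiParameters:
    """Published best-fit reduced parameter set for one data group.

    Groups: ``RyR2+ATP``, ``RyR2-ATP``, ``RyR1-ATP`` (a Unicode minus in the
    group label is accepted).  Used as default fit initialization and as the
    ground truth of the synthetic-data generator.
    """
    key = group.replace("−", "-").replace(" ", "")
    common = dict(K_O0=10800.0, K_I0=10800.0, K_Ca=0.59, K_Mg=36.3, K_M=546.0,
                  f_Mg=3.25, h_MgM=1.0)
    presets = {
        "RyR2+ATP": dict(f_Ca=0.029, h_M=1.0, h_CaM=0.016),
        "RyR2-ATP": dict(f_Ca=0.10, h_M=1.0, h_CaM=0.11),
        "RyR1-ATP": dict(f_Ca=0.15, h_M=0.28, h_CaM=0.11),
    }
    if key not in presets:
        raise KeyError(f"unknown group {group!r}; expected one of {TABLE_GROUPS}")
    return CoiParameters.reduced(**common, **presets[key])
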