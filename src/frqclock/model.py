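"""Core delayed negative-feedback model of the Neurospora clock.

State (6 components, arbitrary concentration units):

====== =====================================================
M_frq  cytosolic *frq* mRNA
F      nuclear FRQ protein (hypo/hyperphosphorylated lumped)
M_wc1  *wc-1* mRNA
W_dark phosphorylated dark-state nuclear WCC
W_lit  light-activated nuclear WCC
V      VVD photoadaptation protein
====== =====================================================

The model realizes the standard FRQ/WC-based oscillator (FWO)
architecture: WCC activates *frq* transcription; FRQ represses WCC
activity (closed here as a Hill repression of *frq* transcription);
FRQ synthesis follows *frq* mRNA with a lumped delay ``tau`` that
absorbs translation, progressive phosphorylation and nuclear
translocation; FRQ supports *wc-1* expression (the positive limb);
blue light converts dark-state WCC to a transcriptionally hyperactive
light state, and VVD — itself induced by light-activated WCC —
divisively inhibits that photoactivation (photoadaptation).

Light induction of *frq* in Neurospora runs through dedicated
light-response promoter elements and fires at every circadian phase,
so the light-activated channel enters additively rather than under the
circadian repression term (which would let the clock gate off the
acute light response entirely).

Equations (dot = d/dt; ``M_tau`` is M_frq evaluated ``tau`` h ago)::

    Mdot_frq = v_dark*W_dark * K_I^h / (K_I^h + F^h) + v_light*W_lit - d_M*M_frq
    Fdot     = k_s*M_tau - d_F*F
    Mdot_wc1 = v_w + k_fw*F - d_Mw*M_wc1
    Wdot_dark= k_w*M_wc1 - k_act*L*W_dark/(1 + V/K_V) + k_rel*W_lit - d_Wd*W_dark
    Wdot_lit = k_act*L*W_dark/(1 + V/K_V) - k_rel*W_lit - d_Wl*W_lit
    Vdot     = k_v*W_lit - d_V*V

with ``L`` the instantaneous light intensity in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields, replace
from importlib import resources
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelState",
    "ModelParameters",
    "STATE_NAMES",
    "derivative",
    "apply_knockout",
    "default_parameters",
    "KNOCKOUTS",
]

STATE_NAMES = ("M_frq", "F", "M_wc1", "W_dark", "W_light", "V")


class ModelState(NamedTuple):
    """One point of the 6-dimensional model state (a.u.)."""

    M_frq: float
    F: float
    M_wc1: float
    W_dark: float
    W_light: float
    V: float

    @classmethod
    def uniform(cls, value: float = 0.1) -> "ModelState":
        return cls(*(value,) * 6)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, Hill terms, the translation delay and knockout flags.

    Units: hours for time, arbitrary concentration units (a.u.) for
    amounts, so first-order rates are 1/h and synthesis rates a.u./h.
    ``tau`` is the lumped translation/phosphorylation/translocation
    delay; FRQ synthesis at time t follows *frq* mRNA at t - tau.
    """

    v_dark: float    # W_dark-driven frq transcription (a.u./h)
    v_light: float   # W_light-driven frq transcription (a.u./h)
    K_I: float       # FRQ repression half-constant (a.u.)
    h: float         # repression Hill exponent (>= 1)
    d_M: float       # frq mRNA degradation (1/h)
    k_s: float       # FRQ synthesis per delayed mRNA (1/h)
    tau: float       # lumped delay (h), several hours
    d_F: float       # FRQ clearance, FWD-1 pathway proxy (1/h)
    v_w: float       # basal wc-1 transcription (a.u./h)
    k_fw: float      # FRQ -> wc-1 support (1/h); 0 disables the positive limb
    d_Mw: float      # wc-1 mRNA degradation (1/h)
    k_w: float       # WCC production per wc-1 mRNA (1/h)
    d_Wd: float      # dark-state WCC clearance (1/h)
    d_Wl: float      # light-state WCC clearance (1/h)
    k_act: float     # light activation of WCC (1/h per unit light)
    k_rel: float     # light-state reversion (1/h)
    K_V: float       # VVD inhibition half-constant (a.u.)
    k_v: float       # VVD induction per W_light (1/h)
    d_V: float       # VVD clearance (1/h)
    frq_null: bool = False
    wc_null: bool = False
    vvd_null: bool = False

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if not 2.0 <= self.tau <= 8.0:
            raise ValueError("tau must lie in [2, 8] h ('several hours')")
        if self.h < 1:
            raise ValueError("Hill exponent h must be >= 1")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.type == "bool" or isinstance(v, bool):
                continue
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite")
            if f.name == "k_fw":
                if v < 0:
                    raise ValueError("k_fw must be >= 0")
                continue
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")

    # effective synthesis rates after knockouts
    @property
    def k_s_eff(self) -> float:
        return 0.0 if self.frq_null else self.k_s

    @property
    def k_w_eff(self) -> float:
        return 0.0 if self.wc_null else self.k_w

    @property
    def k_v_eff(self) -> float:
        return 0.0 if self.vvd_null else self.k_v

    # -- serialization: flat key -> number JSON ------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(doc) - {"frq_null", "wc_null", "vvd_null"}
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**doc)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))


def derivative(
    now: ModelState | np.ndarray,
    delayed: ModelState | np.ndarray,
    light: float,
    p: ModelParameters,
) -> np.ndarray:
    """Time-derivative of the state.

    ``delayed`` is the full state ``tau`` hours ago; only its M_frq
    component enters (the delayed-translation term).
    """
    M, F, Mw, Wd, Wl, V = (float(x) for x in now)
    if not all(np.isfinite(x) for x in (M, F, Mw, Wd, Wl, V)):
        raise FloatingPointError("non-finite model state (integrator blow-up?)")
    if not 0.0 <= light <= 1.0:
        raise ValueError("light must lie in [0, 1]")
    M_tau = float(delayed[0])

    KIh = p.K_I ** p.h
    repress = KIh / (KIh + max(F, 0.0) ** p.h)
    act = p.k_act * light * Wd / (1.0 + V / p.K_V)

    return np.array([
        p.v_dark * Wd * repress + p.v_light * Wl - p.d_M * M,
        p.k_s_eff * M_tau - p.d_F * F,
        p.v_w + p.k_fw * F - p.d_Mw * Mw,
        p.k_w_eff * Mw - act + p.k_rel * Wl - p.d_Wd * Wd,
        act - p.k_rel * Wl - p.d_Wl * Wl,
        p.k_v_eff * Wl - p.d_V * V,
    ])


#: supported strain labels and their parameter effects
KNOCKOUTS = {
    "frq": "frq_null (no FRQ synthesis, as in frq^10)",
    "wc-1": "wc_null (no WCC, as in wc-1^RIP)",
    "vvd": "vvd_null (no photoadaptation, as in vvd^KO)",
    "frq7": "FRQ stabilized (d_F x 0.7): long free-running period",
    "frq2": "FRQ destabilized (d_F x 1.4): short free-running period",
}

# frq7/frq2 are point mutants altering FRQ stability; the scale factors
# were fixed during model calibration so the DD periods straddle 22 h.
_FRQ7_DF_SCALE = 0.7
_FRQ2_DF_SCALE = 1.4


def apply_knockout(p: ModelParameters, gene: str) -> ModelParameters:
    """Return a copy of ``p`` configured as the named mutant strain.

    Supported labels: ``frq`` (frq^10 null), ``wc-1`` (wc-1^RIP),
    ``vvd`` (vvd^KO), ``frq7`` (long-period) and ``frq2``
    (short-period FRQ stability mutants).
    """
    if gene == "frq":
        return replace(p, frq_null=True)
    if gene == "wc-1":
        return replace(p, wc_null=True)
    if gene == "vvd":
        return replace(p, vvd_null=True)
    if gene == "frq7":
        return replace(p, d_F=p.d_F * _FRQ7_DF_SCALE)
    if gene == "frq2":
        return replace(p, d_F=p.d_F * _FRQ2_DF_SCALE)
    raise ValueError(
        f"unknown gene label {gene!r}; supported: {sorted(KNOCKOUTS)}"
    )


_DEFAULT_CACHE: ModelParameters | None = None


def default_parameters() -> ModelParameters:
    """The committed calibrated wild-type parameter set.

    Produced by :func:`frqclock.scan.calibrate` against the printed
    behavioral constraints (22 h DD period; entrainment of FRQ down to
    LD3:3; free run at LD2:2; light response decreasing with cycle
    length; protein smoother than mRNA) and frozen as package data.
    """
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        text = resources.files("frqclock").joinpath("data/default_parameters.json").read_text()
        _DEFAULT_CACHE = ModelParameters.from_json(text)
    return _DEFAULT_CACHE
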