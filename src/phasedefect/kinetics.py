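"""Reaction kinetics for the monodomain model.

Three classic low-dimensional cardiac models are provided:

* ``ap`` -- Aliev-Panfilov two-variable model (dimensionless units),
  producing rigidly rotating spirals with circular cores;
* ``fk`` -- Fenton-Karma three-variable model (ms / mm), whose MLR-I
  parameter set produces rotors with linear cores;
* ``bocf`` -- Bueno-Orovio-Cherry-Fenton minimal four-variable human
  ventricular model (ms / mm), EPI parameter set.

Each model exposes a vectorised ``reaction(state)`` (the local dynamics
``F(u)``), a resting fixed point, the diffusion coefficient of the first
(voltage-like) variable, and the ``(V, R)`` observable pair with the
threshold point ``(V_star, R_star)`` used for phase analysis.  Parameter
values are loaded from the YAML files shipped in ``phasedefect/params``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = ["Kinetics", "get_kinetics", "available_parameter_sets"]

_PARAM_FILES = {
    ("ap", "standard"): "ap_standard.yaml",
    ("fk", "mlr1"): "fk_mlr1.yaml",
    ("fk", "mbr"): "fk_mbr.yaml",
    ("bocf", "epi"): "bocf_epi.yaml",
}

_DEFAULT_SET = {"ap": "standard", "fk": "mlr1", "bocf": "epi"}


def available_parameter_sets() -> list[tuple[str, str]]:
    """Return the ``(model, parameter_set)`` pairs shipped with the package."""
    return sorted(_PARAM_FILES)


@dataclass(frozen=True)
class Kinetics:
    """A reaction-kinetics model plus its phase-analysis conventions.

    Attributes
    ----------
    name : str
        Model identifier: ``"ap"``, ``"fk"`` or ``"bocf"``.
    param_set : str
        Name of the parameter set (e.g. ``"mlr1"``).
    m : int
        Number of state variables.
    rest_state : ndarray, shape (m,)
        Resting fixed point of the local dynamics.
    P11 : float
        Diffusion coefficient of the first state variable; only this
        variable diffuses.
    params : dict
        Model parameters.
    defaults : dict
        Recommended simulation / detection settings for this model
        (``dx``, ``dt``, ``V_star``, ``R_star``, ``dt_lat``, ``dt_c``,
        ``dphi_arr_crit``, ``tau``).
    """

    name: str
    param_set: str
    m: int
    rest_state: np.ndarray
    P11: float
    params: dict = field(repr=False)
    defaults: dict = field(repr=False)

    # -- observables -------------------------------------------------
    @property
    def V_star(self) -> float:
        return float(self.defaults["V_star"])

    @property
    def R_star(self) -> float:
        return float(self.defaults["R_star"])

    def observables(self, state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Extract the ``(V, R)`` observable pair from an ``(m, ...)`` state.

        ``V`` is always the first variable.  ``R`` is the recovery
        observable: ``v`` for the AP model, ``1 - v`` for FK and BOCF.
        """
        V = state[0]
        if self.name == "ap":
            R = state[1]
        else:
            R = 1.0 - state[1]
        return V, R

    @property
    def b_rest(self) -> float:
        """Phase offset that places the resting state at phase 0."""
        V, R = self.observables(self.rest_state.reshape(self.m, 1))
        return -math.atan2(float(R[0]) - self.R_star, float(V[0]) - self.V_star)

    # -- reaction terms ----------------------------------------------
    def reaction(self, state: np.ndarray) -> np.ndarray:
        """Local dynamics ``F(u)`` evaluated pointwise on an ``(m, ...)`` state."""
        if self.name == "ap":
            return self._reaction_ap(state)
        if self.name == "fk":
            return self._reaction_fk(state)
        return self._reaction_bocf(state)

    def _reaction_ap(self, state):
        p = self.params
        u, v = state
        k, a = p["k"], p["a"]
        du = -k * u * (u - a) * (u - 1.0) - u * v
        eps = p["eps0"] + p["mu1"] * v / (u + p["mu2"])
        dv = eps * (-v - k * u * (u - a - 1.0))
        return np.stack([du, dv])

    def _reaction_fk(self, state):
        p = self.params
        u, v, w = state
        q = u >= p["u_c"]            # excited gate
        qv = u >= p["u_v"]
        tau_vm = np.where(qv, p["tau_vm1"], p["tau_vm2"])
        j_fi = np.where(q, -v * (1.0 - u) * (u - p["u_c"]) / p["tau_d"], 0.0)
        j_so = np.where(q, 1.0 / p["tau_r"], u / p["tau_0"])
        j_si = -w * (1.0 + np.tanh(p["k"] * (u - p["u_csi"]))) / (2.0 * p["tau_si"])
        du = -(j_fi + j_so + j_si)
        dv = np.where(q, -v / p["tau_vp"], (1.0 - v) / tau_vm)
        dw = np.where(q, -w / p["tau_wp"], (1.0 - w) / p["tau_wm"])
        return np.stack([du, dv, dw])

    def _reaction_bocf(self, state):
        p = self.params
        u, v, w, s = state
        h_v = u >= p["theta_v"]
        h_w = u >= p["theta_w"]
        h_o = u >= p["theta_o"]
        h_vm = u >= p["theta_vm"]

        tau_vm = np.where(h_vm, p["tau_v2m"], p["tau_v1m"])
        tau_wm = p["tau_w1m"] + (p["tau_w2m"] - p["tau_w1m"]) * (
            1.0 + np.tanh(p["k_wm"] * (u - p["u_wm"]))
        ) / 2.0
        tau_so = p["tau_so1"] + (p["tau_so2"] - p["tau_so1"]) * (
            1.0 + np.tanh(p["k_so"] * (u - p["u_so"]))
        ) / 2.0
        tau_s = np.where(h_w, p["tau_s2"], p["tau_s1"])
        tau_o = np.where(h_o, p["tau_o2"], p["tau_o1"])

        v_inf = np.where(u < p["theta_vm"], 1.0, 0.0)
        w_inf = np.where(h_o, p["w_inf_star"], 1.0 - u / p["tau_winf"])

        j_fi = np.where(h_v, -v * (u - p["theta_v"]) * (p["u_u"] - u) / p["tau_fi"], 0.0)
        j_so = np.where(h_w, 1.0 / tau_so, (u - p["u_o"]) / tau_o)
        j_si = np.where(h_w, -w * s / p["tau_si"], 0.0)

        du = -(j_fi + j_so + j_si)
        dv = np.where(h_v, -v / p["tau_vp"], (v_inf - v) / tau_vm)
        dw = np.where(h_w, -w / p["tau_wp"], (w_inf - w) / tau_wm)
        ds = ((1.0 + np.tanh(p["k_s"] * (u - p["u_s"]))) / 2.0 - s) / tau_s
        return np.stack([du, dv, dw, ds])


def _rest_state(model: str, params: dict) -> np.ndarray:
    if model == "ap":
        return np.array([0.0, 0.0])
    if model == "fk":
        return np.array([0.0, 1.0, 1.0])
    # BOCF: s relaxes to its steady sigmoid value at u = u_o
    s_rest = (1.0 + math.tanh(params["k_s"] * (params["u_o"] - params["u_s"]))) / 2.0
    return np.array([0.0, 1.0, 1.0, s_rest])


def get_kinetics(name: str, param_set: str | None = None) -> Kinetics:
    """Load a kinetics model by name.

    Parameters
    ----------
    name : {"ap", "fk", "bocf"}
        Model family.
    param_set : str, optional
        Parameter set; defaults to ``standard`` (AP), ``mlr1`` (FK) or
        ``epi`` (BOCF).
    """
    name = name.lower()
    if name not in _DEFAULT_SET:
        raise ValueError(f"unknown kinetics {name!r}; choose from ap, fk, bocf")
    param_set = (param_set or _DEFAULT_SET[name]).lower()
    try:
        fname = _PARAM_FILES[(name, param_set)]
    except KeyError:
        raise ValueError(
            f"no parameter set {param_set!r} for model {name!r}; "
            f"available: {available_parameter_sets()}"
        ) from None
    text = resources.files("phasedefect.params").joinpath(fname).read_text()
    cfg = yaml.safe_load(text)
    params = cfg["params"]
    defaults = cfg["defaults"]
    rest = _rest_state(name, params)
    return Kinetics(
        name=name,
        param_set=param_set,
        m=len(rest),
        rest_state=rest,
        P11=float(defaults["P11"]),
        params=params,
        defaults=defaults,
    )
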