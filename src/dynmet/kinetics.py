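"""Common modular rate law, ODE assembly and simulation.

Every reaction Σα_i A_i ⇌ Σβ_j B_j is translated into the flux

    v = u · f_reg · [kcat⁺ Π_i (a_i/kMᵢ)^α_i − kcat⁻ Π_j (b_j/kMⱼ)^β_j]
        / [Π_i (1+a_i/kMᵢ)^α_i + Π_j (1+b_j/kMⱼ)^β_j − 1 + D_reg]

with allosteric regulation f_reg = Π_act (x/kM)/(1+x/kM) · Π_inh 1/(1+x/kM)
and specific regulation D_reg = Σ_act kM/x + Σ_inh x/kM. The network then
integrates dx/dt = S·v(x,k), with boundary species held constant and
concentration changes divided by the compartment volume so that
cross-compartment reactions conserve amounts.

The right-hand side is compiled to a flat-array kernel (numba-jitted when
available) so the robustness harness can afford thousands of simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.integrate import odeint

from .balancing import BalancedParameters
from .network import Network

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "RateLawParameters",
    "KineticModel",
    "SimulationSchedule",
    "Pulse",
    "Trajectory",
    "SimulationError",
    "build_rate_law",
    "rate_laws_from_balanced",
    "assemble_ode_system",
    "simulate",
    "equilibrium_flux_check",
]


class SimulationError(RuntimeError):
    """ODE integration failed; carries the time of failure in the message."""


@dataclass
class RateLawParameters:
    """Per-reaction rate-law constants (s⁻¹ for kcat±, mM for kM and u)."""

    kcat_f: float
    kcat_r: float
    kM: dict[str, float]        # participant kMs
    kM_reg: dict[str, float] = field(default_factory=dict)  # regulator kMs
    u: float = 1.0
    h: float = 1.0

    def __post_init__(self) -> None:
        for name, val in list(self.kM.items()) + list(self.kM_reg.items()):
            if not val > 0:
                raise ValueError(f"kM for {name!r} must be positive, got {val}")
        if self.kcat_f < 0 or self.kcat_r < 0:
            raise ValueError("catalytic rates must be non-negative")
        if self.kcat_f == 0 and self.kcat_r == 0:
            pass  # a dead reaction is allowed (constant trajectory)
        if not self.u > 0:
            raise ValueError("enzyme concentration must be positive")


def build_rate_law(reaction, params: RateLawParameters):
    """Return v(x) for one reaction, x a mapping metabolite id → mM.

    One-sided (exchange) reactions carry the present side's terms only: the
    empty side contributes 1 to the denominator and 0 to the numerator.
    """
    subs = reaction.substrates
    prods = reaction.products

    def v(x: Mapping[str, float]) -> float:
        num_f = den_f = 1.0
        for met, alpha in subs:
            r = max(x[met], 0.0) / params.kM[met]
            num_f *= r ** alpha
            den_f *= (1.0 + r) ** alpha
        num_r = den_r = 1.0
        for met, beta in prods:
            r = max(x[met], 0.0) / params.kM[met]
            num_r *= r ** beta
            den_r *= (1.0 + r) ** beta
        if not subs:
            num_f = 0.0
        if not prods:
            num_r = 0.0
        f_reg, d_reg = 1.0, 0.0
        for reg in reaction.regulators:
            km = params.kM_reg.get(reg.metabolite_id,
                                   params.kM.get(reg.metabolite_id))
            r = max(x[reg.metabolite_id], 0.0) / km
            if reg.mode == "activator":
                if r == 0.0:
                    return 0.0
                f_reg *= r / (1.0 + r)
                d_reg += 1.0 / r
            else:
                f_reg *= 1.0 / (1.0 + r)
                d_reg += r
        den = den_f + den_r - 1.0 + d_reg
        return params.u * f_reg * (params.kcat_f * num_f - params.kcat_r * num_r) / den

    return v


def rate_laws_from_balanced(
    network: Network, balanced: BalancedParameters
) -> dict[str, RateLawParameters]:
    """Median rate-law parameter set for every reaction.

    Irreversible reactions get kcat⁻ fixed to zero.
    """
    out: dict[str, RateLawParameters] = {}
    for rid, rxn in network.reactions.items():
        kM = {met: balanced.median("kM", reaction_id=rid, metabolite_id=met)
              for met in rxn.stoichiometry}
        kM_reg = {
            reg.metabolite_id: balanced.median(
                "kM", reaction_id=rid, metabolite_id=reg.metabolite_id)
            for reg in rxn.regulators
        }
        out[rid] = RateLawParameters(
            kcat_f=balanced.median("kcat_forward", reaction_id=rid),
            kcat_r=0.0 if not rxn.reversible
            else balanced.median("kcat_reverse", reaction_id=rid),
            kM=kM,
            kM_reg=kM_reg,
            u=balanced.median("u", reaction_id=rid),
            h=rxn.cooperativity,
        )
    return out


# The kernel takes two packed buffers plus offset tables so the numba
# dispatch cost per call stays small (the integrator calls it thousands of
# times per trajectory). Integer layout (offsets in ioff):
#   0 sub_ptr  1 prod_ptr  2 act_ptr  3 inh_ptr  4 sub_idx  5 prod_idx
#   6 act_idx  7 inh_idx  8 has_sub  9 has_prod  10 state_mask  11 nr
# Float layout (offsets in foff):
#   0 kcatf  1 kcatr  2 u  3 sub_coef  4 sub_km  5 prod_coef  6 prod_km
#   7 act_km  8 inh_km  9 inv_vol
@njit(cache=False)
def _kernel(x, ibuf, ioff, fbuf, foff, out, vout):
    n = x.shape[0]
    for i in range(n):
        out[i] = 0.0
    nr = ioff[11]
    o_sp, o_pp, o_ap, o_ip = ioff[0], ioff[1], ioff[2], ioff[3]
    o_si, o_pi, o_ai, o_ii = ioff[4], ioff[5], ioff[6], ioff[7]
    o_hs, o_hp, o_mask = ioff[8], ioff[9], ioff[10]
    f_kf, f_kr, f_u = foff[0], foff[1], foff[2]
    f_sc, f_sk, f_pc, f_pk = foff[3], foff[4], foff[5], foff[6]
    f_ak, f_ik, f_iv = foff[7], foff[8], foff[9]
    for j in range(nr):
        num_f = 1.0
        den_f = 1.0
        for k in range(ibuf[o_sp + j], ibuf[o_sp + j + 1]):
            a = x[ibuf[o_si + k]]
            if a < 0.0:
                a = 0.0
            r = a / fbuf[f_sk + k]
            num_f *= r ** fbuf[f_sc + k]
            den_f *= (1.0 + r) ** fbuf[f_sc + k]
        num_r = 1.0
        den_r = 1.0
        for k in range(ibuf[o_pp + j], ibuf[o_pp + j + 1]):
            b = x[ibuf[o_pi + k]]
            if b < 0.0:
                b = 0.0
            r = b / fbuf[f_pk + k]
            num_r *= r ** fbuf[f_pc + k]
            den_r *= (1.0 + r) ** fbuf[f_pc + k]
        if ibuf[o_hs + j] == 0:
            num_f = 0.0
        if ibuf[o_hp + j] == 0:
            num_r = 0.0
        freg = 1.0
        dreg = 0.0
        dead = False
        for k in range(ibuf[o_ap + j], ibuf[o_ap + j + 1]):
            xa = x[ibuf[o_ai + k]]
            if xa <= 0.0:
                dead = True
                break
            r = xa / fbuf[f_ak + k]
            freg *= r / (1.0 + r)
            dreg += 1.0 / r
        if dead:
            vout[j] = 0.0
            continue
        for k in range(ibuf[o_ip + j], ibuf[o_ip + j + 1]):
            xi = x[ibuf[o_ii + k]]
            if xi < 0.0:
                xi = 0.0
            r = xi / fbuf[f_ik + k]
            freg *= 1.0 / (1.0 + r)
            dreg += r
        den = den_f + den_r - 1.0 + dreg
        v = fbuf[f_u + j] * freg * (fbuf[f_kf + j] * num_f
                                    - fbuf[f_kr + j] * num_r) / den
        vout[j] = v
        for k in range(ibuf[o_sp + j], ibuf[o_sp + j + 1]):
            i = ibuf[o_si + k]
            out[i] -= fbuf[f_sc + k] * v * fbuf[f_iv + i]
        for k in range(ibuf[o_pp + j], ibuf[o_pp + j + 1]):
            i = ibuf[o_pi + k]
            out[i] += fbuf[f_pc + k] * v * fbuf[f_iv + i]
    for i in range(n):
        if ibuf[o_mask + i] == 0:
            out[i] = 0.0


@njit(cache=False)
def _jac_kernel(x, ibuf, ioff, fbuf, foff, J):
    """Analytic Jacobian J[i, m] = d(dx_i/dt)/dx_m of the packed system.

    Shares the buffer layout of the flux kernel. Supplied to the stiff
    integrator so it does not have to finite-difference the right-hand
    side (n extra evaluations per Jacobian update).
    """
    n = x.shape[0]
    for i in range(n):
        for m in range(n):
            J[i, m] = 0.0
    nr = ioff[11]
    o_sp, o_pp, o_ap, o_ip = ioff[0], ioff[1], ioff[2], ioff[3]
    o_si, o_pi, o_ai, o_ii = ioff[4], ioff[5], ioff[6], ioff[7]
    o_hs, o_hp, o_mask = ioff[8], ioff[9], ioff[10]
    f_kf, f_kr, f_u = foff[0], foff[1], foff[2]
    f_sc, f_sk, f_pc, f_pk = foff[3], foff[4], foff[5], foff[6]
    f_ak, f_ik, f_iv = foff[7], foff[8], foff[9]
    for j in range(nr):
        s0, s1 = ibuf[o_sp + j], ibuf[o_sp + j + 1]
        p0, p1 = ibuf[o_pp + j], ibuf[o_pp + j + 1]
        a0, a1 = ibuf[o_ap + j], ibuf[o_ap + j + 1]
        i0, i1 = ibuf[o_ip + j], ibuf[o_ip + j + 1]
        num_f = 1.0
        den_f = 1.0
        for k in range(s0, s1):
            a = x[ibuf[o_si + k]]
            if a < 0.0:
                a = 0.0
            r = a / fbuf[f_sk + k]
            num_f *= r ** fbuf[f_sc + k]
            den_f *= (1.0 + r) ** fbuf[f_sc + k]
        num_r = 1.0
        den_r = 1.0
        for k in range(p0, p1):
            b = x[ibuf[o_pi + k]]
            if b < 0.0:
                b = 0.0
            r = b / fbuf[f_pk + k]
            num_r *= r ** fbuf[f_pc + k]
            den_r *= (1.0 + r) ** fbuf[f_pc + k]
        if ibuf[o_hs + j] == 0:
            num_f = 0.0
        if ibuf[o_hp + j] == 0:
            num_r = 0.0
        freg = 1.0
        dreg = 0.0
        dead = False
        for k in range(a0, a1):
            xa = x[ibuf[o_ai + k]]
            if xa <= 0.0:
                dead = True
                break
            r = xa / fbuf[f_ak + k]
            freg *= r / (1.0 + r)
            dreg += 1.0 / r
        if dead:
            continue  # flux pinned at 0 in a neighbourhood; Jacobian block 0
        for k in range(i0, i1):
            xi = x[ibuf[o_ii + k]]
            if xi < 0.0:
                xi = 0.0
            r = xi / fbuf[f_ik + k]
            freg *= 1.0 / (1.0 + r)
            dreg += r
        den = den_f + den_r - 1.0 + dreg
        A = fbuf[f_kf + j] * num_f - fbuf[f_kr + j] * num_r
        u = fbuf[f_u + j]
        base = u * freg / den
        vAD2 = u * freg * A / (den * den)
        # accumulate dv/dx_m for every species touching this reaction and
        # scatter through the stoichiometry in the same pass
        for src in range(s0, s1):
            m = ibuf[o_si + src]
            a = x[m]
            if a < 0.0:
                a = 0.0
            km = fbuf[f_sk + src]
            alpha = fbuf[f_sc + src]
            other = 1.0
            for k in range(s0, s1):
                if k != src:
                    aa = x[ibuf[o_si + k]]
                    if aa < 0.0:
                        aa = 0.0
                    other *= (aa / fbuf[f_sk + k]) ** fbuf[f_sc + k]
            r = a / km
            dnum = alpha * r ** (alpha - 1.0) / km * other \
                if (a > 0.0 or alpha == 1.0) else 0.0
            if ibuf[o_hs + j] == 0:
                dnum = 0.0
            dden = alpha * den_f / (km + a)
            dv = base * fbuf[f_kf + j] * dnum - vAD2 * dden
            _scatter(J, ibuf, fbuf, o_si, o_pi, f_sc, f_pc, f_iv,
                     s0, s1, p0, p1, m, dv)
        for src in range(p0, p1):
            m = ibuf[o_pi + src]
            b = x[m]
            if b < 0.0:
                b = 0.0
            km = fbuf[f_pk + src]
            beta = fbuf[f_pc + src]
            other = 1.0
            for k in range(p0, p1):
                if k != src:
                    bb = x[ibuf[o_pi + k]]
                    if bb < 0.0:
                        bb = 0.0
                    other *= (bb / fbuf[f_pk + k]) ** fbuf[f_pc + k]
            r = b / km
            dnum = beta * r ** (beta - 1.0) / km * other \
                if (b > 0.0 or beta == 1.0) else 0.0
            if ibuf[o_hp + j] == 0:
                dnum = 0.0
            dden = beta * den_r / (km + b)
            dv = -base * fbuf[f_kr + j] * dnum - vAD2 * dden
            _scatter(J, ibuf, fbuf, o_si, o_pi, f_sc, f_pc, f_iv,
                     s0, s1, p0, p1, m, dv)
        for src in range(a0, a1):
            m = ibuf[o_ai + src]
            xa = x[m]
            km = fbuf[f_ak + src]
            r = xa / km
            dfreg_over_freg = 1.0 / (xa * (1.0 + r))
            ddreg = -km / (xa * xa)
            dv = base * A * dfreg_over_freg - vAD2 * ddreg
            _scatter(J, ibuf, fbuf, o_si, o_pi, f_sc, f_pc, f_iv,
                     s0, s1, p0, p1, m, dv)
        for src in range(i0, i1):
            m = ibuf[o_ii + src]
            xi = x[m]
            if xi < 0.0:
                xi = 0.0
            km = fbuf[f_ik + src]
            r = xi / km
            dfreg_over_freg = -1.0 / (km * (1.0 + r))
            ddreg = 1.0 / km
            dv = base * A * dfreg_over_freg - vAD2 * ddreg
            _scatter(J, ibuf, fbuf, o_si, o_pi, f_sc, f_pc, f_iv,
                     s0, s1, p0, p1, m, dv)
    for i in range(n):
        if ibuf[o_mask + i] == 0:
            for m in range(n):
                J[i, m] = 0.0


@njit(cache=False, inline="always")
def _scatter(J, ibuf, fbuf, o_si, o_pi, f_sc, f_pc, f_iv,
             s0, s1, p0, p1, m, dv):
    for k in range(s0, s1):
        i = ibuf[o_si + k]
        J[i, m] -= fbuf[f_sc + k] * dv * fbuf[f_iv + i]
    for k in range(p0, p1):
        i = ibuf[o_pi + k]
        J[i, m] += fbuf[f_pc + k] * dv * fbuf[f_iv + i]


class KineticModel:
    """Network + rate-law parameters compiled to a fast ODE right-hand side.

    The state vector covers every metabolite in network order; boundary
    species keep a zero derivative (constant concentration).
    """

    def __init__(self, network: Network,
                 params: Mapping[str, RateLawParameters]):
        self.network = network
        self.species = network.metabolite_ids
        self._pos = {m: i for i, m in enumerate(self.species)}
        missing = [rid for rid in network.reactions if rid not in params]
        if missing:
            raise ValueError(
                "missing rate-law parameters for reactions: " + ", ".join(missing))
        self.params = dict(params)
        n = len(self.species)
        self.state_mask = np.array(
            [0 if network.metabolites[m].is_boundary else 1 for m in self.species],
            dtype=np.int64)
        self.inv_vol = np.array([1.0 / network.volume_of(m) for m in self.species])

        sub_ptr, prod_ptr, act_ptr, inh_ptr = [0], [0], [0], [0]
        sub_idx, sub_coef, prod_idx, prod_coef = [], [], [], []
        act_idx, inh_idx = [], []
        #: flat kM slot bookkeeping: (kind, reaction_id, metabolite_id)
        self.km_slots: list[tuple[str, str, str]] = []
        has_sub, has_prod = [], []
        for rid, rxn in network.reactions.items():
            for met, alpha in rxn.substrates:
                sub_idx.append(self._pos[met])
                sub_coef.append(alpha)
                self.km_slots.append(("sub", rid, met))
            for met, beta in rxn.products:
                prod_idx.append(self._pos[met])
                prod_coef.append(beta)
                self.km_slots.append(("prod", rid, met))
            for reg in rxn.regulators:
                if reg.mode == "activator":
                    act_idx.append(self._pos[reg.metabolite_id])
                    self.km_slots.append(("act", rid, reg.metabolite_id))
                else:
                    inh_idx.append(self._pos[reg.metabolite_id])
                    self.km_slots.append(("inh", rid, reg.metabolite_id))
            sub_ptr.append(len(sub_idx))
            prod_ptr.append(len(prod_idx))
            act_ptr.append(len(act_idx))
            inh_ptr.append(len(inh_idx))
            has_sub.append(1 if rxn.substrates else 0)
            has_prod.append(1 if rxn.products else 0)
        nr = len(network.reactions)
        int_parts = [np.asarray(a, dtype=np.int64) for a in (
            sub_ptr, prod_ptr, act_ptr, inh_ptr, sub_idx, prod_idx, act_idx,
            inh_idx, has_sub, has_prod, self.state_mask)]
        self._ioff = np.zeros(12, dtype=np.int64)
        pos = 0
        for i, part in enumerate(int_parts):
            self._ioff[i] = pos
            pos += part.size
        self._ioff[11] = nr
        self._ibuf = np.concatenate(int_parts) if pos else np.zeros(0, np.int64)
        nsub, nprod = len(sub_idx), len(prod_idx)
        nact, ninh = len(act_idx), len(inh_idx)
        float_sizes = [nr, nr, nr, nsub, nsub, nprod, nprod, nact, ninh, n]
        self._foff = np.zeros(10, dtype=np.int64)
        pos = 0
        for i, size in enumerate(float_sizes):
            self._foff[i] = pos
            pos += size
        self._fbuf = np.zeros(pos)
        f = self._fbuf
        o = self._foff
        # views into the packed float buffer; refilled in place, never rebound
        self.kcatf = f[o[0]:o[0] + nr]
        self.kcatr = f[o[1]:o[1] + nr]
        self.u = f[o[2]:o[2] + nr]
        self.sub_coef = f[o[3]:o[3] + nsub]
        self.sub_km = f[o[4]:o[4] + nsub]
        self.prod_coef = f[o[5]:o[5] + nprod]
        self.prod_km = f[o[6]:o[6] + nprod]
        self.act_km = f[o[7]:o[7] + nact]
        self.inh_km = f[o[8]:o[8] + ninh]
        self.inv_vol_view = f[o[9]:o[9] + n]
        self.sub_coef[:] = sub_coef
        self.prod_coef[:] = prod_coef
        self.inv_vol_view[:] = self.inv_vol
        ib = self._ibuf
        io = self._ioff
        self.sub_ptr = ib[io[0]:io[0] + nr + 1]
        self.prod_ptr = ib[io[1]:io[1] + nr + 1]
        self.act_ptr = ib[io[2]:io[2] + nr + 1]
        self.inh_ptr = ib[io[3]:io[3] + nr + 1]
        self.sub_idx = ib[io[4]:io[4] + nsub]
        self.prod_idx = ib[io[5]:io[5] + nprod]
        self.act_idx = ib[io[6]:io[6] + nact]
        self.inh_idx = ib[io[7]:io[7] + ninh]
        self.has_sub = ib[io[8]:io[8] + nr]
        self.has_prod = ib[io[9]:io[9] + nr]
        kinds = np.array([{"sub": 0, "prod": 1, "act": 2, "inh": 3}[k]
                          for k, _, _ in self.km_slots])
        self._km_masks = tuple(kinds == i for i in range(4))
        self._n = n
        # scratch buffers for the integration hot path (single-threaded use)
        self._out = np.empty(n)
        self._v = np.empty(nr)
        self._J = np.empty((n, n))
        self._refresh_param_arrays()

    def _refresh_param_arrays(self) -> None:
        rxns = list(self.network.reactions.values())
        self.kcatf[:] = [self.params[r.id].kcat_f for r in rxns]
        self.kcatr[:] = [self.params[r.id].kcat_r for r in rxns]
        self.u[:] = [self.params[r.id].u for r in rxns]
        sub_km, prod_km, act_km, inh_km = [], [], [], []
        for kind, rid, met in self.km_slots:
            p = self.params[rid]
            km = p.kM.get(met, p.kM_reg.get(met))
            if km is None:
                raise ValueError(f"no kM for {met!r} in reaction {rid!r}")
            {"sub": sub_km, "prod": prod_km, "act": act_km, "inh": inh_km}[kind].append(km)
        self.sub_km[:] = sub_km
        self.prod_km[:] = prod_km
        self.act_km[:] = act_km
        self.inh_km[:] = inh_km

    def set_parameters(self, params: Mapping[str, RateLawParameters]) -> None:
        self.params = dict(params)
        self._refresh_param_arrays()

    def set_flat(self, kcatf: np.ndarray, kcatr: np.ndarray, u: np.ndarray,
                 km_flat: np.ndarray) -> None:
        """Fast parameter refill: km_flat follows ``km_slots`` order."""
        self.kcatf[:] = kcatf
        self.kcatr[:] = kcatr
        self.u[:] = u
        m_sub, m_prod, m_act, m_inh = self._km_masks
        self.sub_km[:] = km_flat[m_sub]
        self.prod_km[:] = km_flat[m_prod]
        self.act_km[:] = km_flat[m_act]
        self.inh_km[:] = km_flat[m_inh]

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        out, v = self._out, self._v
        _kernel(x, self._ibuf, self._ioff, self._fbuf, self._foff, out, v)
        return out

    def fluxes(self, x: np.ndarray) -> np.ndarray:
        """Per-reaction flux vector v(x) (mmol·s⁻¹)."""
        out = np.empty(self._n)
        v = np.empty(int(self._ioff[11]))
        _kernel(x, self._ibuf, self._ioff, self._fbuf, self._foff, out, v)
        return v

    def jacobian(self, t: float, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the right-hand side at state x."""
        _jac_kernel(x, self._ibuf, self._ioff, self._fbuf, self._foff,
                    self._J)
        return self._J

    def initial_state(
        self, concentrations: Optional[Mapping[str, float]] = None
    ) -> np.ndarray:
        x0 = np.zeros(self._n)
        for i, mid in enumerate(self.species):
            if concentrations is not None and mid in concentrations:
                x0[i] = concentrations[mid]
            else:
                c = self.network.metabolites[mid].initial_concentration
                if c is None:
                    raise ValueError(
                        f"no initial concentration for metabolite {mid!r}")
                x0[i] = c
        return x0


def assemble_ode_system(
    network: Network, balanced: BalancedParameters
) -> KineticModel:
    """Build the dx/dt = S·v model from balanced medians."""
    return KineticModel(network, rate_laws_from_balanced(network, balanced))


@dataclass
class Pulse:
    time: float
    metabolite_id: str
    action: str = "multiply"  # set | add | multiply
    amount: float = 10.0      # mM for set/add, factor for multiply

    def apply(self, value: float) -> float:
        if self.action == "set":
            return self.amount
        if self.action == "add":
            return value + self.amount
        if self.action == "multiply":
            return value * self.amount
        raise ValueError(f"unknown pulse action {self.action!r}")


@dataclass
class SimulationSchedule:
    """Integration window, output grid and perturbation pulses.

    The default mirrors the standard protocol: 400 s with a ×10
    concentration pulse applied to one metabolite at 200 s.
    """

    t_end: float = 400.0
    n_points: int = 401
    pulses: list[Pulse] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("output grid needs at least 2 points")
        for p in self.pulses:
            if not 0.0 < p.time < self.t_end:
                raise ValueError(f"pulse time {p.time} outside (0, {self.t_end})")

    @classmethod
    def standard(cls, pulse_metabolite: Optional[str] = None,
                 t_end: float = 400.0, pulse_time: float = 200.0,
                 factor: float = 10.0, n_points: int = 401) -> "SimulationSchedule":
        pulses = []
        if pulse_metabolite is not None:
            pulses = [Pulse(pulse_time, pulse_metabolite, "multiply", factor)]
        return cls(t_end=t_end, n_points=n_points, pulses=pulses)


@dataclass
class Trajectory:
    times: np.ndarray                 # s
    concentrations: np.ndarray        # (time × species), mM
    species: list[str]
    diagnostics: dict = field(default_factory=dict)

    def column(self, metabolite_id: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(metabolite_id)]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.concentrations, columns=self.species)
        df.insert(0, "time", self.times)
        return df


def simulate(
    model: KineticModel,
    schedule: Optional[SimulationSchedule] = None,
    initial: Optional[Mapping[str, float]] = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_steps: int = 10000,
) -> Trajectory:
    """Integrate the model with LSODA, restarting at every pulse.

    Pulses are discontinuities: the value stored at a grid point equal to a
    pulse time is the post-pulse value; the pre/post pair is recorded in
    ``diagnostics['pulses']``.
    """
    schedule = schedule or SimulationSchedule()
    grid = np.linspace(0.0, schedule.t_end, schedule.n_points)
    x = model.initial_state(initial)
    pulses = sorted(schedule.pulses, key=lambda p: p.time)
    boundaries = [0.0] + [p.time for p in pulses] + [schedule.t_end]
    out = np.empty((grid.size, x.size))
    out[0] = x
    pulse_log = []
    filled = np.zeros(grid.size, dtype=bool)
    filled[0] = True

    # hot path: bind the kernel arguments once per trajectory
    kern = _kernel
    jkern = _jac_kernel
    ibuf, ioff = model._ibuf, model._ioff
    fbuf, foff = model._fbuf, model._foff
    dx, vbuf, Jbuf = model._out, model._v, model._J

    def f(y, t):
        kern(y, ibuf, ioff, fbuf, foff, dx, vbuf)
        return dx

    def jac(y, t):
        jkern(y, ibuf, ioff, fbuf, foff, Jbuf)
        return Jbuf

    for seg in range(len(boundaries) - 1):
        t0, t1 = boundaries[seg], boundaries[seg + 1]
        inner = np.where((grid > t0) & (grid < t1))[0]
        ts = np.concatenate(([t0], grid[inner], [t1]))
        sol, info = odeint(f, x, ts, Dfun=jac, rtol=rtol, atol=atol,
                           mxstep=max_steps, full_output=True)
        if info["message"] != "Integration successful.":
            t_fail = float(info["tcur"][-1]) if len(info.get("tcur", [])) else t0
            raise SimulationError(
                f"integration failed near t = {t_fail:.3g} s "
                f"({info['message']}); consider loosening rtol/atol or "
                "raising max_steps")
        if not np.all(np.isfinite(sol)):
            raise SimulationError(
                f"non-finite concentrations in segment [{t0:g}, {t1:g}] s")
        out[inner] = sol[1:1 + inner.size]
        filled[inner] = True
        # segment endpoints that coincide with grid points
        for t_end_seg, row in ((t0, sol[0]), (t1, sol[-1])):
            gi = int(round(t_end_seg / (grid[1] - grid[0])))
            if 0 <= gi < grid.size and not filled[gi] \
                    and abs(grid[gi] - t_end_seg) < 1e-9 * max(t_end_seg, 1.0):
                out[gi] = row
                filled[gi] = True
        x = sol[-1].copy()
        if seg < len(pulses):
            p = pulses[seg]
            idx = model.species.index(p.metabolite_id)
            pre = x[idx]
            x[idx] = p.apply(pre)
            pulse_log.append({"time": p.time, "metabolite": p.metabolite_id,
                              "pre": pre, "post": x[idx]})
            hit = np.where(np.isclose(grid, p.time))[0]
            for gi in hit:  # pulse-time grid point carries the post value
                out[gi] = x
                filled[gi] = True
    out[~filled] = np.nan
    return Trajectory(grid, out, list(model.species),
                      {"pulses": pulse_log, "rtol": rtol, "atol": atol})


def equilibrium_flux_check(
    model: KineticModel, balanced: BalancedParameters
) -> dict[str, float]:
    """Relative flux magnitude of each reversible two-sided reaction at Rᴬ = 0.

    For each reaction, concentrations are shifted along the stoichiometry
    direction so that the reaction affinity Σ n_i (μ°_i + RT ln c_i)
    vanishes; a thermodynamically consistent parameter set must then carry
    zero net flux. The residual is |forward − reverse| / (forward + reverse).
    """
    net = model.network
    RT = balanced.system.config.RT
    c0 = balanced.concentrations()
    mu0 = {m: balanced.log_mean("mu0", metabolite_id=m) for m in net.metabolites}
    out: dict[str, float] = {}
    for rid, rxn in net.reactions.items():
        if not rxn.reversible or not rxn.substrates or not rxn.products:
            continue
        n = rxn.stoichiometry
        ra = -sum(ni * (mu0[m] + RT * math.log(c0[m])) for m, ni in n.items())
        delta = ra / (RT * sum(ni * ni for ni in n.values()))
        conc = dict(c0)
        for m, ni in n.items():
            conc[m] = math.exp(math.log(c0[m]) + delta * ni)
        p = model.params[rid]
        fwd = p.kcat_f
        for met, alpha in rxn.substrates:
            fwd *= (conc[met] / p.kM[met]) ** alpha
        rev = p.kcat_r
        for met, beta in rxn.products:
            rev *= (conc[met] / p.kM[met]) ** beta
        out[rid] = abs(fwd - rev) / max(fwd + rev, 1e-300)
    return out
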