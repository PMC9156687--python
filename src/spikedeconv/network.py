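"""Conductance-based CA1-like network of bursty E-cells and fast I-cells.

E-cells follow a quadratic (Izhikevich-style) spiking model with a slow
recovery variable; per-cell burstiness is controlled by the "burst factor"
(BF), the post-spike reset potential, drawn uniformly from [-42, -35] mV
(higher reset = more bursting because the reset lands close to the spiking
threshold while the recovery variable builds up).  I-cells follow the
Wang-Buzsaki interneuron model.  Synapses are conductance-based with
rise/decay gates driven by the presynaptic potential through
``H(V) = (1 + tanh(V/4)) / 2``; wiring is E-to-I, I-to-E, and I-to-I with
out-degree one per rule, and no E-to-E connections.

Integration is explicit second-order Runge-Kutta (endpoint) at
``dt = 0.025`` ms.  Membrane noise follows the same convention as the
two-cell LIF model (per-step voltage increments whose stationary SD on the
passive membrane equals ``sigma``), scaled by a per-class ``noise_gain``
calibrated once so that spontaneous rates fall in the range observed in
CA1 (E-cells: units to a few spk/s; I-cells: tens of spk/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba as nb
import numpy as np

from .trains import SpikeTrain

__all__ = ["NetworkConfig", "build_network", "simulate_network", "E_PARAMS", "I_PARAMS", "SYN_PARAMS"]

# E-cell (quadratic model) parameters
E_PARAMS = dict(
    c=1.0, v_k=0.01, e_l=-60.0, v_t=-45.0, g_n=1.0,
    u_a=0.02, u_b=0.01, v_peak=40.0, sigma=2.0, i_in=0.0,
    v_reset_range=(-42.0, -35.0), u_step_range=(1.12, 1.225),
)
# I-cell (Wang-Buzsaki) parameters
I_PARAMS = dict(
    c=1.0, g_l=0.1, e_l=-65.0, g_na=35.0, e_na=55.0, g_k=9.0, e_k=-90.0,
    g_n=1.0, sigma=2.0, i_in=-0.75,
)
# synapse parameters (AMPA / GABA_A)
SYN_PARAMS = dict(
    tau_r_e=0.1, tau_d_e=3.0, e_rev_e=0.0,
    tau_r_i=0.3, tau_d_i=9.0, e_rev_i=-80.0,
    g_ie=0.055, g_ee=0.0, g_ei=0.25, g_ii=0.25,
    g_ie_lognormal=(0.055, 0.02), g_ei_lognormal=(0.22, 0.08),
    g_ii_lognormal=(0.22, 0.04),
)

# noise gains calibrated once against the target spontaneous-rate phenotype
# (E-cells: CA1-pyramidal-like units to a few spk/s with BF-graded bursting;
# I-cells: interneuron-like tonic 10-30 spk/s without spontaneous bursts)
NOISE_GAIN_E = 2.4
NOISE_GAIN_I = 2.6


@dataclass(frozen=True)
class NetworkConfig:
    """Complete generative specification of one network simulation."""

    n_e: int
    n_i: int
    adjacency: np.ndarray          # conductance matrix, [post, pre], mS/cm^2
    v_reset: np.ndarray            # per-E-cell burst factor (mV)
    u_step: np.ndarray             # per-E-cell recovery increment
    dt: float = 0.025              # ms
    duration: float = 1200.0       # s
    seed: int = 0
    noise_gain_e: float = NOISE_GAIN_E
    noise_gain_i: float = NOISE_GAIN_I

    @property
    def n_cells(self) -> int:
        return self.n_e + self.n_i

    @property
    def cell_class(self) -> np.ndarray:
        return np.array(["E"] * self.n_e + ["I"] * self.n_i)

    def edges(self):
        """(pre, post, sign, conductance) tuples of the ground-truth wiring."""
        out = []
        post_idx, pre_idx = np.nonzero(self.adjacency)
        for post, pre in zip(post_idx, pre_idx):
            sign = "excitatory" if pre < self.n_e else "inhibitory"
            out.append((int(pre), int(post), sign, float(self.adjacency[post, pre])))
        return out


def _lognormal(rng, mean, sd, size):
    s2 = np.log1p((sd / mean) ** 2)
    return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size=size)


def build_network(
    n_e: int = 80,
    n_i: int = 20,
    seed: int = 0,
    lognormal: bool = False,
    duration: float = 1200.0,
    **overrides,
) -> NetworkConfig:
    """Wire a network under the fixed out-degree rule.

    Every E-cell connects to one random I-cell (conductance ``g_ie``), and
    every I-cell connects to one random E-cell (``g_ei``) and one random
    *other* I-cell (``g_ii``); no E-to-E connections and no self-loops.
    With ``lognormal=True`` the conductances are drawn per edge from the
    log-normal distributions in :data:`SYN_PARAMS`.  Per-E-cell burst
    factors are uniform on the reset-potential range, with the recovery
    increment mapped linearly onto the same dial.
    """
    if n_i < 2:
        raise ValueError("need at least 2 I-cells for I-to-I wiring")
    syn = dict(SYN_PARAMS)
    syn.update({k: v for k, v in overrides.items() if k in syn})
    rng = np.random.default_rng(seed)
    n = n_e + n_i
    adj = np.zeros((n, n))
    if lognormal:
        g_ie = _lognormal(rng, *syn["g_ie_lognormal"], n_e)
        g_ei = _lognormal(rng, *syn["g_ei_lognormal"], n_i)
        g_ii = _lognormal(rng, *syn["g_ii_lognormal"], n_i)
    else:
        g_ie = np.full(n_e, syn["g_ie"])
        g_ei = np.full(n_i, syn["g_ei"])
        g_ii = np.full(n_i, syn["g_ii"])
    for e in range(n_e):
        target = n_e + rng.integers(n_i)
        adj[target, e] = g_ie[e]
    for i in range(n_i):
        pre = n_e + i
        adj[rng.integers(n_e), pre] = g_ei[i]
        other = n_e + rng.integers(n_i - 1)
        if other >= pre:
            other += 1
        adj[other, pre] = g_ii[i]
    lo, hi = E_PARAMS["v_reset_range"]
    v_reset = rng.uniform(lo, hi, size=n_e)
    us_lo, us_hi = E_PARAMS["u_step_range"]
    u_step = us_lo + (v_reset - lo) / (hi - lo) * (us_hi - us_lo)
    return NetworkConfig(
        n_e=n_e, n_i=n_i, adjacency=adj, v_reset=v_reset, u_step=u_step,
        duration=duration, seed=seed,
    )


@nb.njit(cache=True, fastmath=True)
def _wb_dvdt(v, h, nk, i_syn, i_in, g_l, e_l, g_na, e_na, g_k, e_k):
    am = 0.2 * (v + 35.0) / (1.0 - np.exp(-(v + 35.0) / 10.0))
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    m_inf = am / (am + bm)
    return (
        i_in
        - g_l * (v - e_l)
        - g_na * h * m_inf**3 * (v - e_na)
        - g_k * nk**4 * (v - e_k)
        - i_syn
    )


@nb.njit(cache=True, fastmath=True)
def _wb_gates(v):
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    an = 0.01 * (v + 34.0) / (1.0 - np.exp(-(v + 34.0) / 10.0))
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    h_inf = ah / (ah + bh)
    tau_h = 0.2 / (ah + bh)
    n_inf = an / (an + bn)
    tau_n = 0.2 / (an + bn)
    return h_inf, tau_h, n_inf, tau_n


@nb.njit(cache=True, fastmath=True)
def _network_core(
    n_steps, dt, n_e, n_i, adj, v_reset_arr, u_step_arr,
    e_c, e_vk, e_el, e_vt, e_ua, e_ub, e_vpeak, e_iin, e_noise_sd,
    i_c, i_gl, i_el, i_gna, i_ena, i_gk, i_ek, i_iin, i_noise_sd,
    tau_r_e, tau_d_e, erev_e, tau_r_i, tau_d_i, erev_i,
    seed,
):
    np.random.seed(seed)
    n = n_e + n_i
    v = np.empty(n)
    u = np.zeros(n_e)
    hh = np.empty(n_i)
    nn = np.empty(n_i)
    for e in range(n_e):
        v[e] = e_el
    for i in range(n_i):
        vi = i_el + i_iin / i_gl
        v[n_e + i] = vi
        h_inf, _, n_inf, _ = _wb_gates(vi)
        hh[i] = h_inf
        nn[i] = n_inf
    s = np.zeros(n)  # one synaptic gate per presynaptic cell
    # adjacency in sparse row form
    max_spikes = int(n_steps * dt * 0.2 * n) + 1000  # generous cap (200 spk/s/cell)
    spike_cell = np.empty(max_spikes, dtype=np.int32)
    spike_step = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    i_refract = np.zeros(n_i, dtype=np.int64)
    refract_steps = int(2.0 / dt)
    for t in range(n_steps):
        # synaptic gates (RK2, gate input frozen at V_pre(t))
        s_new = np.empty(n)
        for c in range(n):
            gate = 0.5 * (1.0 + np.tanh(v[c] / 4.0))
            if c < n_e:
                tr, td = tau_r_e, tau_d_e
            else:
                tr, td = tau_r_i, tau_d_i
            k1 = gate * (1.0 - s[c]) / tr - s[c] / td
            s_mid = s[c] + dt * k1
            k2 = gate * (1.0 - s_mid) / tr - s_mid / td
            s_new[c] = s[c] + 0.5 * dt * (k1 + k2)
        # membrane dynamics
        for c in range(n):
            i_syn1 = 0.0
            i_syn2 = 0.0
            for pre in range(n):
                g = adj[c, pre]
                if g != 0.0:
                    erev = erev_e if pre < n_e else erev_i
                    i_syn1 += g * s[pre] * (v[c] - erev)
                    i_syn2 += g * s_new[pre] * (v[c] - erev)
            if c < n_e:
                k1v = (
                    e_iin + e_vk * (v[c] - e_el) * (v[c] - e_vt) - u[c] - i_syn1
                ) / e_c
                k1u = e_ua * (e_ub * (v[c] - e_el) - u[c])
                vm = v[c] + dt * k1v
                um = u[c] + dt * k1u
                k2v = (e_iin + e_vk * (vm - e_el) * (vm - e_vt) - um - i_syn2) / e_c
                k2u = e_ua * (e_ub * (vm - e_el) - um)
                v[c] += 0.5 * dt * (k1v + k2v) + e_noise_sd * np.random.normal()
                u[c] += 0.5 * dt * (k1u + k2u)
                if v[c] > e_vpeak:
                    if n_spikes < max_spikes:
                        spike_cell[n_spikes] = c
                        spike_step[n_spikes] = t
                        n_spikes += 1
                    v[c] = v_reset_arr[c]
                    u[c] += u_step_arr[c]
                elif v[c] > 200.0 or v[c] < -200.0:
                    return spike_cell[:n_spikes], spike_step[:n_spikes], -1
            else:
                i = c - n_e
                k1v = _wb_dvdt(
                    v[c], hh[i], nn[i], i_syn1, i_iin, i_gl, i_el, i_gna,
                    i_ena, i_gk, i_ek,
                ) / i_c
                h_inf, tau_h, n_inf, tau_n = _wb_gates(v[c])
                k1h = (h_inf - hh[i]) / tau_h
                k1n = (n_inf - nn[i]) / tau_n
                vm = v[c] + dt * k1v
                hm = hh[i] + dt * k1h
                nm = nn[i] + dt * k1n
                k2v = _wb_dvdt(
                    vm, hm, nm, i_syn2, i_iin, i_gl, i_el, i_gna, i_ena,
                    i_gk, i_ek,
                ) / i_c
                h_inf2, tau_h2, n_inf2, tau_n2 = _wb_gates(vm)
                k2h = (h_inf2 - hm) / tau_h2
                k2n = (n_inf2 - nm) / tau_n2
                v_old = v[c]
                v[c] += 0.5 * dt * (k1v + k2v) + i_noise_sd * np.random.normal()
                hh[i] += 0.5 * dt * (k1h + k2h)
                nn[i] += 0.5 * dt * (k1n + k2n)
                if v_old < 0.0 <= v[c] and t >= i_refract[i]:
                    if n_spikes < max_spikes:
                        spike_cell[n_spikes] = c
                        spike_step[n_spikes] = t
                        n_spikes += 1
                    i_refract[i] = t + refract_steps
                if v[c] > 200.0 or v[c] < -200.0:
                    return spike_cell[:n_spikes], spike_step[:n_spikes], -1
        s = s_new
    return spike_cell[:n_spikes], spike_step[:n_spikes], 0


def simulate_network(cfg: NetworkConfig):
    """Simulate the network; returns one :class:`SpikeTrain` per cell.

    E-cell spikes are peak crossings (reset rule applied); I-cell spikes
    are upward zero crossings with a 2-ms double-count guard.  Aborts with
    a RuntimeError on numerical blow-up (|V| > 200 mV).
    """
    n_steps = int(round(cfg.duration * 1e3 / cfg.dt))
    tau_e = E_PARAMS["c"] / (E_PARAMS["v_k"] * (E_PARAMS["v_t"] - E_PARAMS["e_l"]))
    tau_i = I_PARAMS["c"] / I_PARAMS["g_l"]
    e_noise_sd = (
        cfg.noise_gain_e * E_PARAMS["sigma"] * np.sqrt(2.0 * cfg.dt / tau_e)
    )
    i_noise_sd = (
        cfg.noise_gain_i * I_PARAMS["sigma"] * np.sqrt(2.0 * cfg.dt / tau_i)
    )
    cells, steps, status = _network_core(
        n_steps, cfg.dt, cfg.n_e, cfg.n_i, cfg.adjacency,
        cfg.v_reset, cfg.u_step,
        E_PARAMS["c"], E_PARAMS["v_k"], E_PARAMS["e_l"], E_PARAMS["v_t"],
        E_PARAMS["u_a"], E_PARAMS["u_b"], E_PARAMS["v_peak"],
        E_PARAMS["i_in"], e_noise_sd,
        I_PARAMS["c"], I_PARAMS["g_l"], I_PARAMS["e_l"], I_PARAMS["g_na"],
        I_PARAMS["e_na"], I_PARAMS["g_k"], I_PARAMS["e_k"],
        I_PARAMS["i_in"], i_noise_sd,
        SYN_PARAMS["tau_r_e"], SYN_PARAMS["tau_d_e"], SYN_PARAMS["e_rev_e"],
        SYN_PARAMS["tau_r_i"], SYN_PARAMS["tau_d_i"], SYN_PARAMS["e_rev_i"],
        cfg.seed % (2**31),
    )
    if status < 0:
        raise RuntimeError("numerical blow-up (|V| > 200 mV); check parameters")
    trains = []
    for c in range(cfg.n_cells):
        t = steps[cells == c] * cfg.dt * 1e-3
        label = f"E{c}" if c < cfg.n_e else f"I{c - cfg.n_e}"
        trains.append(SpikeTrain(np.asarray(t, float), duration=cfg.duration, label=label))
    return trains
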