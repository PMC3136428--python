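"""Synaptic conductance kernels and the NMDA Mg2+ block.

Pure functions shared by the network engine, the single-cell API and the
tests.  The dual-exponential kernel is also available as the incremental
two-state update the engine integrates (each presynaptic spike adds 1 to a
rise and a decay state; the conductance is their normalized difference),
which matches the closed form to floating-point accuracy at the default
20 us step.
"""

from __future__ import annotations

import numpy as np

from .params import MgBlockParams, SynapseSpec

__all__ = ["dual_exp_conductance", "nmda_mg_block", "DualExpState"]


def dual_exp_conductance(t_since_spike, spec: SynapseSpec):
    """Closed-form conductance ``t_since_spike`` ms after one presynaptic spike.

    ``g(t) = g_peak * norm * (exp(-t/tau_decay) - exp(-t/tau_rise))`` with
    the normalization chosen so the maximum over t equals ``g_peak``.
    Accepts scalars or arrays; negative times raise.
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be >= 0")
    g = spec.peak_conductance * spec.norm * (
        np.exp(-t / spec.tau_decay) - np.exp(-t / spec.tau_rise))
    return float(g) if np.isscalar(t_since_spike) else g


def nmda_mg_block(v_mV, p: MgBlockParams):
    """Open fraction of the NMDA channel at membrane potential ``v_mV``.

    ``1 / (1 + ([Mg]/k0) * exp(-v/vs))``: strictly increasing in v,
    strictly decreasing in [Mg]; identically 1 at [Mg] = 0.
    """
    v = np.asarray(v_mV, dtype=float)
    frac = 1.0 / (1.0 + (p.mg_mM / p.k0_mM) * np.exp(-v / p.vs_mV))
    return float(frac) if np.isscalar(v_mV) else frac


class DualExpState:
    """Incremental two-state evaluation of the dual-exponential kernel.

    State variables r (rise) and d (decay) each jump by 1 per presynaptic
    spike and decay exponentially; ``g = g_peak * norm * (d - r)``.  This is
    exactly what the network kernel integrates, exposed here for testing
    and for metrics-only workflows.
    """

    def __init__(self, spec: SynapseSpec, dt_ms: float):
        self.spec = spec
        self.dt_ms = dt_ms
        self._fr = np.exp(-dt_ms / spec.tau_rise)
        self._fd = np.exp(-dt_ms / spec.tau_decay)
        self.r = 0.0
        self.d = 0.0

    def step(self, n_spikes: int = 0) -> float:
        """Advance one step; spikes arrive at the *start* of the step."""
        self.r = self.r * self._fr + n_spikes
        self.d = self.d * self._fd + n_spikes
        return self.conductance

    @property
    def conductance(self) -> float:
        return self.spec.peak_conductance * self.spec.norm * (self.d - self.r)
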