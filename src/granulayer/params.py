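"""Biophysical parameters of the model neurons and synapses.

Units at every module boundary: mV, ms, pA, pF, nS, mM.  The channel
kinetics are a surrogate set — Traub–Miles-style transient Na and
delayed-rectifier K gates plus a spike-triggered afterhyperpolarization
(AHP) conductance — calibrated against the model's behavioural anchors
(a disinhibited granule cell fires 44 spikes/s under a constant 10.7 pA,
and the default network oscillates at 9 Hz under the small current).  The
values below are the calibrated defaults; ``load_params`` /
``dump_params`` round-trip them through YAML so any constant can be
overridden from a config file.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SynapseSpec",
    "MgBlockParams",
    "SomaParams",
    "GrcParams",
    "GocParams",
    "ModelParams",
    "default_params",
    "load_params",
    "dump_params",
]


@dataclass(frozen=True)
class SynapseSpec:
    """Dual-exponential synaptic conductance.

    The kernel is ``g_peak * norm * (exp(-t/tau_decay) - exp(-t/tau_rise))``
    with ``norm`` fixed so the peak equals ``peak_conductance`` (per
    connection, nS).  Only NMDA carries the voltage-dependent Mg2+ block.
    """

    kind: str  # "AMPA" | "NMDA" | "GABA_A"
    tau_rise: float  # ms
    tau_decay: float  # ms
    peak_conductance: float  # nS per connection
    reversal: float  # mV
    target_compartment: str = "soma"

    def __post_init__(self) -> None:
        if self.tau_rise >= self.tau_decay:
            raise ValueError(
                f"{self.kind}: tau_rise ({self.tau_rise} ms) must be smaller "
                f"than tau_decay ({self.tau_decay} ms)")
        if self.peak_conductance < 0:
            raise ValueError("peak_conductance must be >= 0")

    @property
    def mg_gated(self) -> bool:
        return self.kind == "NMDA"

    @property
    def peak_time(self) -> float:
        """Analytic time-to-peak of the kernel, ms."""
        tr, td = self.tau_rise, self.tau_decay
        return np.log(td / tr) * td * tr / (td - tr)

    @property
    def norm(self) -> float:
        """Normalization making the kernel maximum equal 1."""
        tp = self.peak_time
        return 1.0 / (np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise))


@dataclass(frozen=True)
class MgBlockParams:
    """Voltage-dependent Mg2+ block of the NMDA channel.

    Open fraction ``1 / (1 + ([Mg]/k0) * exp(-V/vs))`` — a Jahr–Stevens-type
    sigmoid: relieved by depolarization, deepened by Mg2+.
    """

    mg_mM: float = 1.2
    k0_mM: float = 3.57
    vs_mV: float = 9.0

    def __post_init__(self) -> None:
        if self.mg_mM < 0:
            raise ValueError("Mg2+ concentration must be >= 0")
        if self.k0_mM <= 0 or self.vs_mV <= 0:
            raise ValueError("k0 and vs must be positive")


@dataclass(frozen=True)
class SomaParams:
    """Active compartment: leak + transient Na + delayed-rectifier K + AHP.

    The AHP is a K-reversal conductance incremented by ``ahp_increment_nS``
    at every somatic spike and decaying with ``ahp_tau_ms``; it enforces
    post-spike refractoriness and keeps tonic rates low.
    """

    capacitance_pF: float
    g_leak_nS: float
    e_leak_mV: float
    g_na_nS: float
    e_na_mV: float
    g_kdr_nS: float
    e_k_mV: float
    ahp_increment_nS: float = 0.0
    ahp_tau_ms: float = 30.0
    #: rigid shift of the Na/K gate kinetics along the voltage axis; a
    #: positive shift raises the spike threshold (different channel isoforms
    #: between cell types)
    v_shift_mV: float = 0.0

    def __post_init__(self) -> None:
        for name in ("capacitance_pF", "g_leak_nS", "g_na_nS", "g_kdr_nS",
                     "ahp_increment_nS", "ahp_tau_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def membrane_tau_ms(self) -> float:
        return self.capacitance_pF / self.g_leak_nS


@dataclass(frozen=True)
class GrcParams:
    """Granule-cell cluster unit: a single active compartment.

    One model grc stands for a ~1,000-cell cluster sharing a glomerulus;
    mossy-fiber drive enters as a somatic current, Golgi inhibition as a
    GABA_A conductance (5 ms rise / 100 ms decay).
    """

    soma: SomaParams
    gaba: SynapseSpec


@dataclass(frozen=True)
class GocParams:
    """Two-compartment Golgi cell: spiking soma + passive dendrite.

    The 300 um dendrite carries the parallel-fiber AMPA (0.03/0.5 ms) and
    NMDA (5/100 ms, Mg2+-gated) channels and couples to the soma through an
    axial conductance chosen to leave it somewhat electrically isolated
    (somatic AHP attenuates dendritic depolarization by < 50%).  The leak
    reversal is drawn uniformly per cell from ``e_leak_range_mV`` to mimic
    the morphological and electrical heterogeneity of Golgi cells.
    """

    soma: SomaParams
    dend_capacitance_pF: float = 6.0
    dend_g_leak_nS: float = 1.0
    axial_g_nS: float = 4.0
    dendrite_length_um: float = 300.0
    e_leak_range_mV: tuple[float, float] = (-60.0, -50.0)
    ampa: SynapseSpec = field(default_factory=lambda: SynapseSpec(
        "AMPA", 0.03, 0.5, 1.0, 0.0, "dendrite"))
    nmda: SynapseSpec = field(default_factory=lambda: SynapseSpec(
        "NMDA", 5.0, 100.0, 0.2, 0.0, "dendrite"))

    def __post_init__(self) -> None:
        lo, hi = self.e_leak_range_mV
        if lo > hi:
            raise ValueError("e_leak_range_mV must be (low, high)")
        if self.dendrite_length_um <= 0:
            raise ValueError("dendrite length must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the granular-layer network."""

    grc: GrcParams
    goc: GocParams
    mg_block: MgBlockParams = field(default_factory=MgBlockParams)
    #: partial in-degree normalization of each target's total synaptic
    #: conductance (cluster-aggregation view of the synapses): per-connection
    #: conductance is scaled by (mean_in_degree / in_degree)**alpha.  0 = raw
    #: unweighted edges, 1 = every target receives the same total.
    normalize_inhibition: float = 0.0
    normalize_excitation: float = 0.0

    def with_mg(self, mg_mM: float) -> "ModelParams":
        return replace(self, mg_block=replace(self.mg_block, mg_mM=mg_mM))


def default_params() -> ModelParams:
    """Calibrated default parameter set (see the methods note).

    Anchors: disinhibited grc at 10.7 pA -> 44 spikes/s; network at the
    small current -> 9 Hz synchronized oscillation; large current at
    [Mg2+] = 1.2 mM -> POT-representing burst-silent alternation.
    """
    grc_soma = SomaParams(
        capacitance_pF=3.1,
        g_leak_nS=1.1,
        e_leak_mV=-70.0,
        g_na_nS=300.0,
        e_na_mV=50.0,
        g_kdr_nS=100.0,
        e_k_mV=-90.0,
        ahp_increment_nS=0.65,
        ahp_tau_ms=8.0,
    )
    grc = GrcParams(
        soma=grc_soma,
        gaba=SynapseSpec("GABA_A", 5.0, 100.0, 0.075, -75.0, "soma"),
    )
    goc_soma = SomaParams(
        capacitance_pF=30.0,
        g_leak_nS=3.0,
        e_leak_mV=-55.0,  # per-cell draw overrides, uniform in [-60, -50]
        g_na_nS=2000.0,
        e_na_mV=50.0,
        g_kdr_nS=700.0,
        e_k_mV=-90.0,
        ahp_increment_nS=40.0,
        ahp_tau_ms=16.0,
        v_shift_mV=18.0,
    )
    goc = GocParams(
        soma=goc_soma,
        dend_capacitance_pF=20.0,
        dend_g_leak_nS=8.0,
        axial_g_nS=8.0,
        ampa=SynapseSpec("AMPA", 0.03, 0.5, 15.0, 0.0, "dendrite"),
        nmda=SynapseSpec("NMDA", 5.0, 100.0, 4.0, 0.0, "dendrite"),
    )
    return ModelParams(grc=grc, goc=goc, mg_block=MgBlockParams(),
                       normalize_inhibition=1.0, normalize_excitation=1.0)


# ---------------------------------------------------------------------------
# YAML round trip

def dump_params(params: ModelParams, path: str | Path | None = None) -> str:
    doc = asdict(params)
    doc["goc"]["e_leak_range_mV"] = list(doc["goc"]["e_leak_range_mV"])
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def _synapse(d: dict) -> SynapseSpec:
    return SynapseSpec(d["kind"], d["tau_rise"], d["tau_decay"],
                       d["peak_conductance"], d["reversal"],
                       d.get("target_compartment", "soma"))


def load_params(source: str | Path | io.TextIOBase) -> ModelParams:
    """Load a full parameter set from YAML text, a path, or a stream."""
    if isinstance(source, io.TextIOBase):
        doc = yaml.safe_load(source)
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = yaml.safe_load(text)
    grc = GrcParams(soma=SomaParams(**doc["grc"]["soma"]),
                    gaba=_synapse(doc["grc"]["gaba"]))
    goc_doc = dict(doc["goc"])
    goc = GocParams(
        soma=SomaParams(**goc_doc["soma"]),
        dend_capacitance_pF=goc_doc["dend_capacitance_pF"],
        dend_g_leak_nS=goc_doc["dend_g_leak_nS"],
        axial_g_nS=goc_doc["axial_g_nS"],
        dendrite_length_um=goc_doc.get("dendrite_length_um", 300.0),
        e_leak_range_mV=tuple(goc_doc.get("e_leak_range_mV", (-60.0, -50.0))),
        ampa=_synapse(goc_doc["ampa"]),
        nmda=_synapse(goc_doc["nmda"]),
    )
    mg = MgBlockParams(**doc.get("mg_block", {}))
    return ModelParams(grc=grc, goc=goc, mg_block=mg,
                       normalize_inhibition=doc.get("normalize_inhibition",
                                                    0.0),
                       normalize_excitation=doc.get("normalize_excitation",
                                                    0.0))
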