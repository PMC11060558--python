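"""Statistical scaffold construction of the two-micromodule olivocerebellar network.

The network spans three regions — cerebellar cortex (granule, Golgi,
Purkinje, stellate and basket cells, plus mossy-fibre and glomerulus relay
elements), the deep cerebellar nuclei (glutamatergic projection neurons
DCN_p and GABAergic nucleo-olivary neurons DCN_GABA) and the inferior olive
(IO) — wired by 24 chemical connection types (15 cortical + 9 involving DCN
and IO).  Purkinje, DCN and IO cells belong to one of two micromodules
split along a 1-D parasagittal coordinate: a *downbound* module (70% of
cells, zebrin-negative PCs with high baseline rate, the one receiving the
US teaching signal) and an *upbound* module (30%, zebrin-positive PCs).
Granular-layer elements and molecular-layer interneurons (MLIs) are shared;
each MLI is labelled downbound- or upbound-preferring according to which
module contains the majority of the Purkinje cells it inhibits.

Construction is statistical: neurons receive a uniform parasagittal
coordinate and connectivity is sampled to honour per-type mean in-degrees
(convergence), micromodule confinement, and a linear parasagittal gradient
of climbing-fibre (IO spillover) innervation of MLIs.  Morphology-
intersection placement is intentionally abstracted away — counts, degrees
and module labels, not 3-D geometry, drive the dynamics modelled here.

Population counts at scale 1 reproduce the reference cortical volume:
29,230 cortical neurons plus 2,453 mossy fibres and glomeruli.  DCN and IO
counts are fallback defaults (the source supplementary tables are not
redistributed here) chosen to preserve plausible PC->DCN convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "ConnectionSpec",
    "Network",
    "POP_SIZES_SCALE1",
    "MODULAR_POPULATIONS",
    "CORTICAL_POPULATIONS",
    "build_network",
    "generate_connectivity",
    "assign_mli_preference",
    "default_connection_specs",
    "cortical_type_names",
    "extracortical_type_names",
]

# Fallback population counts at scale 1.  Cortical counts sum to the printed
# 29,230 neurons; mf + glom sum to the printed 2,453 other elements.  DCN and
# IO counts are fallback defaults (see module docstring).
POP_SIZES_SCALE1: dict[str, int] = {
    "GrC": 28615,
    "GoC": 70,
    "PC": 99,
    "SC": 299,
    "BC": 147,
    "DCN_p": 80,
    "DCN_GABA": 40,
    "IO": 40,
    "mf": 117,
    "glom": 2336,
}

CORTICAL_POPULATIONS = ("GrC", "GoC", "PC", "SC", "BC")
# Populations carrying a micromodule (downbound/upbound) label.
MODULAR_POPULATIONS = ("PC", "DCN_p", "DCN_GABA", "IO")
MLI_POPULATIONS = ("SC", "BC")


@dataclass(frozen=True)
class NetworkConfig:
    """Configuration of the scaffold build."""

    scale_factor: float = 1.0
    population_sizes: dict[str, int] = field(
        default_factory=lambda: dict(POP_SIZES_SCALE1))
    downbound_fraction: float = 0.70
    mf_cs_target_count: int = 45
    mf_total: int = 117
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.scale_factor <= 1.0):
            raise ValueError("scale_factor must be in (0, 1]")
        if not (0.0 < self.downbound_fraction < 1.0):
            raise ValueError("downbound_fraction must be in (0, 1)")
        missing = set(POP_SIZES_SCALE1) - set(self.population_sizes)
        if missing:
            raise ValueError(f"population_sizes missing {sorted(missing)}")

    def scaled_counts(self) -> dict[str, int]:
        """Population counts at the configured scale (rounded)."""
        out = {}
        for pop, n in self.population_sizes.items():
            m = int(round(self.scale_factor * n))
            if m < 1:
                raise ValueError(
                    f"scale_factor {self.scale_factor} yields zero-size "
                    f"population {pop!r}")
            out[pop] = m
        return out

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "scale_factor": self.scale_factor,
            "population_sizes": dict(self.population_sizes),
            "downbound_fraction": self.downbound_fraction,
            "mf_cs_target_count": self.mf_cs_target_count,
            "mf_total": self.mf_total,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass(frozen=True)
class ConnectionSpec:
    """One of the 24 chemical connection types.

    ``synapse_weight`` is a peak conductance in nS whose sign encodes the
    receptor class (negative = inhibitory, reversal below rest).  ``delay``
    in ms (>= 1, the simulation resolution), ``receptor_time_constant`` the
    alpha-synapse rise/decay constant in ms.  ``micromodule_confined`` types
    never connect across micromodules; ``sagittal_gradient`` types (IO
    spillover onto MLIs) pick the presynaptic module with a probability that
    ramps linearly along the parasagittal coordinate, favouring downbound
    climbing fibres near the downbound microzone.
    """

    name: str
    pre_population: str
    post_population: str
    convergence: int
    synapse_weight: float
    delay: float
    receptor_time_constant: float
    n_contacts_per_pair: int = 1
    plastic: bool = False
    micromodule_confined: bool = False
    sagittal_gradient: bool = False
    #: half-width of the parasagittal sampling window; None = global.
    #: Local types model spatially confined axons/dendrites (glomerular
    #: dendrites, ascending axons, Golgi and MLI axons); parallel-fibre
    #: types are global (pfs run mediolaterally across the whole slab).
    local_radius: float | None = None
    #: differentiated weight for synapses onto upbound-module targets
    #: (the table reports "downbound; upbound" where they differ) — here
    #: used to balance the deep-nuclei drive between the large downbound
    #: and small upbound module; None = same weight in both modules.
    synapse_weight_upbound: float | None = None

    def __post_init__(self) -> None:
        if self.delay < 1.0:
            raise ValueError(f"{self.name}: delay must be >= 1 ms")
        if self.receptor_time_constant <= 0:
            raise ValueError(f"{self.name}: receptor_time_constant must be > 0")
        if self.convergence < 1:
            raise ValueError(f"{self.name}: convergence must be >= 1")
        inhibitory_sources = {"GoC", "SC", "BC", "PC", "DCN_GABA"}
        if self.pre_population in inhibitory_sources and self.synapse_weight > 0:
            raise ValueError(
                f"{self.name}: inhibitory source {self.pre_population} must "
                f"have negative-effect weight")

    def with_weight(self, w: float) -> "ConnectionSpec":
        return replace(self, synapse_weight=w)


# The 15 cortical connection types (granular + molecular layer) and the 9
# types brought in by the DCN/IO extension.  Weights are fallback defaults
# calibrated against the population baseline-rate targets (see
# scripts/calibrate_network.py); GrC axon segments are distinguished as
# ascending axon ("aa") and parallel fibre ("pf") types.
_CORTICAL_SPECS = [
    #            name          pre     post   conv   w      d    tau  contacts plastic confined gradient radius
    ("mf_glom",      "mf",   "glom",    1,  1.0,   1.0,  1.0, 1, False, False, False, None),
    ("glom_GrC",     "glom", "GrC",     4,  0.2,   1.0,  2.0, 1, False, False, False, 0.05),
    ("glom_GoC",     "glom", "GoC",    50,  0.1,   1.0,  2.0, 1, False, False, False, 0.10),
    ("GoC_GrC",      "GoC",  "GrC",     2, -0.6,   2.0, 10.0, 1, False, False, False, 0.10),
    ("GoC_GoC",      "GoC",  "GoC",     4, -0.3,   1.0,  5.0, 1, False, False, False, None),
    ("GrC_aa_GoC",   "GrC",  "GoC",   100,  0.1,   2.0,  2.0, 1, False, False, False, 0.05),
    ("GrC_pf_GoC",   "GrC",  "GoC",   400,  0.05,  5.0,  5.0, 1, False, False, False, None),
    ("GrC_aa_PC",    "GrC",  "PC",     50,  0.08,  2.0,  2.0, 1, False, False, False, 0.05),
    ("GrC_pf_PC",    "GrC",  "PC",   1000,  0.16,  5.0,  5.0, 1, True,  False, False, None),
    ("GrC_pf_SC",    "GrC",  "SC",    300,  0.03,  5.0,  5.0, 1, True,  False, False, None),
    ("GrC_pf_BC",    "GrC",  "BC",    300,  0.03,  5.0,  5.0, 1, True,  False, False, None),
    ("SC_PC",        "SC",   "PC",     10, -0.25,  1.0, 10.0, 1, False, False, False, 0.15),
    ("BC_PC",        "BC",   "PC",     10, -0.25,  1.0, 10.0, 1, False, False, False, 0.15),
    ("SC_SC",        "SC",   "SC",      4, -0.2,   1.0,  5.0, 1, False, False, False, 0.15),
    ("BC_BC",        "BC",   "BC",      4, -0.2,   1.0,  5.0, 1, False, False, False, 0.15),
]

_EXTRACORTICAL_SPECS = [
    ("mf_DCN_p",     "mf",       "DCN_p",    20,  0.15,  4.0,  5.0, 2, False, False, False, None),
    ("IO_DCN_p",     "IO",       "DCN_p",     1,  4.0,   4.0,  5.0, 1, False, True,  False, None),
    ("PC_DCN_p",     "PC",       "DCN_p",    25, -0.8,   4.0, 10.0, 1, False, True,  False, None, -4.1),
    ("PC_DCN_GABA",  "PC",       "DCN_GABA", 25, -0.6,   4.0, 10.0, 1, False, True,  False, None, -3.1),
    ("IO_DCN_GABA",  "IO",       "DCN_GABA",  1,  0.8,   4.0,  5.0, 1, False, True,  False, None),
    ("IO_PC",        "IO",       "PC",        1, 80.0,   4.0,  1.5, 1, False, True,  False, None),
    ("IO_SC",        "IO",       "SC",        2,  1.0,   4.0,  1.5, 1, False, False, True,  None),
    ("IO_BC",        "IO",       "BC",        2,  1.0,   4.0,  1.5, 1, False, False, True,  None),
    ("DCN_GABA_IO",  "DCN_GABA", "IO",        4, -0.3,  20.0, 30.0, 1, False, True,  False, None),
]


def _mk_specs(rows) -> list[ConnectionSpec]:
    return [
        ConnectionSpec(
            name=r[0], pre_population=r[1], post_population=r[2],
            convergence=r[3], synapse_weight=r[4], delay=r[5],
            receptor_time_constant=r[6], n_contacts_per_pair=r[7],
            plastic=r[8], micromodule_confined=r[9], sagittal_gradient=r[10],
            local_radius=r[11],
            synapse_weight_upbound=r[12] if len(r) > 12 else None,
        )
        for r in rows
    ]


def cortical_type_names() -> list[str]:
    return [r[0] for r in _CORTICAL_SPECS]


def extracortical_type_names() -> list[str]:
    return [r[0] for r in _EXTRACORTICAL_SPECS]


def default_connection_specs(
    overrides: dict[str, float] | None = None,
) -> list[ConnectionSpec]:
    """The shipped 24-type connectivity table.

    ``overrides`` maps type name -> synapse weight, used by weight
    calibration to ship tuned values without editing the table.
    """
    specs = _mk_specs(_CORTICAL_SPECS) + _mk_specs(_EXTRACORTICAL_SPECS)
    if overrides:
        unknown = set(overrides) - {s.name for s in specs}
        if unknown:
            raise ValueError(f"unknown connection types: {sorted(unknown)}")
        specs = [
            s.with_weight(overrides[s.name]) if s.name in overrides else s
            for s in specs
        ]
    return specs


def save_connection_specs(specs: list[ConnectionSpec],
                          path: str | Path) -> None:
    """Write a connectivity table as a human-readable YAML file (the
    versioned default ships with the package as data/connection_specs.yaml)."""
    from dataclasses import asdict
    Path(path).write_text(yaml.safe_dump(
        {"version": 1, "connection_types": [asdict(s) for s in specs]},
        sort_keys=False))


def load_connection_specs(path: str | Path) -> list[ConnectionSpec]:
    """Read a connectivity table written by :func:`save_connection_specs`."""
    d = yaml.safe_load(Path(path).read_text())
    return [ConnectionSpec(**row) for row in d["connection_types"]]


@dataclass
class Network:
    """Built network: neuron table, synapse table, GoC gap-junction pairs.

    ``neurons`` columns: ``id`` (global, contiguous), ``population``,
    ``micromodule`` (downbound/upbound/shared), ``x`` (parasagittal
    coordinate in [0, 1), downbound side at low x), ``mli_pref``
    (downbound/upbound preference of each MLI, empty elsewhere) and
    ``cs_target`` (mossy fibres inside the central CS-receiving cylinder).

    ``synapses`` columns: ``pre``, ``post`` (global ids), ``type``,
    ``weight`` (signed nS), ``delay`` (ms), ``plastic``.
    """

    config: NetworkConfig
    neurons: pd.DataFrame
    synapses: pd.DataFrame | None = None
    gap_junctions: pd.DataFrame | None = None
    specs: list[ConnectionSpec] | None = None

    # -- lookups ---------------------------------------------------------
    def population_ids(self, pop: str) -> np.ndarray:
        return self.neurons.loc[self.neurons["population"] == pop, "id"].to_numpy()

    def module_ids(self, pop: str, module: str) -> np.ndarray:
        m = (self.neurons["population"] == pop) & (self.neurons["micromodule"] == module)
        return self.neurons.loc[m, "id"].to_numpy()

    def counts(self) -> dict[str, int]:
        return self.neurons["population"].value_counts().to_dict()

    def cortical_neuron_total(self) -> int:
        c = self.counts()
        return sum(c[p] for p in CORTICAL_POPULATIONS)

    def connection_type_counts(self) -> dict[str, int]:
        if self.synapses is None:
            return {}
        return self.synapses["type"].value_counts().to_dict()

    def spec_by_name(self, name: str) -> ConnectionSpec:
        assert self.specs is not None
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- serialization ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.neurons.to_csv(d / "neurons.csv", index=False)
        if self.synapses is not None:
            self.synapses.to_csv(d / "synapses.csv", index=False)
        if self.gap_junctions is not None:
            self.gap_junctions.to_csv(d / "gap_junctions.csv", index=False)
        self.config.to_yaml(d / "network_config.yaml")

    @classmethod
    def load(cls, directory: str | Path) -> "Network":
        d = Path(directory)
        config = NetworkConfig.from_yaml(d / "network_config.yaml")
        neurons = pd.read_csv(d / "neurons.csv", keep_default_na=False)
        synapses = None
        if (d / "synapses.csv").exists():
            synapses = pd.read_csv(d / "synapses.csv")
        gaps = None
        if (d / "gap_junctions.csv").exists():
            gaps = pd.read_csv(d / "gap_junctions.csv")
        return cls(config=config, neurons=neurons, synapses=synapses,
                   gap_junctions=gaps, specs=default_connection_specs())


def _construction_rng(config: NetworkConfig) -> np.random.Generator:
    # Dedicated stream: stimulus/noise seeds never perturb construction.
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0]))


def build_network(config: NetworkConfig) -> Network:
    """Instantiate neurons, parasagittal coordinates and micromodule labels.

    Populations are scaled by ``round(scale * count)``; PC, DCN_p, DCN_GABA
    and IO are split ``round(downbound_fraction * n)`` downbound (low-x side)
    versus upbound.  Mossy fibres closest to the mid-coordinate form the
    central CS-target subset (scaled from 45 of 117).  Deterministic for a
    fixed seed.
    """
    rng = _construction_rng(config)
    counts = config.scaled_counts()
    f = config.downbound_fraction

    rows = []
    next_id = 0
    for pop, n in counts.items():
        x = np.sort(rng.uniform(0.0, 1.0, size=n)) if pop in MODULAR_POPULATIONS \
            else rng.uniform(0.0, 1.0, size=n)
        if pop in MODULAR_POPULATIONS:
            # exact downbound count on the low-x side
            n_down = int(round(f * n))
            module = np.array(["downbound"] * n_down + ["upbound"] * (n - n_down))
            # stretch coordinates so the module boundary sits at x = f
            x = np.concatenate([
                np.sort(rng.uniform(0.0, f, size=n_down)),
                np.sort(rng.uniform(f, 1.0, size=n - n_down)),
            ])
        else:
            module = np.array(["shared"] * n)
        ids = np.arange(next_id, next_id + n)
        next_id += n
        rows.append(pd.DataFrame({
            "id": ids, "population": pop, "micromodule": module,
            "x": x, "mli_pref": "", "cs_target": False,
        }))
    neurons = pd.concat(rows, ignore_index=True)

    # central CS-target mossy fibres (cylinder centred in the granular layer)
    n_mf = counts["mf"]
    n_cs = max(1, int(round(config.mf_cs_target_count / config.mf_total * n_mf)))
    mf_mask = neurons["population"] == "mf"
    mf_idx = neurons.index[mf_mask]
    centrality = (neurons.loc[mf_idx, "x"] - 0.5).abs().to_numpy()
    central = mf_idx[np.argsort(centrality)[:n_cs]]
    neurons.loc[central, "cs_target"] = True

    return Network(config=config, neurons=neurons,
                   specs=default_connection_specs())


def _sample_pres(pool: np.ndarray, conv: int, rng: np.random.Generator,
                 exclude: int | None = None) -> np.ndarray:
    """Sample ``conv`` distinct presynaptic ids from ``pool`` (capped by pool
    size); ``exclude`` removes self-connections."""
    if exclude is not None:
        pool = pool[pool != exclude]
    k = min(conv, pool.size)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(pool, size=k, replace=False)


def generate_connectivity(
    network: Network,
    specs: list[ConnectionSpec] | None = None,
    gap_junction_weight: float = 30.0,
    gap_junction_degree: int = 2,
) -> Network:
    """Realize the synapse table for all 24 connection types.

    Convergence (mean in-degree) is held constant under down-scaling until
    the presynaptic pool size caps it, preserving per-neuron input
    statistics.  Micromodule-confined types draw presynaptic partners only
    from the postsynaptic cell's module; sagittal-gradient types (IO
    spillover onto MLIs) pick the presynaptic module with probability
    ``1 - x`` for downbound, realizing the climbing-fibre gradient that
    favours downbound olivary input near the downbound microzone.
    GoC gap junctions are added as electrical pairs outside the chemical
    connection-type table (fast bidirectional depolarizing spike coupling —
    an approximation of conductance coupling).
    """
    if specs is None:
        specs = network.specs or default_connection_specs()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(network.config.seed), 0xC1]))
    neurons = network.neurons
    pops = set(neurons["population"])
    by_pop = {p: neurons.loc[neurons["population"] == p] for p in pops}

    pre_l, post_l, type_l, w_l, d_l, pl_l = [], [], [], [], [], []

    for spec in specs:
        if spec.pre_population not in pops or spec.post_population not in pops:
            raise ValueError(
                f"{spec.name}: unknown population "
                f"{spec.pre_population!r} or {spec.post_population!r}")
        pre_df = by_pop[spec.pre_population]
        post_df = by_pop[spec.post_population]
        post_ids = post_df["id"].to_numpy()

        if spec.name == "mf_glom":
            # contiguous parasagittal blocks: each glomerulus relays the
            # mossy fibre nearest along x
            mf_sorted = pre_df.sort_values("x")["id"].to_numpy()
            glom_sorted = post_df.sort_values("x")["id"].to_numpy()
            block = np.floor(
                np.arange(glom_sorted.size) * mf_sorted.size / glom_sorted.size
            ).astype(int)
            pres_per_post = {g: np.array([mf_sorted[b]])
                             for g, b in zip(glom_sorted, block)}
        else:
            pres_per_post = {}
            same_pop = spec.pre_population == spec.post_population
            if spec.micromodule_confined:
                pools = {
                    mod: pre_df.loc[pre_df["micromodule"] == mod, "id"].to_numpy()
                    for mod in ("downbound", "upbound")
                }
                for pid, mod in zip(post_ids, post_df["micromodule"]):
                    pres_per_post[pid] = _sample_pres(
                        pools[mod], spec.convergence, rng,
                        exclude=pid if same_pop else None)
            elif spec.sagittal_gradient:
                pools = {
                    mod: pre_df.loc[pre_df["micromodule"] == mod, "id"].to_numpy()
                    for mod in ("downbound", "upbound")
                }
                for pid, x in zip(post_ids, post_df["x"]):
                    # steep linear ramp across the module boundary: MLIs on
                    # the downbound side receive downbound climbing fibres,
                    # those past the boundary upbound ones, with a narrow
                    # mixing band realizing the parasagittal cf gradient
                    p_down = min(1.0, max(0.0, (0.75 - x) / 0.15))
                    mod = "downbound" if rng.random() < p_down else "upbound"
                    pool = pools[mod] if pools[mod].size else pools[
                        "upbound" if mod == "downbound" else "downbound"]
                    pres_per_post[pid] = _sample_pres(pool, spec.convergence, rng)
            elif spec.local_radius is not None:
                # spatially confined sampling along the parasagittal axis;
                # the window widens until it holds the full convergence
                order = np.argsort(pre_df["x"].to_numpy())
                xs = pre_df["x"].to_numpy()[order]
                pool_sorted = pre_df["id"].to_numpy()[order]
                for pid, x in zip(post_ids, post_df["x"]):
                    r = spec.local_radius
                    while True:
                        lo = np.searchsorted(xs, x - r)
                        hi = np.searchsorted(xs, x + r)
                        margin = 1 if same_pop else 0
                        if hi - lo >= min(spec.convergence + margin,
                                          pool_sorted.size) or r > 1.0:
                            break
                        r *= 2.0
                    pres_per_post[pid] = _sample_pres(
                        pool_sorted[lo:hi], spec.convergence, rng,
                        exclude=pid if same_pop else None)
            else:
                pool = pre_df["id"].to_numpy()
                for pid in post_ids:
                    pres_per_post[pid] = _sample_pres(
                        pool, spec.convergence, rng,
                        exclude=pid if same_pop else None)

        module_of_post = dict(zip(post_df["id"], post_df["micromodule"]))
        for pid, pres in pres_per_post.items():
            if pres.size == 0:
                continue
            reps = np.repeat(pres, spec.n_contacts_per_pair)
            pre_l.append(reps)
            post_l.append(np.full(reps.size, pid, dtype=np.int64))
            n = reps.size
            type_l.extend([spec.name] * n)
            w = spec.synapse_weight
            if (spec.synapse_weight_upbound is not None
                    and module_of_post.get(pid) == "upbound"):
                w = spec.synapse_weight_upbound
            w_l.append(np.full(n, w))
            d_l.append(np.full(n, spec.delay))
            pl_l.extend([spec.plastic] * n)

    synapses = pd.DataFrame({
        "pre": np.concatenate(pre_l),
        "post": np.concatenate(post_l),
        "type": np.array(type_l),
        "weight": np.concatenate(w_l),
        "delay": np.concatenate(d_l),
        "plastic": np.array(pl_l, dtype=bool),
    })

    # GoC electrical coupling: ring of nearest neighbours along x
    goc = by_pop["GoC"].sort_values("x")["id"].to_numpy()
    pairs = []
    if goc.size >= 2:
        for i, g in enumerate(goc):
            for k in range(1, gap_junction_degree + 1):
                j = (i + k) % goc.size
                if goc[j] != g:
                    pairs.append((g, goc[j]))
    gaps = pd.DataFrame(pairs, columns=["a", "b"])
    gaps["weight"] = gap_junction_weight

    network.synapses = synapses
    network.gap_junctions = gaps
    network.specs = specs
    return network


def assign_mli_preference(network: Network) -> Network:
    """Label each MLI downbound- or upbound-preferring.

    Majority vote over the micromodules of the Purkinje cells the MLI
    inhibits; ties broken by the module supplying more IO-spillover (cf)
    afferents, then by id parity.  MLIs with no PC targets are labelled by
    cf in-degree alone (logged as a warning).
    """
    if network.synapses is None:
        raise ValueError("connectivity must be generated first")
    syn = network.synapses
    neurons = network.neurons
    module_of = dict(zip(neurons["id"], neurons["micromodule"]))

    mli_ids = neurons.loc[
        neurons["population"].isin(MLI_POPULATIONS), "id"].to_numpy()
    pc_syn = syn[syn["type"].isin(["SC_PC", "BC_PC"])]
    cf_syn = syn[syn["type"].isin(["IO_SC", "IO_BC"])]

    pc_down = pc_syn.assign(
        down=[module_of[p] == "downbound" for p in pc_syn["post"]])
    down_counts = pc_down.groupby("pre")["down"].agg(["sum", "count"])
    cf_down = cf_syn.assign(
        down=[module_of[p] == "downbound" for p in cf_syn["pre"]])
    cf_counts = cf_down.groupby("post")["down"].agg(["sum", "count"])

    prefs = {}
    n_orphan = 0
    for m in mli_ids:
        if m in down_counts.index:
            d, tot = down_counts.loc[m, "sum"], down_counts.loc[m, "count"]
            if 2 * d > tot:
                prefs[m] = "downbound"
                continue
            if 2 * d < tot:
                prefs[m] = "upbound"
                continue
        else:
            n_orphan += 1
        # tie or no PC targets: cf in-degree, then id parity
        if m in cf_counts.index:
            d, tot = cf_counts.loc[m, "sum"], cf_counts.loc[m, "count"]
            if 2 * d != tot:
                prefs[m] = "downbound" if 2 * d > tot else "upbound"
                continue
        prefs[m] = "downbound" if m % 2 == 0 else "upbound"
    if n_orphan:
        logger.warning("%d MLIs have no PC targets; labelled by cf in-degree",
                       n_orphan)

    col = neurons["id"].map(prefs).fillna("")
    neurons["mli_pref"] = np.where(
        neurons["population"].isin(MLI_POPULATIONS), col, "")
    return network
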