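"""Clock-driven (1-ms) network simulation engine.

The engine compiles a built :class:`~cebsim.scaffold.Network` into flat
arrays: one global E-GLIF state vector covering all spiking populations
(per-neuron parameter arrays), one flat alpha-conductance buffer holding a
slot per (connection type, postsynaptic cell), ring-buffer spike histories
honouring per-type delays, and online machinery for the two supervised
plasticity rules.

Synaptic conductances follow the normalized alpha kernel exactly on the
grid via the two-state recurrence

    g(t) = E * (g(t-1) + a(t-1) / tau)       E = exp(-dt/tau)
    a(t) = E * a(t-1) + e * impulse(t)

which reproduces sum_s w * K(t - s), K(u) = (u/tau) e^(1-u/tau), to float
precision.  The same recurrence implements the pf-MLI eligibility trace, so
the online update matches the brute-force convolution oracle exactly (the
kernel value at zero lag is 0, hence a cf-coincident pf spike contributes
no potentiation, as the rule prescribes).

Plasticity bookkeeping is arrival-aligned: "a pf was active just before the
cf spike" is evaluated at the postsynaptic site, comparing arrival times
(presynaptic spike + synaptic delay) of pf and cf spikes; "coincident"
means the same 1-ms step.  The pf-PC depression window counts pf arrivals
in the 200 ms strictly before the cf arrival.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .neurons import NeuronParams
from .params import (DEFAULT_NEURON_PARAMS, PC_IE_DOWNBOUND, PC_IE_UPBOUND,
                     SPIKING_POPULATIONS)
from .plasticity import PC_LTD_WINDOW_MS, PlasticityRuleParams
from .scaffold import Network

__all__ = ["SimulationEngine", "TrialRecord"]

E_REV_EXC = 0.0     # mV
E_REV_INH = -88.0   # mV

#: populations whose spikes are recorded by default
DEFAULT_RECORDED = ("PC", "SC", "BC", "DCN_p", "DCN_GABA", "IO")


class TrialRecord:
    """Spikes of one trial: population -> (local neuron index, time ms)."""

    def __init__(self, spikes: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.spikes = spikes

    def of(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        return self.spikes[pop]

    def cell_train(self, pop: str, local_idx: int) -> np.ndarray:
        ids, ts = self.spikes[pop]
        return ts[ids == local_idx].astype(float)


class _Group:
    """One compiled chemical connection type (non-plastic)."""

    __slots__ = ("name", "pre_pop", "delay", "slot0", "slot1",
                 "W", "indptr", "slot_local", "w_flat", "gather")

    def __init__(self, name, pre_pop, delay, slot0, slot1):
        self.name = name
        self.pre_pop = pre_pop
        self.delay = int(round(delay))
        self.slot0 = slot0
        self.slot1 = slot1


class _PlasticGroup:
    """Compiled plastic type (pf-PC or pf-MLI) with mutable weights."""

    __slots__ = ("name", "post_pop", "delay", "slot0", "slot1", "n_post",
                 "pre", "post", "w", "w_init", "indptr_pre",
                 "order_post", "indptr_post", "is_mli")

    def __init__(self, name, post_pop, pre_ids, post_ids, w, delay,
                 slot0, slot1, n_pre, n_post, is_mli):
        self.name = name
        self.post_pop = post_pop
        self.delay = int(round(delay))
        self.slot0 = slot0
        self.slot1 = slot1
        self.n_post = n_post
        self.is_mli = bool(is_mli)
        order = np.argsort(pre_ids, kind="stable")
        self.pre = pre_ids[order].astype(np.int64)
        self.post = post_ids[order].astype(np.int64)
        self.w = np.abs(w[order]).astype(np.float64)
        self.w_init = self.w.copy()
        self.indptr_pre = np.searchsorted(self.pre, np.arange(n_pre + 1))
        self.order_post = np.argsort(self.post, kind="stable")
        self.indptr_post = np.searchsorted(self.post[self.order_post],
                                           np.arange(n_post + 1))

    def reset_weights(self):
        self.w[:] = self.w_init


class SimulationEngine:
    """Stateful simulator bound to one network, lesion and plasticity config.

    Consecutive ``run_trial`` calls form one continuous stretch of simulated
    time: plastic weights, neuron state, conductances, eligibility traces
    and the delayed-spike ring buffers all persist, so spikes emitted near
    the end of one trial still arrive early in the next.
    ``reset_trial_state`` re-initializes the dynamic state (weights are kept;
    ``reset_weights`` restores those).  All randomness flows through the
    generator handed in at construction, so runs are bit-reproducible for a
    fixed master seed.
    """

    def __init__(
        self,
        network: Network,
        plasticity: PlasticityRuleParams | None = None,
        mli_output_disconnected: bool = False,
        neuron_params: dict[str, NeuronParams] | None = None,
        rng: np.random.Generator | None = None,
        recorded: tuple[str, ...] = DEFAULT_RECORDED,
        plasticity_enabled: bool = True,
        io_input_weight: float = 150.0,
    ):
        self.network = network
        self.plast = plasticity or PlasticityRuleParams()
        self.plasticity_enabled = plasticity_enabled
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.recorded = tuple(recorded)
        self.io_input_weight = float(io_input_weight)
        nparams = dict(DEFAULT_NEURON_PARAMS)
        if neuron_params:
            nparams.update(neuron_params)
        self.nparams = nparams

        self._index_populations()
        self._compile_neurons()
        self._compile_synapses(mli_output_disconnected)
        self._compile_relays()
        self.reset_trial_state(randomize=False)

    # ------------------------------------------------------------------
    def _index_populations(self):
        net = self.network
        self.pops = list(SPIKING_POPULATIONS)
        self.n = {}
        self.off = {}
        self.glob2loc = np.full(int(net.neurons["id"].max()) + 1, -1,
                                dtype=np.int64)
        nxt = 0
        for pop in self.pops:
            ids = net.population_ids(pop)
            self.n[pop] = ids.size
            self.off[pop] = nxt
            self.glob2loc[ids] = np.arange(ids.size)
            nxt += ids.size
        self.N = nxt
        for pop in ("mf", "glom"):
            ids = net.population_ids(pop)
            self.n[pop] = ids.size
            self.glob2loc[ids] = np.arange(ids.size)
        self.module_mask = {}
        nidx = net.neurons.set_index("id")
        for pop in ("PC", "DCN_p", "DCN_GABA", "IO"):
            ids = net.population_ids(pop)
            mods = nidx.loc[ids, "micromodule"].to_numpy()
            self.module_mask[pop] = (mods == "downbound")

    def _glob(self, pop: str, local: np.ndarray) -> np.ndarray:
        return self.off[pop] + local

    def _compile_neurons(self):
        N = self.N
        fields = ("tau_m", "E_L", "V_th", "V_reset", "k_adap", "k2", "k1",
                  "A1", "A2", "t_ref", "escape_sigma", "escape_rate")
        self.par = {f: np.zeros(N) for f in fields}
        self.par["inv_C"] = np.zeros(N)
        self.par["Ie"] = np.zeros(N)
        for pop in self.pops:
            p: NeuronParams = self.nparams[pop]
            s = slice(self.off[pop], self.off[pop] + self.n[pop])
            for f in fields:
                self.par[f][s] = getattr(p, f)
            self.par["inv_C"][s] = 1.0 / p.C
            if pop == "PC":
                down = self.module_mask["PC"]
                self.par["Ie"][s] = np.where(down, PC_IE_DOWNBOUND, PC_IE_UPBOUND)
            else:
                self.par["Ie"][s] = p.I_e
        self.par["inv_tau_m"] = 1.0 / self.par.pop("tau_m")
        self.has_escape = bool(np.any(self.par["escape_sigma"] > 0))
        self.esc_mask = self.par["escape_sigma"] > 0
        self.V = np.zeros(N)
        self.Ia = np.zeros(N)
        self.Id = np.zeros(N)
        self.ref = np.zeros(N)
        # recording mask
        self.rec_mask = np.zeros(N, dtype=bool)
        for pop in self.recorded:
            if pop in self.off:
                self.rec_mask[self.off[pop]:self.off[pop] + self.n[pop]] = True

    def _compile_synapses(self, mli_cut: bool):
        net = self.network
        syn = net.synapses
        if syn is None:
            raise ValueError("network has no synapse table")
        self.groups: list[_Group] = []
        self.plastic_groups: list[_PlasticGroup] = []
        slot_neuron, slot_erev, slot_E, slot_Einvtau = [], [], [], []
        S = 0

        def alloc_slots(post_pop, tau, erev):
            nonlocal S
            n_post = self.n[post_pop]
            s0, s1 = S, S + n_post
            S = s1
            slot_neuron.append(self.off[post_pop] + np.arange(n_post))
            slot_erev.append(np.full(n_post, erev))
            E = np.exp(-1.0 / tau)
            slot_E.append(np.full(n_post, E))
            slot_Einvtau.append(np.full(n_post, E / tau))
            return s0, s1

        gather_pres = {"GrC", "glom", "mf"}
        for name, df in syn.groupby("type", sort=False):
            spec = net.spec_by_name(name)
            if name == "mf_glom":
                continue
            pre_pop, post_pop = spec.pre_population, spec.post_population
            pre_local = self.glob2loc[df["pre"].to_numpy()]
            post_local = self.glob2loc[df["post"].to_numpy()]
            w = df["weight"].to_numpy().copy()
            if mli_cut and name in ("SC_PC", "BC_PC"):
                w = np.zeros_like(w)
            erev = E_REV_INH if spec.synapse_weight < 0 else E_REV_EXC
            s0, s1 = alloc_slots(post_pop, spec.receptor_time_constant, erev)
            if spec.plastic:
                self.plastic_groups.append(_PlasticGroup(
                    name, post_pop, pre_local, post_local, w, spec.delay,
                    s0, s1, self.n[pre_pop], self.n[post_pop],
                    is_mli=post_pop in ("SC", "BC")))
            else:
                g = _Group(name, pre_pop, spec.delay, s0, s1)
                absw = np.abs(w)
                if pre_pop in gather_pres:
                    csc = sp.coo_matrix(
                        (absw, (post_local, pre_local)),
                        shape=(self.n[post_pop], self.n[pre_pop])).tocsc()
                    g.gather = True
                    g.indptr = csc.indptr
                    g.slot_local = csc.indices
                    g.w_flat = csc.data
                    g.W = None
                else:
                    g.gather = False
                    g.W = sp.coo_matrix(
                        (absw, (post_local, pre_local)),
                        shape=(self.n[post_pop], self.n[pre_pop])).tocsr()
                self.groups.append(g)

        # IO stimulus input (US / conditioned IO input): its own slot block
        self._io_slots = alloc_slots("IO", 1.0, E_REV_EXC)

        self.S = S
        self.slot_neuron = np.concatenate(slot_neuron)
        self.slot_erev = np.concatenate(slot_erev)
        self.slot_E = np.concatenate(slot_E)
        self.slot_Einvtau = np.concatenate(slot_Einvtau)
        self.G = np.zeros(S)
        self.A = np.zeros(S)

        self.cf_groups = {g.name: g for g in self.groups
                          if g.name in ("IO_PC", "IO_SC", "IO_BC")}

        gaps = net.gap_junctions
        if gaps is not None and len(gaps):
            a = self.glob2loc[gaps["a"].to_numpy()] + self.off["GoC"]
            b = self.glob2loc[gaps["b"].to_numpy()] + self.off["GoC"]
            wg = gaps["weight"].to_numpy().astype(float)
            self.gap_pre = np.concatenate([a, b])
            self.gap_post = np.concatenate([b, a])
            self.gap_w = np.concatenate([wg, wg])
        else:
            self.gap_pre = np.empty(0, dtype=np.int64)
            self.gap_post = np.empty(0, dtype=np.int64)
            self.gap_w = np.empty(0)

        dmax = max([g.delay for g in self.groups]
                   + [g.delay for g in self.plastic_groups] + [1])
        self.D = dmax + 1
        self.ltd_window = int(PC_LTD_WINDOW_MS)
        self.pop_index = {p: i for i, p in enumerate(self.pops)}
        # pf-MLI eligibility traces (per granule cell, arrival-aligned)
        self.trace_a = np.zeros(self.n["GrC"])
        self.trace_b = np.zeros(self.n["GrC"])
        self.trace_E = float(np.exp(-1.0 / self.plast.tau))

    def _compile_relays(self):
        net = self.network
        syn = net.synapses
        mfg = syn[syn["type"] == "mf_glom"]
        self.glom2mf = np.zeros(self.n["glom"], dtype=np.int64)
        self.glom2mf[self.glob2loc[mfg["post"].to_numpy()]] = \
            self.glob2loc[mfg["pre"].to_numpy()]
        self.mf_glom_delay = int(round(net.spec_by_name("mf_glom").delay))
        mf_df = net.neurons[net.neurons["population"] == "mf"]
        self.cs_mf_mask = np.zeros(self.n["mf"], dtype=bool)
        cs_ids = mf_df.loc[mf_df["cs_target"], "id"].to_numpy()
        self.cs_mf_mask[self.glob2loc[cs_ids]] = True

    # ------------------------------------------------------------------
    def reset_trial_state(self, randomize: bool = True,
                          rng: np.random.Generator | None = None):
        """Reset membrane/conductance/trace state (weights persist)."""
        r = rng if rng is not None else self.rng
        if randomize:
            self.V[:] = self.par["V_reset"] + r.random(self.N) * (
                self.par["V_th"] - self.par["V_reset"])
        else:
            self.V[:] = self.par["E_L"]
        self.Ia[:] = 0.0
        self.Id[:] = 0.0
        self.ref[:] = 0.0
        self.G[:] = 0.0
        self.A[:] = 0.0
        self.trace_a[:] = 0.0
        self.trace_b[:] = 0.0
        # persistent ring buffers: spike history, per-population spike
        # counts, and the pf-arrival window for pf-PC depression.  These
        # survive across run_trial calls so consecutive trials form one
        # continuous stretch of simulated time (delayed spikes from the
        # previous trial still arrive).
        self._hist = np.zeros((self.N, self.D))
        self._popcount = np.zeros((len(self.pops), self.D), dtype=np.int64)
        self._ltd_ring = np.zeros((self.ltd_window, self.n["GrC"]))
        self._ltd_count = np.zeros(self.n["GrC"])
        self._gt = 0   # global step counter (ring phase)

    def reset_weights(self):
        for g in self.plastic_groups:
            g.reset_weights()

    def plastic_weights(self) -> dict[str, np.ndarray]:
        return {g.name: g.w.copy() for g in self.plastic_groups}

    def initial_weights(self) -> dict[str, np.ndarray]:
        return {g.name: g.w_init.copy() for g in self.plastic_groups}

    def plastic_group(self, name: str) -> _PlasticGroup:
        for g in self.plastic_groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def scale_weights(self, multipliers: dict[str, float]):
        """Multiply the weights of given connection types in place (used by
        the bisection weight calibration)."""
        for name, m in multipliers.items():
            found = False
            for g in self.groups:
                if g.name == name:
                    if g.gather:
                        g.w_flat *= m
                    else:
                        g.W.data *= m
                    found = True
            for g in self.plastic_groups:
                if g.name == name:
                    g.w *= m
                    g.w_init *= m
                    found = True
            if not found:
                raise KeyError(name)

    # ------------------------------------------------------------------
    def run_trial(
        self,
        mf_trains: np.ndarray,
        io_input: np.ndarray | None = None,
        duration: int | None = None,
    ) -> TrialRecord:
        """Simulate one trial of ``T`` 1-ms steps.

        ``mf_trains``: bool/int (n_mf, T) exogenous mossy-fibre spikes.
        ``io_input``: optional bool (n_IO, T) stimulus train delivered to IO
        neurons through a strong fast excitatory synapse (US / conditioned
        IO input).
        """
        T = int(duration if duration is not None else mf_trains.shape[1])
        if mf_trains.shape[0] != self.n["mf"]:
            raise ValueError("mf_trains row count != number of mossy fibres")
        mf_f = np.ascontiguousarray(mf_trains, dtype=np.float64)
        glom_f = np.zeros((self.n["glom"], T))
        dg = self.mf_glom_delay
        glom_f[:, dg:] = mf_f[self.glom2mf, : T - dg]
        ext = {"mf": mf_f, "glom": glom_f}

        D = self.D
        hist = self._hist
        popcount = self._popcount
        pop_edges = np.array([self.off[p] for p in self.pops] + [self.N])

        ltd_ring = self._ltd_ring
        ltd_count = self._ltd_count
        t_off = self._gt

        rec_ids: list[np.ndarray] = []
        rec_ts: list[np.ndarray] = []

        par = self.par
        p_EL = par["E_L"]; p_invtau = par["inv_tau_m"]; p_invC = par["inv_C"]
        p_Ie = par["Ie"]; p_kadap = par["k_adap"]; p_k2 = par["k2"]
        p_k1 = par["k1"]; p_A1 = par["A1"]; p_A2 = par["A2"]
        p_tref = par["t_ref"]; p_Vth = par["V_th"]; p_Vr = par["V_reset"]
        esc_idx = np.flatnonzero(self.esc_mask)
        esc_sigma = par["escape_sigma"][esc_idx]
        esc_rate = par["escape_rate"][esc_idx]
        pl = self.plast
        plast_on = self.plasticity_enabled and bool(self.plastic_groups)
        rng = self.rng
        io_s0, io_s1 = self._io_slots
        grc0 = self.off["GrC"]
        n_grc = self.n["GrC"]
        slot_neuron = self.slot_neuron
        slot_erev = self.slot_erev
        slot_E = self.slot_E
        slot_Einvtau = self.slot_Einvtau
        G, A = self.G, self.A
        V, Ia, Id, ref = self.V, self.Ia, self.Id, self.ref
        pidx = self.pop_index
        grc_row = pidx["GrC"]
        io_row = pidx["IO"]
        pop_slices = {p: (self.off[p], self.off[p] + self.n[p])
                      for p in self.pops}

        # per-group cached attributes (avoid attribute lookups in the loop)
        groups = [(g, g.pre_pop in ext,
                   pidx.get(g.pre_pop, -1),
                   pop_slices.get(g.pre_pop, (0, 0)))
                  for g in self.groups]

        if not np.all(np.isfinite(V)):
            raise FloatingPointError("non-finite membrane state at trial start")

        for t in range(T):
            # --- conductance decay (all slots fused) ------------------
            G *= slot_E
            G += slot_Einvtau * A
            A *= slot_E

            # --- impulses from delayed spikes -------------------------
            gt = t_off + t
            for g, is_ext, prow, (plo, phi) in groups:
                if is_ext:
                    tt = t - g.delay
                    if tt < 0:
                        continue
                    vec = ext[g.pre_pop][:, tt]
                    if not vec.any():
                        continue
                else:
                    tt = gt - g.delay
                    if popcount[prow, tt % D] == 0:
                        continue
                    vec = hist[plo:phi, tt % D]
                if g.gather:
                    act = np.flatnonzero(vec)
                    idx = _ranges(g.indptr, act)
                    if idx.size:
                        np.add.at(A, g.slot0 + g.slot_local[idx],
                                  np.e * g.w_flat[idx])
                else:
                    A[g.slot0:g.slot1] += np.e * (g.W @ vec)

            arr_cached = {}
            for g in self.plastic_groups:
                tt = (gt - g.delay) % D
                if popcount[grc_row, tt] == 0:
                    continue
                if tt not in arr_cached:
                    arr_cached[tt] = np.flatnonzero(hist[grc0:grc0 + n_grc, tt])
                act = arr_cached[tt]
                idx = _ranges(g.indptr_pre, act)
                if idx.size:
                    np.add.at(A, g.slot0 + g.post[idx], np.e * g.w[idx])

            if io_input is not None:
                A[io_s0:io_s1] += (np.e * self.io_input_weight) * io_input[:, t]

            # --- synaptic currents ------------------------------------
            Isyn = np.zeros(self.N)
            np.add.at(Isyn, slot_neuron, G * (slot_erev - V[slot_neuron]))

            if self.gap_w.size and popcount[pidx["GoC"], (gt - 1) % D]:
                sp_prev = hist[:, (gt - 1) % D]
                mask = sp_prev[self.gap_pre] > 0
                if mask.any():
                    np.add.at(Isyn, self.gap_post[mask], self.gap_w[mask])

            # --- plasticity -------------------------------------------
            if plast_on:
                pf_delay = self.plastic_groups[0].delay
                tt = (gt - pf_delay) % D
                has_arr = popcount[grc_row, tt] > 0
                arr_vec = hist[grc0:grc0 + n_grc, tt] if has_arr else None
                # advance eligibility traces to time t (K(0)=0: this
                # step's arrivals enter `a` only, not `b`)
                self.trace_b *= self.trace_E
                self.trace_b += (self.trace_E / pl.tau) * self.trace_a
                self.trace_a *= self.trace_E
                arr_idx = None
                if has_arr:
                    arr_idx = np.flatnonzero(arr_vec)
                    self.trace_a[arr_idx] += np.e

                teach = {"PC": None, "SC": None, "BC": None}
                for nm, post_pop in (("IO_PC", "PC"), ("IO_SC", "SC"),
                                     ("IO_BC", "BC")):
                    cg = self.cf_groups.get(nm)
                    if cg is None or popcount[io_row, (gt - cg.delay) % D] == 0:
                        continue
                    lo_, hi_ = pop_slices["IO"]
                    vec = hist[lo_:hi_, (gt - cg.delay) % D]
                    tv = (cg.W @ vec) > 0
                    teach[post_pop] = tv if tv.any() else None

                for g in self.plastic_groups:
                    tvec = teach[g.post_pop]
                    wmax = None
                    if g.is_mli:
                        if tvec is not None and pl.LTP_MLI:
                            jdx = np.flatnonzero(tvec)
                            sl = g.order_post[_ranges(g.indptr_post, jdx)]
                            if sl.size:
                                g.w[sl] = np.minimum(
                                    g.w[sl] + pl.LTP_MLI * self.trace_b[g.pre[sl]],
                                    pl.w_max_factor * g.w_init[sl])
                        if arr_idx is not None and pl.LTD_MLI:
                            idx = _ranges(g.indptr_pre, arr_idx)
                            if idx.size:
                                if tvec is None:
                                    g.w[idx] = np.maximum(
                                        g.w[idx] - pl.LTD_MLI, pl.w_min)
                                else:
                                    dec = np.where(tvec[g.post[idx]], 0.0,
                                                   pl.LTD_MLI)
                                    g.w[idx] = np.maximum(g.w[idx] - dec,
                                                          pl.w_min)
                    else:
                        if tvec is not None and pl.LTD_PC:
                            jdx = np.flatnonzero(tvec)
                            sl = g.order_post[_ranges(g.indptr_post, jdx)]
                            if sl.size:
                                g.w[sl] = np.maximum(
                                    g.w[sl] - pl.LTD_PC * ltd_count[g.pre[sl]],
                                    pl.w_min)
                        if arr_idx is not None and pl.LTP_PC:
                            idx = _ranges(g.indptr_pre, arr_idx)
                            if idx.size:
                                if tvec is None:
                                    g.w[idx] = np.minimum(
                                        g.w[idx] + pl.LTP_PC,
                                        pl.w_max_factor * g.w_init[idx])
                                else:
                                    inc = np.where(tvec[g.post[idx]], 0.0,
                                                   pl.LTP_PC)
                                    g.w[idx] = np.minimum(
                                        g.w[idx] + inc,
                                        pl.w_max_factor * g.w_init[idx])

                # pf-arrival ring for the 200-ms LTD window (strictly
                # before the current step)
                slot = gt % self.ltd_window
                ltd_count -= ltd_ring[slot]
                if arr_vec is not None:
                    ltd_ring[slot] = arr_vec
                    ltd_count += arr_vec
                else:
                    ltd_ring[slot] = 0.0

            # --- neuron update ----------------------------------------
            active = ref <= 0.0
            dV = (-(V - p_EL) * p_invtau
                  + (p_Ie + Isyn + Id - Ia) * p_invC)
            # numerical safeguards for the explicit 1-ms update: bound the
            # per-step change and keep V inside the reversal-potential
            # range (strong conductances on small cells would otherwise
            # make the explicit update oscillate)
            np.clip(dV, -30.0, 30.0, out=dV)
            V_new = np.where(active, V + dV, p_Vr)
            np.clip(V_new, E_REV_INH, 10.0, out=V_new)
            Ia += p_kadap * (V - p_EL) - p_k2 * Ia
            Id -= p_k1 * Id
            ref -= 1.0
            np.maximum(ref, 0.0, out=ref)
            spiked = active & (V_new >= p_Vth)
            if esc_idx.size:
                ve = V_new[esc_idx]
                x = np.clip((ve - p_Vth[esc_idx]) / esc_sigma, -30.0, 30.0)
                prob = 1.0 - np.exp(-esc_rate * np.exp(x))
                spiked[esc_idx] = active[esc_idx] & (
                    rng.random(esc_idx.size) < prob)
            idx = np.flatnonzero(spiked)
            if idx.size:
                V_new[idx] = p_Vr[idx]
                Ia[idx] += p_A2[idx]
                Id[idx] = p_A1[idx]
                ref[idx] = p_tref[idx]
            if t % 50 == 0 and not np.all(np.isfinite(V_new)):
                raise FloatingPointError(
                    f"non-finite membrane potential at step {t}")
            V[:] = V_new
            hist[:, gt % D] = spiked
            popcount[:, gt % D] = np.add.reduceat(
                spiked.astype(np.int64), pop_edges[:-1])
            if idx.size:
                ridx = idx[self.rec_mask[idx]]
                if ridx.size:
                    rec_ids.append(ridx)
                    rec_ts.append(np.full(ridx.size, t, dtype=np.int32))

        self._gt = t_off + T
        # split recorded spikes per population
        if rec_ids:
            all_ids = np.concatenate(rec_ids)
            all_ts = np.concatenate(rec_ts)
        else:
            all_ids = np.empty(0, dtype=np.int64)
            all_ts = np.empty(0, dtype=np.int32)
        out = {}
        for pop in self.recorded:
            lo = self.off[pop]
            hi = lo + self.n[pop]
            m = (all_ids >= lo) & (all_ids < hi)
            out[pop] = ((all_ids[m] - lo).astype(np.int32), all_ts[m])
        return TrialRecord(out)


def _ranges(indptr: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Concatenated index ranges [indptr[i], indptr[i+1]) for active rows."""
    if active.size == 0:
        return np.empty(0, dtype=np.int64)
    starts = indptr[active]
    lens = indptr[active + 1] - starts
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.repeat(starts - np.concatenate(([0], np.cumsum(lens)[:-1])), lens)
    return out + np.arange(total)
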