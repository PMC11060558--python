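import numpy as np
import pandas as pd
import pytest

from cebsim.scaffold import (CORTICAL_POPULATIONS, ConnectionSpec, Network,
                             NetworkConfig, assign_mli_preference,
                             build_network, cortical_type_names,
                             default_connection_specs, extracortical_type_names,
                             generate_connectivity)


class TestBuildNetwork:
    def test_full_scale_cortical_total(self):
        """At scale 1 the cerebellar cortex holds exactly 29,230 neurons and
        2,453 relay elements (mossy fibres + glomeruli)."""
        net = build_network(NetworkConfig(scale_factor=1.0, seed=0))
        assert net.cortical_neuron_total() == 29230
        c = net.counts()
        assert c["mf"] + c["glom"] == 2453

    def test_full_scale_downbound_pc_fraction(self):
        net = build_network(NetworkConfig(scale_factor=1.0, seed=0))
        pc = net.neurons[net.neurons.population == "PC"]
        frac = (pc.micromodule == "downbound").mean()
        assert frac == pytest.approx(0.70, abs=0.01)

    def test_rounding_rule_small_scale(self):
        """100 PCs at scale 0.1 -> 10 PCs, split 7 downbound / 3 upbound."""
        sizes = dict(NetworkConfig().population_sizes)
        sizes["PC"] = 100
        net = build_network(NetworkConfig(scale_factor=0.1,
                                          population_sizes=sizes, seed=0))
        pc = net.neurons[net.neurons.population == "PC"]
        assert len(pc) == 10
        assert (pc.micromodule == "downbound").sum() == 7
        assert (pc.micromodule == "upbound").sum() == 3

    def test_zero_size_population_raises_with_name(self):
        with pytest.raises(ValueError, match="GoC|IO|DCN"):
            NetworkConfig(scale_factor=0.001).scaled_counts()

    def test_population_ratios_preserved_under_scaling(self):
        base = NetworkConfig().population_sizes
        counts = NetworkConfig(scale_factor=0.2).scaled_counts()
        for pop, n in counts.items():
            assert n == round(0.2 * base[pop])

    def test_cs_target_mfs_are_central(self):
        net = build_network(NetworkConfig(scale_factor=0.2, seed=1))
        mf = net.neurons[net.neurons.population == "mf"]
        n_cs = mf.cs_target.sum()
        assert n_cs == round(45 / 117 * len(mf))
        # targeted mfs are the ones nearest the mid-coordinate
        d_target = (mf.loc[mf.cs_target, "x"] - 0.5).abs().max()
        d_other = (mf.loc[~mf.cs_target, "x"] - 0.5).abs().min()
        assert d_target <= d_other


class TestConnectivity:
    def test_fifteen_cortical_plus_nine_extra_types(self, small_network):
        realized = set(small_network.connection_type_counts())
        assert set(cortical_type_names()) <= realized
        assert set(extracortical_type_names()) <= realized
        assert len(cortical_type_names()) == 15
        assert len(extracortical_type_names()) == 9
        assert len(realized) == 24

    def test_confined_types_never_cross_micromodules(self, small_network):
        syn = small_network.synapses
        module = dict(zip(small_network.neurons.id,
                          small_network.neurons.micromodule))
        confined = [s.name for s in small_network.specs
                    if s.micromodule_confined]
        assert "PC_DCN_p" in confined
        sub = syn[syn.type.isin(confined)]
        pre_m = sub.pre.map(module)
        post_m = sub.post.map(module)
        assert (pre_m == post_m).all()

    def test_synapse_counts_sum_to_table_length(self, small_network):
        counts = small_network.connection_type_counts()
        assert sum(counts.values()) == len(small_network.synapses)

    def test_no_self_connections(self, small_network):
        syn = small_network.synapses
        same = syn[syn.type.isin(["GoC_GoC", "SC_SC", "BC_BC"])]
        assert (same.pre != same.post).all()

    def test_realized_convergence_close_to_spec(self, small_network):
        """Mean in-degree per type within 10% of the spec (where the
        presynaptic pool does not cap it)."""
        syn = small_network.synapses
        counts = small_network.counts()
        for spec in small_network.specs:
            if spec.name == "mf_glom" or spec.micromodule_confined:
                continue
            pool = counts[spec.pre_population]
            if pool < spec.convergence * 1.5:
                continue    # capped by the scaled pool
            sub = syn[syn.type == spec.name]
            mean_in = len(sub) / sub.post.nunique() / spec.n_contacts_per_pair
            assert mean_in == pytest.approx(spec.convergence, rel=0.10), spec.name

    def test_reproducible_for_fixed_seed(self):
        cfg = NetworkConfig(scale_factor=0.02, seed=11)
        a = generate_connectivity(build_network(cfg))
        b = generate_connectivity(build_network(cfg))
        pd.testing.assert_frame_equal(a.synapses, b.synapses)
        pd.testing.assert_frame_equal(a.neurons, b.neurons)

    def test_unknown_population_rejected(self, small_network):
        bad = ConnectionSpec("x", "Martian", "PC", 1, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="Martian"):
            generate_connectivity(build_network(small_network.config), [bad])

    def test_n_contacts_realized_as_parallel_synapses(self, small_network):
        spec = small_network.spec_by_name("mf_DCN_p")
        assert spec.n_contacts_per_pair == 2
        sub = small_network.synapses.query("type == 'mf_DCN_p'")
        per_pair = sub.groupby(["pre", "post"]).size()
        assert (per_pair == 2).all()


class TestConnectionSpecValidation:
    def test_inhibitory_source_must_be_negative(self):
        with pytest.raises(ValueError):
            ConnectionSpec("bad", "GoC", "GrC", 2, +0.5, 1.0, 10.0)

    def test_minimum_delay(self):
        with pytest.raises(ValueError):
            ConnectionSpec("bad", "mf", "glom", 1, 1.0, 0.5, 1.0)


class TestMliPreference:
    def test_majority_rule_consistency(self, small_network):
        """Each MLI's label equals the module of the majority of its PC
        targets (ties excluded)."""
        net = small_network
        syn = net.synapses
        module = dict(zip(net.neurons.id, net.neurons.micromodule))
        pref = dict(zip(net.neurons.id, net.neurons.mli_pref))
        sub = syn[syn.type.isin(["SC_PC", "BC_PC"])]
        checked = 0
        for mli, grp in sub.groupby("pre"):
            down = sum(module[p] == "downbound" for p in grp.post)
            tot = len(grp)
            if 2 * down > tot:
                assert pref[mli] == "downbound"
                checked += 1
            elif 2 * down < tot:
                assert pref[mli] == "upbound"
                checked += 1
        assert checked > 0

    def test_preference_fraction_tracks_downbound_fraction(self):
        """Seed-averaged fraction of downbound-preferring MLIs tracks the
        downbound PC fraction within +/- 10 percentage points."""
        fracs = []
        for seed in range(3):
            net = build_network(NetworkConfig(scale_factor=0.2, seed=seed))
            generate_connectivity(net)
            assign_mli_preference(net)
            mli = net.neurons[net.neurons.population.isin(["SC", "BC"])]
            fracs.append((mli.mli_pref == "downbound").mean())
        assert np.mean(fracs) == pytest.approx(0.70, abs=0.10)

    def test_every_mli_labelled(self, small_network):
        mli = small_network.neurons[
            small_network.neurons.population.isin(["SC", "BC"])]
        assert set(mli.mli_pref) <= {"downbound", "upbound"}
        assert (mli.mli_pref != "").all()


class TestSerialization:
    def test_round_trip_lossless(self, small_network, tmp_path):
        small_network.save(tmp_path / "net")
        back = Network.load(tmp_path / "net")
        pd.testing.assert_frame_equal(back.neurons, small_network.neurons)
        pd.testing.assert_frame_equal(back.synapses, small_network.synapses)
        assert back.config == small_network.config


class TestSpecTableFile:
    def test_shipped_table_round_trip(self, tmp_path):
        from pathlib import Path

        import cebsim
        from cebsim.scaffold import (load_connection_specs,
                                     save_connection_specs)
        shipped = Path(cebsim.__file__).parent / "data" / "connection_specs.yaml"
        specs = load_connection_specs(shipped)
        assert specs == default_connection_specs()
        save_connection_specs(specs, tmp_path / "t.yaml")
        assert load_connection_specs(tmp_path / "t.yaml") == specs
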