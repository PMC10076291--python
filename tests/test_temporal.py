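import numpy as np
import pytest

from spacerlink._dna import revcomp
from spacerlink.crispr_detect import detect_arrays
from spacerlink.io_formats import Scaffold
from spacerlink.synthetic_data import SyntheticConfig, generate_community, mutate, random_dna
from spacerlink.temporal import (
    ClusterParams,
    cluster_identity,
    cluster_viral,
    compare_arrays,
    compare_networks,
    dereplicate_mags,
    mash_ani,
    _sketch,
)
from spacerlink.vh_network import HostMAG, ViralElement, build_network
from spacerlink.spacer_match import ProtospacerMatch


def _interior_mutate(seq, n_subs, rng, margin=50):
    """Substitutions away from the ends, so local alignment spans the pair
    end-to-end and identity is exactly (L - n_subs) / L."""
    out = list(seq)
    positions = rng.choice(np.arange(margin, len(seq) - margin), size=n_subs, replace=False)
    for p in positions:
        alt = [b for b in "ACGT" if b != out[p]]
        out[p] = alt[rng.integers(3)]
    return "".join(out)


class TestClusterViral:
    def test_identical_pair_single_cluster_tie_rule(self):
        seq = random_dna(np.random.default_rng(0), 5000)
        asn = cluster_viral([Scaffold("b", seq), Scaffold("a", seq)])
        # equal lengths: lexicographically first id founds the cluster
        assert asn.assignment["a"] == ("VC0", "a", 1.0)
        assert asn.assignment["b"][0] == "VC0"
        assert asn.assignment["b"][1] == "a"

    def test_boundary_95_merges_94_splits(self, rng):
        base = random_dna(rng, 10000)
        s95 = _interior_mutate(base, 500, rng)   # identity exactly 0.9500
        s94 = _interior_mutate(base, 600, rng)   # identity exactly 0.9400
        assert cluster_identity(base, s95) == pytest.approx(0.95)
        assert cluster_identity(base, s94) == pytest.approx(0.94)
        asn = cluster_viral(
            [Scaffold("base", base), Scaffold("m95", s95), Scaffold("m94", s94)]
        )
        assert asn.cluster_of("m95") == asn.cluster_of("base")
        assert asn.cluster_of("m94") != asn.cluster_of("base")

    def test_reverse_complement_joins_cluster(self, rng):
        seq = random_dna(rng, 8000)
        asn = cluster_viral([Scaffold("fwd", seq), Scaffold("rc", revcomp(seq))])
        assert len(asn.clusters()) == 1

    def test_greedy_invariants_against_all_pairs(self, rng):
        """Canonical greedy property on a mixed set, checked by brute force:
        members reach their representative at >= c; no representative reaches
        an earlier representative."""
        seqs = []
        for i in range(10):
            base = random_dna(rng, 1500 + 100 * i)
            seqs.append(Scaffold(f"b{i}", base))
            if i % 2 == 0:
                seqs.append(Scaffold(f"d{i}", _interior_mutate(base, 30, rng, margin=20)))
        asn = cluster_viral(seqs)
        params = ClusterParams()
        reps_in_order = []
        for sc in sorted(seqs, key=lambda s: (-len(s.seq), s.id)):
            cid, rep, ident = asn.assignment[sc.id]
            if rep == sc.id:
                for earlier in reps_in_order:
                    assert cluster_identity(sc.seq, earlier.seq) < params.c
                reps_in_order.append(sc)
            else:
                rep_seq = next(s.seq for s in seqs if s.id == rep)
                assert cluster_identity(sc.seq, rep_seq) >= params.c
                assert ident >= params.c

    def test_generator_duplicates_recovered(self):
        cfg = SyntheticConfig(
            n_hosts=1, n_viruses=6, seed=31,
            viral_len_range=(9000, 11000),
            viral_duplicates=((0, 100), (3, 200)),  # ~99% and ~98% identity
        )
        com = generate_community(cfg)
        asn = cluster_viral(com.viral_scaffolds)
        for src, dup, _n in com.manifest.duplicate_pairs:
            assert asn.cluster_of(src) == asn.cluster_of(dup)


class TestDereplicateMags:
    def test_identical_duplicate_merges(self, rng):
        seq = random_dna(rng, 50000)
        pops = dereplicate_mags({"A": [Scaffold("a", seq)], "B": [Scaffold("b", seq)]})
        assert pops["A"] == pops["B"]

    def test_unrelated_mags_split(self, rng):
        pops = dereplicate_mags(
            {"A": [Scaffold("a", random_dna(rng, 100000))],
             "B": [Scaffold("b", random_dna(rng, 100000))]}
        )
        assert pops["A"] != pops["B"]

    def test_ani_estimate_matches_mash_arithmetic(self, rng):
        """2% substitutions: closed-form Mash ANI is 0.9798; the sketch
        estimate must land within +-0.01 and merge the pair at 0.95."""
        base = random_dna(rng, 100000)
        copy = mutate(base, 2000, rng)
        ska = _sketch([base], 21, 1000)
        skb = _sketch([copy], 21, 1000)
        ani = mash_ani(ska, skb, 21, 1000)
        assert ani == pytest.approx(0.9797972926824805, abs=0.01)
        pops = dereplicate_mags({"A": [Scaffold("a", base)], "B": [Scaffold("b", copy)]})
        assert pops["A"] == pops["B"]


def _two_networks():
    mags_a = [HostMAG(mag_id=f"HA{i}", completeness=90, contamination=1) for i in range(3)]
    mags_b = [HostMAG(mag_id=f"HB{i}", completeness=90, contamination=1) for i in range(3)]
    va = [ViralElement(viral_id=f"VA{i}", length=9000) for i in range(3)]
    vb = [ViralElement(viral_id=f"VB{i}", length=9000) for i in range(3)]

    def _m(h, v):
        return ProtospacerMatch(f"{h}{v}", h, v, 0, 30, "+", 0, 1.0, 60, 1e-10)

    net_a = build_network(
        [_m("HA0", "VA0"), _m("HA1", "VA1"), _m("HA2", "VA2")], mags_a, va, "2016"
    )
    net_b = build_network(
        [_m("HB0", "VB0"), _m("HB1", "VB1"), _m("HB2", "VB2")], mags_b, vb, "2017"
    )
    # population maps: HA0~HB0 same population; VA0~VB0, VA1~VB1 same clusters
    vmap = {"VA0": "C0", "VB0": "C0", "VA1": "C1", "VB1": "C1",
            "VA2": "C2", "VB2": "C3"}
    hmap = {"HA0": "P0", "HB0": "P0", "HA1": "P1", "HB1": "P2",
            "HA2": "P3", "HB2": "P4"}
    return net_a, net_b, vmap, hmap


class TestCompareNetworks:
    def test_identical_networks_full_overlap(self):
        net_a, _nb, vmap, hmap = _two_networks()
        rep = compare_networks(net_a, net_a, vmap, hmap)
        assert rep["pct_viral_a_in_network_b"] == 100.0
        assert rep["pct_mags_a_in_network_b"] == 100.0
        assert rep["shared_host_virus_pairs"] == net_a.unique_links

    def test_constructed_overlap_counts(self):
        net_a, net_b, vmap, hmap = _two_networks()
        rep = compare_networks(net_a, net_b, vmap, hmap)
        assert rep["shared_viral_populations_network"] == 2
        assert rep["pct_viral_a_in_network_b"] == pytest.approx(66.7)
        assert rep["shared_mag_populations_network"] == 1
        assert rep["pct_mags_a_in_network_b"] == pytest.approx(33.3)
        assert rep["shared_host_virus_pairs"] == 1  # (P0, C0)

    def test_fraction_formatting_one_decimal(self):
        from spacerlink._stats import percent

        assert percent(19, 59) == 32.2

    def test_missing_node_in_map_raises(self):
        from spacerlink.vh_network import ConsistencyError

        net_a, net_b, vmap, hmap = _two_networks()
        del vmap["VB2"]
        with pytest.raises(ConsistencyError):
            compare_networks(net_a, net_b, vmap, hmap)


def _array_from_parts(rng, repeat, spacers, flank_5p="", flank_3p=""):
    left = flank_5p or random_dna(rng, 300)
    right = flank_3p or random_dna(rng, 300)
    seq = left + repeat + "".join(s + repeat for s in spacers) + right
    sc = Scaffold("s", seq)
    arrays = detect_arrays(sc)
    assert len(arrays) == 1, "fixture array must be detectable"
    return arrays[0]


class TestCompareArrays:
    def _distinct_spacers(self, rng, n, length=34):
        out = []
        for i in range(n):
            s = random_dna(rng, length)
            out.append("ACGT"[i % 4] + s[1:-1] + "TGCA"[i % 4])
        return out

    def test_array_vs_itself(self, rng):
        repeat = random_dna(rng, 30)
        arr = _array_from_parts(rng, repeat, self._distinct_spacers(rng, 4))
        cmp = compare_arrays(arr, arr)
        assert cmp.shared_spacer_count == cmp.total_a == 4
        assert cmp.order_conserved

    def test_subset_array_order_conserved(self, rng):
        """A shorter early array that is a strict subset of the later one."""
        repeat = random_dna(rng, 30)
        spacers = self._distinct_spacers(rng, 6)
        long_arr = _array_from_parts(rng, repeat, spacers)
        short_arr = _array_from_parts(rng, repeat, spacers[2:5])
        cmp = compare_arrays(short_arr, long_arr)
        assert cmp.shared_spacer_count == 3
        assert cmp.order_conserved

    def test_no_shared_spacers_but_degraded_repeat_flank(self, rng):
        """Zero shared spacers with a mutated repeat copy in the flank is
        evidence of shared array origin."""
        repeat = random_dna(rng, 30)
        degraded = mutate(repeat, 6, rng)  # 80% identity copy
        a = _array_from_parts(
            rng, repeat, self._distinct_spacers(rng, 3),
            flank_5p=random_dna(rng, 200) + degraded + random_dna(rng, 40),
        )
        b = _array_from_parts(rng, repeat, self._distinct_spacers(rng, 3))
        cmp = compare_arrays(a, b)
        assert cmp.shared_spacer_count == 0
        assert cmp.flank_degraded_repeat
        assert "a:5p" in cmp.flank_location

    def test_shared_count_symmetric(self, rng):
        repeat = random_dna(rng, 28)
        spacers = self._distinct_spacers(rng, 5)
        a = _array_from_parts(rng, repeat, spacers[:4])
        b = _array_from_parts(rng, repeat, spacers[2:])
        assert (
            compare_arrays(a, b).shared_spacer_count
            == compare_arrays(b, a).shared_spacer_count
            == 2
        )
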