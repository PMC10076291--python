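import pytest

from spacerlink.spacer_match import ProtospacerMatch
from spacerlink.vh_network import (
    ConsistencyError,
    CrossTaxonCandidate,
    HostMAG,
    QualityParams,
    ViralElement,
    build_network,
    curate_cross_taxon,
    find_cross_taxon,
    find_hyper_targeted,
    quality_filter_mags,
    summarize_network,
)


def _mag(mag_id, completeness=90.0, contamination=1.0, phylum="Firmicutes",
         domain="Bacteria", site="LW1"):
    return HostMAG(
        mag_id=mag_id, completeness=completeness, contamination=contamination,
        lineage=(domain, phylum, "", "", "", "", ""), site=site, year=2016,
    )


def _virus(vid, site="GW1"):
    return ViralElement(viral_id=vid, length=10000, site=site, year=2016)


def _matches(host, virus, n, in_array=False):
    return [
        ProtospacerMatch(
            spacer_id=f"{host}:{virus}:{i}", owner_id=host, target_id=virus,
            start=100 * i, end=100 * i + 30, strand="+", n_mismatches=0,
            query_coverage=1.0, score=60, evalue=1e-10, in_array=in_array,
        )
        for i in range(n)
    ]


class TestQualityFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (70.13, 1.8, True),   # just above the completeness floor
            (70.0, 5.0, False),   # strict inequality on completeness
            (90.0, 10.0, False),  # strict inequality on contamination
            (100.0, 0.0, True),
            (70.01, 9.99, True),
        ],
    )
    def test_strict_boundaries(self, completeness, contamination, kept):
        mags = [_mag("M", completeness, contamination)]
        assert bool(quality_filter_mags(mags)) is kept


class TestBuildNetwork:
    def test_weight_counts_distinct_loci(self):
        ms = _matches("H0", "V0", 3)
        net = build_network(ms, [_mag("H0")], [_virus("V0")])
        assert net.unique_links == 1
        assert net.weights[("H0", "V0")] == 3

    def test_same_locus_from_two_spacers_counts_once(self):
        a = _matches("H0", "V0", 1)[0]
        b = _matches("H0", "V0", 1)[0]
        b.spacer_id = "other_spacer"
        net = build_network([a, b], [_mag("H0")], [_virus("V0")])
        assert net.weights[("H0", "V0")] == 1
        assert len(net.edges[("H0", "V0")]) == 2

    def test_in_array_matches_excluded(self):
        ms = _matches("H0", "V0", 2, in_array=True)
        net = build_network(ms, [_mag("H0")], [_virus("V0")])
        assert net.unique_links == 0

    def test_unknown_ids_raise(self):
        with pytest.raises(ConsistencyError):
            build_network(_matches("H9", "V0", 1), [_mag("H0")], [_virus("V0")])
        with pytest.raises(ConsistencyError):
            build_network(_matches("H0", "V9", 1), [_mag("H0")], [_virus("V0")])

    def test_generator_network_equals_manifest(self, small_community):
        from spacerlink.crispr_detect import detect_arrays, excise_spacers
        from spacerlink.spacer_match import (
            build_target_index,
            find_protospacers,
            flag_in_array,
        )

        com = small_community
        spacers = []
        for mag_id, scs in com.host_scaffolds.items():
            for sc in scs:
                for arr in detect_arrays(sc):
                    spacers.extend(excise_spacers(arr, mag_id))
        viral_arrays = [
            a for sc in com.viral_scaffolds for a in detect_arrays(sc)
        ]
        matches = find_protospacers(spacers, build_target_index(com.viral_scaffolds))
        matches = flag_in_array(matches, viral_arrays)
        net = build_network(matches, com.mags, com.virals, "recovery")
        # expected: planted <=1-mismatch links, plus targeting a host acquires
        # by integrating a CRISPR-encoding provirus (its array's protospacer
        # targets become the host's; spacer-spacer hits are flagged out)
        expected_w = {
            (h, v): n for h, v, n, mm in com.manifest.links if mm <= 1
        }
        for pv in com.manifest.proviruses:
            if pv.mode != "integrated":
                continue
            for p in com.manifest.protospacers:
                if p.spacer_owner_id == pv.virus_id and p.n_mismatches <= 1:
                    key = (pv.host_mag_id, p.virus_id)
                    expected_w[key] = expected_w.get(key, 0) + 1
        assert set(net.edges) == set(expected_w)
        assert net.weights == expected_w


class TestYearPairDesign:
    def test_four_year_combination_networks(self):
        """Two host years crossed with two virus years give four labeled
        networks (within-year and across-year in both directions)."""
        from spacerlink.crispr_detect import detect_arrays, excise_spacers
        from spacerlink.spacer_match import build_target_index, find_protospacers
        from spacerlink.synthetic_data import SyntheticConfig, generate_community

        communities = {
            year: generate_community(
                SyntheticConfig(
                    n_hosts=2, n_viruses=4, seed=50 + year, year=year,
                    planted_links=((0, 1, 2, 0), (1, 2, 2, 0)),
                )
            )
            for year in (2016, 2017)
        }
        spacers = {}
        for year, com in communities.items():
            sps = []
            for mag_id, scs in com.host_scaffolds.items():
                for sc in scs:
                    for arr in detect_arrays(sc):
                        sps.extend(excise_spacers(arr, mag_id))
            spacers[year] = sps
        nets = {}
        for hy in (2016, 2017):
            for vy in (2016, 2017):
                com_v = communities[vy]
                index = build_target_index(com_v.viral_scaffolds)
                ms = find_protospacers(spacers[hy], index)
                nets[(hy, vy)] = build_network(
                    ms, communities[hy].mags, com_v.virals,
                    label=f"{hy}-hosts-to-{vy}-viruses",
                )
        assert len(nets) == 4
        assert len({n.label for n in nets.values()}) == 4
        # within-year networks recover their planted links; spacers from one
        # year find nothing in the other year's independent viruses
        for y in (2016, 2017):
            assert set(nets[(y, y)].edges) == communities[y].manifest.links_with_max_mismatches(1)
        assert nets[(2016, 2017)].unique_links == 0
        assert nets[(2017, 2016)].unique_links == 0


class TestSummarize:
    def test_complete_bipartite(self):
        ms = []
        for h in ("H0", "H1"):
            for v in ("V0", "V1"):
                ms += _matches(h, v, 1)
        net = build_network(ms, [_mag("H0"), _mag("H1")], [_virus("V0"), _virus("V1")])
        s = summarize_network(net)
        assert (s["n_host_mags"], s["n_viral_scaffolds"], s["unique_links"]) == (2, 2, 4)
        assert s["pct_hosts_multi_viral"] == 100.0
        assert s["pct_virals_multi_host"] == 100.0

    def test_single_edge(self):
        net = build_network(_matches("H0", "V0", 1), [_mag("H0")], [_virus("V0")])
        s = summarize_network(net)
        assert (s["n_host_mags"], s["n_viral_scaffolds"], s["unique_links"]) == (1, 1, 1)
        assert s["pct_hosts_multi_viral"] == 0.0

    def test_summary_matches_brute_recount(self, rng):
        hosts = [_mag(f"H{i}") for i in range(5)]
        virals = [_virus(f"V{i}") for i in range(8)]
        ms = []
        pairs = set()
        while len(pairs) < 12:
            pairs.add((int(rng.integers(5)), int(rng.integers(8))))
        for h, v in pairs:
            ms += _matches(f"H{h}", f"V{v}", int(rng.integers(1, 4)))
        net = build_network(ms, hosts, virals)
        s = summarize_network(net)
        # brute-force recount from the raw pair list
        hd = {}
        vd = {}
        for h, v in pairs:
            hd[h] = hd.get(h, 0) + 1
            vd[v] = vd.get(v, 0) + 1
        assert s["unique_links"] == len(pairs)
        assert s["pct_hosts_multi_viral"] == pytest.approx(
            100 * sum(1 for d in hd.values() if d >= 2) / len(hd)
        )
        assert s["pct_virals_multi_host"] == pytest.approx(
            100 * sum(1 for d in vd.values() if d >= 2) / len(vd)
        )


class TestHyperTargeting:
    def test_threshold_boundary(self):
        ms = (
            _matches("H0", "V19", 19) + _matches("H1", "V20", 20) + _matches("H2", "V21", 21)
        )
        mags = [_mag(f"H{i}") for i in range(3)]
        virals = [_virus(v) for v in ("V19", "V20", "V21")]
        net = build_network(ms, mags, virals)
        hyper = find_hyper_targeted(net, threshold=20)
        assert [(v, h, n) for v, h, n in hyper] == [("V21", "H2", 21), ("V20", "H1", 20)]

    def test_two_hosts_per_virus_reported_separately(self):
        """A virus hyper-targeted by two hosts yields two records."""
        ms = _matches("H0", "V0", 25) + _matches("H1", "V0", 30)
        net = build_network(ms, [_mag("H0"), _mag("H1")], [_virus("V0")])
        assert len(find_hyper_targeted(net)) == 2


class TestCrossTaxon:
    def _net(self, host_specs, virus="V0"):
        mags = [
            _mag(h, phylum=p, domain=d) for h, p, d in host_specs
        ]
        ms = []
        for h, _p, _d in host_specs:
            ms += _matches(h, virus, 1)
        return build_network(ms, mags, [_virus(virus)]), mags

    def test_three_phyla_candidate(self):
        net, _ = self._net(
            [("H0", "Firmicutes", "Bacteria"),
             ("H1", "Patescibacteria", "Bacteria"),
             ("H2", "Muirbacteria", "Bacteria")]
        )
        cands = find_cross_taxon(net, "phylum")
        assert len(cands) == 1
        assert set(cands[0].rank_values) == {"Firmicutes", "Patescibacteria", "Muirbacteria"}

    def test_same_phylum_not_candidate(self):
        net, _ = self._net([("H0", "Firmicutes", "Bacteria"), ("H1", "Firmicutes", "Bacteria")])
        assert find_cross_taxon(net, "phylum") == []

    def test_archaeal_and_bacterial_domain_candidate(self):
        net, _ = self._net([("H0", "Firmicutes", "Bacteria"), ("H1", "Halobacteriota", "Archaea")])
        assert len(find_cross_taxon(net, "domain")) == 1

    def test_unrankable_host_not_counted(self):
        net, _ = self._net([("H0", "Firmicutes", "Bacteria"), ("H1", "", "Bacteria")])
        assert find_cross_taxon(net, "phylum") == []


class TestCuration:
    def _candidate(self, hosts=("H0", "H1")):
        return CrossTaxonCandidate(
            viral_id="V0", rank="phylum", host_ids=tuple(hosts),
            rank_values=("Firmicutes", "Patescibacteria"), unrankable_hosts=(),
        )

    def test_quality_failure_fails_verdict(self):
        mags = [_mag("H0", completeness=60.0), _mag("H1")]
        info = {"H0": [("s0", 20000, ["AAA"])], "H1": [("s1", 20000, ["CCC"])]}
        v = curate_cross_taxon([self._candidate()], mags, info)[0]
        assert not v.quality_ok and not v.passed
        assert any("quality" in r for r in v.reasons)

    def test_56_shared_spacers_pass_with_hgt_annotation(self):
        """Heavy identical-spacer sharing marks horizontal transfer but passes."""
        shared = [f"SP{i}" for i in range(56)]
        mags = [_mag("H0"), _mag("H1")]
        info = {
            "H0": [("s0", 20000, shared + ["X1"])],
            "H1": [("s1", 20000, shared + ["Y1"])],
        }
        v = curate_cross_taxon([self._candidate()], mags, info)[0]
        assert v.passed
        assert v.shared_spacer_counts[("H0", "H1")] == 56
        assert ("H0", "H1") in v.possible_hgt_pairs

    def test_incongruent_scaffold_taxonomy_fails(self):
        mags = [_mag("H0"), _mag("H1", phylum="Patescibacteria")]
        info = {"H0": [("s0", 20000, ["A"])], "H1": [("s1", 20000, ["B"])]}
        taxonomy = {"s1": ("Bacteria", "Firmicutes", "", "", "", "", "")}
        v = curate_cross_taxon([self._candidate()], mags, info, scaffold_taxonomy=taxonomy)[0]
        assert v.taxonomy_ok is False and not v.passed

    def test_short_scaffold_flag_does_not_fail(self):
        mags = [_mag("H0"), _mag("H1")]
        info = {"H0": [("s0", 3000, ["A"])], "H1": [("s1", 20000, ["B"])]}
        v = curate_cross_taxon([self._candidate()], mags, info)[0]
        assert v.short_scaffold_hosts == ("H0",)
        assert v.passed
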