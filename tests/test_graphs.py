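"""AV-net / V-net construction, degrees, components, and round-trips."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from avnet.graphs import (audio_id, build_av_net, build_phono_layer,
                          build_v_net, build_viseme_layer, components,
                          graph_summary, lec_degree, read_graphml, visual_id,
                          write_graphml)
from avnet.lexicon import (Lexicon, WordEntry, default_viseme_map,
                           lec_partition, phonological_neighbors)
from avnet.synthetic import LexiconGenSpec, generate_lexicon
from conftest import bfs_components

VMAP = default_viseme_map()


def entries(*phonos):
    return Lexicon([WordEntry(p, p) for p in phonos])


class TestPhonoLayer:
    def test_single_substitution_edge(self):
        g = build_phono_layer(entries("pEt", "bEt"))
        assert set(g.nodes) == {"pEtA", "bEtA"}
        assert g.number_of_edges() == 1

    def test_unrelated_words_unconnected(self):
        g = build_phono_layer(entries("pEt", "mun"))
        assert g.number_of_edges() == 0

    def test_addition_deletion_edges_across_lengths(self):
        g = build_phono_layer(entries("pEt", "pEts", "Et"))
        assert g.has_edge("pEtA", "pEtsA")
        assert g.has_edge("pEtA", "EtA")
        assert not g.has_edge("EtA", "pEtsA")

    def test_degree_equals_neighbor_count_on_synthetic_lexicon(self):
        lex = generate_lexicon(LexiconGenSpec(n_words=200, seed=3))
        g = build_phono_layer(lex)
        for e in lex:
            assert g.degree(audio_id(e.phono)) == \
                len(phonological_neighbors(e, lex))


class TestVisemeLayer:
    def test_single_viseme_substitution_edge(self):
        g = build_viseme_layer({"bes": set(), "beC": set()})
        assert g.has_edge("besV", "beCV")

    def test_multi_substitution_no_edge(self):
        g = build_viseme_layer({"bes": set(), "kon": set()})
        assert g.number_of_edges() == 0

    def test_unequal_lengths_never_connected(self):
        g = build_viseme_layer({"bes": set(), "bess": set()})
        assert g.number_of_edges() == 0

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            build_viseme_layer({})

    def test_edges_match_brute_force_hamming_scan(self):
        rng = np.random.default_rng(11)
        classes = {"".join(rng.choice(list("bfTwrCskneoaW"),
                                      size=rng.integers(2, 5)))
                   for _ in range(100)}
        g = build_viseme_layer({v: set() for v in classes})
        expected = {
            frozenset((a, b)) for a, b in combinations(classes, 2)
            if len(a) == len(b)
            and sum(x != y for x, y in zip(a, b)) == 1
        }
        got = {frozenset((g.nodes[u]["payload"], g.nodes[v]["payload"]))
               for u, v in g.edges}
        assert got == expected


class TestAvNet:
    def test_node_and_interlayer_counts(self, toy_lexicon):
        # 5 words in 3 LECs -> 8 nodes, 5 interlayer edges
        av = build_av_net(toy_lexicon)
        s = graph_summary(av)
        assert s["n_audio_nodes"] == 5
        assert s["n_visual_nodes"] == 3
        assert s["n_interlayer_edges"] == 5

    def test_three_words_two_lecs(self):
        av = build_av_net(entries("bEl", "mEn", "kup"))
        s = graph_summary(av)
        assert s["n_nodes"] == 5 and s["n_interlayer_edges"] == 3

    def test_every_audio_node_has_exactly_one_interlayer_edge(self, toy_lexicon):
        av = build_av_net(toy_lexicon)
        for n, d in av.nodes(data=True):
            if d["layer"] == "audio":
                inter = [1 for _, _, t in av.edges(n, data="edge_type")
                         if t == "interlayer"]
                assert len(inter) == 1

    def test_edges_respect_layer_constraints(self, toy_lexicon):
        av = build_av_net(toy_lexicon)
        expected = {"phono": ("audio", "audio"),
                    "viseme": ("visual", "visual"),
                    "interlayer": ("audio", "visual")}
        for u, v, t in av.edges(data="edge_type"):
            layers = tuple(sorted((av.nodes[u]["layer"], av.nodes[v]["layer"])))
            assert layers == tuple(sorted(expected[t]))

    def test_synthetic_av_net_is_single_component(self):
        # dense CVC lexicons connect fully through the viseme layer
        lex = generate_lexicon(LexiconGenSpec(n_words=500, seed=5))
        av = build_av_net(lex)
        assert len(components(av)) == 1


class TestVNet:
    def test_ablation_keeps_only_viseme_structure(self, toy_lexicon):
        av = build_av_net(toy_lexicon)
        v = build_v_net(av)
        assert all(d["layer"] == "visual" for _, d in v.nodes(data=True))
        assert all(t == "viseme" for _, _, t in v.edges(data="edge_type"))

    def test_equals_direct_viseme_layer_build(self, toy_lexicon):
        av = build_av_net(toy_lexicon)
        direct = build_viseme_layer(lec_partition(toy_lexicon, VMAP))
        v = build_v_net(av)
        assert set(v.nodes) == set(direct.nodes)
        assert {frozenset(e) for e in v.edges} == \
            {frozenset(e) for e in direct.edges}

    def test_visual_degrees_preserved(self, toy_lexicon):
        av = build_av_net(toy_lexicon)
        v = build_v_net(av)
        for n in v.nodes:
            assert v.degree(n) == lec_degree(n, av)


class TestComponentsAndDegree:
    def test_star_single_component(self):
        g = nx.star_graph(4)
        assert len(components(g)) == 1

    def test_two_disjoint_edges(self):
        g = nx.Graph([(0, 1), (2, 3)])
        assert len(components(g)) == 2

    def test_agrees_with_bfs_oracle(self, random_graphs):
        for g in random_graphs:
            got = components(g)
            want = bfs_components(g)
            assert sorted(map(sorted, got)) == sorted(map(sorted, want))

    def test_lec_degree_counts_only_viseme_edges(self, toy_lexicon):
        av = build_av_net(toy_lexicon)
        # "bes" and "ben" differ in one viseme; "kob" differs from both in 2+
        assert lec_degree(visual_id("bes"), av) == 1
        assert lec_degree(visual_id("kob"), av) == 0

    def test_lec_degree_matches_hamming_scan(self):
        lex = generate_lexicon(LexiconGenSpec(n_words=150, seed=9))
        av = build_av_net(lex)
        keys = list(lec_partition(lex, VMAP))
        for v in keys:
            want = sum(1 for u in keys
                       if len(u) == len(v)
                       and sum(a != b for a, b in zip(u, v)) == 1)
            assert lec_degree(visual_id(v), av) == want

    def test_lec_degree_rejects_bad_nodes(self, toy_lexicon):
        av = build_av_net(toy_lexicon)
        with pytest.raises(KeyError):
            lec_degree("nopeV", av)
        with pytest.raises(ValueError):
            lec_degree(audio_id("pEt"), av)


class TestRoundTrip:
    def test_graphml_preserves_nodes_edges_and_tags(self, toy_lexicon, tmp_path):
        av = build_av_net(toy_lexicon)
        path = tmp_path / "av.graphml"
        write_graphml(av, path)
        back = read_graphml(path)
        assert set(back.nodes) == set(av.nodes)
        assert {frozenset(e) for e in back.edges} == \
            {frozenset(e) for e in av.edges}
        for n in av.nodes:
            assert back.nodes[n]["layer"] == av.nodes[n]["layer"]
            assert back.nodes[n]["payload"] == av.nodes[n]["payload"]
        for u, v, t in av.edges(data="edge_type"):
            assert back.edges[u, v]["edge_type"] == t
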