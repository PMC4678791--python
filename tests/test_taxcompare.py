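import random

import pytest

from _oracles import brute_force_clusters, random_binary_topology, to_newick, tree_leaves

from cvtree import (
    Lineage,
    LineageTable,
    apply_modifications,
    collapse,
    full_report,
    monophyly_status,
    read_newick,
    taxon_members,
)
from cvtree.io_lineage import RANKS, UNCLASSIFIED, parse_lineage_line
from cvtree.taxcompare import (
    collapsed_newick,
    collapsed_text,
    format_nm,
    report_summary,
    report_to_frame,
)


def table_from(lines):
    return LineageTable(dict(parse_lineage_line(ln) for ln in lines))


class TestFormatNM:
    @pytest.mark.parametrize(
        "n,m,expected", [(5, 0, "{5}"), (0, 3, "{0 + 3}"), (2, 7, "{2 + 7}")]
    )
    def test_rendering_rules(self, n, m, expected):
        assert format_nm(n, m) == expected


class TestTaxonMembers:
    def test_complete_incomplete_split(self):
        lt = table_from(
            [
                "g1 <D>B<K>k<P>Firmicutes<C>c<O>o<F>f<G>g<S>s<T>t",
                "g2 <D>B<K>k<P>Firmicutes",
            ]
        )
        groups = taxon_members(lt, "P")
        key = ("B", "k", "Firmicutes")
        assert groups[key] == ({"g1"}, {"g2"})  # the {1 + 1} split

    def test_unclassified_forms_its_own_bucket(self):
        lt = table_from(["g1 <D>B<P>Firmicutes", "g2 <D>B"])
        groups = taxon_members(lt, "P")
        assert ("B", UNCLASSIFIED, UNCLASSIFIED) in groups
        assert groups[("B", UNCLASSIFIED, UNCLASSIFIED)][1] == {"g2"}

    def test_empty_table_gives_empty_map(self):
        assert taxon_members(LineageTable({}), "P") == {}

    def test_homonyms_under_different_parents_stay_apart(self):
        lt = table_from(["g1 <D>B<K>k1<P>SameName", "g2 <D>B<K>k2<P>SameName"])
        groups = taxon_members(lt, "P")
        assert len(groups) == 2


class TestMonophylyStatus:
    def test_exact_clade_is_monophyletic(self):
        t = read_newick("((a,b),(c,d));")
        s = monophyly_status(t, {"a", "b"}, name="X")
        assert s.status == "monophyletic"
        assert s.clusters == [2]

    def test_split_members_are_convergent(self):
        t = read_newick("((a,b),(c,d));")
        s = monophyly_status(t, {"a", "c"}, name="X")
        assert s.status == "convergent"
        assert s.clusters == [1, 1]
        assert s.render() == "X{1/2}, X{1/2}"

    def test_nested_clade_is_monophyletic(self):
        t = read_newick("(((a,b),c),(d,e));")
        s = monophyly_status(t, {"a", "b", "c"})
        assert s.status == "monophyletic"
        assert s.clusters == [3]

    def test_singleton_is_flagged_separately(self):
        t = read_newick("((a,b),(c,d));")
        assert monophyly_status(t, {"a"}).status == "singleton"

    def test_unknown_member_is_an_error(self):
        t = read_newick("((a,b),(c,d));")
        with pytest.raises(KeyError):
            monophyly_status(t, {"a", "zzz"})

    def test_cluster_sizes_sum_to_member_count(self):
        t = read_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        s = monophyly_status(t, {"a", "c", "e", "f"})
        assert sum(s.clusters) == 4

    def test_unrooted_mode_ignores_root_placement(self):
        # rooted reading splits {c,d}: root child clades are (a,(b,(c,d)))
        t = read_newick("(a,(b,(c,d)));")
        t2 = read_newick("(c,(d,(a,b)));")  # same unrooted topology, re-rooted
        for members in ({"a", "b"}, {"c", "d"}):
            s1 = monophyly_status(t, members, rooted=False)
            s2 = monophyly_status(t2, members, rooted=False)
            assert s1.status == s2.status == "monophyletic"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_clade_enumeration(self, seed):
        rng = random.Random(seed)
        for _ in range(100):
            n = rng.randint(3, 12)
            labels = [f"x{i}" for i in range(n)]
            topo = random_binary_topology(labels, rng)
            tree = read_newick(to_newick(topo))
            members = set(rng.sample(labels, rng.randint(1, n)))
            expected = brute_force_clusters(topo, members)
            got = monophyly_status(tree, members)
            assert got.clusters == expected


class TestCollapse:
    def lineage_for_two_phyla(self):
        return table_from(
            [
                "a <D>Bact<K>k<P>Firmicutes",
                "b <D>Bact<K>k<P>Firmicutes",
                "c <D>Bact<K>k<P>Tenericutes",
                "d <D>Bact<K>k<P>Tenericutes",
            ]
        )

    def test_shared_domain_collapses_to_one_node(self):
        t = read_newick("((a,b),(c,d));")
        lt = self.lineage_for_two_phyla()
        node = collapse(t, lt, max_rank="D")
        assert node.is_leaf
        assert node.label == "<D>Bact{0 + 4}"
        assert node.member_ids == frozenset("abcd")

    def test_mixed_phyla_collapse_to_two_children(self):
        t = read_newick("((a,b),(c,d));")
        lt = self.lineage_for_two_phyla()
        node = collapse(t, lt, max_rank="P")
        leaves = node.leaf_nodes()
        assert len(leaves) == 2
        assert {lf.label for lf in leaves} == {
            "<P>Firmicutes{0 + 2}",
            "<P>Tenericutes{0 + 2}",
        }

    def test_no_shared_ranks_leaves_singletons(self):
        t = read_newick("((a,b),(c,d));")
        lt = table_from([f"{g} <P>phy_{g}" for g in "abcd"])
        node = collapse(t, lt, max_rank="P")
        assert len(node.leaf_nodes()) == 4
        assert {lf.label for lf in node.leaf_nodes()} == {
            f"<P>phy_{g}{{0 + 1}}" for g in "abcd"
        }

    def test_unclassified_never_licenses_collapsing(self):
        t = read_newick("((a,b),(c,d));")
        lt = table_from([f"{g} <D>Bact" for g in "ab"] + [f"{g} " + "<D>Arch" for g in "cd"])
        # at rank P everything is Unclassified below the domain; collapse at P
        node = collapse(t, lt, max_rank="P")
        labels = {lf.label for lf in node.leaf_nodes()}
        assert labels == {"<D>Bact{0 + 2}", "<D>Arch{0 + 2}"}

    def test_incomplete_genomes_counted_in_m_inside_named_taxon(self):
        lt = table_from(
            [
                "a <D>B<K>k<P>Firm<C>c<O>o<F>f<G>g<S>s<T>t",
                "b <D>B<K>k<P>Firm",
            ]
        )
        t = read_newick("((a,b),(c,d));")
        lt.entries["c"] = Lineage.unclassified()
        lt.entries["d"] = Lineage.unclassified()
        node = collapse(t, lt, max_rank="P")
        labels = {lf.label for lf in node.leaf_nodes()}
        assert "<P>Firm{1 + 1}" in labels
        # fully unclassified genomes stay expanded under their own ids
        assert {"c", "d"} <= labels

    def test_conservation_of_genomes(self, small_sim):
        _, tree, lt = small_sim
        for rank in RANKS:
            node = collapse(tree, lt, max_rank=rank)
            assert node.all_member_ids() == {lf.taxon.label for lf in tree.leaf_node_iter()}
            assert sum(len(lf.member_ids) for lf in node.leaf_nodes()) == len(lt)

    def test_monophyletic_iff_single_collapsed_node(self, small_sim):
        _, tree, lt = small_sim
        for rank in ("K", "P"):
            node = collapse(tree, lt, max_rank=rank)
            per_name: dict[str, int] = {}
            for lf in node.leaf_nodes():
                if lf.rank == rank:
                    per_name[lf.name] = per_name.get(lf.name, 0) + 1
            for prefix, (comp, incomp) in taxon_members(lt, rank).items():
                if prefix[-1] == UNCLASSIFIED:
                    continue
                status = monophyly_status(tree, comp | incomp)
                if status.status in ("monophyletic", "singleton"):
                    assert per_name.get(prefix[-1]) == 1

    def test_newick_and_text_renderings(self):
        t = read_newick("((a,b),(c,d));")
        node = collapse(t, self.lineage_for_two_phyla(), max_rank="P")
        nwk = collapsed_newick(node)
        assert nwk.endswith(";")
        assert "'<P>Firmicutes{0 + 2}'" in nwk
        text = collapsed_text(node)
        assert "<P>Tenericutes{0 + 2}" in text


class TestFullReport:
    def test_constructed_two_phyla_both_monophyletic(self):
        t = read_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        lt = table_from(
            [f"{g} <D>B<P>PhyOne" for g in "abcd"] + [f"{g} <D>B<P>PhyTwo" for g in "efgh"]
        )
        rep = full_report(t, lt)
        phyla = [s for s in rep if s.rank == "P"]
        assert len(phyla) == 2
        assert all(s.status == "monophyletic" for s in phyla)

    def test_three_one_split_is_convergent(self):
        t = read_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        lt = table_from(
            [f"{g} <D>B<P>PhyOne" for g in "abc"]
            + ["d <D>B<P>PhyTwo"]
            + [f"{g} <D>B<P>PhyTwo" for g in "efgh"]
        )
        rep = full_report(t, lt)
        one = next(s for s in rep if s.name == "PhyOne")
        assert one.status == "convergent"
        assert one.clusters == [2, 1]  # (a,b) clade plus c
        two = next(s for s in rep if s.name == "PhyTwo")
        assert two.clusters == [4, 1]

    def test_strain_rank_excluded_and_sorted(self, small_sim):
        _, tree, lt = small_sim
        rep = full_report(tree, lt)
        assert all(s.rank != "T" for s in rep)
        for rank in set(s.rank for s in rep):
            sizes = [s.n_members for s in rep if s.rank == rank]
            assert sizes == sorted(sizes, reverse=True)

    def test_true_tree_reports_all_named_taxa_monophyletic(self, small_sim):
        _, tree, lt = small_sim
        rep = full_report(tree, lt)
        assert rep, "synthetic project must yield taxa"
        assert all(s.status in ("monophyletic", "singleton") for s in rep)

    def test_summary_counts_match_report(self, small_sim):
        _, tree, lt = small_sim
        rep = full_report(tree, lt)
        summary = report_summary(rep)
        total = summary[["monophyletic", "convergent", "singleton"]].sum().sum()
        assert total == len(rep)

    def test_cluster_sums_equal_member_counts_everywhere(self, small_sim):
        _, tree, lt = small_sim
        for s in full_report(tree, lt):
            assert sum(s.clusters) == s.n_members

    def test_modifications_change_only_touched_taxa(self, small_sim):
        _, tree, lt = small_sim
        mods = LineageTable({"g01": Lineage(
            {**Lineage.unclassified().names, "P": "taxP_g03"}
        )})
        lt2 = apply_modifications(lt, mods)
        before = {(s.rank, s.prefix): (s.status, tuple(s.clusters)) for s in full_report(tree, lt)}
        after = {(s.rank, s.prefix): (s.status, tuple(s.clusters)) for s in full_report(tree, lt2)}
        changed_names = {k for k in set(before) | set(after)
                         if before.get(k) != after.get(k)}
        # only the donor and recipient phylum-level taxa may change
        assert changed_names
        assert all(any(name.startswith("taxP_") for name in key[1]) or key[0] == "P"
                   for key in changed_names)

    def test_report_frame_columns(self, small_sim):
        _, tree, lt = small_sim
        frame = report_to_frame(full_report(tree, lt))
        assert list(frame.columns) == ["rank", "name", "n", "m", "status", "clusters", "rendered"]
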