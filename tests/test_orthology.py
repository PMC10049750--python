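"""Orthology assignment: translation, profile scoring, the E-value and
quartile filters, reciprocal best hit, and ground-truth recovery."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from polymatrix import orthology
from polymatrix.orthology import (
    EmpiricalNull,
    Hit,
    HitTable,
    build_profile,
    filter_hits,
    reciprocal_best_hit,
    score_query,
    translate_six_frames,
)
from polymatrix.simulate import simulate_cluster, simulate_gene_family, simulate_species_tree
from polymatrix.submat import Cluster


class TestTranslation:
    def test_forward_frame(self):
        assert translate_six_frames("ATGGCC")[0] == "MA"

    def test_short_sequence_frame_lengths(self):
        frames = translate_six_frames("ATG")
        assert [len(f) for f in frames[:3]] == [1, 0, 0]

    def test_reverse_frames_match_reverse_complement(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 300))
        frames = translate_six_frames(seq)
        rc = str(Seq(seq).reverse_complement())
        for offset in range(3):
            sub = rc[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            assert frames[3 + offset] == str(Seq(sub).translate())

    def test_empty_input(self):
        assert translate_six_frames("") == [""] * 6


@pytest.fixture(scope="module")
def profile_setup(protein_matrix):
    cluster = simulate_cluster(4, 80, 0.95, seed=20)
    members = [("ref_taxon", "ref_seq", cluster.members[0][2])] + [
        (t, s, seq) for t, s, seq in cluster.members[1:]
    ]
    cluster = Cluster(id="OG1", members=members)
    profile = build_profile(cluster, protein_matrix, "ref_taxon")
    return cluster, profile


class TestProfileScoring:
    def test_reference_member_required(self, protein_matrix):
        cluster = simulate_cluster(3, 50, 0.9, seed=1)
        with pytest.raises(ValueError):
            build_profile(cluster, protein_matrix, "not_present")

    def test_consensus_scores_highest(self, profile_setup, protein_matrix):
        cluster, profile = profile_setup
        null = EmpiricalNull(seed=1)
        rng = np.random.default_rng(3)
        consensus_hit = score_query(profile, profile.consensus, null)
        for _ in range(10):
            other = "".join(
                rng.choice(list(protein_matrix.alphabet), len(profile.consensus))
            )
            h = score_query(profile, other, null, min_score=-math.inf)
            assert h is None or h.score <= consensus_hit.score

    def test_true_member_has_tiny_evalue_shuffled_does_not(self, profile_setup):
        cluster, profile = profile_setup
        null = EmpiricalNull(seed=1)
        member = cluster.members[1][2]
        hit = score_query(profile, member, null)
        assert hit is not None and hit.evalue <= 1e-5
        rng = np.random.default_rng(4)
        shuffled = "".join(rng.permutation(list(member)))
        bad = score_query(profile, shuffled, null, min_score=-math.inf)
        assert bad is None or bad.evalue > 1e-5

    def test_short_query_skipped(self, profile_setup):
        _, profile = profile_setup
        assert score_query(profile, "MA", EmpiricalNull(seed=1)) is None


class TestFilterHits:
    def _hits(self, scores, evalues=None, group="g"):
        evalues = evalues or [1e-9] * len(scores)
        return HitTable([
            Hit(query_id=f"q{i}", group_id=group, score=s, evalue=e, start=0, end=10)
            for i, (s, e) in enumerate(zip(scores, evalues))
        ])

    def test_four_distinct_scores_keep_best(self):
        out = filter_hits(self._hits([10, 8, 6, 4]))
        assert [h.score for h in out.hits] == [10]

    def test_single_passing_hit_kept(self):
        out = filter_hits(self._hits([5.0]))
        assert len(out) == 1

    def test_boundary_ties_all_retained(self):
        out = filter_hits(self._hits([10, 9, 9, 8, 7, 6, 5, 4]))
        assert sorted(h.score for h in out.hits) == [9, 9, 10]

    def test_evalue_cutoff_applied_first(self):
        out = filter_hits(self._hits([10, 9], evalues=[1e-3, 1e-9]))
        assert [h.score for h in out.hits] == [9]

    def test_subset_and_idempotent(self):
        table = self._hits([9, 7, 5, 3, 1], group="g1")
        once = filter_hits(table)
        twice = filter_hits(once)
        ids = {h.query_id for h in table}
        assert {h.query_id for h in once.hits} <= ids
        assert [h.query_id for h in twice.hits] == [h.query_id for h in once.hits]

    def test_per_group_not_global(self):
        hits = self._hits([10, 1], group="g1").hits + self._hits([5], group="g2").hits
        out = filter_hits(HitTable(hits))
        assert {h.group_id for h in out.hits} == {"g1", "g2"}


class TestReciprocalBestHit:
    def test_exact_copy_accepted(self, profile_setup, protein_matrix):
        cluster, profile = profile_setup
        ref = cluster.members[0][2]
        proteome = {"ref_seq": ref, "other": "W" * 40}
        result = reciprocal_best_hit("cand", ref, profile, proteome, protein_matrix)
        assert result.accepted

    def test_forward_mismatch_rejected(self, profile_setup, protein_matrix):
        cluster, profile = profile_setup
        decoy_target = simulate_cluster(2, 80, 0.95, seed=77).members[0][2]
        proteome = {"ref_seq": cluster.members[0][2], "decoy": decoy_target}
        result = reciprocal_best_hit(
            "cand", decoy_target, profile, proteome, protein_matrix
        )
        assert not result.accepted
        assert result.reason == "forward best-hit mismatch"

    def test_reverse_mismatch_rejected(self, profile_setup, protein_matrix):
        cluster, profile = profile_setup
        ref = cluster.members[0][2]
        # another candidate from the same taxon aligns better to the reference
        candidate = cluster.members[1][2]
        pool = {"cand": candidate, "better": ref}
        result = reciprocal_best_hit(
            "cand", candidate, profile, {"ref_seq": ref}, protein_matrix,
            taxon_candidates=pool,
        )
        assert not result.accepted
        assert result.reason == "reverse best-hit mismatch"

    def test_empty_proteome_rejected(self, profile_setup, protein_matrix):
        _, profile = profile_setup
        with pytest.raises(ValueError):
            reciprocal_best_hit("c", "MA", profile, {}, protein_matrix)

    def test_out_paralog_vs_brute_force_scores(self, protein_matrix):
        """The RBH forward direction agrees with all-vs-all best scores."""
        from polymatrix.align import smith_waterman

        fam_a = simulate_cluster(3, 60, 0.9, seed=31)
        fam_b = simulate_cluster(3, 60, 0.9, seed=32)
        proteome = {"refA": fam_a.members[0][2], "refB": fam_b.members[0][2]}
        cluster = Cluster(
            id="A", members=[("ref_taxon", "refA", fam_a.members[0][2])]
        )
        profile = build_profile(cluster, protein_matrix, "ref_taxon")
        # a member of family B must lose the forward test against profile A
        candidate = fam_b.members[1][2]
        scores = {
            rid: smith_waterman(candidate, seq, protein_matrix).score
            for rid, seq in proteome.items()
        }
        result = reciprocal_best_hit("c", candidate, profile, proteome, protein_matrix)
        assert max(scores, key=scores.get) == "refB"
        assert not result.accepted


class TestAssignOrthologs:
    def test_recovers_one_to_one_families(self, protein_matrix):
        sp = simulate_species_tree(5, seed=40)
        taxa = sorted(t.label for t in sp.taxon_namespace)
        ref_taxon = taxa[0]
        profiles, proteome, queries = [], {}, {t: {} for t in taxa}
        families = [simulate_gene_family(sp, 0.0, 0.0, seed=s) for s in (41, 42)]
        for g, fam in enumerate(families):
            gid = f"OG{g}"
            ref_label = f"{ref_taxon}@copy1"
            proteome[f"{gid}_ref"] = fam.sequences[ref_label]
            cluster = Cluster(
                id=gid, members=[(ref_taxon, f"{gid}_ref", fam.sequences[ref_label])]
            )
            profiles.append(build_profile(cluster, protein_matrix, ref_taxon))
            for label, seq in fam.sequences.items():
                taxon = label.split("@")[0]
                if taxon != ref_taxon:
                    queries[taxon][f"{gid}:{label}"] = seq
        groups = orthology.assign_orthologs(
            queries, profiles, proteome, protein_matrix,
            null=EmpiricalNull(seed=0),
        )
        for g, group in enumerate(groups):
            assert group.taxa == set(taxa) - {ref_taxon}
            for taxon, entries in group.members.items():
                assert len(entries) == 1
                sid, seq = entries[0]
                assert sid.startswith(f"OG{g}:")

    def test_decoy_absent_from_all_groups(self, protein_matrix):
        sp = simulate_species_tree(4, seed=50)
        taxa = sorted(t.label for t in sp.taxon_namespace)
        ref_taxon = taxa[0]
        fam = simulate_gene_family(sp, 0.0, 0.0, seed=51)
        proteome = {"OG0_ref": fam.sequences[f"{ref_taxon}@copy1"]}
        cluster = Cluster(
            id="OG0", members=[(ref_taxon, "OG0_ref", proteome["OG0_ref"])]
        )
        profiles = [build_profile(cluster, protein_matrix, ref_taxon)]
        rng = np.random.default_rng(52)
        decoy = "".join(rng.choice(list(protein_matrix.alphabet), 120))
        queries = {taxa[1]: {
            "true": fam.sequences[f"{taxa[1]}@copy1"],
            "decoy": decoy,
        }}
        groups = orthology.assign_orthologs(
            queries, profiles, proteome, protein_matrix, null=EmpiricalNull(seed=0)
        )
        members = [sid for g in groups for v in g.members.values() for sid, _ in v]
        assert "decoy" not in members

    def test_empty_queries_give_empty_groups(self, protein_matrix, profile_setup):
        _, profile = profile_setup
        groups = orthology.assign_orthologs(
            {}, [profile], {"ref_seq": "MA" * 20}, protein_matrix
        )
        assert all(not g.members for g in groups)

    def test_invalid_quartile_rejected(self, protein_matrix, profile_setup):
        _, profile = profile_setup
        with pytest.raises(ValueError):
            orthology.assign_orthologs(
                {}, [profile], {"r": "MA"}, protein_matrix, quartile_fraction=0.0
            )


class TestHmmerImport:
    DOMTBL = """\
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
t1::q1               -            100 OG0                  -            80    1e-30  200.0   0.0   1   1   1e-32     1e-30  199.0   0.0     1    80     5    84     5    84  0.98 -
t2::q2               -            100 OG0                  -            80    0.5      8.0   0.0   1   1   0.6       0.9      7.0   0.0     1    50     2    52     2    52  0.80 -
"""

    def test_parse_and_filter(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        path.write_text(self.DOMTBL)
        table = orthology.read_hmmer_domtbl(path)
        assert len(table) == 2
        assert table.provenance == "hmmer-import"
        kept = filter_hits(table)
        assert [h.query_id for h in kept.hits] == ["t1::q1"]
        assert kept.hits[0].start == 4 and kept.hits[0].end == 84
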