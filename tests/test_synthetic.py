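"""The fixture generators: determinism, planted signals, degradation."""

import pandas as pd
import pytest
from scipy.stats import binomtest

from tpsinv.classify import classify_panel
from tpsinv.motifs import count_qw, detect_tm_helix, scan
from tpsinv.synthetic import (
    ClusterLayout,
    CtDesign,
    PanelSpec,
    generate_cluster_locus,
    generate_ct_table,
    generate_protein_panel,
    mutate_sequence,
)


class TestMutateSequence:
    def test_zero_rate_identity(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        assert mutate_sequence(seq, 0.0, set(), seed=1) == seq

    def test_full_protection_identity(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        assert mutate_sequence(seq, 0.999, set(range(len(seq))), seed=1) == seq

    def test_length_preserved_and_only_outside_protected(self):
        seq = "A" * 200
        protected = set(range(50, 100))
        out = mutate_sequence(seq, 0.5, protected, seed=3)
        assert len(out) == len(seq)
        assert out[50:100] == seq[50:100]

    def test_substitution_fraction_matches_rate(self):
        """Observed substitutions fall in the binomial 99% interval for p=0.05."""
        n, rate = 10_000, 0.05
        out = mutate_sequence("A" * n, rate, set(), seed=7)
        k = sum(1 for c in out if c != "A")
        assert binomtest(k, n, rate).pvalue >= 0.01

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("AAAA", 1.0, set(), seed=0)


class TestProteinPanel:
    def test_one_protein_per_leaf(self, clean_panel, taxonomy):
        records, _, truth = clean_panel
        assert len(records) == 15
        assert set(truth["group_id"]) == {g.id for g in taxonomy.leaves}

    def test_seed_determinism_bytes(self):
        spec = PanelSpec(n_per_group=2, mutation_rate=0.1, seed=7)
        a = generate_protein_panel(spec)
        b = generate_protein_panel(spec)
        assert a[0] == b[0]
        assert a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_planted_motifs_present_verbatim(self, clean_panel, patterns):
        records, _, truth = clean_panel
        seqs = dict(records)
        required = {
            "tri5": {"tri5_aspartate", "tri5_triad"},
            "had_bifunctional": {"DDxxE", "DxDTT"},
            "class2_diterpene": {"DxDD"},
            "oxidosqualene_cyclase": {"DCTAE_family", "QW"},
        }
        for _, row in truth.iterrows():
            names = {h.pattern_name for h in scan(seqs[row.protein_id], patterns)}
            assert required.get(row.group_id, set()) <= names

    def test_osc_has_exactly_five_qw(self, clean_panel):
        seqs = dict(clean_panel[0])
        assert count_qw(seqs["oxidosqualene_cyclase_01"]) == 5

    def test_sqs_tm_helix_is_23_residues(self, clean_panel):
        seqs = dict(clean_panel[0])
        res = detect_tm_helix(seqs["squalene_synthase_01"])
        assert res is not None
        assert res[1] == 23

    def test_domain_rows_carry_group_accessions(self, clean_panel):
        _, domains, _ = clean_panel
        by_protein = {}
        for d in domains:
            by_protein.setdefault(d.protein_id, set()).add(d.accession)
        assert by_protein["tri5_01"] == {"PF06330", "PIRSF001388"}
        assert by_protein["squalene_synthase_01"] == {"PF00494", "PTHR11626:SF2", "PS01044"}

    def test_mutation_protects_planted_windows(self, patterns):
        heavy = generate_protein_panel(PanelSpec(n_per_group=1, mutation_rate=0.3, seed=2))
        seqs = dict(heavy[0])
        names = {h.pattern_name for h in scan(seqs["tri5_01"], patterns)}
        assert {"tri5_aspartate", "tri5_triad"} <= names

    def test_accuracy_degrades_monotonically_with_mutation(self):
        """Label recovery is non-increasing in mutation rate (binomial slack)."""
        rates = [0.0, 0.05, 0.15, 0.30]
        n_per_group = 20
        accs = []
        ks = []
        n_total = None
        for rate in rates:
            records, domains, truth = generate_protein_panel(
                PanelSpec(n_per_group=n_per_group, mutation_rate=rate, seed=5)
            )
            table, _ = classify_panel(records, domains)
            merged = table.merge(truth, on="protein_id", suffixes=("", "_true"))
            correct = int((merged["group_id"] == merged["group_id_true"]).sum())
            n_total = len(merged)
            ks.append(correct)
            accs.append(correct / n_total)
        assert accs[0] == 1.0
        for prev_k, next_k in zip(ks, ks[1:]):
            p_prev = prev_k / n_total
            if next_k <= prev_k:
                continue
            # apparent increase must be explicable by sampling noise
            assert binomtest(next_k, n_total, p_prev, alternative="greater").pvalue >= 0.01

    def test_domain_determined_groups_survive_heavy_mutation(self):
        """Groups identified purely by TSV domains keep accuracy 1.0 at rate 0.3."""
        domain_only = {
            "tri5_unchar1",
            "tri5_unchar2",
            "tsc_unchar3",
            "tsc_unchar4",
            "protein_prenylation",
            "sqs_psy_unchar5",
        }
        records, domains, truth = generate_protein_panel(
            PanelSpec(n_per_group=5, mutation_rate=0.3, seed=9)
        )
        table, _ = classify_panel(records, domains)
        merged = table.merge(truth, on="protein_id", suffixes=("", "_true"))
        sub = merged[merged["group_id_true"].isin(domain_only)]
        assert (sub["group_id"] == sub["group_id_true"]).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PanelSpec(n_per_group=0)
        with pytest.raises(ValueError):
            PanelSpec(mutation_rate=1.0)


class TestClusterLocusGenerator:
    def test_default_emits_seven_features_spanning_21_2_kb(self):
        loc = generate_cluster_locus(seed=0)
        assert len(loc.features) == 7
        span = (loc.features[-1].end - loc.features[0].start + 1) / 1000
        assert span == pytest.approx(21.2)

    def test_span_invariant_of_layout(self):
        layout = ClusterLayout()
        ordered, lengths, gaps = layout.resolve()
        assert sum(lengths) + sum(gaps) == round(layout.total_span * 1000)
        assert [n for n, _ in ordered].count(layout.anchor_name) == 1

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            ClusterLayout(intergenic_gaps=(500, -1, 500, 500, 500, 500))

    def test_zero_member_layout(self):
        loc = generate_cluster_locus(ClusterLayout(member_roles=(), total_span=1.5))
        assert len(loc.features) == 1
        assert loc.features[0].end - loc.features[0].start + 1 == 1500

    def test_default_roles_match_design(self):
        loc = generate_cluster_locus(seed=0)
        assert loc.roles == {
            "tgA": "Zn2-C6 transcription factor",
            "tgB": "oxygenase",
            "tgC": "alpha-beta hydrolase",
            "tri5": "trichodiene synthase",
            "tgD": "oxygenase",
            "tgE": "MFS transporter",
            "tgF": "carbonic anhydrase",
        }

    def test_seed_determinism(self):
        a = generate_cluster_locus(seed=3)
        b = generate_cluster_locus(seed=3)
        assert a.features == b.features
        assert a.proteins == b.proteins


class TestCtGenerator:
    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            CtDesign(planted_fold={("ts4", "sucrose"): -1.0})
        with pytest.raises(ValueError):
            CtDesign(planted_fold={("ts4", "MM"): 2.0})
        with pytest.raises(ValueError):
            CtDesign(planted_fold={("beta-tubulin", "sucrose"): 2.0})
        with pytest.raises(ValueError):
            CtDesign(noise_sd=-0.1)

    def test_absent_cells_are_nan(self):
        design = CtDesign(absent=frozenset({("ts4", "sucrose")}))
        table = generate_ct_table(design)
        cell = table[(table.gene == "ts4") & (table.condition == "sucrose")]
        assert cell["ct"].isna().all()

    def test_replicate_structure(self):
        design = CtDesign(n_bio=4, n_tech=2)
        table = generate_ct_table(design)
        counts = table.groupby(["gene", "condition"]).size()
        assert (counts == 8).all()

    def test_seed_determinism(self):
        d = CtDesign(noise_sd=0.4, seed=11)
        pd.testing.assert_frame_equal(generate_ct_table(d), generate_ct_table(d))
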