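import numpy as np
import pandas as pd
import pytest

from mirseed import roc, scoring, simulate
from mirseed.io import NTC, VEHICLE, write_sequences


SMALL = dict(n_mirnas=60, genes=("A", "B"), plates_per_gene=1, replicates=2)


class TestScreenGeneration:
    def test_same_seed_bit_identical(self):
        cfg = simulate.SimConfig(**SMALL, rng_seed=5)
        w1, t1 = simulate.generate_screen(cfg)
        w2, t2 = simulate.generate_screen(cfg)
        pd.testing.assert_frame_equal(w1, w2)
        assert t1.interactions == t2.interactions

    def test_structure_matches_config(self):
        cfg = simulate.SimConfig(**SMALL, rng_seed=5)
        wells, truth = simulate.generate_screen(cfg)
        assert set(wells["gene"]) == {"A", "B"}
        per_plate = wells.groupby("plate").size()
        assert (per_plate == 60 + 8).all()
        for _, sub in wells.groupby("plate"):
            assert (sub["treatment"] == NTC).sum() == 4
            assert (sub["treatment"] == VEHICLE).sum() == 4
        assert all(e <= 0 for e in truth.interactions.values())

    def test_study_scale_defaults(self):
        cfg = simulate.SimConfig()
        assert cfg.n_mirnas == 470
        assert len(cfg.genes) == 17
        assert cfg.plates_per_gene == 6
        assert cfg.replicates_for("TP53") == 3
        assert cfg.replicates_for("MYCN") == 2
        # 470 × 17 = 7990 probed combinations
        assert cfg.n_mirnas * len(cfg.genes) == 7990

    def test_infeasible_layout_rejected(self):
        with pytest.raises(simulate.SimulationError, match="layout"):
            simulate.SimConfig(n_mirnas=200, plates_per_gene=2)

    def test_null_screen_false_call_rate(self):
        """No effects, no bias: interaction scores are centered noise and the
        empirical false-call rate at any cutoff tracks the negatives."""
        cfg = simulate.SimConfig(**SMALL, interaction_prevalence=0.0,
                                 mirna_bias_sd=0.0, rng_seed=9)
        wells, truth = simulate.generate_screen(cfg)
        assert truth.interactions == {}
        mats = scoring.score_screen(wells)
        med = mats["interaction"].data.groupby("mirna")["value"].median()
        assert med.abs().max() < 1e-9
        avg = scoring.average_replicates(mats["interaction"])["avg_score"]
        q05 = float(np.quantile(avg, 0.05))
        assert (avg <= q05).mean() == pytest.approx(0.05, abs=0.02)

    def test_bias_shows_in_z_not_interaction(self):
        """Injected per-miRNA bias shifts z-score medians but never
        interaction-score medians."""
        cfg = simulate.SimConfig(**SMALL, interaction_prevalence=0.0,
                                 mirna_bias_sd=1.0, rng_seed=11)
        wells, _ = simulate.generate_screen(cfg)
        mats = scoring.score_screen(wells)
        z_med = mats["z"].data.groupby("mirna")["value"].median()
        i_med = mats["interaction"].data.groupby("mirna")["value"].median()
        assert z_med.std() > 0.5
        assert i_med.abs().max() < 1e-9

    def test_edge_effect_field_applied(self):
        cfg = simulate.SimConfig(**SMALL, noise_sd=0.0, plate_sd=0.0,
                                 mirna_bias_sd=0.0, gene_baseline_sd=0.0,
                                 interaction_prevalence=0.0, edge_effect=1.0,
                                 rng_seed=2)
        wells = scoring.add_nra(simulate.generate_screen(cfg)[0])
        edge = wells["row"].isin(["A", "H"]) | wells["column"].isin([1, 12])
        assert wells.loc[edge, "nra"].mean() == pytest.approx(1.0, abs=1e-9)
        assert wells.loc[~edge, "nra"].mean() == pytest.approx(0.0, abs=1e-9)


class TestEmptyScreen:
    def test_truth_has_no_interactions_and_is_deterministic(self):
        cfg = simulate.SimConfig(**SMALL, rng_seed=4)
        w1, t1 = simulate.generate_empty_screen(cfg)
        w2, _ = simulate.generate_empty_screen(cfg)
        assert t1.interactions == {}
        pd.testing.assert_frame_equal(w1, w2)

    def test_roc_against_implanted_positives(self):
        """Empty-screen scores used as ROC negatives give high AUC for
        strong implanted effects."""
        cfg = simulate.SimConfig(n_mirnas=100, genes=("A", "B"), plates_per_gene=2,
                                 replicates=2, effect_mean=-3.0, noise_sd=0.5,
                                 interaction_prevalence=0.08, rng_seed=13)
        wells, truth = simulate.generate_screen(cfg)
        empty, _ = simulate.generate_empty_screen(
            simulate.SimConfig(n_mirnas=100, plates_per_gene=2, rng_seed=14),
            shared_truth=truth,
        )
        avg = scoring.average_replicates(scoring.score_screen(wells)["interaction"])
        key = avg.set_index(["mirna", "gene"])["avg_score"]
        pos = np.array([key[p] for p in truth.interactions])
        neg = scoring.average_replicates(
            scoring.score_screen(empty)["interaction"])["avg_score"].to_numpy()
        assert roc.roc_analysis(roc.ControlScores(pos, neg)).auc > 0.9


class TestSequenceFixtures:
    def test_one_8mer_per_utr_found_at_truth_coordinates(self):
        from mirseed.sites import scan_pair

        mirnas, utrs, truth = simulate.generate_sequence_fixtures(
            4, 12, 100, implant_spec=[("8mer", 1)], rng_seed=3
        )
        assert len(truth) == 12
        for j, utr in enumerate(utrs):
            mir = mirnas[j % 4]
            found = [s for s in scan_pair(mir, utr, classes=("8mer",))]
            row = truth[truth["utr"] == utr.id].iloc[0]
            assert len(found) == 1
            assert (found[0].start, found[0].end) == (row["start"], row["end"])

    def test_empty_spec_background_site_rate_is_analytic(self):
        """Canonical 6mer seed matches on random background occur at the
        Bernoulli rate 4^-6 per register."""
        from mirseed.sites import scan_canonical

        mirnas, utrs, _ = simulate.generate_sequence_fixtures(
            30, 30, 400, implant_spec=(), rng_seed=8
        )
        n_sites = sum(
            len(scan_canonical(m, u)) for m, u in zip(mirnas, utrs)
        )
        registers = 30 * (400 - 5)
        expected = registers * 4 ** -6
        sd = np.sqrt(registers * 4 ** -6)
        assert abs(n_sites - expected) < 4 * sd + 1

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        a = simulate.generate_sequence_fixtures(3, 5, 80, [("6mer", 1)], rng_seed=6)
        b = simulate.generate_sequence_fixtures(3, 5, 80, [("6mer", 1)], rng_seed=6)
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        write_sequences(a[1], pa)
        write_sequences(b[1], pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_every_class_can_be_implanted_and_recovered(self):
        from mirseed.sites import scan_pair

        spec = [("7mer-m8", 1), ("7mer-A1", 1), ("6mer", 1), ("offset6", 1),
                ("gu_wobble", 1), ("seed_mismatch", 1), ("gbulge", 1),
                ("centered", 1)]
        mirnas, utrs, truth = simulate.generate_sequence_fixtures(
            2, 4, 300, implant_spec=spec, rng_seed=17
        )
        for j, utr in enumerate(utrs):
            mir = mirnas[j % 2]
            found = {(s.site_class, s.start, s.end)
                     for s in scan_pair(mir, utr, classes=tuple(c for c, _ in spec))}
            expected = set(map(tuple,
                               truth.loc[truth["utr"] == utr.id,
                                         ["site_class", "start", "end"]].values))
            # every implant recovered; extras only at registers the implants
            # themselves entail (e.g. an offset 6mer is also a 1-mismatch
            # window one register over)
            assert expected <= found
            spans = [(s, e) for _, s, e in expected]
            for _, s, e in found - expected:
                assert any(s <= te and e >= ts for ts, te in spans)

    def test_infeasible_implant_rejected(self):
        with pytest.raises(simulate.SimulationError):
            simulate.generate_sequence_fixtures(1, 1, 10, [("centered", 3)], rng_seed=0)
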