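"""The synthetic-study generator: determinism, generative contracts,
parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from consdock import (
    Direction,
    GeneratorConfig,
    MechClass,
    borda_aggregate,
    classification_metrics,
    classify_by_threshold,
    generate_interactions,
    generate_scores,
    generate_study,
    intersection_threshold,
    merge_consensus_interactions,
    relative_ranks,
    write_study,
)
from consdock.io import read_score_table
from consdock.synthetic import FunctionConfig, default_functions


class TestConfig:
    def test_default_study_shape(self):
        cfg = GeneratorConfig()
        assert len(cfg.ligand_ids()) == 28
        assert len(cfg.functions) == 11
        assert sorted({f.program for f in cfg.functions}) == ["GOLD", "Glide"]
        classes = [a.mech_class for a in cfg.annotations()]
        assert classes.count(MechClass.CI_inhibitor) == 14
        assert classes.count(MechClass.CIII_inhibitor) == 11
        assert classes.count(MechClass.uncoupler) == 3

    @pytest.mark.parametrize("field,value", [
        ("p_fail", 1.5), ("binder_sd", -1.0), ("p_core", -0.1),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            GeneratorConfig(**{field: value})

    def test_nonpositive_gain_rejected(self):
        fns = default_functions()
        fns[0] = dataclasses.replace(fns[0], gain=0.0)
        with pytest.raises(ValueError, match="gain"):
            GeneratorConfig(functions=fns)


class TestScores:
    def test_same_seed_identical_bundles(self, tmp_path):
        b1 = generate_study(GeneratorConfig(seed=3))
        b2 = generate_study(GeneratorConfig(seed=3))
        for t in ("CI", "CIII"):
            pd.testing.assert_frame_equal(b1.score_tables[t].scores,
                                          b2.score_tables[t].scores)
        assert b1.activities.pic50 == b2.activities.pic50
        assert b1.interactions == b2.interactions

    def test_noiseless_limit_exact_latent_order(self):
        """With all noise off and no failures, every function ranks
        ligands in exact latent order and the aggregated rank recovers
        the latent ordering perfectly."""
        fns = [dataclasses.replace(f, noise_sd=0.0) for f in default_functions()]
        cfg = GeneratorConfig(functions=fns, program_noise_sd=0.0, p_fail=0.0,
                              seed=5)
        tables, latents = generate_scores(cfg)
        t = tables["CI"]
        order_latent = latents["CI"].rank(ascending=False)
        ranks = relative_ranks(t, cfg.specs())
        for fn in t.function_names:
            assert np.allclose(ranks.ranks[fn], order_latent)
        agg = borda_aggregate(ranks).aggregated_rank
        assert np.allclose(agg, order_latent)

    def test_direction_flip_negates_scores_keeps_ranks(self):
        """Flipping a function's direction flag negates its emitted
        scores and leaves its relative ranks unchanged."""
        fns = default_functions()
        flipped = [dataclasses.replace(
            f, direction=(Direction.lower_is_better
                          if f.direction is Direction.higher_is_better
                          else Direction.higher_is_better))
            for f in fns]
        cfg1 = GeneratorConfig(functions=fns, p_fail=0.0, seed=9)
        cfg2 = GeneratorConfig(functions=flipped, p_fail=0.0, seed=9)
        t1, _ = generate_scores(cfg1)
        t2, _ = generate_scores(cfg2)
        assert np.allclose(t1["CI"].scores.values, -t2["CI"].scores.values)
        r1 = relative_ranks(t1["CI"], cfg1.specs())
        r2 = relative_ranks(t2["CI"], cfg2.specs())
        pd.testing.assert_frame_equal(r1.ranks, r2.ranks)

    def test_failures_hit_whole_program(self):
        cfg = GeneratorConfig(p_fail=0.4, seed=13)
        tables, _ = generate_scores(cfg)
        by_prog = {p: [f.name for f in cfg.functions if f.program == p]
                   for p in ("GOLD", "Glide")}
        df = tables["CI"].scores
        for prog, fns in by_prog.items():
            sub = df[fns].isna()
            # per ligand, a program's functions are all missing or all present
            assert (sub.all(axis=1) | (~sub.any(axis=1))).all()

    def test_binder_scores_beat_nonbinder_scores(self):
        """Generative contract: under each function's direction, binders
        score better than nonbinders on average in nearly all replicates."""
        ok = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = GeneratorConfig(seed=2000 + seed)
            tables, _ = generate_scores(cfg)
            binders = [l for l in cfg.ligand_ids() if l.startswith("CI-")]
            others = [l for l in cfg.ligand_ids() if not l.startswith("CI-")]
            df = tables["CI"].scores
            good = True
            for fc in cfg.functions:
                mb = df.loc[binders, fc.name].mean()
                mn = df.loc[others, fc.name].mean()
                better = mb > mn if fc.direction is Direction.higher_is_better else mb < mn
                good &= bool(better)
            ok += good
        assert ok / n_rep >= 0.9


class TestInteractions:
    def test_p_core_one_no_spurious_full_consensus(self):
        cfg = GeneratorConfig(p_core=1.0, p_core_nonbinder=0.0, spur_rate=0.0,
                              seed=1)
        bundle = generate_study(cfg)
        sets = merge_consensus_interactions(
            bundle.interactions[("CI", "GOLD")],
            bundle.interactions[("CI", "Glide")])
        for s in sets:
            if s.ligand_id.startswith("CI-"):
                assert len(s) == cfg.core_size
            else:
                assert len(s) == 0

    def test_p_core_zero_all_empty(self):
        cfg = GeneratorConfig(p_core=0.0, p_core_nonbinder=0.0, seed=1)
        bundle = generate_study(cfg)
        sets = merge_consensus_interactions(
            bundle.interactions[("CI", "GOLD")],
            bundle.interactions[("CI", "Glide")])
        assert all(len(s) == 0 for s in sets)

    def test_binder_consensus_size_matches_binomial_expectation(self):
        """Mean binder consensus size over replicates is within 3 SE of
        core_size * p_core**2 (spurious keys never coincide across
        programs, so only core coverage contributes)."""
        cfg0 = GeneratorConfig()
        sizes = []
        n_rep = 100
        for seed in range(n_rep):
            cfg = GeneratorConfig(seed=3000 + seed)
            bundle = generate_study(cfg)
            sets = merge_consensus_interactions(
                bundle.interactions[("CI", "GOLD")],
                bundle.interactions[("CI", "Glide")])
            for s in sets:
                if s.ligand_id.startswith("CI-"):
                    sizes.append(len(s))
        expected = cfg0.core_size * cfg0.p_core**2
        se = np.std(sizes, ddof=1) / np.sqrt(len(sizes))
        assert abs(np.mean(sizes) - expected) <= 3 * se

    def test_within_class_similarity_exceeds_cross_class(self):
        """Binders of a target share the core, so their mean pairwise
        Tanimoto exceeds binder-vs-nonbinder similarity."""
        from consdock import build_fingerprint_matrix, tanimoto_matrix
        bundle = generate_study(GeneratorConfig(seed=17))
        sets = merge_consensus_interactions(
            bundle.interactions[("CI", "GOLD")],
            bundle.interactions[("CI", "Glide")])
        fp = build_fingerprint_matrix(sets)
        sim = tanimoto_matrix(fp)
        ids = sim.ligand_ids
        bi = [i for i, l in enumerate(ids) if l.startswith("CI-")]
        ni = [i for i, l in enumerate(ids) if not l.startswith("CI-")]
        within = np.mean([sim.values[i, j] for i in bi for j in bi if i < j])
        across = np.mean([sim.values[i, j] for i in bi for j in ni])
        assert within > across


class TestStudyBundle:
    def test_roundtrip_through_files(self, tmp_path, small_cfg):
        """Written artifacts parse back loss-free through the I/O layer."""
        bundle = generate_study(small_cfg)
        write_study(bundle, tmp_path)
        back = read_score_table(tmp_path / "scores_CI.csv", bundle.specs,
                                target_id="CI")
        pd.testing.assert_frame_equal(back.scores, bundle.score_tables["CI"].scores)

    def test_write_is_deterministic(self, tmp_path, small_cfg):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study(generate_study(small_cfg), d1)
        write_study(generate_study(small_cfg), d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_zero_activity_noise_perfect_latent_correlation(self):
        from consdock import rank_correlation
        cfg = GeneratorConfig(act_noise_sd=0.0, seed=21)
        bundle = generate_study(cfg)
        latent = {l: bundle.latents.at[l, "CIII"]
                  for l in bundle.activities.pic50}
        rho, _ = rank_correlation(latent, bundle.activities.pic50)
        assert rho == pytest.approx(1.0)

    def test_parameter_recovery_at_strong_separation(self):
        """With d' = 3 in the thresholded score channel the KDE
        classifier recovers the generating classes with BAC >= 0.9, and
        the threshold falls between the class score means.  Function
        noise is off so the score-channel d' equals the latent d'."""
        fns = [dataclasses.replace(f, noise_sd=0.0)
               for f in default_functions()]
        cfg = GeneratorConfig(n_ci=50, n_ciii=40, n_unc=10,
                              binder_mean=3.0, nonbinder_mean=0.0,
                              binder_sd=1.0, nonbinder_sd=1.0,
                              functions=fns, program_noise_sd=0.0,
                              p_fail=0.0, seed=23)
        bundle = generate_study(cfg)
        table = bundle.score_tables["CI"]
        truth = {l: "positive" if l.startswith("CI-") else "negative"
                 for l in table.ligand_ids}
        fn = "Glide IFDScore"
        col = table.scores[fn]
        pos = [col[l] for l in truth if truth[l] == "positive"]
        neg = [col[l] for l in truth if truth[l] == "negative"]
        model = intersection_threshold(pos, neg, function_name=fn)
        assert min(np.mean(pos), np.mean(neg)) < model.threshold < \
            max(np.mean(pos), np.mean(neg))
        pred = classify_by_threshold(col.to_dict(), model)
        m = classification_metrics(pred, truth)
        assert m.bac >= 0.9
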