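import numpy as np
import pytest

from recharge.errors import ValidationError
from recharge.optimize import (
    OptimizerConfig,
    TargetSpec,
    ci_overlap_converged,
    load_targets,
    objective,
    optimization_cycle,
    relative_ci95,
    run_optimization,
    _project_with_cap,
)
from recharge.reweight import reweighted_mean_ci, uniform_weights
from recharge.topology import ChargeSet
from recharge.toys import metropolis_sample, two_species_fluid

# Table of training targets: (system, property, mean, ci95, scale)
TRAINING_TABLE = [
    ("TOG", "IT", 30.6, 2.4, 0.040),
    ("DOG", "IT", 17.2, 1.4, 0.040),
    ("EOOP", "ST", 23.8, 1.9, 0.035),
    ("EGDA", "ST", 33.0, 2.6, 0.035),
    ("TAGL", "ST", 37.0, 3.0, 0.035),
    ("EOOP", "density", 0.884, 0.018, 1.000),
    ("EGDA", "density", 1.101, 0.022, 1.000),
    ("TAGL", "density", 1.158, 0.023, 1.000),
    ("TOG", "density", 0.909, 0.018, 1.000),
]


def make_targets():
    return [
        TargetSpec(s, p, m, c, sc, "obs") for s, p, m, c, sc in TRAINING_TABLE
    ]


class TestRelativeCI:
    @pytest.mark.parametrize(
        "mean,expected", [(30.6, 2.4), (17.2, 1.4), (23.8, 1.9), (33.0, 2.6),
                          (37.0, 3.0)]
    )
    def test_tensions_8pct(self, mean, expected):
        assert relative_ci95(mean) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "mean,expected",
        [(0.884, 0.018), (1.101, 0.022), (1.158, 0.023), (0.909, 0.018)],
    )
    def test_densities_2pct(self, mean, expected):
        assert relative_ci95(mean, rel=0.02, decimals=3) == pytest.approx(expected)


class TestObjective:
    def _neutral_pair(self, vals):
        q = np.asarray(vals, dtype=float)
        return ChargeSet(("A", "B"), q, np.zeros(2))

    def test_perfect_fit_zero(self):
        targets = make_targets()
        means = [t.exp_mean for t in targets]
        q = self._neutral_pair([0.0, 0.0])
        assert objective(targets, means, q, q, 1.0) == 0.0

    def test_single_target_hand_value(self):
        # scale 0.040, exp 30.6 +/- 2.4, model 33.0:
        # F = (0.040 * 2.4 / 2.4)^2 = 0.0016
        t = TargetSpec("TOG", "IT", 30.6, 2.4, 0.040, "obs")
        q = self._neutral_pair([0.0, 0.0])
        assert objective([t], [33.0], q, q, 0.0) == pytest.approx(0.0016)

    def test_doubling_ci_quarters_data_term(self):
        targets = make_targets()
        rng = np.random.default_rng(3)
        means = [t.exp_mean * (1 + 0.1 * rng.standard_normal()) for t in targets]
        q = self._neutral_pair([0.0, 0.0])
        f1 = objective(targets, means, q, q, 0.0)
        wide = [
            TargetSpec(t.system, t.property, t.exp_mean, 2 * t.ci95, t.scale, "obs")
            for t in targets
        ]
        f2 = objective(wide, means, q, q, 0.0)
        assert f2 == pytest.approx(f1 / 4.0)

    def test_regularization_counts_free_only(self):
        q = ChargeSet(
            ("A", "B"), np.array([0.3, -0.3]), np.zeros(2),
            frozen_mask=np.array([False, True]),
        )
        ref = q.with_charges(np.zeros(2))
        assert objective([], [], q, ref, 2.0) == pytest.approx(2.0 * 0.09)

    def test_missing_model_mean(self):
        q = self._neutral_pair([0.0, 0.0])
        with pytest.raises(ValidationError):
            objective(make_targets(), [1.0], q, q, 0.0)


class TestCIOverlap:
    def test_reported_converged_case(self):
        done, flags = ci_overlap_converged([(31.2, 1.4)], [(30.6, 2.4)])
        assert done and flags == [True]

    def test_reported_non_converged_case(self):
        done, flags = ci_overlap_converged([(17.3, 2.0)], [(30.6, 2.4)])
        assert not done and flags == [False]

    def test_touching_endpoints_overlap(self):
        done, _ = ci_overlap_converged([(1.5, 0.5)], [(2.5, 0.5)])
        assert done

    def test_all_targets_required(self):
        done, flags = ci_overlap_converged(
            [(31.2, 1.4), (17.3, 2.0)], [(30.6, 2.4), (30.6, 2.4)]
        )
        assert flags == [True, False] and not done


class TestConfig:
    def test_presets(self):
        assert OptimizerConfig.from_preset("C36-c").cap_per_cycle == 0.005
        assert OptimizerConfig.from_preset("C36-p").cap_per_cycle == 0.02

    def test_unknown_preset(self):
        with pytest.raises(ValidationError):
            OptimizerConfig(preset="C99")


class TestCapProjection:
    def test_clip_then_neutrality_hand_case(self):
        start = np.array([0.1, -0.1])
        base = ChargeSet(("A", "B"), start, start.copy())
        raw = np.array([0.13, -0.11])  # proposed (+0.03, -0.01), cap 0.02
        out = _project_with_cap(base, raw, start, 0.02)
        # clip -> (0.12, -0.11); neutrality spreads -0.005 each
        np.testing.assert_allclose(out.charges, [0.115, -0.115], atol=1e-12)
        assert np.max(np.abs(out.charges - start)) <= 0.02 + 1e-12

    def test_cap_zero_is_identity(self):
        start = np.array([0.1, -0.1])
        base = ChargeSet(("A", "B"), start, start.copy())
        out = _project_with_cap(base, np.array([0.4, -0.2]), start, 0.0)
        np.testing.assert_allclose(out.charges, start, atol=1e-12)


def toy_sampler(base_system, steps=40000, stride=25):
    def sampler(cs, seed):
        ens = metropolis_sample(
            base_system.with_charges(cs), steps,
            seed=np.random.default_rng(seed), stride=stride,
        )
        return {"TOY": ens}

    return sampler


@pytest.fixture(scope="module")
def truth_target():
    """Hidden-truth toy observable mean, measured from a long run."""
    truth = two_species_fluid(8, 8, 0.2)
    ens = metropolis_sample(truth, 150000, seed=99991, stride=25)
    mc = reweighted_mean_ci(
        ens, "inv_r_cross", uniform_weights(ens.n_frames),
        n_blocks=20, rng=0, ess_floor=0.0,
    )
    return truth, mc


class TestOptimizationCycle:
    def test_cap_zero_leaves_charges(self, truth_target):
        truth, mc = truth_target
        ens = metropolis_sample(truth, 10000, seed=5, stride=25)
        targets = [TargetSpec("TOY", "IT", mc.mean, 1.0, 1.0, "inv_r_cross")]
        cfg = OptimizerConfig(cap_per_cycle=0.0, seed=0, n_boot=200)
        rep = optimization_cycle({"TOY": ens}, targets, truth.charge_set, cfg)
        np.testing.assert_array_equal(
            rep.charges_after.charges, rep.charges_before.charges
        )

    def test_cycle_respects_constraints_and_decreases_objective(self, truth_target):
        truth, mc = truth_target
        start = truth.charge_set.with_param_values(np.array([0.24, -0.24]))
        ens = metropolis_sample(
            truth.with_charges(start), 40000, seed=11, stride=25
        )
        targets = [TargetSpec("TOY", "IT", mc.mean, 0.5, 1.0, "inv_r_cross")]
        cfg = OptimizerConfig(cap_per_cycle=0.02, seed=1, n_boot=200)
        rep = optimization_cycle({"TOY": ens}, targets, start, cfg)
        rep.validate(cfg.cap_per_cycle)
        before = objective(
            targets,
            [float(ens.observable("inv_r_cross").mean())],
            start, start.with_charges(start.reference_charges),
            cfg.regularization_weight,
        )
        assert rep.objective_value <= before + 1e-12
        assert rep.n_inner_steps >= 1


class TestRunOptimization:
    def test_already_converged_zero_cycles(self, truth_target):
        truth, mc = truth_target
        targets = [TargetSpec("TOY", "IT", mc.mean, 5.0, 1.0, "inv_r_cross")]
        cfg = OptimizerConfig(cap_per_cycle=0.02, max_cycles=5, seed=0, n_boot=200)
        res = run_optimization(
            toy_sampler(truth, steps=20000), targets, truth.charge_set, cfg
        )
        assert res.converged and res.n_cycles == 0

    def test_max_cycles_exhaustion_reports_nonconverged(self, truth_target):
        truth, mc = truth_target
        # unreachable target: tiny CI far from any attainable mean
        targets = [TargetSpec("TOY", "IT", mc.mean + 50.0, 0.01, 1.0, "inv_r_cross")]
        cfg = OptimizerConfig(cap_per_cycle=0.005, max_cycles=2, seed=0, n_boot=100)
        res = run_optimization(
            toy_sampler(truth, steps=8000), targets, truth.charge_set, cfg
        )
        assert not res.converged
        assert res.n_cycles == 2

    def test_large_lambda_pins_to_reference(self, truth_target):
        truth, mc = truth_target
        start = truth.charge_set.with_param_values(np.array([0.24, -0.24]))
        targets = [TargetSpec("TOY", "IT", mc.mean, 0.2, 1.0, "inv_r_cross")]
        cfg = OptimizerConfig(
            cap_per_cycle=0.05, max_cycles=4, seed=2,
            regularization_weight=1e8, n_boot=100,
        )
        res = run_optimization(
            toy_sampler(truth, steps=8000), targets, start, cfg
        )
        # reference is the truth set (0.2); huge lambda drags charges back
        np.testing.assert_allclose(
            res.charges.charges, truth.charge_set.charges, atol=5e-3
        )

    def test_recovery_small_seed_sample(self, truth_target):
        truth, mc = truth_target
        targets = [TargetSpec("TOY", "IT", mc.mean, 0.3, 1.0, "inv_r_cross")]
        ok = 0
        for seed in range(5):
            start = truth.charge_set.with_param_values(
                np.array([0.25, -0.25])
            ).project()
            cfg = OptimizerConfig(cap_per_cycle=0.02, max_cycles=10,
                                  seed=seed, n_boot=300)
            res = run_optimization(
                toy_sampler(truth, steps=60000), targets, start, cfg
            )
            for rep in res.cycles:
                rep.validate(cfg.cap_per_cycle)
            ok += res.converged
        assert ok >= 4

    def test_deterministic_given_seed(self, truth_target):
        truth, mc = truth_target
        targets = [TargetSpec("TOY", "IT", mc.mean, 0.5, 1.0, "inv_r_cross")]
        runs = []
        for _ in range(2):
            start = truth.charge_set.with_param_values(np.array([0.23, -0.23]))
            cfg = OptimizerConfig(cap_per_cycle=0.02, max_cycles=3, seed=7,
                                  n_boot=100)
            res = run_optimization(
                toy_sampler(truth, steps=8000), targets, start, cfg
            )
            runs.append(res.charges.charges.copy())
        np.testing.assert_array_equal(runs[0], runs[1])


class TestLoadTargets:
    def test_toml_round_trip(self, tmp_path):
        toml = tmp_path / "targets.toml"
        lines = ["[[targets]]\n"
                 f'system = "{s}"\nproperty = "{p}"\nexp_mean = {m}\n'
                 f"ci95 = {c}\nscale = {sc}\nobs_key = \"obs\"\n"
                 for s, p, m, c, sc in TRAINING_TABLE]
        toml.write_text("\n".join(lines))
        targets = load_targets(toml)
        assert len(targets) == len(TRAINING_TABLE)
        assert targets[0].exp_mean == 30.6
        assert targets[2].scale == 0.035

    def test_csv(self, tmp_path):
        csv = tmp_path / "targets.csv"
        csv.write_text(
            "system,property,exp_mean,ci95,scale,obs_key\n"
            "TOG,IT,30.6,2.4,0.040,obs\n"
        )
        (t,) = load_targets(csv)
        assert t.ci95 == 2.4 and t.scale == 0.04
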