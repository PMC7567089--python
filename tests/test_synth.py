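"""Forward-model generator: determinism, round trips, mass balance."""

import numpy as np
import pandas as pd
import pytest

from spongeflux.pipeline import RunConfig, run_all
from spongeflux.stats import DesignTable, permanova
from spongeflux.synth import (
    FLUX_PRESETS,
    SPECIES_PRESETS,
    GeneratorConfig,
    beta_params,
    generate_experiment,
    generate_null_dataset,
)


def test_species_profiles_sum_to_100():
    for preset in SPECIES_PRESETS.values():
        assert sum(preset.plfa_profile.values()) == pytest.approx(100.0)


def test_beta_params_reproduce_moments():
    a, b = beta_params(0.77, 0.20)
    assert a / (a + b) == pytest.approx(0.77)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert np.sqrt(var) == pytest.approx(0.20)


def test_same_seed_byte_identical(tmp_path):
    cfg = GeneratorConfig(preset="vazella_dom", seed=3)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_experiment(cfg).write(d1)
    generate_experiment(cfg).write(d2)
    for f in d1.iterdir():
        assert (d2 / f.name).read_bytes() == f.read_bytes()


def test_different_seed_differs():
    b1 = generate_experiment(GeneratorConfig(preset="vazella_dom", seed=3))
    b2 = generate_experiment(GeneratorConfig(preset="vazella_dom", seed=4))
    assert not b1.bulk_isotopes.delta13c.equals(b2.bulk_isotopes.delta13c)


def test_noise_off_recovery_exact(exact_bundle):
    """With measurement noise off the pipeline inverts the forward model."""
    res = run_all(RunConfig(permutations=0), bundle=exact_bundle)
    truth = exact_bundle.truth.set_index("specimen_id")
    rc = res.rates[res.rates.element == "C"].set_index("specimen_id")
    assert np.allclose(rc.assimilation_rate, truth.assimilation_rate_c, rtol=1e-9)
    assert np.allclose(rc.respiration_rate, truth.respiration_rate_c, rtol=1e-9)
    assert np.allclose(rc.efficiency_pct, truth.efficiency_pct, rtol=1e-9)
    rn = res.rates[res.rates.element == "N"].set_index("specimen_id")
    assert np.allclose(rn.assimilation_rate, truth.assimilation_rate_n, rtol=1e-9)
    inc_tot = res.plfa_incorporation.groupby("sample_id")["rate"].sum()
    assert np.allclose(
        inc_tot.reindex(truth.index), truth.plfa_incorporation_rate, rtol=1e-6
    )


@pytest.mark.parametrize("preset", sorted(FLUX_PRESETS))
def test_mass_balance_per_pulse(preset):
    """Label fed per pulse always covers tissue uptake plus respiration."""
    bundle = generate_experiment(GeneratorConfig(preset=preset, seed=5,
                                                 include_plfa=False))
    flux = FLUX_PRESETS[preset]
    pulse_days = flux.pulse_duration_h / 24.0
    t = bundle.truth
    uptake_c = t.total_c_rate * (t.c_org_umol / 1000.0) * pulse_days
    assert (uptake_c <= t.fed_c_tracer_per_pulse_umol + 1e-9).all()
    uptake_n = t.assimilation_rate_n * (t.n_org_umol / 1000.0) * pulse_days
    assert (uptake_n <= t.fed_n_tracer_per_pulse_umol + 1e-9).all()


def test_truth_table_complete(noisy_bundle):
    t = noisy_bundle.truth
    assert {"total_c_rate", "assimilation_rate_c", "respiration_rate_c",
            "efficiency_pct", "assimilation_rate_n", "cn_assimilation",
            "plfa_incorporation_rate", "mass_balance_capped"} <= set(t.columns)
    assert np.allclose(
        t.total_c_rate, t.assimilation_rate_c + t.respiration_rate_c
    )


def test_unlabelled_specimens_center_on_zero_excess():
    """In a null bundle read back through the pipeline, excess enrichment of
    DIC in control chambers scatters around zero."""
    bundle = generate_experiment(GeneratorConfig(preset="geodia_dom", seed=21,
                                                 include_plfa=False))
    dic = bundle.dic_samples
    ctrl = dic[dic.incubation_id.str.contains("CTRL")]
    t0 = ctrl[ctrl.time_point == "t0"].delta13c.to_numpy()
    te = ctrl[ctrl.time_point == "t_end"].delta13c.to_numpy()
    assert abs(np.mean(te) - np.mean(t0)) < 0.1  # ‰, noise only


def test_null_dataset_has_no_group_effect():
    """PERMANOVA on recovered rates from a null bundle is non-significant at
    a fixed seed and the two groups share the truth distribution."""
    cfg = GeneratorConfig(preset="hymedesmia_bacteria", seed=9, include_plfa=False)
    bundle = generate_null_dataset(cfg, n_groups=2)
    assert bundle.specimens.species.nunique() == 2
    res = run_all(RunConfig(permutations=999, seed=1), bundle=bundle)
    rc = res.rates[res.rates.element == "C"]
    design = DesignTable(rc.total_processing.to_numpy(), rc.species.to_numpy())
    out = permanova(design, permutations=999, seed=2)[0]
    assert out.p_perm > 0.05


def test_recovery_unbiased_over_replicates():
    """Grand means over 60 noisy replicates track the preset expectations
    within Monte Carlo error."""
    reps = 60
    tot, eff = [], []
    for r in range(reps):
        b = generate_experiment(
            GeneratorConfig(preset="vazella_bacteria", seed=3000 + r,
                            include_plfa=False)
        )
        res = run_all(RunConfig(permutations=0), bundle=b)
        rc = res.rates[res.rates.element == "C"]
        tot.append(rc.total_processing.mean())
        eff.append(rc.efficiency_pct.mean())
    exp = FLUX_PRESETS["vazella_bacteria"].expected
    se_tot = np.std(tot) / np.sqrt(reps)
    assert np.mean(tot) == pytest.approx(exp["total_c_rate"], abs=4 * se_tot + 0.02)
    assert np.mean(eff) == pytest.approx(exp["efficiency_pct"], abs=1.0)
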