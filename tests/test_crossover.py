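"""Mismatch profiles, background/foreground, sigmoid fit and fusion call."""

import numpy as np
import pandas as pd
import pytest

from parafuse import (CallConfig, annotate_interval, background_level,
                      build_mismatch_profile, call_fusion, call_sample,
                      fit_crossover_sigmoid, foreground_level, genotype_read,
                      subsample_stability)
from parafuse.alignment import OBS_A, OBS_B, OBS_NEITHER, ReadSiteCalls
from parafuse.crossover import MismatchProfile, SigmoidFit
from parafuse.reference import align_gene_pair, extract_informative_sites
from parafuse.simulate import make_chimera, simulate_reads

from _oracles import percentile_interpolated


def _manual_calls(catalog, disc_rows, amb_rows):
    """Build ReadSiteCalls from explicit per-read observation rows."""
    return [
        ReadSiteCalls(f"r{i}", "+", 0.0, 0.0,
                      np.asarray(d, dtype=np.int8), np.asarray(a, dtype=np.int8))
        for i, (d, a) in enumerate(zip(disc_rows, amb_rows))
    ]


def _profile_from_rates(disc, amb=(), disc_pos=None, amb_pos=None, n=100):
    rows = []
    disc_pos = disc_pos if disc_pos is not None else np.arange(len(disc)) * 10
    amb_pos = amb_pos if amb_pos is not None else np.arange(len(amb)) * 10 + 5
    for p, r in zip(disc_pos, disc):
        rows.append({"position": int(p), "kind": "discriminating", "n": n,
                     "m": int(round(r * n)), "rate": r})
    for p, r in zip(amb_pos, amb):
        rows.append({"position": int(p), "kind": "ambiguous", "n": n,
                     "m": int(round(r * n)), "rate": r})
    df = pd.DataFrame(rows).sort_values("position").reset_index(drop=True)
    return MismatchProfile(reference="A", sites=df, n_reads=n)


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def test_profile_of_pure_gene_a_reads(toy_pair, toy_catalog):
    pair, _ = toy_pair
    calls = [genotype_read(pair.seq_a, pair, toy_catalog) for _ in range(10)]
    profile = build_mismatch_profile(calls, toy_catalog)
    assert (profile.sites["rate"] == 0).all()


def test_profile_of_perfect_chimeras(toy_pair, toy_catalog):
    pair, _ = toy_pair
    c = 1000
    template, _, _ = make_chimera(pair, c)
    calls = [genotype_read(template, pair, toy_catalog) for _ in range(5)]
    profile = build_mismatch_profile(calls, toy_catalog)
    disc = profile.rates("discriminating")
    left = disc[disc["position"] < c - 5]
    right = disc[disc["position"] > c + 5]
    assert (left["rate"] == 0).all()
    assert (right["rate"] == 1).all()
    amb = profile.rates("ambiguous")
    assert (amb["rate"] == 0).all()


def test_matches_neither_excluded_from_coverage(toy_catalog):
    n_units = len(toy_catalog.disc_units)
    n_amb = len(toy_catalog._amb_pos_a)
    rows_d = [[OBS_A] * n_units for _ in range(9)] + [[OBS_NEITHER] * n_units]
    rows_a = [[0] * n_amb for _ in range(10)]
    calls = _manual_calls(toy_catalog, rows_d, rows_a)
    profile = build_mismatch_profile(calls, toy_catalog)
    disc = profile.rates("discriminating")
    assert (disc["n"] == 9).all()  # the matches-neither read is excluded
    assert (disc["rate"] == 0).all()


def test_profile_requires_coverage(toy_catalog):
    n_units = len(toy_catalog.disc_units)
    n_amb = len(toy_catalog._amb_pos_a)
    calls = _manual_calls(toy_catalog, [[3] * n_units], [[2] * n_amb])
    with pytest.raises(ValueError, match="no informative coverage"):
        build_mismatch_profile(calls, toy_catalog)


def test_label_swap_duality(toy_pair, toy_catalog, toy_model):
    pair, _ = toy_pair
    template, _, _ = make_chimera(pair, 1000)
    reads = simulate_reads(template, n_reads=40, seed=5)
    calls = [genotype_read(r, pair, toy_catalog) for r in reads]
    prof_a = build_mismatch_profile(calls, toy_catalog, "A")
    prof_b = build_mismatch_profile(calls, toy_catalog, "B")
    da = prof_a.rates("discriminating").set_index(prof_a.rates("discriminating").index)
    db = prof_b.rates("discriminating")
    # same units, complementary rates
    assert len(da) == len(db)
    np.testing.assert_allclose(np.sort(da["rate"]), np.sort(1 - db["rate"]),
                               atol=1e-12)
    _, call_a = call_sample(calls, toy_catalog, toy_model, "A")
    _, call_b = call_sample(calls, toy_catalog, toy_model, "B")
    assert call_a.status == call_b.status == "fused"


# ---------------------------------------------------------------------------
# background / foreground
# ---------------------------------------------------------------------------

def test_background_zero_when_all_ambiguous_clean():
    profile = _profile_from_rates([0, 1, 1, 0], amb=[0.0] * 20)
    assert background_level(profile) == 0.0


def test_background_matches_interpolation_oracle():
    rates = np.round(np.arange(100) / 100.0, 2)
    profile = _profile_from_rates([], amb=rates)
    want = percentile_interpolated(list(rates), 99)
    assert background_level(profile) == pytest.approx(want)
    assert background_level(profile) == pytest.approx(0.9801)


def test_background_randomized_against_oracle():
    rng = np.random.default_rng(17)
    for _ in range(100):
        rates = rng.random(int(rng.integers(1, 60)))
        profile = _profile_from_rates([], amb=rates)
        want = percentile_interpolated(list(rates), 99)
        assert background_level(profile) == pytest.approx(want, abs=1e-12)


def test_background_of_singleton():
    profile = _profile_from_rates([], amb=[0.05])
    assert background_level(profile) == 0.05


def test_background_requires_ambiguous_coverage():
    profile = _profile_from_rates([0, 1, 0, 1])
    with pytest.raises(ValueError):
        background_level(profile)


def test_background_monotone_in_any_rate():
    rng = np.random.default_rng(3)
    rates = rng.random(30)
    base = background_level(_profile_from_rates([], amb=rates))
    bumped = rates.copy()
    bumped[7] = min(1.0, bumped[7] + 0.3)
    assert background_level(_profile_from_rates([], amb=bumped)) >= base


def test_foreground_examples():
    prof = _profile_from_rates([0, 0, 1, 1])
    assert foreground_level(prof, 0.02) == 1.0
    prof2 = _profile_from_rates([0.5, 0.9])
    assert foreground_level(prof2, 0.1) == pytest.approx(0.7)
    prof3 = _profile_from_rates([0.01, 0.02])
    assert foreground_level(prof3, 0.05) is None


def test_foreground_is_exact_mean_of_defining_subset():
    rng = np.random.default_rng(8)
    rates = rng.random(50)
    prof = _profile_from_rates(rates)
    b = 0.4
    want = rates[rates > b].mean()
    assert foreground_level(prof, b) == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# sigmoid fit
# ---------------------------------------------------------------------------

def test_fit_noiseless_step():
    rates = [0.0] * 25 + [1.0] * 25
    pos = np.arange(50) * 10
    fit = fit_crossover_sigmoid(_profile_from_rates(rates, disc_pos=pos))
    assert fit.converged
    assert pos[24] <= fit.inflection <= pos[25]
    assert abs(fit.left - 0) < 0.05 and abs(fit.right - 1) < 0.05


def test_fit_constant_data_is_degenerate():
    fit = fit_crossover_sigmoid(_profile_from_rates([0.0] * 30))
    assert fit.amplitude < 0.30 or not fit.converged


def test_fit_recovers_noisy_step_location():
    rng = np.random.default_rng(123)
    errs = []
    for _ in range(20):
        pos = np.sort(rng.choice(3000, 50, replace=False)).astype(float)
        true_c = 1500.0
        rates = np.clip((pos > true_c).astype(float)
                        + rng.normal(0, 0.05, 50), 0, 1)
        fit = fit_crossover_sigmoid(_profile_from_rates(rates, disc_pos=pos))
        assert fit.converged
        errs.append(abs(fit.inflection - true_c))
    spacing = np.median(np.diff(np.sort(pos)))
    assert np.median(errs) <= 2 * max(spacing, 3000 / 50)


def test_fit_requires_four_sites():
    fit = fit_crossover_sigmoid(_profile_from_rates([0, 1, 1]))
    assert not fit.converged


# ---------------------------------------------------------------------------
# fusion call
# ---------------------------------------------------------------------------

def test_call_perfect_chimera_labels_crossover(toy_pair, toy_catalog, toy_model):
    pair, _ = toy_pair
    # crossover inside the toy model's intron 2
    i2 = next(f for f in toy_model.features if f[0] == "I2")
    c = (i2[1] + i2[2]) // 2
    template, _, _ = make_chimera(pair, c)
    calls = [genotype_read(template, pair, toy_catalog) for _ in range(25)]
    profile, fusion = call_sample(calls, toy_catalog, toy_model)
    assert fusion.status == "fused"
    lo, hi = fusion.crossover_interval
    assert lo <= c <= hi
    assert fusion.region_label in ("I2", "E2-I2", "I2-E3")


def test_call_no_fusion_on_flat_intermediate_noise():
    rng = np.random.default_rng(4)
    rates = np.clip(rng.normal(0.5, 0.03, 60), 0, 1)
    profile = _profile_from_rates(rates, amb=np.full(40, 0.02))
    b = background_level(profile)
    f = foreground_level(profile, b)
    fit = fit_crossover_sigmoid(profile)
    call = call_fusion(profile, fit, b, f)
    assert call.status == "no_fusion"


def test_call_no_fusion_on_pure_paralog(toy_pair, toy_catalog, toy_model):
    pair, _ = toy_pair
    reads = simulate_reads(pair.seq_b, n_reads=20, seed=6)
    calls = [genotype_read(r, pair, toy_catalog) for r in reads]
    _, fusion = call_sample(calls, toy_catalog, toy_model)
    assert fusion.status == "no_fusion"
    assert fusion.region_label == "No fusion observed"
    assert fusion.crossover_interval is None


def test_noiseless_interval_contains_breakpoint(toy_pair, toy_catalog, toy_model):
    pair, _ = toy_pair
    for c in (700, 1100, 1500):
        template, _, _ = make_chimera(pair, c)
        calls = [genotype_read(template, pair, toy_catalog) for _ in range(25)]
        _, fusion = call_sample(calls, toy_catalog, toy_model)
        assert fusion.status == "fused"
        lo, hi = fusion.crossover_interval
        assert lo <= c <= hi


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def test_subsample_full_depth_concordant(chimera_sample, toy_model):
    pair, model, reads, truth = chimera_sample
    from parafuse.reference import align_gene_pair, extract_informative_sites
    catalog = extract_informative_sites(align_gene_pair(pair))
    calls = [genotype_read(r, pair, catalog) for r in reads]
    table = subsample_stability(calls, catalog, model, depths=(len(calls),),
                                replicates=3, seed=1)
    assert table["concordant"].all()


def test_subsample_skips_excess_depth(chimera_sample):
    pair, model, reads, _ = chimera_sample
    catalog = extract_informative_sites(align_gene_pair(pair))
    calls = [genotype_read(r, pair, catalog) for r in reads[:20]]
    table = subsample_stability(calls, catalog, model, depths=(10, 10**6),
                                replicates=2, seed=0)
    assert set(table["depth"]) == {10}
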