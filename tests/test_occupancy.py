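import warnings

import numpy as np
import pytest

from rotpos.energy import energy_track, normalize_unit_range
from rotpos.errors import EmptyTrackError, InvalidArgumentError, InvalidStateError
from rotpos.occupancy import (
    envelope_occupancy,
    gaussian_weights,
    local_maxima,
    occupancy_model1,
    positioning_scores,
    rotational_positioning_index,
    wave_packet,
)
from rotpos.synthetic import SyntheticSpec, generate_periodic_sequence
from rotpos.track import EnergyTrack, PositioningScoreTrack, RPITrack, Track


def kernel_sum_oracle():
    """Independent brute-force W = sum_{k=-73}^{73} exp(-k^2/800)."""
    return sum(np.exp(-(k**2) / 800.0) for k in range(-73, 74))


def make_energy(values, normalized=True, kind="bending", start=0):
    return EnergyTrack(
        chrom="t", start=start, values=np.asarray(values, float),
        kind=kind, window_len=101, normalized=normalized,
    )


def make_scores(values, start=0, kind="bending"):
    return PositioningScoreTrack(
        chrom="t", start=start, values=np.asarray(values, float), beta=1.0, source_kind=kind
    )


# -- positioning scores ---------------------------------------------------


def test_score_of_zero_energy_is_one():
    p = positioning_scores(make_energy([0.0, 0.0]))
    np.testing.assert_allclose(p.values, 1.0)


def test_score_of_minus_one_is_e():
    p = positioning_scores(make_energy([-1.0]))
    assert p.values[0] == pytest.approx(np.e)


def test_beta_zero_gives_flat_scores(rng):
    p = positioning_scores(make_energy(rng.uniform(-1, 1, 50)), beta=0.0)
    np.testing.assert_allclose(p.values, 1.0)


def test_scores_require_normalized_track():
    with pytest.raises(InvalidStateError):
        positioning_scores(make_energy([0.5], normalized=False))


def test_scores_bounded_by_exp_beta(rng):
    beta = 1.7
    p = positioning_scores(make_energy(rng.uniform(-1, 1, 200)), beta=beta)
    assert np.all(p.values >= np.exp(-beta) - 1e-12)
    assert np.all(p.values <= np.exp(beta) + 1e-12)


# -- model #1 -------------------------------------------------------------


def test_model1_kernel_sum_oracle():
    p = make_scores(np.ones(300))
    occ = occupancy_model1(p)
    np.testing.assert_allclose(occ.values, kernel_sum_oracle(), atol=1e-9)


def test_model1_delta_readout():
    vals = np.zeros(301)
    vals[150] = 1.0
    occ = occupancy_model1(make_scores(vals))
    for i in occ.positions():
        k = i - 150
        want = np.exp(-(k**2) / 800.0) if abs(k) <= 73 else 0.0
        assert occ.value_at(i) == pytest.approx(want, abs=1e-12)


def test_model1_linearity(rng):
    vals = rng.uniform(0.5, 2.0, 400)
    occ1 = occupancy_model1(make_scores(vals))
    occ2 = occupancy_model1(make_scores(2 * vals))
    np.testing.assert_allclose(occ2.values, 2 * occ1.values, rtol=1e-12)


def test_model1_defined_region_shrinks_by_73():
    occ = occupancy_model1(make_scores(np.ones(200), start=10))
    assert occ.start == 10 + 73
    assert occ.end == 10 + 200 - 73


def test_model1_short_interval_rejected():
    with pytest.raises(EmptyTrackError):
        occupancy_model1(make_scores(np.ones(146)))


def test_model1_shift_equivariance(rng):
    vals = rng.uniform(0.5, 2.0, 300)
    a = occupancy_model1(make_scores(vals, start=0))
    b = occupancy_model1(make_scores(vals, start=17))
    assert b.start - a.start == 17
    np.testing.assert_array_equal(a.values, b.values)


# -- rotational positioning index ----------------------------------------


def test_wave_packet_shape():
    f = wave_packet()
    assert len(f) == 147
    assert f[73] == pytest.approx(1.0)  # exp(0)*exp(0)
    np.testing.assert_allclose(np.abs(f), np.exp(-np.arange(-73, 74) ** 2 / 800.0))


def test_rpi_of_constant_scores_is_tiny():
    # Gaussian-windowed complex exponential: direct summation gives the
    # small DC leakage exactly; it is ~5e-5 of the kernel sum W.
    rpi = rotational_positioning_index(make_scores(np.ones(400)))
    W = kernel_sum_oracle()
    leak = np.real(np.sum(wave_packet()))
    np.testing.assert_allclose(rpi.values[np.isfinite(rpi.values)], leak, atol=1e-12)
    assert np.nanmax(np.abs(rpi.values)) < 1e-4 * W


def test_rpi_oracle_on_cosine():
    P = 9.906
    j = np.arange(600)
    p = make_scores(1 + np.cos(2 * np.pi * j / P))
    rpi = rotational_positioning_index(p, period=P)
    # independent direct-summation oracle at a few positions
    k = np.arange(-73, 74)
    f = np.exp(-(k**2) / 800.0) * np.exp(2j * np.pi * k / P)
    for pos in (200, 300, 417):
        want = np.real(np.sum(p.values[pos - 73 : pos + 74] * f))
        assert rpi.value_at(pos) == pytest.approx(want, abs=1e-9)
    # maximum sits at cosine peaks with value ~ W/2
    W = kernel_sum_oracle()
    peak_pos = int(round(30 * P))  # cos peak near index 297
    assert rpi.value_at(peak_pos) == pytest.approx(W / 2, rel=0.01)
    assert np.nanmax(rpi.values) == pytest.approx(W / 2, rel=0.02)


def test_rpi_half_period_shift_flips_sign():
    P = 10.0
    j = np.arange(600)
    base = 1 + np.cos(2 * np.pi * j / P)
    r1 = rotational_positioning_index(make_scores(base), period=P)
    r2 = rotational_positioning_index(make_scores(np.roll(base, 5)), period=P)
    assert np.sign(r1.value_at(300)) == -np.sign(r2.value_at(300))
    # equal magnitude up to the small DC leakage of the packet
    leak = np.real(np.sum(wave_packet(period=P)))
    assert r1.value_at(300) - leak == pytest.approx(-(r2.value_at(300) - leak), abs=1e-9)


def test_rpi_shift_equivariance(rng):
    vals = rng.uniform(0.5, 2.0, 300)
    a = rotational_positioning_index(make_scores(vals, start=0))
    b = rotational_positioning_index(make_scores(vals, start=23))
    assert b.start - a.start == 23
    np.testing.assert_array_equal(a.values, b.values)


def test_rpi_warns_on_shearing_scores():
    with pytest.warns(UserWarning, match="bending"):
        rotational_positioning_index(make_scores(np.ones(200), kind="shearing"))


def test_rpi_rejects_nonpositive_period():
    with pytest.raises(InvalidArgumentError):
        rotational_positioning_index(make_scores(np.ones(200)), period=0.0)


def test_rpi_magnitude_bound(rng):
    vals = rng.uniform(0.5, 2.0, 400)
    rpi = rotational_positioning_index(make_scores(vals), store_complex=True)
    bound = vals.max() * np.sum(np.abs(wave_packet()))
    assert np.nanmax(np.abs(rpi.values)) <= bound + 1e-9


# -- local maxima / envelope ----------------------------------------------


def test_local_maxima_strict_and_plateau():
    v = np.array([0, 2, 0, 1, 1, 1, 0, 3, 3, 0, 5], float)
    # strict peak at 1; plateau [3,5] midpoint 4; plateau [7,8] -> 7; endpoint 10 ignored
    np.testing.assert_array_equal(local_maxima(v), [1, 4, 7])


def test_envelope_of_constant_amplitude_cosine():
    A = 2.5
    i = np.arange(500)
    rpi = RPITrack(chrom="t", start=0, values=A * np.cos(2 * np.pi * i / 10.0))
    env = envelope_occupancy(rpi)
    inner = slice(20, 480)
    assert np.all(np.abs(env.values[inner] - A) <= 0.05 * A)


def test_envelope_exact_at_knots(rng):
    vals = np.cumsum(rng.normal(size=400))
    vals = vals - vals.mean() + 2 * np.sin(np.arange(400) / 7.0)
    rpi = RPITrack(chrom="t", start=5, values=vals)
    env = envelope_occupancy(rpi)
    for k in local_maxima(vals):
        assert env.values[k] >= vals[k] - 1e-12
        assert env.values[k] == pytest.approx(max(vals[k], 0.0), abs=1e-9)


def test_envelope_nonpositive_rpi_gives_zero():
    vals = -1.0 - np.abs(np.sin(np.arange(300) / 3.0))
    env = envelope_occupancy(RPITrack(chrom="t", start=0, values=vals))
    np.testing.assert_array_equal(env.values, 0.0)


def test_envelope_degenerate_single_peak_warns():
    vals = -((np.arange(51) - 25.0) ** 2)  # one interior maximum
    with pytest.warns(UserWarning, match="local maxima"):
        env = envelope_occupancy(RPITrack(chrom="t", start=0, values=vals))
    assert env.degenerate
    np.testing.assert_allclose(env.values, 0.0)  # max is 0 -> floor keeps 0


def test_envelope_boundary_held_constant():
    i = np.arange(400)
    vals = np.cos(2 * np.pi * i / 10.0)
    env = envelope_occupancy(RPITrack(chrom="t", start=0, values=vals))
    first_knot = local_maxima(vals)[0]
    np.testing.assert_allclose(env.values[:first_knot], vals[first_knot])


def test_envelope_peak_near_planted_dyad(params, template101):
    spec = SyntheticSpec(n_nucleosomes=1, seed=11, pad=200)
    seq, truth = generate_periodic_sequence(spec)
    bend = energy_track(seq, template101, params, "bending")
    p = positioning_scores(normalize_unit_range(bend))
    rpi = rotational_positioning_index(p)
    env = envelope_occupancy(rpi)
    d = truth.dyads[0]
    # every 101-bp window fully inside the planted footprint shares the
    # same expected energy, so the envelope is a plateau across the
    # footprint: the maximum lies within the window half-width of the
    # dyad and the dyad itself sits essentially at plateau height.
    best = int(env.positions()[np.nanargmax(env.values)])
    assert abs(best - d) <= 50
    assert env.value_at(d) >= 0.85 * np.nanmax(env.values)


def test_model2_dyads_beat_linker_midpoints(params, template101):
    hits = 0
    n = 12
    for seed in range(n):
        spec = SyntheticSpec(n_nucleosomes=5, spacing=180, seed=seed)
        seq, truth = generate_periodic_sequence(spec)
        bend = energy_track(seq, template101, params, "bending")
        p = positioning_scores(normalize_unit_range(bend))
        env = envelope_occupancy(rotational_positioning_index(p))
        at_dyads = np.mean([env.value_at(d) for d in truth.dyads])
        linkers = (truth.dyads[:-1] + truth.dyads[1:]) // 2
        at_linkers = np.mean([env.value_at(m) for m in linkers])
        hits += at_dyads > at_linkers
    assert hits >= 0.95 * n


def test_gaussian_weights_match_definition():
    w = gaussian_weights()
    k = np.arange(-73, 74)
    np.testing.assert_allclose(w, np.exp(-0.5 * (k / 20.0) ** 2))
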