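"""Epoching, task GLM, channel selection, trial metrics, spatial measures."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from nirsac import (
    beta_map,
    cnr,
    cor_measure,
    epoch_and_baseline,
    epoch_template,
    make_trial_schedule,
    sdc_cormat,
    select_best_channel,
    srmse,
    task_glm,
    trial_metrics,
)
from nirsac.constants import FS
from nirsac.evaluate import EPOCH_POST_S, EPOCH_PRE_S, TaskGLM
from nirsac.glm import OLS

from conftest import make_hemo

N_PRE = int(round(EPOCH_PRE_S * FS))  # 39
N_LEN = N_PRE + int(round(EPOCH_POST_S * FS))  # 234


# ---------------------------------------------------------------------------
# epoching


def test_epoch_shape_and_count(zero_noise_hemo, sim_schedule):
    ep = epoch_and_baseline(zero_noise_hemo, sim_schedule)
    assert ep.hbo.shape == (5, 24, N_LEN)
    assert ep.hbr.shape == (5, 24, N_LEN)
    assert ep.n_trials == 5
    assert ep.n_baseline == N_PRE


def test_epoch_baseline_is_zero_mean(sa_hemo, sim_schedule):
    ep = epoch_and_baseline(sa_hemo, sim_schedule)
    base = ep.hbo[:, :, :N_PRE].mean(axis=2)
    assert np.max(np.abs(base)) < 1e-10


def test_epoch_drops_overrunning_trials(layout, sim_schedule):
    # truncate the recording so the last trial's +25 s window overruns
    n = int(round((sim_schedule.onsets[-1] + 10.0) * FS))
    hemo = make_hemo(layout, np.zeros((24, n)), np.zeros((24, n)))
    hemo.hbo += np.linspace(0, 1, n)[None, :]
    ep = epoch_and_baseline(hemo, sim_schedule)
    assert ep.n_trials == len(sim_schedule.onsets) - 1


def test_epoch_no_trials_raises(layout, sim_schedule):
    hemo = make_hemo(layout, np.zeros((24, 10)), np.zeros((24, 10)))
    with pytest.raises(ValueError):
        epoch_and_baseline(hemo, sim_schedule)


def test_epoch_template_structure():
    tpl = epoch_template(FS)
    assert len(tpl) == N_LEN
    assert np.all(tpl[:N_PRE] == 0)
    assert tpl.max() == pytest.approx(1.0)
    # peak 6 s after onset
    assert abs((np.argmax(tpl) - N_PRE) / FS - 6.0) < 0.2


# ---------------------------------------------------------------------------
# task GLM and channel selection


def test_task_glm_recovers_injected_amplitudes(zero_noise_hemo, sim_schedule):
    glm = task_glm(zero_noise_hemo, sim_schedule, mode="hrf", solver=OLS)
    # intercept + (regressor, d1, d2)
    assert glm.fits["hbo"].betas.shape == (4, 16)
    b_hbo = glm.task_betas("SIM", "hbo")
    b_hbr = glm.task_betas("SIM", "hbr")
    assert b_hbo[5] == pytest.approx(10.0, abs=0.2)
    assert b_hbo[7] == pytest.approx(5.0, abs=0.2)
    assert b_hbr[5] == pytest.approx(-10.0 / 3, abs=0.1)
    others = np.delete(b_hbo, [5, 7])
    assert np.max(np.abs(others)) < 0.2


def test_select_best_channel_semisim(zero_noise_hemo, sim_schedule):
    glm = task_glm(zero_noise_hemo, sim_schedule, mode="hrf", solver=OLS)
    assert select_best_channel(glm, "SIM", "hbo") == 6
    assert select_best_channel(glm, "SIM", "hbr") == 6


def _fake_glm(layout, betas_hbo):
    b = np.zeros((2, 16))
    b[1] = betas_hbo
    return TaskGLM({"hbo": SimpleNamespace(betas=b)}, {"SIM": 1}, layout)


def test_select_best_channel_tie_breaks_low_id(layout):
    betas = np.zeros(16)
    roi = layout.roi_channels("M1_LEFT")
    betas[np.array(roi) - 1] = 1.0  # all tied
    assert select_best_channel(_fake_glm(layout, betas), "SIM", "hbo") == min(roi)


def test_select_best_channel_skips_pruned(layout):
    roi = sorted(layout.roi_channels("M1_LEFT"))
    betas = np.zeros(16)
    betas[roi[0] - 1] = np.nan  # best-by-tie channel pruned
    betas[roi[1] - 1] = 0.5
    assert select_best_channel(_fake_glm(layout, betas), "SIM", "hbo") == roi[1]


def test_select_best_channel_all_pruned_raises(layout):
    betas = np.zeros(16)
    for cid in layout.roi_channels("M1_LEFT"):
        betas[cid - 1] = np.nan
    with pytest.raises(ValueError):
        select_best_channel(_fake_glm(layout, betas), "SIM", "hbo")


# ---------------------------------------------------------------------------
# single-trial metrics


def test_srmse_perfect_fit_is_zero():
    tpl = epoch_template(FS)
    assert srmse(3.0 * tpl + 1.5, tpl) < 1e-10
    assert srmse(-2.0 * tpl + 0.3, tpl, species="hbr") < 1e-10


def test_srmse_affine_invariance():
    rng = np.random.default_rng(0)
    tpl = epoch_template(FS)
    y = tpl + rng.normal(0, 0.3, len(tpl))
    assert srmse(5.0 * y - 2.0, tpl) == pytest.approx(srmse(y, tpl), abs=1e-12)


def test_srmse_matches_regression_oracle():
    rng = np.random.default_rng(1)
    tpl = epoch_template(FS)
    y = tpl + rng.normal(0, 0.5, len(tpl))
    ys = (y - y.min()) / (y.max() - y.min())
    xs = (tpl - tpl.min()) / (tpl.max() - tpl.min())
    slope, icpt, *_ = stats.linregress(xs, ys)
    expected = float(np.sqrt(np.mean((ys - icpt - slope * xs) ** 2)))
    assert srmse(y, tpl) == pytest.approx(expected, abs=1e-12)


def test_srmse_flat_epoch_nan():
    tpl = epoch_template(FS)
    assert np.isnan(srmse(np.zeros(len(tpl)), tpl))


def test_cor_perfect_template_hits_clamp():
    tpl = epoch_template(FS)
    # monotone transform preserves ranks -> rho = 1, clamped before atanh
    assert cor_measure(np.exp(tpl), tpl) == pytest.approx(np.arctanh(1 - 1e-7))
    assert cor_measure(-tpl, tpl, species="hbr") == pytest.approx(np.arctanh(1 - 1e-7))


def test_cor_matches_spearman_oracle():
    rng = np.random.default_rng(2)
    tpl = epoch_template(FS)
    y = tpl + rng.normal(0, 1.0, len(tpl))
    rho = stats.spearmanr(y, tpl).statistic
    assert cor_measure(y, tpl) == pytest.approx(np.arctanh(rho), abs=1e-12)


def test_cor_anticorrelated_is_negative():
    tpl = epoch_template(FS)
    assert cor_measure(-tpl, tpl) < -5  # atanh of clamped -1


def test_cnr_scale_invariant():
    rng = np.random.default_rng(3)
    y = epoch_template(FS) + rng.normal(0, 0.2, N_LEN)
    assert cnr(7.0 * y, FS) == pytest.approx(cnr(y, FS), abs=1e-12)


def test_cnr_positive_for_clean_response_and_hbr_flip():
    rng = np.random.default_rng(4)
    noise = rng.normal(0, 0.1, N_LEN)
    y = epoch_template(FS) + noise
    assert cnr(y, FS) > 2
    assert cnr(-y, FS, species="hbr") == pytest.approx(cnr(y, FS))


def test_cnr_zero_variance_nan():
    assert np.isnan(cnr(np.zeros(N_LEN), FS))


def test_cnr_matches_manual_computation():
    rng = np.random.default_rng(5)
    y = epoch_template(FS) + rng.normal(0, 0.2, N_LEN)
    base, post = y[:N_PRE], y[N_PRE:]
    peak = int(np.argmax(post))
    hw = int(round(2.0 * FS))
    task = post[max(0, peak - hw) : peak + hw + 1]
    expected = (task.mean() - base.mean()) / np.sqrt(task.var() + base.var())
    assert cnr(y, FS) == pytest.approx(expected, abs=1e-12)


def test_cnr_decreases_with_noise():
    rng = np.random.default_rng(6)
    tpl = epoch_template(FS)
    lo = np.mean([cnr(tpl + rng.normal(0, 0.05, N_LEN), FS) for _ in range(20)])
    hi = np.mean([cnr(tpl + rng.normal(0, 1.0, N_LEN), FS) for _ in range(20)])
    assert lo > hi


def test_trial_metrics_shapes(zero_noise_hemo, sim_schedule):
    ep = epoch_and_baseline(zero_noise_hemo, sim_schedule)
    m = trial_metrics(ep, 6, "hbo")
    assert set(m) == {"srmse", "cor", "cnr"}
    for v in m.values():
        assert v.shape == (5,)
    # injected channel matches the template almost perfectly on every trial
    assert np.all(m["srmse"] < 0.05)
    assert np.all(m["cor"] > 2.0)


# ---------------------------------------------------------------------------
# spatial specificity


def test_sdc_cormat_properties(sa_hemo, sim_schedule):
    ep = epoch_and_baseline(sa_hemo, sim_schedule)
    mats = sdc_cormat(ep, ep)
    for sp in ("hbo", "hbr"):
        M = mats[sp]
        assert M.shape == (24, 24)
        assert np.allclose(M, M.T, atol=1e-10)
        assert np.allclose(np.diag(M), 1.0, atol=1e-10)
        assert np.nanmax(np.abs(M)) <= 1 + 1e-10


def test_sdc_cormat_identical_rows_give_one(layout, sim_schedule):
    rng = np.random.default_rng(7)
    n = int(round(sim_schedule.end_time * FS)) + 300
    base = rng.normal(size=n)
    hbo = np.tile(base, (24, 1))
    hemo = make_hemo(layout, hbo, hbo.copy())
    ep = epoch_and_baseline(hemo, sim_schedule)
    M = sdc_cormat(ep, ep)["hbo"]
    assert np.allclose(M, 1.0, atol=1e-10)


def test_sdc_cormat_pruned_channel_nan(layout, sim_schedule):
    rng = np.random.default_rng(8)
    n = int(round(sim_schedule.end_time * FS)) + 300
    hbo = rng.normal(size=(24, n))
    hbo[2] = np.nan
    hemo = make_hemo(layout, hbo, rng.normal(size=(24, n)))
    M = sdc_cormat(
        epoch_and_baseline(hemo, sim_schedule),
        epoch_and_baseline(hemo, sim_schedule),
    )["hbo"]
    assert np.isnan(M[2]).all() and np.isnan(M[:, 2]).all()
    mask = np.ones(24, bool)
    mask[2] = False
    assert np.isfinite(M[np.ix_(mask, mask)]).all()


def test_sdc_cormat_sdc_rows_come_from_reference(layout, sim_schedule):
    # the method epochs' SDC rows must be ignored: SDC block comes from the
    # reference (uncorrected) epochs
    rng = np.random.default_rng(9)
    n = int(round(sim_schedule.end_time * FS)) + 300
    hbo = rng.normal(size=(24, n))
    hemo_ref = make_hemo(layout, hbo, hbo.copy())
    corrupted = hbo.copy()
    corrupted[16:] = 0.0
    hemo_m = make_hemo(layout, corrupted, corrupted.copy())
    M = sdc_cormat(
        epoch_and_baseline(hemo_m, sim_schedule),
        epoch_and_baseline(hemo_ref, sim_schedule),
    )["hbo"]
    assert np.isfinite(M[16:, :16]).all()


# ---------------------------------------------------------------------------
# beta maps


def test_beta_map_mean_and_counts():
    betas = np.arange(6.0 * 16).reshape(6, 16)
    bm = beta_map(betas, lambda v: 42.0)
    assert np.allclose(bm.mean_beta, betas.mean(axis=0))
    assert np.all(bm.n_subjects == 6)
    assert np.allclose(bm.bf10, 42.0)


def test_beta_map_nan_handling():
    betas = np.ones((4, 16))
    betas[:, 0] = np.nan  # 0 subjects
    betas[1:, 1] = np.nan  # 1 subject
    betas[2:, 2] = np.nan  # 2 subjects: mean but no BF
    bm = beta_map(betas, lambda v: float(len(v)))
    assert np.isnan(bm.mean_beta[0]) and np.isnan(bm.bf10[0])
    assert np.isnan(bm.mean_beta[1]) and np.isnan(bm.bf10[1])
    assert bm.mean_beta[2] == 1.0 and np.isnan(bm.bf10[2])
    assert bm.mean_beta[3] == 1.0 and bm.bf10[3] == 4.0
    assert list(bm.n_subjects[:4]) == [0, 1, 2, 4]


def test_beta_map_bf_fn_receives_nan_free_values():
    betas = np.ones((5, 16))
    betas[0, 3] = np.nan
    seen = []

    def bf(v):
        seen.append(np.asarray(v))
        return 1.0

    bm = beta_map(betas, bf)
    assert all(np.isfinite(v).all() for v in seen)
    assert bm.n_subjects[3] == 4


# ---------------------------------------------------------------------------
# directionality across seeds


def test_metrics_rank_injected_channels_across_seeds():
    # channel 6 (10 uM) should out-score channel 8 (5 uM) under shared SA
    from nirsac import (
        HRFSpec,
        SAParams,
        inject_canonical_hrf,
        intensity_to_od,
        make_probe_layout,
        make_trial_schedule,
        od_to_hemoglobin,
        simulate_rest_recording,
    )
    from nirsac.preprocess import bandpass

    layout = make_probe_layout()
    wins = 0
    for seed in (0, 1, 2):
        sched = make_trial_schedule("SIM", 4, seed=seed)
        raw = simulate_rest_recording(layout, sched.end_time + 15, SAParams(), 65.0, seed)
        hemo = bandpass(
            inject_canonical_hrf(
                od_to_hemoglobin(intensity_to_od(raw), 65.0),
                sched,
                HRFSpec({6: 10.0, 8: 5.0}),
            )
        )
        ep = epoch_and_baseline(hemo, sched)
        c6 = np.nanmean(trial_metrics(ep, 6, "hbo")["cnr"])
        c8 = np.nanmean(trial_metrics(ep, 8, "hbo")["cnr"])
        wins += c6 > c8
    assert wins >= 2
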