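"""Single-trial quality metrics and spatial-specificity measures.

Epochs are cut [-5, 25) s around stimulus onset and baseline corrected with
the mean of the 5 s pre-onset window.  Signal improvement is quantified per
trial by the scaled RMSE of a min-max-normalized regression on the canonical
HRF, the Fisher-z-transformed Spearman correlation with the HRF, and the
contrast-to-noise ratio of the peak window against baseline.  Spatial
specificity is summarized by 24x24 channel/SDC Spearman correlation matrices
and group-level beta maps.

For HbR the template is sign-flipped (and CNR negated) so that larger values
always mean better signal quality for both species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import AR_IRLS, GLMFit, fit_glm
from .preprocess import HemoSeries, canonical_hrf
from .probe import TASK_ROI, ProbeLayout
from .synth import Session, TrialSchedule

EPOCH_PRE_S = 5.0
EPOCH_POST_S = 25.0


# ---------------------------------------------------------------------------
# epoching


@dataclass
class Epochs:
    """Baseline-corrected trial windows, (trials, channels, samples) per species."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    layout: ProbeLayout
    pre_s: float = EPOCH_PRE_S
    post_s: float = EPOCH_POST_S

    @property
    def n_trials(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_baseline(self) -> int:
        return int(round(self.pre_s * self.fs))

    def species(self, name: str) -> np.ndarray:
        return self.hbo if name == "hbo" else self.hbr


def epoch_and_baseline(hemo: HemoSeries, schedule: TrialSchedule) -> Epochs:
    """Cut [-5, 25) s windows at each onset and subtract the baseline mean.

    Onsets are snapped to the nearest sample; trials whose window overruns the
    recording are dropped.
    """
    n_pre = int(round(EPOCH_PRE_S * hemo.fs))
    n_post = int(round(EPOCH_POST_S * hemo.fs))
    n_len = n_pre + n_post
    segs = {"hbo": [], "hbr": []}
    for onset in schedule.onsets:
        i0 = int(round(onset * hemo.fs)) - n_pre
        if i0 < 0 or i0 + n_len > hemo.n_samples:
            continue
        for sp in segs:
            seg = hemo.species(sp)[:, i0 : i0 + n_len].copy()
            seg -= seg[:, :n_pre].mean(axis=1, keepdims=True)
            segs[sp].append(seg)
    if not segs["hbo"]:
        raise ValueError("no trial fits within the recording")
    return Epochs(np.stack(segs["hbo"]), np.stack(segs["hbr"]), hemo.fs, hemo.layout)


def epoch_template(fs: float, peak_s: float = 6.0) -> np.ndarray:
    """Canonical-HRF reference on the epoch grid: zeros pre-onset, HRF after."""
    n_pre = int(round(EPOCH_PRE_S * fs))
    n_post = int(round(EPOCH_POST_S * fs))
    tpl = canonical_hrf(fs, duration_s=EPOCH_POST_S + 1, peak_s=peak_s)[:n_post]
    return np.concatenate([np.zeros(n_pre), tpl])


# ---------------------------------------------------------------------------
# task GLM and channel selection


@dataclass
class TaskGLM:
    fits: dict[str, GLMFit]  # species -> fit over the 16 regular channels
    task_columns: dict[str, int]  # condition label -> design column
    layout: ProbeLayout

    def task_betas(self, label: str, species: str) -> np.ndarray:
        """(16,) beta per regular channel for a condition."""
        return self.fits[species].betas[self.task_columns[label]]


def _with_derivatives(reg: np.ndarray) -> list[np.ndarray]:
    d1 = np.gradient(reg)
    d2 = np.gradient(d1)
    return [reg, d1, d2]


def _hrf_regressor(onsets: np.ndarray, n: int, fs: float) -> np.ndarray:
    tpl = canonical_hrf(fs, 30.0)
    reg = np.zeros(n)
    for onset in onsets:
        i0 = int(round(onset * fs))
        i1 = min(i0 + len(tpl), n)
        if i0 < n:
            reg[i0:i1] += tpl[: i1 - i0]
    return reg


def _block_regressor(onsets: np.ndarray, duration_s: float, n: int, fs: float) -> np.ndarray:
    box = np.zeros(n)
    for onset in onsets:
        i0 = int(round(onset * fs))
        i1 = min(i0 + int(round(duration_s * fs)), n)
        if 0 <= i0 < n:
            box[i0:i1] = 1.0
    tpl = canonical_hrf(fs, 30.0)
    reg = np.convolve(box, tpl)[:n]
    m = np.abs(reg).max()
    return reg / m if m > 0 else reg


def task_glm(
    hemo: HemoSeries,
    schedules: TrialSchedule | Session,
    mode: str = "hrf",
    solver: str = AR_IRLS,
    max_ar_order: int | None = None,
) -> TaskGLM:
    """Fit the task-activation GLM on the 16 regular channels, per species.

    ``mode="hrf"`` (semisimulation): one regressor holding a canonical HRF at
    every onset.  ``mode="block"`` (real-task): one boxcar-convolved-HRF
    regressor per condition plus instruction and break regressors.  Every
    regressor enters with its first and second temporal derivatives; an
    intercept is always included.
    """
    n = hemo.n_samples
    fs = hemo.fs
    cols: list[np.ndarray] = [np.ones(n)]
    task_columns: dict[str, int] = {}

    if isinstance(schedules, TrialSchedule):
        sched_list = [schedules]
        instructions = breaks = None
    else:
        sched_list = list(schedules.schedules)
        instructions, breaks = schedules.instructions, schedules.breaks

    for sched in sched_list:
        if mode == "hrf":
            reg = _hrf_regressor(sched.onsets, n, fs)
        elif mode == "block":
            reg = _block_regressor(sched.onsets, sched.task_duration, n, fs)
        else:
            raise ValueError("mode must be 'hrf' or 'block'")
        task_columns[sched.task_label] = len(cols)
        cols.extend(_with_derivatives(reg))
    if mode == "block" and instructions is not None and len(instructions):
        cols.extend(_with_derivatives(_block_regressor(instructions, 2.0, n, fs)))
    if mode == "block" and breaks is not None and len(breaks):
        onsets = breaks[:, 0]
        dur = float(breaks[0, 1])
        cols.extend(_with_derivatives(_block_regressor(onsets, dur, n, fs)))

    X = np.column_stack(cols)
    n_reg = hemo.layout.n_regular
    fits = {
        sp: fit_glm(hemo.species(sp)[:n_reg].T, X, solver=solver, max_ar_order=max_ar_order)
        for sp in ("hbo", "hbr")
    }
    return TaskGLM(fits, task_columns, hemo.layout)


def select_best_channel(glm: TaskGLM, task_label: str, species: str) -> int:
    """Pick the strongest-activation channel within the task-specific ROI.

    Highest task beta for HbO, lowest for HbR; ties break toward the lowest
    channel id; fully pruned ROIs raise.
    """
    roi = TASK_ROI[task_label]
    betas = glm.task_betas(task_label, species)
    candidates = [
        (betas[cid - 1], cid)
        for cid in glm.layout.roi_channels(roi)
        if not np.isnan(betas[cid - 1])
    ]
    if not candidates:
        raise ValueError(f"ROI {roi} fully pruned; no channel selectable")
    sign = 1.0 if species == "hbo" else -1.0
    best = max(candidates, key=lambda t: (sign * t[0], -t[1]))
    return best[1]


# ---------------------------------------------------------------------------
# single-trial metrics


def srmse(
    epoch: np.ndarray,
    hrf_template: np.ndarray,
    species: str = "hbo",
    printed_form: bool = False,
) -> float:
    """Scaled RMSE of the min-max-normalized epoch against the HRF template.

    Both series are scaled to [0, 1]; the scaled epoch is regressed on the
    scaled template (with intercept) and the root mean squared residual is
    returned.  ``printed_form=True`` instead returns the plain residual mean,
    which is ~0 by construction for an intercept regression and kept only for
    reference.  For HbR the template is sign-flipped before scaling.
    """
    tpl = -hrf_template if species == "hbr" else hrf_template
    rng_e = epoch.max() - epoch.min()
    rng_t = tpl.max() - tpl.min()
    if rng_e == 0 or rng_t == 0:
        return np.nan
    ys = (epoch - epoch.min()) / rng_e
    xs = (tpl - tpl.min()) / rng_t
    X = np.column_stack([np.ones_like(xs), xs])
    beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ beta
    if printed_form:
        return float(resid.mean())
    return float(np.sqrt(np.mean(resid**2)))


def cor_measure(epoch: np.ndarray, hrf_template: np.ndarray, species: str = "hbo") -> float:
    """Fisher-z-transformed Spearman correlation of epoch and HRF template."""
    tpl = -hrf_template if species == "hbr" else hrf_template
    if np.all(epoch == epoch[0]) or np.all(tpl == tpl[0]):
        return np.nan
    rho = stats.spearmanr(epoch, tpl).statistic
    rho = float(np.clip(rho, -(1 - 1e-7), 1 - 1e-7))
    return float(np.arctanh(rho))


def cnr(
    epoch: np.ndarray,
    fs: float,
    species: str = "hbo",
    pre_s: float = EPOCH_PRE_S,
    peak_halfwidth_s: float = 2.0,
    printed_form: bool = False,
) -> float:
    """Contrast-to-noise ratio of the peak window against the baseline.

    The task segment is the +-2 s window around the post-onset peak (maximum
    for HbO, minimum for HbR), clipped to the epoch bounds; the baseline is
    the [-5, 0) s window.  Returns ``(mean_task - mean_base) /
    sqrt(var_task + var_base)`` (the square root is dropped when
    ``printed_form``), sign-flipped for HbR so larger is better.
    """
    n_pre = int(round(pre_s * fs))
    base = epoch[:n_pre]
    post = epoch[n_pre:]
    peak = int(np.argmin(post)) if species == "hbr" else int(np.argmax(post))
    hw = int(round(peak_halfwidth_s * fs))
    lo = max(0, peak - hw)
    hi = min(len(post), peak + hw + 1)
    task = post[lo:hi]
    denom = task.var() + base.var()
    if denom == 0:
        return np.nan
    if not printed_form:
        denom = np.sqrt(denom)
    val = (task.mean() - base.mean()) / denom
    return float(-val if species == "hbr" else val)


def trial_metrics(
    epochs: Epochs, channel_id: int, species: str, peak_s: float = 6.0
) -> dict[str, np.ndarray]:
    """Per-trial sRMSE / COR / CNR for one channel, plus their trial means."""
    tpl = epoch_template(epochs.fs, peak_s)
    row = channel_id - 1
    data = epochs.species(species)[:, row, :]
    out = {
        "srmse": np.array([srmse(tr, tpl, species) for tr in data]),
        "cor": np.array([cor_measure(tr, tpl, species) for tr in data]),
        "cnr": np.array([cnr(tr, epochs.fs, species) for tr in data]),
    }
    return out


# ---------------------------------------------------------------------------
# spatial specificity


def _rank_or_nan(x: np.ndarray) -> np.ndarray:
    if np.any(np.isnan(x)):
        return np.full_like(x, np.nan)
    return stats.rankdata(x)


def sdc_cormat(epochs_method: Epochs, epochs_nosac: Epochs) -> dict[str, np.ndarray]:
    """Trial-averaged 24x24 Spearman matrices, per species.

    Rows/columns are the 16 regular channels (from the method under test)
    followed by the 8 SDCs taken from the uncorrected (NO SAC) epochs.
    Pruned channels yield NaN rows/columns; trial averaging is NaN-aware.
    """
    n_reg = epochs_method.layout.n_regular
    out = {}
    for sp in ("hbo", "hbr"):
        mats = []
        for t in range(epochs_method.n_trials):
            reg = epochs_method.species(sp)[t, :n_reg, :]
            sdc = epochs_nosac.species(sp)[t, n_reg:, :]
            block = np.vstack([reg, sdc])
            ranks = np.array([_rank_or_nan(row) for row in block])
            with np.errstate(invalid="ignore", divide="ignore"):
                mats.append(np.corrcoef(ranks))
        with np.errstate(invalid="ignore"):
            out[sp] = np.nanmean(np.stack(mats), axis=0)
    return out


@dataclass
class BetaMap:
    """Group summary per regular channel: mean beta and one-sample BF10."""

    mean_beta: np.ndarray  # (16,)
    bf10: np.ndarray  # (16,)
    n_subjects: np.ndarray  # (16,) subjects contributing per channel


def beta_map(subject_betas: np.ndarray, bf_fn) -> BetaMap:
    """Average per-subject channel betas and test each channel against zero.

    ``subject_betas``: (subjects, 16) with NaN for pruned channels.
    ``bf_fn(x) -> float`` computes a one-sample Bayes factor.  Channels with
    fewer than 2 defined subjects get NaN and no test.
    """
    subject_betas = np.asarray(subject_betas, dtype=float)
    n_ch = subject_betas.shape[1]
    mean = np.full(n_ch, np.nan)
    bf = np.full(n_ch, np.nan)
    counts = np.zeros(n_ch, dtype=int)
    for c in range(n_ch):
        vals = subject_betas[:, c]
        vals = vals[~np.isnan(vals)]
        counts[c] = len(vals)
        if len(vals) >= 2:
            mean[c] = vals.mean()
        if len(vals) >= 3:
            bf[c] = bf_fn(vals)
    return BetaMap(mean, bf, counts)
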