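"""Systemic-activity correction methods.

Five corrections of band-passed hemoglobin data, plus the uncorrected
reference:

* ``NO_SAC`` - pass-through reference.
* ``CAR``    - common average reference: subtract the mean over regular channels.
* ``GCR``    - global component removal: SVD spatial vectors smoothed by a
  Gaussian kernel over inter-channel great-circle distances isolate the
  global component, which is subtracted.
* ``SSR``    - short separation regression: scalar least-squares removal of
  the Euclidean-nearest short-distance channel.
* ``GLM_ALL`` / ``GLM_BH`` - residuals of an AR-IRLS regression of each
  regular channel on short-distance-channel time courses (all eight, or SDCs
  4 and 7 only), both species included as regressors.

CAR and GCR never consult SDC data; SSR and the GLM methods never consult
other regular channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import AR_IRLS, fit_glm
from .preprocess import HemoSeries
from .probe import ProbeLayout

NO_SAC = "NO_SAC"
CAR = "CAR"
GCR = "GCR"
SSR = "SSR"
GLM_ALL = "GLM_ALL"
GLM_BH = "GLM_BH"

METHODS = (NO_SAC, CAR, GCR, SSR, GLM_ALL, GLM_BH)
SDC_METHODS = (SSR, GLM_ALL, GLM_BH)
GLM_BH_SDCS = (4, 7)

SPECIES = ("hbo", "hbr")


@dataclass
class CorrectionResult:
    method: str
    corrected: HemoSeries
    diagnostics: dict = field(default_factory=dict)


def correct_nosac(hemo: HemoSeries) -> CorrectionResult:
    """Uncorrected reference data."""
    return CorrectionResult(NO_SAC, hemo.copy(), {})


# ---------------------------------------------------------------------------
# common average reference


def correct_car(hemo: HemoSeries) -> CorrectionResult:
    """Subtract the per-sample mean over non-pruned regular channels.

    SDC rows pass through uncorrected; the subtracted mean trace per species
    is returned as a diagnostic.
    """
    n_reg = hemo.layout.n_regular
    out = hemo.copy()
    diags = {}
    for sp in SPECIES:
        data = out.species(sp)
        reg = data[:n_reg]
        ok = ~np.any(np.isnan(reg), axis=1)
        if ok.sum() < 2:
            raise ValueError("CAR needs at least 2 usable regular channels")
        mean_trace = reg[ok].mean(axis=0)
        reg[ok] -= mean_trace[None, :]
        diags[f"mean_trace_{sp}"] = mean_trace
    return CorrectionResult(CAR, out, diags)


# ---------------------------------------------------------------------------
# global component removal


@dataclass
class KernelMatrix:
    """Gaussian smoothing kernel over regular-channel angular distances."""

    D: np.ndarray  # (n, n) great-circle distances, degrees
    sigma_deg: float
    G: np.ndarray  # row-normalized kernel

    @classmethod
    def from_distances(cls, D: np.ndarray, sigma_deg: float) -> "KernelMatrix":
        G = np.exp(-(D**2) / (2.0 * sigma_deg**2))
        return cls(D, sigma_deg, G / G.sum(axis=1, keepdims=True))

    def unnormalized(self) -> np.ndarray:
        return np.exp(-(self.D**2) / (2.0 * self.sigma_deg**2))

    def subset(self, idx: np.ndarray) -> "KernelMatrix":
        """Kernel restricted to a channel subset, re-normalized per row."""
        G = self.G[np.ix_(idx, idx)]
        return KernelMatrix(
            self.D[np.ix_(idx, idx)], self.sigma_deg, G / G.sum(axis=1, keepdims=True)
        )


def build_gcr_kernel(layout: ProbeLayout, sigma_deg: float = 46.0) -> KernelMatrix:
    """Gaussian kernel ``G = exp(-D^2 / 2 sigma^2)`` over channel midpoints.

    Distances are great-circle angles (degrees) on the layout sphere; rows are
    normalized to sum to one so smoothing preserves scale.
    """
    return KernelMatrix.from_distances(layout.distances_deg(), sigma_deg)


def correct_gcr(hemo: HemoSeries, kernel: KernelMatrix | None = None) -> CorrectionResult:
    """Global component removal on the regular channels, per species.

    The data matrix (samples x channels) is decomposed by SVD; each spatial
    singular vector is smoothed by the kernel, the smoothed reconstruction is
    the global component, and its subtraction leaves the localized part.
    """
    if kernel is None:
        kernel = build_gcr_kernel(hemo.layout)
    n_reg = hemo.layout.n_regular
    out = hemo.copy()
    diags = {}
    for sp in SPECIES:
        data = out.species(sp)
        reg = data[:n_reg]
        ok = np.where(~np.any(np.isnan(reg), axis=1))[0]
        if len(ok) < 3:
            raise ValueError("GCR needs at least 3 usable regular channels")
        Y = reg[ok].T  # (samples, channels)
        G = kernel.subset(ok).G
        U, s, Vt = np.linalg.svd(Y, full_matrices=False)
        V_star = (G @ Vt.T).T  # smooth each spatial vector
        Y_global = U @ np.diag(s) @ V_star
        reg[ok] = (Y - Y_global).T
        diags[f"y_global_{sp}"] = Y_global.T
    return CorrectionResult(GCR, out, diags)


# ---------------------------------------------------------------------------
# short separation regression


def ssr_alpha(y_sdc: np.ndarray, y_rc: np.ndarray) -> float:
    """Least-squares scaling ``alpha = <y_sdc, y_rc> / <y_sdc, y_sdc>``."""
    denom = float(np.dot(y_sdc, y_sdc))
    if denom == 0:
        return 0.0
    return float(np.dot(y_sdc, y_rc)) / denom


def correct_ssr(hemo: HemoSeries) -> CorrectionResult:
    """Regress out the Euclidean-nearest (species-matched) SDC per channel.

    If a channel's nearest SDC is pruned, the next-nearest non-pruned SDC is
    used (recorded in the diagnostics); if all SDCs are pruned the correction
    refuses.
    """
    layout = hemo.layout
    n_reg = layout.n_regular
    out = hemo.copy()
    alphas: dict[str, dict[int, float]] = {}
    mapping: dict[int, int] = {}
    for sp in SPECIES:
        data = out.species(sp)
        sdc_rows = data[n_reg:]
        sdc_ok = {
            s.sdc_id: not np.any(np.isnan(sdc_rows[s.sdc_id - 1]))
            for s in layout.sdc_channels
        }
        if not any(sdc_ok.values()):
            raise ValueError("all SDCs pruned: SSR impossible")
        alphas[sp] = {}
        for ch in layout.regular_channels:
            row = ch.channel_id - 1
            if np.any(np.isnan(data[row])):
                continue
            sdc_id = next(
                sid for sid in layout.sdc_distance_rank(ch.channel_id) if sdc_ok[sid]
            )
            mapping[ch.channel_id] = sdc_id
            y_sdc = hemo.species(sp)[n_reg + sdc_id - 1]
            a = ssr_alpha(y_sdc, data[row])
            data[row] = data[row] - a * y_sdc
            alphas[sp][ch.channel_id] = a
    return CorrectionResult(SSR, out, {"alpha": alphas, "sdc_mapping": mapping})


# ---------------------------------------------------------------------------
# GLM with SDC regressors


def _sdc_design(hemo: HemoSeries, sdc_ids: tuple[int, ...]) -> np.ndarray:
    """Intercept plus mean-centered SDC regressors of both species."""
    n_reg = hemo.layout.n_regular
    cols = [np.ones(hemo.n_samples)]
    for sp in SPECIES:
        for sid in sdc_ids:
            x = hemo.species(sp)[n_reg + sid - 1]
            if np.any(np.isnan(x)):
                raise ValueError(f"SDC {sid} ({sp}) is pruned; GLM correction refused")
            cols.append(x - x.mean())
    return np.column_stack(cols)


def correct_glm_sdc(
    hemo: HemoSeries,
    subset: str = "ALL",
    solver: str = AR_IRLS,
    max_ar_order: int | None = None,
) -> CorrectionResult:
    """GLM-based correction: residuals of a regression on SDC time courses.

    ``subset="ALL"`` uses all eight SDCs of both species (16 regressors);
    ``subset="BH"`` uses SDCs 4 and 7 only (one per hemisphere, 4 regressors).
    Each regular channel is fit independently (AR-IRLS by default); the
    corrected signal subtracts only the SDC contribution, ``Y - X_SDC
    beta_SDC``, so the fitted intercept (channel offset) is retained.
    """
    if subset == "ALL":
        sdc_ids = tuple(s.sdc_id for s in hemo.layout.sdc_channels)
        method = GLM_ALL
    elif subset == "BH":
        sdc_ids = GLM_BH_SDCS
        method = GLM_BH
    else:
        raise ValueError("subset must be 'ALL' or 'BH'")

    X = _sdc_design(hemo, sdc_ids)
    n_reg = hemo.layout.n_regular
    out = hemo.copy()
    betas = {}
    for sp in SPECIES:
        Y = hemo.species(sp)[:n_reg].T  # (samples, channels)
        fit = fit_glm(Y, X, solver=solver, max_ar_order=max_ar_order)
        # residual + fitted intercept: only the SDC part is subtracted
        out.species(sp)[:n_reg] = (fit.residuals + fit.betas[0][None, :]).T
        betas[sp] = fit.betas
    return CorrectionResult(method, out, {"beta_sdc": betas, "sdc_ids": sdc_ids})


def apply_correction(hemo: HemoSeries, method: str, **kwargs) -> CorrectionResult:
    """Dispatch a correction by method name."""
    if method == NO_SAC:
        return correct_nosac(hemo)
    if method == CAR:
        return correct_car(hemo)
    if method == GCR:
        return correct_gcr(hemo, **kwargs)
    if method == SSR:
        return correct_ssr(hemo)
    if method == GLM_ALL:
        return correct_glm_sdc(hemo, "ALL", **kwargs)
    if method == GLM_BH:
        return correct_glm_sdc(hemo, "BH", **kwargs)
    raise ValueError(f"unknown method {method!r}")
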