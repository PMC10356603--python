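"""Detection and sub-pixel localization of diffraction-limited mRNA foci.

The smFISH channel shows each transcript as a near-Gaussian spot of PSF width
on top of background and slowly varying autofluorescence.  Detection follows
the standard single-molecule recipe: scale-normalized Laplacian-of-Gaussian
band-pass (suppresses both pixel noise and broad autofluorescent blobs),
strict local-maximum candidates with minimum separation, automatic threshold
selection at the plateau of the count-vs-threshold curve, and per-candidate
least-squares Gaussian fits that yield sub-pixel centers, background-corrected
amplitudes and a fit-quality gate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

__all__ = [
    "SpotDetectionParams",
    "ThresholdCurve",
    "bandpass_filter",
    "detect_candidates",
    "build_threshold_curve",
    "select_threshold",
    "fit_spots",
    "detect_spots",
    "detect_spots_stack",
]

logger = logging.getLogger(__name__)

SPOT_COLUMNS = ["id", "z", "y", "x", "amplitude", "background", "fit_r2", "cell_id", "coloc"]


def empty_spot_table() -> pd.DataFrame:
    df = pd.DataFrame(columns=SPOT_COLUMNS)
    return df.astype({"id": int, "z": float, "y": float, "x": float,
                      "amplitude": float, "background": float, "fit_r2": float,
                      "cell_id": int, "coloc": object})


@dataclass
class SpotDetectionParams:
    """Detection settings.

    ``psf_sigma_xy``/``psf_sigma_z`` are the expected spot widths in px;
    ``threshold`` is a fixed band-pass response cutoff or ``"auto"`` for the
    plateau rule; ``fit_quality_min`` is the minimum R² of the local Gaussian
    fit for a candidate to survive.
    """

    psf_sigma_xy: float = 1.5
    psf_sigma_z: float = 1.0
    min_separation: float = 2.0
    threshold: float | str = "auto"
    fit_radius: int = 3
    fit_quality_min: float = 0.5
    n_threshold_grid: int = 60

    def __post_init__(self):
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValueError("psf sigmas must be > 0")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        if not 0 <= self.fit_quality_min <= 1:
            raise ValueError("fit_quality_min must be in [0, 1]")


@dataclass
class ThresholdCurve:
    """Count-vs-threshold curve and the threshold selected from it."""

    thresholds: np.ndarray
    counts: np.ndarray
    selected: Optional[float] = None
    plateau_span: Optional[tuple[int, int]] = None
    low_confidence: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "count": self.counts})


def bandpass_filter(image: np.ndarray, psf_sigma: float) -> np.ndarray:
    """Scale-normalized, sign-flipped Laplacian of Gaussian.

    Spots of width ``psf_sigma`` become positive peaks whose height is
    comparable across sigmas (the sigma² normalization of scale-space
    theory); structures much broader than the PSF are strongly suppressed.
    """
    img = np.asarray(image, float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    resp = -(psf_sigma**2) * ndi.gaussian_laplace(img, psf_sigma)
    # the truncated discrete LoG kernel has a tiny nonzero sum; remove that
    # DC gain so a constant image gives exactly zero response
    n = int(8 * psf_sigma) + 5
    dc = float(-(psf_sigma**2) * ndi.gaussian_laplace(np.ones((n, n)), psf_sigma)[n // 2, n // 2])
    return resp - dc * img


def detect_candidates(filtered: np.ndarray, min_separation: float = 3.0) -> pd.DataFrame:
    """Strict local maxima of a band-passed image with minimum separation.

    A candidate pixel must exceed all its 8 neighbours and have response > 0;
    greedy suppression by descending response then enforces pairwise
    Euclidean distance >= ``min_separation``.  Ties are broken by (y, x)
    lexicographic order so the result is fully deterministic.

    Returns a DataFrame (y, x, response) sorted by descending response.
    """
    filtered = np.asarray(filtered, float)
    neighbors = ndi.maximum_filter(filtered, footprint=_ring_footprint(),
                                   mode="constant", cval=-np.inf)
    is_max = (filtered > neighbors) & (filtered > 0)
    ys, xs = np.nonzero(is_max)
    if len(ys) == 0:
        return pd.DataFrame(columns=["y", "x", "response"])
    resp = filtered[ys, xs]
    order = np.lexsort((xs, ys, -resp))
    ys, xs, resp = ys[order], xs[order], resp[order]

    keep = _greedy_min_separation(ys, xs, min_separation)
    return pd.DataFrame({"y": ys[keep], "x": xs[keep], "response": resp[keep]})


def _ring_footprint():
    f = np.ones((3, 3), bool)
    f[1, 1] = False
    return f


def _greedy_min_separation(ys, xs, min_sep):
    """Indices to keep (in given priority order) at pairwise distance >= min_sep."""
    pts = np.column_stack([ys, xs]).astype(float)
    tree = cKDTree(pts)
    suppressed = np.zeros(len(pts), bool)
    keep = []
    # strictly-less-than comparison: distance exactly min_sep is allowed
    for i in range(len(pts)):
        if suppressed[i]:
            continue
        keep.append(i)
        for j in tree.query_ball_point(pts[i], min_sep - 1e-9):
            if j != i:
                suppressed[j] = True
    return np.array(keep, dtype=int)


def build_threshold_curve(candidates: pd.DataFrame, n_threshold_grid: int = 60,
                          lower: float | None = None) -> ThresholdCurve:
    """Candidate counts above each threshold of a log-spaced grid.

    The grid spans the candidate response range (its lower end can be pinned
    to ``lower``, e.g. the noise floor, so the plateau between noise and
    signal responses is resolvable); counts are strictly-above, hence
    non-increasing in the threshold.  Empty candidates give a degenerate
    (empty) curve.
    """
    if len(candidates) == 0:
        return ThresholdCurve(np.array([]), np.array([], dtype=int))
    resp = np.asarray(candidates["response"], float)
    lo, hi = resp.min(), resp.max()
    if lower is not None and lower > 0:
        lo = min(lo, lower)
    lo = max(lo, hi * 1e-6)
    if hi <= lo:
        grid = np.array([lo])
    else:
        grid = np.geomspace(lo, hi, n_threshold_grid)
    counts = (resp[None, :] > grid[:, None]).sum(axis=1)
    return ThresholdCurve(grid, counts)


# plateau flatness: |Δ log10(count)| per grid step below this
PLATEAU_FLATNESS = 0.02
PLATEAU_MIN_RUN = 3  # grid points


def select_threshold(curve: ThresholdCurve) -> ThresholdCurve:
    """Select the detection threshold at the plateau of the count curve.

    The plateau is the longest contiguous run of grid points over which the
    spot count is stable (|Δ log10 count| < 0.02 per step, counts > 0); its
    midpoint is the selected threshold — the standard automatic smFISH
    criterion, which makes counting robust to the exact cutoff.  If no run of
    >= 3 points exists the curve is featureless (no separation between noise
    and signal responses) and the selection falls back to Otsu's threshold on
    the log responses, flagged ``low_confidence``.

    Returns the curve with ``selected``, ``plateau_span`` and
    ``low_confidence`` filled in.
    """
    if len(curve.thresholds) == 0:
        raise ValueError("no candidates")
    counts = curve.counts
    ok = counts > 0
    dlog = np.full(len(counts) - 1, np.inf)
    idx = np.nonzero(ok[:-1] & ok[1:])[0]
    with np.errstate(divide="ignore"):
        logc = np.log10(counts.astype(float))
    dlog[idx] = np.abs(np.diff(logc)[idx])
    flat = dlog < PLATEAU_FLATNESS

    best = _longest_run(flat)
    if best is not None and best[1] - best[0] + 2 >= PLATEAU_MIN_RUN:
        i0, i1 = best[0], best[1] + 1  # run of flat steps -> grid points [i0, i1]
        mid = (i0 + i1) // 2
        curve.selected = float(curve.thresholds[mid])
        # reported span: the stable range around the selection — counts
        # within +-5% of the midpoint count (per-step flatness allows a slow
        # cumulative drift over a long run; the span should not)
        c_mid = counts[mid]
        lo_i, hi_i = mid, mid
        while lo_i > i0 and abs(counts[lo_i - 1] - c_mid) <= 0.05 * c_mid:
            lo_i -= 1
        while hi_i < i1 and abs(counts[hi_i + 1] - c_mid) <= 0.05 * c_mid:
            hi_i += 1
        curve.plateau_span = (int(lo_i), int(hi_i))
        curve.low_confidence = False
        return curve

    # featureless curve: fall back to Otsu on log responses
    warnings.warn("no threshold plateau found; falling back to Otsu (low confidence)")
    resp = curve.thresholds
    if len(resp) >= 2:
        # reconstruct a response sample from the curve grid weighted by counts
        weights = -np.diff(np.append(curve.counts, 0))
        sample = np.repeat(np.log10(resp), np.maximum(weights, 0))
        sel = 10 ** threshold_otsu(sample) if len(np.unique(sample)) > 1 else resp[len(resp) // 2]
    else:
        sel = resp[0]
    curve.selected = float(sel)
    curve.plateau_span = None
    curve.low_confidence = True
    return curve


def _longest_run(flags: np.ndarray):
    """(start, stop) of the longest True run; later run wins ties."""
    best = None
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        if (not f or i == len(flags) - 1) and start is not None:
            stop = i if f else i - 1
            if best is None or stop - start >= best[1] - best[0]:
                best = (start, stop)
            start = None
    return best


# ---------------------------------------------------------------------------
# Gaussian fitting
# ---------------------------------------------------------------------------

def _gauss2d_residual(p, yy, xx, data):
    a, yc, xc, s, b = p
    model = a * np.exp(-((yy - yc) ** 2 + (xx - xc) ** 2) / (2.0 * s**2)) + b
    return (model - data).ravel()


def _gauss2d_jac(p, yy, xx, data):
    a, yc, xc, s, b = p
    dy = yy - yc
    dx = xx - xc
    e = np.exp(-(dy**2 + dx**2) / (2.0 * s**2))
    n = e.size
    jac = np.empty((n, 5))
    jac[:, 0] = e.ravel()
    jac[:, 1] = (a * e * dy / s**2).ravel()
    jac[:, 2] = (a * e * dx / s**2).ravel()
    jac[:, 3] = (a * e * (dy**2 + dx**2) / s**3).ravel()
    jac[:, 4] = 1.0
    return jac


def fit_spots(
    image: np.ndarray,
    candidates: pd.DataFrame,
    fit_radius: int = 4,
    psf_sigma: float = 1.5,
    fit_quality_min: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Least-squares Gaussian + constant fit around each candidate.

    Each candidate gets a (2·fit_radius+1)² window fit with model
    ``A·exp(-r²/2σ²) + B``; the result records the sub-pixel center, the
    background-corrected amplitude A, background B, and R² of the fit.
    Candidates are dropped when the fit fails, R² < ``fit_quality_min``, or
    the center drifts more than ``fit_radius`` from the candidate pixel;
    reasons are tallied in the returned diagnostics dict.
    """
    img = np.asarray(image, float)
    h, w = img.shape
    rows = []
    diag = {"n_fit_input": len(candidates), "fit_failed": 0, "low_r2": 0, "drifted": 0}
    for _, cand in candidates.iterrows():
        cy, cx = int(round(cand["y"])), int(round(cand["x"]))
        y0, y1 = max(0, cy - fit_radius), min(h, cy + fit_radius + 1)
        x0, x1 = max(0, cx - fit_radius), min(w, cx + fit_radius + 1)
        win = img[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        b0 = float(np.median(win))
        a0 = max(img[cy, cx] - b0, 1e-6)
        p0 = [a0, float(cy), float(cx), psf_sigma, b0]
        try:
            res = least_squares(_gauss2d_residual, p0, jac=_gauss2d_jac,
                                args=(yy, xx, win), method="lm",
                                xtol=1e-10, ftol=1e-10, max_nfev=200)
        except Exception:
            diag["fit_failed"] += 1
            continue
        a, yc, xc, s, b = res.x
        s = abs(s)
        if not (a > 0 and 0.25 * psf_sigma <= s <= 4.0 * psf_sigma):
            diag["fit_failed"] += 1
            continue
        ss_res = float(np.sum(res.fun**2))
        ss_tot = float(np.sum((win - win.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        r2 = float(np.clip(r2, 0.0, 1.0))
        if np.hypot(yc - cy, xc - cx) > fit_radius:
            diag["drifted"] += 1
            continue
        if r2 < fit_quality_min:
            diag["low_r2"] += 1
            continue
        rows.append((0.0, yc, xc, a, b, r2))

    df = pd.DataFrame(rows, columns=["z", "y", "x", "amplitude", "background", "fit_r2"])
    diag["n_fit"] = len(df)
    return df, diag


# ---------------------------------------------------------------------------
# full detection
# ---------------------------------------------------------------------------

def detect_spots(
    rna_image: np.ndarray,
    params: SpotDetectionParams | None = None,
) -> tuple[pd.DataFrame, Optional[ThresholdCurve], dict]:
    """Detect mRNA foci in a 2D smFISH image.

    Composition: band-pass -> candidate maxima -> threshold (auto plateau or
    fixed) -> Gaussian fits -> quality gate -> final minimum-separation
    dedup on fitted centers.  Fully deterministic for fixed input and
    parameters.

    Returns ``(spot_table, threshold_curve, diagnostics)``; the curve is
    None when a fixed threshold was supplied.
    """
    params = params or SpotDetectionParams()
    filtered = bandpass_filter(rna_image, params.psf_sigma_xy)
    candidates = detect_candidates(filtered, params.min_separation)
    diag = {"n_candidates": len(candidates)}
    if len(candidates) == 0:
        return empty_spot_table(), None, {**diag, "n_spots": 0}

    # robust noise floor of the band-pass response: below ~2 sigma the count
    # curve is trivially flat (every noise maximum survives), so the curve
    # and the plateau search only consider candidates above it
    mad = float(np.median(np.abs(filtered - np.median(filtered))))
    noise_floor = 2.0 * 1.4826 * mad
    diag["noise_floor"] = noise_floor
    significant = candidates[candidates["response"] > noise_floor]
    diag["n_above_noise_floor"] = len(significant)

    curve = None
    if params.threshold == "auto":
        if len(significant) == 0:
            diag["n_spots"] = 0
            return empty_spot_table(), None, diag
        # anchor the grid at the noise floor (or well below the signal when
        # the image is noise-free) so the noise/signal plateau is visible
        lower = noise_floor if noise_floor > 0 else float(significant["response"].max()) * 1e-3
        curve = build_threshold_curve(significant, params.n_threshold_grid, lower=lower)
        curve = select_threshold(curve)
        threshold = max(curve.selected, noise_floor)
        diag["low_confidence_threshold"] = curve.low_confidence
    else:
        threshold = float(params.threshold)
    diag["threshold"] = threshold

    kept = candidates[candidates["response"] > threshold]
    diag["n_above_threshold"] = len(kept)

    fitted, fit_diag = fit_spots(rna_image, kept, params.fit_radius,
                                 params.psf_sigma_xy, params.fit_quality_min)
    diag.update(fit_diag)

    if len(fitted):
        # dedup on the *fitted* centers: drift can pull two fits together
        order = np.lexsort((fitted["x"], fitted["y"], -fitted["amplitude"]))
        fitted = fitted.iloc[order].reset_index(drop=True)
        keep = _greedy_min_separation(fitted["y"].to_numpy(), fitted["x"].to_numpy(),
                                      params.min_separation)
        fitted = fitted.iloc[keep].reset_index(drop=True)

        med = fitted["amplitude"].median()
        n_bright = int((fitted["amplitude"] > 5 * med).sum())
        if n_bright:
            logger.info("%d foci brighter than 5x median amplitude "
                        "(possible multi-molecule foci, counted as one each)", n_bright)
        diag["n_bright_foci"] = n_bright

    table = empty_spot_table()
    if len(fitted):
        table = fitted.copy()
        table.insert(0, "id", np.arange(len(table)))
        table["cell_id"] = -1  # unassigned
        table["coloc"] = pd.NA
        table = table[SPOT_COLUMNS]
    diag["n_spots"] = len(table)
    return table, curve, diag


def detect_spots_stack(
    stack: np.ndarray,
    params: SpotDetectionParams | None = None,
    z_dedup: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-slice detection in a (z, y, x) stack with cross-z deduplication.

    Each plane is detected independently (the 2D quantification frame);
    with ``z_dedup`` a molecule appearing in adjacent planes within
    ``min_separation`` in (y, x) is kept once, at its brightest plane.
    """
    params = params or SpotDetectionParams()
    frames = []
    diags = []
    for z in range(stack.shape[0]):
        tab, _, d = detect_spots(stack[z], params)
        tab = tab.copy()
        tab["z"] = float(z)
        frames.append(tab)
        diags.append(d)
    spots = pd.concat(frames, ignore_index=True)
    n_before = len(spots)
    if z_dedup and len(spots):
        order = np.lexsort((spots["x"], spots["y"], spots["z"], -spots["amplitude"]))
        spots = spots.iloc[order].reset_index(drop=True)
        pts = spots[["y", "x"]].to_numpy()
        zs = spots["z"].to_numpy()
        tree = cKDTree(pts)
        suppressed = np.zeros(len(spots), bool)
        keep = []
        for i in range(len(spots)):
            if suppressed[i]:
                continue
            keep.append(i)
            for j in tree.query_ball_point(pts[i], params.min_separation - 1e-9):
                if j != i and abs(zs[j] - zs[i]) <= 1:
                    suppressed[j] = True
        spots = spots.iloc[keep].reset_index(drop=True)
    spots["id"] = np.arange(len(spots))
    diag = {"per_plane": diags, "n_before_z_dedup": n_before, "n_spots": len(spots)}
    return spots, diag
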