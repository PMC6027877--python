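"""Two-stage genetic-map cleaning: residual filtering and monotone splines.

Stage one fits a locally weighted regression (LOESS) of observed genetic
position on physical position per chromosome and track, and removes markers
whose absolute residual exceeds 1 cM (strict) — the signature of markers
whose genetic placement disagrees with their reported physical position.
Stage two fits a shape-preserving monotone piecewise-cubic interpolant
(PCHIP, Fritsch–Carlson type) through the retained anchors, giving a smooth
non-decreasing bp → cM model whose derivative is the local recombination
rate in cM/Mb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import TRACKS, GeneticMap, HsmapError

__all__ = ["CleaningReport", "MapModel", "residual_filter", "clean_map", "fit_map_model", "local_rate"]

MIN_MARKERS_FOR_FILTER = 10


@dataclass
class CleaningReport:
    """Per-marker fitted values, residuals and removal flags for one filter run."""

    frame: pd.DataFrame  # marker_id, chromosome, track, observed_cm, fitted_cm, residual_cm, removed
    span: float = 0.1
    threshold_cm: float = 1.0
    skipped_chromosomes: list = field(default_factory=list)

    @property
    def removed(self) -> list:
        sub = self.frame.loc[self.frame["removed"], "marker_id"]
        return list(dict.fromkeys(sub))


def _flag_outliers(residual: np.ndarray, threshold_cm: float) -> np.ndarray:
    """The removal rule: absolute residual strictly above the threshold."""
    return np.abs(residual) > threshold_cm


def _robust_loess(obs: np.ndarray, bp: np.ndarray, span: float, threshold_cm: float, iters: int) -> np.ndarray:
    """LOESS fit with gross outliers excluded and the fit re-run.

    Without the exclusion pass a handful of grossly displaced markers drag
    the local fit toward themselves, pushing their clean neighbours over the
    fixed residual threshold.
    """
    keep = np.ones(bp.size, bool)
    fitted = lowess(obs, bp, frac=span, it=0, return_sorted=False)
    for _ in range(iters):
        resid = obs - fitted
        med = np.median(resid[keep])
        sd = 1.4826 * np.median(np.abs(resid[keep] - med))
        cut = max(3.0 * sd, threshold_cm)
        new_keep = np.abs(resid - med) <= cut
        if new_keep.sum() < max(3, int(2 / max(span, 1e-6))) or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        fitted_k = lowess(obs[keep], bp[keep], frac=span, it=0, return_sorted=False)
        fitted = np.interp(bp, bp[keep], fitted_k)
    return fitted


def residual_filter(
    gmap: GeneticMap,
    sex: str,
    span: float = 0.1,
    threshold_cm: float = 1.0,
    robust_iters: int = 2,
):
    """LOESS residual filter of one map track.

    A local linear fit with tricube weights (window = ``span`` of the
    chromosome's markers; gross outliers are excluded and the fit re-run up
    to ``robust_iters`` times) is computed per chromosome for the track's
    observed genetic positions (cumulative cM plus any placement offset);
    markers with ``|observed - fitted| > threshold_cm`` (strict) are
    removed.  Chromosomes with fewer than 10 markers are left unfiltered
    with a warning.  Returns ``(retained marker ids, CleaningReport)``.
    """
    if not 0 < span <= 1:
        raise HsmapError("span must be a fraction in (0, 1]")
    col = gmap.track(sex)
    obs_all = gmap.observed(sex)
    rows = []
    skipped = []
    for chrom in gmap.chromosomes:
        mask = (gmap.frame["chromosome"] == chrom).to_numpy()
        bp = gmap.frame.loc[mask, "position_bp"].to_numpy(float)
        obs = obs_all[mask]
        ids = gmap.frame.loc[mask, "marker_id"].to_numpy(object)
        if bp.size < MIN_MARKERS_FOR_FILTER:
            warnings.warn(f"chromosome {chrom}: <{MIN_MARKERS_FOR_FILTER} markers, not filtered")
            skipped.append(chrom)
            fitted = obs.copy()
        else:
            fitted = _robust_loess(obs, bp, span, threshold_cm, robust_iters)
        resid = obs - fitted
        removed = _flag_outliers(resid, threshold_cm)
        if chrom in skipped:
            removed[:] = False
        rows.append(
            pd.DataFrame(
                {
                    "marker_id": ids,
                    "chromosome": chrom,
                    "track": sex,
                    "observed_cm": obs,
                    "fitted_cm": fitted,
                    "residual_cm": resid,
                    "removed": removed,
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    report = CleaningReport(frame=frame, span=span, threshold_cm=threshold_cm, skipped_chromosomes=skipped)
    retained = list(frame.loc[~frame["removed"], "marker_id"])
    return retained, report


def clean_map(
    gmap: GeneticMap,
    span: float = 0.1,
    threshold_cm: float = 1.0,
    tracks: tuple = ("male", "female"),
    robust_iters: int = 2,
):
    """Run the residual filter per sex track and drop flagged markers.

    A marker removed in any track is removed from all tracks, keeping the
    three tracks on a single marker set.  The cleaned map's placement
    offsets are reset to zero (the diagnostic is consumed by the filter).
    Returns ``(cleaned GeneticMap, combined CleaningReport)``.
    """
    reports = []
    removed: set = set()
    for track in tracks:
        _, rep = residual_filter(gmap, track, span=span, threshold_cm=threshold_cm, robust_iters=robust_iters)
        reports.append(rep.frame)
        removed.update(rep.removed)
    keep = ~gmap.frame["marker_id"].isin(removed)
    cleaned = gmap.frame.loc[keep].reset_index(drop=True).copy()
    cleaned["offset_cm"] = 0.0
    report = CleaningReport(
        frame=pd.concat(reports, ignore_index=True), span=span, threshold_cm=threshold_cm
    )
    return GeneticMap(cleaned), report


class MapModel:
    """Monotone piecewise-cubic bp → cM interpolants per chromosome and track.

    The interpolant reproduces every retained anchor exactly and is
    non-decreasing everywhere; its derivative (scaled to cM/Mb) is the local
    recombination rate.  Beyond the terminal anchors the model extrapolates
    linearly at the terminal-segment slope, clamped at cM ≥ 0.
    """

    def __init__(self, anchors: dict):
        # anchors: (chrom, track) -> (bp array, cm array), cm non-decreasing
        self.anchors = {}
        self._interp = {}
        for key, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.size < 2:
                raise HsmapError(f"need at least two anchors for {key}")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < -1e-12):
                raise HsmapError(f"anchors for {key} not monotone")
            self.anchors[key] = (bp, cm)
            self._interp[key] = PchipInterpolator(bp, np.maximum.accumulate(cm), extrapolate=False)

    @property
    def chromosomes(self) -> list:
        seen, out = set(), []
        for c, _ in self.anchors:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def _terminal(self, key):
        bp, cm = self.anchors[key]
        d = self._interp[key].derivative()
        return (bp[0], cm[0], max(float(d(bp[0])), 0.0)), (bp[-1], cm[-1], max(float(d(bp[-1])), 0.0))

    def cm_at(self, chrom, bp, track: str = "avg", return_flags: bool = False):
        """Interpolated genetic position(s); out-of-range queries extrapolate."""
        key = (chrom, track)
        bp = np.atleast_1d(np.asarray(bp, dtype=np.float64))
        f = self._interp[key]
        out = f(bp)
        (b0, c0, s0), (b1, c1, s1) = self._terminal(key)
        left = bp < b0
        right = bp > b1
        out[left] = np.maximum(c0 - s0 * (b0 - bp[left]), 0.0)
        out[right] = c1 + s1 * (bp[right] - b1)
        flags = left | right
        if return_flags:
            return out, flags
        return out

    def rate_at(self, chrom, bp, track: str = "avg", return_flags: bool = False):
        """Local recombination rate(s) in cM/Mb (derivative of the model)."""
        key = (chrom, track)
        bp = np.atleast_1d(np.asarray(bp, dtype=np.float64))
        d = self._interp[key].derivative()
        out = d(bp)
        (b0, _, s0), (b1, _, s1) = self._terminal(key)
        left = bp < b0
        right = bp > b1
        out[left] = s0
        out[right] = s1
        out = np.maximum(out, 0.0) * 1e6
        if return_flags:
            return out, left | right
        return out

    def chrom_total_cm(self, chrom, track: str = "avg") -> float:
        return float(self.anchors[(chrom, track)][1][-1])

    def to_frame(self) -> pd.DataFrame:
        """Anchor table sufficient to reconstruct the model bit-exactly."""
        rows = []
        for (chrom, track), (bp, cm) in self.anchors.items():
            rows.append(pd.DataFrame({"chromosome": chrom, "track": track, "position_bp": bp.astype(np.int64), "cm": cm}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MapModel":
        anchors = {
            (chrom, track): (sub["position_bp"].to_numpy(float), sub["cm"].to_numpy(float))
            for (chrom, track), sub in df.groupby(["chromosome", "track"], sort=False)
        }
        return cls(anchors)


def _prepare_anchors(bp: np.ndarray, cm: np.ndarray):
    """Collapse bp ties to mean cM and project residual non-monotonicity away."""
    order = np.argsort(bp, kind="stable")
    bp, cm = bp[order], cm[order]
    ub, inv = np.unique(bp, return_inverse=True)
    if ub.size != bp.size:
        sums = np.bincount(inv, weights=cm)
        counts = np.bincount(inv)
        bp, cm = ub, sums / counts
    if np.any(np.diff(cm) < 0):
        iso = IsotonicRegression(increasing=True)
        cm = iso.fit_transform(bp, cm)
    return bp, cm


def fit_map_model(gmap: GeneticMap, tracks: tuple = TRACKS) -> MapModel:
    """Fit monotone cubic interpolants through a (cleaned) map's markers."""
    anchors = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chrom(chrom)
        bp = sub["position_bp"].to_numpy(float)
        for track in tracks:
            cm = sub[gmap.track(track)].to_numpy(float)
            if bp.size < 2:
                raise HsmapError(f"chromosome {chrom}: need at least 2 anchors")
            anchors[(chrom, track)] = _prepare_anchors(bp, cm)
    return MapModel(anchors)


def local_rate(model: MapModel, chrom, position_bp, track: str = "avg"):
    """Local recombination rate in cM/Mb at physical position(s)."""
    return model.rate_at(chrom, position_bp, track=track)
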