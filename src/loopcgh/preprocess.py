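"""Per-array signal correction.

Two stages, applied before segmentation:

1. spatial correction — a loess-style locally weighted polynomial surface is
   fitted to the log2 ratios over the array's (x, y) grid coordinates and
   subtracted (applied to the Cy3 channel so intensities stay consistent);
2. q-spline normalization — each channel is mapped through a monotone cubic
   spline fitted through paired empirical quantiles against the
   geometric-mean pseudo-reference of the two channels.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator

from .exceptions import DataError, FormatError, InvalidArgumentError
from .synthetic import ProbeRatioTable


def _loess_surface(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    span: float,
    grid: int = 12,
    passes: int = 2,
) -> np.ndarray:
    """Locally weighted linear regression surface evaluated at the probes.

    The surface is fitted at ``grid x grid`` nodes — each node regresses on
    the ``span`` fraction of nearest probes with tricube weights — then
    bilinearly interpolated back to probe positions. A second pass
    downweights outliers with bisquare robustness weights.
    """
    n = len(z)
    k = max(8, int(np.ceil(span * n)))
    gx = np.linspace(x.min(), x.max(), grid)
    gy = np.linspace(y.min(), y.max(), grid)
    # normalize coordinates so the distance metric is isotropic
    sx = max(x.max() - x.min(), 1.0)
    sy = max(y.max() - y.min(), 1.0)
    xn, yn = x / sx, y / sy
    robust = np.ones(n)
    surface_at_probes = np.zeros(n)
    for _ in range(passes):
        node_vals = np.empty((grid, grid))
        for i, cx in enumerate(gx):
            dx2 = (xn - cx / sx) ** 2
            for j, cy in enumerate(gy):
                d = np.sqrt(dx2 + (yn - cy / sy) ** 2)
                idx = np.argpartition(d, min(k, n - 1))[:k]
                dmax = d[idx].max()
                w = (1 - (d[idx] / max(dmax, 1e-12)) ** 3) ** 3
                w = np.clip(w, 0, None) * robust[idx]
                if w.sum() <= 0:
                    w = np.ones(len(idx))
                a = np.column_stack(
                    [np.ones(len(idx)), xn[idx] - cx / sx, yn[idx] - cy / sy]
                )
                aw = a * w[:, None]
                beta, *_ = np.linalg.lstsq(aw.T @ a, aw.T @ z[idx], rcond=None)
                node_vals[i, j] = beta[0]
        interp = RegularGridInterpolator(
            (gx, gy), node_vals, bounds_error=False, fill_value=None
        )
        surface_at_probes = interp(np.column_stack([x, y]))
        resid = z - surface_at_probes
        s = np.median(np.abs(resid)) + 1e-12
        robust = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return surface_at_probes


def spatial_correct(
    table: ProbeRatioTable, span: float = 0.3, grid: int = 12
) -> ProbeRatioTable:
    """Remove the smooth spatial trend of the log2 ratios over (x, y).

    Returns a new table; the fitted surface is mean-centered before
    subtraction so the genome-wide ratio level is untouched.
    """
    if not 0 < span <= 1:
        raise InvalidArgumentError("span must be in (0, 1]")
    frame = table.frame
    if "x" not in frame.columns or "y" not in frame.columns:
        raise FormatError("probe table lacks array grid coordinates x/y")
    if frame[["x", "y"]].isna().any().any():
        raise FormatError("probe table has missing grid coordinates")
    x = frame["x"].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    z = frame["ratio"].to_numpy(dtype=float)
    surface = _loess_surface(x, y, z, span=span, grid=grid)
    surface = surface - surface.mean()
    out = table.copy()
    out.frame["ratio"] = z - surface
    out.frame["ch1"] = out.frame["ch1"] * np.power(2.0, -surface)
    return out


def _monotone_quantile_map(values: np.ndarray, target: np.ndarray, n_quantiles: int):
    """Monotone cubic (PCHIP) map through paired empirical quantiles,
    extended linearly beyond the anchor range."""
    p = (np.arange(n_quantiles) + 0.5) / n_quantiles
    qx = np.quantile(values, p)
    qy = np.quantile(target, p)
    # collapse duplicate anchors so the interpolant is strictly defined
    keep = np.concatenate([[True], np.diff(qx) > 0])
    qx, qy = qx[keep], np.maximum.accumulate(qy[keep])
    if len(qx) < 2:
        return lambda v: np.full_like(v, qy[0] if len(qy) else 0.0)
    spline = PchipInterpolator(qx, qy, extrapolate=False)
    d0 = float(spline.derivative()(qx[0]))
    d1 = float(spline.derivative()(qx[-1]))

    def apply(v: np.ndarray) -> np.ndarray:
        out = spline(np.clip(v, qx[0], qx[-1]))
        lo = v < qx[0]
        hi = v > qx[-1]
        out[lo] = qy[0] + max(d0, 0.0) * (v[lo] - qx[0])
        out[hi] = qy[-1] + max(d1, 0.0) * (v[hi] - qx[-1])
        return out

    return apply


def qspline_normalize(
    table: ProbeRatioTable, n_quantiles: int = 100
) -> ProbeRatioTable:
    """Quantile-spline normalize both channels against their geometric mean.

    Both channels are passed through smooth monotone quantile maps onto the
    pseudo-reference, which removes dye bias and intensity-dependent
    distortions; log2 ratios are recomputed afterwards.
    """
    if n_quantiles < 2:
        raise InvalidArgumentError("n_quantiles must be >= 2")
    frame = table.frame
    ch1 = frame["ch1"].to_numpy(dtype=float)
    ch2 = frame["ch2"].to_numpy(dtype=float)
    for name, channel in (("ch1", ch1), ("ch2", ch2)):
        if np.any(~(channel > 0)):
            probe = frame["probe_id"].iloc[int(np.argmin(channel > 0))]
            raise DataError(f"non-positive {name} intensity at probe {probe}")
    # fit in log space: intensity distributions are roughly log-normal
    l1, l2 = np.log2(ch1), np.log2(ch2)
    ref = 0.5 * (l1 + l2)
    m1 = _monotone_quantile_map(l1, ref, n_quantiles)
    m2 = _monotone_quantile_map(l2, ref, n_quantiles)
    n1, n2 = m1(l1), m2(l2)
    out = table.copy()
    out.frame["ch1"] = np.power(2.0, n1)
    out.frame["ch2"] = np.power(2.0, n2)
    out.frame["ratio"] = n1 - n2
    return out


def drop_missing(table: ProbeRatioTable) -> tuple[ProbeRatioTable, int]:
    """Drop probes with missing or non-positive intensities.

    Returns the cleaned table and the number of rows removed.
    """
    frame = table.frame
    ok = (
        frame["ch1"].notna()
        & frame["ch2"].notna()
        & (frame["ch1"] > 0)
        & (frame["ch2"] > 0)
    )
    cleaned = table.copy()
    cleaned.frame = frame[ok].reset_index(drop=True)
    return cleaned, int((~ok).sum())


def preprocess_table(
    table: ProbeRatioTable,
    span: float = 0.3,
    n_quantiles: int = 100,
    spatial: bool = True,
    normalize: bool = True,
) -> ProbeRatioTable:
    """Full per-array correction: drop bad probes, spatial correct, q-spline."""
    cleaned, _ = drop_missing(table)
    if spatial:
        cleaned = spatial_correct(cleaned, span=span)
    if normalize:
        cleaned = qspline_normalize(cleaned, n_quantiles=n_quantiles)
    return cleaned
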