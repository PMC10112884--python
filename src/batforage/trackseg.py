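"""GPS track segmentation: first-passage time, Lavielle changepoints,
and foraging/traveling classification.

The pipeline regularizes fixes onto a 10 s grid in local projected
metres, computes first-passage times (FPT) for radii 5–400 m in 5 m
steps, picks the operating scale as the radius maximising the variance
of log-FPT, segments the per-step distance series with the Lavielle
penalized-contrast method (dynamic programming, minimum 5 locations per
segment, at most 50 segments), verifies bimodality of per-segment
distances, fits a 2-component Gaussian mixture and thresholds at the
lower quartile of the traveling component: segments moving less than the
threshold per 10 s are classed as foraging (area-restricted search).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from batforage import geo

BC_THRESHOLD = 5.0 / 9.0
DEFAULT_RADII = np.arange(5.0, 401.0, 5.0)  # 80 radii

__all__ = [
    "GpsTrack",
    "FptProfile",
    "TrackSegmentation",
    "regularize_track",
    "step_distances",
    "first_passage_time",
    "fpt_variance_profile",
    "lavielle_segment",
    "bimodality_coefficient",
    "ars_threshold",
    "classify_track",
]


@dataclass
class GpsTrack:
    t: np.ndarray  # s, regular grid
    x: np.ndarray  # m east
    y: np.ndarray  # m north
    dt: float
    origin: tuple[float, float] = (0.0, 0.0)  # lat0, lon0

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class FptProfile:
    radii: np.ndarray
    var_log_fpt: np.ndarray

    @property
    def operating_scale(self) -> float:
        v = np.where(np.isfinite(self.var_log_fpt), self.var_log_fpt, -np.inf)
        return float(self.radii[int(np.argmax(v))])


@dataclass
class TrackSegmentation:
    changepoints: np.ndarray  # start index of each segment (first is 0)
    K: int
    contrast_curve: np.ndarray = field(default=None, repr=False)

    def segments(self, n: int) -> list[tuple[int, int]]:
        """Half-open index ranges [i, j) of each segment over n points."""
        cps = list(self.changepoints) + [n]
        return [(int(a), int(b)) for a, b in zip(cps[:-1], cps[1:])]


def regularize_track(fixes: pd.DataFrame, dt: float = 10.0, gap_s: float = 60.0) -> list[GpsTrack]:
    """Project lat/lon to local metres and linearly interpolate onto a
    ``dt``-second grid.  Time gaps larger than ``gap_s`` split the track;
    one GpsTrack is returned per contiguous piece.
    """
    if len(fixes) < 2:
        raise ValueError("need at least two GPS fixes")
    t = fixes["t"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("all fixes at the same time")
    order = np.argsort(t)
    t = t[order]
    lat = fixes["lat"].to_numpy(dtype=float)[order]
    lon = fixes["lon"].to_numpy(dtype=float)[order]
    lat0, lon0 = float(np.mean(lat)), float(np.mean(lon))
    x, y = geo.project(lat, lon, lat0, lon0)

    splits = np.nonzero(np.diff(t) > gap_s)[0]
    bounds = [0, *list(splits + 1), len(t)]
    tracks = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        grid = np.arange(t[a], t[b - 1] + 1e-9, dt)
        tracks.append(
            GpsTrack(
                t=grid,
                x=np.interp(grid, t[a:b], x[a:b]),
                y=np.interp(grid, t[a:b], y[a:b]),
                dt=dt,
                origin=(lat0, lon0),
            )
        )
    if not tracks:
        raise ValueError("no contiguous track piece with >= 2 fixes")
    return tracks


def step_distances(track: GpsTrack) -> np.ndarray:
    """Distance moved per grid step (m per dt); length n - 1."""
    return np.hypot(np.diff(track.x), np.diff(track.y))


def _passage(track: GpsTrack, i: int, r: float, direction: int) -> float | None:
    """Time to first exit the circle of radius r centred on point i, going
    forward (+1) or backward (-1); crossing linearly interpolated.
    Returns None if the track ends inside the circle."""
    x0, y0 = track.x[i], track.y[i]
    n = len(track)
    j = i
    prev_d = 0.0
    while True:
        j += direction
        if j < 0 or j >= n:
            return None
        d = np.hypot(track.x[j] - x0, track.y[j] - y0)
        if d > r:
            # interpolate crossing between j-direction and j
            frac = (r - prev_d) / (d - prev_d) if d > prev_d else 1.0
            steps = abs(j - i) - 1 + frac
            return steps * track.dt
        prev_d = d


def first_passage_time(track: GpsTrack, r: float) -> np.ndarray:
    """First-passage time at every location: backward + forward time for
    the track to first leave the circle of radius ``r`` centred there.
    NaN where the track ends inside the circle (censored)."""
    if r <= 0:
        raise ValueError("radius must be > 0")
    n = len(track)
    out = np.full(n, np.nan)
    for i in range(n):
        fwd = _passage(track, i, r, +1)
        bwd = _passage(track, i, r, -1)
        if fwd is not None and bwd is not None:
            out[i] = fwd + bwd
    return out


def fpt_variance_profile(track: GpsTrack, radii: np.ndarray = DEFAULT_RADII) -> FptProfile:
    """Variance of log first-passage time per radius; the radius of maximum
    variance is the operating scale of area-restricted search."""
    radii = np.asarray(radii, dtype=float)
    var = np.full(len(radii), np.nan)
    for k, r in enumerate(radii):
        fpt = first_passage_time(track, r)
        good = np.isfinite(fpt) & (fpt > 0)
        if good.sum() >= 2:
            var[k] = float(np.var(np.log(fpt[good])))
    if not np.isfinite(var).any():
        raise ValueError("no radius with at least two defined first-passage times")
    return FptProfile(radii=radii, var_log_fpt=var)


# ---------------------------------------------------------------------------
# Lavielle penalized-contrast segmentation


def _contrast_matrix(x: np.ndarray, contrast: str) -> np.ndarray:
    """C[i, j] = contrast of segment x[i..j] inclusive.

    'meanvar': n * log(ML variance); 'mean': sum of squared deviations
    from the segment mean.  A variance floor keeps constant segments
    finite.
    """
    n = len(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x**2)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = (j - i + 1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = c1[j + 1] - c1[i]
        ss = c2[j + 1] - c2[i]
        var = ss / cnt - (s / cnt) ** 2
    var = np.maximum(var, 1e-12)
    if contrast == "meanvar":
        C = cnt * np.log(var)
    elif contrast == "mean":
        C = cnt * var
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    C[j < i] = np.inf
    return C


def lavielle_segment(
    series: np.ndarray,
    Lmin: int = 5,
    Kmax: int = 50,
    K: int | None = None,
    contrast: str = "meanvar",
) -> TrackSegmentation:
    """Optimal changepoint segmentation by dynamic programming.

    Minimizes the summed per-segment Gaussian contrast over all
    segmentations with ``K`` segments of at least ``Lmin`` points, for
    every K up to ``Kmax``; unless ``K`` is forced, the returned K is the
    elbow of the normalized contrast curve (largest second difference),
    or 1 when the series carries no segmentation structure.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < Lmin:
        raise ValueError(f"series of {n} points shorter than Lmin={Lmin}")
    kmax_possible = n // Lmin
    if Kmax > kmax_possible:
        if K is not None and K > kmax_possible:
            warnings.warn(f"K reduced from {K} to {kmax_possible} (Lmin * K > n)")
            K = kmax_possible
        Kmax = kmax_possible
    Kmax = max(Kmax, 1)

    C = _contrast_matrix(x, contrast)
    INF = np.inf
    # J[k, j]: best contrast splitting x[0..j] into k+1 segments
    J = np.full((Kmax, n), INF)
    back = np.zeros((Kmax, n), dtype=int)
    J[0, :] = C[0, :]
    J[0, : Lmin - 1] = INF  # a single segment must also satisfy Lmin
    for k in range(1, Kmax):
        for j in range((k + 1) * Lmin - 1, n):
            # last segment starts at i, i in [k*Lmin, j-Lmin+1]
            i_lo, i_hi = k * Lmin, j - Lmin + 2
            if i_hi <= i_lo:
                continue
            cand = J[k - 1, i_lo - 1 : i_hi - 1] + C[i_lo:i_hi, j]
            b = int(np.argmin(cand))
            J[k, j] = cand[b]
            back[k, j] = i_lo + b

    JK = J[:, n - 1]  # optimal contrast for K = 1..Kmax

    def changepoints_for(kk: int) -> np.ndarray:
        cps = []
        j = n - 1
        for k in range(kk - 1, 0, -1):
            i = back[k, j]
            cps.append(i)
            j = i - 1
        return np.array([0] + cps[::-1], dtype=int)

    if K is None:
        finite = np.isfinite(JK)
        if not finite.any():
            K = 1
        else:
            lo, hi = JK[finite].min(), JK[finite].max()
            scale = max(abs(lo), abs(hi), 1.0)
            if (hi - lo) / scale < 1e-9:
                K = 1
            else:
                Jn = (JK - lo) / (hi - lo)
                if Kmax < 3:
                    K = 1 if Kmax == 1 else (2 if Jn[1] < Jn[0] - 0.5 else 1)
                else:
                    d2 = np.full(Kmax, -np.inf)
                    for k in range(1, Kmax - 1):
                        if finite[k - 1] and finite[k] and finite[k + 1]:
                            d2[k] = Jn[k - 1] - 2 * Jn[k] + Jn[k + 1]
                    K = int(np.argmax(d2)) + 1 if np.isfinite(d2).any() else 1
    K = int(min(K, Kmax))
    return TrackSegmentation(changepoints=changepoints_for(K), K=K, contrast_curve=JK)


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient with bias-corrected sample moments.

    BC = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3))); BC > 5/9 flags a
    bimodal (or heavily skewed) distribution.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("bimodality coefficient needs n >= 4")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def ars_threshold(
    distances: np.ndarray,
    require_bimodal: bool = True,
    random_state: int = 0,
    n_init: int = 10,
) -> tuple[float, np.ndarray]:
    """Distance threshold separating foraging from traveling.

    Fits a 2-component Gaussian mixture to per-segment distances, takes
    the higher-mean component as traveling, and returns its lower
    quartile as the threshold together with the per-point traveling
    assignment.  Distances below the threshold indicate foraging.
    """
    x = np.asarray(distances, dtype=float).reshape(-1, 1)
    if len(x) < 4:
        raise ValueError("need at least 4 segment distances")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate fit: all distances identical; pass require_bimodal=False with manual threshold")
    if require_bimodal and bimodality_coefficient(x.ravel()) <= BC_THRESHOLD:
        raise ValueError(
            "distance distribution not bimodal (BC <= 5/9); use require_bimodal=False to override"
        )
    gmm = GaussianMixture(
        n_components=2, n_init=n_init, init_params="kmeans", random_state=random_state, reg_covar=1e-6
    ).fit(x)
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    if abs(means[0] - means[1]) < 0.5 * min(sds):
        raise ValueError("degenerate fit: mixture components collapsed; override with a manual threshold")
    traveling = int(np.argmax(means))
    labels = gmm.predict(x)
    is_travel = labels == traveling
    thr = float(np.percentile(x[is_travel], 25))
    return thr, is_travel


def classify_track(
    track: GpsTrack,
    seg: TrackSegmentation,
    threshold: float,
    habitat: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-segment summary: mean distance per step, foraging/traveling
    class (foraging below the threshold), and optional habitat labels.

    ``habitat`` maps segment index -> label; 'both'/'other' labels are
    kept but flagged excluded from habitat summaries.  A label for an
    unknown segment raises.
    """
    d = step_distances(track)
    rows = []
    ranges = seg.segments(len(d))
    if habitat:
        unknown = set(habitat) - set(range(len(ranges)))
        if unknown:
            raise ValueError(f"habitat labels reference unknown segments: {sorted(unknown)}")
    for s, (a, b) in enumerate(ranges):
        dist = float(np.mean(d[a:b])) if b > a else np.nan
        cls = "foraging" if dist < threshold else "traveling"
        hab = habitat.get(s) if habitat else None
        rows.append(
            {
                "segment": s,
                "start": float(track.t[a]),
                "end": float(track.t[min(b, len(track) - 1)]),
                "n": b - a,
                "dist_per_step": dist,
                "class": cls,
                "habitat": hab if hab is not None else "NA",
                "in_habitat_summary": hab in ("field", "forest") if hab is not None else False,
            }
        )
    return pd.DataFrame(rows)
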