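"""Spot detection and frame-to-frame linking.

Detection finds bright diffraction-limited puncta in each frame of a
time-lapse; linking joins per-frame detections into trajectories with a
nearest-neighbour assignment bounded by a maximum displacement, tolerating
short detection dropouts (gap closing) before a track is terminated.

The parameter surface mirrors the common particle-tracker contract:
``radius`` (particle size), ``cutoff`` (absolute rejection threshold on the
summed disc intensity), ``percentile`` (how far below the image maximum a
local maximum may sit and still count as a spot), ``link_range`` (frames a
particle may go missing before its track ends) and ``max_disp`` (largest
allowed inter-frame displacement, pixels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.feature import peak_local_max

from .trajectory import Trajectory

__all__ = [
    "AcquisitionGeometry",
    "Detection",
    "TrackingParams",
    "compute_geometry",
    "detect_particles",
    "link_detections",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Field geometry of one movie.

    d = L/N is the pixel width (um/px) and tau = T/(F-1) the frame interval
    (s): L um across N pixels, F frames spanning T seconds.
    """

    L: float
    N: int
    T: float
    F: int

    def __post_init__(self) -> None:
        if self.L <= 0 or self.T <= 0:
            raise ValueError("field width L and duration T must be positive")
        if self.N < 1:
            raise ValueError("pixel count N must be >= 1")
        if self.F < 2:
            raise ValueError("frame count F must be >= 2 (frame interval undefined)")

    @property
    def d(self) -> float:
        """Pixel width in um/px."""
        return self.L / self.N

    @property
    def tau(self) -> float:
        """Frame interval in seconds."""
        return self.T / (self.F - 1)


def compute_geometry(L: float, N: int, T: float, F: int) -> AcquisitionGeometry:
    """Derive pixel width and frame interval from acquisition settings."""
    return AcquisitionGeometry(L=float(L), N=int(N), T=float(T), F=int(F))


@dataclass(frozen=True)
class Detection:
    """One sub-pixel spot localization in one frame.

    x, y are 0-based pixel coordinates (x rightward along columns, y downward
    along rows, origin at the top-left pixel centre); intensity is the summed
    intensity inside the detection disc.
    """

    frame: int
    x: float
    y: float
    intensity: float


@dataclass(frozen=True)
class TrackingParams:
    radius: int = 3
    cutoff: float = 0.0
    percentile: float = 1.0
    link_range: int = 3
    max_disp: float = 10.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be a positive integer")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")
        if self.link_range < 1:
            raise ValueError("link_range must be >= 1")
        if self.max_disp <= 0:
            raise ValueError("max_disp must be positive")


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    inside = rr ** 2 + cc ** 2 <= radius ** 2
    return rr[inside], cc[inside]


def detect_particles(frame_image: np.ndarray, params: TrackingParams,
                     frame: int = 0) -> list[Detection]:
    """Detect bright puncta in one frame.

    Candidate pixels are local maxima (within ``radius``) whose value lies in
    the top ``percentile`` of the image intensity range.  Each candidate is
    refined to a background-subtracted intensity-weighted centroid over the
    disc of the given radius; candidates whose summed disc intensity falls
    below ``cutoff`` are dropped, and detections closer than ``radius`` are
    merged keeping the brighter one.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame_image must be a 2D array")
    if np.any(img < 0):
        raise ValueError("frame_image must be non-negative")
    vmin, vmax = float(img.min()), float(img.max())
    if vmax == vmin:
        return []  # constant image: nothing stands out
    threshold = vmax - (params.percentile / 100.0) * (vmax - vmin)

    peaks = peak_local_max(img, min_distance=params.radius,
                           threshold_abs=threshold, exclude_border=False)
    if peaks.size == 0:
        return []

    drr, dcc = _disc_offsets(params.radius)
    h, w = img.shape
    candidates: list[Detection] = []
    for r0, c0 in peaks:
        rr = np.clip(r0 + drr, 0, h - 1)
        cc = np.clip(c0 + dcc, 0, w - 1)
        patch = img[rr, cc]
        weights = patch - patch.min()
        total = float(patch.sum())
        if total < params.cutoff:
            continue
        if weights.sum() > 0:
            cy = float(np.sum(rr * weights) / weights.sum())
            cx = float(np.sum(cc * weights) / weights.sum())
        else:
            cy, cx = float(r0), float(c0)
        candidates.append(Detection(frame=frame, x=cx, y=cy, intensity=total))

    # merge refined centroids that drifted within one radius of each other
    candidates.sort(key=lambda det: -det.intensity)
    kept: list[Detection] = []
    for det in candidates:
        if all(np.hypot(det.x - k.x, det.y - k.y) >= params.radius for k in kept):
            kept.append(det)
    kept.sort(key=lambda det: (det.y, det.x))
    return kept


class _OpenTrack:
    __slots__ = ("id", "frames", "xs", "ys", "intens", "last_frame")

    def __init__(self, track_id: int, det: Detection):
        self.id = track_id
        self.frames = [det.frame]
        self.xs = [det.x]
        self.ys = [det.y]
        self.intens = [det.intensity]
        self.last_frame = det.frame

    def append(self, det: Detection) -> None:
        self.frames.append(det.frame)
        self.xs.append(det.x)
        self.ys.append(det.y)
        self.intens.append(det.intensity)
        self.last_frame = det.frame


def link_detections(detections: Sequence[Sequence[Detection]],
                    params: TrackingParams,
                    geometry: AcquisitionGeometry) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    ``detections`` is a sequence indexed by frame.  Assignment within each
    frame is greedy by ascending candidate distance (ties broken by lower
    track id, then detection order), restricted to pairs closer than
    ``max_disp`` pixels.  A track missing from up to ``link_range - 1``
    consecutive frames may be gap-closed; once a particle has been absent
    for ``link_range`` consecutive frames its track is terminated.  Output
    positions are converted to micrometres via the pixel width.

    Every detection belongs to exactly one trajectory (unmatched detections
    seed new tracks).
    """
    if geometry is None:
        raise ValueError("acquisition geometry is required to scale positions")
    d = geometry.d
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    next_id = 0

    for frame_idx, frame_dets in enumerate(detections):
        # retire tracks absent for link_range consecutive frames
        still_open = []
        for tr in open_tracks:
            if frame_idx - tr.last_frame > params.link_range:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        frame_dets = list(frame_dets)
        pairs = []
        for ti, tr in enumerate(open_tracks):
            for di, det in enumerate(frame_dets):
                dist = np.hypot(det.x - tr.xs[-1], det.y - tr.ys[-1])
                if dist <= params.max_disp:
                    pairs.append((dist, tr.id, di, ti))
        pairs.sort()

        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, _tid, di, ti in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            open_tracks[ti].append(frame_dets[di])
            used_tracks.add(ti)
            used_dets.add(di)

        for di, det in enumerate(frame_dets):
            if di not in used_dets:
                open_tracks.append(_OpenTrack(next_id, det))
                next_id += 1

    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr.id)
    return [
        Trajectory(
            id=tr.id,
            frames=np.array(tr.frames, dtype=np.int64),
            x=np.array(tr.xs) * d,
            y=np.array(tr.ys) * d,
            intensity=np.array(tr.intens),
        )
        for tr in closed
    ]
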