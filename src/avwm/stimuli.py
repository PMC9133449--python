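"""Stimulus generation: tonal contours, visual shapes, and matched controls.

Auditory objects are *tonal contours*: spectrotemporal patterns of upward
and downward frequency sweeps on an 81-channel tonotopic axis, with the
duration of a single-syllable word (~200-300 ms).  Visual objects are
simple 9 x 9 shape patterns.  Each stimulus carries a saliency scalar in
[0, 1] (the loudness/luminance analog) that multiplies its input drive.
Control stimuli (auditory random-noise patterns and degraded shapes) match
the mean input energy of their object counterparts to within 10%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

N_CHANNELS = 81
SHAPE_SIDE = 9
#: spectral spread of the instantaneous sweep peak, channels
SWEEP_SIGMA = 1.5
#: total drive energy of a full-saliency auditory object (loudness
#: equalization: every object delivers the same total input energy)
CONTOUR_ENERGY = 200.0


def _bump(center_idx: float, n: int = N_CHANNELS, sigma: float = SWEEP_SIGMA) -> np.ndarray:
    idx = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((idx - center_idx) / sigma) ** 2)


@dataclass(frozen=True)
class Segment:
    """One frequency sweep: channels are 1-based tonotopic indices."""

    direction: str  # "up" | "down"
    start_channel: float
    end_channel: float
    duration_ms: float

    def __post_init__(self) -> None:
        for ch in (self.start_channel, self.end_channel):
            if not (1 <= ch <= N_CHANNELS):
                raise ValueError(f"channel {ch} outside [1, {N_CHANNELS}]")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.direction == "up" and self.end_channel <= self.start_channel:
            raise ValueError("up segment must increase in channel")
        if self.direction == "down" and self.end_channel >= self.start_channel:
            raise ValueError("down segment must decrease in channel")
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class TonalContour:
    """An auditory object: an ordered list of channel-continuous sweeps."""

    segments: tuple[Segment, ...]
    saliency: float = 1.0
    channels: int = N_CHANNELS

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("contour needs at least one segment")
        if not (0.0 <= self.saliency <= 1.0):
            raise ValueError(f"saliency {self.saliency} outside [0, 1]")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.end_channel - b.start_channel) > 1e-9:
                raise ValueError("adjacent segments must be channel-continuous")

    @property
    def duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    @property
    def modality(self) -> str:
        return "a"

    def peak_channels(self, dt_ms: float) -> np.ndarray:
        """Instantaneous peak channel (1-based) per frame."""
        out = []
        for seg in self.segments:
            n = max(1, int(round(seg.duration_ms / dt_ms)))
            frac = (np.arange(n) + 0.5) / n
            out.append(seg.start_channel + frac * (seg.end_channel - seg.start_channel))
        return np.concatenate(out)

    def render(self, dt_ms: float) -> dict[str, np.ndarray]:
        """Input drive frames for the sweep-direction-selective A1 submodules.

        Returns {"A1_up": (T, 81), "A1_down": (T, 81)} with amplitude equal
        to the stimulus saliency.
        """
        frames_up, frames_down = [], []
        for seg in self.segments:
            n = max(1, int(round(seg.duration_ms / dt_ms)))
            frac = (np.arange(n) + 0.5) / n
            centers = seg.start_channel + frac * (seg.end_channel - seg.start_channel)
            block = np.stack([_bump(c - 1.0) for c in centers])
            zeros = np.zeros_like(block)
            if seg.direction == "up":
                frames_up.append(block)
                frames_down.append(zeros)
            else:
                frames_up.append(zeros)
                frames_down.append(block)
        up = np.concatenate(frames_up)
        down = np.concatenate(frames_down)
        # loudness equalization: fixed total energy, scaled by saliency
        total = up.sum() + down.sum()
        scale = self.saliency * CONTOUR_ENERGY / total if total > 0 else 0.0
        return {"A1_up": scale * up, "A1_down": scale * down}

    def footprint(self) -> np.ndarray:
        """Binary mask of tonotopic channels the contour traverses."""
        mask = np.zeros(N_CHANNELS)
        for c in self.peak_channels(dt_ms=5.0):
            mask = np.maximum(mask, _bump(c - 1.0))
        return (mask > 0.5).astype(float)

    def n_direction_changes(self) -> int:
        dirs = [s.direction for s in self.segments]
        return sum(a != b for a, b in zip(dirs, dirs[1:]))


@dataclass(frozen=True)
class VisualShape:
    """A visual object: a static 9 x 9 activity pattern."""

    frame: np.ndarray
    duration_ms: float = 250.0
    saliency: float = 1.0

    def __post_init__(self) -> None:
        frame = np.asarray(self.frame, dtype=float)
        if frame.shape != (SHAPE_SIDE, SHAPE_SIDE):
            raise ValueError(f"frame must be {SHAPE_SIDE} x {SHAPE_SIDE}")
        if frame.min() < 0 or frame.max() > 1:
            raise ValueError("frame values must lie in [0, 1]")
        if frame.max() == 0:
            raise ValueError("a non-blank shape needs at least one active element")
        if not (0.0 <= self.saliency <= 1.0):
            raise ValueError(f"saliency {self.saliency} outside [0, 1]")
        object.__setattr__(self, "frame", frame)

    @property
    def modality(self) -> str:
        return "v"

    #: luminance onset ramp, ms (shapes do not appear instantaneously;
    #: also aligns the visual response rise with the auditory sweep buildup)
    ONSET_RAMP_MS = 75.0

    def render(self, dt_ms: float) -> dict[str, np.ndarray]:
        n = max(1, int(round(self.duration_ms / dt_ms)))
        flat = self.saliency * self.frame.ravel()
        ramp = np.clip((np.arange(n) + 1) * dt_ms / self.ONSET_RAMP_MS, 0, 1)
        return {"V1": ramp[:, None] * flat[None, :]}

    def footprint(self) -> np.ndarray:
        return (self.frame.ravel() > 0.3).astype(float)


@dataclass(frozen=True)
class AuditoryNoise:
    """Control stimulus: random spectrotemporal noise, energy-matched."""

    centers: tuple[float, ...]        # per-frame random peak channels (1-based)
    directions: tuple[int, ...]       # per-frame submodule assignment (0=up, 1=down)
    amplitude: float
    frame_ms: float
    saliency: float = 1.0
    kind: str = field(default="auditory-noise")

    @property
    def duration_ms(self) -> float:
        return len(self.centers) * self.frame_ms

    @property
    def modality(self) -> str:
        return "a"

    def render(self, dt_ms: float) -> dict[str, np.ndarray]:
        if abs(dt_ms - self.frame_ms) > 1e-9:
            raise ValueError("noise control must be rendered at its native frame step")
        T = len(self.centers)
        up = np.zeros((T, N_CHANNELS))
        down = np.zeros((T, N_CHANNELS))
        for t, (c, d) in enumerate(zip(self.centers, self.directions)):
            target = up if d == 0 else down
            target[t] = self.saliency * self.amplitude * _bump(c - 1.0)
        return {"A1_up": up, "A1_down": down}

    def footprint(self) -> np.ndarray:
        mask = np.zeros(N_CHANNELS)
        for c in self.centers:
            mask = np.maximum(mask, _bump(c - 1.0))
        return (mask > 0.5).astype(float)


def drive_energy(stim, dt_ms: float = 5.0) -> float:
    """Total input drive (summed over time and channels)."""
    return float(sum(arr.sum() for arr in stim.render(dt_ms).values()))


# ----------------------------------------------------------------------
# procedural generation


def make_tonal_contour(seed: int | None = None, rng: np.random.Generator | None = None,
                       duration_ms: float | None = None, saliency: float = 1.0,
                       n_segments: int | None = None) -> TonalContour:
    """Draw a random tonal contour (seed-reproducible).

    Total duration is drawn from [200, 300] ms; the peak-channel path is a
    continuous sequence of 1-3 alternating-direction sweeps.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if duration_ms is None:
        duration_ms = float(rng.uniform(200, 300))
    if not (200 <= duration_ms <= 300):
        raise ValueError("object stimulus duration must be in [200, 300] ms")
    if n_segments is None:
        # default objects are triple sweeps (two reversals): every channel
        # receives repeated drive and the contour-selective units engage,
        # giving objects of homogeneous overall strength
        n_segments = 3
    # durations split evenly (rounded to 5 ms frames, total kept in range)
    seg_dur = round(duration_ms / n_segments / 5) * 5.0
    seg_dur = min(max(seg_dur, np.ceil(200.0 / n_segments / 5) * 5), 100.0)
    direction = "up" if rng.random() < 0.5 else "down"
    extent = float(rng.uniform(10, 14))
    lo = 4 + extent if direction == "down" else 4
    hi = N_CHANNELS - 3 - (extent if direction == "up" else 0)
    ch = float(rng.uniform(lo, hi))
    segments = []
    for _ in range(n_segments):
        step = extent if direction == "up" else -extent
        end = ch + step
        if not (3 <= end <= N_CHANNELS - 2):  # reflect at the axis edges
            direction = "down" if direction == "up" else "up"
            step = -step
            end = ch + step
        segments.append(Segment(direction, ch, end, seg_dur))
        ch = end
        direction = "down" if direction == "up" else "up"
    return TonalContour(tuple(segments), saliency=saliency)


_STROKES = ("h", "v", "d")


def make_visual_shape(seed: int | None = None, rng: np.random.Generator | None = None,
                      duration_ms: float = 250.0, saliency: float = 1.0) -> VisualShape:
    """Draw a random simple shape: 2-3 line strokes on the 9 x 9 grid."""
    rng = np.random.default_rng(seed) if rng is None else rng
    frame = np.zeros((SHAPE_SIDE, SHAPE_SIDE))
    n_strokes = 3
    for _ in range(n_strokes):
        kind = _STROKES[rng.integers(len(_STROKES))]
        length = int(rng.integers(5, 8))
        r0 = int(rng.integers(0, SHAPE_SIDE - (0 if kind == "h" else length - 1)))
        c0 = int(rng.integers(0, SHAPE_SIDE - (0 if kind == "v" else length - 1)))
        for j in range(length):
            r = r0 + (0 if kind == "h" else j)
            c = c0 + (0 if kind == "v" else j)
            frame[r, c] = 1.0
    return VisualShape(frame, duration_ms=duration_ms, saliency=saliency)


def pattern_overlap(a, b) -> float:
    """Cosine overlap of the stimulus footprints, in [0, 1]."""
    fa, fb = a.footprint(), b.footprint()
    denom = np.linalg.norm(fa) * np.linalg.norm(fb)
    return float(fa @ fb / denom) if denom > 0 else 0.0


def stimulus_library(n: int, modality: str, seed: int = 0,
                     max_overlap: float = 0.6, max_tries: int = 2000) -> list:
    """A seed-reproducible library of >= n mutually distinct stimuli."""
    rng = np.random.default_rng(seed)
    maker = make_tonal_contour if modality == "a" else make_visual_shape
    items: list = []
    tries = 0
    ceiling = max_overlap
    while len(items) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not build a library of distinct stimuli")
        if tries % 500 == 0:
            ceiling = min(ceiling + 0.05, 0.8)  # relax if packing stalls
        cand = maker(rng=rng)
        if all(pattern_overlap(cand, it) < ceiling for it in items):
            items.append(cand)
    return items


def shifted_contour(contour: TonalContour, delta: float) -> TonalContour:
    """A related lure: the same contour transposed by ``delta`` channels."""
    segs = []
    for seg in contour.segments:
        a, b = seg.start_channel + delta, seg.end_channel + delta
        if not (1 <= a <= N_CHANNELS and 1 <= b <= N_CHANNELS):
            raise ValueError("shift moves the contour off the tonotopic axis")
        segs.append(Segment(seg.direction, a, b, seg.duration_ms))
    return TonalContour(tuple(segs), saliency=contour.saliency)


def make_lure(target: TonalContour, rng: np.random.Generator,
              min_shift: float = 5.0, max_shift: float = 9.0) -> TonalContour:
    """Nonmatch probe: the target transposed by a random small interval.

    The transposition preserves the sweep structure, so the lure shares the
    target's temporal features while its tonotopic footprint only partially
    overlaps — the discrimination difficulty is set by the shift range.
    """
    delta = float(rng.uniform(min_shift, max_shift)) * (1 if rng.random() < 0.5 else -1)
    for d in (delta, -delta):
        try:
            return shifted_contour(target, d)
        except ValueError:
            continue
    # target spans the axis edge: shift inward by the maximum
    lo = min(min(s.start_channel, s.end_channel) for s in target.segments)
    hi = max(max(s.start_channel, s.end_channel) for s in target.segments)
    inward = (N_CHANNELS - hi) - (lo - 1)
    return shifted_contour(target, np.sign(inward) * max_shift)


def make_probe(target, match: bool, seed: int = 0, library: list | None = None,
               max_overlap: float = 0.5):
    """Probe stimulus: the target itself (match) or a distinct random draw."""
    if match:
        return target
    rng = np.random.default_rng(seed)
    maker = make_tonal_contour if target.modality == "a" else make_visual_shape
    for _ in range(500):
        cand = maker(rng=rng) if library is None else library[rng.integers(len(library))]
        if pattern_overlap(cand, target) < max_overlap:
            return dataclasses.replace(cand, saliency=target.saliency)
    raise RuntimeError("could not draw a nonmatch probe below the overlap ceiling")


def apply_saliency(stimulus, s: float):
    """Return a copy of the stimulus with its input drive scaled by ``s``.

    Saliency maps identically onto drive amplitude (loudness/luminance
    analog): s = 0 silences the drive, s = 1 leaves it at full scale.
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"saliency {s} outside [0, 1]")
    return dataclasses.replace(stimulus, saliency=s)


def noise_control(reference: TonalContour, seed: int = 0,
                  dt_ms: float = 5.0) -> AuditoryNoise:
    """Random spectrotemporal noise matched in input energy to ``reference``.

    The peak channel performs a band-limited random walk, so the noise has
    the spectral locality and sweep-step statistics of an object (and the
    same total input energy) but no coherent contour.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(reference.duration_ms / dt_ms))
    lo, hi = 5.0, float(N_CHANNELS - 4)
    width = 24.0
    start = float(rng.uniform(lo, hi - width))
    c = start + rng.uniform(0, width)
    centers, directions = [], []
    for _ in range(n_frames):
        step = float(rng.uniform(-2.5, 2.5))
        nxt = c + step
        if not (start <= nxt <= start + width):
            step = -step
            nxt = c + step
        directions.append(0 if step >= 0 else 1)
        c = nxt
        centers.append(c)
    ref_energy = drive_energy(reference, dt_ms) / max(reference.saliency, 1e-12)
    unit = AuditoryNoise(tuple(centers), tuple(directions), amplitude=1.0,
                         frame_ms=dt_ms, saliency=1.0)
    amp = ref_energy / drive_energy(unit, dt_ms)
    return AuditoryNoise(tuple(centers), tuple(directions), amplitude=amp,
                         frame_ms=dt_ms, saliency=reference.saliency)


def degraded_control(reference: VisualShape, seed: int = 0,
                     keep_fraction: float = 0.5) -> VisualShape:
    """Degraded shape: scrambles part of the pattern, preserving energy."""
    rng = np.random.default_rng(seed)
    frame = reference.frame.copy()
    active = np.flatnonzero(frame.ravel() > 0)
    drop = rng.choice(active, size=int(len(active) * (1 - keep_fraction)), replace=False)
    flat = frame.ravel()
    flat[drop] = 0.0
    empty = np.flatnonzero(flat == 0)
    dest = rng.choice(empty, size=len(drop), replace=False)
    flat[dest] = 1.0  # scatter the dropped energy at random positions
    return VisualShape(flat.reshape(SHAPE_SIDE, SHAPE_SIDE),
                       duration_ms=reference.duration_ms, saliency=reference.saliency)
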