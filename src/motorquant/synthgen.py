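"""Ground-truthed synthetic datasets for every assay pipeline.

Each generator draws all randomness from one ``numpy.random.default_rng(seed)``
and returns, next to the dataset, a :class:`SyntheticTruth` sidecar holding
every generative parameter, so the ground-truth summary curves can be
recomputed and the same call is bit-reproducible.

The scenes are deliberately minimal optical models: fluorescent objects are
rendered as 2-D Gaussian spots (sd ~1.3 px, a point-spread-function
stand-in), photon counting is emulated with per-pixel Poisson noise over a
flat background, and no camera gain, aberration or diffusion physics is
included.  They reproduce the *statistical* structure each quantification
step assumes — compact vs dispersed staining, radial organelle motion,
a photoconverted zone emptying at a set rate, Poisson landing with
exponential run lengths — not the full appearance of real micrographs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .imagedata import BinaryMask, ImageStack, Trajectory, TrajectorySet

__all__ = [
    "SyntheticTruth",
    "gen_poisson_field",
    "gen_golgi_scene",
    "gen_perox_movie",
    "gen_sliding_movie",
    "gen_trajectories",
    "render_spots",
]

SPOT_SIGMA_PX = 1.3  # PSF stand-in for all rendered point sources


@dataclass
class SyntheticTruth:
    """Ground-truth sidecar attached to every simulated dataset."""

    seed: int
    scenario: str
    params: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "scenario": self.scenario, "params": self.params},
            indent=2, sort_keys=True, default=_jsonify,
        ) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        return cls(seed=obj["seed"], scenario=obj["scenario"], params=obj["params"])


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def render_spots(
    shape: tuple[int, int],
    rows: np.ndarray,
    cols: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float = SPOT_SIGMA_PX,
) -> np.ndarray:
    """Render 2-D Gaussian spots of total photon count ``amplitudes``.

    Each spot integrates to its amplitude (up to frame-edge clipping); this
    is the noise-free expected image used both by the generators and by
    ground-truth oracles.
    """
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(4 * sigma_px))
    for r, c, a in zip(np.atleast_1d(rows), np.atleast_1d(cols), np.atleast_1d(amplitudes)):
        r0, r1 = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
        c0, c1 = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, shape[0]), min(c1, shape[1])
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
        g = np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma_px**2))
        img[rr0:rr1, cc0:cc1] += a * g / (2 * np.pi * sigma_px**2)
    return img


def gen_poisson_field(
    mean_level: float,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    pixel_size_nm: float = 100.0,
) -> ImageStack:
    """A pure shot-noise field: every pixel iid Poisson(``mean_level``).

    This is the test bed for exposure-insensitivity of intensity statistics:
    for Poisson light, variance equals mean, so SD/sqrt(mean) is 1 at any
    illumination level.
    """
    if mean_level <= 0:
        raise ValueError("mean_level must be > 0")
    rng = np.random.default_rng(seed)
    data = rng.poisson(mean_level, size=shape).astype(float)
    return ImageStack(data[None, None], pixel_size_nm=pixel_size_nm)


def gen_golgi_scene(
    state: str,
    nucleus_radius_px: int = 20,
    total_signal: float = 2.0e5,
    seed: int = 0,
    shape: tuple[int, int] = (160, 160),
    background: float = 20.0,
    cell_radius_px: int = 65,
    n_compact_spots: int = 15,
    n_dispersed_spots: int = 40,
    pixel_size_nm: float = 100.0,
) -> tuple[ImageStack, SyntheticTruth]:
    """A fixed-cell two-channel scene: Golgi staining over a nucleus channel.

    ``state="compact"`` places the Golgi signal in a crescent of Gaussian
    spots hugging the nucleus border (within 10 px of it, the perinuclear
    phenotype); ``state="dispersed"`` splits the *same* expected total signal
    into many spots scattered uniformly over the rest of the cell footprint
    (the scattered-vesicle phenotype).  Poisson noise is applied last, so
    total expected signal is equal across states.
    """
    if state not in ("compact", "dispersed"):
        raise ValueError("state must be 'compact' or 'dispersed'")
    if total_signal <= 0:
        raise ValueError("total_signal must be > 0")
    centre = (shape[0] / 2, shape[1] / 2)
    if nucleus_radius_px + 12 >= min(centre):
        raise ValueError("nucleus does not fit in the frame")
    rng = np.random.default_rng(seed)

    if state == "compact":
        n_spots = n_compact_spots
        # crescent: half-circle arc, radius within [r+2, r+8] px of the border
        theta0 = rng.uniform(0, 2 * np.pi)
        thetas = theta0 + rng.uniform(0, np.pi, n_spots)
        radii = nucleus_radius_px + rng.uniform(2.0, 8.0, n_spots)
    else:
        n_spots = n_dispersed_spots
        thetas = rng.uniform(0, 2 * np.pi, n_spots)
        # uniform over the cytoplasmic annulus (area-weighted radius)
        r2 = rng.uniform(nucleus_radius_px**2, cell_radius_px**2, n_spots)
        radii = np.sqrt(r2)
    rows = centre[0] + radii * np.sin(thetas)
    cols = centre[1] + radii * np.cos(thetas)
    amplitudes = np.full(n_spots, total_signal / n_spots)

    golgi = render_spots(shape, rows, cols, amplitudes) + background
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    nucleus_disc = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= nucleus_radius_px**2
    nucleus = np.where(nucleus_disc, 800.0, 0.0) + background

    data = np.stack([rng.poisson(golgi), rng.poisson(nucleus)]).astype(float)
    stack = ImageStack(
        data[None], pixel_size_nm=pixel_size_nm,
        channel_names=["golgi", "nucleus"],
    )
    truth = SyntheticTruth(
        seed=seed, scenario=f"golgi_{state}",
        params={
            "dispersion_state": state,
            "nucleus_radius_px": nucleus_radius_px,
            "nucleus_centre_rc": list(centre),
            "cell_radius_px": cell_radius_px,
            "total_signal": total_signal,
            "background_level": background,
            "spot_rows": rows, "spot_cols": cols,
            "spot_amplitudes": amplitudes,
            "poisson_noise": True,
        },
    )
    return stack, truth


def gen_perox_movie(
    n_spots: int = 30,
    speed_nm_s: float = 20.0,
    t_treat_s: float = 300.0,
    n_frames: int = 40,
    interval_s: float = 15.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 100.0,
    spot_signal: float = 4000.0,
    background: float = 20.0,
    jitter_nm: float = 30.0,
    cell_radius_um: float = 11.0,
    green_plateau: float = 2000.0,
    green_ramp_s: float = 60.0,
) -> tuple[ImageStack, tuple[float, float], SyntheticTruth]:
    """An inducible organelle-redistribution time-lapse (561/488 channels).

    Puncta in the 561 channel sit at random radii around the cell centre and
    only jitter (Brownian, sd ``jitter_nm`` per frame) until the treatment
    time, after which each moves radially outward at ``speed_nm_s`` and
    clamps at the cell boundary.  The 488 channel (motor recruitment) ramps
    from background to a plateau on the spots over ``green_ramp_s`` after
    treatment.  Returns the movie, the cell centre ``(x_nm, y_nm)`` and the
    ground truth.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if interval_s <= 0:
        raise ValueError("interval_s must be > 0")
    if t_treat_s > (n_frames - 1) * interval_s:
        raise ValueError("t_treat_s is beyond the end of the movie")
    rng = np.random.default_rng(seed)
    centre_rc = (shape[0] / 2, shape[1] / 2)
    centre_nm = (centre_rc[1] * pixel_size_nm, centre_rc[0] * pixel_size_nm)

    r0_nm = rng.uniform(2000.0, 7000.0, n_spots)  # initial radii, 2-7 um
    theta = rng.uniform(0, 2 * np.pi, n_spots)
    cell_radius_nm = cell_radius_um * 1000.0

    frames = []
    true_mean_radius_um = []
    for k in range(n_frames):
        t = k * interval_s
        dt_post = max(0.0, t - t_treat_s)
        radii = np.minimum(r0_nm + speed_nm_s * dt_post, cell_radius_nm)
        jitter = rng.normal(0.0, jitter_nm, (2, n_spots))
        x_nm = centre_nm[0] + radii * np.cos(theta) + jitter[0]
        y_nm = centre_nm[1] + radii * np.sin(theta) + jitter[1]
        rows, cols = y_nm / pixel_size_nm, x_nm / pixel_size_nm
        red = render_spots(shape, rows, cols, np.full(n_spots, spot_signal))
        ramp = 0.0 if dt_post <= 0 else min(1.0, dt_post / green_ramp_s)
        green = render_spots(shape, rows, cols, np.full(n_spots, ramp * green_plateau))
        frame = np.stack([
            rng.poisson(red + background),
            rng.poisson(green + background),
        ]).astype(float)
        frames.append(frame)
        true_mean_radius_um.append(float(np.mean(radii)) / 1000.0)

    stack = ImageStack(
        np.stack(frames), pixel_size_nm=pixel_size_nm,
        frame_interval_s=interval_s, channel_names=["561", "488"],
    )
    truth = SyntheticTruth(
        seed=seed, scenario="perox_redistribution",
        params={
            "n_spots": n_spots, "perox_speed_nm_s": speed_nm_s,
            "t_treat_s": t_treat_s, "interval_s": interval_s,
            "centre_nm": list(centre_nm), "initial_radii_nm": r0_nm,
            "cell_radius_um": cell_radius_um, "jitter_nm": jitter_nm,
            "background_level": background, "poisson_noise": True,
            "true_mean_radius_um": true_mean_radius_um,
        },
    )
    return stack, centre_nm, truth


def _mt_segment(rng: np.random.Generator, n_steps: int, step_px: float,
                start: np.ndarray, max_turn_rad: float = 0.35,
                bounds: tuple[float, float] | None = None,
                heading: float | None = None) -> np.ndarray:
    """A piecewise-linear filament: random walk with bounded curvature.

    With ``bounds=(lo, hi)`` the walk is deflected so every vertex stays
    inside ``[lo, hi]`` on both axes.
    """
    if heading is None:
        heading = rng.uniform(0, 2 * np.pi)
    pts = [start.astype(float)]
    for _ in range(n_steps):
        heading += rng.uniform(-max_turn_rad, max_turn_rad)
        nxt = pts[-1] + step_px * np.array([np.sin(heading), np.cos(heading)])
        if bounds is not None:
            for _ in range(8):
                if np.all((nxt >= bounds[0]) & (nxt <= bounds[1])):
                    break
                heading += np.pi / 2
                nxt = pts[-1] + step_px * np.array([np.sin(heading), np.cos(heading)])
        pts.append(nxt)
    return np.array(pts)


def _raster_polyline(img: np.ndarray, pts: np.ndarray, value: float) -> None:
    from skimage.draw import line

    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = line(int(round(a[0])), int(round(a[1])),
                      int(round(b[0])), int(round(b[1])))
        keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
        img[rr[keep], cc[keep]] = np.maximum(img[rr[keep], cc[keep]], value)


def gen_sliding_movie(
    rate_pct_min: float = 5.0,
    zone_fraction: float = 0.2,
    n_frames: int = 11,
    interval_s: float = 60.0,
    bleach_per_frame: float = 0.02,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    n_segments: int = 40,
    plateau_pct: float = 85.0,
    mt_intensity: float = 600.0,
    background: float = 15.0,
    pixel_size_nm: float = 100.0,
) -> tuple[ImageStack, SyntheticTruth]:
    """A photoconverted-microtubule sliding time-lapse with known %MF curve.

    Short curvilinear filaments all start inside a compact central zone
    covering ``zone_fraction`` of the frame.  At frame ``k`` the scheduled
    number of filaments needed to make the ground-truth motile fraction
    ``min(rate_pct_min * t_min, plateau_pct)`` has been translated outside
    the zone.  The whole scene is multiplied by ``(1 - bleach_per_frame)``
    each frame (photobleaching) and Poisson noise is applied.
    """
    if not 0 < zone_fraction < 1:
        raise ValueError("zone_fraction must be in (0, 1)")
    if not 0 <= bleach_per_frame < 1:
        raise ValueError("bleach_per_frame must be in [0, 1)")
    if rate_pct_min < 0:
        raise ValueError("rate_pct_min must be >= 0")
    t_last_min = (n_frames - 1) * interval_s / 60.0
    if rate_pct_min * t_last_min > 100.0 and plateau_pct >= 100.0:
        raise ValueError("rate implies motile fraction > 100% before plateau")
    rng = np.random.default_rng(seed)

    centre = np.array([shape[0] / 2, shape[1] / 2])
    zone_radius = np.sqrt(zone_fraction * shape[0] * shape[1] / np.pi)
    # moved filaments need room between the zone edge and the frame border
    if np.hypot(min(shape) / 2 - 14.0, min(shape) / 2 - 14.0) <= zone_radius + 24.0:
        raise ValueError(
            "frame too small for this zone_fraction: no room outside the zone")
    # filaments start well inside the zone so the frame-0 hull stays compact
    # seed points spread through the zone with a minimum spacing, so
    # filaments rarely overlap and pixel counts track filament counts
    spawn_radius = 0.72 * zone_radius
    min_spacing = min(10.0, 1.6 * spawn_radius / np.sqrt(n_segments))
    starts: list[np.ndarray] = []
    while len(starts) < n_segments:
        r = np.sqrt(rng.uniform(0, spawn_radius**2))
        ang = rng.uniform(0, 2 * np.pi)
        cand = centre + r * np.array([np.sin(ang), np.cos(ang)])
        if all(np.linalg.norm(cand - s) >= min_spacing for s in starts):
            starts.append(cand)
    segments = [_mt_segment(rng, n_steps=4, step_px=3.0, start=s) for s in starts]
    # precomputed destination for each filament once scheduled to move: a
    # point outside the zone but safely inside the frame
    shifts = np.zeros((n_segments, 2))
    lo, hi = 14.0, min(shape) - 14.0
    for i, seg in enumerate(segments):
        centroid = seg.mean(axis=0)
        while True:
            target = rng.uniform(lo, hi, 2)
            if np.linalg.norm(target - centre) > zone_radius + 16.0:
                break
        shifts[i] = target - centroid
    move_order = rng.permutation(n_segments)

    frames = []
    true_mf_pct = []
    for k in range(n_frames):
        t_min = k * interval_s / 60.0
        mf_target = min(rate_pct_min * t_min, plateau_pct)
        n_moved = int(round(n_segments * mf_target / 100.0))
        moved = set(move_order[:n_moved].tolist())
        expected = np.zeros(shape)
        for i, seg in enumerate(segments):
            pts = seg + (shifts[i] if i in moved else 0.0)
            _raster_polyline(expected, pts, mt_intensity)
        expected = (expected + background) * (1.0 - bleach_per_frame) ** k
        frames.append(rng.poisson(expected).astype(float))
        true_mf_pct.append(100.0 * n_moved / n_segments)

    stack = ImageStack(
        np.stack(frames)[:, None], pixel_size_nm=pixel_size_nm,
        frame_interval_s=interval_s,
    )
    truth = SyntheticTruth(
        seed=seed, scenario="mt_sliding",
        params={
            "sliding_rate_pct_min": rate_pct_min, "zone_fraction": zone_fraction,
            "interval_s": interval_s, "bleach_per_frame": bleach_per_frame,
            "n_segments": n_segments, "plateau_pct": plateau_pct,
            "background_level": background, "poisson_noise": True,
            "true_mf_pct": true_mf_pct,
        },
    )
    return stack, truth


def gen_trajectories(
    mt_length_um: float = 40.0,
    duration_min: float = 2.0,
    landing_rate_per_um_min: float = 0.5,
    motile_fraction: float = 0.7,
    mean_run_nm: float = 1200.0,
    mean_velocity_nm_s: float = 300.0,
    velocity_sd: float = 60.0,
    immotile_dwell_range_s: tuple[float, float] = (2.5, 10.0),
    loc_noise_nm: float = 15.0,
    sample_interval_s: float = 0.1017,
    seed: int = 0,
    pixel_size_nm: float = 107.0,
    field_px: int = 256,
) -> tuple[TrajectorySet, BinaryMask, SyntheticTruth]:
    """Single-molecule landing events on a simulated microtubule field.

    Landings are a Poisson process with expectation
    ``landing_rate * mt_length * duration``.  A landing is motile with
    probability ``motile_fraction``: its true run length is
    Exponential(``mean_run_nm``) and its velocity Normal(truncated > 0);
    otherwise it dwells immotile for Uniform(``immotile_dwell_range_s``)
    seconds with zero net displacement.  Positions are sampled every
    ``sample_interval_s`` along the filament polyline plus isotropic
    Gaussian localization noise.  The microtubule mask is the rasterized
    filament set dilated by one pixel.

    Start times are drawn so each event completes within the movie — the
    generator models complete, unclipped engagements, trading a slight
    thinning of late landings for unbiased run-length statistics.
    """
    if min(mt_length_um, duration_min, landing_rate_per_um_min,
           mean_run_nm, mean_velocity_nm_s) <= 0:
        raise ValueError("rates and means must be > 0")
    if not 0 <= motile_fraction <= 1:
        raise ValueError("motile_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    # --- filament geometry: a few polylines totalling mt_length_um
    step_px = 4.0
    step_um = step_px * pixel_size_nm / 1000.0
    n_filaments = max(1, int(round(mt_length_um / 12.0)))
    per_fil_um = mt_length_um / n_filaments
    n_steps = max(2, int(round(per_fil_um / step_um)))
    filaments = []
    margin = 12
    centre_px = np.array([field_px / 2, field_px / 2])
    for _ in range(n_filaments):
        start = rng.uniform(4 * margin, field_px - 4 * margin, 2)
        # taxol-stabilized microtubules are close to straight at field
        # scale; aim each one across the field so it stays in frame
        aim = centre_px - start
        heading = np.arctan2(aim[0], aim[1]) + rng.uniform(-0.4, 0.4)
        filaments.append(_mt_segment(
            rng, n_steps, step_px, start, max_turn_rad=0.08,
            bounds=(margin, field_px - 1 - margin), heading=heading,
        ))
    # arclength tables (in nm) per filament
    arcs = []
    for pts in filaments:
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1) * pixel_size_nm
        arcs.append(np.concatenate([[0.0], np.cumsum(steps)]))
    total_len_nm = float(sum(a[-1] for a in arcs))

    mask_img = np.zeros((field_px, field_px))
    for pts in filaments:
        _raster_polyline(mask_img, pts, 1.0)
    from scipy import ndimage

    mask = BinaryMask(ndimage.binary_dilation(mask_img > 0, iterations=1),
                      provenance="microtubule")

    duration_s = duration_min * 60.0
    n_land = rng.poisson(landing_rate_per_um_min * mt_length_um * duration_min)
    weights = np.array([a[-1] for a in arcs]) / total_len_nm

    def point_at(fil: int, s_nm: float) -> np.ndarray:
        """(row, col) px at arclength s_nm along filament fil (clamped)."""
        a, pts = arcs[fil], filaments[fil]
        s = np.clip(s_nm, 0.0, a[-1])
        i = int(np.searchsorted(a, s, side="right") - 1)
        i = min(i, len(pts) - 2)
        frac = (s - a[i]) / (a[i + 1] - a[i])
        return pts[i] + frac * (pts[i + 1] - pts[i])

    trajectories: list[Trajectory] = []
    truth_events = []
    for j in range(n_land):
        fil = int(rng.choice(len(filaments), p=weights))
        s0 = rng.uniform(0, arcs[fil][-1])
        motile = rng.random() < motile_fraction
        if motile:
            run = rng.exponential(mean_run_nm)
            v = rng.normal(mean_velocity_nm_s, velocity_sd)
            while v <= 0:
                v = rng.normal(mean_velocity_nm_s, velocity_sd)
            dur = run / v
            room_fwd = arcs[fil][-1] - s0
            direction = 1.0 if room_fwd >= s0 else -1.0
            if run > max(room_fwd, s0):  # run longer than the filament allows
                run = max(room_fwd, s0)
                dur = run / v
        else:
            run, v = 0.0, 0.0
            dur = rng.uniform(*immotile_dwell_range_s)
            direction = 0.0
        if dur > duration_s:  # an engagement cannot outlast the movie
            dur = 0.999 * duration_s
            if motile:
                run = v * dur
        t0 = rng.uniform(0, max(duration_s - dur, 1e-6))
        n_samp = int(np.floor(dur / sample_interval_s)) + 1
        t_rel = np.arange(n_samp) * sample_interval_s
        t_rel = t_rel[t_rel < dur - 1e-9]
        t_rel = np.append(t_rel, dur)  # always sample the detachment point
        pos_px = np.array([point_at(fil, s0 + direction * v * t) for t in t_rel])
        xy_nm = pos_px[:, ::-1] * pixel_size_nm  # (row, col) -> (x, y)
        # the realized net displacement: equals the exponential draw except
        # where filament curvature bends the path or an end truncated it
        chord_nm = float(np.hypot(*(xy_nm[-1] - xy_nm[0])))
        xy_nm = xy_nm + rng.normal(0.0, loc_noise_nm, xy_nm.shape)
        samples = np.column_stack([t0 + t_rel, xy_nm])
        trajectories.append(Trajectory(track_id=f"trk{j:05d}", samples=samples))
        truth_events.append({
            "track_id": f"trk{j:05d}",
            "true_class": "motile" if motile else "immotile",
            "true_run_nm": chord_nm if motile else 0.0,
            "true_velocity_nm_s": v, "true_duration_s": dur,
        })

    tset = TrajectorySet(
        trajectories=trajectories, movie_duration_s=duration_s,
        pixel_size_nm=pixel_size_nm, field_id=f"sim{seed}",
    )
    truth = SyntheticTruth(
        seed=seed, scenario="sm_trajectories",
        params={
            "mt_length_um": mt_length_um, "duration_min": duration_min,
            "landing_rate_per_um_min": landing_rate_per_um_min,
            "motile_fraction": motile_fraction, "mean_run_nm": mean_run_nm,
            "mean_velocity_nm_s": mean_velocity_nm_s, "velocity_sd": velocity_sd,
            "immotile_dwell_range_s": list(immotile_dwell_range_s),
            "loc_noise_nm": loc_noise_nm, "sample_interval_s": sample_interval_s,
            "pixel_size_nm": pixel_size_nm,
            "polyline_length_nm": total_len_nm,
            "events": truth_events,
        },
    )
    return tset, mask, truth
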