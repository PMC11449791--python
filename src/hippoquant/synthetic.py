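"""Synthetic inputs with embedded ground truth.

Every downstream stage of the pipeline is exercised against signals and
images generated here, so each generator carries its ground truth out with
the data: the colored-noise spectral exponent, the theta epoch boundaries
and cycle (peak) times, spine class labels, and puncta centers/areas.

Generators are pure functions of their seed: the same seed yields
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import Recording
from .trees import NeuronTree
from .spines import SpineRecord
from .imaging import PunctaImage

__all__ = [
    "LfpSimParams",
    "GroundTruth",
    "generate_colored_noise",
    "generate_lfp",
    "generate_neuron_tree",
    "generate_spines",
    "generate_puncta_image",
]


def generate_colored_noise(
    beta: float, n: int, fs: float, seed: int, knee_hz: float = 0.0
) -> np.ndarray:
    """Gaussian 1/f^beta noise by frequency-domain spectral synthesis.

    Fourier amplitudes are drawn proportional to ``f**(-beta/2)`` with
    independent uniform phases and Hermitian symmetry, so the expected
    periodogram follows ``f**-beta`` exactly — the exponent is analytic
    ground truth, unlike AR-filtered approximations. The series is
    normalized to zero mean and unit variance.

    ``knee_hz > 0`` flattens the spectrum below that frequency (amplitude
    ``max(f, knee)**(-beta/2)``), emulating the infra-slow plateau of real
    recordings; the exponent above the knee is unchanged.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros(freqs.size)
    amp[1:] = np.maximum(freqs[1:], knee_hz) ** (-beta / 2.0)
    # random Rayleigh magnitudes + uniform phases = complex Gaussian spectrum
    re = rng.standard_normal(freqs.size)
    im = rng.standard_normal(freqs.size)
    spec = amp * (re + 1j * im)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


@dataclass
class LfpSimParams:
    """Conditions for one synthetic CA1 LFP recording.

    Amplitudes are in units of the background-noise standard deviation
    (the signal is unitless, mirroring a z-scored recording). ``theta_freq_hz``
    may be a single frequency or a ``(lo, hi)`` range for slow frequency
    modulation; default is 6–10 Hz FM so instantaneous-frequency estimation
    is exercised, with theta amplitude 3 — a locomotion theta that stands
    clearly above the slow background, as in dorsal CA1 stratum pyramidale.
    The background spectrum is 1/f^beta above ``f_knee_hz`` and plateaus
    below it (real recordings do not carry unbounded infra-slow power).
    The theta-nested gamma is broadband noise band-passed to
    ``gamma_band_hz``, amplitude-locked to the theta peak, and scaled so
    its average in-band power is ``gamma_rel`` times the aperiodic floor
    there — a visible bump that stresses the slope fit without redefining
    the band's underlying exponent.
    """

    duration_s: float = 60.0
    fs_hz: float = 1000.0
    beta: float = 2.5
    f_knee_hz: float = 1.0
    theta_freq_hz: float | tuple[float, float] = (6.0, 10.0)
    theta_amp: float = 3.0
    gamma_band_hz: tuple[float, float] = (30.0, 50.0)
    gamma_rel: float = 1.0
    line_hz: float = 50.0
    line_amp: float = 0.2
    move_duty: float = 1.0
    fs_vel_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        f = self.theta_freq_hz
        flo, fhi = (f, f) if np.isscalar(f) else f
        if self.theta_amp > 0 and not (5.0 < flo <= fhi < 12.0):
            warnings.warn(
                "theta frequency outside (5, 12) Hz: generating anyway "
                "(negative-control signal)",
                stacklevel=2,
            )
        nyq = self.fs_hz / 2.0
        fmax = max(fhi, self.gamma_band_hz[1], 2 * self.line_hz)
        if fmax >= nyq:
            raise ValueError("fs_hz must be at least twice the fastest component")


@dataclass
class GroundTruth:
    """What the generator actually put into a synthetic recording."""

    true_beta: float
    theta_epochs: list[tuple[float, float]]
    true_cycle_times: np.ndarray
    moving_mask: np.ndarray  # boolean, on the velocity time base
    fs_vel_hz: float = 50.0


def _movement_epochs(
    duration_s: float, duty: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Alternating run/rest bouts covering ``duty`` of the session."""
    if duty >= 1.0:
        return [(0.0, duration_s)]
    if duty <= 0.0:
        return []
    epochs = []
    t = 0.0
    while t < duration_s:
        run = rng.uniform(3.0, 8.0)
        rest = run * (1.0 - duty) / duty
        start = t
        end = min(t + run, duration_s)
        if end - start >= 1.0:
            epochs.append((start, end))
        t = end + rest
    return epochs


def generate_lfp(params: LfpSimParams) -> tuple[Recording, GroundTruth]:
    """Synthesize one LFP recording plus its ground truth.

    The signal is unit-variance 1/f^beta background noise, plus a
    movement-gated (optionally frequency-modulated) theta oscillation,
    theta-phase-locked bursts in ``gamma_band_hz``, and a mains sinusoid
    at ``line_hz`` with its first harmonic. The velocity trace exceeds
    2 cm/s exactly during theta epochs.
    """
    p = params
    n = int(round(p.duration_s * p.fs_hz))
    rng = np.random.default_rng(p.seed)
    t = np.arange(n) / p.fs_hz

    noise = generate_colored_noise(
        p.beta, n, p.fs_hz, int(rng.integers(2**31)), knee_hz=p.f_knee_hz
    )

    epochs = _movement_epochs(p.duration_s, p.move_duty, rng)
    gate = np.zeros(n)
    for start, end in epochs:
        i0, i1 = int(round(start * p.fs_hz)), int(round(end * p.fs_hz))
        gate[i0:i1] = 1.0
    # 100 ms cosine ramps at epoch edges avoid broadband onset clicks
    ramp_n = int(0.1 * p.fs_hz)
    if ramp_n > 1 and epochs and p.move_duty < 1.0:
        kernel = np.hanning(2 * ramp_n + 1)
        kernel /= kernel.sum()
        gate = np.convolve(gate, kernel, mode="same")

    # theta phase: integrate a (possibly slowly modulated) frequency track
    if np.isscalar(p.theta_freq_hz):
        f_inst = np.full(n, float(p.theta_freq_hz))
    else:
        flo, fhi = p.theta_freq_hz
        mid, half = 0.5 * (flo + fhi), 0.5 * (fhi - flo)
        mod_phase = rng.uniform(0, 2 * np.pi)
        f_inst = mid + half * np.sin(2 * np.pi * 0.05 * t + mod_phase)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / p.fs_hz
    theta = p.theta_amp * gate * np.cos(phase)

    # theta-nested gamma: broadband noise band-passed to gamma_band_hz,
    # amplitude maximal at the theta peak, average in-band power set to
    # gamma_rel times the aperiodic floor of the background there
    g_lo, g_hi = p.gamma_band_hz
    if p.gamma_rel > 0:
        from scipy import signal as sps

        sos = sps.butter(4, [g_lo, g_hi], btype="bandpass", fs=p.fs_hz,
                         output="sos")
        # carrier shares the background exponent, so the burst elevates the
        # in-band spectrum uniformly instead of tilting it
        carrier = sps.sosfiltfilt(
            sos,
            generate_colored_noise(
                p.beta, n, p.fs_hz, int(rng.integers(2**31)), knee_hz=p.f_knee_hz
            ),
        )
        carrier /= carrier.std()
        noise_band = sps.sosfiltfilt(sos, noise)
        g_env = 0.5 * (1.0 + np.cos(phase)) * gate
        mean_env2 = float(np.mean(g_env**2))
        if mean_env2 > 0:
            target_var = p.gamma_rel * float(np.var(noise_band))
            gamma = np.sqrt(target_var / mean_env2) * g_env * carrier
        else:
            gamma = np.zeros(n)
    else:
        gamma = np.zeros(n)

    line = p.line_amp * (
        np.sin(2.0 * np.pi * p.line_hz * t)
        + 0.3 * np.sin(2.0 * np.pi * 2.0 * p.line_hz * t)
    )

    lfp = noise + theta + gamma + line

    # velocity: > 2 cm/s exactly inside epochs, < 2 outside
    n_vel = int(round(p.duration_s * p.fs_vel_hz))
    t_vel = np.arange(n_vel) / p.fs_vel_hz
    vel = 0.5 + 0.4 * np.abs(rng.standard_normal(n_vel))
    moving = np.zeros(n_vel, dtype=bool)
    for start, end in epochs:
        in_ep = (t_vel >= start) & (t_vel < end)
        moving |= in_ep
        vel[in_ep] = 6.0 + 2.0 * np.abs(rng.standard_normal(int(in_ep.sum())))
    vel = np.clip(vel, 0.0, None)

    # ground-truth cycle times: theta peaks (phase = 2*pi*k) inside epochs
    if p.theta_amp > 0:
        k_max = int(phase[-1] // (2 * np.pi))
        peak_phases = 2 * np.pi * np.arange(1, k_max + 1)
        peak_times = np.interp(peak_phases, phase, t)
        in_epoch = np.zeros(peak_times.size, dtype=bool)
        for start, end in epochs:
            in_epoch |= (peak_times >= start) & (peak_times < end)
        cycle_times = peak_times[in_epoch]
    else:
        cycle_times = np.array([])

    rec = Recording(
        samples=lfp,
        fs_hz=p.fs_hz,
        velocity=vel,
        fs_vel_hz=p.fs_vel_hz,
        meta={"synthetic": True, "beta": p.beta, "seed": p.seed},
    )
    truth = GroundTruth(
        true_beta=p.beta,
        theta_epochs=epochs,
        true_cycle_times=cycle_times,
        moving_mask=moving,
        fs_vel_hz=p.fs_vel_hz,
    )
    return rec, truth


def generate_neuron_tree(
    n_branch_events: int,
    step_um: float = 5.0,
    seed: int = 0,
    length_um: float = 100.0,
    jitter_rad: float = 0.0,
) -> NeuronTree:
    """Random rooted 3-D tree in SWC semantics, soma at the origin.

    The trunk grows radially outward in ``step_um`` steps; each branch event
    splits a random active tip into two divergent daughters. With
    ``n_branch_events=0`` and no jitter the result is a single straight
    radial cable of ``length_um``. ``jitter_rad`` adds per-step angular
    wobble for irregular test trees.
    """
    if n_branch_events < 0:
        raise ValueError("n_branch_events must be >= 0")
    rng = np.random.default_rng(seed)

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    def jitter(d: np.ndarray) -> np.ndarray:
        if jitter_rad <= 0:
            return d
        w = rng.standard_normal(3) * jitter_rad
        return unit(d + w)

    nodes = [(1, 1, 0.0, 0.0, 0.0, 2.0, -1)]  # id, type, x, y, z, radius, parent
    next_id = 2
    # branch events scheduled at path distances from the soma
    branch_at = sorted(rng.uniform(0.15, 0.7, size=n_branch_events) * length_um)
    # each tip: (parent node id, position, direction, path grown so far)
    tips = [(1, np.zeros(3), unit(rng.standard_normal(3)), 0.0)]
    while tips:
        parent, pos, dirn, path = tips.pop(0)
        step = min(step_um, length_um - path)
        if step <= 1e-9:
            continue
        pos2 = pos + step * dirn
        nodes.append((next_id, 3, float(pos2[0]), float(pos2[1]), float(pos2[2]), 0.5, parent))
        me = next_id
        next_id += 1
        path2 = path + step
        if branch_at and path < branch_at[0] <= path2 and length_um - path2 > step_um:
            branch_at.pop(0)
            axis = unit(np.cross(dirn, rng.standard_normal(3)))
            ang = rng.uniform(0.3, 0.7)
            d1 = unit(np.cos(ang) * dirn + np.sin(ang) * axis)
            d2 = unit(np.cos(ang) * dirn - np.sin(ang) * axis)
            tips.append((me, pos2, jitter(d1), path2))
            tips.append((me, pos2, jitter(d2), path2))
        elif path2 < length_um - 1e-9:
            tips.append((me, pos2, jitter(dirn), path2))
    return NeuronTree.from_rows(nodes, soma_id=1)


_SPINE_CLASSES = ("stubby", "mushroom", "thin")


def generate_spines(
    n: int,
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    max_position_um: float = 150.0,
) -> list[SpineRecord]:
    """Class-conditional spine geometries with embedded true labels.

    Each record is sampled strictly inside its class's decision region
    (no geometry sits on a rule boundary such as 1.0 or 1.5 um), so a
    correct classifier recovers the generating label exactly:

    * stubby   — length in (0.3, 0.95) um, no neck, no discernible head;
    * mushroom — length in (1.05, 1.45) um, neck present, head diameter
      drawn at 1.6–2.5x the neck length (comfortably past the 1.5x rule);
    * thin     — length in (1.55, 3.0) um, thin neck, small head.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    mix = np.asarray(class_mix, dtype=float)
    if mix.size != 3 or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("class_mix must be three non-negative proportions summing to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n, p=mix)
    out: list[SpineRecord] = []
    for lab in labels:
        pos = float(rng.uniform(0.0, max_position_um))
        if lab == 0:  # stubby
            rec = SpineRecord(
                length_um=float(rng.uniform(0.3, 0.95)),
                head_diam_um=None,
                neck_len_um=None,
                head_discernible=False,
                neck_present=False,
                position_um=pos,
            )
        elif lab == 1:  # mushroom
            neck = float(rng.uniform(0.2, 0.45))
            rec = SpineRecord(
                length_um=float(rng.uniform(1.05, 1.45)),
                head_diam_um=neck * float(rng.uniform(1.6, 2.5)),
                neck_len_um=neck,
                head_discernible=True,
                neck_present=True,
                position_um=pos,
            )
        else:  # thin
            neck = float(rng.uniform(0.5, 1.2))
            rec = SpineRecord(
                length_um=float(rng.uniform(1.55, 3.0)),
                head_diam_um=neck * float(rng.uniform(0.3, 0.9)),
                neck_len_um=neck,
                head_discernible=True,
                neck_present=True,
                position_um=pos,
            )
        rec.true_class = _SPINE_CLASSES[lab]
        out.append(rec)
    return out


def generate_puncta_image(
    field_um: tuple[float, float] = (18.33, 18.33),
    px_um: float = 0.125,
    n_puncta: int = 10,
    area_range_um2: tuple[float, float] = (0.3, 1.2),
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 20.0,
    foreground: float = 200.0,
    max_tries: int = 2000,
) -> tuple[PunctaImage, pd.DataFrame]:
    """Grayscale field with ``n_puncta`` non-overlapping bright disks.

    The default 18.33 x 18.33 um field reproduces the 336 um^2 neuropil
    squares used for puncta densitometry. Disk placement is by rejection
    sampling with a one-pixel clearance; failure to place all disks within
    ``max_tries`` attempts raises. Returns the 8-bit image and a truth
    table with one row per punctum (center and area in um).
    """
    w_um, h_um = field_um
    rng = np.random.default_rng(seed)
    w_px = int(round(w_um / px_um))
    h_px = int(round(h_um / px_um))
    lo, hi = area_range_um2
    if lo <= 0 or hi < lo:
        raise ValueError("invalid area_range_um2")

    placed: list[tuple[float, float, float]] = []  # x_um, y_um, r_um
    rows = []
    clearance = px_um  # one pixel
    for _ in range(n_puncta):
        area = float(rng.uniform(lo, hi))
        r = float(np.sqrt(area / np.pi))
        for _try in range(max_tries):
            x = float(rng.uniform(r + clearance, w_um - r - clearance))
            y = float(rng.uniform(r + clearance, h_um - r - clearance))
            if all(
                np.hypot(x - px_, y - py_) > r + pr_ + 2 * clearance
                for px_, py_, pr_ in placed
            ):
                placed.append((x, y, r))
                rows.append({"x_um": x, "y_um": y, "radius_um": r, "area_um2": area})
                break
        else:
            raise RuntimeError(
                f"could not place {n_puncta} non-overlapping puncta in the field"
            )

    img = np.full((h_px, w_px), background, dtype=float)
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    xx_um = (xx + 0.5) * px_um
    yy_um = (yy + 0.5) * px_um
    for x, y, r in placed:
        img[(xx_um - x) ** 2 + (yy_um - y) ** 2 <= r**2] = foreground
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img8 = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(rows, columns=["x_um", "y_um", "radius_um", "area_um2"])
    return PunctaImage(pixels=img8, px_um=px_um), truth
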