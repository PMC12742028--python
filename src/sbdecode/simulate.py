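"""Synthetic parcel-level M/EEG sessions with planted state effects.

The generator emulates the signal features the downstream pipeline consumes,
at the level of parcellated source time series (no sensor space, head model
or beamforming):

* a 1/f aperiodic background with a state- and region-dependent exponent,
  synthesized by spectral shaping so the target exponent holds by
  construction;
* band-limited alpha (8–12 Hz) and beta (25–29 Hz) oscillations — narrowband
  filtered noise rather than sinusoids, so the spectral peaks have realistic
  bandwidth; the beta amplitude carries the planted self-boundary effect
  (reduced in SB−);
* a broadband white-noise component whose mixing weight ("complexity drive")
  monotonically raises Lempel-Ziv complexity, giving a testable handle on the
  planted complexity effect;
* optional cross-region mixing to induce inter-regional correlation.

State segments are generated independently, so analysis epochs never straddle
a state boundary by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.typing import NDArray
from scipy import signal as sps

from .protocol import REST, SB_MINUS, SB_PLUS, STATES, SessionProtocol

__all__ = [
    "EffectSpec",
    "ParcelTimeSeries",
    "generate_session",
    "generate_cohort",
    "save_session",
    "load_session",
    "write_segment_manifest",
]

ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (25.0, 29.0)


def _per_state_per_region(value, region_count: int) -> dict[str, NDArray[np.float64]]:
    """Broadcast a scalar / per-state scalar / per-state vector spec to
    ``{state: (region_count,) array}``."""
    if isinstance(value, dict):
        out = {}
        for s in STATES:
            v = np.broadcast_to(np.asarray(value[s], dtype=float), (region_count,))
            out[s] = np.array(v)
        return out
    v = np.broadcast_to(np.asarray(value, dtype=float), (region_count,))
    return {s: np.array(v) for s in STATES}


@dataclass
class EffectSpec:
    """Per-state, per-region generative parameters.

    Parameters accept scalars, per-state scalars (``{state: value}``) or
    per-state vectors of length ``region_count``.

    Attributes
    ----------
    beta_amp_multiplier
        Multiplicative factor on the 25–29 Hz oscillation amplitude
        (dimensionless, > 0). Values < 1 in SB− plant the beta-power
        reduction associated with self-boundary dissolution.
    aperiodic_exponent
        Target 1/f exponent chi (power ∝ f^−chi) of the background.
    complexity_drive
        Mixing weight w ∈ [0, 1] of broadband white noise versus the
        structured (1/f + oscillation) component; higher w raises normalized
        Lempel-Ziv complexity.
    cross_region_mixing
        Optional (R, R) matrix applied to the region stack; rows must sum
        to 1. ``None`` means identity (independent regions).
    noise_sd
        Overall amplitude scale (arbitrary units).
    """

    region_count: int = 62
    beta_amp_multiplier: dict[str, NDArray[np.float64]] = field(default=None)  # type: ignore[assignment]
    aperiodic_exponent: dict[str, NDArray[np.float64]] = field(default=None)  # type: ignore[assignment]
    complexity_drive: dict[str, NDArray[np.float64]] = field(default=None)  # type: ignore[assignment]
    cross_region_mixing: NDArray[np.float64] | None = None
    noise_sd: float = 1.0
    alpha_amp: float = 0.5
    beta_amp: float = 0.4

    def __post_init__(self) -> None:
        if self.beta_amp_multiplier is None:
            self.beta_amp_multiplier = 1.0  # type: ignore[assignment]
        if self.aperiodic_exponent is None:
            self.aperiodic_exponent = 1.0  # type: ignore[assignment]
        if self.complexity_drive is None:
            self.complexity_drive = 0.2  # type: ignore[assignment]
        self.beta_amp_multiplier = _per_state_per_region(
            self.beta_amp_multiplier, self.region_count
        )
        self.aperiodic_exponent = _per_state_per_region(
            self.aperiodic_exponent, self.region_count
        )
        self.complexity_drive = _per_state_per_region(
            self.complexity_drive, self.region_count
        )
        for s in STATES:
            if np.any(self.beta_amp_multiplier[s] <= 0):
                raise ValueError("beta_amp_multiplier must be positive")
            w = self.complexity_drive[s]
            if np.any((w < 0) | (w > 1)):
                raise ValueError("complexity_drive must lie in [0, 1]")
        if self.cross_region_mixing is not None:
            m = np.asarray(self.cross_region_mixing, dtype=float)
            if m.shape != (self.region_count, self.region_count):
                raise ValueError("cross_region_mixing must be (R, R)")
            if not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("cross_region_mixing rows must sum to 1")
            self.cross_region_mixing = m
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    # -- presets ---------------------------------------------------------

    @classmethod
    def null(cls, region_count: int = 62, **kw) -> "EffectSpec":
        """All states share identical parameters: no decodable signal."""
        return cls(region_count=region_count, **kw)

    @classmethod
    def study_like(cls, region_count: int = 62) -> "EffectSpec":
        """Planted effects emulating the self-boundary dissolution findings.

        SB− carries a beta-amplitude reduction and a broadband complexity
        increase relative to rest, with SB+ intermediate (meditation states
        resemble each other more than either resembles rest). Magnitudes are
        calibrated so LZc effect sizes between SB− and rest land in the
        small-to-medium Cohen's d band (≈ 0.2–0.4).
        """
        return cls(
            region_count=region_count,
            beta_amp_multiplier={REST: 1.0, SB_MINUS: 0.95, SB_PLUS: 0.98},
            aperiodic_exponent={REST: 1.0, SB_MINUS: 0.97, SB_PLUS: 1.0},
            complexity_drive={REST: 0.20, SB_MINUS: 0.21, SB_PLUS: 0.205},
        )

    @classmethod
    def strong_beta(cls, region_count: int = 62, n_affected: int = 10) -> "EffectSpec":
        """Separable regime: beta amplitude cut to 0.3 in the first
        ``n_affected`` regions during SB−, leaving all else null."""
        mult = np.ones(region_count)
        mult[:n_affected] = 0.3
        return cls(
            region_count=region_count,
            beta_amp_multiplier={REST: 1.0, SB_MINUS: mult, SB_PLUS: 1.0},
        )

    def jittered(self, rng: np.random.Generator, sd: float) -> "EffectSpec":
        """Participant-level draw around this cohort spec.

        Multiplicative lognormal jitter on the beta multiplier, additive
        Gaussian jitter on the exponent, additive (clipped) jitter on the
        complexity drive; one draw per state, shared across regions, so each
        participant is a coherent shift of the cohort parameters. ``sd = 0``
        reproduces the cohort spec exactly.
        """
        if sd == 0:
            return replace(self)
        beta = {
            s: self.beta_amp_multiplier[s] * np.exp(sd * rng.standard_normal())
            for s in STATES
        }
        chi = {
            s: self.aperiodic_exponent[s] + sd * rng.standard_normal()
            for s in STATES
        }
        drive = {
            s: np.clip(
                self.complexity_drive[s] + sd * rng.standard_normal(), 0.0, 1.0
            )
            for s in STATES
        }
        return EffectSpec(
            region_count=self.region_count,
            beta_amp_multiplier=beta,
            aperiodic_exponent=chi,
            complexity_drive=drive,
            cross_region_mixing=self.cross_region_mixing,
            noise_sd=self.noise_sd,
            alpha_amp=self.alpha_amp,
            beta_amp=self.beta_amp,
        )


@dataclass
class ParcelTimeSeries:
    """Region × sample signal matrix with per-sample state labels."""

    values: NDArray[np.float64]
    sampling_rate: float
    state_labels: NDArray[np.str_]
    participant_id: str
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.state_labels = np.asarray(self.state_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be region × sample")
        if self.values.shape[1] != self.state_labels.shape[0]:
            raise ValueError("state_labels must have one entry per sample")
        if len(self.region_labels) != self.values.shape[0]:
            raise ValueError("region_labels must have one entry per region")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region_labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite samples")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def segments(self) -> list[tuple[str, int, int]]:
        """Contiguous runs of identical state label as (state, start, stop)."""
        labels = self.state_labels
        boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [labels.shape[0]]])
        return [(str(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def _default_region_labels(region_count: int) -> list[str]:
    if region_count == 62:
        from .parcellation import default_atlas

        return default_atlas().merged_labels
    return [f"R{i:03d}" for i in range(region_count)]


def _one_over_f(
    rng: np.random.Generator, n: int, fs: float, exponent: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Unit-SD 1/f-shaped noise, one row per region, exact exponent by
    spectral shaping of white Gaussian noise."""
    n_regions = exponent.shape[0]
    white = rng.standard_normal((n_regions, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros((n_regions, freqs.shape[0]))
    with np.errstate(divide="ignore"):
        scale[:, 1:] = freqs[np.newaxis, 1:] ** (-exponent[:, np.newaxis] / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], rows: int
) -> NDArray[np.float64]:
    """Unit-SD band-limited noise (4th-order zero-phase Butterworth)."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((rows, n)), axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_session(
    protocol: SessionProtocol,
    effects: EffectSpec,
    seed: int,
    participant_id: str = "P000",
) -> ParcelTimeSeries:
    """Simulate one labeled session under the given protocol and effects.

    Each state segment is generated independently; within a segment, region
    r receives ``(1 − w)·(onef(chi) + a_alpha·alpha + a_beta·mult·beta)
    + w·white``, rescaled by ``noise_sd``, with all components unit-SD so the
    complexity drive w trades structure for stochasticity at roughly constant
    amplitude. Identical seeds reproduce the series bit-for-bit.
    """
    if not protocol.block_layout:
        raise ValueError("protocol has no segments")
    if protocol.sampling_rate < 200:
        raise ValueError(
            "sampling_rate must be ≥ 200 Hz so the 1–100 Hz band is below Nyquist"
        )
    fs = protocol.sampling_rate
    rng = np.random.default_rng(seed)
    R = effects.region_count
    chunks: list[NDArray[np.float64]] = []
    labels: list[NDArray[np.str_]] = []
    # every segment is synthesized on one common, padded length and cropped
    # to its duration: segments of different lengths would otherwise differ
    # slightly in spectral discretization (the 1/f shaping is circular on
    # the generation grid) and in filter-transient content, which plants a
    # spurious, duration-linked state difference
    pad_s = 4.0
    n_pad = int(round(pad_s * fs))
    max_n = max(int(round(d * fs)) for _, d in protocol.block_layout)
    n_gen = max_n + 2 * n_pad
    for state, dur in protocol.block_layout:
        n = int(round(dur * fs))
        chi = effects.aperiodic_exponent[state]
        w = effects.complexity_drive[state]
        mult = effects.beta_amp_multiplier[state]
        structured = (
            _one_over_f(rng, n_gen, fs, chi)
            + effects.alpha_amp * _narrowband(rng, n_gen, fs, ALPHA_BAND, R)
            + effects.beta_amp * mult[:, np.newaxis] * _narrowband(rng, n_gen, fs, BETA_BAND, R)
        )[:, n_pad : n_pad + n]
        # analytic unit-SD normalization (components are independent and
        # unit-SD themselves) so w trades determinism for noise; a realized
        # per-segment std here would couple the mixing ratio to segment
        # duration through estimator noise
        denom = np.sqrt(
            1.0 + effects.alpha_amp**2 + (effects.beta_amp * mult) ** 2
        )
        structured = structured / denom[:, np.newaxis]
        white = rng.standard_normal((R, n))
        seg = (1.0 - w[:, np.newaxis]) * structured + w[:, np.newaxis] * white
        if effects.cross_region_mixing is not None:
            seg = effects.cross_region_mixing @ seg
        chunks.append(effects.noise_sd * seg)
        labels.append(np.full(n, state))
    return ParcelTimeSeries(
        values=np.concatenate(chunks, axis=1),
        sampling_rate=fs,
        state_labels=np.concatenate(labels),
        participant_id=participant_id,
        region_labels=_default_region_labels(R),
    )


def generate_cohort(
    n_participants: int,
    effects: EffectSpec,
    between_participant_sd: float = 0.0,
    seed: int = 0,
    protocol: SessionProtocol | None = None,
) -> list[ParcelTimeSeries]:
    """Simulate a cohort with participant-level parameter variability.

    Each participant's effect parameters are drawn around the cohort
    ``effects`` via :meth:`EffectSpec.jittered`; ``between_participant_sd = 0``
    makes all participants share identical parameters (their noise
    realizations still differ).
    """
    if n_participants < 2:
        raise ValueError(
            "n_participants must be ≥ 2 (across-participant splits are undefined "
            "for a single participant)"
        )
    if protocol is None:
        protocol = SessionProtocol(
            block_layout=default_layout(), sampling_rate=300.0
        )
    master = np.random.default_rng(seed)
    sessions = []
    for i in range(n_participants):
        spec_i = effects.jittered(master, between_participant_sd)
        child_seed = int(master.integers(2**31))
        sessions.append(
            generate_session(protocol, spec_i, child_seed, participant_id=f"P{i:03d}")
        )
    return sessions


def default_layout() -> tuple[tuple[str, int], ...]:
    from .protocol import default_protocol

    return default_protocol().block_layout


# -- persistence ---------------------------------------------------------


def save_session(ts: ParcelTimeSeries, directory: str | Path) -> Path:
    """Write one session as an .npz array container plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / ts.participant_id
    np.savez(
        stem.with_suffix(".npz"),
        values=ts.values,
        state_labels=ts.state_labels.astype("U"),
    )
    sidecar = {
        "participant_id": ts.participant_id,
        "sampling_rate": ts.sampling_rate,
        "region_labels": list(ts.region_labels),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".npz")


def load_session(npz_path: str | Path) -> ParcelTimeSeries:
    npz_path = Path(npz_path)
    data = np.load(npz_path)
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    return ParcelTimeSeries(
        values=data["values"],
        sampling_rate=sidecar["sampling_rate"],
        state_labels=data["state_labels"],
        participant_id=sidecar["participant_id"],
        region_labels=sidecar["region_labels"],
    )


def write_segment_manifest(sessions: list[ParcelTimeSeries], path: str | Path) -> None:
    """TSV manifest of contiguous state segments across a cohort."""
    lines = ["participant\tstate\tstart_s\tend_s"]
    for ts in sessions:
        for state, a, b in ts.segments():
            lines.append(
                f"{ts.participant_id}\t{state}\t{a / ts.sampling_rate:g}\t"
                f"{b / ts.sampling_rate:g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
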