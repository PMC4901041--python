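"""Breakage simulator: synthetic fragment-length datasets.

Two break processes on a circle of contour length ``L``:

* **Uniform** — the number of double-strand breaks per plasmid is
  Poisson(``mu``) and break positions are i.i.d. uniform on the circle.
  This is the sparse-ionisation (low-LET) null model.
* **Clustered** — radiation tracks hit a plasmid as Poisson(``track_rate``);
  each track deposits a cluster of breaks (size drawn from a discrete law)
  uniformly inside a window of width ``cluster_span_nm`` centred on the
  track position, wrapped on the circle. This is the dense-ionisation
  (high-LET) model and produces an excess of very short fragments.

A :class:`DetectionModel` optionally emulates measurement: Gaussian
length noise (resampled to stay positive) and a minimum detectable
length below which fragments are dropped.

Randomness contract: one master seed; independent sub-streams are
derived for break counts, cluster sizes, track positions, intra-cluster
offsets and noise, each consumed sequentially in plasmid order. Growing
``n_plasmids`` therefore extends a noise-free dataset without
reshuffling the draws for earlier plasmids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .plasmid import PlasmidSpec, PUC19
from .records import SampleMeasurement

__all__ = [
    "UniformBreakModel",
    "ClusterSizeLaw",
    "ClusteredBreakModel",
    "DetectionModel",
    "DoseCalibration",
    "break_positions_uniform",
    "fragments_from_breaks",
    "simulate_sample",
    "dose_to_break_rate",
    "dose_from_fluence",
    "KEV_UM_FLUENCE_TO_GY",
]


# ---------------------------------------------------------------------------
# model parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformBreakModel:
    """Poisson-uniform breakage: ``mu`` mean DSBs per plasmid."""

    mu: float

    def __post_init__(self) -> None:
        if not self.mu >= 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")

    @property
    def mean_breaks(self) -> float:
        return self.mu


@dataclass(frozen=True)
class ClusterSizeLaw:
    """Discrete distribution of breaks per track, support on integers >= 1."""

    sizes: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes)
        probs = np.asarray(self.probs, dtype=float)
        if sizes.size == 0 or sizes.size != probs.size:
            raise ValueError("sizes and probs must be non-empty and equal length")
        if np.any(sizes < 1) or np.any(sizes != np.round(sizes)):
            raise ValueError("cluster sizes must be integers >= 1")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError("cluster-size probabilities must be >= 0 and sum to 1")

    @property
    def mean(self) -> float:
        return float(np.dot(self.sizes, self.probs))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(np.asarray(self.sizes), size=n, p=np.asarray(self.probs))

    @classmethod
    def fixed(cls, k: int) -> "ClusterSizeLaw":
        return cls(sizes=(int(k),), probs=(1.0,))

    @classmethod
    def geometric(cls, mean: float, max_size: int = 64) -> "ClusterSizeLaw":
        """Geometric law on {1, 2, ...} truncated at ``max_size``.

        ``mean`` is the mean of the *untruncated* geometric (p = 1/mean);
        truncation at a generous ``max_size`` shifts the realised mean
        negligibly for means well below ``max_size``.
        """
        if mean < 1:
            raise ValueError(f"geometric cluster mean must be >= 1, got {mean}")
        p = 1.0 / mean
        sizes = np.arange(1, max_size + 1)
        probs = p * (1 - p) ** (sizes - 1)
        probs /= probs.sum()
        return cls(sizes=tuple(int(s) for s in sizes), probs=tuple(probs))


@dataclass(frozen=True)
class ClusteredBreakModel:
    """Compound-Poisson track model for densely ionising radiation."""

    track_rate: float
    cluster_size_law: ClusterSizeLaw
    cluster_span_nm: float = 50.0

    def __post_init__(self) -> None:
        if not self.track_rate >= 0:
            raise ValueError(f"track_rate must be >= 0, got {self.track_rate}")
        if not self.cluster_span_nm > 0:
            raise ValueError(
                f"cluster_span_nm must be > 0, got {self.cluster_span_nm}"
            )

    @property
    def mean_breaks(self) -> float:
        return self.track_rate * self.cluster_size_law.mean


@dataclass(frozen=True)
class DetectionModel:
    """Measurement emulation: detection floor and Gaussian length noise."""

    min_detectable_nm: float = 0.0
    length_noise_sd_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.min_detectable_nm < 0 or self.length_noise_sd_nm < 0:
            raise ValueError("detection parameters must be non-negative")

    @property
    def is_off(self) -> bool:
        return self.min_detectable_nm == 0 and self.length_noise_sd_nm == 0

    @classmethod
    def off(cls) -> "DetectionModel":
        return cls(0.0, 0.0)


@dataclass(frozen=True)
class DoseCalibration:
    """Linear dose response: mean DSBs per plasmid = ``alpha`` x dose(Gy)."""

    alpha: float

    def __post_init__(self) -> None:
        if not self.alpha >= 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


BreakModel = Union[UniformBreakModel, ClusteredBreakModel]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def break_positions_uniform(
    k: int, L: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``k`` i.i.d. uniform break positions on the circle ``[0, L)``."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if not L > 0:
        raise ValueError(f"L must be > 0, got {L}")
    return rng.uniform(0.0, L, size=int(k))


def fragments_from_breaks(positions: Sequence[float], L: float) -> tuple[np.ndarray, bool]:
    """Fragment lengths produced by cutting the circle at ``positions``.

    Returns ``(lengths, is_circular)``. With k >= 1 cuts the circle falls
    into exactly k linear fragments (the spacings between sorted cut
    points, including the wrap-around gap) whose lengths sum to ``L``;
    with zero cuts the plasmid stays one circular molecule of length ``L``.

    A single cut yields one full-length linear fragment of length ``L``
    exactly: the wrap-around length is computed as ``L`` minus the sum of
    the other spacings, which also pins the total to ``L`` in floating
    point.
    """
    if not L > 0:
        raise ValueError(f"L must be > 0, got {L}")
    pos = np.sort(np.asarray(positions, dtype=float))
    if pos.size == 0:
        return np.array([L]), True
    if np.any(pos < 0) or np.any(pos >= L):
        raise ValueError("all break positions must lie in [0, L)")
    inner = np.diff(pos)
    lengths = np.append(inner, L - inner.sum())
    return lengths, False


def dose_to_break_rate(dose_Gy: float, cal: DoseCalibration) -> float:
    """Mean DSBs per plasmid at ``dose_Gy`` under a linear response."""
    if dose_Gy < 0:
        raise ValueError(f"dose must be >= 0, got {dose_Gy}")
    return cal.alpha * dose_Gy


#: keV/µm x particles/cm² -> Gy (unit density).
#: 1 keV = 1.602176634e-16 J; LET[J/m] = LET[keV/µm] * 1.602176634e-10;
#: fluence[m^-2] = fluence[cm^-2] * 1e4; rho[kg/m³] = rho[g/cm³] * 1e3.
#: Dose = fluence * LET / rho  =>  1.602176634e-10 * 1e4 / 1e3 = 1.602176634e-9.
KEV_UM_FLUENCE_TO_GY = 1.602176634e-9


def dose_from_fluence(
    fluence_rate: float, let: float, time_s: float, density: float = 1.0
) -> float:
    """Dose (Gy) from fluence rate (cm⁻²s⁻¹), LET (keV/µm) and beam-on time.

    ``dose = fluence_rate * time_s * let * 1.602e-9 / density`` with
    density in g/cm³ (water = 1). See :data:`KEV_UM_FLUENCE_TO_GY` for the
    unit derivation.
    """
    if fluence_rate < 0 or let < 0 or time_s < 0:
        raise ValueError("fluence_rate, let and time_s must all be >= 0")
    if not density > 0:
        raise ValueError(f"density must be > 0, got {density}")
    return fluence_rate * time_s * let * KEV_UM_FLUENCE_TO_GY / density


# ---------------------------------------------------------------------------
# bulk simulation
# ---------------------------------------------------------------------------

def _spacings_bulk(
    pos: np.ndarray, pid: np.ndarray, L: float, dtype=np.float64
) -> tuple[np.ndarray, np.ndarray]:
    """Circular spacings for many plasmids at once.

    ``pos``/``pid`` are parallel arrays of break positions and plasmid
    indices (pid need not be sorted). Returns fragment lengths and the
    plasmid index of each fragment. The last fragment of each plasmid is
    ``L - sum(other fragments)`` so per-plasmid totals equal ``L`` up to
    one rounding of the accumulated sum.
    """
    if pos.size == 0:
        return np.empty(0, dtype=dtype), np.empty(0, dtype=pid.dtype)
    order = np.lexsort((pos, pid))
    p = pos[order]
    g = pid[order]
    new_group = np.empty(p.size, dtype=bool)
    new_group[0] = True
    np.not_equal(g[1:], g[:-1], out=new_group[1:])
    is_last = np.empty(p.size, dtype=bool)
    is_last[:-1] = new_group[1:]
    is_last[-1] = True
    lengths = np.empty(p.size, dtype=dtype)
    lengths[:-1] = p[1:] - p[:-1]
    lengths[-1] = 0.0
    inner = np.where(is_last, 0.0, lengths)
    starts = np.flatnonzero(new_group)
    inner_sums = np.add.reduceat(inner, starts)
    lengths[is_last] = L - inner_sums
    return lengths, g


def _breaks_uniform(
    model: UniformBreakModel, L: float, n: int, streams: list[np.random.Generator]
) -> tuple[np.ndarray, np.ndarray]:
    rng_counts, _rng_cluster, rng_pos, _rng_offset = streams
    k = rng_counts.poisson(model.mu, size=n)
    pid = np.repeat(np.arange(n, dtype=np.int64), k)
    pos = rng_pos.uniform(0.0, L, size=int(k.sum()))
    return pos, pid


def _breaks_clustered(
    model: ClusteredBreakModel, L: float, n: int, streams: list[np.random.Generator]
) -> tuple[np.ndarray, np.ndarray]:
    if model.cluster_span_nm > L:
        raise ValueError(
            f"cluster_span_nm ({model.cluster_span_nm}) must not exceed L ({L})"
        )
    rng_counts, rng_cluster, rng_pos, rng_offset = streams
    tracks = rng_counts.poisson(model.track_rate, size=n)
    n_tracks = int(tracks.sum())
    track_pid = np.repeat(np.arange(n, dtype=np.int64), tracks)
    sizes = model.cluster_size_law.sample(rng_cluster, n_tracks)
    centres = rng_pos.uniform(0.0, L, size=n_tracks)
    break_track = np.repeat(np.arange(n_tracks, dtype=np.int64), sizes)
    half = 0.5 * model.cluster_span_nm
    offsets = rng_offset.uniform(-half, half, size=break_track.size)
    pos = np.mod(centres[break_track] + offsets, L)
    return pos, track_pid[break_track]


def simulate_sample(
    model: BreakModel,
    plasmid: PlasmidSpec = PUC19,
    n_plasmids: int = 1000,
    detection: DetectionModel | None = None,
    seed: int = 0,
    sample_id: str | None = None,
    radiation: str | None = None,
    dose_Gy: float = 0.0,
    let_keV_um: float = 0.0,
) -> SampleMeasurement:
    """Simulate one irradiated aliquot of ``n_plasmids`` plasmids.

    Plasmids with zero breaks appear as circular records of full contour
    length; broken plasmids contribute one linear fragment per break.
    With detection off, every plasmid's fragment lengths sum to the
    contour length, so downstream molecule counting is exact.
    """
    if n_plasmids <= 0:
        raise ValueError(f"n_plasmids must be > 0, got {n_plasmids}")
    if detection is None:
        detection = DetectionModel.off()
    L = plasmid.length_nm

    root = np.random.SeedSequence(seed)
    children = root.spawn(5)
    streams = [np.random.default_rng(c) for c in children[:4]]
    rng_noise = np.random.default_rng(children[4])

    if isinstance(model, UniformBreakModel):
        pos, pid = _breaks_uniform(model, L, n_plasmids, streams)
        model_name = "uniform"
        model_params = {"mu": model.mu}
    elif isinstance(model, ClusteredBreakModel):
        pos, pid = _breaks_clustered(model, L, n_plasmids, streams)
        model_name = "clustered"
        model_params = {
            "track_rate": model.track_rate,
            "cluster_mean": model.cluster_size_law.mean,
            "cluster_span_nm": model.cluster_span_nm,
        }
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported break model: {type(model).__name__}")

    frag_len, frag_pid = _spacings_bulk(pos, pid, L)

    broken = np.zeros(n_plasmids, dtype=bool)
    broken[frag_pid] = True
    n_circular = int(n_plasmids - broken.sum())

    lengths = np.concatenate([frag_len, np.full(n_circular, L)])
    is_linear = np.zeros(lengths.size, dtype=bool)
    is_linear[: frag_len.size] = True

    if detection.length_noise_sd_nm > 0:
        noise = rng_noise.normal(0.0, detection.length_noise_sd_nm, size=lengths.size)
        noisy = lengths + noise
        bad = noisy <= 0
        while bad.any():  # resample rather than truncate: keeps lengths positive
            noisy[bad] = lengths[bad] + rng_noise.normal(
                0.0, detection.length_noise_sd_nm, size=int(bad.sum())
            )
            bad = noisy <= 0
        lengths = noisy
    if detection.min_detectable_nm > 0:
        keep = (lengths >= detection.min_detectable_nm) | ~is_linear
        lengths = lengths[keep]
        is_linear = is_linear[keep]

    if sample_id is None:
        sample_id = f"{model_name}-seed{seed}"
    sample = SampleMeasurement.from_arrays(
        sample_id,
        lengths,
        is_linear,
        radiation=radiation if radiation is not None else f"{model_name}-sim",
        dose_Gy=dose_Gy,
        let_keV_um=let_keV_um,
        plasmid=plasmid,
        extras={
            "seed": seed,
            "model": model_name,
            "model_params": model_params,
            "n_plasmids": n_plasmids,
            "detection": {
                "min_detectable_nm": detection.min_detectable_nm,
                "length_noise_sd_nm": detection.length_noise_sd_nm,
            },
        },
    )
    return sample
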