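"""Fragment-length statistics: size distributions, DSB counts, RBE.

The accounting rests on one identity for circular targets: a plasmid cut
by ``k`` double-strand breaks yields exactly ``k`` linear fragments whose
lengths sum to the intact contour length ``L``. Hence

* number of molecules  = (sum of all measured lengths) / L,
* DSBs per molecule    = (number of linear fragments) / molecules,
* DSBs per broken molecule uses only linear fragments in the denominator.

Size distributions use fixed-width bins over (0, L] with a left-open /
right-closed convention, so a full-length linear fragment falls in the
last bin. The spatial DSB profile divides per-bin fragment counts by the
molecule count; it sums to DSB/DNA by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .plasmid import PlasmidSpec
from .records import RecordsLike, coerce_length_topology

__all__ = [
    "SizeDistribution",
    "DSBStats",
    "SpatialDSBProfile",
    "RBEResult",
    "bin_fragments",
    "count_molecules",
    "dsb_per_dna",
    "dsb_per_broken_dna",
    "spatial_dsb_profile",
    "compute_rbe",
    "bootstrap_std",
    "bp_nm_convert",
    "analyze_sample",
]

logger = logging.getLogger(__name__)

#: lengths exceeding L by at most this relative amount are clamped to L
CLAMP_TOLERANCE = 0.02

DEFAULT_BIN_WIDTH = 50.0


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class SizeDistribution:
    """Binned fragment-length histogram over (0, L]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_fragments: int
    rel_freq: np.ndarray
    n_invalid: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class DSBStats:
    """Molecule counts and break rates for one sample."""

    n_fragments: int
    n_molecules: float
    n_broken_molecules: float
    dsb_per_dna: float
    dsb_per_broken_dna: float
    std: float = float("nan")


@dataclass
class SpatialDSBProfile:
    """DSBs per molecule attributed to each fragment-length interval."""

    bin_edges: np.ndarray
    dsb_per_dna_per_bin: np.ndarray

    @property
    def total_dsb_per_dna(self) -> float:
        return float(self.dsb_per_dna_per_bin.sum())


@dataclass
class RBEResult:
    """Ratio of DSB yields relative to a reference radiation."""

    rbe: float
    std: float
    test_label: str = "test"
    reference_label: str = "reference"

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """Report-style rounding; internal values keep full precision."""
        return round(self.rbe, ndigits), round(self.std, ndigits)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _bin_edges(L: float, w: float) -> np.ndarray:
    n_bins = L / w
    if not math.isclose(n_bins, round(n_bins), rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"bin width {w} does not divide contour length {L}")
    return np.linspace(0.0, L, int(round(n_bins)) + 1)


def _validate_lengths(lengths: np.ndarray, L: float) -> tuple[np.ndarray, int]:
    """Clamp small overshoots of L, drop gross ones. Returns (clean, n_dropped)."""
    over = lengths > L
    gross = lengths > L * (1 + CLAMP_TOLERANCE)
    n_gross = int(gross.sum())
    if n_gross:
        logger.warning(
            "excluding %d record(s) with length > %.4g nm (beyond %.0f%% tolerance)",
            n_gross, L * (1 + CLAMP_TOLERANCE), CLAMP_TOLERANCE * 100,
        )
    n_clamp = int(over.sum()) - n_gross
    if n_clamp:
        logger.warning("clamping %d record(s) with length slightly above L to L", n_clamp)
    clean = np.minimum(lengths[~gross], L)
    return clean, n_gross


def bin_fragments(
    records: RecordsLike, L: float, w: float = DEFAULT_BIN_WIDTH
) -> SizeDistribution:
    """Histogram linear fragments into bins (0, w], (w, 2w], ..., (L-w, L].

    Circular records are ignored; the distribution describes fragments.
    Lengths at most ``CLAMP_TOLERANCE`` above ``L`` are clamped to ``L``
    (measurement noise); anything larger is excluded and counted in
    ``n_invalid``.
    """
    lengths, is_linear = coerce_length_topology(records)
    lengths = lengths[is_linear]
    edges = _bin_edges(L, w)
    lengths, n_invalid = _validate_lengths(lengths, L)
    # left-open/right-closed: x = 50 falls in (0, 50], x = L in the last bin
    idx = np.searchsorted(edges, lengths, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)  # x exactly 0 cannot occur (lengths > 0)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(np.int64)
    n = int(counts.sum())
    rel = counts / n if n else np.zeros_like(counts, dtype=float)
    return SizeDistribution(
        bin_edges=edges, counts=counts, n_fragments=n, rel_freq=rel, n_invalid=n_invalid
    )


def count_molecules(records: RecordsLike, L: float) -> float:
    """Number of DNA molecules: total measured length / intact length.

    Circular (unbroken) records count through their length like any
    other; on noise-free simulated data the result is the exact number
    of plasmids.
    """
    if not L > 0:
        raise ValueError(f"L must be > 0, got {L}")
    lengths, _ = coerce_length_topology(records)
    if lengths.size == 0:
        return 0.0
    return float(lengths.sum() / L)


def dsb_per_dna(records: RecordsLike, L: float) -> DSBStats:
    """DSBs per molecule over *all* molecules, intact circles included.

    Each linear fragment marks one break; circular records enter the
    molecule denominator only. ``std`` is left NaN — fill it with
    :func:`bootstrap_std` or use :func:`analyze_sample`.
    """
    lengths, is_linear = coerce_length_topology(records)
    n_molecules = count_molecules(records, L)
    if n_molecules <= 0:
        raise ValueError("cannot compute DSB/DNA: zero molecules in input")
    n_fragments = int(is_linear.sum())
    linear_lengths = lengths[is_linear]
    n_broken = float(linear_lengths.sum() / L)
    per_dna = n_fragments / n_molecules
    per_broken = n_fragments / n_broken if n_broken > 0 else float("nan")
    return DSBStats(
        n_fragments=n_fragments,
        n_molecules=n_molecules,
        n_broken_molecules=n_broken,
        dsb_per_dna=per_dna,
        dsb_per_broken_dna=per_broken,
    )


def dsb_per_broken_dna(records: RecordsLike, L: float) -> float:
    """DSBs per molecule over broken (fragmented) molecules only."""
    lengths, is_linear = coerce_length_topology(records)
    linear_lengths = lengths[is_linear]
    if linear_lengths.size == 0:
        raise ValueError("no linear fragments: DSB per broken DNA is undefined")
    return float(linear_lengths.size / (linear_lengths.sum() / L))


def spatial_dsb_profile(
    records: RecordsLike, L: float, w: float = DEFAULT_BIN_WIDTH
) -> SpatialDSBProfile:
    """Per-bin fragment count divided by the total molecule count.

    The first bin quantifies breaks falling within ``w`` of each other
    on a molecule; the profile sums exactly to DSB/DNA because both use
    the same fragment set and molecule denominator.
    """
    dist = bin_fragments(records, L, w)
    n_molecules = count_molecules(records, L)
    if n_molecules <= 0:
        raise ValueError("cannot compute spatial profile: zero molecules in input")
    return SpatialDSBProfile(
        bin_edges=dist.bin_edges,
        dsb_per_dna_per_bin=dist.counts / n_molecules,
    )


def compute_rbe(
    dsb_test: float,
    std_test: float,
    dsb_ref: float,
    std_ref: float,
    test_label: str = "test",
    reference_label: str = "reference",
) -> RBEResult:
    """Relative biological effectiveness of a radiation vs. a reference.

    ``rbe = dsb_test / dsb_ref``; the uncertainty of the ratio of two
    independent estimates propagates in quadrature:
    ``std = rbe * sqrt((std_test/dsb_test)^2 + (std_ref/dsb_ref)^2)``.
    """
    if not dsb_ref > 0:
        raise ValueError(f"reference DSB/DNA must be > 0, got {dsb_ref}")
    if std_test < 0 or std_ref < 0:
        raise ValueError("standard deviations must be >= 0")
    rbe = dsb_test / dsb_ref
    if dsb_test > 0:
        std = rbe * math.sqrt((std_test / dsb_test) ** 2 + (std_ref / dsb_ref) ** 2)
    else:
        std = std_test / dsb_ref
    return RBEResult(rbe=rbe, std=std, test_label=test_label, reference_label=reference_label)


def bootstrap_std(
    records: RecordsLike,
    L: float,
    B: int = 1000,
    seed: int = 0,
    _max_draws_per_chunk: int = 20_000_000,
) -> float:
    """Bootstrap standard deviation of DSB/DNA.

    Resamples the record list with replacement ``B`` times and returns
    the sample standard deviation of the DSB/DNA statistic across
    resamples. Deterministic for a given seed.
    """
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    lengths, is_linear = coerce_length_topology(records)
    n = lengths.size
    if n < 2:
        raise ValueError("bootstrap requires at least 2 records")
    rng = np.random.default_rng(seed)
    lin = is_linear.astype(np.float64)
    values = np.empty(B)
    chunk = max(1, _max_draws_per_chunk // n)
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        frag = lin[idx].sum(axis=1)
        mol = lengths[idx].sum(axis=1) / L
        values[done : done + b] = frag / mol
        done += b
    return float(values.std(ddof=1))


def bp_nm_convert(value: float, direction: str, plasmid: PlasmidSpec) -> float:
    """Convert between base pairs and nanometres using the plasmid's rise.

    ``direction`` is ``"bp_to_nm"`` or ``"nm_to_bp"``. The scale factor is
    ``length_nm / length_bp`` of the plasmid (~0.3165 nm/bp for the
    bundled 2686 bp / 850 nm circle).
    """
    if direction == "bp_to_nm":
        return plasmid.bp_to_nm(value)
    if direction == "nm_to_bp":
        return plasmid.nm_to_bp(value)
    raise ValueError(f"direction must be 'bp_to_nm' or 'nm_to_bp', got {direction!r}")


def analyze_sample(
    records: RecordsLike,
    L: float,
    w: float = DEFAULT_BIN_WIDTH,
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> tuple[DSBStats, SizeDistribution, SpatialDSBProfile]:
    """Full single-sample pipeline: stats (with bootstrap std), histogram, profile."""
    stats = dsb_per_dna(records, L)
    stats.std = bootstrap_std(records, L, B=bootstrap_B, seed=seed)
    dist = bin_fragments(records, L, w)
    profile = spatial_dsb_profile(records, L, w)
    logger.info(
        "analyzed sample: %d fragments, %.2f molecules, DSB/DNA=%.3f (std %.3f)",
        stats.n_fragments, stats.n_molecules, stats.dsb_per_dna, stats.std,
    )
    return stats, dist, profile
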