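"""Fragment records and sample containers.

A measured (or simulated) dataset is a table of individual fragment
lengths. Internally a :class:`SampleMeasurement` stores the table as a
pandas ``DataFrame`` with columns ``sample_id``, ``fragment_id``,
``length_nm`` and ``topology`` — cheap for millions of simulated
fragments — while :class:`FragmentRecord` gives a typed row view.

Topology matters: a plasmid with zero breaks stays a circle of full
contour length; one break linearises it at full length. The two are
indistinguishable by length alone, so the flag is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd

from .plasmid import PlasmidSpec, PUC19

__all__ = [
    "TOPOLOGIES",
    "FragmentRecord",
    "SampleMeasurement",
    "coerce_length_topology",
]

TOPOLOGIES = ("linear", "circular")

_COLUMNS = ["sample_id", "fragment_id", "length_nm", "topology"]


@dataclass(frozen=True)
class FragmentRecord:
    """One measured DNA piece."""

    sample_id: str
    length_nm: float
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.length_nm > 0:
            raise ValueError(f"length_nm must be > 0, got {self.length_nm}")
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"topology must be one of {TOPOLOGIES}, got {self.topology!r}"
            )


@dataclass
class SampleMeasurement:
    """A collection of fragment records plus radiation metadata.

    Attributes
    ----------
    records : pandas.DataFrame
        Columns ``sample_id``, ``fragment_id``, ``length_nm``, ``topology``.
    radiation : str
        Radiation label (e.g. ``"Co-60"``, ``"uniform-sim"``).
    dose_Gy : float
        Absorbed dose in gray.
    let_keV_um : float
        Linear energy transfer in keV/µm.
    plasmid : PlasmidSpec
        The target plasmid.
    extras : dict
        Free-form provenance (model parameters, seed, ...).
    """

    records: pd.DataFrame
    radiation: str = "unknown"
    dose_Gy: float = 0.0
    let_keV_um: float = 0.0
    plasmid: PlasmidSpec = PUC19
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records frame missing columns: {missing}")
        topo = self.records["topology"]
        bad = ~topo.isin(TOPOLOGIES)
        if bad.any():
            raise ValueError(
                f"invalid topology values: {sorted(topo[bad].unique())}"
            )
        if (self.records["length_nm"] <= 0).any():
            raise ValueError("all length_nm values must be > 0")
        ids = self.records["sample_id"].unique()
        if len(ids) > 1:
            raise ValueError(f"records must share one sample_id, got {list(ids)}")

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        lengths_nm: np.ndarray,
        is_linear: np.ndarray,
        **metadata,
    ) -> "SampleMeasurement":
        """Build a sample from parallel length / linear-flag arrays."""
        lengths_nm = np.asarray(lengths_nm, dtype=float)
        is_linear = np.asarray(is_linear, dtype=bool)
        topo = pd.Categorical.from_codes(
            (~is_linear).astype(np.int8), categories=list(TOPOLOGIES)
        )
        frame = pd.DataFrame(
            {
                "sample_id": pd.Categorical([sample_id] * len(lengths_nm)),
                "fragment_id": np.arange(len(lengths_nm), dtype=np.int64),
                "length_nm": lengths_nm,
                "topology": topo,
            }
        )
        return cls(records=frame, **metadata)

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord], **metadata) -> "SampleMeasurement":
        recs = list(records)
        if not recs:
            raise ValueError("cannot build a SampleMeasurement from zero records")
        sample_id = recs[0].sample_id
        return cls.from_arrays(
            sample_id,
            np.array([r.length_nm for r in recs]),
            np.array([r.topology == "linear" for r in recs]),
            **metadata,
        )

    @property
    def sample_id(self) -> str:
        return str(self.records["sample_id"].iloc[0]) if len(self.records) else ""

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def lengths_nm(self) -> np.ndarray:
        return self.records["length_nm"].to_numpy()

    @property
    def is_linear(self) -> np.ndarray:
        return (self.records["topology"].to_numpy() == "linear")

    def iter_records(self) -> Iterator[FragmentRecord]:
        sid = self.sample_id
        for length, topo in zip(self.records["length_nm"], self.records["topology"]):
            yield FragmentRecord(sid, float(length), str(topo))


RecordsLike = Union[
    SampleMeasurement, pd.DataFrame, Sequence[FragmentRecord], Sequence[float], np.ndarray
]


def coerce_length_topology(records: RecordsLike) -> tuple[np.ndarray, np.ndarray]:
    """Normalise any accepted record container to ``(lengths, is_linear)``.

    Bare numeric sequences are interpreted as linear fragment lengths,
    which keeps hand-written test inputs short.
    """
    if isinstance(records, SampleMeasurement):
        return records.lengths_nm, records.is_linear
    if isinstance(records, pd.DataFrame):
        lengths = records["length_nm"].to_numpy(dtype=float)
        is_linear = records["topology"].to_numpy() == "linear"
        return lengths, is_linear
    records = list(records)
    if records and isinstance(records[0], FragmentRecord):
        lengths = np.array([r.length_nm for r in records], dtype=float)
        is_linear = np.array([r.topology == "linear" for r in records])
        return lengths, is_linear
    lengths = np.asarray(records, dtype=float)
    return lengths, np.ones(lengths.shape, dtype=bool)
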