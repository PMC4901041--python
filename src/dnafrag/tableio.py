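"""Readers/writers for fragment tables and result files, plus run config.

Canonical table dialect: tab-separated, UTF-8, '.' decimal, header
``sample_id  fragment_id  length_nm  topology``. Comma-separated input is
auto-detected on read but never written. Results are JSON with a
provenance block (package version, seed, config hash) so every output is
traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fragstats import DSBStats, SizeDistribution, SpatialDSBProfile
from .plasmid import PlasmidSpec, PUC19
from .records import TOPOLOGIES, SampleMeasurement

__all__ = [
    "FragmentTableError",
    "read_fragment_table",
    "write_fragment_table",
    "read_metadata",
    "write_metadata",
    "RunConfig",
    "config_hash",
    "provenance_block",
    "write_stats_json",
    "write_distribution_csv",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["sample_id", "fragment_id", "length_nm", "topology"]


class FragmentTableError(ValueError):
    """Malformed fragment table; message carries 1-based line numbers."""


def _detect_separator(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_fragment_table(path, metadata: dict | None = None) -> SampleMeasurement:
    """Read a fragment table (TSV, or CSV by sniffing the header line).

    Rows failing validation (non-positive or non-numeric length, unknown
    topology) are rejected with their file line numbers. ``metadata``
    may carry radiation/dose/LET/plasmid fields, e.g. from a JSON sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FragmentTableError(f"{path}: empty file")
    sep = _detect_separator(path)
    frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "topology": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FragmentTableError(f"{path}: missing required column(s) {missing}")
    if len(frame) == 0:
        raise FragmentTableError(f"{path}: no data rows")

    # header is line 1; first data row is line 2
    lines = frame.index.to_numpy() + 2
    lengths = pd.to_numeric(frame["length_nm"], errors="coerce")
    bad_length = ~(lengths > 0)
    bad_topo = ~frame["topology"].isin(TOPOLOGIES)
    bad = bad_length | bad_topo
    if bad.to_numpy().any():
        problems = []
        for line, is_len, is_topo in zip(lines[bad], bad_length[bad], bad_topo[bad]):
            what = []
            if is_len:
                what.append("length_nm must be a number > 0")
            if is_topo:
                what.append(f"topology must be one of {TOPOLOGIES}")
            problems.append(f"line {line}: " + "; ".join(what))
        raise FragmentTableError(f"{path}: {len(problems)} malformed row(s)\n" + "\n".join(problems))

    frame = frame.assign(length_nm=lengths.astype(float))
    meta = dict(metadata or {})
    plasmid = meta.pop("plasmid", None)
    if isinstance(plasmid, dict):
        plasmid = PlasmidSpec(**plasmid)
    sample = SampleMeasurement(
        records=frame[REQUIRED_COLUMNS],
        radiation=meta.pop("radiation", "unknown"),
        dose_Gy=float(meta.pop("dose_Gy", 0.0)),
        let_keV_um=float(meta.pop("let_keV_um", 0.0)),
        plasmid=plasmid or PUC19,
        extras=meta,
    )
    logger.info("read %d records from %s", sample.n_records, path)
    return sample


def write_fragment_table(sample: SampleMeasurement, path) -> None:
    """Write the canonical TSV fragment table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sample.records.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d records to %s", sample.n_records, path)


def write_metadata(sample: SampleMeasurement, path, seed: int | None = None) -> None:
    """JSON sidecar with radiation metadata, plasmid and model provenance."""
    payload = {
        "sample_id": sample.sample_id,
        "radiation": sample.radiation,
        "dose_Gy": sample.dose_Gy,
        "let_keV_um": sample.let_keV_um,
        "plasmid": {"length_bp": sample.plasmid.length_bp, "length_nm": sample.plasmid.length_nm},
        **sample.extras,
    }
    if seed is not None:
        payload["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# run configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable run parameters; hashed into every output file."""

    seed: int = 0
    bin_width_nm: float = 50.0
    bootstrap_B: int = 1000
    plasmid_length_bp: int = PUC19.length_bp
    plasmid_length_nm: float = PUC19.length_nm
    model: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    @property
    def plasmid(self) -> PlasmidSpec:
        return PlasmidSpec(self.plasmid_length_bp, self.plasmid_length_nm)


def config_hash(config: RunConfig | dict) -> str:
    """SHA-256 of the canonical (sorted-key) JSON encoding of the config."""
    d = config.to_dict() if isinstance(config, RunConfig) else config
    blob = json.dumps(d, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def provenance_block(config: RunConfig | dict, seed: int | None = None) -> dict:
    block = {"package": "dnafrag", "version": __version__, "config_sha256": config_hash(config)}
    if seed is not None:
        block["seed"] = seed
    return block


def write_stats_json(
    stats: DSBStats, path, config: RunConfig | dict, seed: int | None = None,
    sample_id: str = "", extra: dict | None = None,
) -> None:
    payload = {
        "sample_id": sample_id,
        "n_fragments": stats.n_fragments,
        "n_molecules": stats.n_molecules,
        "n_broken_molecules": stats.n_broken_molecules,
        "dsb_per_dna": stats.dsb_per_dna,
        "dsb_per_broken_dna": stats.dsb_per_broken_dna,
        "std": stats.std,
        "provenance": provenance_block(config, seed),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_distribution_csv(
    dist: SizeDistribution, profile: SpatialDSBProfile, path
) -> None:
    """Distribution CSV: bin_start_nm, bin_end_nm, count, rel_freq, dsb_per_dna_per_bin."""
    frame = pd.DataFrame(
        {
            "bin_start_nm": dist.bin_edges[:-1],
            "bin_end_nm": dist.bin_edges[1:],
            "count": dist.counts,
            "rel_freq": dist.rel_freq,
            "dsb_per_dna_per_bin": profile.dsb_per_dna_per_bin,
        }
    )
    frame.to_csv(path, index=False)
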