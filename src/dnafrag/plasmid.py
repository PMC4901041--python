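"""Plasmid geometry: base-pair count and measured contour length.

The analysis treats a plasmid as a circle of contour length ``length_nm``.
All fragment lengths are expressed in nanometres; conversion to base pairs
uses the plasmid's own nm-per-bp factor rather than the canonical B-DNA
rise, because deposition and tip convolution change the apparent rise.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PlasmidSpec", "PUC19"]


@dataclass(frozen=True)
class PlasmidSpec:
    """A circular plasmid target.

    Parameters
    ----------
    length_bp : int
        Number of base pairs (> 0).
    length_nm : float
        Measured contour length of the intact circle in nanometres (> 0).
    """

    length_bp: int
    length_nm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be > 0, got {self.length_bp}")
        if not self.length_nm > 0:
            raise ValueError(f"length_nm must be > 0, got {self.length_nm}")

    @property
    def nm_per_bp(self) -> float:
        """Apparent helical rise (nm per base pair) for this plasmid."""
        return self.length_nm / self.length_bp

    def bp_to_nm(self, bp: float) -> float:
        return bp * self.nm_per_bp

    def nm_to_bp(self, nm: float) -> float:
        return nm / self.nm_per_bp


#: The standard cloning plasmid used throughout: 2686 bp, 850 nm contour.
PUC19 = PlasmidSpec(length_bp=2686, length_nm=850.0)
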