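"""Recombination / conversion event records shared by the simulator and caller."""

from __future__ import annotations

from dataclasses import dataclass, field

CO = "CO"
NCO = "NCO"
PREMEIOTIC_LOH = "PREMEIOTIC_LOH"
COMPLEX = "COMPLEX"

KINDS = (CO, NCO, PREMEIOTIC_LOH, COMPLEX)


@dataclass
class RecombinationEvent:
    """A crossover, gene-conversion or premeiotic-LOH call (or its truth).

    ``inner`` is the tightest interval supported by the data: for a CO it
    is the flanking-marker interval containing the breakpoint (or the
    exact breakpoint, width 0, for simulated truth); for an NCO/LOH it
    spans the first to last supporting marker.  ``max_tract`` extends to
    the closest flanking markers with 2:2 segregation (chromosome end if
    none), half-open.  ``spores`` names the involved spores: exactly two
    (reciprocal) for a CO, one for an NCO, none for 4:0 patterns where
    the converted pair cannot be identified.
    """

    kind: str
    chromosome: str
    inner_start: float
    inner_end: float
    max_start: float | None = None
    max_end: float | None = None
    spores: tuple[int, ...] = ()
    n_markers: int = 0
    note: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.inner_end < self.inner_start:
            raise ValueError("inner interval reversed")
        if self.max_start is not None and self.max_end is not None:
            if not (self.max_start <= self.inner_start and self.inner_end <= self.max_end):
                raise ValueError("inner interval not contained in max tract")

    @property
    def max_tract_length(self) -> float | None:
        if self.max_start is None or self.max_end is None:
            return None
        return self.max_end - self.max_start
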