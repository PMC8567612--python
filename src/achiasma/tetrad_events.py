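"""Parental-origin assignment, segregation patterns and CO/NCO/LOH calling.

At every discriminant marker each of a tetrad's four spores is assigned
the origin of parent 1 or parent 2 (or missing).  Markers then classify
as 2:2, 3:1/1:3 or 4:0/0:4, and runs of non-2:2 patterns (or phase
switches between 2:2 patterns) become events:

* CO — exactly two spores switch origin reciprocally between flanking
  2:2 regions;
* NCO — a single spore converted over a 3:1 run flanked by 2:2;
* premeiotic LOH — a 4:0/0:4 run (both chromatids of one homolog carry
  the other parent's alleles, i.e. the event preceded meiosis);
* complex — anything contradictory (three-spore switches, mixed runs);
  flagged, never dropped.

Maximum tract bounds extend to the closest flanking markers with 2:2
segregation, or to the chromosome end when none exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .events import CO, COMPLEX, NCO, PREMEIOTIC_LOH, RecombinationEvent
from .markers import MarkerTable, SiteCall

logger = logging.getLogger(__name__)

P1, P2, MISSING = 0, 1, -1
ORIGIN_CODES = {P1: "P1", P2: "P2", MISSING: "NA"}
CODE_ORIGINS = {v: k for k, v in ORIGIN_CODES.items()}


@dataclass
class OriginMatrix:
    """Markers x 4 spores parental-origin matrix, per chromosome.

    ``origins[chrom]`` has shape ``(n, 4)`` with values 0 (P1), 1 (P2)
    or -1 (missing); ``positions[chrom]`` is 0-based and strictly
    increasing.  ``chrom_lengths`` (optional) lets max tracts extend to
    chromosome ends.
    """

    positions: dict[str, np.ndarray]
    origins: dict[str, np.ndarray]
    spore_names: tuple[str, str, str, str] = ("spore1", "spore2", "spore3", "spore4")
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.spore_names) != 4:
            raise ValueError("exactly 4 spores required")
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = pos
            org = np.asarray(self.origins[chrom], dtype=np.int8)
            self.origins[chrom] = org
            if org.shape != (pos.size, 4):
                raise ValueError(f"origin matrix shape mismatch on {chrom!r}")
            if pos.size > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not sorted on {chrom!r}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    @property
    def n_markers(self) -> int:
        return sum(int(p.size) for p in self.positions.values())

    @classmethod
    def from_truth(cls, truth, missing_rate: float = 0.0, seed=None) -> "OriginMatrix":
        """Origin matrix straight from simulated TetradTruth (optionally degraded)."""
        from .simulate import as_rng

        rng = as_rng(seed)
        positions, origins = {}, {}
        for chrom, mat in truth.spore_origins.items():
            org = mat.T.astype(np.int8).copy()
            if missing_rate > 0:
                mask = rng.random(org.shape) < missing_rate
                org[mask] = MISSING
            positions[chrom] = truth.pair.positions[chrom].copy()
            origins[chrom] = org
        return cls(positions=positions, origins=origins,
                   chrom_lengths=truth.pair.genome.chrom_lengths)


def assign_origin(
    markers: MarkerTable,
    spore_calls: Iterable[SiteCall],
    min_depth: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> OriginMatrix:
    """Assign each spore's parental origin at every marker.

    A cell is P1/P2 when the spore's allele equals the respective
    parental allele, and missing on no-call, sub-threshold depth or a
    third allele (warned).
    """
    lookup: dict[tuple[str, int], SiteCall] = {}
    spore_names: tuple[str, ...] | None = None
    for site in spore_calls:
        if spore_names is None:
            spore_names = tuple(site.samples)
            if len(spore_names) != 4:
                raise ValueError(f"expected 4 spore samples, got {len(spore_names)}")
        lookup[(site.chromosome, site.position - 1)] = site
    if spore_names is None:
        spore_names = ("spore1", "spore2", "spore3", "spore4")

    positions, origins = {}, {}
    n_foreign = 0
    for chrom in markers.chromosomes:
        pos = markers.positions(chrom)
        alle = markers.alleles(chrom)
        org = np.full((pos.size, 4), MISSING, dtype=np.int8)
        for i, p in enumerate(pos):
            site = lookup.get((chrom, int(p)))
            if site is None:
                continue
            a1, a2 = alle[i]
            for j, name in enumerate(spore_names):
                call = site.samples.get(name)
                if call is None or call.depth < min_depth:
                    continue
                if call.genotype in ("0", "1") and site.alts:
                    allele = site.ref if call.genotype == "0" else site.alts[0]
                elif call.depth > 0:
                    allele = site.ref if call.ref_depth >= call.alt_depth else (
                        site.alts[0] if site.alts else site.ref)
                else:
                    continue
                if allele == a1:
                    org[i, j] = P1
                elif allele == a2:
                    org[i, j] = P2
                else:
                    n_foreign += 1
        positions[chrom] = pos
        origins[chrom] = org
    if n_foreign:
        logger.warning("%d spore calls matched neither parental allele", n_foreign)
    return OriginMatrix(positions=positions, origins=origins,
                        spore_names=spore_names, chrom_lengths=chrom_lengths)


@dataclass(frozen=True)
class SegPattern:
    """Per-marker segregation summary: origin counts and pattern label."""

    chromosome: str
    position: int
    n_p1: int
    n_p2: int
    n_missing: int
    label: str

    def __post_init__(self) -> None:
        if self.n_p1 + self.n_p2 + self.n_missing != 4:
            raise ValueError("counts must total 4 spores")


def _label(n_p1: int, n_p2: int, n_missing: int) -> str:
    if n_missing:
        return "incomplete"
    return {0: "0:4", 1: "1:3", 2: "2:2", 3: "3:1", 4: "4:0"}[n_p1]


def classify_sites(origin: OriginMatrix) -> list[SegPattern]:
    """Segregation counts and labels for every marker."""
    out = []
    for chrom in origin.chromosomes:
        pos = origin.positions[chrom]
        org = origin.origins[chrom]
        for i in range(pos.size):
            row = org[i]
            n1 = int(np.sum(row == P1))
            n2 = int(np.sum(row == P2))
            nm = 4 - n1 - n2
            out.append(SegPattern(chrom, int(pos[i]), n1, n2, nm, _label(n1, n2, nm)))
    return out


@dataclass
class _Run:
    pattern: tuple[int, int, int, int]
    label: str
    first: int  # index into the complete-marker sequence
    last: int


def _compress(patterns: list[tuple[int, int, int, int]]) -> list[_Run]:
    runs: list[_Run] = []
    for i, pat in enumerate(patterns):
        if runs and runs[-1].pattern == pat:
            runs[-1].last = i
        else:
            n1 = pat.count(P1)
            runs.append(_Run(pat, _label(n1, 4 - n1, 0), i, i))
    return runs


def _diff_spores(a, b) -> tuple[int, ...]:
    return tuple(i for i in range(4) if a[i] != b[i])


def call_events(
    origin: OriginMatrix,
    min_nco_markers: int = 1,
    merge_distance: int = 5000,
) -> list[RecombinationEvent]:
    """Call CO, NCO, premeiotic-LOH and complex events from an origin matrix.

    Markers with missing cells support no events but do not break runs.
    A reciprocal double switch restoring the original phase is reported
    as two COs only when >= 2 markers separate the switches or they are
    farther apart than ``merge_distance``; otherwise it is one complex
    event (indistinguishable from a short double event).
    """
    events: list[RecombinationEvent] = []
    for chrom in origin.chromosomes:
        pos_all = origin.positions[chrom]
        org_all = origin.origins[chrom]
        complete = np.all(org_all != MISSING, axis=1)
        idx = np.flatnonzero(complete)
        if idx.size == 0:
            continue
        pos = pos_all[idx].astype(float)
        patterns = [tuple(int(v) for v in org_all[i]) for i in idx]
        chrom_end = float(origin.chrom_lengths[chrom]) if origin.chrom_lengths else float(pos_all[-1])
        runs = _compress(patterns)
        events.extend(
            _events_of_chromosome(chrom, runs, pos, idx, chrom_end,
                                  min_nco_markers, merge_distance)
        )
    events.sort(key=lambda e: (e.chromosome, e.inner_start, e.inner_end))
    return events


def _events_of_chromosome(
    chrom: str,
    runs: list[_Run],
    pos: np.ndarray,
    idx: np.ndarray,
    chrom_end: float,
    min_nco_markers: int,
    merge_distance: int,
) -> list[RecombinationEvent]:
    events: list[RecombinationEvent] = []

    # --- blocks of consecutive non-2:2 runs, with their 2:2 flanks
    j = 0
    while j < len(runs):
        if runs[j].label == "2:2":
            j += 1
            continue
        a = j
        while j < len(runs) and runs[j].label != "2:2":
            j += 1
        b = j - 1
        left = runs[a - 1] if a > 0 else None
        right = runs[b + 1] if b + 1 < len(runs) else None
        events.extend(
            _block_event(chrom, runs[a:b + 1], left, right, pos, chrom_end, min_nco_markers)
        )

    # --- phase switches between adjacent 2:2 runs
    boundary_events: dict[int, RecombinationEvent] = {}
    for k in range(len(runs) - 1):
        r1, r2 = runs[k], runs[k + 1]
        if r1.label != "2:2" or r2.label != "2:2":
            continue
        diff = _diff_spores(r1.pattern, r2.pattern)
        inner = (float(pos[r1.last]), float(pos[r2.first]))
        note = ""
        if idx[r2.first] - idx[r1.last] > 1 and inner[1] - inner[0] > merge_distance:
            note = "bridged_missing_gap"
        if len(diff) == 2:
            boundary_events[k] = RecombinationEvent(
                kind=CO, chromosome=chrom, inner_start=inner[0], inner_end=inner[1],
                max_start=inner[0], max_end=inner[1], spores=diff, n_markers=0, note=note)
        else:  # 4 spores switching at once: two coincident COs or worse
            boundary_events[k] = RecombinationEvent(
                kind=COMPLEX, chromosome=chrom, inner_start=inner[0], inner_end=inner[1],
                max_start=inner[0], max_end=inner[1], spores=diff, n_markers=0,
                note="four_spore_switch")

    # --- collapse short phase restorations (A B A with <2 markers in B)
    suppressed: set[int] = set()
    for k in range(1, len(runs) - 1):
        r_prev, r_mid, r_next = runs[k - 1], runs[k], runs[k + 1]
        if not (r_prev.label == r_mid.label == r_next.label == "2:2"):
            continue
        if r_prev.pattern != r_next.pattern or r_mid.pattern == r_prev.pattern:
            continue
        n_sep = r_mid.last - r_mid.first + 1
        span = float(pos[r_next.first]) - float(pos[r_prev.last])
        if n_sep < 2 and span <= merge_distance:
            suppressed.update((k - 1, k))
            events.append(RecombinationEvent(
                kind=COMPLEX, chromosome=chrom,
                inner_start=float(pos[r_prev.last]), inner_end=float(pos[r_next.first]),
                max_start=float(pos[r_prev.last]), max_end=float(pos[r_next.first]),
                spores=_diff_spores(r_prev.pattern, r_mid.pattern),
                n_markers=n_sep, note="reciprocal_double_switch"))
    events.extend(ev for k, ev in boundary_events.items() if k not in suppressed)
    return events


def _block_event(
    chrom: str,
    block: list[_Run],
    left: _Run | None,
    right: _Run | None,
    pos: np.ndarray,
    chrom_end: float,
    min_nco_markers: int,
) -> list[RecombinationEvent]:
    first, last = block[0].first, block[-1].last
    inner = (float(pos[first]), float(pos[last]))
    max_start = float(pos[left.last]) if left is not None else 0.0
    max_end = float(pos[right.first]) if right is not None else chrom_end
    n_markers = last - first + 1
    labels = {r.label for r in block}
    patterns = {r.pattern for r in block}

    def complex_event(note: str) -> list[RecombinationEvent]:
        return [RecombinationEvent(kind=COMPLEX, chromosome=chrom,
                                   inner_start=inner[0], inner_end=inner[1],
                                   max_start=max_start, max_end=max_end,
                                   n_markers=n_markers, note=note)]

    if len(patterns) > 1:
        return complex_event("mixed_patterns_in_run")
    pattern = block[0].pattern

    if labels <= {"3:1", "1:3"}:
        flank = left.pattern if left is not None else (right.pattern if right is not None else None)
        if flank is None:
            # whole chromosome non-2:2: converted spore = minority origin
            minority = P2 if pattern.count(P2) == 1 else P1
            spore = pattern.index(minority)
            diff = (spore,)
        else:
            diff = _diff_spores(pattern, flank)
        if len(diff) != 1:
            return complex_event("multi_spore_conversion")
        if left is not None and right is not None and left.pattern != right.pattern:
            co_spores = _diff_spores(left.pattern, right.pattern)
            if len(co_spores) == 2:
                return [RecombinationEvent(
                    kind=CO, chromosome=chrom, inner_start=inner[0], inner_end=inner[1],
                    max_start=max_start, max_end=max_end, spores=co_spores,
                    n_markers=n_markers, note="conversion_adjacent",
                    annotations={"conversion_spore": diff[0]})]
            return complex_event("discordant_flanks")
        if n_markers < min_nco_markers:
            return []
        return [RecombinationEvent(
            kind=NCO, chromosome=chrom, inner_start=inner[0], inner_end=inner[1],
            max_start=max_start, max_end=max_end, spores=diff, n_markers=n_markers)]

    if labels <= {"4:0", "0:4"}:
        if left is not None and right is not None and left.pattern != right.pattern:
            return complex_event("loh_with_phase_switch")
        return [RecombinationEvent(
            kind=PREMEIOTIC_LOH, chromosome=chrom, inner_start=inner[0], inner_end=inner[1],
            max_start=max_start, max_end=max_end, spores=(), n_markers=n_markers)]

    return complex_event("mixed_labels_in_run")


def meiotic_event_counts(events: list[RecombinationEvent]) -> dict[str, int]:
    """Counts per kind; premeiotic LOH is tallied but is not a meiotic event."""
    out = {CO: 0, NCO: 0, PREMEIOTIC_LOH: 0, COMPLEX: 0}
    for ev in events:
        out[ev.kind] += 1
    return out


# ---------------------------------------------------------------------------
# Seg file round-trip (minimal tab-separated dialect, 1-based positions)


def write_seg(origin: OriginMatrix) -> str:
    """Serialize an origin matrix to Seg text (one row per marker)."""
    lines = ["#chrom\tpos\t" + "\t".join(origin.spore_names)]
    for chrom in origin.chromosomes:
        pos = origin.positions[chrom]
        org = origin.origins[chrom]
        for i in range(pos.size):
            codes = "\t".join(ORIGIN_CODES[int(v)] for v in org[i])
            lines.append(f"{chrom}\t{int(pos[i]) + 1}\t{codes}")
    return "\n".join(lines) + "\n"


def read_seg(text: str, chrom_lengths: dict[str, int] | None = None) -> OriginMatrix:
    """Parse Seg text back into an OriginMatrix (lossless round-trip)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError("Seg text must start with a header line")
    spore_names = tuple(lines[0].lstrip("#").split("\t")[2:])
    if len(spore_names) != 4:
        raise ValueError("Seg header must name 4 spores")
    positions: dict[str, list[int]] = {}
    origins: dict[str, list[list[int]]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        chrom, p = fields[0], int(fields[1]) - 1
        codes = fields[2:6]
        positions.setdefault(chrom, []).append(p)
        origins.setdefault(chrom, []).append([CODE_ORIGINS[c] for c in codes])
    return OriginMatrix(
        positions={c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        origins={c: np.array(v, dtype=np.int8) for c, v in origins.items()},
        spore_names=spore_names,
        chrom_lengths=chrom_lengths,
    )
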