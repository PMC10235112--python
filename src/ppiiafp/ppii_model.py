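"""Segmentation of glycine-rich AFPs into polyproline type II helix bundles.

Collembolan antifreeze proteins fold as two stacked layers of short,
antiparallel polyproline type II (PPII) helices. Each turn of a PPII helix
is exactly three residues, so the sequence reads as tripeptide repeats
G-X1-X2: the first (anchor) position points into the core and is almost
always glycine, X1 is often glycine too, and X2 points outward. Helices
carry 3–4 tripeptides and are joined by loops of 3–6 residues. The X2
residues of alternating helices form the flat, Ala/Ser/Thr/Val-rich
ice-binding surface (IBS); the opposite layer carries larger polar or
charged residues.

This module turns a mature sequence into that schematic: maximal tripeptide
runs, helices, loops, terminal tails, a face (IBS / non-IBS) assignment,
and composition metrics used as evidence of the fold.

Coordinates are 0-based half-open throughout; helix ordinals are 1-based so
that "the even-numbered helices" reads as in the structural literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Tripeptide",
    "HelixSegment",
    "LoopSegment",
    "BundleModel",
    "IBS_RESIDUES",
    "find_tripeptide_runs",
    "segment_helices",
    "assign_faces",
    "afp_likeness",
    "render_schematic",
]

#: Small/hydrophobic residues characteristic of the ice-binding surface.
IBS_RESIDUES = frozenset("ASTV")

DEFAULT_G_ALPHABET = frozenset("G")
DEFAULT_REPEATS = (3, 4)
DEFAULT_LOOP = (3, 6)


@dataclass(frozen=True)
class Tripeptide:
    """One G-X1-X2 repeat (one turn of a PPII helix)."""

    start: int
    g: str
    x1: str
    x2: str

    @property
    def residues(self) -> str:
        return self.g + self.x1 + self.x2


@dataclass(frozen=True)
class Run:
    """A maximal chain of consecutive in-frame anchored tripeptides."""

    start: int
    count: int

    @property
    def end(self) -> int:
        return self.start + 3 * self.count

    @property
    def frame(self) -> int:
        return self.start % 3


@dataclass(frozen=True)
class HelixSegment:
    ordinal: int  # 1-based
    start: int
    end: int  # half-open
    tripeptides: tuple[Tripeptide, ...]

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("helix length must be divisible by 3")

    @property
    def n_repeats(self) -> int:
        return len(self.tripeptides)

    @property
    def x2_residues(self) -> str:
        return "".join(t.x2 for t in self.tripeptides)


@dataclass(frozen=True)
class LoopSegment:
    start: int
    end: int
    canonical: bool  # length within the canonical 3-6 residue band

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BundleModel:
    """A PPII helix-bundle annotation of one mature sequence."""

    sequence: str
    helices: list[HelixSegment]
    loops: list[LoopSegment]
    tails: list[tuple[int, int]]
    face_map: dict[int, str] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    @property
    def is_ppii(self) -> bool:
        return self.n_helices > 0

    def ibs_helices(self) -> list[HelixSegment]:
        return [h for h in self.helices if self.face_map.get(h.ordinal) == "IBS"]

    def to_dict(self) -> dict:
        """JSON-ready representation (0-based half-open coordinates)."""
        return {
            "sequence": self.sequence,
            "n_helices": self.n_helices,
            "helices": [
                {
                    "ordinal": h.ordinal,
                    "start": h.start,
                    "end": h.end,
                    "n_repeats": h.n_repeats,
                    "face": self.face_map.get(h.ordinal, "unassigned"),
                }
                for h in self.helices
            ],
            "loops": [
                {"start": lp.start, "end": lp.end, "canonical": lp.canonical}
                for lp in self.loops
            ],
            "tails": [{"start": s, "end": e} for s, e in self.tails],
            "metrics": dict(self.metrics),
        }

    def helix_table(self) -> list[dict]:
        """Per-helix rows with 1-based inclusive coordinates for human-facing TSV."""
        return [
            {
                "helix": h.ordinal,
                "first": h.start + 1,
                "last": h.end,
                "repeats": h.n_repeats,
                "sequence": self.sequence[h.start : h.end],
                "face": self.face_map.get(h.ordinal, "unassigned"),
            }
            for h in self.helices
        ]


def _chain_runs(sequence: str, g_alphabet: frozenset[str], min_run: int) -> list[Run]:
    """All maximal anchored tripeptide chains, over all 3 frame offsets."""
    n = len(sequence)
    runs: list[Run] = []
    for frame in range(3):
        start = None
        count = 0
        pos = frame
        while pos + 3 <= n:
            if sequence[pos] in g_alphabet:
                if start is None:
                    start = pos
                    count = 0
                count += 1
                pos += 3
            else:
                if start is not None and count >= min_run:
                    runs.append(Run(start, count))
                start = None
                pos += 3
        if start is not None and count >= min_run:
            runs.append(Run(start, count))
    return runs


def find_tripeptide_runs(
    sequence: str,
    g_alphabet: Iterable[str] = DEFAULT_G_ALPHABET,
    min_run: int = DEFAULT_REPEATS[0],
) -> list[Run]:
    """Maximal G-X1-X2 tripeptide runs, one frame chosen per region.

    Candidate runs are collected in all three frame offsets; overlapping
    candidates are resolved greedily by coverage (longest run first, then
    lowest start index), so each region of the sequence reports the frame
    that explains the most of it.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    candidates = _chain_runs(sequence, frozenset(g_alphabet), min_run)
    candidates.sort(key=lambda r: (-r.count, r.start))
    chosen: list[Run] = []
    for run in candidates:
        if all(run.end <= c.start or run.start >= c.end for c in chosen):
            chosen.append(run)
    chosen.sort(key=lambda r: r.start)
    return chosen


def _split_run(run: Run, min_rep: int, max_rep: int) -> list[tuple[int, int]]:
    """Split a long run into helix-sized (start, count) pieces, greedily
    left-to-right at the maximum size; a trailing remainder shorter than the
    minimum is dropped into the adjacent loop."""
    pieces = []
    start, remaining = run.start, run.count
    while remaining >= min_rep:
        take = min(remaining, max_rep)
        pieces.append((start, take))
        start += 3 * take
        remaining -= take
    return pieces


def segment_helices(
    sequence: str,
    repeats_per_helix: tuple[int, int] = DEFAULT_REPEATS,
    loop_len: tuple[int, int] = DEFAULT_LOOP,
    g_alphabet: Iterable[str] = DEFAULT_G_ALPHABET,
) -> BundleModel:
    """Segment a mature sequence into a PPII helix bundle model.

    Helices, loops and terminal tails partition the sequence exactly. A
    sequence shorter than one minimal helix yields a model with zero
    helices (``is_ppii`` False).
    """
    sequence = sequence.upper()
    min_rep, max_rep = repeats_per_helix
    helices: list[HelixSegment] = []
    if len(sequence) >= 3 * min_rep:
        runs = find_tripeptide_runs(sequence, g_alphabet, min_run=min_rep)
        ordinal = 0
        for run in runs:
            for start, count in _split_run(run, min_rep, max_rep):
                ordinal += 1
                trips = tuple(
                    Tripeptide(
                        start + 3 * k,
                        sequence[start + 3 * k],
                        sequence[start + 3 * k + 1],
                        sequence[start + 3 * k + 2],
                    )
                    for k in range(count)
                )
                helices.append(
                    HelixSegment(ordinal, start, start + 3 * count, trips)
                )
    loops: list[LoopSegment] = []
    tails: list[tuple[int, int]] = []
    if helices:
        if helices[0].start > 0:
            tails.append((0, helices[0].start))
        for a, b in zip(helices, helices[1:]):
            if b.start > a.end:
                length = b.start - a.end
                loops.append(
                    LoopSegment(a.end, b.start, loop_len[0] <= length <= loop_len[1])
                )
        if helices[-1].end < len(sequence):
            tails.append((helices[-1].end, len(sequence)))
    elif sequence:
        tails.append((0, len(sequence)))

    model = BundleModel(sequence, helices, loops, tails)
    model.metrics = _composition_metrics(model)
    model.face_map = assign_faces(model)
    return model


def _composition_metrics(model: BundleModel) -> dict[str, float]:
    seq = model.sequence
    n = len(seq)
    covered = sum(h.end - h.start for h in model.helices)
    return {
        "gly_fraction": seq.count("G") / n if n else 0.0,
        "gly_ala_fraction": (seq.count("G") + seq.count("A")) / n if n else 0.0,
        "tripeptide_coverage": covered / n if n else 0.0,
    }


def assign_faces(model: BundleModel) -> dict[int, str]:
    """Assign each helix to the IBS or non-IBS layer.

    Consecutive helices alternate layers (the bundle is two antiparallel
    sheets). The layer whose pooled X2 residues are richer in Ala/Ser/Thr/
    Val is called the ice-binding surface; on a tie the even-numbered
    layer is IBS, the convention reported for nine-helix AFPs.
    """
    if model.n_helices < 2:
        return {h.ordinal: "unassigned" for h in model.helices}

    def ibs_score(parity: int) -> float:
        x2 = "".join(
            h.x2_residues for h in model.helices if h.ordinal % 2 == parity
        )
        return sum(r in IBS_RESIDUES for r in x2) / len(x2) if x2 else 0.0

    even, odd = ibs_score(0), ibs_score(1)
    ibs_parity = 0 if even >= odd else 1
    return {
        h.ordinal: "IBS" if h.ordinal % 2 == ibs_parity else "non-IBS"
        for h in model.helices
    }


@dataclass(frozen=True)
class LikenessReport:
    gly_fraction: float
    gly_ala_fraction: float
    tripeptide_coverage: float
    verdict: bool


def afp_likeness(
    sequence: str,
    gly_threshold: float = 0.20,
    coverage_threshold: float = 0.50,
    **segment_kwargs,
) -> LikenessReport:
    """Composition- and repeat-based evidence that a sequence is a PPII AFP.

    The verdict is positive iff the glycine mole fraction and the fraction
    of the sequence covered by anchored tripeptide runs both clear their
    thresholds — the two diagnostics used to flag glycine-rich AFPs.
    """
    if not sequence:
        raise ValueError("empty sequence")
    model = segment_helices(sequence, **segment_kwargs)
    m = model.metrics
    verdict = (
        m["gly_fraction"] >= gly_threshold
        and m["tripeptide_coverage"] >= coverage_threshold
    )
    return LikenessReport(
        m["gly_fraction"], m["gly_ala_fraction"], m["tripeptide_coverage"], verdict
    )


def render_schematic(model: BundleModel) -> str:
    """Plain-text schematic: one line per segment, helices one tripeptide
    per column, IBS helices marked with ``*``. Concatenating the residue
    fields in reading order reproduces the mature sequence exactly."""
    if not model.is_ppii:
        if not model.sequence:
            return "no PPII bundle detected"
        return "no PPII bundle detected\ntail\t" + model.sequence

    segments: list[tuple[int, str]] = []  # (start, line)
    for s, e in model.tails:
        segments.append((s, f"tail\t{model.sequence[s:e]}"))
    for lp in model.loops:
        tag = "loop" if lp.canonical else "loop!"
        segments.append((lp.start, f"{tag}\t{model.sequence[lp.start:lp.end]}"))
    for h in model.helices:
        mark = "*" if model.face_map.get(h.ordinal) == "IBS" else " "
        cols = " ".join(t.residues for t in h.tripeptides)
        segments.append((h.start, f"H{h.ordinal}{mark}\t{cols}"))
    segments.sort(key=lambda t: t[0])
    return "\n".join(line for _, line in segments)
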