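"""Synthetic PPII antifreeze proteins and mass lists with known ground truth.

Real study material — cold-acclimated springtails, ice-affinity-purified
extracts, MALDI and tandem-MS runs — is emulated by a generator that
assembles proteins from the PPII fold grammar and simulates the two kinds
of mass observation the pipeline consumes. Every stage carries an explicit
truth record, so segmentation, matching and clustering can be validated by
round-trip rather than against external data.

Generated proteins follow the fold grammar of collembolan AFPs:

* 6–13 helices of 3–4 G-X1-X2 tripeptides each, glycine at every anchor,
  X1 drawn glycine-heavy, X2 drawn from a small/hydrophobic alphabet
  (Ala/Ser/Thr/Val) on the ice-binding layer and from a polar/charged
  alphabet on the other layer;
* loops of 3–6 residues joining helices, free of glycine (so helix
  boundaries are unambiguous) but carrying the Lys/Arg residues that make
  the proteins tryptically digestible, plus occasional Pro — a loop-final
  Pro ahead of a helix anchor creates an X-P-G hydroxylation site;
* optional cysteines placed in loops, and an optional cleavable signal
  peptide of 19–24 residues.

All randomness flows through a single ``numpy.random.default_rng``
generator seeded per call: identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from . import seqmass
from .digest_match import Peak, enumerate_ptm_forms, in_source_products, tryptic_digest
from .isoforms import ProteinRecord

__all__ = [
    "SimParams",
    "TruthRecord",
    "generate_afp",
    "generate_family",
    "mutate_family",
    "simulate_maldi",
    "simulate_fragment_peaks",
]


def _weights(d: dict[str, float]) -> tuple[list[str], np.ndarray]:
    if not d:
        raise ValueError("empty alphabet")
    letters = sorted(d)
    w = np.array([d[l] for l in letters], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and sum > 0")
    return letters, w / w.sum()


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the generator.

    Defaults mirror the fold grammar above; composition weights are chosen
    so generated mature proteins land at a glycine mole fraction of roughly
    0.3–0.45, qualitatively matching glycine-rich AFP compositions.
    """

    n_helices: int | None = None  # None: draw uniformly from 6..13
    n_helices_range: tuple[int, int] = (6, 13)
    repeats_per_helix: tuple[int, int] = (3, 4)
    loop_len: tuple[int, int] = (3, 6)
    x1_weights: dict[str, float] = field(
        default_factory=lambda: {"G": 0.45, "A": 0.25, "S": 0.10, "T": 0.10, "V": 0.10}
    )
    ibs_x2_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.55, "S": 0.15, "T": 0.15, "V": 0.15}
    )
    non_ibs_x2_weights: dict[str, float] = field(
        default_factory=lambda: {
            "N": 0.30, "Q": 0.15, "D": 0.12, "E": 0.08,
            "H": 0.10, "Y": 0.10, "P": 0.15,
        }
    )
    loop_weights: dict[str, float] = field(
        default_factory=lambda: {
            "N": 0.17, "T": 0.14, "S": 0.14, "D": 0.10,
            "K": 0.15, "R": 0.05, "P": 0.13, "Q": 0.12,
        }
    )
    n_cysteines: int = 2
    signal_peptide: bool = True
    signal_len: tuple[int, int] = (19, 24)
    mutation_rate: float = 0.0
    hydroxylation_rate: float = 1 / 6  # ~one modified X-P-G motif in six
    pyroglutamate_rate: float = 0.5
    mass_noise_sd: float = 0.05  # Da
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.n_helices_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_helices_range")
        if self.n_helices is not None and self.n_helices < 1:
            raise ValueError("n_helices must be >= 1")
        for rate in (self.mutation_rate, self.hydroxylation_rate, self.pyroglutamate_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mass_noise_sd < 0:
            raise ValueError("mass_noise_sd must be >= 0")
        for alphabet in (
            self.x1_weights, self.ibs_x2_weights,
            self.non_ibs_x2_weights, self.loop_weights,
        ):
            _weights(alphabet)


@dataclass
class TruthRecord:
    """Ground truth for one generated protein."""

    record: ProteinRecord
    helix_spans: list[tuple[int, int]]  # mature coordinates, half-open
    faces: dict[int, str]  # helix ordinal -> IBS | non-IBS
    anchor_positions: list[int]  # mature indices of tripeptide anchors
    hydroxylation_sites: list[int]  # mature indices of eligible X-P-G Pro
    family: str | None = None


def _draw(rng: np.random.Generator, letters: list[str], probs: np.ndarray, k: int) -> str:
    return "".join(rng.choice(letters, size=k, p=probs)) if k else ""


def generate_afp(
    params: SimParams = SimParams(), seed: int | None = None
) -> tuple[ProteinRecord, TruthRecord]:
    """Generate one synthetic AFP precursor with its ground truth."""
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n_h = params.n_helices
    if n_h is None:
        lo, hi = params.n_helices_range
        n_h = int(rng.integers(lo, hi + 1))
    x1_l, x1_p = _weights(params.x1_weights)
    ibs_l, ibs_p = _weights(params.ibs_x2_weights)
    non_l, non_p = _weights(params.non_ibs_x2_weights)
    loop_l, loop_p = _weights(params.loop_weights)

    ibs_parity = int(rng.integers(0, 2))  # helix ordinal % 2 == parity -> IBS
    faces = {
        h: "IBS" if h % 2 == ibs_parity else "non-IBS" for h in range(1, n_h + 1)
    }

    parts: list[str] = []
    helix_spans: list[tuple[int, int]] = []
    anchors: list[int] = []
    pos = 0
    for h in range(1, n_h + 1):
        if h > 1:
            loop = _draw(
                rng, loop_l, loop_p, int(rng.integers(params.loop_len[0], params.loop_len[1] + 1))
            )
            parts.append(loop)
            pos += len(loop)
        n_rep = int(
            rng.integers(params.repeats_per_helix[0], params.repeats_per_helix[1] + 1)
        )
        x2_l, x2_p = (ibs_l, ibs_p) if faces[h] == "IBS" else (non_l, non_p)
        helix = "".join(
            "G" + _draw(rng, x1_l, x1_p, 1) + _draw(rng, x2_l, x2_p, 1)
            for _ in range(n_rep)
        )
        anchors.extend(pos + 3 * k for k in range(n_rep))
        helix_spans.append((pos, pos + len(helix)))
        parts.append(helix)
        pos += len(helix)
    mature = "".join(parts)

    # cysteines go into loops (between consecutive helix spans)
    loop_positions = [
        p
        for (s0, e0), (s1, _) in zip(helix_spans, helix_spans[1:])
        for p in range(e0, s1)
    ]
    seq = list(mature)
    if params.n_cysteines and loop_positions:
        chosen = rng.choice(
            loop_positions, size=min(params.n_cysteines, len(loop_positions)), replace=False
        )
        for p in sorted(int(c) for c in chosen):
            seq[p] = "C"
    mature = "".join(seq)

    signal_end = None
    full = mature
    if params.signal_peptide:
        slen = int(rng.integers(params.signal_len[0], params.signal_len[1] + 1))
        hydrophobic = list("LAVFIST")
        signal = "M" + "".join(rng.choice(hydrophobic, size=slen - 1))
        full = signal + mature
        signal_end = slen

    rec = ProteinRecord(f"synthAFP_seed{seed}", full, signal_end)
    hyp_sites = [
        i for i in range(len(mature) - 1) if mature[i] == "P" and mature[i + 1] == "G"
    ]
    truth = TruthRecord(rec, helix_spans, faces, anchors, hyp_sites)
    return rec, truth


_SUBSTITUTION_ALPHABET = list("ASTNQDEVH")  # no G (anchors), no K/R (cleavage sites)


def mutate_family(
    record: ProteinRecord,
    n_members: int,
    rate: float,
    seed: int | None = None,
    protect_positions: list[int] | None = None,
) -> list[ProteinRecord]:
    """Derive an isoform family by per-residue point substitution.

    Substitutions hit the mature sequence at the given per-residue rate;
    positions in ``protect_positions`` (typically the glycine anchors of
    the helices) are never touched, emulating the strong conservation of
    the packing core relative to loops and the non-IBS face.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    protected = set(protect_positions or [])
    members = []
    offset = record.signal_end or 0
    mature = record.mature
    for k in range(n_members):
        seq = list(mature)
        hits = rng.random(len(seq)) < rate
        for i in np.nonzero(hits)[0]:
            if int(i) in protected:
                continue
            seq[int(i)] = str(rng.choice(_SUBSTITUTION_ALPHABET))
        members.append(
            ProteinRecord(
                f"{record.id}_iso{k + 1}",
                record.sequence[:offset] + "".join(seq),
                record.signal_end,
            )
        )
    return members


def generate_family(
    params: SimParams = SimParams(),
    n_members: int = 5,
    seed: int | None = None,
) -> tuple[list[ProteinRecord], TruthRecord]:
    """One founder AFP plus a mutated isoform family (anchors protected)."""
    rec, truth = generate_afp(params, seed)
    sub_seed = None if seed is None else (seed + 1) % (2**31)
    members = mutate_family(
        rec, n_members, params.mutation_rate, sub_seed, truth.anchor_positions
    )
    truth.family = rec.id
    return members, truth


def simulate_maldi(
    records: list[ProteinRecord],
    params: SimParams = SimParams(),
    seed: int | None = None,
) -> tuple[list[Peak], list[dict]]:
    """Simulate a linear-mode MALDI peak list for intact mature proteins.

    Each record contributes its base average mass (all cysteines paired)
    and, when hydroxylation is simulated, a ladder of +16 Da satellites:
    K eligible Pro-Gly sites are drawn hydroxylated per the hydroxylation
    rate and peaks are emitted for 0..K modifications, the satellite
    pattern seen for singly-gened AFPs. Gaussian mass noise is additive.

    Returns the sorted peak list and a truth table of dicts
    ``{record_id, n_hydroxylations, true_mass}`` aligned with the peaks.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    entries = []
    for rec in records:
        mature = rec.mature
        base = seqmass.protein_average_mass(mature)
        sites = sum(
            1 for i in range(len(mature) - 1)
            if mature[i] == "P" and mature[i + 1] == "G"
        )
        kmax = int(rng.binomial(sites, params.hydroxylation_rate)) if sites else 0
        for k in range(kmax + 1):
            true_mass = base + k * seqmass.DEFAULT_TABLE.oxygen_avg
            mz = true_mass + rng.normal(0.0, params.mass_noise_sd)
            entries.append(
                (
                    Peak(mz, 1.0, f"{rec.id}+{k}OH"),
                    {"record_id": rec.id, "n_hydroxylations": k, "true_mass": true_mass},
                )
            )
    entries.sort(key=lambda e: e[0].mz)
    return [p for p, _ in entries], [t for _, t in entries]


def simulate_fragment_peaks(
    record: ProteinRecord,
    params: SimParams = SimParams(),
    seed: int | None = None,
    include_in_source: bool = True,
) -> tuple[list[Peak], list[dict]]:
    """Simulate a tandem-MS tryptic fragment [M+H]+ peak list.

    The mature protein is digested (no missed cleavages); optionally the
    in-source products of Lys-Pro / Arg-Pro bonds are added. Each peptide
    receives a hydroxylation count drawn per site at the hydroxylation
    rate and, if it starts with Gln, pyroglutamate at the pyroglutamate
    rate. Truth dicts record the peptide and its planted modifications.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    forms = tryptic_digest(record.mature, 0, record.id)
    if include_in_source:
        forms = forms + [p for f in forms for p in in_source_products(f)]
    entries = []
    for form in forms:
        seq = form.sequence
        sites = [
            i for i in range(len(seq) - 1) if seq[i] == "P" and seq[i + 1] == "G"
        ]
        chosen = tuple(
            int(i) for i in sites if rng.random() < params.hydroxylation_rate
        )
        pyroglu = bool(
            seq[:1] == "Q" and rng.random() < params.pyroglutamate_rate
        )
        modded = enumerate_ptm_forms(form, 0)[0]  # unmodified copy
        modded = _dc_replace(modded, pyroglu=pyroglu, hyp_sites=chosen)
        mz = modded.mh + rng.normal(0.0, params.mass_noise_sd)
        entries.append(
            (
                Peak(mz, 1.0, f"{record.id}:{form.start}-{form.end}"),
                {
                    "record_id": record.id,
                    "start": form.start,
                    "end": form.end,
                    "sequence": seq,
                    "n_hydroxylations": len(chosen),
                    "hyp_sites": list(chosen),
                    "pyroglutamate": pyroglu,
                    "true_mh": modded.mh,
                    "tryptic": form.tryptic,
                },
            )
        )
    entries.sort(key=lambda e: e[0].mz)
    return [p for p, _ in entries], [t for _, t in entries]
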