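"""In-silico tryptic digestion, PTM enumeration and mass-list matching.

Ties observed masses back to candidate AFP isoform sequences at two levels:

* tandem-MS tryptic fragments — trypsin cleaves after Lys/Arg except when
  the next residue is Pro; those protected Lys-Pro / Arg-Pro bonds can
  still break non-enzymatically in the instrument source, so in-source
  products of tryptic peptides are enumerated separately;
* intact MALDI masses — linear-mode peak labels compared against predicted
  average masses of mature proteins, with disulfide correction and
  successive +16 Da proline-hydroxylation satellites.

Modification hypotheses follow the collagen-like rule: hydroxyproline only
at Pro immediately followed by Gly, pyroglutamate only at an N-terminal Gln.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

from . import seqmass
from .seqmass import (
    DEFAULT_TABLE,
    HYDROXYLATION,
    PYROGLUTAMATE,
    ModificationSpec,
)

__all__ = [
    "Peak",
    "PeptideForm",
    "FragmentMatch",
    "IntactMatch",
    "FragmentMatchReport",
    "tryptic_digest",
    "in_source_products",
    "enumerate_ptm_forms",
    "match_fragment_peaks",
    "reconcile_maldi",
]


class Peak(NamedTuple):
    """One entry of a peak list (m/z in Da)."""

    mz: float
    intensity: float | None = None
    label: str | None = None


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    out = [p if isinstance(p, Peak) else Peak(*p) for p in peaks]
    for p in out:
        if p.mz <= 0:
            raise ValueError(f"non-positive m/z {p.mz}")
    return sorted(out, key=lambda p: p.mz)


@dataclass(frozen=True)
class PeptideForm:
    """A peptide subsequence plus one modification hypothesis.

    ``start``/``end`` are 0-based half-open in the parent mature sequence;
    ``hyp_sites`` are peptide-relative indices of hydroxylated prolines.
    """

    parent_id: str | None
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    pyroglu: bool = False
    hyp_sites: tuple[int, ...] = ()
    tryptic: bool = True

    def __post_init__(self) -> None:
        if self.pyroglu and self.sequence[:1] != "Q":
            raise ValueError("pyroglutamate requires an N-terminal Gln")
        for i in self.hyp_sites:
            nxt = self.sequence[i + 1 : i + 2]
            if self.sequence[i] != "P" or nxt != "G":
                raise ValueError(
                    f"hydroxyproline site {i} violates the Pro-Gly rule"
                )

    @property
    def n_hydroxylations(self) -> int:
        return len(self.hyp_sites)

    def _mods(self) -> dict[ModificationSpec, int]:
        mods: dict[ModificationSpec, int] = {}
        if self.pyroglu:
            mods[PYROGLUTAMATE] = 1
        if self.hyp_sites:
            mods[HYDROXYLATION] = len(self.hyp_sites)
        return mods

    @property
    def neutral_mass(self) -> float:
        return seqmass.peptide_neutral_mass(self.sequence, self._mods())

    @property
    def mh(self) -> float:
        return seqmass.peptide_mh(self.sequence, self._mods())


def _cleavage_boundaries(sequence: str) -> list[int]:
    """Boundaries of zero-missed tryptic peptides: after K/R not before P."""
    cuts = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    return cuts


def tryptic_digest(
    sequence: str,
    missed_cleavages_max: int = 0,
    parent_id: str | None = None,
) -> list[PeptideForm]:
    """Unmodified tryptic peptides with up to the given missed cleavages.

    Zero-missed-cleavage peptides tile the input exactly; peptides with m
    missed cleavages are concatenations of m+1 consecutive tiles.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    bounds = _cleavage_boundaries(sequence)
    forms = []
    n_tiles = len(bounds) - 1
    for i in range(n_tiles):
        for m in range(missed_cleavages_max + 1):
            if i + m + 1 > n_tiles:
                break
            s, e = bounds[i], bounds[i + m + 1]
            forms.append(
                PeptideForm(parent_id, s, e, sequence[s:e], missed_cleavages=m)
            )
    forms.sort(key=lambda f: (f.start, f.end))
    return forms


def in_source_products(form: PeptideForm) -> list[PeptideForm]:
    """Sub-peptides from non-enzymatic breakage at internal K|P / R|P bonds.

    For every protected junction both flanking products are emitted and
    marked non-tryptic. Their neutral masses sum to the parent's plus one
    water (hydrolysis balance).
    """
    seq = form.sequence
    products = []
    for j in range(len(seq) - 1):
        if seq[j] in "KR" and seq[j + 1] == "P":
            products.append(
                replace(
                    form,
                    end=form.start + j + 1,
                    sequence=seq[: j + 1],
                    tryptic=False,
                )
            )
            products.append(
                replace(
                    form,
                    start=form.start + j + 1,
                    sequence=seq[j + 1 :],
                    tryptic=False,
                )
            )
    return products


def enumerate_ptm_forms(
    form: PeptideForm, max_hydroxylations: int | None = None
) -> list[PeptideForm]:
    """All modification hypotheses for one peptide.

    Every combination of 0..min(max, n_sites) hydroxylations over the
    eligible Pro-Gly sites, crossed with pyroglutamate on/off when the
    peptide starts with Gln.
    """
    seq = form.sequence
    sites = [
        i for i in range(len(seq) - 1) if seq[i] == "P" and seq[i + 1] == "G"
    ]
    kmax = len(sites) if max_hydroxylations is None else min(
        max_hydroxylations, len(sites)
    )
    pyroglu_options = (False, True) if seq[:1] == "Q" else (False,)
    out = []
    for k in range(kmax + 1):
        for combo in itertools.combinations(sites, k):
            for pg in pyroglu_options:
                out.append(replace(form, pyroglu=pg, hyp_sites=combo))
    return out


@dataclass(frozen=True)
class FragmentMatch:
    peak: Peak
    form: PeptideForm
    predicted_mh: float
    delta: float  # observed - predicted, Da
    isoform_ids: tuple[str, ...]  # every isoform containing the subsequence


@dataclass(frozen=True)
class FragmentMatchReport:
    matches: list[FragmentMatch]
    unmatched: list[Peak]


def _as_id_map(isoforms) -> dict[str, str]:
    """Accept a mapping id->mature sequence or records with .id/.mature."""
    if isinstance(isoforms, dict):
        return {str(k): v.upper() for k, v in isoforms.items()}
    out = {}
    for rec in isoforms:
        out[rec.id] = rec.mature.upper()
    return out


def match_fragment_peaks(
    peaks: Iterable[Peak],
    isoforms,
    tolerance_da: float = 0.3,
    missed_cleavages_max: int = 1,
    max_hydroxylations: int | None = None,
    include_in_source: bool = True,
) -> FragmentMatchReport:
    """Match observed fragment [M+H]+ peaks against candidate isoforms.

    ``isoforms`` is a mapping of isoform id to mature sequence (or an
    iterable of records exposing ``.id`` and ``.mature``). Every
    (peak, peptide-form) pair within the absolute tolerance is reported;
    each match is attributed to all isoforms containing that exact
    subsequence. Peaks matching nothing are listed separately.
    """
    if tolerance_da < 0:
        raise ValueError("tolerance must be >= 0")
    seqs = _as_id_map(isoforms)
    if not seqs:
        raise ValueError("empty isoform set")
    peaks = sort_peaks(peaks)

    candidates: dict[tuple, tuple[PeptideForm, float]] = {}
    for iso_id, mature in seqs.items():
        base_forms = tryptic_digest(mature, missed_cleavages_max, iso_id)
        if include_in_source:
            base_forms += [
                p for f in base_forms for p in in_source_products(f)
            ]
        for f in base_forms:
            for form in enumerate_ptm_forms(f, max_hydroxylations):
                key = (form.sequence, form.pyroglu, form.hyp_sites)
                if key not in candidates:
                    candidates[key] = (form, form.mh)

    matches = []
    unmatched = []
    for peak in peaks:
        hit = False
        for form, mh in candidates.values():
            delta = peak.mz - mh
            if abs(delta) <= tolerance_da:
                owners = tuple(
                    sorted(i for i, s in seqs.items() if form.sequence in s)
                )
                matches.append(FragmentMatch(peak, form, mh, delta, owners))
                hit = True
        if not hit:
            unmatched.append(peak)
    matches.sort(key=lambda m: (m.peak.mz, abs(m.delta), m.form.sequence))
    return FragmentMatchReport(matches, unmatched)


@dataclass(frozen=True)
class IntactMatch:
    peak: Peak
    record_id: str
    n_hydroxylations: int
    n_disulfides: int
    predicted_mass: float
    delta: float  # observed - predicted, Da


def reconcile_maldi(
    records,
    peaks: Iterable[Peak],
    relative_tolerance: float = 0.002,
    n_disulfides: int | None = None,
    max_hydroxylations: int | None = None,
) -> list[IntactMatch]:
    """Reconcile intact MALDI peaks with predicted average protein masses.

    For each record the predicted average mass of the mature protein (with
    the disulfide correction, default all cysteines paired) and its
    hydroxylation satellites (+one oxygen per eligible Pro-Gly site, up to
    ``max_hydroxylations``) are compared with the peak list. Linear-mode
    MALDI labels are treated as average masses; at the default 0.2%
    relative tolerance the proton mass is negligible.
    """
    peaks = sort_peaks(peaks)
    matches = []
    for rec in records:
        mature = rec.mature.upper()
        n_ss = rec.mature.count("C") // 2 if n_disulfides is None else n_disulfides
        sites = sum(
            1
            for i in range(len(mature) - 1)
            if mature[i] == "P" and mature[i + 1] == "G"
        )
        kmax = sites if max_hydroxylations is None else min(max_hydroxylations, sites)
        for k in range(kmax + 1):
            predicted = seqmass.protein_average_mass(
                mature, n_disulfides=n_ss, n_hydroxylations=k
            )
            for peak in peaks:
                delta = peak.mz - predicted
                if abs(delta) <= relative_tolerance * predicted:
                    matches.append(
                        IntactMatch(peak, rec.id, k, n_ss, predicted, delta)
                    )
    matches.sort(key=lambda m: (m.peak.mz, m.record_id, m.n_hydroxylations))
    return matches
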