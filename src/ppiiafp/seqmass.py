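"""Residue mass tables and peptide/protein mass computation.

Masses follow the standard convention for linear peptides: a neutral
peptide weighs the sum of its residue masses plus one water (the N- and
C-terminal H and OH). Singly protonated species ([M+H]+) add one proton.

The modification chemistry covers what is seen in glycine-rich collembolan
antifreeze proteins (AFPs):

* pyroglutamate — N-terminal Gln cyclization, loss of ammonia (−17.027 Da);
* hydroxylation — proline → hydroxyproline, gain of one oxygen
  (+15.995 Da), restricted to Pro immediately followed by Gly
  (the X-P-G motif familiar from collagen);
* disulfide bonds — loss of two hydrogens per bond;
* carbamidomethylation of cysteine — opt-in; AFP preparations in this
  pipeline treat cysteines as free thiols by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "ResidueMassTable",
    "ModificationSpec",
    "PYROGLUTAMATE",
    "HYDROXYLATION",
    "DISULFIDE",
    "CARBAMIDOMETHYL",
    "DEFAULT_TABLE",
    "peptide_neutral_mass",
    "peptide_mh",
    "peptide_mz",
    "protein_average_mass",
    "b_ion_ladder",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _formula_mass(formula: str, average: bool = False) -> float:
    return _pmass.calculate_mass(formula=formula, average=average)


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue monoisotopic and average masses plus physical constants (Da)."""

    mono: Mapping[str, float]
    avg: Mapping[str, float]
    water_mono: float
    water_avg: float
    proton_mono: float
    ammonia_mono: float
    oxygen_mono: float
    oxygen_avg: float
    hydrogen_mono: float
    hydrogen_avg: float
    ammonia_avg: float

    def residue_mass(self, residue: str, scale: str = "mono") -> float:
        table = self.mono if scale == "mono" else self.avg
        try:
            return table[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r}") from None


def _default_table() -> ResidueMassTable:
    mono = {}
    avg = {}
    for aa in STANDARD_RESIDUES:
        comp = _pmass.std_aa_comp[aa]
        mono[aa] = _pmass.calculate_mass(composition=comp)
        avg[aa] = _pmass.calculate_mass(composition=comp, average=True)
    return ResidueMassTable(
        mono=mono,
        avg=avg,
        water_mono=_formula_mass("H2O"),
        water_avg=_formula_mass("H2O", average=True),
        proton_mono=_pmass.nist_mass["H+"][0][0],
        ammonia_mono=_formula_mass("NH3"),
        ammonia_avg=_formula_mass("NH3", average=True),
        oxygen_mono=_formula_mass("O"),
        oxygen_avg=_formula_mass("O", average=True),
        hydrogen_mono=_formula_mass("H"),
        hydrogen_avg=_formula_mass("H", average=True),
    )


DEFAULT_TABLE = _default_table()


def _n_pyroglu_sites(sequence: str) -> int:
    return 1 if sequence[:1] == "Q" else 0


def _hydroxylation_sites(sequence: str) -> list[int]:
    """0-based indices of Pro immediately followed by Gly."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] == "P" and sequence[i + 1] == "G"
    ]


def _n_disulfide_sites(sequence: str) -> int:
    return sequence.count("C") // 2


def _n_cys(sequence: str) -> int:
    return sequence.count("C")


@dataclass(frozen=True)
class ModificationSpec:
    """A mass modification with a site-eligibility rule.

    ``site_rule`` names the rule used to count how many copies of the
    modification a given sequence can carry; requesting more copies than
    there are eligible sites is rejected.
    """

    name: str
    delta_mono: float
    delta_avg: float
    site_rule: str

    def max_sites(self, sequence: str) -> int:
        if self.site_rule == "N-terminal-Gln":
            return _n_pyroglu_sites(sequence)
        if self.site_rule == "Pro-followed-by-Gly":
            return len(_hydroxylation_sites(sequence))
        if self.site_rule == "per-disulfide":
            return _n_disulfide_sites(sequence)
        if self.site_rule == "per-cysteine":
            return _n_cys(sequence)
        raise ValueError(f"unknown site rule {self.site_rule!r}")


_T = DEFAULT_TABLE

PYROGLUTAMATE = ModificationSpec(
    "pyroglutamate", -_T.ammonia_mono, -_T.ammonia_avg, "N-terminal-Gln"
)
HYDROXYLATION = ModificationSpec(
    "hydroxylation", _T.oxygen_mono, _T.oxygen_avg, "Pro-followed-by-Gly"
)
DISULFIDE = ModificationSpec(
    "disulfide", -2 * _T.hydrogen_mono, -2 * _T.hydrogen_avg, "per-disulfide"
)
CARBAMIDOMETHYL = ModificationSpec(
    "carbamidomethyl",
    _formula_mass("C2H3NO"),
    _formula_mass("C2H3NO", average=True),
    "per-cysteine",
)

ModCounts = Mapping[ModificationSpec, int] | Iterable[ModificationSpec] | None


def _normalize_mods(mods: ModCounts) -> dict[ModificationSpec, int]:
    if mods is None:
        return {}
    if isinstance(mods, Mapping):
        return {m: int(n) for m, n in mods.items() if n}
    counts: dict[ModificationSpec, int] = {}
    for m in mods:
        counts[m] = counts.get(m, 0) + 1
    return counts


def _validate_sequence(sequence: str, table: ResidueMassTable) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for i, ch in enumerate(sequence):
        if ch not in table.mono:
            raise ValueError(f"unknown residue {ch!r} at position {i}")


def peptide_neutral_mass(
    sequence: str,
    mods: ModCounts = None,
    scale: str = "mono",
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Neutral mass of a linear peptide with optional modifications (Da).

    ``mods`` maps :class:`ModificationSpec` to a multiplicity (or is an
    iterable of specs, one entry per copy). Each spec's site rule must be
    satisfiable on ``sequence`` at the requested multiplicity.
    """
    sequence = sequence.upper()
    _validate_sequence(sequence, table)
    if scale not in ("mono", "avg"):
        raise ValueError(f"scale must be 'mono' or 'avg', got {scale!r}")
    total = sum(table.residue_mass(r, scale) for r in sequence)
    total += table.water_mono if scale == "mono" else table.water_avg
    for spec, n in _normalize_mods(mods).items():
        if n < 0:
            raise ValueError(f"negative multiplicity for {spec.name}")
        available = spec.max_sites(sequence)
        if n > available:
            raise ValueError(
                f"{spec.name} ×{n} requested but only {available} eligible "
                f"site(s) in {sequence!r}"
            )
        total += n * (spec.delta_mono if scale == "mono" else spec.delta_avg)
    return total


def peptide_mh(
    sequence: str,
    mods: ModCounts = None,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Monoisotopic [M+H]+ of a peptide (Da)."""
    return peptide_neutral_mass(sequence, mods, "mono", table) + table.proton_mono


def peptide_mz(
    sequence: str,
    charge: int,
    mods: ModCounts = None,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """m/z of the peptide at the given positive charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    neutral = peptide_neutral_mass(sequence, mods, "mono", table)
    return (neutral + charge * table.proton_mono) / charge


def protein_average_mass(
    sequence: str,
    n_disulfides: int | None = None,
    n_hydroxylations: int = 0,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Average (chemical) mass of a mature protein (Da).

    ``n_disulfides`` defaults to ``floor(nCys / 2)`` — all cysteines paired
    where possible, matching how intact masses of these AFPs are predicted.
    Each bond removes two hydrogens.
    """
    sequence = sequence.upper()
    _validate_sequence(sequence, table)
    if n_disulfides is None:
        n_disulfides = _n_disulfide_sites(sequence)
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    if 2 * n_disulfides > _n_cys(sequence):
        raise ValueError(
            f"{n_disulfides} disulfide(s) requested but sequence has only "
            f"{_n_cys(sequence)} cysteine(s)"
        )
    mods: dict[ModificationSpec, int] = {}
    if n_hydroxylations:
        mods[HYDROXYLATION] = n_hydroxylations
    mass = peptide_neutral_mass(sequence, mods, "avg", table)
    return mass - n_disulfides * 2 * table.hydrogen_avg


def b_ion_ladder(
    sequence: str,
    mods: ModCounts = None,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[float]:
    """Monoisotopic b-ion masses b1..bN for a peptide (Da).

    b_n is the sum of the first n residue masses plus one proton. An
    N-terminal pyroglutamate shifts every rung; hydroxylations shift the
    rungs at and after their site (sites filled leftmost-first over the
    eligible Pro-Gly positions). The final rung equals [M+H]+ − water.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("b-ion ladder requires a sequence of length >= 2")
    _validate_sequence(sequence, table)
    counts = _normalize_mods(mods)
    pyroglu = counts.get(PYROGLUTAMATE, 0)
    n_hyp = counts.get(HYDROXYLATION, 0)
    for spec, n in counts.items():
        if spec not in (PYROGLUTAMATE, HYDROXYLATION):
            raise ValueError(f"b-ion ladder does not support {spec.name}")
        if n > spec.max_sites(sequence):
            raise ValueError(f"{spec.name} site rule unsatisfied on {sequence!r}")
    hyp_sites = set(_hydroxylation_sites(sequence)[:n_hyp])
    ladder = []
    running = table.proton_mono + pyroglu * PYROGLUTAMATE.delta_mono
    for i, r in enumerate(sequence):
        running += table.residue_mass(r, "mono")
        if i in hyp_sites:
            running += HYDROXYLATION.delta_mono
        ladder.append(running)
    return ladder
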