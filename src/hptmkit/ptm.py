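"""PTM registry, peptidoform masses, MS1 matching and search-set selection.

An untargeted histone search cannot place every known modification in one
pass: the variable-modification space explodes combinatorially.  The strategy
modelled here is (1) enumerate, per MS1 feature, every modified-peptide
candidate whose monoisotopic mass explains the precursor within a ppm
tolerance, then (2) pick a small number of variable-modification *sets*
sequentially, each round choosing the set that explains the most not-yet
covered candidates (greedy maximum coverage).  The fraction of candidates
covered by the chosen sets is the *comprehensiveness* of the search plan.

All modification masses derive from elemental formulas (single source of
truth); monoisotopic arithmetic is delegated to :mod:`pyteomics.mass`.
"""

from __future__ import annotations

import bisect
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

from .digestion import DerivatizationState, PeptideProduct, derivatize

__all__ = [
    "PTMDefinition",
    "PROPIONYL",
    "default_registry",
    "Peptidoform",
    "make_peptidoform",
    "mono_mass",
    "enumerate_peptidoforms",
    "CandidateMatch",
    "match_features",
    "PTMSetSelection",
    "select_ptm_sets",
    "AnnotationRecord",
    "classify_annotations",
]

logger = logging.getLogger(__name__)

WATER = _pmass.calculate_mass(formula="H2O")


@dataclass(frozen=True, order=True)
class PTMDefinition:
    """A modification defined by its elemental composition.

    ``formula`` is a Hill-notation element delta (e.g. acetyl ``C2H2O``);
    the monoisotopic delta is always computed from it, never hard-coded.
    """

    name: str
    formula: str
    targets: frozenset[str]
    n_term: bool = False
    curated: bool = True
    source: str = ""

    @property
    def elemental_delta(self) -> dict[str, int]:
        return dict(_pmass.Composition(formula=self.formula))

    @property
    def mono_delta(self) -> float:
        return _pmass.calculate_mass(formula=self.formula)


#: chemical derivatization label (propionyl), not a biological modification
PROPIONYL = PTMDefinition(
    name="pr",
    formula="C3H4O",
    targets=frozenset("K"),
    n_term=True,
    curated=True,
    source="derivatization",
)


def default_registry() -> dict[str, PTMDefinition]:
    """Curated biological modifications quantified on histone H3/H4.

    me/me2 also target arginine (e.g. H3R40me2); phospho targets S/T/Y.
    """
    defs = [
        PTMDefinition("me", "CH2", frozenset("KR"), source="SwissProt"),
        PTMDefinition("me2", "C2H4", frozenset("KR"), source="SwissProt"),
        PTMDefinition("me3", "C3H6", frozenset("K"), source="SwissProt"),
        PTMDefinition("ac", "C2H2O", frozenset("K"), source="SwissProt"),
        PTMDefinition("cr", "C4H4O", frozenset("K"), source="SwissProt"),
        PTMDefinition("hib", "C4H6O2", frozenset("K"), source="SwissProt"),
        PTMDefinition("ph", "HPO3", frozenset("STY"), source="SwissProt"),
    ]
    return {d.name: d for d in defs}


@dataclass(frozen=True)
class Peptidoform:
    """A peptide with located biological mods and its derivatization state."""

    peptide: PeptideProduct
    located_mods: tuple[tuple[int, PTMDefinition], ...]
    derivatization: DerivatizationState
    mono_mass: float

    @property
    def mod_names(self) -> tuple[str, ...]:
        """Biological modification names, sorted (a multiset fingerprint)."""
        return tuple(sorted(m.name for _, m in self.located_mods))

    def describe(self) -> str:
        if not self.located_mods:
            return f"{self.peptide.sequence} (unmodified)"
        mods = "+".join(
            f"{self.peptide.residue(p)}{p}{m.name}" for p, m in sorted(self.located_mods)
        )
        return f"{self.peptide.sequence} {mods}"


def _backbone_mass(sequence: str) -> float:
    try:
        return _pmass.fast_mass(sequence)
    except Exception as exc:  # unknown residue letter
        raise ValueError(f"cannot compute mass of {sequence!r}: {exc}") from exc


def make_peptidoform(
    peptide: PeptideProduct,
    located_mods: Sequence[tuple[int, PTMDefinition]] = (),
) -> Peptidoform:
    """Build a peptidoform: validate mods, derivatize, compute the mass.

    At most one biological modification per position; positions are absolute
    mature coordinates inside the peptide span.  The monoisotopic mass is
    backbone + water + biological deltas + one propionyl per derivatized site.
    """
    deriv = derivatize(peptide, located_mods)  # validates targets/duplicates
    mods = tuple(sorted(located_mods, key=lambda pm: (pm[0], pm[1].name)))
    m = _backbone_mass(peptide.sequence)
    m += sum(mod.mono_delta for _, mod in mods)
    m += PROPIONYL.mono_delta * deriv.propionyl_count
    return Peptidoform(
        peptide=peptide, located_mods=mods, derivatization=deriv, mono_mass=m
    )


def mono_mass(peptidoform: Peptidoform) -> float:
    """Monoisotopic neutral mass of a peptidoform (recomputed, not cached)."""
    return make_peptidoform(peptidoform.peptide, peptidoform.located_mods).mono_mass


def enumerate_peptidoforms(
    peptide: PeptideProduct,
    registry: Iterable[PTMDefinition] | Mapping[str, PTMDefinition],
    max_mods: int,
) -> list[Peptidoform]:
    """All placements of up to ``max_mods`` registry mods on valid residues.

    Derivatization is recomputed per placement, so a lysine stops being
    propionylated as soon as it carries anything but monomethyl.  Output
    order is deterministic: by modified positions, then modification names.
    """
    if max_mods < 0:
        raise ValueError("max_mods must be >= 0")
    mods = list(registry.values()) if isinstance(registry, Mapping) else list(registry)
    site_options: list[tuple[int, list[PTMDefinition]]] = []
    for offset, letter in enumerate(peptide.sequence):
        pos = peptide.start + offset
        valid = sorted(m for m in mods if letter in m.targets)
        if valid:
            site_options.append((pos, valid))
    forms = [make_peptidoform(peptide, ())]
    for r in range(1, max_mods + 1):
        for combo in itertools.combinations(site_options, r):
            positions = [pos for pos, _ in combo]
            for choice in itertools.product(*(opts for _, opts in combo)):
                forms.append(
                    make_peptidoform(peptide, tuple(zip(positions, choice)))
                )
    forms.sort(
        key=lambda f: (
            tuple(p for p, _ in f.located_mods),
            tuple(m.name for _, m in f.located_mods),
        )
    )
    return forms


@dataclass(frozen=True)
class CandidateMatch:
    """One (feature, peptidoform) pair whose masses agree within tolerance."""

    feature_id: str
    peptidoform: Peptidoform
    ppm_error: float
    ptm_combination: tuple[str, ...]


def match_features(
    features: Sequence[tuple[str, float]],
    peptidoforms: Sequence[Peptidoform],
    tol_ppm: float,
) -> list[CandidateMatch]:
    """MS1 matching: every candidate within a symmetric ppm window.

    ``features`` are (id, neutral monoisotopic mass) pairs — charge handling
    (decharging) is the caller's concern.  The error is signed,
    ``1e6 * (obs - theo) / theo``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    order = sorted(range(len(peptidoforms)), key=lambda i: peptidoforms[i].mono_mass)
    theo = [peptidoforms[i].mono_mass for i in order]
    out: list[CandidateMatch] = []
    for fid, obs in features:
        lo = bisect.bisect_left(theo, obs / (1 + tol_ppm * 1e-6))
        hi = bisect.bisect_right(theo, obs / (1 - tol_ppm * 1e-6))
        for k in range(lo, hi):
            pf = peptidoforms[order[k]]
            ppm = 1e6 * (obs - pf.mono_mass) / pf.mono_mass
            if abs(ppm) <= tol_ppm:
                out.append(
                    CandidateMatch(
                        feature_id=fid,
                        peptidoform=pf,
                        ppm_error=ppm,
                        ptm_combination=pf.mod_names,
                    )
                )
    return out


@dataclass(frozen=True)
class PTMSetSelection:
    """Ordered variable-modification sets with coverage bookkeeping."""

    rounds: tuple[frozenset[str], ...]
    covered_per_round: tuple[int, ...]
    total_candidates: int

    @property
    def comprehensiveness(self) -> float:
        """Fraction of all candidates explained by the selected sets."""
        if self.total_candidates == 0:
            return 1.0
        return sum(self.covered_per_round) / self.total_candidates

    @property
    def comprehensiveness_by_round(self) -> tuple[float, ...]:
        if self.total_candidates == 0:
            return tuple(1.0 for _ in self.rounds)
        acc, out = 0, []
        for c in self.covered_per_round:
            acc += c
            out.append(acc / self.total_candidates)
        return tuple(out)


def select_ptm_sets(
    candidates: Sequence[CandidateMatch],
    set_size: int,
    n_rounds: int,
) -> PTMSetSelection:
    """Greedy sequential choice of variable-modification sets.

    Each round picks the PTM-name set of size <= ``set_size`` covering the
    most not-yet-covered candidates (a candidate is covered when its
    combination's name set is a subset of the chosen set), removes them, and
    repeats.  Ties prefer the smaller set, then lexicographic order.  Greedy
    is exact for a single round and the usual (1 - 1/e) heuristic beyond.
    """
    if set_size < 1 or n_rounds < 1:
        raise ValueError("set_size and n_rounds must be >= 1")
    total = len(candidates)
    if total == 0:
        logger.warning("select_ptm_sets: empty candidate list, vacuous selection")
        return PTMSetSelection(rounds=(), covered_per_round=(), total_candidates=0)

    remaining: dict[frozenset[str], int] = {}
    for c in candidates:
        names = frozenset(c.ptm_combination)
        remaining[names] = remaining.get(names, 0) + 1

    all_names = sorted(set().union(*remaining.keys())) if remaining else []
    rounds: list[frozenset[str]] = []
    covered: list[int] = []
    for _ in range(n_rounds):
        if not remaining:
            break
        best: tuple[int, int, tuple[str, ...]] | None = None  # (-count, size, names)
        for r in range(0, min(set_size, len(all_names)) + 1):
            for combo in itertools.combinations(all_names, r):
                cset = frozenset(combo)
                count = sum(n for names, n in remaining.items() if names <= cset)
                key = (-count, r, combo)
                if best is None or key < best:
                    best = key
        assert best is not None
        count, chosen = -best[0], frozenset(best[2])
        if count == 0:
            break
        rounds.append(chosen)
        covered.append(count)
        remaining = {names: n for names, n in remaining.items() if not names <= chosen}
    return PTMSetSelection(
        rounds=tuple(rounds),
        covered_per_round=tuple(covered),
        total_candidates=total,
    )


@dataclass(frozen=True)
class AnnotationRecord:
    """One exported search annotation for a feature."""

    feature_id: str
    candidate: str
    n_msms_support: int
    curated: bool
    biologically_modified: bool
    score_above_threshold: bool

    def __post_init__(self) -> None:
        if self.n_msms_support < 0:
            raise ValueError("n_msms_support must be >= 0")


def classify_annotations(records: Sequence[AnnotationRecord]) -> str:
    """Classify one feature's annotations by curation, support and ambiguity.

    Classes: ``unannotated`` (no records), ``non_curated`` (no curated
    above-threshold candidate), ``ambiguous`` (more than one distinct curated
    candidate above threshold), ``curated_reproducible`` (single curated
    candidate seen on more than one MSMS spectrum), else
    ``curated_single_support``.
    """
    if not records:
        return "unannotated"
    fids = {r.feature_id for r in records}
    if len(fids) > 1:
        raise ValueError(f"records span multiple features: {sorted(fids)}")
    curated = [r for r in records if r.curated and r.score_above_threshold]
    if not curated:
        return "non_curated"
    distinct = {r.candidate for r in curated}
    if len(distinct) > 1:
        return "ambiguous"
    support = max(r.n_msms_support for r in curated)
    return "curated_reproducible" if support > 1 else "curated_single_support"
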