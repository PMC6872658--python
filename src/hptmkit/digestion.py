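"""In-silico propionylation / ArgC digestion model.

Propionic-anhydride derivatization converts every unmodified or monomethylated
lysine epsilon-amine (and each peptide N-terminus) to its propionyl amide.
Because propionylated lysine is no longer a tryptic substrate, trypsin on a
propionylated histone behaves as ArgC: cleavage only C-terminal of arginine.
Aspecific over-propionylation of S/T/Y hydroxyls is chemically reversed, so
those residues carry no propionyl in the modelled end state.

The module also enumerates "clipped" products: histone tails truncated in
vivo by proteolysis, observable as peptides whose N-terminus is not an
enzymatic boundary.  Clipping at residue ``c`` is modelled as cleavage
C-terminal of ``c`` (the clipped peptide starts at ``c + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Protocol, Sequence

from .sequences import HistoneVariant, VariantGroup

__all__ = [
    "NTermKind",
    "PeptideProduct",
    "DerivatizationState",
    "DEFAULT_MAX_MISSED_CLEAVAGES",
    "DEFAULT_MIN_LENGTH",
    "DEFAULT_MAX_LENGTH",
    "digest",
    "derivatize",
    "enumerate_clipped_products",
]

# Search-style defaults: one missed cleavage, and a 4-30 residue window for
# the observable peptide universe (configurable at every call site).
DEFAULT_MAX_MISSED_CLEAVAGES = 1
DEFAULT_MIN_LENGTH = 4
DEFAULT_MAX_LENGTH = 30

#: lysine modifications that leave the epsilon-amine free for propionylation
_PROPIONYLATABLE_K_MODS = frozenset({"me"})


class NTermKind(str, Enum):
    ENZYMATIC = "enzymatic"
    PROTEIN_N_TERM = "protein_n_term"
    CLIPPED = "clipped"


class _ModLike(Protocol):
    name: str
    targets: frozenset[str]


@dataclass(frozen=True)
class PeptideProduct:
    """One digestion product on mature coordinates (1-based inclusive span)."""

    variant_group: VariantGroup
    start: int
    end: int
    sequence: str
    n_term_kind: NTermKind
    missed_cleavages: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match span")
        internal_r = self.sequence[:-1].count("R")
        if internal_r != self.missed_cleavages:
            raise ValueError(
                f"missed_cleavages={self.missed_cleavages} but sequence has "
                f"{internal_r} internal arginines"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def residue(self, position: int) -> str:
        """Residue letter at an absolute mature position within the span."""
        if not self.start <= position <= self.end:
            raise IndexError(f"position {position} outside span {self.span}")
        return self.sequence[position - self.start]

    def positions_of(self, letter: str) -> list[int]:
        return [self.start + i for i, aa in enumerate(self.sequence) if aa == letter]


@dataclass(frozen=True)
class DerivatizationState:
    """Propionylation end state of one peptide.

    ``propionylated_lysines`` holds absolute positions of K residues carrying
    a propionyl group (free or monomethylated lysines).  ``reversal_applied``
    records that aspecific S/T/Y propionylation was reversed, so hydroxyl
    residues never appear here.
    """

    n_term_propionyl: bool
    propionylated_lysines: frozenset[int]
    reversal_applied: bool = True

    @property
    def propionyl_count(self) -> int:
        return int(self.n_term_propionyl) + len(self.propionylated_lysines)


def _singleton_group(variant: HistoneVariant) -> VariantGroup:
    return VariantGroup.build([variant.name], variant.family)


def _cleavage_boundaries(sequence: str) -> list[int]:
    """0-based boundary offsets: start of sequence, after each R, end."""
    bounds = [0]
    bounds.extend(i + 1 for i, aa in enumerate(sequence) if aa == "R")
    if bounds[-1] != len(sequence):
        bounds.append(len(sequence))
    return bounds


def digest(
    variant: HistoneVariant,
    max_missed_cleavages: int = DEFAULT_MAX_MISSED_CLEAVAGES,
    min_length: int = 1,
    max_length: int | None = None,
) -> list[PeptideProduct]:
    """ArgC digestion of one variant: cleave after every arginine.

    Zero-missed-cleavage products tile the full sequence; products with up to
    ``max_missed_cleavages`` retained internal R are added on top.  The length
    window is applied last.
    """
    seq = variant.sequence
    if not seq:
        raise ValueError(f"variant {variant.name} has an empty sequence")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    if min_length < 1 or (max_length is not None and max_length < min_length):
        raise ValueError("need 1 <= min_length <= max_length")
    group = _singleton_group(variant)
    bounds = _cleavage_boundaries(seq)
    products: list[PeptideProduct] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(bounds))):
            lo, hi = bounds[i], bounds[j]
            sub = seq[lo:hi]
            if not min_length <= len(sub) <= (max_length or len(seq)):
                continue
            products.append(
                PeptideProduct(
                    variant_group=group,
                    start=lo + 1,
                    end=hi,
                    sequence=sub,
                    n_term_kind=(
                        NTermKind.PROTEIN_N_TERM if lo == 0 else NTermKind.ENZYMATIC
                    ),
                    missed_cleavages=j - i - 1,
                )
            )
    return products


def derivatize(
    peptide: PeptideProduct,
    biological_mods: Sequence[tuple[int, _ModLike]] = (),
) -> DerivatizationState:
    """Propionylation state of a peptide given its located biological mods.

    Rules: the N-terminus is always propionylated; each lysine is
    propionylated unless it carries a biological modification other than
    monomethyl (monomethyl-K stacks methyl + propionyl); S/T/Y carry no
    propionyl because the aspecific over-propionylation is reversed.

    Raises
    ------
    ValueError
        If a modification is placed on a residue letter it does not target.
    """
    mods_by_pos: dict[int, str] = {}
    for pos, mod in biological_mods:
        letter = peptide.residue(pos)
        if letter not in mod.targets:
            raise ValueError(
                f"{mod.name} does not target {letter!r} (position {pos})"
            )
        if pos in mods_by_pos:
            raise ValueError(f"more than one biological mod at position {pos}")
        mods_by_pos[pos] = mod.name
    prop_k = frozenset(
        pos
        for pos in peptide.positions_of("K")
        if mods_by_pos.get(pos) is None or mods_by_pos[pos] in _PROPIONYLATABLE_K_MODS
    )
    return DerivatizationState(
        n_term_propionyl=True,
        propionylated_lysines=prop_k,
        reversal_applied=True,
    )


def enumerate_clipped_products(
    variant: HistoneVariant,
    clip_site: int,
    max_missed_cleavages: int = DEFAULT_MAX_MISSED_CLEAVAGES,
) -> list[PeptideProduct]:
    """Semi-ArgC products created by tail clipping C-terminal of ``clip_site``.

    Every product starts at ``clip_site + 1`` and ends at an enzymatic
    boundary (after an R, or the protein C-terminus), with up to
    ``max_missed_cleavages`` internal arginines.  A clip site at or beyond
    the C-terminus yields an empty list.
    """
    seq = variant.sequence
    if not 1 <= clip_site <= len(seq):
        raise ValueError(f"clip_site {clip_site} outside 1..{len(seq)}")
    if clip_site == len(seq):
        return []
    group = _singleton_group(variant)
    start0 = clip_site  # 0-based start offset of the clipped peptide
    ends = [i + 1 for i, aa in enumerate(seq) if aa == "R" and i + 1 > start0]
    if not ends or ends[-1] != len(seq):
        ends.append(len(seq))
    products = []
    for k, hi in enumerate(ends[: max_missed_cleavages + 1]):
        sub = seq[start0:hi]
        products.append(
            PeptideProduct(
                variant_group=group,
                start=clip_site + 1,
                end=hi,
                sequence=sub,
                n_term_kind=NTermKind.CLIPPED,
                missed_cleavages=k,
            )
        )
    return products
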